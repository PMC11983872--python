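"""Alpha-diversity estimators: observed, Chao1, and asymptotic Shannon.

Asymptotic (sample-size-corrected) Hill numbers of order q = 0 and q = 1:
bias-corrected Chao1 richness and the Chao–Jost asymptotic Shannon entropy
estimator, both on natural logs. These are the published default asymptotic
estimators for incidence-free abundance data and converge to the plug-in
values as sample completeness approaches one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

logger = logging.getLogger(__name__)


@dataclass
class DiversityEstimate:
    sample_id: str
    observed_richness: int
    chao1: float
    shannon_entropy: float  # asymptotic, nats
    hill_q1: float  # exp(asymptotic entropy)
    observed_shannon: float


def _clean(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero count vector")
    return x


def chao1_richness(counts) -> float:
    """Bias-corrected Chao1: S_obs + ((n−1)/n)·f1(f1−1)/(2(f2+1)).

    f1 and f2 are the numbers of taxa observed exactly once and twice and n
    the total read count. With no singletons the estimate collapses to the
    observed richness.
    """
    x = _clean(counts)
    n = x.sum()
    s_obs = x.size
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if n <= 1:
        return float(s_obs)
    return s_obs + ((n - 1.0) / n) * f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))


def observed_metrics(counts) -> tuple[int, float]:
    """Observed richness and plug-in Shannon entropy (nats)."""
    x = _clean(counts)
    p = x / x.sum()
    return int(x.size), float(-(p * np.log(p)).sum())


def asymptotic_shannon(counts) -> tuple[float, float]:
    """Chao–Jost asymptotic Shannon entropy and its Hill number exp(H).

    The estimator combines an observed-frequency part,
    Σ_{1≤X_i≤n−1} (X_i/n)(ψ(n) − ψ(X_i)), with an unseen-species correction
    driven by the singleton count f1:

        (f1/n)(1−A)^{1−n} [ −log A − Σ_{r=1}^{n−1} (1/r)(1−A)^r ],

    where A = 2f2/((n−1)f1 + 2f2) when f2 > 0, A = 2/((n−1)(f1−1) + 2) when
    f2 = 0 and f1 > 1, and A = 1 otherwise (correction vanishes). In the
    degenerate all-singletons case (f1 = n) the estimator is unstable and the
    plug-in entropy is returned with a warning.
    """
    x = _clean(counts)
    n = x.sum()
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if n <= 1:
        return 0.0, 1.0
    if f1 == n:
        logger.warning(
            "all observations are singletons; falling back to plug-in entropy"
        )
        _, h = observed_metrics(counts)
        return h, float(np.exp(h))
    # Σ_{k=X_i}^{n-1} 1/k = ψ(n) − ψ(X_i)
    obs_part = float(np.sum((x / n) * (digamma(n) - digamma(x))))
    if f1 > 0:
        if f2 > 0:
            a = 2.0 * f2 / ((n - 1.0) * f1 + 2.0 * f2)
        elif f1 > 1:
            a = 2.0 / ((n - 1.0) * (f1 - 1.0) + 2.0)
        else:
            a = 1.0
    else:
        a = 1.0
    if a < 1.0:
        r = np.arange(1, int(n))
        series = float(np.sum((1.0 / r) * (1.0 - a) ** r))
        correction = (f1 / n) * (1.0 - a) ** (1.0 - n) * (-np.log(a) - series)
    else:
        correction = 0.0
    entropy = obs_part + correction
    return float(entropy), float(np.exp(entropy))


def diversity_table(table) -> pd.DataFrame:
    """Per-sample diversity estimates for an :class:`~microturn.AsvTable`.

    Returns a DataFrame indexed by sample id with the fields of
    :class:`DiversityEstimate` as columns.
    """
    rows = []
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        rich, h_obs = observed_metrics(counts)
        h_asy, hill = asymptotic_shannon(counts)
        rows.append(
            DiversityEstimate(
                sample_id=sample,
                observed_richness=rich,
                chao1=chao1_richness(counts),
                shannon_entropy=h_asy,
                hill_q1=hill,
                observed_shannon=h_obs,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("sample_id")
    return df
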