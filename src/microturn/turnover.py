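"""Within-individual microbiota turnover analysis.

Turnover is quantified as the dissimilarity between repeat samples of the
same animal as a function of the time elapsed between them. Two competing
mean models are fitted to the (Δt, distance) cloud and compared by AIC:

* a (log-)linear model, d(t) = β0 + β1·t (or β1·log t) — turnover keeps
  rising over the observed window;
* a quadratic-plateau model — turnover rises as a + b·t + c·t² (c < 0) up to
  the vertex t* = −b/(2c) and is flat at a − b²/(4c) beyond it, i.e.
  community composition decorrelates and then saturates. The piecewise curve
  joins at the vertex, so it is continuous with continuous slope by
  construction; t* is the "critical point of inflexion" marking saturation.

The module also decomposes communities by when each taxon was first detected
(origin tracking), measures start-to-end retention, finds persistent taxa
(detected in every sample of every listed animal), and computes shared-ASV
fractions (the complement of binary Jaccard distance).

All within-individual pairs enter the fits, not only consecutive ones, and
pairs are treated as independent observations; the resulting
pseudo-replication is a property of the analysis design, not corrected here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .asv_table import AsvTable, ValidationError, to_relative_abundance
from .distances import DistanceMatrix

_AIC_K = {"linear": 3, "plateau": 4}  # coefficients + error variance


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian-likelihood AIC up to an additive constant shared across models
    return n * float(np.log(rss / n)) + 2 * k


def _data_hash(t: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.round(np.asarray(t, float), 9).tobytes())
    h.update(np.round(np.asarray(y, float), 9).tobytes())
    return h.hexdigest()[:16]


# -- pair extraction --------------------------------------------------------


def within_individual_pairs(
    d: DistanceMatrix, metadata: pd.DataFrame, group_col: str | None = None
) -> pd.DataFrame:
    """All unordered within-individual sample pairs with their Δt.

    Returns a DataFrame with columns ``animal_id, sample_a, sample_b,
    delta_days, distance`` (plus ``group_col`` copied through if given, e.g.
    a cage-density stratum). Individuals with a single sample contribute no
    pairs; a sample without a recorded day is an error.
    """
    rows = []
    labels = set(d.labels)
    meta = metadata.loc[[s for s in metadata.index if s in labels]]
    missing_day = [s for s in meta.index if pd.isna(meta.loc[s, "day"])]
    if missing_day:
        raise ValidationError(f"samples with no collection day: {missing_day}")
    for animal, sub in meta.groupby("animal_id", sort=True):
        samples = list(sub.index)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = samples[i], samples[j]
                row = {
                    "animal_id": animal,
                    "sample_a": a,
                    "sample_b": b,
                    "delta_days": abs(float(sub.loc[a, "day"]) - float(sub.loc[b, "day"])),
                    "distance": d[a, b],
                }
                if group_col is not None:
                    row[group_col] = sub.loc[a, group_col]
                rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["animal_id", "sample_a", "sample_b", "delta_days", "distance"]
        + ([group_col] if group_col else []),
    )


# -- model fits -------------------------------------------------------------


@dataclass
class LinearFit:
    intercept: float
    slope: float
    r2: float
    aic: float
    rss: float
    n: int
    time_scale: str = "linear"
    model: str = "linear"
    data_hash: str = ""


@dataclass
class PlateauFit:
    a: float
    b: float
    c: float
    t_crit: float
    plateau_value: float
    r2: float
    aic: float
    rss: float
    n: int
    converged: bool = True
    t_crit_outside_range: bool = False
    model: str = "plateau"
    data_hash: str = ""


def _extract_ty(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        t = pairs["delta_days"].to_numpy(float)
        y = pairs["distance"].to_numpy(float)
    else:
        t, y = (np.asarray(v, float) for v in pairs)
    return t, y


def fit_linear_turnover(pairs, time_scale: str = "linear") -> LinearFit:
    """Ordinary least squares of distance on Δt (or log Δt)."""
    t, y = _extract_ty(pairs)
    n = t.size
    if n < 3:
        raise ValidationError("need at least 3 pairs for a linear fit")
    if time_scale == "log":
        if (t <= 0).any():
            raise ValidationError("log time scale requires all delta_days > 0")
        x = np.log(t)
    elif time_scale == "linear":
        x = t
    else:
        raise ValueError("time_scale must be 'linear' or 'log'")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate design: all time intervals equal")
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LinearFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        r2=max(r2, 0.0),
        aic=_aic(max(rss, 1e-300), n, _AIC_K["linear"]),
        rss=rss,
        n=n,
        time_scale=time_scale,
        data_hash=_data_hash(t, y),
    )


def plateau_curve(t, a: float, b: float, c: float) -> np.ndarray:
    """Quadratic-plateau mean curve joined at the vertex t* = −b/(2c)."""
    t = np.asarray(t, float)
    t_crit = -b / (2.0 * c)
    return np.where(t <= t_crit, a + b * t + c * t * t, a - b * b / (4.0 * c))


def fit_quadratic_plateau(pairs) -> PlateauFit:
    """Nonlinear least-squares fit of the quadratic-plateau turnover model.

    Initialised from an unconstrained quadratic OLS fit and refined by
    bounded nonlinear least squares with c < 0 (and b ≥ 0, so that the
    vertex lies at positive Δt) enforced. If the fitted vertex falls outside
    the observed Δt range the result is flagged, not rejected — on truly
    linear data the vertex migrates to the upper boundary and AIC prefers
    the linear model.
    """
    t, y = _extract_ty(pairs)
    n = t.size
    if n < 5:
        raise ValidationError("need at least 5 pairs for a plateau fit")
    if np.unique(t).size < 3:
        raise ValidationError("degenerate design: need ≥3 distinct intervals")

    # initialisation: plain quadratic OLS
    X = np.column_stack([np.ones(n), t, t * t])
    (a0, b0, c0), *_ = np.linalg.lstsq(X, y, rcond=None)
    t_max = float(t.max())
    if not (c0 < 0):
        c0 = -1e-4 / max(t_max, 1.0)
    if not (b0 > 0):
        b0 = max((y.max() - y.min()) / max(t_max, 1.0), 1e-6)

    def resid(theta):
        return plateau_curve(t, *theta) - y

    eps = 1e-12
    sol = least_squares(
        resid,
        x0=[float(a0), float(b0), float(max(c0, -1e6))],
        bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, -eps]),
        method="trf",
    )
    if not sol.success:
        raise ValidationError(
            f"plateau fit failed to converge: {sol.message}; "
            f"init=(a={a0:.4g}, b={b0:.4g}, c={c0:.4g})"
        )
    a, b, c = (float(v) for v in sol.x)
    rss = float(sol.fun @ sol.fun)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    t_crit = -b / (2.0 * c)
    return PlateauFit(
        a=a,
        b=b,
        c=c,
        t_crit=t_crit,
        plateau_value=a - b * b / (4.0 * c),
        r2=max(r2, 0.0),
        aic=_aic(max(rss, 1e-300), n, _AIC_K["plateau"]),
        rss=rss,
        n=n,
        converged=bool(sol.success),
        t_crit_outside_range=not (t.min() < t_crit < t.max()),
        data_hash=_data_hash(t, y),
    )


def select_turnover_model(fits) -> tuple[object, pd.DataFrame]:
    """Pick the fit with minimal AIC and tabulate ΔAIC against it.

    All fits must come from the same (Δt, distance) observations; fits on
    different data are rejected.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValidationError("need at least two fits to compare")
    hashes = {f.data_hash for f in fits}
    if len(hashes) != 1:
        raise ValidationError("fits were computed on different data")
    best = min(fits, key=lambda f: f.aic)
    rows = [
        {
            "model": f.model + (f":" + f.time_scale if f.model == "linear" else ""),
            "aic": f.aic,
            "delta_aic": f.aic - best.aic,
            "r2": f.r2,
            "n": f.n,
        }
        for f in fits
    ]
    return best, pd.DataFrame(rows)


def simulate_plateau_pairs(
    t_crit: float,
    plateau: float,
    n: int,
    sigma: float,
    seed: int,
    t_max: float | None = None,
    baseline: float = 0.0,
    linear: bool = False,
) -> pd.DataFrame:
    """Draw (Δt, distance) pairs from a known turnover curve plus noise.

    The mean curve is the quadratic plateau through (0, ``baseline``) with
    vertex at (``t_crit``, ``plateau``); with ``linear=True`` a straight line
    of the same endpoints over [0, t_max] is used instead. Δt values are
    uniform on [0, t_max] (default 3·t_crit) and Gaussian noise of scale
    ``sigma`` is added. Used for parameter-recovery and model-selection
    experiments.
    """
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 3.0 * t_crit
    t = rng.uniform(0.0, t_max, size=n)
    rise = plateau - baseline
    if linear:
        mean = baseline + rise * t / t_max
    else:
        # vertex form: a=baseline, b=2·rise/t*, c=−rise/t*²
        b = 2.0 * rise / t_crit
        c = -rise / (t_crit**2)
        mean = plateau_curve(t, baseline, b, c)
    y = mean + rng.normal(0.0, sigma, size=n)
    return pd.DataFrame({"delta_days": t, "distance": y})


# -- origin tracking, retention, persistence --------------------------------


@dataclass
class OriginTrack:
    animal_id: str
    timepoints: list[float]
    #: DataFrame indexed by (day, origin_day) with asv_count_fraction and
    #: relabund_fraction columns.
    fractions: pd.DataFrame = field(repr=False, default=None)


def _animal_samples_by_day(table: AsvTable, animal_id: str) -> list[tuple[float, str]]:
    meta = table.metadata
    sub = meta[meta["animal_id"] == animal_id]
    if sub.empty:
        raise ValidationError(f"no samples for animal {animal_id!r}")
    days = sub["day"].astype(float)
    if days.duplicated().any():
        dup = sorted(days[days.duplicated()].unique().tolist())
        raise ValidationError(f"animal {animal_id!r} has duplicate days: {dup}")
    return sorted(zip(days, sub.index))


def track_asv_origins(table: AsvTable, animal_id: str) -> OriginTrack:
    """Decompose each timepoint's community by first-detection timepoint.

    Detection is count > 0 with no abundance threshold. For every timepoint
    the detected ASVs are binned by the day they were first seen in this
    animal; both the fraction of detected ASVs and the summed relative
    abundance per origin bin are reported, each summing to one per timepoint.
    """
    ordered = _animal_samples_by_day(table, animal_id)
    if len(ordered) < 2:
        raise ValidationError(f"animal {animal_id!r} has fewer than 2 timepoints")
    rel = to_relative_abundance(table.subset_samples([s for _, s in ordered]))
    first_seen: dict[str, float] = {}
    rows = []
    for day, sample in ordered:
        detected = table.counts[sample] > 0
        asvs = table.counts.index[detected]
        for asv in asvs:
            first_seen.setdefault(asv, day)
        n_det = len(asvs)
        ra = rel.values[sample]
        by_origin: dict[float, list] = {}
        for asv in asvs:
            by_origin.setdefault(first_seen[asv], []).append(asv)
        total_ra = float(ra[list(asvs)].sum())
        for origin_day in sorted(by_origin):
            members = by_origin[origin_day]
            rows.append(
                {
                    "day": day,
                    "origin_day": origin_day,
                    "asv_count_fraction": len(members) / n_det,
                    "relabund_fraction": float(ra[members].sum()) / total_ra,
                }
            )
    frame = pd.DataFrame(rows).set_index(["day", "origin_day"])
    return OriginTrack(
        animal_id=animal_id, timepoints=[d for d, _ in ordered], fractions=frame
    )


def retention_summary(table: AsvTable, animal_id: str) -> tuple[float, float]:
    """Start-to-end retention of an animal's community.

    Returns (asv_retention, abundance_retention): the fraction of first-
    timepoint ASVs still detected at the last timepoint, and the share of
    the last timepoint's total relative abundance carried by ASVs already
    present at the first.
    """
    ordered = _animal_samples_by_day(table, animal_id)
    if len(ordered) < 2:
        raise ValidationError(f"animal {animal_id!r} has fewer than 2 timepoints")
    first_sample, last_sample = ordered[0][1], ordered[-1][1]
    first = set(table.counts.index[table.counts[first_sample] > 0])
    last = set(table.counts.index[table.counts[last_sample] > 0])
    if not first:
        raise ValidationError(f"first sample of {animal_id!r} is empty")
    asv_retention = len(first & last) / len(first)
    rel = to_relative_abundance(table.subset_samples([last_sample]))
    ra_last = rel.values[last_sample]
    abundance_retention = float(ra_last[list(first & last)].sum())
    return asv_retention, abundance_retention


def persistent_asvs(
    table: AsvTable,
    animal_ids,
    reference_samples=None,
    k: int | None = None,
) -> dict:
    """Taxa detected in every sample of every listed animal.

    Returns a dict with the persistent ASV set, the per-animal combined
    relative abundance of the set (averaged over that animal's timepoints),
    and — when ``reference_samples`` is given — the fraction of those
    samples containing the full set and, if ``k`` is set, containing at
    least k of its members.
    """
    animal_ids = list(animal_ids)
    if not animal_ids:
        raise ValidationError("empty animal list")
    meta = table.metadata
    persistent = set(table.asv_ids)
    all_samples: dict[str, list[str]] = {}
    for animal in animal_ids:
        samples = list(meta.index[meta["animal_id"] == animal])
        if len(samples) < 2:
            raise ValidationError(f"animal {animal!r} has fewer than 2 timepoints")
        all_samples[animal] = samples
        detected_everywhere = (table.counts[samples] > 0).all(axis=1)
        persistent &= set(table.counts.index[detected_everywhere])
    persistent_sorted = sorted(persistent)

    per_animal = {}
    for animal, samples in all_samples.items():
        rel = to_relative_abundance(table.subset_samples(samples))
        per_animal[animal] = float(
            rel.values.loc[persistent_sorted].sum(axis=0).mean()
        ) if persistent_sorted else 0.0

    result = {
        "asvs": persistent_sorted,
        "per_animal_relabund": per_animal,
    }
    if reference_samples is not None:
        ref = list(reference_samples)
        pres = table.counts[ref].loc[persistent_sorted] > 0 if persistent_sorted else None
        if pres is None or not len(ref):
            result["prevalence_full"] = 0.0
        else:
            hits = pres.sum(axis=0)
            result["prevalence_full"] = float((hits == len(persistent_sorted)).mean())
            if k is not None:
                result["prevalence_at_least_k"] = float((hits >= k).mean())
                result["k"] = k
    return result


def shared_asv_fraction(table: AsvTable, sample_a: str, sample_b: str) -> float:
    """|A∩B| / |A∪B| of two samples' presence sets (1 − binary Jaccard)."""
    a = set(table.counts.index[table.counts[sample_a] > 0])
    b = set(table.counts.index[table.counts[sample_b] > 0])
    union = a | b
    if not union:
        raise ValidationError(f"samples {sample_a!r}, {sample_b!r} share an empty union")
    return len(a & b) / len(union)
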