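"""Permutation-based hypothesis tests on beta-diversity matrices.

Pairwise dissimilarities are not independent observations, so group
comparisons of distances are made permutational: group labels are permuted
at the *sample* level (never at the pair level) and the test statistic is
recomputed under each relabelling. The add-one convention
p = (1 + #{permutation statistic at least as extreme}) / (1 + n_perm)
guarantees a valid p-value, bounded below by 1/(n_perm + 1).

Provides: the plain Mann–Whitney/Wilcoxon rank-sum test, its permutational
variant on within-group distance sets, single-factor PERMANOVA (Anderson's
pseudo-F on the squared-distance decomposition), and a permutation test of
beta dispersion (homogeneity of distances to group centroids in principal-
coordinate space, negative eigenvalues handled with signed contributions).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .asv_table import ValidationError
from .distances import DistanceMatrix


@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    method: str

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class PermanovaResult:
    f_stat: float
    r2: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    seed: int
    method: str = "permanova_one_factor"

    def to_json(self) -> dict:
        return asdict(self)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U with midrank ties.

    Exact p when min(n, m) ≤ 8 and there are no ties; otherwise the normal
    approximation with tie correction (and continuity correction). Returns
    (U of the first sample, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("empty input sample")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _u_statistic(values: np.ndarray, is_a: np.ndarray) -> float:
    """Rank-sum U of the group-A values within a pooled vector."""
    ranks = rankdata(values)
    n_a = int(is_a.sum())
    return float(ranks[is_a].sum() - n_a * (n_a + 1) / 2.0)


def _normalise_groups(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, dict):
        labels = np.array([groups[s] for s in d.labels])
    elif isinstance(groups, pd.Series):
        labels = groups.loc[list(d.labels)].to_numpy()
    else:
        labels = np.asarray(groups)
        if labels.size != len(d.labels):
            raise ValidationError("group vector length does not match matrix")
    return labels


def permutational_wilcoxon(
    d: DistanceMatrix, groups, n_perm: int = 1000, seed: int = 0
) -> PermTestResult:
    """Permutational rank-sum test of within-group distance sets.

    The observed statistic is the Mann–Whitney U comparing the within-group-A
    pairwise distances against the within-group-B ones. The null is built by
    permuting *sample* labels (keeping group sizes) and recomputing, which
    respects the dependence between pairs sharing a sample. Two-sided via
    the symmetry of U about its permutation mean.
    """
    labels = _normalise_groups(d, groups)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq}")
    counts = {g: int((labels == g).sum()) for g in uniq}
    if min(counts.values()) < 2:
        raise ValidationError("each group needs at least 2 samples")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")

    v = d.values
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    pair_d = v[iu, ju]

    def stat(lab) -> tuple[float, float]:
        in_a = lab[iu] == uniq[0]
        in_b = lab[iu] == uniq[1]
        within_a = in_a & (lab[ju] == uniq[0])
        within_b = in_b & (lab[ju] == uniq[1])
        sel = within_a | within_b
        if not sel.any() or not within_a.any() or not within_b.any():
            raise ValidationError("contrast yields an empty distance set")
        vals = pair_d[sel]
        is_a = within_a[sel]
        # centre of U's null distribution for this pair layout
        n_a, n_b = int(is_a.sum()), int((~is_a).sum())
        return _u_statistic(vals, is_a), n_a * n_b / 2.0

    u_obs, centre = stat(labels)
    t_obs = abs(u_obs - centre)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        u_p, centre_p = stat(perm)
        if abs(u_p - centre_p) >= t_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermTestResult(
        statistic=u_obs,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
        method="permutational_wilcoxon",
    )


def permanova_one_factor(
    d: DistanceMatrix, groups, n_perm: int = 1000, seed: int = 0
) -> PermanovaResult:
    """Single-factor PERMANOVA (pseudo-F on squared distances).

    SS_total = (1/N)·Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²_ij,
    SS_between = SS_total − SS_within, F = (SS_between/(a−1)) /
    (SS_within/(N−a)); significance by permuting group labels; R² =
    SS_between/SS_total.
    """
    labels = _normalise_groups(d, groups)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = {g: int((labels == g).sum()) for g in uniq}
    singletons = [g for g, c in sizes.items() if c < 2]
    if singletons:
        raise ValidationError(f"singleton group(s): {singletons}")

    v2 = d.values**2
    n = len(labels)
    a = len(uniq)
    iu, ju = np.triu_indices(n, k=1)
    d2 = v2[iu, ju]
    ss_total = d2.sum() / n

    def f_stat(lab) -> float:
        ss_within = 0.0
        for g in uniq:
            mask = (lab[iu] == g) & (lab[ju] == g)
            ss_within += d2[mask].sum() / sizes[g]
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / (a - 1)) / (ss_within / (n - a))

    f_obs = f_stat(labels)
    ss_within_obs = sum(
        v2[np.ix_(labels == g, labels == g)][np.triu_indices(sizes[g], k=1)].sum()
        / sizes[g]
        for g in uniq
    )
    r2 = (ss_total - ss_within_obs) / ss_total if ss_total > 0 else 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if f_stat(rng.permutation(labels)) >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(
        f_stat=float(f_obs),
        r2=float(r2),
        p_value=(1 + hits) / (1 + n_perm),
        df_between=a - 1,
        df_within=n - a,
        n_permutations=n_perm,
        seed=seed,
    )


def _centroid_distances(d: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    All axes are retained: positive-eigenvalue axes contribute positively to
    the squared distance, negative-eigenvalue axes negatively (the signed
    combination used by the standard beta-dispersion procedure). Negative
    squared distances are clipped at zero before the square root.
    """
    v = d.values
    n = v.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (v**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    keep = np.abs(evals) > 1e-10 * max(np.abs(evals).max(), 1.0)
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(np.abs(evals))
    signs = np.sign(evals)
    z2 = np.empty(n)
    for g in np.unique(labels):
        mask = labels == g
        centroid = coords[mask].mean(axis=0)
        diff2 = (coords[mask] - centroid) ** 2
        z2[mask] = diff2 @ signs
    return np.sqrt(np.clip(z2, 0.0, None))


def beta_dispersion_test(
    d: DistanceMatrix, groups, n_perm: int = 1000, seed: int = 0
) -> PermTestResult:
    """Permutation test of multivariate dispersion homogeneity.

    Embeds the samples by principal coordinates (keeping negative-eigenvalue
    axes with signed squared contributions), computes each sample's distance
    to its group centroid, then a one-way ANOVA F across groups on those
    distances; significance by permuting the group labels of the
    distance-to-centroid values.
    """
    labels = _normalise_groups(d, groups)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    sizes = {g: int((labels == g).sum()) for g in uniq}
    if min(sizes.values()) < 2:
        raise ValidationError("each group needs at least 2 samples")
    z = _centroid_distances(d, labels)

    def anova_f(vals, lab) -> float:
        grand = vals.mean()
        ss_between = sum(
            sizes[g] * (vals[lab == g].mean() - grand) ** 2 for g in uniq
        )
        ss_within = sum(
            ((vals[lab == g] - vals[lab == g].mean()) ** 2).sum() for g in uniq
        )
        df_b, df_w = len(uniq) - 1, len(vals) - len(uniq)
        if ss_within <= 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = anova_f(z, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if anova_f(z, rng.permutation(labels)) >= f_obs - 1e-12:
            hits += 1
    return PermTestResult(
        statistic=float(f_obs),
        p_value=(1 + hits) / (1 + n_perm),
        n_permutations=n_perm,
        seed=seed,
        method="beta_dispersion",
    )
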