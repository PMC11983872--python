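"""Pairwise beta-diversity metrics and principal coordinates analysis.

Implements binary Jaccard, Aitchison (Euclidean on CLR), and unweighted /
weighted-normalised UniFrac, all returned as a labelled symmetric
:class:`DistanceMatrix`. UniFrac is computed with a single post-order
traversal that aggregates per-branch descendant abundance for every sample
at once, so each pair costs O(#branches).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .asv_table import AsvTable, ValidationError, to_relative_abundance

METRICS = ("jaccard", "aitchison", "unifrac_unweighted", "unifrac_weighted")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels and a metric tag."""

    labels: list[str]
    values: np.ndarray
    metric: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValidationError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if (v < -1e-12).any():
            raise ValidationError("negative distances")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __getitem__(self, pair) -> float:
        a, b = pair
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, labels) -> "DistanceMatrix":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path, metric="custom") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index), df.to_numpy(), metric)


# -- metric constructors ----------------------------------------------------


def jaccard_matrix(table: AsvTable) -> DistanceMatrix:
    """Binary Jaccard distance, 1 − |A∩B|/|A∪B| on presence sets."""
    presence = table.presence().to_numpy().T  # samples × ASVs
    empty = [s for s, row in zip(table.sample_ids, presence) if not row.any()]
    if empty:
        raise ValidationError(f"samples with empty presence set: {empty}")
    d = squareform(pdist(presence, metric="jaccard"))
    return DistanceMatrix(table.sample_ids, d, "jaccard")


def aitchison_matrix(clr: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed sample columns."""
    d = squareform(pdist(clr.to_numpy().T, metric="euclidean"))
    return DistanceMatrix(list(clr.columns), d, "aitchison")


def _branch_table(table: AsvTable, tree: TreeNode):
    """Per-branch lengths and per-branch, per-sample descendant abundance.

    Returns (lengths, fractions) where fractions[b, s] is the relative
    abundance of sample s descending through branch b. One post-order pass;
    tree leaves absent from the table contribute zero abundance.
    """
    missing = set(table.asv_ids) - {leaf.name for leaf in tree.tips()}
    if missing:
        raise ValidationError(f"ASVs missing from tree: {sorted(missing)}")
    rel = to_relative_abundance(table).values
    n_samples = rel.shape[1]
    row_of = {asv: i for i, asv in enumerate(table.asv_ids)}
    rel_np = rel.to_numpy()

    lengths = []
    fractions = []
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = row_of.get(node.name)
            vec = rel_np[i] if i is not None else np.zeros(n_samples)
        else:
            vec = np.zeros(n_samples)
            for child in node.children:
                vec = vec + partial.pop(id(child))
        partial[id(node)] = vec
        if node.parent is not None:  # the root has no branch above it
            lengths.append(node.length if node.length is not None else 0.0)
            fractions.append(vec)
    return np.asarray(lengths, dtype=float), np.asarray(fractions)


def unifrac(table: AsvTable, tree: TreeNode, weighted: bool = False) -> DistanceMatrix:
    """UniFrac distances over a rooted phylogeny.

    unweighted: unique branch length / total branch length over the union of
    the two samples' branch sets. weighted (normalised):
    Σ l·|p_A − p_B| / Σ l·(p_A + p_B).
    """
    lengths, fractions = _branch_table(table, tree)
    n = len(table.sample_ids)
    d = np.zeros((n, n))
    presence = fractions > 0
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                pa, pb = fractions[:, i], fractions[:, j]
                denom = float(np.sum(lengths * (pa + pb)))
                num = float(np.sum(lengths * np.abs(pa - pb)))
            else:
                a, b = presence[:, i], presence[:, j]
                denom = float(np.sum(lengths[a | b]))
                num = float(np.sum(lengths[a ^ b]))
            d[i, j] = d[j, i] = num / denom if denom > 0 else 0.0
    tag = "unifrac_weighted" if weighted else "unifrac_unweighted"
    return DistanceMatrix(table.sample_ids, d, tag)


# -- ordination -------------------------------------------------------------


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples × retained (positive-eigenvalue) axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives included)
    labels: list[str] = field(default_factory=list)


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Classical scaling (principal coordinates analysis).

    The doubly centred −½·d² matrix is eigendecomposed; axes with positive
    eigenvalues are returned scaled by the square root of their eigenvalue,
    in decreasing order. Negative eigenvalues are reported in
    ``eigenvalues`` but their axes are dropped (no Lingoes/Cailliez
    correction).
    """
    v = d.values
    n = v.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (v**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * max(evals.max(), 0.0))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.labels, columns=cols),
        eigenvalues=evals,
        labels=list(d.labels),
    )
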