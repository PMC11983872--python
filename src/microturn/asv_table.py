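"""ASV count-table data model, loaders, and table-processing steps.

The central object is :class:`AsvTable`: an integer count matrix (ASVs ×
samples) bundled with per-ASV taxonomy and per-sample metadata.  Processing
follows the standard longitudinal 16S workflow: per-source read-depth
filtering, removal of dataset-wide singleton/doubleton ASVs, normalisation to
relative abundance, and the centred log-ratio (CLR) transform used for
Aitchison distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Taxonomic ranks carried for every ASV, coarse to fine.
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Required per-sample metadata columns.
METADATA_COLUMNS = ("animal_id", "group", "source", "day", "read_count")


class ValidationError(ValueError):
    """Raised when table inputs violate a structural invariant."""


@dataclass
class AsvTable:
    """Integer ASV counts with aligned taxonomy and sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, rows indexed by ASV id, columns
        by sample id.
    taxonomy
        DataFrame indexed by ASV id with columns ``domain`` … ``species``;
        missing ranks are empty strings.
    metadata
        DataFrame indexed by sample id with columns ``animal_id``, ``group``,
        ``source`` (``lab``/``wild``), ``day`` (may be NaN) and
        ``read_count``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dupes = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dupes}")
        if c.columns.has_duplicates:
            dupes = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if (c.to_numpy() < 0).any():
            raise ValidationError("negative counts present")
        missing_meta = [s for s in c.columns if s not in self.metadata.index]
        if missing_meta:
            raise ValidationError(
                f"samples missing from metadata: {missing_meta}"
            )
        missing_cols = [col for col in METADATA_COLUMNS if col not in self.metadata.columns]
        if missing_cols:
            raise ValidationError(f"metadata lacks columns: {missing_cols}")
        # taxonomy: every count ASV gets a row; absentees become all-missing
        absent = c.index.difference(self.taxonomy.index)
        if len(absent) > 0:
            filler = pd.DataFrame(
                "", index=absent, columns=list(TAXONOMY_RANKS)
            )
            self.taxonomy = pd.concat([self.taxonomy, filler])
        extra = self.taxonomy.index.difference(c.index)
        if len(extra) > 0:
            logger.warning(
                "taxonomy has %d ASVs absent from counts; ignoring them", len(extra)
            )
        self.taxonomy = self.taxonomy.reindex(c.index).fillna("")
        self.metadata = self.metadata.loc[list(c.columns)]

    # -- accessors ----------------------------------------------------------

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_depths(self) -> pd.Series:
        """Column sums (reads per sample)."""
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "AsvTable":
        sample_ids = list(sample_ids)
        return AsvTable(
            counts=self.counts[sample_ids].copy(),
            taxonomy=self.taxonomy.copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
        )

    def subset_asvs(self, asv_ids) -> "AsvTable":
        asv_ids = list(asv_ids)
        return AsvTable(
            counts=self.counts.loc[asv_ids].copy(),
            taxonomy=self.taxonomy.loc[asv_ids].copy(),
            metadata=self.metadata.copy(),
        )

    def presence(self) -> pd.DataFrame:
        """Boolean detection matrix (count > 0)."""
        return self.counts > 0


@dataclass
class RelAbundTable:
    """Per-sample relative abundances; columns sum to one."""

    values: pd.DataFrame
    source: AsvTable | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        colsums = self.values.sum(axis=0).to_numpy()
        if not np.allclose(colsums, 1.0, atol=1e-9):
            bad = self.values.columns[~np.isclose(colsums, 1.0, atol=1e-9)]
            raise ValidationError(f"columns do not sum to 1: {list(bad)}")


# -- loaders ----------------------------------------------------------------


def load_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="asv_id")
    return df.astype(np.int64)


def load_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="asv_id", dtype=str, keep_default_na=False)
    return df


def load_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return df


def load_dataset(counts_path, taxonomy_path, metadata_path) -> AsvTable:
    """Load and cross-validate the three core tables.

    Samples present in counts but absent from metadata raise
    :class:`ValidationError` naming the offenders; taxonomy rows for ASVs
    not in the count table are ignored with a logged warning; count-table
    ASVs without a taxonomy row get all-missing taxonomy.
    """
    counts = load_counts(counts_path)
    taxonomy = load_taxonomy(taxonomy_path)
    metadata = load_metadata(metadata_path)
    table = AsvTable(counts=counts, taxonomy=taxonomy, metadata=metadata)
    # read_count consistency: trust the counts, refresh metadata column
    table.metadata = table.metadata.assign(read_count=table.sample_depths.astype(int))
    return table


# -- processing steps -------------------------------------------------------


def filter_by_depth(table: AsvTable, min_depth: int) -> AsvTable:
    """Drop samples whose total read count is below ``min_depth``.

    The threshold is inclusive: a sample with exactly ``min_depth`` reads is
    retained. The ASV set is unchanged.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")
    keep = table.sample_depths >= min_depth
    if not keep.any():
        raise ValidationError(f"depth filter at {min_depth} removed every sample")
    return table.subset_samples(table.counts.columns[keep])


def filter_by_depth_per_source(table: AsvTable, min_depths: dict) -> AsvTable:
    """Apply source-specific depth thresholds (e.g. lab 7500, wild 5000)."""
    depths = table.sample_depths
    src = table.metadata["source"]
    unknown = set(src.unique()) - set(min_depths)
    if unknown:
        raise ValidationError(f"no depth threshold for source(s): {sorted(unknown)}")
    keep = [s for s in table.sample_ids if depths[s] >= min_depths[src[s]]]
    if not keep:
        raise ValidationError("depth filter removed every sample")
    return table.subset_samples(keep)


def remove_rare_asvs(table: AsvTable) -> AsvTable:
    """Remove singleton and doubleton ASVs (total count ≤ 2 across the table).

    Rarity is defined on total read count within the table passed in, so the
    caller applies this separately to each dataset partition (e.g. the wild
    and lab subsets).
    """
    totals = table.counts.sum(axis=1)
    keep = totals.index[~totals.isin([1, 2])]
    return table.subset_asvs(keep)


def to_relative_abundance(table: AsvTable) -> RelAbundTable:
    """Normalise each sample column to proportions."""
    sums = table.sample_depths
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total count: {zero}")
    values = table.counts / sums
    return RelAbundTable(values=values, source=table)


def clr_transform(rel: RelAbundTable) -> pd.DataFrame:
    """Centred log-ratio transform with a global half-minimum pseudocount.

    Zeros are replaced by half the smallest nonzero relative abundance taken
    over the whole matrix, then each column x becomes log(x) − mean(log(x)).
    No renormalisation is performed after the replacement; CLR is robust to
    the resulting small departure from unit sum. Output columns sum to zero.
    """
    v = rel.values.to_numpy(dtype=float)
    nonzero = v[v > 0]
    if nonzero.size == 0:
        raise ValidationError("relative-abundance matrix is entirely zero")
    pseudo = nonzero.min() / 2.0
    filled = np.where(v > 0, v, pseudo)
    logs = np.log(filled)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=rel.values.index, columns=rel.values.columns)
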