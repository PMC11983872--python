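"""Rule-based bacterial aerotolerance classification and community summaries.

Each ASV is placed in one of three categories — ``obligate_anaerobe``,
``aerotolerant`` (anything other than an obligate anaerobe for which
tolerance information exists, facultative anaerobes included), or
``unknown`` — by a three-tier decision rule over curated reference tables:

1. *genus* tier: the assigned genus carries a single category → use it;
2. *family* tier: only when the genus tier fails (genus unassigned or not in
   the database), and only if every genus recorded for the family shares one
   category → use that shared category;
3. *species-override* tier: a genus recorded as ``mixed`` (containing both
   obligate anaerobes and aerotolerant species) defers to an exact
   species-level override table (built upstream from full-identity,
   full-coverage 16S matches); a miss stays ``unknown``.

The database content is an input; this module ships only the schema,
loaders, and the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .asv_table import AsvTable, RelAbundTable, ValidationError

CATEGORIES = ("obligate_anaerobe", "aerotolerant", "unknown")
GENUS_CATEGORIES = CATEGORIES[:2] + ("mixed",)
TIERS = ("genus", "family", "species_override", "unresolved")


@dataclass
class AerotoleranceDB:
    """Genus, family, and species-override lookup tables.

    genus_map
        genus name → ``obligate_anaerobe`` | ``aerotolerant`` | ``mixed``.
    family_map
        family name → list of (genus name, category) records, as curated for
        the family (used only when the genus tier fails).
    species_override
        (key_type, key) → category, with key_type ``asv`` (ASV identifier)
        or ``species`` (binomial name).
    """

    genus_map: dict[str, str] = field(default_factory=dict)
    family_map: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    species_override: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, cat in self.genus_map.items():
            if cat not in GENUS_CATEGORIES:
                raise ValidationError(f"genus {g!r}: unknown category {cat!r}")
        for fam, records in self.family_map.items():
            if not records:
                raise ValidationError(f"family {fam!r} has an empty genus list")
            for g, cat in records:
                if cat not in CATEGORIES:
                    raise ValidationError(
                        f"family {fam!r} genus {g!r}: unknown category {cat!r}"
                    )
        for (ktype, key), cat in self.species_override.items():
            if ktype not in ("asv", "species"):
                raise ValidationError(f"override key type {ktype!r} invalid")
            if cat not in CATEGORIES[:2]:
                raise ValidationError(f"override {key!r}: unknown category {cat!r}")

    def family_consensus(self, family: str) -> str | None:
        """Shared category of a family's genera, or None if discordant/absent."""
        records = self.family_map.get(family)
        if not records:
            return None
        cats = {cat for _, cat in records}
        if len(cats) == 1 and (cat := cats.pop()) in CATEGORIES[:2]:
            return cat
        return None

    # -- TSV round-trip (genus, family, override tables) -------------------

    @classmethod
    def from_tsv(cls, genus_path, family_path, override_path) -> "AerotoleranceDB":
        genus_df = pd.read_csv(genus_path, sep="\t", dtype=str)
        family_df = pd.read_csv(family_path, sep="\t", dtype=str)
        over_df = pd.read_csv(override_path, sep="\t", dtype=str)
        genus_map = dict(zip(genus_df["genus"], genus_df["category"]))
        family_map: dict[str, list[tuple[str, str]]] = {}
        for row in family_df.itertuples(index=False):
            family_map.setdefault(row.family, []).append((row.genus, row.category))
        override = {
            (row.key_type, row.key): row.category
            for row in over_df.itertuples(index=False)
        }
        return cls(genus_map=genus_map, family_map=family_map, species_override=override)

    def write_tsv(self, genus_path, family_path, override_path) -> None:
        pd.DataFrame(
            sorted(self.genus_map.items()), columns=["genus", "category"]
        ).to_csv(genus_path, sep="\t", index=False)
        fam_rows = [
            (fam, g, cat)
            for fam in sorted(self.family_map)
            for g, cat in self.family_map[fam]
        ]
        pd.DataFrame(fam_rows, columns=["family", "genus", "category"]).to_csv(
            family_path, sep="\t", index=False
        )
        over_rows = [
            (ktype, key, cat)
            for (ktype, key), cat in sorted(self.species_override.items())
        ]
        pd.DataFrame(over_rows, columns=["key_type", "key", "category"]).to_csv(
            override_path, sep="\t", index=False
        )


@dataclass
class AerotoleranceCall:
    asv_id: str
    category: str  # obligate_anaerobe | aerotolerant | unknown
    tier: str  # genus | family | species_override | unresolved


def classify_asvs(table: AsvTable, db: AerotoleranceDB) -> list[AerotoleranceCall]:
    """Apply the three-tier aerotolerance rule to every ASV in the table."""
    calls = []
    for asv in table.asv_ids:
        tax = table.taxonomy.loc[asv]
        genus = str(tax.get("genus", "") or "")
        family = str(tax.get("family", "") or "")
        species = str(tax.get("species", "") or "")
        calls.append(_classify_one(asv, genus, family, species, db))
    return calls


def _classify_one(asv, genus, family, species, db) -> AerotoleranceCall:
    if genus and genus in db.genus_map:
        cat = db.genus_map[genus]
        if cat != "mixed":
            return AerotoleranceCall(asv, cat, "genus")
        # mixed genus: species-level evidence or nothing
        hit = db.species_override.get(("asv", asv))
        if hit is None and species:
            hit = db.species_override.get(("species", species))
        if hit is not None:
            return AerotoleranceCall(asv, hit, "species_override")
        return AerotoleranceCall(asv, "unknown", "unresolved")
    # genus unassigned or not in the database: family tier
    if family:
        consensus = db.family_consensus(family)
        if consensus is not None:
            return AerotoleranceCall(asv, consensus, "family")
    return AerotoleranceCall(asv, "unknown", "unresolved")


def calls_to_frame(calls: list[AerotoleranceCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls]).set_index("asv_id")


def aerotolerance_profile(
    rel: RelAbundTable, calls: list[AerotoleranceCall], basis: str = "abundance"
) -> pd.DataFrame:
    """Per-sample aerotolerance summary.

    Columns: summed relative abundance per category (``ra_aerotolerant``,
    ``ra_anaerobe``, ``ra_unknown``; they sum to one), ``prop_aero_of_known``
    (NaN when no taxa of known tolerance are present), and detected-ASV
    richness per category. With ``basis='richness'`` the proportion is
    computed on category richness instead of abundance.
    """
    if basis not in ("abundance", "richness"):
        raise ValueError("basis must be 'abundance' or 'richness'")
    call_map = {c.asv_id: c.category for c in calls}
    uncovered = [a for a in rel.values.index if a not in call_map]
    if uncovered:
        raise ValidationError(f"ASVs without aerotolerance calls: {uncovered}")
    cats = pd.Series({a: call_map[a] for a in rel.values.index})
    masks = {
        "aerotolerant": (cats == "aerotolerant").to_numpy(),
        "anaerobe": (cats == "obligate_anaerobe").to_numpy(),
        "unknown": (cats == "unknown").to_numpy(),
    }
    v = rel.values.to_numpy()
    detected = v > 0
    out = {}
    for name, mask in masks.items():
        out[f"ra_{name}"] = v[mask].sum(axis=0)
        out[f"richness_{name}"] = detected[mask].sum(axis=0)
    df = pd.DataFrame(out, index=rel.values.columns)
    if basis == "abundance":
        denom = df["ra_aerotolerant"] + df["ra_anaerobe"]
        df["prop_aero_of_known"] = np.where(
            denom > 0, df["ra_aerotolerant"] / denom.replace(0, np.nan), np.nan
        )
    else:
        denom = df["richness_aerotolerant"] + df["richness_anaerobe"]
        df["prop_aero_of_known"] = np.where(
            denom > 0, df["richness_aerotolerant"] / denom.replace(0, np.nan), np.nan
        )
    return df


def partition_by_category(
    table: AsvTable, calls: list[AerotoleranceCall], category: str
) -> AsvTable:
    """Subtable of the ASVs with a given aerotolerance category.

    The sample set is unchanged; samples left without any detected ASV are
    permitted here (downstream distance calls reject them explicitly).
    """
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}")
    keep = [c.asv_id for c in calls if c.category == category and c.asv_id in set(table.asv_ids)]
    return table.subset_asvs(keep)
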