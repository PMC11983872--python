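"""Synthetic longitudinal ASV datasets with lab-like and wild-like dynamics.

The generator emulates the statistical structure the downstream analysis
assumes, for repeat-sampled individuals from two contrasting arms:

* a **persistent core** of taxa per individual that is never replaced and
  holds a fixed share of community abundance (high in the lab-like arm, low
  in the wild-like arm, mirroring the persistent-taxon abundance means of
  ~62% vs ~9% reported for laboratory and wild house mice);
* **transient taxa**, each independently replaced between consecutive
  timepoints with an arm-specific probability, the replacement drawn from
  the metacommunity pool proportional to base abundance and excluding taxa
  currently present (keeps richness approximately stationary);
* an arm-specific **aerotolerant abundance share**, imposed by rescaling the
  latent weights of aerotolerant-labelled taxa;
* **multinomial read-depth noise** at a depth drawn uniformly from a stated
  range; a latent mode bypasses the noise for exact oracles (weights are
  emitted as deterministic integer counts at a fixed 1e9 scale so presence
  sets and relative abundances are exact to 1e-9).

Fixtures written by :func:`write_fixture_set` round-trip through the loaders
in :mod:`microturn.asv_table`.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .aerotolerance import AerotoleranceDB
from .asv_table import AsvTable, TAXONOMY_RANKS, load_dataset

ARMS = ("lab_like", "wild_like")
LATENT_SCALE = 10**9


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def _per_arm(value, name):
    """Accept either a scalar or a {arm: value} mapping."""
    if isinstance(value, dict):
        missing = [a for a in ARMS if a not in value]
        if missing:
            raise ConfigurationError(f"{name}: missing arm(s) {missing}")
        return dict(value)
    return {a: value for a in ARMS}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the conditions the analysis is designed around: five
    repeat-sampled individuals per arm at roughly weekly intervals over one
    month (days 0, 9, 15, 23, 29 for the lab-like arm), a metacommunity of
    400 taxa, per-individual cores of 35 (lab-like) / 8 (wild-like) taxa
    holding 62% / 9% of abundance, per-timepoint transient replacement
    probabilities of 0.06 / 0.45, aerotolerant abundance targets of 11.2% /
    37.7%, and read depths uniform on [5000, 60000].
    """

    n_individuals_per_arm: int = 5
    sampling_days: dict = field(
        default_factory=lambda: {
            "lab_like": (0, 9, 15, 23, 29),
            "wild_like": (0, 7, 14, 23, 31),
        }
    )
    pool_size: int = 400
    core_size: dict | int = field(
        default_factory=lambda: {"lab_like": 35, "wild_like": 8}
    )
    transient_size: dict | int = 90
    replacement_prob: dict | float = field(
        default_factory=lambda: {"lab_like": 0.06, "wild_like": 0.45}
    )
    core_share: dict | float = field(
        default_factory=lambda: {"lab_like": 0.62, "wild_like": 0.09}
    )
    aerotolerant_target: dict | float = field(
        default_factory=lambda: {"lab_like": 0.112, "wild_like": 0.377}
    )
    #: metacommunity fractions of (obligate_anaerobe, aerotolerant, unknown)
    category_fractions: tuple = (0.5, 0.3, 0.2)
    depth_range: tuple = (5000, 60000)
    seed: int = 0

    def __post_init__(self) -> None:
        self.sampling_days = _per_arm(self.sampling_days, "sampling_days")
        self.core_size = _per_arm(self.core_size, "core_size")
        self.transient_size = _per_arm(self.transient_size, "transient_size")
        self.replacement_prob = _per_arm(self.replacement_prob, "replacement_prob")
        self.core_share = _per_arm(self.core_share, "core_share")
        self.aerotolerant_target = _per_arm(
            self.aerotolerant_target, "aerotolerant_target"
        )
        self.validate()

    def validate(self) -> None:
        if self.n_individuals_per_arm < 1:
            raise ConfigurationError("n_individuals_per_arm: must be >= 1")
        if self.pool_size < 1:
            raise ConfigurationError("pool_size: must be >= 1")
        for arm in ARMS:
            if len(self.sampling_days[arm]) < 1:
                raise ConfigurationError(f"sampling_days[{arm}]: empty schedule")
            if len(set(self.sampling_days[arm])) != len(self.sampling_days[arm]):
                raise ConfigurationError(f"sampling_days[{arm}]: duplicate days")
            if self.core_size[arm] + self.transient_size[arm] > self.pool_size:
                raise ConfigurationError(
                    f"core_size[{arm}]: core + transients exceed pool_size"
                )
            if not 0.0 <= self.replacement_prob[arm] <= 1.0:
                raise ConfigurationError(f"replacement_prob[{arm}]: not in [0, 1]")
            if not 0.0 <= self.aerotolerant_target[arm] <= 1.0:
                raise ConfigurationError(f"aerotolerant_target[{arm}]: not in [0, 1]")
            if not 0.0 <= self.core_share[arm] <= 1.0:
                raise ConfigurationError(f"core_share[{arm}]: not in [0, 1]")
        fr = self.category_fractions
        if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError("category_fractions: must be 3 non-negative values summing to 1")
        dmin, dmax = self.depth_range
        if dmin < 1 or dmax < dmin:
            raise ConfigurationError("depth_range: need 1 <= min <= max")


@dataclass
class MetacommunityPool:
    """The regional taxon pool a simulated host community draws from."""

    asv_ids: list[str]
    taxonomy: pd.DataFrame
    true_aerotolerance: pd.Series  # per ASV, ground truth
    tree: TreeNode
    base_abundance: pd.Series  # strictly positive sampling weights
    db: AerotoleranceDB  # reference DB consistent with the taxonomy strata


def allocate_counts(total: int, fractions) -> list[int]:
    """Largest-remainder allocation of ``total`` items across fractions.

    Floors each share, then hands remaining items to the largest fractional
    parts (ties broken by category order). Exact fractions allocate exactly.
    """
    raw = [total * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _stable_hash(s: str) -> int:
    # process-independent (unlike built-in hash); used for cosmetic ranks only
    return zlib.crc32(s.encode())


def _random_tree(asv_ids, rng) -> TreeNode:
    """Random rooted binary tree with Exp(1) branch lengths."""
    nodes = [TreeNode(name=a, length=float(rng.exponential(1.0))) for a in asv_ids]
    if len(nodes) == 1:
        root = TreeNode(children=[nodes[0]])
        return root
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(1.0)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# classifier-tier strata, cycled within each true-tolerance category:
# genus-resolved, family-resolved, mixed genus with species override,
# mixed genus without override, discordant family (genus unassigned)
_STRATA = ("genus", "family", "mixed_hit", "mixed_miss", "family_discordant")
_STRATA_WEIGHTS = (12, 3, 2, 2, 1)


def build_metacommunity(config: SimulationConfig) -> MetacommunityPool:
    """Build the taxon pool: ids, taxonomy, tolerance labels, tree, weights.

    The taxonomy is constructed so that the aerotolerance classifier's three
    tiers are all exercised: some genera are in the reference DB with a
    fixed category, some taxa are only family-resolvable (concordant or
    discordant families), some belong to mixed genera with or without
    species-level overrides, and taxa of truly unknown tolerance carry
    genera absent from the DB.
    """
    rng = np.random.default_rng(config.seed)
    n = config.pool_size
    width = len(str(n))
    asv_ids = [f"ASV{str(i + 1).zfill(width)}" for i in range(n)]

    cat_counts = allocate_counts(n, config.category_fractions)
    categories = (
        ["obligate_anaerobe"] * cat_counts[0]
        + ["aerotolerant"] * cat_counts[1]
        + ["unknown"] * cat_counts[2]
    )

    stratum_cycle = [s for s, w in zip(_STRATA, _STRATA_WEIGHTS) for _ in range(w)]
    genus_map: dict[str, str] = {}
    family_map: dict[str, list[tuple[str, str]]] = {}
    override: dict[tuple[str, str], str] = {}
    tax_rows = []

    known_idx = {"obligate_anaerobe": 0, "aerotolerant": 0}
    unknown_idx = 0
    for asv, cat in zip(asv_ids, categories):
        if cat == "unknown":
            # genus present but absent from the DB: tier (iv) unresolved
            g_i = unknown_idx // 6
            unknown_idx += 1
            genus, family = f"Ignotus{g_i:02d}", f"Ignotaceae{g_i // 3:02d}"
            species = ""
        else:
            k = known_idx[cat]
            known_idx[cat] = k + 1
            stratum = stratum_cycle[k % len(stratum_cycle)]
            short = "anaero" if cat == "obligate_anaerobe" else "aero"
            g_i = k // 6  # ~6 ASVs per genus
            f_i = g_i // 2  # two genera per family
            genus = f"G{short}{g_i:02d}"
            family = f"F{short}{f_i:02d}"
            species = ""
            if stratum == "genus":
                genus_map.setdefault(genus, cat)
            elif stratum == "family":
                genus = ""  # genus-level taxonomy unassigned
                family = f"Conc{short}{f_i:02d}"
                family_map.setdefault(
                    family,
                    [(f"{family}_gA", cat), (f"{family}_gB", cat)],
                )
            elif stratum in ("mixed_hit", "mixed_miss"):
                genus = f"Mixtus{g_i:02d}"
                genus_map[genus] = "mixed"
                if stratum == "mixed_hit":
                    species = f"Mixtus{g_i:02d} sp{k:03d}"
                    override[("species", species)] = cat
            else:  # family_discordant
                genus = ""
                family = f"Disc{f_i:02d}"
                family_map.setdefault(
                    family,
                    [
                        (f"{family}_gA", "obligate_anaerobe"),
                        (f"{family}_gB", "aerotolerant"),
                    ],
                )
        tax_rows.append(
            {
                "asv_id": asv,
                "domain": "Bacteria",
                "phylum": f"Phylum{_stable_hash(family) % 4:d}" if family else "",
                "class": f"Class{_stable_hash(family) % 8:d}" if family else "",
                "order": f"Order{_stable_hash(family) % 12:d}" if family else "",
                "family": family,
                "genus": genus,
                "species": species,
            }
        )

    taxonomy = pd.DataFrame(tax_rows).set_index("asv_id")[list(TAXONOMY_RANKS)]
    true_tol = pd.Series(categories, index=asv_ids, name="true_aerotolerance")
    base = pd.Series(
        rng.lognormal(mean=0.0, sigma=1.2, size=n), index=asv_ids, name="base_abundance"
    )
    tree = _random_tree(asv_ids, rng)
    db = AerotoleranceDB(
        genus_map=genus_map, family_map=family_map, species_override=override
    )
    return MetacommunityPool(
        asv_ids=asv_ids,
        taxonomy=taxonomy,
        true_aerotolerance=true_tol,
        tree=tree,
        base_abundance=base,
        db=db,
    )


# -- per-individual dynamics ------------------------------------------------


@dataclass
class IndividualSeries:
    """One host's simulated time series plus generator bookkeeping."""

    individual_id: str
    arm: str
    counts: pd.DataFrame  # pool ASVs × samples, integers
    metadata: pd.DataFrame  # sample_id-indexed rows
    core: list[str]
    membership: list[set]  # latent community per timepoint
    latent_weights: pd.DataFrame  # pool ASVs × samples, proportions


def _weighted_sample(rng, candidates: np.ndarray, weights: np.ndarray, size: int):
    p = weights / weights.sum()
    return rng.choice(candidates, size=size, replace=False, p=p)


def simulate_individual_series(
    pool: MetacommunityPool,
    arm: str,
    config: SimulationConfig,
    individual_id: str,
    seed,
    latent: bool = False,
) -> IndividualSeries:
    """Simulate one individual's longitudinal samples.

    The latent community at each timepoint is a fixed core (never replaced)
    plus transient taxa, each independently replaced between consecutive
    timepoints with the arm's replacement probability; replacements are
    drawn from the pool proportional to base abundance, excluding currently
    present taxa. Observed counts are multinomial at a depth drawn uniformly
    from ``depth_range``; with ``latent=True`` the noiseless weights are
    emitted instead (scaled deterministic integers).
    """
    if arm not in ARMS:
        raise ConfigurationError(f"arm: unknown arm {arm!r}")
    rng = np.random.default_rng(seed)
    ids = np.array(pool.asv_ids)
    base = pool.base_abundance.to_numpy()
    idx_of = {a: i for i, a in enumerate(ids)}
    days = list(config.sampling_days[arm])

    n_core = config.core_size[arm]
    n_trans = config.transient_size[arm]
    core = list(_weighted_sample(rng, ids, base, n_core)) if n_core else []
    core_set = set(core)
    remaining_mask = np.array([a not in core_set for a in ids])
    transients = list(
        _weighted_sample(rng, ids[remaining_mask], base[remaining_mask], n_trans)
    ) if n_trans else []

    r = config.replacement_prob[arm]
    tau = config.aerotolerant_target[arm]
    share_core = config.core_share[arm] if (n_core and n_trans) else float(bool(n_core))
    is_aero = (pool.true_aerotolerance == "aerotolerant").to_numpy()

    membership: list[set] = []
    weight_cols = {}
    count_cols = {}
    meta_rows = []
    for k, day in enumerate(days):
        if k > 0 and transients and r > 0:
            replaced = np.flatnonzero(rng.random(len(transients)) < r)
            if replaced.size:
                present = core_set | set(transients)
                cand_mask = np.array([a not in present for a in ids])
                draws = _weighted_sample(
                    rng, ids[cand_mask], base[cand_mask], replaced.size
                )
                for slot, new in zip(replaced, draws):
                    transients[slot] = new
        present = core + transients
        membership.append(set(present))

        w = np.zeros(len(ids))
        if core:
            ci = [idx_of[a] for a in core]
            w_core = base[ci]
            w[ci] = share_core * w_core / w_core.sum()
        if transients:
            ti = [idx_of[a] for a in transients]
            w_t = base[ti]
            w[ti] = (1.0 - share_core) * w_t / w_t.sum()
        # impose the arm's aerotolerant abundance share
        s_aero = w[is_aero].sum()
        if 0.0 < s_aero < 1.0:
            w[is_aero] *= tau / s_aero
            w[~is_aero] *= (1.0 - tau) / (1.0 - s_aero)
        w = w / w.sum()

        sample_id = f"{individual_id}_d{day:g}"
        if latent:
            counts = np.rint(w * LATENT_SCALE).astype(np.int64)
        else:
            depth = int(rng.integers(config.depth_range[0], config.depth_range[1] + 1))
            counts = rng.multinomial(depth, w).astype(np.int64)
        weight_cols[sample_id] = w
        count_cols[sample_id] = counts
        meta_rows.append(
            {
                "sample_id": sample_id,
                "animal_id": individual_id,
                "group": arm,
                "source": "lab" if arm == "lab_like" else "wild",
                "day": float(day),
                "read_count": int(counts.sum()),
            }
        )
    counts_df = pd.DataFrame(count_cols, index=list(ids))
    weights_df = pd.DataFrame(weight_cols, index=list(ids))
    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    return IndividualSeries(
        individual_id=individual_id,
        arm=arm,
        counts=counts_df,
        metadata=meta_df,
        core=core,
        membership=membership,
        latent_weights=weights_df,
    )


@dataclass
class SyntheticDataset:
    """A full two-arm cohort: table, pool, and per-individual bookkeeping."""

    table: AsvTable
    pool: MetacommunityPool
    config: SimulationConfig
    series: dict[str, IndividualSeries]


def simulate_dataset(config: SimulationConfig, latent: bool = False) -> SyntheticDataset:
    """Simulate the whole cohort (both arms) from a single seed."""
    pool = build_metacommunity(config)
    series: dict[str, IndividualSeries] = {}
    frames = []
    metas = []
    for ai, arm in enumerate(ARMS):
        for ii in range(config.n_individuals_per_arm):
            animal = f"{arm}_{ii + 1:02d}"
            child_seed = np.random.SeedSequence(
                entropy=(config.seed, ai, ii)
            )
            s = simulate_individual_series(pool, arm, config, animal, child_seed, latent=latent)
            series[animal] = s
            frames.append(s.counts)
            metas.append(s.metadata)
    counts = pd.concat(frames, axis=1)
    metadata = pd.concat(metas, axis=0)
    table = AsvTable(counts=counts, taxonomy=pool.taxonomy.copy(), metadata=metadata)
    return SyntheticDataset(table=table, pool=pool, config=config, series=series)


def expected_jaccard_distance(config: SimulationConfig, arm: str, k_steps: int) -> float:
    """Expected latent Jaccard distance between timepoints k steps apart.

    Under the replacement model a transient survives k steps with
    probability (1−r)^k; treating replacement draws as novel taxa, the
    expected shared/union sizes give
    1 − (C + m·s) / (C + 2m − m·s) with s = (1−r)^k, C the core size and m
    the transient count. Re-acquisition of previously held taxa makes the
    realised distance slightly smaller; the approximation is validated by
    simulation.
    """
    c = config.core_size[arm]
    m = config.transient_size[arm]
    s = (1.0 - config.replacement_prob[arm]) ** k_steps
    denom = c + 2.0 * m - m * s
    if denom == 0:
        return 0.0
    return 1.0 - (c + m * s) / denom


# -- fixture writing --------------------------------------------------------

FIXTURE_FILES = {
    "counts": "counts.tsv",
    "taxonomy": "taxonomy.tsv",
    "metadata": "metadata.tsv",
    "tree": "tree.nwk",
    "aero_genus": "aerotolerance_genus.tsv",
    "aero_family": "aerotolerance_family.tsv",
    "aero_override": "aerotolerance_override.tsv",
}


def write_fixture_set(dataset: SyntheticDataset, directory) -> dict:
    """Write the full fixture set (tables, tree, DB) plus a JSON manifest.

    The manifest records each file with its row/column counts; tables
    round-trip through :func:`microturn.asv_table.load_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = dataset.table
    paths = {k: directory / v for k, v in FIXTURE_FILES.items()}

    t.counts.to_csv(paths["counts"], sep="\t", index_label="asv_id")
    t.taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="asv_id")
    t.metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    dataset.pool.tree.write(str(paths["tree"]), format="newick")
    dataset.pool.db.write_tsv(
        paths["aero_genus"], paths["aero_family"], paths["aero_override"]
    )

    manifest = {
        "seed": dataset.config.seed,
        "files": {
            "counts": {
                "path": FIXTURE_FILES["counts"],
                "rows": int(t.counts.shape[0]),
                "columns": int(t.counts.shape[1]),
            },
            "taxonomy": {
                "path": FIXTURE_FILES["taxonomy"],
                "rows": int(t.taxonomy.shape[0]),
                "columns": int(t.taxonomy.shape[1]),
            },
            "metadata": {
                "path": FIXTURE_FILES["metadata"],
                "rows": int(t.metadata.shape[0]),
                "columns": int(t.metadata.shape[1]),
            },
            "tree": {"path": FIXTURE_FILES["tree"], "leaves": len(dataset.pool.asv_ids)},
            "aero_genus": {
                "path": FIXTURE_FILES["aero_genus"],
                "rows": len(dataset.pool.db.genus_map),
            },
            "aero_family": {
                "path": FIXTURE_FILES["aero_family"],
                "rows": sum(len(v) for v in dataset.pool.db.family_map.values()),
            },
            "aero_override": {
                "path": FIXTURE_FILES["aero_override"],
                "rows": len(dataset.pool.db.species_override),
            },
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_fixture_set(directory) -> AsvTable:
    """Load a fixture directory written by :func:`write_fixture_set`."""
    directory = Path(directory)
    return load_dataset(
        directory / FIXTURE_FILES["counts"],
        directory / FIXTURE_FILES["taxonomy"],
        directory / FIXTURE_FILES["metadata"],
    )
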