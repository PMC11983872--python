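"""End-to-end analysis pipeline over a dataset directory.

Sequences the full workflow — load → per-source depth filter → per-source
rare-ASV removal → relative abundance / CLR → diversity estimates → distance
matrices → group comparisons → aerotolerance classification, profiles and
category-partitioned re-analysis → within-individual turnover fits and
origin tracking — writing every intermediate as TSV/JSON plus a manifest.

The pipeline is a pure function of (inputs, config, seed): manifests are
hash-identical across re-runs. The manifest deliberately omits absolute
paths and timestamps; the free-form run log (not hashed) carries those.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from . import aerotolerance as aero
from . import asv_table as at
from . import distances as dist
from . import diversity as divr
from . import perm_stats as ps
from . import turnover as to
from .synthetic import FIXTURE_FILES

logger = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = {"lab": 7500, "wild": 5000}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    counts: str
    taxonomy: str
    metadata: str
    output_dir: str
    tree: str | None = None
    aero_genus: str | None = None
    aero_family: str | None = None
    aero_override: str | None = None
    min_depth: dict = field(default_factory=lambda: dict(DEFAULT_MIN_DEPTH))
    metrics: tuple = ("jaccard", "aitchison", "unifrac_unweighted", "unifrac_weighted")
    turnover_models: tuple = ("linear", "log_linear", "plateau")
    n_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts", "taxonomy", "metadata"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"{name} file not found: {getattr(self, name)}")
        unknown = set(self.metrics) - set(dist.METRICS)
        if unknown:
            raise ConfigError(f"unsupported metrics: {sorted(unknown)}")
        if any(m.startswith("unifrac") for m in self.metrics) and not self.tree:
            raise ConfigError("unifrac metrics requested but no tree file given")
        if self.tree and not Path(self.tree).exists():
            raise ConfigError(f"tree file not found: {self.tree}")
        if any(d <= 0 for d in self.min_depth.values()):
            raise ConfigError("min_depth values must be positive")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("metrics", "turnover_models"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    @classmethod
    def from_fixture_dir(cls, directory, output_dir, **overrides) -> "PipelineConfig":
        """Point the pipeline at a fixture directory written by the simulator."""
        d = Path(directory)
        kwargs = dict(
            counts=str(d / FIXTURE_FILES["counts"]),
            taxonomy=str(d / FIXTURE_FILES["taxonomy"]),
            metadata=str(d / FIXTURE_FILES["metadata"]),
            tree=str(d / FIXTURE_FILES["tree"]),
            aero_genus=str(d / FIXTURE_FILES["aero_genus"]),
            aero_family=str(d / FIXTURE_FILES["aero_family"]),
            aero_override=str(d / FIXTURE_FILES["aero_override"]),
            output_dir=str(output_dir),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def echo(self) -> dict:
        """Config echo for the manifest: no absolute paths, just basenames."""
        d = asdict(self)
        d.pop("output_dir", None)  # run-specific, would break re-run identity
        for key in ("counts", "taxonomy", "metadata", "tree",
                    "aero_genus", "aero_family", "aero_override"):
            if d.get(key):
                d[key] = Path(d[key]).name
        d["metrics"] = list(self.metrics)
        d["turnover_models"] = list(self.turnover_models)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fit_to_dict(fit) -> dict:
    d = dict(fit.__dict__)
    d.pop("data_hash", None)
    return {k: (round(v, 10) if isinstance(v, float) else v) for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("microturn")
    root.addHandler(handler)
    logger.info("pipeline start; seed=%d; config=%s", config.seed, config.echo())

    manifest: dict = {"config": config.echo(), "seed": config.seed,
                      "stages": {}, "files": {}}
    written: list[Path] = []

    def emit_tsv(name: str, df: pd.DataFrame, index_label: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")
        written.append(path)

    def emit_json(name: str, payload) -> None:
        path = out / name
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)
        written.append(path)

    stage = "load"
    try:
        table = at.load_dataset(config.counts, config.taxonomy, config.metadata)
        tree = TreeNode.read(config.tree) if config.tree else None
        db = None
        if config.aero_genus:
            db = aero.AerotoleranceDB.from_tsv(
                config.aero_genus, config.aero_family, config.aero_override
            )
        manifest["stages"][stage] = "OK"

        stage = "depth_filter"
        table = at.filter_by_depth_per_source(table, config.min_depth)
        manifest["stages"][stage] = "OK"

        stage = "rare_asv_removal"
        sources = sorted(table.metadata["source"].unique())
        parts = []
        kept_asvs: set = set()
        for src in sources:
            sub = table.subset_samples(
                table.metadata.index[table.metadata["source"] == src]
            )
            sub = at.remove_rare_asvs(sub)
            kept_asvs |= set(sub.asv_ids)
            parts.append(sub)
        table = table.subset_asvs([a for a in table.asv_ids if a in kept_asvs])
        emit_tsv("processed_counts.tsv", table.counts, "asv_id")
        emit_tsv("processed_metadata.tsv", table.metadata, "sample_id")
        manifest["stages"][stage] = "OK"

        stage = "normalise"
        rel = at.to_relative_abundance(table)
        clr = at.clr_transform(rel)
        manifest["stages"][stage] = "OK"

        stage = "diversity"
        div = divr.diversity_table(table)
        emit_tsv("diversity.tsv", div, "sample_id")
        manifest["stages"][stage] = "OK"

        stage = "distances"
        matrices: dict[str, dist.DistanceMatrix] = {}
        for metric in config.metrics:
            if metric == "jaccard":
                m = dist.jaccard_matrix(table)
            elif metric == "aitchison":
                m = dist.aitchison_matrix(clr)
            elif metric == "unifrac_unweighted":
                m = dist.unifrac(table, tree, weighted=False)
            else:
                m = dist.unifrac(table, tree, weighted=True)
            matrices[metric] = m
            emit_tsv(f"distance_{metric}.tsv", m.to_dataframe(), "sample_id")
        manifest["stages"][stage] = "OK"

        stage = "group_tests"
        src_groups = table.metadata["source"]
        results: dict = {"alpha": {}, "beta": {}}
        wild_mask = src_groups == "wild"
        for col in ("observed_richness", "chao1", "shannon_entropy", "hill_q1"):
            u, p = ps.wilcoxon_rank_sum(
                div.loc[wild_mask[div.index], col],
                div.loc[~wild_mask[div.index], col],
            )
            results["alpha"][col] = {"U": u, "p_value": p, "method": "wilcoxon_rank_sum"}
        for metric, m in matrices.items():
            res = {
                "permanova": ps.permanova_one_factor(
                    m, src_groups, config.n_permutations, config.seed
                ).to_json(),
                "beta_dispersion": ps.beta_dispersion_test(
                    m, src_groups, config.n_permutations, config.seed
                ).to_json(),
                "permutational_wilcoxon_within_group": ps.permutational_wilcoxon(
                    m, src_groups, config.n_permutations, config.seed
                ).to_json(),
            }
            results["beta"][metric] = res
        emit_json("group_tests.json", results)
        manifest["stages"][stage] = "OK"

        stage = "aerotolerance"
        if db is not None:
            calls = aero.classify_asvs(table, db)
            emit_tsv("aerotolerance_calls.tsv", aero.calls_to_frame(calls), "asv_id")
            profile = aero.aerotolerance_profile(rel, calls)
            emit_tsv("aerotolerance_profile.tsv", profile, "sample_id")
            aero_tests: dict = {}
            for col in ("prop_aero_of_known", "ra_aerotolerant", "richness_aerotolerant",
                        "richness_anaerobe"):
                vals = profile[col].dropna()
                wild_vals = vals[table.metadata.loc[vals.index, "source"] == "wild"]
                lab_vals = vals[table.metadata.loc[vals.index, "source"] == "lab"]
                if len(wild_vals) and len(lab_vals):
                    u, p = ps.wilcoxon_rank_sum(wild_vals, lab_vals)
                    aero_tests[col] = {"U": u, "p_value": p}
            category_analysis: dict = {}
            for category in ("obligate_anaerobe", "aerotolerant"):
                sub = aero.partition_by_category(table, calls, category)
                pres = sub.presence().any(axis=0)
                empty = list(pres.index[~pres])
                keep = list(pres.index[pres])
                entry: dict = {"n_asvs": len(sub.asv_ids), "samples_dropped_empty": empty}
                if len(sub.asv_ids) and len(keep) >= 4:
                    subk = sub.subset_samples(keep)
                    m = dist.jaccard_matrix(subk)
                    grp = subk.metadata["source"]
                    if grp.nunique() == 2 and grp.value_counts().min() >= 2:
                        entry["permanova"] = ps.permanova_one_factor(
                            m, grp, config.n_permutations, config.seed
                        ).to_json()
                category_analysis[category] = entry
            emit_json(
                "aerotolerance_tests.json",
                {"rank_sum_wild_vs_lab": aero_tests, "by_category": category_analysis},
            )
        manifest["stages"][stage] = "OK" if db is not None else "SKIPPED(no DB)"

        stage = "turnover"
        jac = matrices.get("jaccard") or dist.jaccard_matrix(table)
        turnover_report: dict = {}
        for src in sources:
            samples = list(table.metadata.index[table.metadata["source"] == src])
            sub_d = jac.submatrix(samples)
            pairs = to.within_individual_pairs(sub_d, table.metadata.loc[samples])
            entry = {"n_pairs": int(len(pairs))}
            if len(pairs) >= 5 and pairs["delta_days"].nunique() >= 3:
                emit_tsv(
                    f"turnover_pairs_{src}.tsv",
                    pairs.reset_index(drop=True),
                    "pair_id",
                )
                fits = []
                if "linear" in config.turnover_models:
                    fits.append(to.fit_linear_turnover(pairs, "linear"))
                if "log_linear" in config.turnover_models and (pairs["delta_days"] > 0).all():
                    fits.append(to.fit_linear_turnover(pairs, "log"))
                if "plateau" in config.turnover_models:
                    fits.append(to.fit_quadratic_plateau(pairs))
                best, delta = to.select_turnover_model(fits)
                entry["fits"] = [_fit_to_dict(f) for f in fits]
                entry["selected_model"] = best.model + (
                    ":" + best.time_scale if best.model == "linear" else ""
                )
                entry["delta_aic"] = delta.to_dict(orient="records")

            sub_table = table.subset_samples(samples)
            meta = sub_table.metadata
            animals = [
                a for a, g in meta.groupby("animal_id")
                if len(g) >= 2 and not g["day"].duplicated().any()
            ]
            origin_rows = []
            retention = {}
            for animal in animals:
                track = to.track_asv_origins(sub_table, animal)
                frame = track.fractions.reset_index()
                frame.insert(0, "animal_id", animal)
                origin_rows.append(frame)
                retention[animal] = to.retention_summary(sub_table, animal)
            if origin_rows:
                emit_tsv(
                    f"origin_tracks_{src}.tsv",
                    pd.concat(origin_rows, ignore_index=True),
                    "row",
                )
            entry["retention"] = {
                a: {"asv_retention": r[0], "abundance_retention": r[1]}
                for a, r in retention.items()
            }
            if animals:
                pers = to.persistent_asvs(
                    sub_table, animals, reference_samples=samples,
                    k=max(1, len(animals)),
                )
                entry["persistent"] = {
                    "n_asvs": len(pers["asvs"]),
                    "asvs": pers["asvs"],
                    "per_animal_relabund": pers["per_animal_relabund"],
                    "prevalence_full": pers.get("prevalence_full"),
                }
            shared = 1.0 - pairs["distance"] if len(pairs) else pd.Series(dtype=float)
            entry["shared_asv_fraction"] = {
                "mean": float(shared.mean()) if len(shared) else None,
                "sd": float(shared.std(ddof=1)) if len(shared) > 1 else None,
            }
            turnover_report[src] = entry
        emit_json("turnover_report.json", turnover_report)
        manifest["stages"][stage] = "OK"

    except Exception as exc:
        manifest["stages"][stage] = "FAILED"
        manifest["error"] = {"stage": stage, "message": str(exc)}
        _finalise_manifest(manifest, written, out)
        root.removeHandler(handler)
        handler.close()
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    _finalise_manifest(manifest, written, out)
    logger.info("pipeline complete: %d files", len(written))
    root.removeHandler(handler)
    handler.close()
    return manifest


def _finalise_manifest(manifest: dict, written: list[Path], out: Path) -> None:
    for path in written:
        manifest["files"][path.name] = {"sha256": _sha256(path), "bytes": path.stat().st_size}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
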