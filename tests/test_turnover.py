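"""Turnover pairs, model fits with oracles, origin tracking, persistence."""

import numpy as np
import pandas as pd
import pytest

from microturn import (
    LinearFit,
    PlateauFit,
    SimulationConfig,
    ValidationError,
    fit_linear_turnover,
    fit_quadratic_plateau,
    jaccard_matrix,
    persistent_asvs,
    plateau_curve,
    retention_summary,
    select_turnover_model,
    shared_asv_fraction,
    simulate_dataset,
    simulate_plateau_pairs,
    track_asv_origins,
    within_individual_pairs,
)

from conftest import make_table


def grid_search_plateau(t, y, step=0.5):
    """Profile-likelihood oracle: scan the vertex over a grid.

    For a fixed vertex t*, the curve p + c·(min(t, t*) − t*)² is linear in
    (p, c) and solved by OLS; the grid minimiser of the residual sum of
    squares is an implementation-independent check on the nonlinear fit.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    best = (np.inf, None)
    for t_star in np.arange(step, t.max() + step, step):
        z = (np.minimum(t, t_star) - t_star) ** 2
        X = np.column_stack([np.ones_like(t), z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        if rss < best[0]:
            best = (rss, t_star)
    return best[1]


def ols_oracle(x, y):
    """Normal-equation least squares, independent of the fitting path."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


def longitudinal_table(schedule: dict[str, dict[float, dict[str, int]]]):
    """Build a table from {animal: {day: {asv: count}}}."""
    counts = {}
    metadata = {}
    for animal, days in schedule.items():
        for day, vec in days.items():
            sid = f"{animal}_d{day:g}"
            counts[sid] = vec
            metadata[sid] = {"animal_id": animal, "day": float(day)}
    return make_table(counts, metadata=metadata)


class TestWithinIndividualPairs:
    def test_three_timepoints_give_three_pairs(self):
        t = longitudinal_table({"m1": {0: {"a": 1}, 7: {"a": 1}, 14: {"a": 1}}})
        pairs = within_individual_pairs(jaccard_matrix(t), t.metadata)
        assert sorted(pairs["delta_days"]) == [7.0, 7.0, 14.0]

    def test_single_sample_contributes_nothing(self):
        t = longitudinal_table(
            {"m1": {0: {"a": 1}}, "m2": {0: {"a": 1}, 5: {"b": 1}}}
        )
        pairs = within_individual_pairs(jaccard_matrix(t), t.metadata)
        assert set(pairs["animal_id"]) == {"m2"} and len(pairs) == 1

    def test_all_pairs_combinatorics_on_cohort_fixture(self):
        # 16 animals, 99 samples in the most even 5-7 split (13x6 + 3x7):
        # all unordered within-individual pairs number sum C(c_i, 2) = 258
        sizes = [6] * 13 + [7] * 3
        assert sum(sizes) == 99
        schedule = {
            f"m{i}": {float(7 * k): {"a": 1, f"x{i}_{k}": 1} for k in range(c)}
            for i, c in enumerate(sizes)
        }
        t = longitudinal_table(schedule)
        pairs = within_individual_pairs(jaccard_matrix(t), t.metadata)
        assert len(pairs) == sum(c * (c - 1) // 2 for c in sizes) == 258

    def test_missing_day_is_named(self):
        t = longitudinal_table({"m1": {0: {"a": 1}, 7: {"a": 1}}})
        t.metadata.loc["m1_d7", "day"] = np.nan
        with pytest.raises(ValidationError, match="m1_d7"):
            within_individual_pairs(jaccard_matrix(t), t.metadata)

    def test_group_column_passthrough(self):
        t = longitudinal_table({"m1": {0: {"a": 1}, 7: {"b": 1}}})
        t.metadata["cage_density"] = 3
        pairs = within_individual_pairs(
            jaccard_matrix(t), t.metadata, group_col="cage_density"
        )
        assert (pairs["cage_density"] == 3).all()


class TestLinearFit:
    def test_exact_line(self):
        t = np.arange(0, 30, 1.0)
        y = 0.1 + 0.002 * t
        fit = fit_linear_turnover((t, y))
        assert fit.slope == pytest.approx(0.002, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        t = np.arange(5.0)
        fit = fit_linear_turnover((t, np.full(5, 0.3)))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        t = rng.uniform(0, 50, 80)
        y = 0.2 + 0.01 * t + rng.normal(0, 0.05, 80)
        fit = fit_linear_turnover((t, y))
        b0, b1 = ols_oracle(t, y)
        assert fit.intercept == pytest.approx(b0, abs=1e-9)
        assert fit.slope == pytest.approx(b1, abs=1e-9)

    def test_log_time_scale(self):
        t = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        y = 0.1 + 0.2 * np.log(t)
        fit = fit_linear_turnover((t, y), time_scale="log")
        assert fit.slope == pytest.approx(0.2, abs=1e-10)
        with pytest.raises(ValidationError):
            fit_linear_turnover((np.array([0.0, 1, 2]), np.zeros(3)), time_scale="log")

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError):
            fit_linear_turnover((np.full(5, 3.0), np.arange(5.0)))


class TestPlateauFit:
    def test_noiseless_exact_recovery(self):
        t = np.arange(0.0, 61.0, 1.0)
        y = plateau_curve(t, 0.2, 0.04, -0.001)
        fit = fit_quadratic_plateau((t, y))
        assert fit.t_crit == pytest.approx(20.0, abs=1e-6)
        assert fit.plateau_value == pytest.approx(0.6, abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_vertex_algebra(self):
        b, c = 0.04, -0.001
        assert -b / (2 * c) == pytest.approx(20.0)

    def test_noisy_recovery_matches_grid_oracle(self):
        pairs = simulate_plateau_pairs(t_crit=20, plateau=0.6, n=300, sigma=0.05, seed=5)
        fit = fit_quadratic_plateau(pairs)
        oracle = grid_search_plateau(
            pairs["delta_days"].to_numpy(), pairs["distance"].to_numpy()
        )
        assert abs(fit.t_crit - 20) / 20 < 0.25
        assert fit.t_crit == pytest.approx(oracle, abs=1.0)

    def test_linear_data_pushes_vertex_to_boundary(self):
        pairs = simulate_plateau_pairs(
            t_crit=20, plateau=0.6, n=200, sigma=0.02, seed=9, linear=True
        )
        fit = fit_quadratic_plateau(pairs)
        assert fit.t_crit > pairs["delta_days"].max() * 0.8
        assert fit.t_crit_outside_range or fit.t_crit > 48

    def test_parameter_recovery_grid(self):
        # median absolute error < 15% across true vertices and seeds
        errors = {10: [], 20: [], 40: []}
        for true_t in errors:
            for seed in range(50):
                pairs = simulate_plateau_pairs(
                    t_crit=true_t, plateau=0.6, n=300, sigma=0.05, seed=seed
                )
                fit = fit_quadratic_plateau(pairs)
                errors[true_t].append(abs(fit.t_crit - true_t) / true_t)
        for true_t, errs in errors.items():
            assert np.median(errs) < 0.15, f"t_crit={true_t}"


class TestModelSelection:
    def test_plateau_generated_selects_plateau(self):
        pairs = simulate_plateau_pairs(t_crit=20, plateau=0.6, n=300, sigma=0.05, seed=2)
        fits = [fit_linear_turnover(pairs), fit_quadratic_plateau(pairs)]
        best, delta = select_turnover_model(fits)
        assert best.model == "plateau"
        assert delta["delta_aic"].max() > 10

    def test_linear_generated_selects_linear(self):
        pairs = simulate_plateau_pairs(
            t_crit=20, plateau=0.6, n=300, sigma=0.05, seed=2, linear=True
        )
        fits = [fit_linear_turnover(pairs), fit_quadratic_plateau(pairs)]
        best, _ = select_turnover_model(fits)
        assert best.model == "linear"

    def test_identical_rss_gives_two_delta_k(self):
        lin = LinearFit(0, 0, 0.5, 0.0, rss=1.0, n=50, data_hash="h")
        lin.aic = 50 * np.log(1.0 / 50) + 2 * 3
        plat = PlateauFit(0, 1, -1, 0.5, 0.25, 0.5, 0.0, rss=1.0, n=50, data_hash="h")
        plat.aic = 50 * np.log(1.0 / 50) + 2 * 4
        best, delta = select_turnover_model([lin, plat])
        assert best is lin
        assert delta["delta_aic"].max() == pytest.approx(2.0)

    def test_fits_on_different_data_rejected(self):
        p1 = simulate_plateau_pairs(20, 0.6, 50, 0.05, seed=1)
        p2 = simulate_plateau_pairs(20, 0.6, 50, 0.05, seed=2)
        with pytest.raises(ValidationError):
            select_turnover_model(
                [fit_linear_turnover(p1), fit_quadratic_plateau(p2)]
            )


class TestOriginTracking:
    def test_two_timepoint_split(self):
        t = longitudinal_table(
            {"m1": {0: {"a": 1, "b": 1}, 1: {"a": 1, "c": 1}}}
        )
        track = track_asv_origins(t, "m1")
        at_t1 = track.fractions.loc[1.0]
        assert at_t1.loc[0.0, "asv_count_fraction"] == pytest.approx(0.5)
        assert at_t1.loc[1.0, "asv_count_fraction"] == pytest.approx(0.5)

    def test_fractions_sum_to_one(self):
        cfg = SimulationConfig(
            seed=3, n_individuals_per_arm=2, pool_size=120,
            core_size={"lab_like": 10, "wild_like": 4}, transient_size=30,
        )
        ds = simulate_dataset(cfg)
        track = track_asv_origins(ds.table, "wild_like_01")
        sums = track.fractions.groupby(level="day").sum()
        np.testing.assert_allclose(sums["asv_count_fraction"], 1.0, atol=1e-9)
        np.testing.assert_allclose(sums["relabund_fraction"], 1.0, atol=1e-9)

    def test_zero_turnover_all_origin_zero(self):
        cfg = SimulationConfig(
            seed=4, n_individuals_per_arm=1, pool_size=100,
            core_size={"lab_like": 10, "wild_like": 10}, transient_size=20,
            replacement_prob=0.0,
        )
        ds = simulate_dataset(cfg, latent=True)
        for animal in ds.series:
            track = track_asv_origins(ds.table, animal)
            origins = track.fractions.index.get_level_values("origin_day").unique()
            assert list(origins) == [0.0]

    def test_matches_hand_enumeration(self):
        sched = {
            "m": {
                0: {"a": 1, "b": 1},
                1: {"a": 1, "c": 1},
                2: {"b": 1, "c": 1, "d": 1},
                3: {"d": 2, "e": 1},
                4: {"a": 4, "e": 1},
            }
        }
        t = longitudinal_table(sched)
        track = track_asv_origins(t, "m")
        # brute-force first-detection table
        first = {"a": 0, "b": 0, "c": 1, "d": 2, "e": 3}
        for day, present in [(2.0, ["b", "c", "d"]), (4.0, ["a", "e"])]:
            sub = track.fractions.loc[day]
            for origin in sub.index:
                members = [p for p in present if first[p] == origin]
                assert sub.loc[origin, "asv_count_fraction"] == pytest.approx(
                    len(members) / len(present)
                )

    def test_duplicate_days_rejected(self):
        t = longitudinal_table({"m1": {0: {"a": 1}, 7: {"a": 1}}})
        t.metadata.loc[:, "day"] = 0.0
        with pytest.raises(ValidationError, match="duplicate"):
            track_asv_origins(t, "m1")


class TestRetention:
    def test_half_retained(self):
        t = longitudinal_table(
            {"m": {0: {"a": 1, "b": 1, "c": 1, "d": 1}, 30: {"a": 1, "b": 1, "x": 1}}}
        )
        asv_ret, _ = retention_summary(t, "m")
        assert asv_ret == pytest.approx(0.5)

    def test_identical_endpoints(self):
        t = longitudinal_table({"m": {0: {"a": 3, "b": 1}, 30: {"a": 5, "b": 2}}})
        assert retention_summary(t, "m") == (1.0, 1.0)

    def test_abundance_retention_definition(self):
        t = longitudinal_table({"m": {0: {"a": 1}, 30: {"a": 6, "x": 4}}})
        _, ab_ret = retention_summary(t, "m")
        assert ab_ret == pytest.approx(0.6)


class TestPersistence:
    def test_membership_rule(self):
        t = longitudinal_table(
            {
                "m1": {0: {"p": 1, "q": 1}, 7: {"p": 1}, 14: {"p": 1, "q": 1}},
                "m2": {0: {"p": 1, "q": 1}, 7: {"p": 2, "q": 1}, 14: {"p": 1, "q": 3}},
            }
        )
        res = persistent_asvs(t, ["m1", "m2"])
        assert res["asvs"] == ["p"]  # q absent once in m1

    def test_zero_turnover_latent_equals_initial_membership(self):
        cfg = SimulationConfig(
            seed=6, n_individuals_per_arm=2, pool_size=100,
            core_size={"lab_like": 8, "wild_like": 8}, transient_size=15,
            replacement_prob=0.0,
        )
        ds = simulate_dataset(cfg, latent=True)
        animals = [a for a in ds.series if a.startswith("lab")]
        res = persistent_asvs(ds.table.subset_samples(
            ds.table.metadata.index[ds.table.metadata["animal_id"].isin(animals)]
        ), animals)
        expected = set.intersection(*(ds.series[a].membership[0] for a in animals))
        assert set(res["asvs"]) == expected

    def test_combined_relabund(self):
        # persistent set {p, q} with constant shares 0.3 and 0.2 -> 0.5
        t = longitudinal_table(
            {
                "m": {0: {"p": 3, "q": 2, "x": 5}, 7: {"p": 30, "q": 20, "x": 50}},
                "other": {0: {"p": 1, "q": 1, "x": 1}, 7: {"q": 1, "x": 1}},
            }
        )
        res = persistent_asvs(t, ["m"])
        assert set(res["asvs"]) == {"p", "q", "x"}
        t_pq = t.subset_asvs(["p", "q", "x"])
        res_m = persistent_asvs(t_pq, ["m", "other"])
        assert set(res_m["asvs"]) == {"q", "x"}
        assert res_m["per_animal_relabund"]["m"] == pytest.approx(0.2 + 0.5)

    def test_monotone_in_animal_set(self):
        t = longitudinal_table(
            {
                "m1": {0: {"p": 1, "q": 1}, 7: {"p": 1, "q": 1}},
                "m2": {0: {"p": 1}, 7: {"p": 1, "q": 1}},
            }
        )
        only_m1 = set(persistent_asvs(t, ["m1"])["asvs"])
        both = set(persistent_asvs(t, ["m1", "m2"])["asvs"])
        assert both <= only_m1

    def test_prevalence_counts(self):
        t = longitudinal_table(
            {
                "m1": {0: {"p": 1, "q": 1}, 7: {"p": 1, "q": 1}},
                "ref": {0: {"p": 1}, 7: {"p": 1, "q": 1}},
            }
        )
        res = persistent_asvs(
            t, ["m1"], reference_samples=["ref_d0", "ref_d7"], k=1
        )
        assert res["prevalence_full"] == pytest.approx(0.5)
        assert res["prevalence_at_least_k"] == pytest.approx(1.0)

    def test_empty_animal_list_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            persistent_asvs(small_dataset.table, [])


class TestSharedFraction:
    def test_worked_example(self):
        t = make_table(
            {
                "s1": {k: 1 for k in "abcde"},
                "s2": {k: 1 for k in "cdefg"},
            }
        )
        assert shared_asv_fraction(t, "s1", "s2") == pytest.approx(3 / 7)

    def test_identity_with_jaccard(self, small_dataset):
        t = small_dataset.table
        d = jaccard_matrix(t)
        for a, b in zip(t.sample_ids[:6], t.sample_ids[6:12]):
            assert shared_asv_fraction(t, a, b) == pytest.approx(1.0 - d[a, b])

    def test_identical_and_disjoint(self):
        t = make_table({"s1": {"a": 1}, "s2": {"a": 2}, "s3": {"b": 1}})
        assert shared_asv_fraction(t, "s1", "s2") == 1.0
        assert shared_asv_fraction(t, "s1", "s3") == 0.0
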