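import numpy as np
import pandas as pd
import pytest

from twinmethyl.cohort import discordance_table
from twinmethyl.synthetic_data import (
    SimulationConfig,
    TruthSet,
    generate_cohort,
    generate_counts,
    generate_reference,
    plant_truth,
    read_study,
    simulate_study,
    write_study,
)


def small_config(**kw):
    base = dict(
        n_pairs_per_sex=4,
        n_chromosomes=2,
        chrom_length_bp=100_000,
        n_planted_dmrs=3,
        dmr_span_windows=(1, 2),
        n_latent_modules=1,
        module_size_windows=10,
        n_genes=20,
        seed=5,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_rejects_non_multiple_chrom_length(self):
        with pytest.raises(ValueError, match="multiple"):
            SimulationConfig(chrom_length_bp=1500, window_size_bp=1000)

    def test_rejects_negative_dispersion(self):
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=-0.1)

    def test_rejects_bad_module_trait_r(self):
        with pytest.raises(ValueError):
            SimulationConfig(module_trait_r=1.5)


class TestReference:
    def test_cpg_table_matches_brute_force_rescan(self, rng):
        cfg = small_config()
        ref, grid = generate_reference(cfg, np.random.default_rng(cfg.seed))
        # independent oracle: sliding scan of the written sequence
        for row in grid.sample(30, random_state=0).itertuples():
            seq = ref[row.chrom][row.start : row.end]
            scan = sum(
                1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"
            )
            assert scan == row.cpg

    def test_density_range_spans_one_to_ten_per_100bp(self):
        cfg = small_config()
        _, grid = generate_reference(cfg, np.random.default_rng(0))
        dens = 100 * grid["cpg"] / (grid["end"] - grid["start"])
        assert dens.min() == pytest.approx(1.0)
        assert dens.max() == pytest.approx(10.0)

    def test_no_cg_without_planting(self):
        # a window filled from the background alphabet alone has zero CpG
        assert "CG" not in "ACACAC" * 100


class TestCohort:
    def test_anchored_published_pair_values_present(self):
        cohort = generate_cohort(small_config(), np.random.default_rng(1))
        m = cohort[cohort["pair_id"] == "M01"]
        assert set(m["mvpa_min_week"]) == {66.0, 266.0}
        assert set(m["walkability_score"]) == {25.7, 82.0}
        assert set(m["bmi"]) == {28.4, 35.2}

    def test_full_discordance_fraction_classifies_every_pair(self):
        cfg = small_config(
            fraction_discordant_pa=1.0,
            fraction_discordant_walkability=1.0,
            fraction_discordant_bmi=1.0,
        )
        cohort = generate_cohort(cfg, np.random.default_rng(2))
        table = discordance_table(cohort)
        assert table["pa_discordant"].all()
        assert table["walkability_discordant"].all()
        assert table["bmi_discordant"].all()

    def test_fixed_seed_reproduces_trait_table(self):
        cfg = small_config()
        a = generate_cohort(cfg, np.random.default_rng(9))
        b = generate_cohort(cfg, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)


class TestTruth:
    def test_planted_dmrs_align_to_windows_and_avoid_modules(self):
        cfg = small_config(n_planted_dmrs=5, n_latent_modules=2)
        _, grid = generate_reference(cfg, np.random.default_rng(3))
        truth = plant_truth(cfg, grid, np.random.default_rng(3))
        w = cfg.window_size_bp
        assert ((truth.planted_dmrs["start"] % w) == 0).all()
        assert ((truth.planted_dmrs["end"] % w) == 0).all()
        overlap = truth.dmr_windows(grid) & set(truth.module_membership.index)
        assert not overlap

    def test_module_ids_partition_disjointly(self):
        cfg = small_config(n_latent_modules=3, module_size_windows=8)
        _, grid = generate_reference(cfg, np.random.default_rng(4))
        truth = plant_truth(cfg, grid, np.random.default_rng(4))
        assert not truth.module_membership.index.has_duplicates
        assert (
            truth.module_membership.value_counts() == 8
        ).all()


class TestCounts:
    def test_poisson_limit_variance_matches_mean(self):
        # phi=0, no pair effect, no planted structure, fixed library sizes
        cfg = small_config(
            dispersion=0.0,
            pair_effect_sd=0.0,
            lib_size_range=(1.0, 1.0),
            n_planted_dmrs=0,
            n_latent_modules=0,
            n_pairs_per_sex=16,
        )
        study = simulate_study(cfg)
        X = study.counts.counts.to_numpy(dtype=float)
        m = X.mean(axis=1)
        v = X.var(axis=1, ddof=1)
        # pooled index of dispersion ~ 1 under Poisson
        assert v.sum() / m.sum() == pytest.approx(1.0, abs=0.05)

    def test_planted_log2fc_reflected_in_arm_means(self):
        # Monte-Carlo check at high depth: mean ratio between arms ~ 2**log2fc
        cfg = small_config(
            mean_depth=200.0,
            dispersion=0.05,
            pair_effect_sd=0.0,
            n_planted_dmrs=4,
            dmr_log2fc=2.0,
            dmr_traits=("pa",),
            n_latent_modules=0,
            fraction_discordant_pa=1.0,
            n_pairs_per_sex=8,
        )
        study = simulate_study(cfg)
        table = discordance_table(study.cohort)
        low = table["pa_low"].tolist()
        high = table["pa_high"].tolist()
        wins = sorted(study.truth.dmr_windows(study.grid))
        X = study.counts.counts
        ratio = (
            X.loc[wins, high].to_numpy().mean()
            / X.loc[wins, low].to_numpy().mean()
        )
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_pair_effect_creates_within_pair_correlation(self):
        # per window, co-twin counts across pairs are correlated through the
        # shared log-normal pair baseline; mismatched pairings are not
        cfg = small_config(
            pair_effect_sd=0.6,
            n_planted_dmrs=0,
            n_latent_modules=0,
            n_pairs_per_sex=16,
            lib_size_range=(1.0, 1.0),
        )
        study = simulate_study(cfg)
        pairs = study.cohort.groupby("pair_id")["participant_id"].apply(list)
        a_ids = [p[0] for p in pairs]
        b_ids = [p[1] for p in pairs]
        A = study.counts.counts[a_ids].to_numpy(dtype=float)
        B = study.counts.counts[b_ids].to_numpy(dtype=float)
        B_mismatched = np.roll(B, 1, axis=1)

        def mean_window_cor(X, Y):
            xc = X - X.mean(axis=1, keepdims=True)
            yc = Y - Y.mean(axis=1, keepdims=True)
            num = (xc * yc).sum(axis=1)
            den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
            return float(np.mean(num / den))

        within = mean_window_cor(A, B)
        between = mean_window_cor(A, B_mismatched)
        assert within > between + 0.1

    def test_library_sizes_equal_column_sums(self, tiny_study):
        pd.testing.assert_series_equal(
            tiny_study.counts.lib_sizes,
            tiny_study.counts.counts.sum(axis=0),
            check_names=False,
        )


class TestRoundTripAndDeterminism:
    def test_write_read_round_trip(self, tmp_path):
        study = simulate_study(small_config())
        write_study(study, tmp_path)
        back = read_study(tmp_path)
        pd.testing.assert_frame_equal(back.counts.counts, study.counts.counts)
        pd.testing.assert_frame_equal(
            back.truth.planted_dmrs, study.truth.planted_dmrs
        )
        pd.testing.assert_series_equal(
            back.truth.module_membership, study.truth.module_membership
        )
        assert back.reference == study.reference
        np.testing.assert_array_equal(back.grid["cpg"], study.grid["cpg"])
        pd.testing.assert_frame_equal(
            back.cohort.reset_index(drop=True), study.cohort, check_dtype=False
        )

    def test_fixed_seed_fixes_every_output_byte(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_study(simulate_study(small_config()), d1)
        p2 = write_study(simulate_study(small_config()), d2)
        for name in p1:
            b1 = open(p1[name], "rb").read()
            b2 = open(p2[name], "rb").read()
            assert b1 == b2, f"{name} differs between identical-seed runs"

    def test_truth_json_round_trip(self, tmp_path):
        study = simulate_study(small_config())
        path = tmp_path / "truth.json"
        study.truth.to_json(path)
        back = TruthSet.from_json(path)
        pd.testing.assert_frame_equal(back.planted_dmrs, study.truth.planted_dmrs)
        pd.testing.assert_frame_equal(back.trait_links, study.truth.trait_links)
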