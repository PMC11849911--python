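import numpy as np
import pandas as pd
import pytest

from dielwl.containers import ZT_GRID
from dielwl.diel import (
    EigengeneBasis,
    build_eigengene_basis,
    drop_low_signal_accessions,
    filter_genes,
    impute_course,
    impute_missing_replicate,
    jaccard_overlap,
    normalize_counts,
    pattern_change_scores,
    permutation_calls,
    tmm_factors,
    validate_with_pointwise_tests,
)
from dielwl.synthetic import ExpressionSimDesign, gen_expression_data

from conftest import make_course, cosinor_course


def cosine_basis(phase=1.0):
    zts = np.asarray(ZT_GRID, float)
    prof = np.cos(2 * np.pi * (zts - phase) / 24.0)
    profiles = pd.DataFrame([prof], index=["E1"], columns=list(ZT_GRID))
    return EigengeneBasis(profiles, pd.Series([1], index=["E1"]))


class TestFilterGenes:
    def test_five_gene_fixture(self):
        # 2 constant genes, 1 gene with all replicate means <= 0, 2 keepers
        rows = np.array(
            [
                [3.0] * 12,                      # constant -> removed
                [0.0] * 12,                      # constant -> removed
                list(np.repeat([-1.0, -0.5, -0.2, -2.0], 3)),  # all means <= 0
                list(np.repeat([-1.0, -0.5, 0.2, -2.0], 3)),   # one mean > 0 -> kept
                list(np.repeat([5.0, 4.0, 3.0, 2.0], 3)),      # kept
            ]
        )
        ww = make_course(rows, treatment="WW")
        wl = make_course(rows, treatment="WL")
        (fww, fwl), report = filter_genes([ww, wl])
        assert list(fww.genes) == ["g4", "g5"]
        reasons = report.set_index("gene_id")["reason"]
        assert reasons["g1"] == "zero_variance"
        assert reasons["g3"] == "low_expression"

    def test_warns_when_everything_removed(self):
        ww = make_course(np.ones((2, 12)))
        wl = make_course(np.ones((2, 12)), treatment="WL")
        with pytest.warns(RuntimeWarning):
            (fww, _), _ = filter_genes([ww, wl])
        assert len(fww.genes) == 0


class TestNormalization:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {"s1": rng.integers(1, 500, 50), "s2": 0}, dtype=float
        )
        counts["s2"] = counts["s1"]
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)
        logx, _ = normalize_counts(counts)
        assert np.allclose(logx["s1"], logx["s2"])

    def test_depth_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame({"a": rng.integers(1, 500, 80)}, dtype=float)
        counts["b"] = counts["a"] * 2
        logx, _ = normalize_counts(counts)
        assert np.allclose(logx["a"], logx["b"], atol=1e-9)

    def test_tmm_matches_brute_force(self):
        # independent hand computation of the doubly trimmed weighted mean
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {
                "ref": rng.integers(5, 400, 18).astype(float),
                "obs": rng.integers(5, 400, 18).astype(float),
            }
        )
        f = tmm_factors(counts, ref_column="ref")
        n_o, n_r = counts["obs"].sum(), counts["ref"].sum()
        p_o, p_r = counts["obs"] / n_o, counts["ref"] / n_r
        m = np.log2(p_o / p_r)
        a = 0.5 * np.log2(p_o * p_r)
        w = (n_o - counts["obs"]) / (n_o * counts["obs"]) + (n_r - counts["ref"]) / (
            n_r * counts["ref"]
        )
        keep = (
            (m >= np.quantile(m, 0.3))
            & (m <= np.quantile(m, 0.7))
            & (a >= np.quantile(a, 0.05))
            & (a <= np.quantile(a, 0.95))
        )
        expected = 2 ** ((m[keep] / w[keep]).sum() / (1 / w[keep]).sum())
        ratio = f["obs"] / f["ref"]  # geometric-mean rescale cancels in the ratio
        assert ratio == pytest.approx(expected / 1.0, rel=1e-9)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError):
            tmm_factors(counts)

    def test_fpkm_like_lengths(self):
        counts = pd.DataFrame({"a": [100.0, 100.0], "b": [100.0, 100.0]})
        lengths = pd.Series([1000.0, 2000.0], index=counts.index)
        logx, _ = normalize_counts(counts, gene_lengths=lengths)
        # per-kb correction halves the second gene's value before log2
        assert 2 ** logx["a"].iloc[0] - 1 == pytest.approx(
            2 * (2 ** logx["a"].iloc[1] - 1)
        )


class TestImputation:
    def test_median_of_two(self):
        assert impute_missing_replicate([4.0, 10.0]) == 7.0
        assert impute_missing_replicate([3.0, 3.0]) == 3.0
        with pytest.raises(ValueError):
            impute_missing_replicate([1.0])

    def test_impute_course_single_dropout(self):
        vals = np.tile(np.repeat([1.0, 2.0, 3.0, 4.0], 3), (2, 1)).astype(float)
        tc = make_course(vals)
        tc.data.iloc[0, tc.data.columns.get_loc((7, 2))] = np.nan
        tc.data.iloc[0, 0] = 0.0  # make the two ZT7 replicates {2, 2}
        out, bad = impute_course(tc)
        assert bad == []
        assert out.data.loc["g1", (7, 2)] == 2.0
        assert out.imputed.loc["g1", (7, 2)]
        # downstream replicate mean equals the mean of the two real values
        assert out.replicate_mean().loc["g1", 7] == 2.0

    def test_two_missing_flags_gene_unusable(self):
        vals = np.tile(np.repeat([1.0, 2.0, 3.0, 4.0], 3), (2, 1)).astype(float)
        tc = make_course(vals)
        tc.data.loc["g2", (13, 1)] = np.nan
        tc.data.loc["g2", (13, 2)] = np.nan
        _, bad = impute_course(tc)
        assert bad == ["g2"]


class TestEigengeneBasis:
    def test_single_shared_shape_gives_one_eigengene(self):
        ww = cosinor_course([13.0] * 30, noise_sd=0.05)
        wl = cosinor_course([13.0] * 30, treatment="WL", noise_sd=0.05)
        basis = build_eigengene_basis([ww, wl], min_cluster_size=5)
        assert len(basis.profiles) == 1
        zts = np.asarray(ZT_GRID, float)
        shape = np.cos(2 * np.pi * (zts - 13.0) / 24.0)
        r = np.corrcoef(basis.profiles.iloc[0], shape)[0, 1]
        assert abs(r) > 0.95

    def test_two_planted_shapes_recovered(self):
        ww = cosinor_course([1.0] * 25 + [7.0] * 25, noise_sd=0.05)
        wl = cosinor_course([1.0] * 25 + [7.0] * 25, treatment="WL", noise_sd=0.05)
        basis = build_eigengene_basis([ww, wl], min_cluster_size=5, cut_height=0.2)
        assert len(basis.profiles) >= 2
        zts = np.asarray(ZT_GRID, float)
        for ph in (1.0, 7.0):
            target = np.cos(2 * np.pi * (zts - ph) / 24.0)
            best = max(
                abs(np.corrcoef(row, target)[0, 1])
                for _, row in basis.profiles.iterrows()
            )
            assert best > 0.9


class TestScores:
    def test_identical_treatments_score_zero(self):
        ww = cosinor_course([1, 7, 13, 19], noise_sd=0.0)
        wl = cosinor_course([1, 7, 13, 19], treatment="WL", noise_sd=0.0)
        s = pattern_change_scores(ww, wl, cosine_basis())
        assert np.allclose(s["kME"], 0.0)
        assert np.allclose(s["Med"], 0.0)

    @pytest.mark.parametrize("profile", ["per_replicate", "replicate_mean"])
    def test_noiseless_antiphase_scores_two(self, profile):
        ww = cosinor_course([1.0], noise_sd=0.0)
        wl = cosinor_course([13.0], treatment="WL", noise_sd=0.0)  # 12 h flip
        s = pattern_change_scores(ww, wl, cosine_basis(phase=1.0), profile=profile)
        assert s["kME"].iloc[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("profile", ["per_replicate", "replicate_mean"])
    def test_pure_median_shift(self, profile):
        delta = 0.8
        ww = cosinor_course([7.0] * 3, noise_sd=0.0)
        wl = cosinor_course([7.0] * 3, baseline=4.0 + delta, treatment="WL",
                            noise_sd=0.0)
        s = pattern_change_scores(ww, wl, cosine_basis(), profile=profile)
        assert np.allclose(s["Med"], delta)
        assert np.allclose(s["kME"], 0.0, atol=1e-12)

    def test_kme_invariant_to_constant_offset_med_exact(self):
        rng = np.random.default_rng(5)
        ww = cosinor_course([1, 7, 13, 19, 1], noise_sd=0.2, rng=rng)
        wl = cosinor_course([13, 1, 7, 13, 19], treatment="WL", noise_sd=0.2, rng=rng)
        base = pattern_change_scores(ww, wl, cosine_basis())
        signed = wl.data.stack([0, 1], future_stack=True).groupby("gene_id").median() - \
            ww.data.stack([0, 1], future_stack=True).groupby("gene_id").median()
        shifted = wl.copy()
        shifted.data = shifted.data + 2.5
        s = pattern_change_scores(ww, shifted, cosine_basis())
        assert np.allclose(s["kME"], base["kME"])
        assert np.allclose(s["Med"], (signed.loc[s.index] + 2.5).abs())

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        ww = cosinor_course([1, 7, 13], noise_sd=0.3, rng=rng)
        wl = cosinor_course([13, 1, 7], treatment="WL", noise_sd=0.3, rng=rng)
        s = pattern_change_scores(ww, wl, cosine_basis())
        perm = ["g3", "g1", "g2"]
        ww2 = make_course(ww.data.loc[perm].to_numpy(), genes=perm)
        wl2 = make_course(wl.data.loc[perm].to_numpy(), genes=perm, treatment="WL")
        s2 = pattern_change_scores(ww2, wl2, cosine_basis())
        assert np.allclose(s.loc[perm, "kME"], s2["kME"])

    def test_flat_profile_flagged(self):
        ww = make_course(np.ones((1, 12)) * 2.0)
        wl = make_course(np.ones((1, 12)) * 2.0, treatment="WL")
        s = pattern_change_scores(ww, wl, cosine_basis())
        assert bool(s["flat_profile"].iloc[0])
        assert s["kME"].iloc[0] == 0.0


class TestPermutationCalls:
    def test_zero_permutations_rejected(self):
        ww = cosinor_course([1, 7], noise_sd=0.1)
        wl = cosinor_course([1, 7], treatment="WL", noise_sd=0.1)
        with pytest.raises(ValueError):
            permutation_calls(ww, wl, cosine_basis(), n_perm=0)

    def test_antiphase_power_and_determinism(self):
        design = ExpressionSimDesign(
            n_ortholog_groups=100, accessions=("Ab",), responsive_fraction=0.15,
            phase_shift_menu=(12,), noise_sd=0.2, seed=7,
        )
        courses, _, truth = gen_expression_data(design)
        ww, wl = courses[("Ab", "WW")], courses[("Ab", "WL")]
        (ww, wl), _ = filter_genes([ww, wl])
        basis = build_eigengene_basis([ww, wl])
        calls = permutation_calls(ww, wl, basis, n_perm=60, seed=1)
        calls2 = permutation_calls(ww, wl, basis, n_perm=60, seed=1)
        pd.testing.assert_frame_equal(calls, calls2)
        planted = {
            r["gene_id"] for r in truth["responsive"]
            if r["accession"] == "Ab" and r["phase_shift"] != 0
        }
        called = set(calls.index[calls["called_kME"]])
        assert len(planted & called) / len(planted) >= 0.8

    def test_null_data_rarely_called(self):
        design = ExpressionSimDesign(
            n_ortholog_groups=120, accessions=("Ab",), responsive_fraction=0.0,
            seed=13,
        )
        courses, _, _ = gen_expression_data(design)
        ww, wl = courses[("Ab", "WW")], courses[("Ab", "WL")]
        basis = build_eigengene_basis([ww, wl])
        calls = permutation_calls(ww, wl, basis, n_perm=60, fdr_target=0.05, seed=2)
        frac = (calls["called_kME"] | calls["called_Med"]).mean()
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(calls))


class TestPointwiseValidation:
    def test_planted_shift_detected_null_mostly_clean(self):
        rng = np.random.default_rng(3)
        n, n_shift = 60, 20
        base = np.tile(np.repeat([4.0, 5.0, 4.0, 3.0], 3), (n, 1))
        ww = make_course(base + 0.2 * rng.standard_normal((n, 12)))
        wl_vals = base + 0.2 * rng.standard_normal((n, 12))
        wl_vals[:n_shift, 3:6] += 6 * 0.2  # 6-sd shift at ZT7
        wl = make_course(wl_vals, treatment="WL")
        res = validate_with_pointwise_tests(ww, wl, alpha=0.05)
        assert res["any_zt_significant"].iloc[:n_shift].mean() >= 0.7
        assert res["any_zt_significant"].iloc[n_shift:].mean() < 0.1

    def test_insufficient_replicates_flagged(self):
        ww = cosinor_course([1, 7], noise_sd=0.1)
        wl = cosinor_course([1, 7], treatment="WL", noise_sd=0.1)
        wl.data.loc["g1", (7, 1)] = np.nan
        wl.data.loc["g1", (7, 2)] = np.nan
        res = validate_with_pointwise_tests(ww, wl)
        assert bool(res["skipped_zt"].iloc[0])

    def test_overlap_with_median_calls_on_median_shift_simulation(self):
        design = ExpressionSimDesign(
            n_ortholog_groups=100, accessions=("Ab",), responsive_fraction=0.2,
            phase_shift_menu=(0,), median_shift=1.5, noise_sd=0.2, seed=9,
        )
        courses, _, _ = gen_expression_data(design)
        ww, wl = courses[("Ab", "WW")], courses[("Ab", "WL")]
        basis = build_eigengene_basis([ww, wl])
        calls = permutation_calls(ww, wl, basis, n_perm=60, seed=3)
        pw = validate_with_pointwise_tests(ww, wl, alpha=0.05)
        jac = jaccard_overlap(
            calls.index[calls["called_Med"]],
            pw.index[pw["any_zt_significant"]],
        )
        assert jac >= 0.7


class TestAccessionQC:
    def test_low_kme_accession_dropped(self):
        calls = {"Qu": 17, "Ze": 16, "Ab": 900}
        retained, log = drop_low_signal_accessions(calls, min_kme_genes=50)
        assert retained == ["Ab"]
        assert set(log.loc[log["dropped"], "accession"]) == {"Qu", "Ze"}

    def test_threshold_zero_keeps_everyone(self):
        retained, _ = drop_low_signal_accessions({"A": 0, "B": 5}, min_kme_genes=0)
        assert retained == ["A", "B"]
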