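"""Harmonic regression, preprocessing, circular statistics, comparisons."""

import numpy as np
import pandas as pd
import pytest

from _oracles import SG_5_2_COEFFS, circ_corr_direct, harmonic_grid_fit
from clockmine.datatypes import ExpressionSeries
from clockmine.rhythm import (
    analyze_matrix,
    call_oscillators,
    circular_correlation,
    compare_all,
    compare_datasets,
    concat_replicates,
    core_diurnal_set,
    harmonic_regression,
    l2m_transform,
    matrix_to_series,
    sg_coefficients,
    sg_smooth,
)
from clockmine.simulate import simulate_expression

T12 = np.arange(0.0, 48.0, 4.0)


def series(values, t=T12, gene="g"):
    return ExpressionSeries(gene, np.asarray(t, float), np.asarray(values, float))


class TestL2M:
    def test_constant_row_maps_to_zero(self):
        out = l2m_transform(pd.DataFrame([[4.0, 4.0, 4.0, 4.0]], index=["g"]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_direct_formula(self):
        row = np.array([1.0, 2.0, 4.0, 8.0])
        out = l2m_transform(pd.DataFrame([row], index=["g"]))
        assert np.allclose(out.to_numpy()[0], np.log2(row / row.mean()))

    def test_zero_entry_applies_offset_with_warning(self, caplog):
        frame = pd.DataFrame([[0.0, 2.0, 4.0, 8.0]], index=["g"])
        with caplog.at_level("WARNING"):
            out = l2m_transform(frame)
        assert "offset" in caplog.text
        shifted = np.array([2.0, 4.0, 6.0, 10.0])
        assert np.allclose(out.to_numpy()[0], np.log2(shifted / shifted.mean()))

    def test_all_zero_row_dropped(self, caplog):
        frame = pd.DataFrame([[0.0] * 4, [1.0, 2.0, 3.0, 4.0]], index=["dead", "live"])
        with caplog.at_level("WARNING"):
            out = l2m_transform(frame)
        assert list(out.index) == ["live"]


class TestConcatReplicates:
    def test_identical_replicates_keep_phase(self):
        y = 1.5 * np.cos(2 * np.pi * (T12 - 10) / 24)
        merged = concat_replicates(series(y), series(y))
        assert len(merged) == 24
        fit = harmonic_regression(merged)
        assert fit.phase == pytest.approx(10.0, abs=1e-9)

    def test_antiphasic_replicates_shrink_amplitude(self):
        y1 = np.cos(2 * np.pi * (T12 - 4) / 24)
        y2 = np.cos(2 * np.pi * (T12 - 16) / 24)
        amp_single = harmonic_regression(series(y1)).amplitude
        amp_merged = harmonic_regression(concat_replicates(series(y1), series(y2))).amplitude
        assert amp_merged < amp_single

    def test_empty_replicate_returns_other(self):
        full = series(np.ones(12))
        empty = ExpressionSeries("g", np.array([]), np.array([]))
        assert concat_replicates(full, empty) is full
        assert concat_replicates(empty, full) is full


class TestSavitzkyGolay:
    def test_reproduces_quadratic_exactly(self):
        y = T12**2
        out = sg_smooth(series(y))
        assert np.allclose(out.values, y, atol=1e-9)

    def test_central_coefficients_match_published_table(self):
        assert np.allclose(sg_coefficients(5, 2), SG_5_2_COEFFS)

    def test_spike_attenuated_and_interior_matches_convolution(self):
        y = np.ones(12)
        y[6] = 5.0
        out = sg_smooth(series(y))
        assert out.values[6] < y[6]
        expected = np.convolve(y, SG_5_2_COEFFS[::-1], mode="valid")
        assert np.allclose(out.values[2:-2], expected, atol=1e-12)

    def test_window_larger_than_series_errors(self):
        with pytest.raises(ValueError):
            sg_smooth(series(np.ones(4), t=np.arange(4.0)), window=5)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 4.0, 8.0, 13.0, 16.0, 20.0, 24.0])
        with pytest.raises(ValueError, match="non-uniform"):
            sg_smooth(series(np.ones(7), t=t))


class TestHarmonicRegression:
    def test_noiseless_recovery_is_exact(self):
        y = 2 + 3 * np.cos(2 * np.pi * (T12 - 8) / 24)
        result = harmonic_regression(series(y))
        assert result.amplitude == pytest.approx(3.0, abs=1e-6)
        assert result.phase == pytest.approx(8.0, abs=1e-6)
        assert result.p < 1e-10

    def test_constant_series_has_no_rhythm(self):
        result = harmonic_regression(series(np.full(12, 2.5)))
        assert result.amplitude == pytest.approx(0.0, abs=1e-9)
        assert result.p == 1.0

    def test_matches_grid_search_oracle_with_noise(self):
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(50):
            phi, amp = rng.uniform(0, 24), rng.uniform(0.5, 2.0)
            y = amp * np.cos(2 * np.pi * (T12 - phi) / 24) + rng.normal(0, 0.3, 12)
            fit = harmonic_regression(series(y))
            phi_oracle, amp_oracle = harmonic_grid_fit(T12, y)
            diff = abs(fit.phase - phi_oracle)
            assert min(diff, 24 - diff) <= 0.011
            assert fit.amplitude == pytest.approx(amp_oracle, abs=0.01)
            hits += 1
        assert hits == 50

    def test_phase_equivariant_under_time_shift(self):
        rng = np.random.default_rng(4)
        y = np.cos(2 * np.pi * (T12 - 5) / 24) + rng.normal(0, 0.2, 12)
        base = harmonic_regression(series(y))
        shifted = harmonic_regression(series(y, t=T12 + 6.0))
        assert shifted.phase == pytest.approx((base.phase + 6.0) % 24, abs=1e-9)

    def test_amplitude_scale_equivariant(self):
        rng = np.random.default_rng(6)
        y = np.cos(2 * np.pi * (T12 - 5) / 24) + rng.normal(0, 0.2, 12)
        base = harmonic_regression(series(y))
        scaled = harmonic_regression(series(3.0 * y))
        assert scaled.amplitude == pytest.approx(3.0 * base.amplitude, rel=1e-9)

    def test_degenerate_design_flagged(self):
        s = ExpressionSeries("g", np.full(6, 2.0), np.arange(6.0))
        result = harmonic_regression(s)
        assert not result.ok

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            harmonic_regression(series(np.ones(5), t=np.arange(5.0)))


class TestOscillatorCalls:
    def test_all_null_pvalues_yield_no_oscillators(self):
        from clockmine.datatypes import OscillationResult

        results = [OscillationResult(f"g{i}", p=1.0, phase=0, amplitude=0) for i in range(5)]
        assert not any(r.oscillating for r in call_oscillators(results))

    def test_single_gene_q_equals_p(self):
        from clockmine.datatypes import OscillationResult

        out = call_oscillators([OscillationResult("g", p=0.04, phase=0, amplitude=1)])
        assert out[0].q == pytest.approx(0.04)
        assert out[0].oscillating

    def test_planted_oscillators_recovered_with_low_fdr(self):
        """20% sinusoids at high SNR among trend-only genes: recall >= 0.9 and
        empirical FDR <= 0.1 against the generator's truth table."""
        sim = simulate_expression(1000, frac_oscillating=0.2, amp_dist=1.0,
                                  noise_sd=0.25, seed=12)
        res = analyze_matrix(sim.matrix, transform=False)
        truth = sim.truth["oscillating"].to_numpy()
        called = res["oscillating"].to_numpy()
        recall = (called & truth).sum() / truth.sum()
        fdr = (called & ~truth).sum() / max(called.sum(), 1)
        assert recall >= 0.9
        assert fdr <= 0.1

    def test_type_one_error_calibrated_on_pure_trend_genes(self):
        sim = simulate_expression(1000, frac_oscillating=0.0, noise_sd=0.5, seed=11)
        res = analyze_matrix(sim.matrix, transform=False)
        frac = float((res["p"] <= 0.05).mean())
        assert 0.03 <= frac <= 0.07


class TestCircularCorrelation:
    def test_identity_and_rotation_invariance(self):
        phases = np.array([0.0, 6.0, 12.0, 20.0, 3.0])
        rho, _ = circular_correlation(phases, phases)
        assert rho == pytest.approx(1.0, abs=1e-12)
        rho_rot, _ = circular_correlation(phases, (phases + 3.0) % 24.0)
        assert rho_rot == pytest.approx(1.0, abs=1e-12)

    def test_reflection_antisymmetry(self):
        rng = np.random.default_rng(13)
        a = rng.uniform(0, 24, 20)
        b = rng.uniform(0, 24, 20)
        rho, _ = circular_correlation(a, b)
        rho_ref, _ = circular_correlation(a, (-b) % 24.0)
        assert rho_ref == pytest.approx(-rho, abs=1e-10)

    def test_direct_formula_oracle(self):
        a = [0.0, 6.0, 12.0, 20.0]
        b = [2.0, 4.0, 14.0, 18.0]
        rho, _ = circular_correlation(a, b)
        assert rho == pytest.approx(circ_corr_direct(a, b), abs=1e-12)

    def test_matches_pingouin_reference(self):
        import pingouin

        rng = np.random.default_rng(77)
        a = rng.uniform(0, 24, 30)
        b = (a + rng.normal(0, 2, 30)) % 24
        rho, p = circular_correlation(a, b)
        ref_r, ref_p = pingouin.circ_corrcc(
            2 * np.pi * a / 24, 2 * np.pi * b / 24
        )
        assert rho == pytest.approx(ref_r, abs=1e-9)
        assert p == pytest.approx(ref_p, abs=1e-9)

    def test_zero_variance_undefined(self):
        rho, p = circular_correlation([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            circular_correlation([1.0, 2.0], [3.0, 4.0])


class TestCompareDatasets:
    def _twin_results(self, noise_sd=0.1, seed=5):
        base = simulate_expression(300, frac_oscillating=0.5, amp_dist=("uniform", 0.5, 2.0),
                                   noise_sd=0.0, seed=seed)
        rng_a, rng_b = np.random.default_rng(seed + 1), np.random.default_rng(seed + 2)
        mat_a = base.matrix + rng_a.normal(0, noise_sd, base.matrix.shape)
        mat_b = base.matrix + rng_b.normal(0, noise_sd, base.matrix.shape)
        return (
            analyze_matrix(mat_a, transform=False),
            analyze_matrix(mat_b, transform=False),
        )

    def test_self_comparison_is_perfect(self):
        res, _ = self._twin_results()
        cmp = compare_datasets(res, res)
        assert cmp.rho_ccc == pytest.approx(1.0, abs=1e-9)
        assert cmp.rho_amplitude == pytest.approx(1.0, abs=1e-12)

    def test_twin_datasets_strongly_correlated(self):
        res_a, res_b = self._twin_results()
        cmp = compare_datasets(res_a, res_b)
        assert cmp.n_shared >= 100
        assert cmp.rho_ccc > 0.9
        assert cmp.p_ccc < 0.01

    def test_disjoint_oscillator_sets_skipped(self, caplog):
        idx = [f"g{i}" for i in range(4)]
        res_a = pd.DataFrame(
            {"oscillating": [True, True, False, False], "phase": 1.0, "amplitude": 1.0},
            index=idx,
        )
        res_b = pd.DataFrame(
            {"oscillating": [False, False, True, True], "phase": 1.0, "amplitude": 1.0},
            index=idx,
        )
        with caplog.at_level("WARNING"):
            assert compare_datasets(res_a, res_b) is None

    def test_homolog_map_joins_across_gene_ids(self):
        res_a = pd.DataFrame(
            {"oscillating": True, "phase": [1.0, 5.0, 9.0, 13.0], "amplitude": 1.0},
            index=["a1", "a2", "a3", "a4"],
        )
        res_b = pd.DataFrame(
            {"oscillating": True, "phase": [2.0, 6.0, 10.0, 14.0], "amplitude": 1.0},
            index=["b1", "b2", "b3", "b4"],
        )
        hom = pd.DataFrame(
            [("grp%d" % i, ds, g)
             for i, (ga, gb) in enumerate(zip(res_a.index, res_b.index))
             for ds, g in (("x", ga), ("y", gb))],
            columns=["group_id", "dataset", "gene_id"],
        )
        cmp = compare_datasets(res_a, res_b, homolog_map=hom, names=("x", "y"))
        assert cmp.n_shared == 4
        assert cmp.rho_ccc == pytest.approx(1.0, abs=1e-9)


class TestCoreDiurnalSet:
    def _results(self, flags, idx):
        return pd.DataFrame({"oscillating": flags, "phase": 0.0, "amplitude": 1.0}, index=idx)

    def test_single_dataset_returns_its_oscillators(self):
        res = self._results([True, False], ["g1", "g2"])
        assert core_diurnal_set({"a": res}) == {"g1"}

    def test_intersection_across_datasets(self):
        idx = ["g1", "g2", "g3"]
        res = {
            "a": self._results([True, True, False], idx),
            "b": self._results([True, False, True], idx),
        }
        assert core_diurnal_set(res) == {"g1"}

    def test_empty_when_no_common_oscillator(self):
        idx = ["g1", "g2"]
        res = {
            "a": self._results([True, False], idx),
            "b": self._results([False, True], idx),
        }
        assert core_diurnal_set(res) == set()

    def test_planted_universal_oscillators_recovered(self):
        """Genes oscillating in all three synthetic datasets are exactly the
        planted universal set."""
        sims = [
            simulate_expression(200, frac_oscillating=0.3, amp_dist=1.5,
                                noise_sd=0.2, seed=s)
            for s in (31, 32, 33)
        ]
        results = {
            f"d{i}": analyze_matrix(s.matrix, transform=False) for i, s in enumerate(sims)
        }
        core = core_diurnal_set(results)
        truth_core = set.intersection(
            *[set(s.truth.index[s.truth["oscillating"]]) for s in sims]
        )
        # at this SNR detection is essentially perfect
        assert core == truth_core

    def test_compare_all_emits_every_pair(self):
        sim = simulate_expression(100, frac_oscillating=0.5, noise_sd=0.1, seed=41)
        res = analyze_matrix(sim.matrix, transform=False)
        table = compare_all({"a": res, "b": res, "c": res})
        assert len(table) == 3
        assert set(zip(table["dataset_a"], table["dataset_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }
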