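import numpy as np
import pytest
from scipy import stats

from traffiq import fret
from traffiq import simulate as sim
from traffiq.io import DegenerateInputError, ImageStack


def triple(cfp, yfp, fr):
    return ImageStack(
        channels={"CFP": np.asarray(cfp, float), "YFP": np.asarray(yfp, float),
                  "FRET": np.asarray(fr, float)}
    )


class TestBleedthroughEstimation:
    def test_exact_proportionality_recovered(self, rng):
        cfp = rng.uniform(10, 200, size=(1, 10, 10))
        stack = triple(cfp, np.zeros_like(cfp), 0.5 * cfp)
        coef, n = fret.estimate_bleedthrough(stack, "CFP", "FRET")
        assert coef == pytest.approx(0.5, abs=1e-12)
        assert n == 100

    def test_zero_fret_channel_gives_zero_coefficient(self, rng):
        cfp = rng.uniform(10, 200, size=(1, 10, 10))
        stack = triple(cfp, np.zeros_like(cfp), np.zeros_like(cfp))
        coef, _ = fret.estimate_bleedthrough(stack, "CFP", "FRET")
        assert coef == 0.0

    def test_negative_slope_clamped_with_warning(self, rng):
        cfp = rng.uniform(10, 200, size=(1, 10, 10))
        stack = triple(cfp, np.zeros_like(cfp), -0.2 * cfp)
        with pytest.warns(UserWarning, match="clamped"):
            coef, _ = fret.estimate_bleedthrough(stack, "CFP", "FRET")
        assert coef == 0.0

    def test_pixel_floor_enforced(self, rng):
        cfp = rng.uniform(10, 200, size=(1, 4, 4))
        stack = triple(cfp, np.zeros_like(cfp), 0.5 * cfp)
        with pytest.raises(DegenerateInputError, match="pixels"):
            fret.estimate_bleedthrough(stack, "CFP", "FRET", min_pixels=50)

    def test_noisy_control_recovery_within_tolerance(self):
        # donor-only controls with shot noise; ~9e3 signal pixels each
        errors = []
        for seed in range(10):
            _, donor_only, _, truth = sim.make_fret_triplet(
                shape=(1, 96, 96), a_donor=0.62, b_acceptor=0.3, seed=seed
            )
            coef, n = fret.estimate_bleedthrough(
                donor_only, "CFP", "FRET", min_intensity=50.0
            )
            assert n > 1000
            errors.append(coef - truth.a_donor)
        assert max(abs(e) for e in errors) <= 0.02


class TestCorrectedFret:
    def test_zero_coefficients_are_identity(self, rng):
        fr = rng.uniform(0, 50, size=(1, 6, 6))
        stack = triple(rng.uniform(0, 50, (1, 6, 6)), rng.uniform(0, 50, (1, 6, 6)), fr)
        out = fret.corrected_fret(stack, fret.FretCalibration(0.0, 0.0))
        np.testing.assert_array_equal(out, fr)

    def test_direct_formula_evaluation(self):
        stack = triple([[[80.0]]], [[[80.0]]], [[[100.0]]])
        out = fret.corrected_fret(stack, fret.FretCalibration(0.5, 0.25))
        assert out[0, 0, 0] == pytest.approx(40.0)

    def test_noiseless_pipeline_recovers_sensitized_grid(self):
        expt, _, _, truth = sim.make_fret_triplet(
            sensitized=25.0, a_donor=0.45, b_acceptor=0.15, noise=None, seed=3
        )
        out = fret.corrected_fret(expt, fret.FretCalibration(0.45, 0.15))
        np.testing.assert_allclose(out, truth.sensitized, atol=1e-9)

    def test_linearity_under_intensity_scaling(self, rng):
        stack = triple(
            rng.uniform(0, 50, (1, 6, 6)),
            rng.uniform(0, 50, (1, 6, 6)),
            rng.uniform(0, 50, (1, 6, 6)),
        )
        calib = fret.FretCalibration(0.4, 0.2)
        base = fret.corrected_fret(stack, calib)
        scaled = ImageStack(channels={n: 2.5 * g for n, g in stack.channels.items()})
        np.testing.assert_allclose(
            fret.corrected_fret(scaled, calib), 2.5 * base, rtol=1e-12
        )


class TestFretnRoi:
    def test_arithmetic(self):
        stack = triple(np.full((1, 4, 4), 80.0), np.full((1, 4, 4), 80.0),
                       np.full((1, 4, 4), 100.0))
        fretc = np.full((1, 4, 4), 40.0)
        res = fret.fretn_roi(stack, fretc, ((0, 1), (0, 4), (0, 4)))
        assert res.fretn == pytest.approx(40.0 / (80.0 * 80.0))
        assert res.fretn == pytest.approx(0.00625)
        assert res.stoichiometry_ratio == 1.0
        assert res.included

    def test_stoichiometry_gate_excludes_ratio_above_three(self):
        stack = triple(np.full((1, 4, 4), 100.0), np.full((1, 4, 4), 400.0),
                       np.full((1, 4, 4), 100.0))
        res = fret.fretn_roi(stack, np.ones((1, 4, 4)), ((0, 1), (0, 4), (0, 4)))
        assert res.stoichiometry_ratio == pytest.approx(4.0)
        assert not res.included

    def test_ratio_exactly_three_included(self):
        stack = triple(np.full((1, 4, 4), 100.0), np.full((1, 4, 4), 300.0),
                       np.full((1, 4, 4), 100.0))
        res = fret.fretn_roi(stack, np.ones((1, 4, 4)), ((0, 1), (0, 4), (0, 4)))
        assert res.included

    def test_nonpositive_channel_mean_is_degenerate(self):
        stack = triple(np.zeros((1, 4, 4)), np.full((1, 4, 4), 10.0),
                       np.full((1, 4, 4), 10.0))
        with pytest.raises(DegenerateInputError):
            fret.fretn_roi(stack, np.ones((1, 4, 4)), ((0, 1), (0, 4), (0, 4)))

    def test_empty_roi_rejected(self, rng):
        stack = triple(*[rng.uniform(1, 10, (1, 4, 4)) for _ in range(3)])
        with pytest.raises(ValueError, match="empty"):
            fret.fretn_roi(stack, np.ones((1, 4, 4)), ((0, 0), (0, 4), (0, 4)))


class TestCompareFretn:
    @staticmethod
    def roi_result(fretn, included=True):
        return fret.FretRoiResult(
            fretc_mean=1.0, cfp_mean=1.0, yfp_mean=1.0, fretn=fretn,
            stoichiometry_ratio=1.0 if included else 5.0, included=included,
        )

    def test_identical_groups_give_p_one_t_zero(self):
        group = [self.roi_result(v) for v in (0.004, 0.005, 0.006)]
        out = fret.compare_fretn({"a": list(group), "b": list(group)})
        assert out[("a", "b")] == (0.0, 1.0)

    def test_separated_groups_highly_significant(self, rng):
        a = [self.roi_result(v) for v in rng.normal(0.005, 1e-4, 15)]
        b = [self.roi_result(v) for v in rng.normal(0.010, 1e-4, 15)]
        t, p = fret.compare_fretn({"a": a, "b": b})[("a", "b")]
        # oracle: closed-form Welch t on the same values
        t0, p0 = stats.ttest_ind(
            [r.fretn for r in a], [r.fretn for r in b], equal_var=False
        )
        assert p == pytest.approx(float(p0))
        assert p < 1e-6

    def test_excluded_rois_never_enter_comparison(self, rng):
        a = [self.roi_result(v) for v in rng.normal(0.005, 1e-4, 10)]
        b = [self.roi_result(v) for v in rng.normal(0.005, 1e-4, 10)]
        # gate-violating outliers must not shift the statistic
        a_out = a + [self.roi_result(10.0, included=False)]
        base = fret.compare_fretn({"a": a, "b": b})[("a", "b")]
        with_outlier = fret.compare_fretn({"a": a_out, "b": b})[("a", "b")]
        assert base == with_outlier

    def test_single_roi_group_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            fret.compare_fretn(
                {"a": [self.roi_result(0.005)], "b": [self.roi_result(0.004)] * 3}
            )


class TestEndToEnd:
    def test_roi_fretn_recovered_from_synthetic_pipeline(self):
        roi = ((0, 1), (30, 66), (30, 66))
        sl = (0, slice(30, 66), slice(30, 66))
        rel_errors = []
        for seed in range(10):
            expt, dctrl, actrl, truth = sim.make_fret_triplet(
                sensitized=40.0, a_donor=0.5, b_acceptor=0.2, seed=seed
            )
            calib = fret.calibrate(dctrl, actrl, min_intensity=50.0)
            fretc = fret.corrected_fret(expt, calib)
            res = fret.fretn_roi(expt, fretc, roi)
            truth_fretn = truth.sensitized[sl].mean() / (
                truth.yfp_clean[sl].mean() * truth.cfp_clean[sl].mean()
            )
            rel_errors.append(res.fretn / truth_fretn - 1.0)
        assert max(abs(e) for e in rel_errors) <= 0.10

    def test_zero_sensitized_control_indistinguishable_from_zero(self):
        roi = ((0, 1), (30, 66), (30, 66))
        n_pass = 0
        for seed in range(10):
            expt, dctrl, actrl, _ = sim.make_fret_triplet(
                sensitized=0.0, a_donor=0.5, b_acceptor=0.2, seed=seed
            )
            calib = fret.calibrate(dctrl, actrl, min_intensity=50.0)
            fretc = fret.corrected_fret(expt, calib)
            vals = fretc[0, 30:66, 30:66].ravel()
            _, p = stats.ttest_1samp(vals, 0.0)
            n_pass += p > 0.05
        assert n_pass >= 9
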