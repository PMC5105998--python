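import numpy as np
import pytest

from nrfkit.nrf_model import RHO1, RHO2, NRFParams, forward
from nrfkit.rf_analysis import (adjust_network, contours, display_strf,
                                ec_score, effective_hus, ie_score,
                                interpolate_strf, power_strf, tuning_widths)


def random_params(rng, J=4, F=5, H=4, scale=0.6):
    return NRFParams(w_in=scale * rng.standard_normal((J, F, H)),
                     b_hidden=scale * rng.standard_normal(J),
                     w_out=scale * rng.standard_normal(J),
                     b_out=scale * float(rng.standard_normal()))


class TestAdjustNetwork:
    def test_all_positive_network_unchanged(self, rng):
        p = NRFParams(w_in=np.abs(rng.standard_normal((2, 3, 2))),
                      b_hidden=rng.standard_normal(2),
                      w_out=rng.standard_normal(2), b_out=0.1)
        adj = adjust_network(p)
        assert not adj.flipped.any()
        assert np.array_equal(adj.params.w_in, p.w_in)

    def test_idempotent_and_prediction_preserving(self, rng):
        X = rng.standard_normal((60, 5, 4))
        for _ in range(100):
            p = random_params(rng)
            adj = adjust_network(p)
            assert np.allclose(forward(p, X).y_hat,
                               forward(adj.params, X).y_hat, atol=1e-10)
            twice = adjust_network(adj.params)
            assert not twice.flipped.any()
            sums = adj.params.w_in.reshape(p.J, -1).sum(axis=1)
            assert np.all(sums >= 0)

    def test_negative_strf_negative_output_weight_becomes_excitatory(self):
        # a unit with all-negative STRF weights and negative w_j has a
        # positive, excitatory influence; adjustment makes that explicit
        p = NRFParams(w_in=-np.ones((1, 2, 2)), b_hidden=np.array([0.3]),
                      w_out=np.array([-0.8]), b_out=0.0)
        adj = adjust_network(p)
        assert adj.flipped[0]
        assert adj.params.w_out[0] > 0

    def test_nonneg_description_bias_shift(self):
        p = NRFParams(w_in=np.ones((2, 2, 2)), b_hidden=np.zeros(2),
                      w_out=np.array([0.5, -0.25]), b_out=0.4)
        adj = adjust_network(p)
        assert adj.nonneg_bias_shift == pytest.approx(0.4 - RHO1 * 0.25)


class TestEffectiveHUs:
    def test_single_active_hu_takes_all_variance(self, rng):
        w_in = np.zeros((3, 4, 2))
        w_in[1] = rng.standard_normal((4, 2))
        p = NRFParams(w_in=w_in, b_hidden=np.zeros(3),
                      w_out=np.array([0.0, 1.0, 0.0]), b_out=0.0)
        profs = effective_hus(p, rng.standard_normal((200, 4, 2)))
        assert profs[1].variance_fraction == pytest.approx(1.0)
        assert profs[1].effective and not profs[0].effective

    def test_duplicated_hus_split_variance_evenly(self, rng):
        w = rng.standard_normal((4, 2))
        p = NRFParams(w_in=np.stack([w, w]), b_hidden=np.zeros(2),
                      w_out=np.array([0.7, 0.7]), b_out=0.0)
        profs = effective_hus(p, rng.standard_normal((200, 4, 2)))
        assert profs[0].variance_fraction == pytest.approx(0.5)
        assert profs[1].variance_fraction == pytest.approx(0.5)

    def test_constructed_variance_fractions_mark_three_effective(self, rng):
        # near-linear regime with orthonormal zero-mean inputs: weighted-
        # output variances are proportional to (c_j * w_j)^2 exactly
        T, F = 4000, 4
        Q, _ = np.linalg.qr(rng.standard_normal((T, F)))
        Q -= Q.mean(axis=0)
        Q, _ = np.linalg.qr(Q)
        X = (Q * np.sqrt(T))[:, :, None]  # unit-variance columns
        targets = np.array([0.70, 0.20, 0.06, 0.04])
        c = 1e-3 * np.sqrt(targets)
        w_in = np.zeros((4, F, 1))
        for j in range(4):
            w_in[j, j, 0] = c[j]
        p = NRFParams(w_in=w_in, b_hidden=np.zeros(4), w_out=np.ones(4),
                      b_out=0.0)
        profs = effective_hus(p, X)
        fracs = np.array([q.variance_fraction for q in profs])
        assert np.allclose(fracs, targets, atol=1e-6)
        assert [q.effective for q in profs] == [True, True, True, False]

    def test_variance_fractions_sum_to_one(self, rng):
        p = random_params(rng)
        profs = effective_hus(p, rng.standard_normal((150, 5, 4)))
        assert sum(q.variance_fraction for q in profs) == pytest.approx(
            1.0, abs=1e-12)


class TestScores:
    def test_ie_anchor_cases(self):
        assert ie_score(np.array([[1.0, 2.0]]), 0.5) == 1.0
        assert ie_score(np.array([[-1.0, -2.0]]), 0.5) == -1.0
        assert ie_score(np.array([[1.0, -1.0]]), 0.5) == 0.0
        assert ie_score(np.array([[2.0, -1.0]]), -1.0) == pytest.approx(-1 / 3)

    def test_ie_undefined_for_zero_strf(self):
        with pytest.raises(ValueError):
            ie_score(np.zeros((2, 2)), 1.0)

    def test_ie_and_ec_invariant_to_sign_flip(self, rng):
        X = rng.standard_normal((300, 5, 4))
        p = random_params(rng)
        q = NRFParams(w_in=p.w_in * -1, b_hidden=p.b_hidden * -1,
                      w_out=p.w_out * -1, b_out=p.b_out)
        a = effective_hus(p, X)
        b = effective_hus(q, X)
        for pa, pb in zip(a, b):
            assert pa.ie == pytest.approx(pb.ie, abs=1e-12)
            assert pa.ec == pytest.approx(pb.ec, abs=1e-12)

    def test_ec_anchors_for_network_units(self):
        assert ec_score(np.full(10, -RHO1)) == pytest.approx(-1.0)
        assert ec_score(np.full(10, RHO1)) == pytest.approx(1.0)
        assert ec_score(np.zeros(10)) == pytest.approx(0.0)

    def test_ec_anchors_for_ln_units(self):
        rho1, rho4 = 2.0, 0.3
        kw = dict(rho1=rho1, rho4=rho4, rho5=1.0, rho6=2.0)
        assert ec_score(np.full(5, rho4), **kw) == pytest.approx(-1.0)
        assert ec_score(np.full(5, rho4 + rho1), **kw) == pytest.approx(1.0)
        assert ec_score(np.full(5, rho4 + rho1 / 2), **kw) == pytest.approx(0.0)


class TestDisplaySTRF:
    def test_sign_convention(self, rng):
        w = rng.standard_normal((3, 2))
        assert np.array_equal(display_strf(w, "excitatory"), w)
        assert np.array_equal(display_strf(w, "inhibitory"), -w)
        assert np.array_equal(
            display_strf(display_strf(w, "inhibitory"), "inhibitory"), w)


def oracle_widths(w, frac, spacing=1 / 6, bin_ms=5.0, factor=8):
    """Independent width oracle: scipy spline sampled point by point."""
    from scipy.interpolate import RectBivariateSpline
    nf, nh = w.shape
    spl = RectBivariateSpline(np.arange(nf), np.arange(nh), w,
                              kx=min(3, nf - 1), ky=min(3, nh - 1), s=0)
    ff = np.linspace(0, nf - 1, (nf - 1) * factor + 1)
    hh = np.linspace(0, nh - 1, (nh - 1) * factor + 1)
    P = np.array([[spl(a, b)[0, 0] ** 2 for b in hh] for a in ff])
    fp, tp = P.sum(axis=1), P.sum(axis=0)
    return (np.sum(fp >= frac * fp.max()) * spacing / factor,
            np.sum(tp >= frac * tp.max()) * bin_ms / factor)


class TestTuningWidths:
    def test_interpolated_grid_resolution(self):
        w = np.random.default_rng(0).standard_normal((10, 6))
        interp = interpolate_strf(w)
        assert interp.shape == ((10 - 1) * 8 + 1, (6 - 1) * 8 + 1)
        # 1/6-octave channels at 8x -> 1/48-octave interpolated bins

    def test_boxcar_spanning_six_channels_is_one_octave(self):
        w = np.zeros((18, 12))
        w[6:12, 4:8] = 1.0  # 6 channels at 1/6 octave = 1 octave
        tw = tuning_widths(power_strf(w))
        assert tw.freq_width_quarter == pytest.approx(1.0, abs=0.12)
        assert tw.freq_width_half == pytest.approx(1.0, abs=0.12)

    def test_matches_independent_oracle(self, rng):
        w = rng.standard_normal((7, 6))
        tw = tuning_widths(power_strf(w))
        fq, tq = oracle_widths(w, 0.25)
        fh, th = oracle_widths(w, 0.5)
        assert tw.freq_width_quarter == pytest.approx(fq, abs=1e-9)
        assert tw.time_width_quarter == pytest.approx(tq, abs=1e-9)
        assert tw.freq_width_half == pytest.approx(fh, abs=1e-9)
        assert tw.time_width_half == pytest.approx(th, abs=1e-9)

    def test_single_dominant_bin_has_narrow_temporal_width(self):
        w = np.zeros((8, 10))
        w[4, 5] = 1.0
        tw = tuning_widths(power_strf(w))
        assert tw.time_width_quarter <= 10.0  # within a ~2-bin neighborhood
        _, tq = oracle_widths(w, 0.25)
        assert tw.time_width_quarter == pytest.approx(tq, abs=1e-9)

    def test_half_height_narrower_and_scale_invariant(self, rng):
        w = rng.standard_normal((8, 6))
        tw = tuning_widths(power_strf(w))
        assert tw.freq_width_half <= tw.freq_width_quarter
        assert tw.time_width_half <= tw.time_width_quarter
        tw2 = tuning_widths(power_strf(3.7 * w))
        assert tw2 == tw

    def test_nrf_power_strf_weights_hus_by_variance(self, rng):
        from nrfkit.synthetic_data import make_ground_truth
        gt = make_ground_truth(1, 1, F=12, H=10, seed=0)
        X = rng.standard_normal((400, 12, 10))
        P = power_strf(gt.params, X)
        assert P.shape == ((12 - 1) * 8 + 1, (10 - 1) * 8 + 1)
        assert P.max() > 0
        widths = tuning_widths(P)
        assert widths.freq_width_half <= widths.freq_width_quarter

    def test_all_zero_power_rejected(self):
        with pytest.raises(ValueError):
            tuning_widths(np.zeros((9, 9)))


class TestContours:
    def gauss(self, F=10, H=10, centers=((5, 5),)):
        f, t = np.mgrid[0:F, 0:H]
        w = np.zeros((F, H))
        for cf, ct in centers:
            w += np.exp(-((f - cf) ** 2 + (t - ct) ** 2) / 1.5)
        return w

    def test_single_bump_single_closed_contour(self):
        cs = contours(self.gauss(), "excitatory")
        assert len(cs) == 1
        assert np.allclose(cs[0][0], cs[0][-1])  # closed

    def test_two_separated_bumps_two_contours(self):
        cs = contours(self.gauss(16, 16, centers=((4, 4), (12, 12))),
                      "excitatory")
        assert len(cs) == 2

    def test_inhibitory_mirror_has_identical_geometry(self):
        w = self.gauss()
        ce = contours(w, "excitatory")
        ci = contours(-w, "inhibitory")
        assert len(ce) == len(ci) == 1

        def canon(c):  # same polygon up to start point and orientation
            c = c[:-1]
            starts = [np.roll(v, -np.lexsort((v[:, 1], v[:, 0]))[0], axis=0)
                      for v in (c, c[::-1])]
            return starts

        a, b = canon(ce[0]), canon(ci[0])
        assert any(np.allclose(x, y, atol=1e-9) for x in a for y in b)

    def test_flat_strf_yields_no_contours(self):
        assert contours(np.ones((6, 6)), "excitatory") == []
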