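"""Line scans, peripheral fractions, lane densitometry and decay summaries."""
import numpy as np
import pytest

from nucmorph import (
    DecaySpec,
    LineProfile,
    VoxelGrid,
    lane_auc,
    long_axis,
    make_decay_course,
    peripheral_fraction,
    sample_profile,
    summarize_decay,
)
from nucmorph.profiles import fit_half_life


def ellipse_mask(a_um, b_um, px=0.2, pad=3.0):
    w = int(round(2 * (a_um + pad) / px))
    h = int(round(2 * (b_um + pad) / px))
    yy, xx = np.mgrid[0:h, 0:w]
    x = (xx + 0.5) * px - w * px / 2
    y = (yy + 0.5) * px - h * px / 2
    return (x / a_um) ** 2 + (y / b_um) ** 2 <= 1.0, px


class TestLongAxis:
    def test_ellipse_axis_along_major_direction(self):
        mask, px = ellipse_mask(8.0, 4.0)
        p0, p1 = long_axis(mask, (px, px))
        direction = (p1 - p0) / np.linalg.norm(p1 - p0)
        assert abs(direction[1]) < 0.05  # along x
        chord = np.linalg.norm(p1 - p0) - 4.0  # remove 2 um overshoot each side
        assert chord == pytest.approx(16.0, abs=px)

    def test_circle_any_diameter(self):
        mask, px = ellipse_mask(5.0, 5.0)
        p0, p1 = long_axis(mask, (px, px))
        chord = np.linalg.norm(p1 - p0) - 4.0
        assert chord == pytest.approx(10.0, abs=px)

    def test_elongated_blob_matches_farthest_pair_oracle(self):
        # rotated ellipse, aspect 2.5: principal axis ~ farthest boundary pair
        px = 0.2
        n = 160
        yy, xx = np.mgrid[0:n, 0:n]
        x = (xx + 0.5) * px - n * px / 2
        y = (yy + 0.5) * px - n * px / 2
        th = np.deg2rad(30)
        u = x * np.cos(th) + y * np.sin(th)
        v = -x * np.sin(th) + y * np.cos(th)
        mask = (u / 10.0) ** 2 + (v / 4.0) ** 2 <= 1.0
        p0, p1 = long_axis(mask, (px, px))
        direction = (p1 - p0) / np.linalg.norm(p1 - p0)
        # brute-force farthest pair of boundary pixels
        from scipy import ndimage
        boundary = mask & ~ndimage.binary_erosion(mask)
        iy, ix = np.nonzero(boundary)
        pts = np.stack([(ix + 0.5) * px, (iy + 0.5) * px], axis=1)
        d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmax(d2), d2.shape)
        ref = pts[j] - pts[i]
        ref /= np.linalg.norm(ref)
        assert abs(abs(direction @ ref) - 1.0) < 1e-3

    def test_empty_or_disconnected_raises(self):
        with pytest.raises(ValueError, match="empty"):
            long_axis(np.zeros((10, 10), bool), (1, 1))
        m = np.zeros((10, 10), bool)
        m[1:3, 1:3] = True
        m[7:9, 7:9] = True
        with pytest.raises(ValueError, match="connected"):
            long_axis(m, (1, 1))


class TestSampleProfile:
    def test_constant_image(self):
        mask, px = ellipse_mask(6.0, 4.0)
        chan = VoxelGrid(np.full(mask.shape, 3.5), (px, px))
        prof = sample_profile(chan, long_axis(mask, (px, px)), mask)
        assert np.allclose(prof.intensities, 3.5)

    def test_linear_ramp_preserved(self):
        mask, px = ellipse_mask(6.0, 4.0)
        w = mask.shape[1]
        ramp = np.tile(((np.arange(w) + 0.5) * px * 2.0), (mask.shape[0], 1))
        chan = VoxelGrid(ramp, (px, px))
        prof = sample_profile(chan, ((1.0, 4.2), (10.0, 4.2)), mask)
        slopes = np.diff(prof.intensities) / np.diff(prof.positions_um)
        assert np.allclose(slopes, 2.0, atol=1e-6)

    def test_out_of_bounds_raises(self):
        mask, px = ellipse_mask(6.0, 4.0)
        chan = VoxelGrid(np.ones(mask.shape), (px, px))
        with pytest.raises(ValueError, match="bounds"):
            sample_profile(chan, ((-5.0, 4.0), (100.0, 4.0)), mask)


class TestPeripheralFraction:
    def uniform_profile(self, L=10.0, step=0.1, pad=2.0):
        pos = np.arange(-pad, L + pad + step / 2, step)
        return LineProfile(pos, np.ones_like(pos), 0.0, L)

    def test_uniform_closed_form(self):
        pf = peripheral_fraction(self.uniform_profile(), 3.0)
        assert pf.value == pytest.approx(0.6, abs=0.006)  # 2d/L with one-step slack

    @pytest.mark.parametrize("L", [8.0, 12.5, 20.0])
    def test_uniform_any_span(self, L):
        pf = peripheral_fraction(self.uniform_profile(L=L), 3.0)
        assert pf.value == pytest.approx(6.0 / L, abs=0.1 / L * 2)

    def test_all_signal_near_left_edge(self):
        pos = np.arange(0.0, 10.01, 0.1)
        inten = np.where(pos <= 1.0, 5.0, 0.0)
        pf = peripheral_fraction(LineProfile(pos, inten, 0.0, 10.0), 3.0)
        assert pf.value == pytest.approx(1.0)

    def test_discrete_profile_brute_force(self):
        # intensity 5 on [0,3] and [7,10], 1 on (3,7); trapezoid oracle coded directly
        pos = np.arange(0.0, 10.5, 1.0)
        inten = np.array([5, 5, 5, 5, 1, 1, 1, 5, 5, 5, 5], dtype=float)
        prof = LineProfile(pos, inten, 0.0, 10.0)
        # independent summation: trapezoid over unit intervals
        def seg(i0, i1):
            return sum((inten[i] + inten[i + 1]) / 2 for i in range(i0, i1))
        expect = (seg(0, 3) + seg(7, 10)) / seg(0, 10)
        pf = peripheral_fraction(prof, 3.0)
        assert pf.value == pytest.approx(expect, rel=1e-12)

    def test_margin_covering_span_flagged(self):
        pf = peripheral_fraction(self.uniform_profile(L=5.0), 3.0)
        assert pf.flagged and pf.value == 1.0

    def test_zero_signal_raises(self):
        pos = np.arange(0.0, 10.1, 0.5)
        with pytest.raises(ValueError, match="no signal"):
            peripheral_fraction(LineProfile(pos, np.zeros_like(pos), 0.0, 10.0), 3.0)

    def test_intensity_scale_invariance(self):
        pos = np.arange(0.0, 10.05, 0.1)
        rng = np.random.default_rng(4)
        inten = rng.random(pos.size) + 0.1
        a = peripheral_fraction(LineProfile(pos, inten, 0.0, 10.0), 3.0)
        b = peripheral_fraction(LineProfile(pos, inten * 37.5, 0.0, 10.0), 3.0)
        assert a.value == pytest.approx(b.value, rel=1e-12)


class TestLaneAuc:
    def test_rectangular_band(self):
        x = np.arange(0.0, 30.0, 0.01)
        y = np.where((x >= 10) & (x <= 15), 4.0, 0.0)
        res = lane_auc(y, positions=x, background_mode="zero")
        assert res.auc == pytest.approx(20.0, rel=0.01)

    def test_identical_lanes_normalized_to_one(self):
        y = np.exp(-0.5 * ((np.arange(100) - 50) / 5.0) ** 2)
        control = lane_auc(y, background_mode="zero").auc
        res = lane_auc(y, background_mode="zero", control_auc=control)
        assert res.normalized == pytest.approx(1.0)

    def test_gaussian_band_area(self):
        x = np.arange(0.0, 60.0, 0.05)
        y = 10.0 * np.exp(-0.5 * ((x - 30) / 2.0) ** 2)
        res = lane_auc(y, positions=x)
        assert res.auc == pytest.approx(10 * 2.0 * np.sqrt(2 * np.pi), rel=0.01)

    def test_linearity_under_zero_background(self):
        rng = np.random.default_rng(2)
        y = rng.random(80)
        assert lane_auc(3.0 * y).auc == pytest.approx(3.0 * lane_auc(y).auc, rel=1e-12)

    def test_zero_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            lane_auc(np.ones(10), control_auc=0.0)

    def test_min_background_subtracts_floor(self):
        y = np.array([2.0, 2.0, 7.0, 2.0, 2.0])
        assert lane_auc(y, background_mode="min").auc == pytest.approx(
            lane_auc(y - 2.0, background_mode="zero").auc)


class TestDecaySummary:
    def test_noiseless_half_life_exact(self):
        course = make_decay_course(DecaySpec(rate_per_h=np.log(2) / 6.0, noise_cv=0.0))
        assert fit_half_life(course) == pytest.approx(6.0, abs=1e-9)

    def test_identical_conditions_p_one(self):
        a = make_decay_course(DecaySpec(noise_cv=0.0))
        df = summarize_decay(a, other=a)
        assert np.allclose(df.t_test_p, 1.0)

    def test_half_life_recovery_under_noise(self):
        # parameter-recovery simulation: two rates, 5% noise, 3 replicates
        for k, t_half in ((np.log(2) / 4, 4.0), (np.log(2) / 12, 12.0)):
            errs = []
            for seed in range(100):
                course = make_decay_course(
                    DecaySpec(rate_per_h=k, noise_cv=0.05, replicates=3, seed=seed))
                errs.append(abs(fit_half_life(course) / t_half - 1.0))
            assert max(errs) < 0.15

    def test_different_rates_detected(self):
        a = make_decay_course(DecaySpec(rate_per_h=np.log(2) / 4, noise_cv=0.05, seed=1))
        b = make_decay_course(DecaySpec(rate_per_h=np.log(2) / 12, noise_cv=0.05, seed=2))
        df = summarize_decay(a, other=b)
        assert (df.t_test_p[df.timepoint_h > 0] < 0.05).all()

    def test_nonpositive_levels_rejected(self):
        course = make_decay_course(DecaySpec(noise_cv=0.0))
        course.levels[0, 0] = 0.0
        with pytest.raises(ValueError, match="nonpositive"):
            fit_half_life(course)
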