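"""Worm-like chain, contour algebra and Bell-Evans kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtforce.mechanics import (
    KBT_ROOM,
    KineticParameters,
    SegmentTable,
    WlcParameters,
    bell_rate,
    calibrate_koff,
    contour_increment,
    most_probable_force,
    rupture_force_cdf,
    sample_rupture_force,
    wlc_extension,
    wlc_force,
    wlc_stiffness,
)

DEFAULT = WlcParameters()


class TestWlcForce:
    def test_zero_extension_gives_zero_force(self):
        assert wlc_force(0.0, 30.0, DEFAULT) == 0.0

    def test_half_extension_value(self):
        # direct evaluation of the interpolation at x/Lc = 0.5:
        # (4.114/0.4) * (0.25/0.25 - 0.25 + 0.5) = 12.85625 pN
        assert wlc_force(15.0, 30.0, DEFAULT) == pytest.approx(12.85625, abs=1e-6)

    def test_divergence_near_full_extension(self):
        # independent evaluation: at x/Lc = 0.99 the interpolation gives
        # (kBT/p) * (0.25/1e-4 - 0.25 + 0.99) ~ 2.5718e4 pN, and the force
        # keeps growing monotonically toward the contour length
        assert wlc_force(29.7, 30.0, DEFAULT) == pytest.approx(
            (KBT_ROOM / 0.4) * (0.25 / 0.01**2 - 0.25 + 0.99), rel=1e-12
        )
        f = [wlc_force(x, 30.0, DEFAULT) for x in np.linspace(29.0, 29.999, 50)]
        assert np.all(np.diff(f) > 0)
        assert f[-1] > 1e5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wlc_force(30.0, 30.0, DEFAULT)
        with pytest.raises(ValueError):
            wlc_force(31.0, 30.0, DEFAULT)
        with pytest.raises(ValueError):
            wlc_force(1.0, -5.0, DEFAULT)
        with pytest.raises(ValueError):
            wlc_force(-1.0, 30.0, DEFAULT)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        t1=st.floats(0.01, 0.95),
        t2=st.floats(0.01, 0.95),
        lc=st.floats(5.0, 200.0),
    )
    def test_strictly_increasing_in_extension(self, t1, t2, lc):
        lo, hi = sorted((t1, t2))
        if hi - lo < 1e-6:
            return
        assert wlc_force(hi * lc, lc, DEFAULT) > wlc_force(lo * lc, lc, DEFAULT)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        x=st.floats(1.0, 20.0),
        lc1=st.floats(21.0, 100.0),
        scale=st.floats(1.05, 3.0),
    )
    def test_increasing_in_inverse_contour_length(self, x, lc1, scale):
        # shorter chain at the same extension pulls harder
        assert wlc_force(x, lc1, DEFAULT) > wlc_force(x, lc1 * scale, DEFAULT)

    def test_stiffness_is_force_derivative(self):
        x, lc, h = 20.0, 30.0, 1e-6
        num = (wlc_force(x + h, lc, DEFAULT) - wlc_force(x - h, lc, DEFAULT)) / (2 * h)
        assert wlc_stiffness(x, lc, DEFAULT) == pytest.approx(num, rel=1e-6)


class TestWlcExtension:
    def test_zero_force(self):
        assert wlc_extension(0.0, 30.0, DEFAULT) == 0.0

    def test_matches_forward_example(self):
        assert wlc_extension(12.85625, 30.0, DEFAULT) == pytest.approx(15.0, abs=1e-9)

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            wlc_extension(-1.0, 30.0, DEFAULT)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(force=st.floats(0.0, 800.0), lc=st.floats(5.0, 300.0))
    def test_round_trip(self, force, lc):
        x = wlc_extension(force, lc, DEFAULT)
        assert 0.0 <= x < lc
        assert wlc_force(x, lc, DEFAULT) == pytest.approx(force, abs=1e-6)


class TestContourIncrement:
    @pytest.mark.parametrize(
        "n_aa, folded, expected",
        [
            (34, 1.3, 10.94),  # alpha-domain one-step segment (printed 10.9)
            (25, 1.2, 7.8),  # beta-domain segment
            (0, 0.0, 0.0),
        ],
    )
    def test_published_segment_arithmetic(self, n_aa, folded, expected):
        assert contour_increment(n_aa, folded) == pytest.approx(expected, abs=1e-9)

    def test_non_positive_increment_warns(self):
        with pytest.warns(UserWarning):
            assert contour_increment(2, 5.0) < 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            contour_increment(-1, 0.0)
        with pytest.raises(ValueError):
            contour_increment(5, -0.1)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.integers(0, 200),
        b=st.integers(0, 200),
        d1=st.floats(0.0, 5.0),
        d2=st.floats(0.0, 5.0),
    )
    def test_linearity(self, a, b, d1, d2):
        lhs = contour_increment(a + b, d1 + d2)
        rhs = contour_increment(a, d1) + contour_increment(b, d2)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestSegmentTable:
    def test_default_self_consistency(self):
        table = SegmentTable.default()
        for e in table.entries:
            assert e.theoretical_dlc == pytest.approx(
                table.residue_length * e.n_aa - e.folded_distance, abs=1e-9
            )
            assert e.theoretical_dlc > 0

    def test_default_published_values(self):
        table = SegmentTable.default()
        assert table.get("alpha:Cys34-Cys67").theoretical_dlc == pytest.approx(10.94)
        assert table.get("alpha:Cys34-Cys45").theoretical_dlc == pytest.approx(3.6)
        assert table.get("alpha:Cys45-Cys67").theoretical_dlc == pytest.approx(7.5)
        assert table.get("beta:Cys6-Cys30").theoretical_dlc == pytest.approx(7.8)

    def test_tsv_round_trip(self, tmp_path):
        table = SegmentTable.default()
        path = tmp_path / "segments.tsv"
        table.to_tsv(path)
        back = SegmentTable.from_tsv(path)
        assert [e.label for e in back.entries] == [e.label for e in table.entries]
        for a, b in zip(back.entries, table.entries):
            assert a.theoretical_dlc == pytest.approx(b.theoretical_dlc, abs=1e-4)

    def test_inconsistent_entry_rejected(self):
        from mtforce.mechanics import SegmentEntry

        with pytest.raises(ValueError):
            SegmentTable(entries=[SegmentEntry("bad", 10, 1.0, 99.0)])


class TestBellKinetics:
    PARAMS = KineticParameters(25.0, 0.2)

    def test_zero_force_limit(self):
        assert bell_rate(0.0, self.PARAMS) == pytest.approx(self.PARAMS.k_off)

    def test_unit_exponent_identity(self):
        f = KBT_ROOM / self.PARAMS.delta_x
        assert bell_rate(f, self.PARAMS) == pytest.approx(
            self.PARAMS.k_off * np.e, rel=1e-12
        )

    def test_exponential_evaluation(self):
        # 25 * exp(100*0.2/4.114) = 3.231e3 1/s
        assert bell_rate(100.0, self.PARAMS) == pytest.approx(
            25.0 * np.exp(20.0 / KBT_ROOM), rel=1e-12
        )
        assert bell_rate(100.0, self.PARAMS) == pytest.approx(3.23e3, rel=0.01)

    def test_monotone_and_bounded_below(self):
        forces = np.linspace(0, 300, 50)
        rates = bell_rate(forces, self.PARAMS)
        assert np.all(np.diff(rates) > 0)
        assert np.all(rates >= self.PARAMS.k_off)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            KineticParameters(0.0, 0.2)
        with pytest.raises(ValueError):
            KineticParameters(25.0, -0.1)


class TestMostProbableForce:
    PARAMS = KineticParameters(25.0, 0.2)

    def test_log_argument_one_gives_zero(self):
        r = self.PARAMS.k_off * KBT_ROOM / self.PARAMS.delta_x
        assert most_probable_force(r, self.PARAMS) == 0.0

    def test_direct_value(self):
        # (4.114/0.2) * ln(1e4*0.2/(25*4.114)) = 61.04 pN
        assert most_probable_force(1e4, self.PARAMS) == pytest.approx(61.04, abs=0.05)

    def test_clipped_at_zero_for_low_rates(self):
        assert most_probable_force(1e-3, self.PARAMS) == 0.0

    def test_slope_identity(self):
        scale = KBT_ROOM / self.PARAMS.delta_x
        for r in (1e3, 1e4, 1e5):
            diff = most_probable_force(10 * r, self.PARAMS) - most_probable_force(
                r, self.PARAMS
            )
            assert diff == pytest.approx(scale * np.log(10.0), rel=1e-9)

    def test_calibration_round_trip(self):
        koff = calibrate_koff(180.0, 5e4, 0.3)
        fitted = most_probable_force(5e4, KineticParameters(koff, 0.3))
        assert fitted == pytest.approx(180.0, abs=1e-9)


class TestRuptureForceSampler:
    PARAMS = KineticParameters(25.0, 0.2)

    def test_fixed_seed_reproducible(self):
        a = sample_rupture_force(1e4, self.PARAMS, rng=7, size=100)
        b = sample_rupture_force(1e4, self.PARAMS, rng=7, size=100)
        assert np.array_equal(a, b)

    def test_ks_distance_against_analytic_cdf(self):
        f = np.sort(sample_rupture_force(1e4, self.PARAMS, rng=1, size=100_000))
        ecdf = np.arange(1, f.size + 1) / f.size
        ks = np.max(np.abs(ecdf - rupture_force_cdf(f, 1e4, self.PARAMS)))
        assert ks < 0.01

    def test_histogram_mode_matches_most_probable_force(self):
        f = sample_rupture_force(1e4, self.PARAMS, rng=2, size=100_000)
        counts, edges = np.histogram(f, bins=np.arange(0, 200, 1.0))
        mode = 0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1])
        assert mode == pytest.approx(most_probable_force(1e4, self.PARAMS), abs=2.0)

    def test_invalid_loading_rate(self):
        with pytest.raises(ValueError):
            sample_rupture_force(0.0, self.PARAMS)
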