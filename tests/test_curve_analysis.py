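"""Curve analysis: smoothing, detection, WLC fitting, selection."""

import numpy as np
import pytest

from mtforce.curve_analysis import (
    BranchFitError,
    ForceExtensionCurve,
    RupturePeak,
    SelectionCriteria,
    analyze_curve,
    compute_dlc,
    detect_peaks,
    fit_branch_wlc,
    select_single_molecule,
    smooth,
)
from mtforce.mechanics import WlcParameters, wlc_force
from mtforce.synthetic import build_construct, simulate_curve
from tests.conftest import match_in_order, resolvable_events


def _curve(x, f, **meta):
    return ForceExtensionCurve(np.asarray(x, float), np.asarray(f, float), meta)


class TestCurveContainer:
    def test_rejects_mismatched_and_nan(self):
        with pytest.raises(ValueError):
            _curve([0, 1, 2], [0, 1])
        with pytest.raises(ValueError):
            _curve([0, 1, 2], [0, np.nan, 1])
        with pytest.raises(ValueError):
            _curve([0, 2, 1], [0, 1, 2])


class TestSmooth:
    def test_constant_series_unchanged(self):
        c = _curve(np.arange(50.0), np.full(50, 7.0))
        assert np.allclose(smooth(c, 11).force, 7.0)

    def test_linear_ramp_preserved_in_interior(self):
        c = _curve(np.arange(100.0), np.arange(100.0) * 2.0)
        s = smooth(c, 11)
        assert np.allclose(s.force[10:-10], c.force[10:-10], atol=1e-9)

    def test_white_noise_variance_reduction(self, rng):
        noise = rng.normal(0, 8.0, 5000)
        c = _curve(np.arange(5000.0), noise)
        resid = smooth(c, 11).force
        # moving-average variance: sd/sqrt(11) ~ 2.4 pN
        assert np.std(resid) < 4.0

    def test_window_validation(self):
        c = _curve(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            smooth(c, 4)
        with pytest.raises(ValueError):
            smooth(c, 1)
        with pytest.raises(ValueError):
            smooth(c, 11)  # longer than the series


class TestDetectPeaks:
    def test_single_marker_noiseless_two_peaks(self, marker_config_noiseless):
        curve, _ = simulate_curve(marker_config_noiseless, 3)
        peaks = detect_peaks(curve)
        assert len(peaks) == 2
        assert peaks[-1].is_detachment and not peaks[0].is_detachment

    def test_six_markers_plus_one_step_eight_peaks(self, alpha_config_noiseless):
        # pick a seed whose cluster scenario is a detectable one-step event
        for seed in range(40):
            curve, truth = simulate_curve(alpha_config_noiseless, seed)
            scen = list(truth.scenarios.values())[0]
            resolvable = resolvable_events(truth, alpha_config_noiseless)
            if scen["one_step"] and len(resolvable) == len(truth.events):
                assert len(detect_peaks(curve)) == 8  # 7 unfoldings + detachment
                return
        pytest.fail("no fully resolvable one-step curve among 40 seeds")

    def test_flat_curve_no_peaks(self):
        c = _curve(np.arange(500.0) * 0.1, np.zeros(500))
        assert detect_peaks(c) == []

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(_curve([], []))

    def test_constant_offset_invariance(self, marker_config_noiseless):
        curve, _ = simulate_curve(marker_config_noiseless, 8)
        shifted = ForceExtensionCurve(
            curve.extension, curve.force + 35.0, curve.metadata
        )
        p1 = [(p.peak_index, round(p.rupture_force, 6)) for p in detect_peaks(curve)]
        p2 = [(p.peak_index, round(p.rupture_force, 6)) for p in detect_peaks(shifted)]
        assert p1 == p2


class TestFitBranchWlc:
    WLC = WlcParameters()

    def _branch(self, lc, noise_sd, n=300, rng=None):
        x = np.linspace(0.3 * lc, 0.9 * lc, n)
        f = np.array([wlc_force(v, lc, self.WLC) for v in x])
        if noise_sd:
            f = f + rng.normal(0, noise_sd, n)
        return _curve(x, f)

    def test_noiseless_branch_exact(self):
        c = self._branch(30.0, 0.0)
        lc, rms, n = fit_branch_wlc(c, (0, len(c) - 1), self.WLC)
        assert lc == pytest.approx(30.0, abs=0.01)
        assert rms < 1e-3

    def test_noisy_branch_within_two_percent(self, rng):
        errs = []
        for _ in range(20):
            c = self._branch(30.0, 8.0, n=300, rng=rng)
            lc, _, _ = fit_branch_wlc(c, (0, len(c) - 1), self.WLC)
            errs.append(abs(lc - 30.0) / 30.0)
        assert max(errs) < 0.02

    def test_short_branch_rejected(self):
        c = self._branch(30.0, 0.0, n=5)
        with pytest.raises(BranchFitError):
            fit_branch_wlc(c, (0, len(c) - 1), self.WLC)


class TestComputeDlc:
    @pytest.mark.parametrize(
        "lcs, expected",
        [
            ([50.0, 68.0], [18.0]),  # marker increment
            ([50.0, 61.6], [11.6]),  # alpha one-step measured mean
            ([40.0], []),
        ],
    )
    def test_increments(self, lcs, expected):
        assert compute_dlc(lcs) == pytest.approx(expected)


def _peak(dlc, force, detach=False):
    return RupturePeak(
        branch_start=0, peak_index=0, rupture_force=force, dlc=dlc,
        is_detachment=detach,
    )


class TestSelectSingleMolecule:
    def test_accept_with_six_markers_and_target(self):
        peaks = [_peak(11.2, 80.0)] + [_peak(18.0, 170.0) for _ in range(6)]
        peaks.append(_peak(None, 390.0, detach=True))
        accepted, targets = select_single_molecule(peaks)
        assert accepted
        assert [p.dlc for p in targets] == [11.2]

    def test_reject_below_marker_count(self):
        peaks = [_peak(18.0, 170.0), _peak(18.0, 165.0)]
        accepted, _ = select_single_molecule(peaks)
        assert not accepted

    def test_apo_accepts_with_empty_target_list(self):
        peaks = [_peak(18.0, 170.0) for _ in range(6)]
        peaks.append(_peak(None, 390.0, detach=True))
        accepted, targets = select_single_molecule(peaks)
        assert accepted and targets == []

    def test_low_force_marker_sized_event_not_attributed_to_target(self):
        peaks = [_peak(17.9, 60.0)] + [_peak(18.0, 170.0) for _ in range(5)]
        accepted, targets = select_single_molecule(peaks)
        assert accepted
        assert targets == []
        assert peaks[0].attribution == "marker_lowforce"

    def test_no_double_attribution(self, analyzed_alpha_batch):
        for _curve, _truth, res in analyzed_alpha_batch[:40]:
            kinds = [p.attribution for p in res.peaks]
            assert all(
                k in (
                    "marker", "marker_lowforce", "target", "detachment",
                    "excluded", "unattributed",
                )
                for k in kinds
            )
            assert kinds.count("detachment") <= 1


class TestPipelineRoundTrip:
    def test_noiseless_recovery_exact(self, alpha_config_noiseless):
        """Simulator -> analyzer fidelity: every resolvable ground-truth
        event is recovered with dLc error < 0.1 nm and no false peaks."""
        n_checked = 0
        for seed in range(25):
            curve, truth = simulate_curve(alpha_config_noiseless, seed)
            res = analyze_curve(curve, estimate_rates=False)
            det = [p for p in res.peaks if not p.is_detachment]
            assert len(det) <= len(truth.events)  # zero false peaks
            resolvable = resolvable_events(truth, alpha_config_noiseless)
            matched = match_in_order([p.dlc for p in det], resolvable, tol=0.1)
            assert len(matched) == len(resolvable)
            n_checked += len(matched)
        assert n_checked > 100

    def test_noisy_marker_increment_fidelity(self, analyzed_alpha_batch):
        dlcs = [
            p.dlc
            for _c, _t, res in analyzed_alpha_batch
            for p in res.peaks
            if p.attribution == "marker"
        ]
        assert len(dlcs) > 400
        assert np.mean(dlcs) == pytest.approx(18.0, abs=0.2)

    def test_acceptance_rate_reasonable(self, analyzed_alpha_batch):
        frac = np.mean([res.accepted for _c, _t, res in analyzed_alpha_batch])
        assert frac > 0.9


class TestSelectionCriteriaValidation:
    def test_empty_marker_window_rejected(self):
        with pytest.raises(ValueError):
            SelectionCriteria(marker_dlc_window=(20.0, 16.0))

    def test_even_smoothing_window_rejected(self):
        with pytest.raises(ValueError):
            SelectionCriteria(smooth_window=10)
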