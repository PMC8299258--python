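"""Shared fixtures: constructs and small simulated datasets.

Everything is generated at test time from seeds; no stored data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from mtforce.curve_analysis import analyze_curve
from mtforce.synthetic import build_construct, simulate_curve


@pytest.fixture(scope="session")
def alpha_config():
    """Marker-flanked Zn-bound alpha-domain construct, default instrument."""
    return build_construct("Zn-aMT")


@pytest.fixture(scope="session")
def alpha_config_noiseless():
    return build_construct("Zn-aMT", {"force_noise_sd": 0.0})


@pytest.fixture(scope="session")
def marker_config():
    """Single GB1 marker, no flanks."""
    return build_construct("GB1x1")


@pytest.fixture(scope="session")
def marker_config_noiseless():
    return build_construct("GB1x1", {"force_noise_sd": 0.0})


@pytest.fixture(scope="session")
def analyzed_alpha_batch(alpha_config):
    """120 simulated + analyzed alpha-domain curves with their truths."""
    out = []
    for seed in range(120):
        curve, truth = simulate_curve(alpha_config, 5000 + seed)
        out.append((curve, truth, analyze_curve(curve, estimate_rates=False)))
    return out


def _post_rupture_drop(force, dlc, lc_before, config):
    """Force drop produced by releasing ``dlc`` at the given rupture force,
    with the cantilever relaxing at fixed piezo position."""
    from scipy.optimize import brentq

    from mtforce.mechanics import wlc_extension, wlc_force

    kc = config.cantilever_stiffness
    x = wlc_extension(force, lc_before, config.wlc)
    z = x + force / kc
    lc_after = lc_before + dlc

    def g(xx):
        return wlc_force(xx, lc_after, config.wlc) - kc * (z - xx)

    x2 = brentq(g, 0.0, min(z, lc_after * (1 - 1e-9)))
    return force - kc * (z - x2)


def resolvable_events(
    truth, config, min_force=23.0, min_drop=15.0, min_separation=33
):
    """Ground-truth events any analyzer of this trace could see.

    Three physical limits of the measurement (not analysis defects) hide an
    event: a rupture below the detection force floor leaves no peak; a
    rupture whose force drop is smaller than the detection threshold leaves
    no prominence; and two ruptures closer than the smoothing scale cannot
    form separate maxima.  Margins above the detector thresholds keep
    borderline events out of the must-recover set.
    """
    lc = config.handle_length + sum(d.folded_extension for d in config.construct)
    visible = []
    for e in truth.events:
        drop = _post_rupture_drop(e.force, e.dlc, lc, config)
        lc += e.dlc
        visible.append(e.force >= min_force and drop >= min_drop)
    # an invisible rupture silently adds its increment to the branch that
    # follows, corrupting the measured dLc of the preceding visible event,
    # so that neighbour cannot be held to exact recovery either
    vis = [
        e
        for i, e in enumerate(truth.events)
        if visible[i] and (i + 1 >= len(visible) or visible[i + 1])
    ]
    out = []
    for i, e in enumerate(vis):
        prev_ok = i == 0 or e.sample_index - vis[i - 1].sample_index >= min_separation
        nxt_ok = (
            i == len(vis) - 1
            or vis[i + 1].sample_index - e.sample_index >= min_separation
        )
        if prev_ok and nxt_ok:
            out.append(e)
    return out


def match_in_order(detected_dlcs, events, tol=0.1):
    """Greedy in-order matching of detected increments to truth events.

    An unmatched event does not consume detections: later events may still
    match detections after the last committed one.
    """
    j = 0
    matched = []
    for e in events:
        for k in range(j, len(detected_dlcs)):
            d = detected_dlcs[k]
            if d is not None and abs(d - e.dlc) <= tol:
                matched.append(e)
                j = k + 1
                break
    return matched


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
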