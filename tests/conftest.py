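import numpy as np
import pytest

from stepcount import MagnitudeSeries, MotionState, WalkSpec, generate_walk


@pytest.fixture(scope="session")
def normal_walk():
    """A clean 60-step normal walk with its ground truth (fixed seed)."""
    return generate_walk(WalkSpec(state=MotionState.NORMAL, n_steps=60, seed=1))


@pytest.fixture(scope="session")
def noisy_normal_walk():
    return generate_walk(WalkSpec(state=MotionState.NORMAL, n_steps=60, noise_sd=0.05, seed=2))


def make_mag(values, fs=50.0, filtered=True):
    """Wrap a plain array as a MagnitudeSeries on a uniform grid."""
    values = np.asarray(values, dtype=float)
    return MagnitudeSeries(t=np.arange(len(values)) / fs, acc=values, fs=fs, filtered=filtered)


@pytest.fixture
def mag_factory():
    return make_mag


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive implementations)

def brute_candidate_indices(acc, d):
    """Scan every interior index; windows clipped at the edges."""
    n = len(acc)
    out = []
    for j in range(1, n - 1):
        left = acc[max(0, j - d) : j]
        right = acc[j + 1 : j + d + 1]
        if all(acc[j] >= v for v in left) and all(acc[j] >= v for v in right):
            out.append(j)
    # keep the higher of any pair within d samples (ties -> earlier)
    kept = []
    for j in out:
        if kept and j - kept[-1] <= d:
            if acc[j] > acc[kept[-1]]:
                kept[-1] = j
        else:
            kept.append(j)
    return kept


def ten_peak_topology():
    """Piecewise-linear signal with seven tall peaks and three shallow bumps.

    Mimics the canonical prominence-analysis example: ten local maxima where
    the 3rd, 6th and 8th sit on the flanks of taller neighbours and have far
    smaller prominence. Returns (values, true_peak_indices, false_peak_indices).
    """
    knots = [
        (0, 1.0), (20, 1.55), (30, 1.0), (40, 1.75), (50, 1.35), (55, 1.43),
        (60, 1.30), (70, 1.0), (80, 1.5), (90, 1.05), (100, 1.6), (108, 1.25),
        (112, 1.34), (116, 1.18), (130, 1.45), (136, 1.20), (142, 1.28),
        (148, 1.12), (160, 1.8), (170, 1.0), (180, 1.5), (200, 1.0),
    ]
    x = np.arange(201)
    y = np.interp(x, [k[0] for k in knots], [k[1] for k in knots])
    true_idx = [20, 40, 80, 100, 130, 160, 180]
    false_idx = [55, 112, 142]
    return y, true_idx, false_idx


def brute_prominence(acc, j, lo, hi):
    """Walk outward sample by sample until a strictly higher value."""
    amp = acc[j]

    def side_min(rng):
        vals = []
        for k in rng:
            if acc[k] > amp:
                break
            vals.append(acc[k])
        return min(vals) if vals else amp

    left_min = side_min(range(j - 1, lo - 1, -1))
    right_min = side_min(range(j + 1, hi + 1))
    return amp - max(left_min, right_min)
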