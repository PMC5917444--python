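"""Shared fixtures: small and full-size synthetic phantoms.

The full-size phantoms (64x64x39x198, the target acquisition geometry)
are expensive, so they are session-scoped; most tests use small-geometry
phantoms, which exercise identical code paths.
"""

import pytest

from coilqc.phantom import PhantomSpec, make_phantom

# thr = 3 separation regime: increment = 15 >= 5*thr, per-voxel
# fluctuation sd = 0.3 <= thr/10
SEPARATION = dict(
    background_sd=0.3,
    noise_amplitude_fraction_of_brain=0.015,  # increment 15 at brain 1000
)


@pytest.fixture(scope="session")
def clean_phantom_full():
    """Clean full-geometry phantom with realistic background jitter."""
    spec = PhantomSpec(noise_fraction_volumes=0.0, seed=11)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom_full():
    """Full-geometry phantom, separation regime, heavy noise load."""
    spec = PhantomSpec(noise_fraction_volumes=0.45, seed=12, **SEPARATION)
    return make_phantom(spec)


@pytest.fixture()
def small_spec():
    return PhantomSpec(n_x=20, n_y=20, n_slices=6, n_volumes=60,
                       noise_fraction_volumes=0.2, seed=5, **SEPARATION)


@pytest.fixture()
def small_phantom(small_spec):
    return make_phantom(small_spec)


def brute_force_detect_slice(series, thr):
    """Literal per-step transcription of the slice detector.

    Kept as a plain-Python loop, independent of the vectorized
    implementation, to serve as its oracle.
    """
    I = [float(v) for v in series]
    N = len(I)
    # step 2.2: successive differences
    delta = [I[n] - I[n - 1] for n in range(1, N)]
    # step 2.3: volumes whose jump exceeds the threshold
    n_p = [n for n in range(1, N) if I[n] - I[n - 1] > thr]
    if n_p:
        # step 2.4: minimum noisy level among the jump targets
        min_noise = min(I[n] for n in n_p)
        below = [I[n] for n in range(N) if I[n] < min_noise]
        if not below:
            return [True] * N
        # step 2.5: robust background estimate
        i_bg = _median(below)
    else:
        i_bg = _median(I)
    # step 2.6: flag volumes above background + threshold
    return [I[n] - i_bg > thr for n in range(N)]


def _median(xs):
    s = sorted(xs)
    n = len(s)
    if n % 2 == 1:
        return s[n // 2]
    return 0.5 * (s[n // 2 - 1] + s[n // 2])
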