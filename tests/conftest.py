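import numpy as np
import pytest

from stereocount.geometry import Spheroid


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_spheroid(rng, id=1, center_lo=0.0, center_hi=50.0, ax_lo=0.5, ax_hi=8.0):
    c = rng.uniform(center_lo, center_hi, size=3)
    a = rng.uniform(ax_lo, ax_hi, size=3)
    return Spheroid(id=id, center=tuple(c), semi_axes=tuple(a))


def sample_in_spheroid(rng, s: Spheroid, n: int) -> np.ndarray:
    """n points uniform in the closed spheroid (ball transform)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.uniform(0.0, 1.0, size=(n, 1)) ** (1.0 / 3.0)
    return np.asarray(s.center) + v * r * np.asarray(s.semi_axes)


def torus_field(rng, n, L, semi_axes, reach):
    """Spheroids uniform on an L-torus, materialised with ghost copies so a
    probe of extent < reach anywhere in [0, L)^3 sees the periodic field.

    ``semi_axes`` may be a single triple or an (n, 3) array per particle.
    """
    C = rng.uniform(0.0, L, size=(n, 3))
    axes = np.asarray(semi_axes, dtype=float)
    if axes.ndim == 1:
        axes = np.tile(axes, (n, 1))
    parts = []
    pid = 1
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                Cs = C + np.array([i, j, k]) * L
                keep = np.all((Cs > -reach) & (Cs < L + reach), axis=1)
                for c, a in zip(Cs[keep], axes[keep]):
                    parts.append(Spheroid(id=pid, center=tuple(c), semi_axes=tuple(a)))
                    pid += 1
    return parts
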