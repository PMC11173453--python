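"""Finite-difference helpers used as independent oracles in the tests."""

import numpy as np


def fd_gradient(energy_fn, x, h=1e-6):
    """Central-difference gradient of a scalar function of (N, dim) positions."""
    x = np.asarray(x, float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        g[idx] = (float(energy_fn(xp)) - float(energy_fn(xm))) / (2 * h)
    return g


def fd_surface_gradient(surface, x, h=1e-6):
    return fd_gradient(lambda y: surface.energy(y), x, h)
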