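"""Brute-force explicit finite-difference oracle for dC/dt = D lap(C) - k C.

Independent of the package's closed-form evaluation: starts from the
analytic field at an early time (a matched point-source release) and steps
forward with a 7-point FTCS stencil and zero Dirichlet boundaries.  Used
only to cross-check the closed form on coarse grids.
"""

import numpy as np


def fd_evolve(c0: np.ndarray, D: float, k: float, dx: float, t_span: float, dt_max: float | None = None) -> np.ndarray:
    """Advance a concentration volume by ``t_span`` seconds."""
    dt_stable = dx * dx / (6.0 * D) * 0.5
    dt = min(dt_stable, dt_max or dt_stable)
    n_steps = int(np.ceil(t_span / dt))
    dt = t_span / n_steps
    c = c0.copy()
    coef = D * dt / (dx * dx)
    for _ in range(n_steps):
        lap = (
            np.roll(c, 1, 0) + np.roll(c, -1, 0)
            + np.roll(c, 1, 1) + np.roll(c, -1, 1)
            + np.roll(c, 1, 2) + np.roll(c, -1, 2)
            - 6.0 * c
        )
        c = c + coef * lap - k * dt * c
        # zero Dirichlet boundary (tracer has not reached the box edge)
        c[0, :, :] = c[-1, :, :] = 0.0
        c[:, 0, :] = c[:, -1, :] = 0.0
        c[:, :, 0] = c[:, :, -1] = 0.0
    return c
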