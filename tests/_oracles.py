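"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: the rigid-fit oracle
searches SE(3) by brute force instead of solving in closed form, and the
Euler oracle multiplies hand-written axis matrices instead of calling any
rotation library.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def euler_xyz_matrix(rx_deg, ry_deg, rz_deg):
    """R = Rx @ Ry @ Rz from explicitly written single-axis matrices."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def _rigid_cost(params, src, dst):
    R = euler_xyz_matrix(*params[:3])
    return float(np.sum((src @ R.T + params[3:] - dst) ** 2))


def brute_force_rigid_rms(src, dst, rot_span_deg=30.0, n_grid=7):
    """Minimum RMS residual of a rigid fit found by a dense Euler-angle /
    translation grid followed by Nelder-Mead refinement."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    angles = np.linspace(-rot_span_deg, rot_span_deg, n_grid)
    t0 = dst.mean(axis=0) - src.mean(axis=0)
    best, best_p = np.inf, None
    for rx, ry, rz in itertools.product(angles, repeat=3):
        p = np.array([rx, ry, rz, *t0])
        c = _rigid_cost(p, src, dst)
        if c < best:
            best, best_p = c, p
    res = minimize(_rigid_cost, best_p, args=(src, dst), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20000,
                            "maxfev": 40000})
    res = minimize(_rigid_cost, res.x, args=(src, dst), method="Nelder-Mead",
                   options={"xatol": 1e-13, "fatol": 1e-18, "maxiter": 20000,
                            "maxfev": 40000})
    return float(np.sqrt(res.fun / len(src)))
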