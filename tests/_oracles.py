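"""Independent numeric oracles used by the test suite.

These deliberately avoid the code paths they check: the rotation search
below minimises RMSD by brute force over orientation space (coarse Euler
grid followed by Nelder-Mead refinement) instead of the closed-form
Kabsch solution.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def rotation_search_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimal RMSD over rigid motions, by grid search + simplex refinement."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def rmsd_of(euler):
        R = Rotation.from_euler("zyx", euler).as_matrix()
        d = Pc - Qc @ R.T
        return float(np.sqrt((d ** 2).sum() / len(P)))

    grid = np.deg2rad(np.arange(0, 360, 30))
    half = np.deg2rad(np.arange(-90, 91, 30))
    best = min(
        itertools.product(grid, half, grid),
        key=lambda e: rmsd_of(e),
    )
    res = minimize(rmsd_of, np.array(best), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)
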