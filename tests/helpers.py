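"""Independent oracles used by both the unit and acceptance suites.

These deliberately avoid the package's own code paths: the partial
correlation oracle solves the normal equations explicitly, and the loop
vector potential oracle is the closed-form elliptic-integral expression.
"""

import numpy as np
from scipy.special import ellipe, ellipk


def partial_corr_oracle(seed: np.ndarray, vertex: np.ndarray,
                        covariate: np.ndarray) -> float:
    """Residual Pearson correlation via explicit normal equations."""
    t = seed.shape[0]
    x = np.column_stack([np.ones(t), covariate])
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = x @ xtx_inv @ x.T
    rs = seed - hat @ seed
    rv = vertex - hat @ vertex
    return float((rs @ rv) / np.sqrt((rs @ rs) * (rv @ rv)))


def loop_a_phi_exact(radius: float, rho: float, z: float) -> float:
    """Closed-form azimuthal vector potential (T*m per ampere) of a circular
    current loop of the given radius, at cylindrical position (rho, z).
    Lengths may be in any single consistent unit."""
    k2 = 4.0 * radius * rho / ((radius + rho) ** 2 + z**2)
    k = np.sqrt(k2)
    mu0_over_pi = 4e-7
    return (mu0_over_pi / k) * np.sqrt(radius / rho) * (
        (1.0 - k2 / 2.0) * ellipk(k2) - ellipe(k2)
    )


def brute_force_nearest(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-point index per vertex; ties to the lowest index."""
    d = np.linalg.norm(vertices[:, None, :] - points[None, :, :], axis=2)
    return d.argmin(axis=1)  # argmin returns the first (lowest) index on ties
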