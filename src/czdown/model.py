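"""Cubic bistable state model: equilibria, folds and linearized relaxation times.

The latent state ``z`` obeys

    dz/dt = -z^3 + 1e-3 * r * z + 1e-3 * k

where ``r`` shapes the fold geometry and ``k`` is the slow drive.  All
functions here are closed-form; the stochastic integrator lives in
:mod:`czdown.synthetic`.
"""

from __future__ import annotations

import numpy as np

#: scaling applied to both the linear term and the drive of the cubic
A_SCALE = 1.0e-3


class InvalidParameterError(ValueError):
    """Raised when model parameters admit no valid solution."""


def drift(z, r: float, k) -> np.ndarray:
    """Deterministic right-hand side of the state equation."""
    z = np.asarray(z, dtype=float)
    return -z ** 3 + A_SCALE * r * z + A_SCALE * np.asarray(k, dtype=float)


def drift_dz(z, r: float) -> np.ndarray:
    """Derivative of the drift with respect to the state."""
    z = np.asarray(z, dtype=float)
    return -3.0 * z ** 2 + A_SCALE * r


def critical_point(r: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Both saddle-node folds of the cubic, as ``((z*, k*), (-z*, -k*))``.

    At each fold the drift and its state-derivative vanish simultaneously:
    ``z* = sqrt(1e-3 * r / 3)`` and ``k* = 1e3 * z*^3 - r * z*``.

    Parameters
    ----------
    r : float
        Bifurcation-shape parameter; must be positive, otherwise the
        cubic is monotone and no fold exists.
    """
    if r <= 0:
        raise InvalidParameterError(f"no fold exists for r={r!r}; r must be > 0")
    z_star = float(np.sqrt(A_SCALE * r / 3.0))
    k_star = float(z_star ** 3 / A_SCALE - r * z_star)
    return ((z_star, k_star), (-z_star, -k_star))


def linearized_time_constant(z_eq: float, r: float) -> float:
    """Relaxation time ``tau = 1 / |f'(z_eq)|`` of the linearized system.

    Only defined at stable equilibria (``f'(z_eq) < 0``); diverges as the
    equilibrium approaches a fold.
    """
    d = float(drift_dz(z_eq, r))
    if d >= 0:
        raise InvalidParameterError(
            f"equilibrium z={z_eq!r} is not stable for r={r!r} "
            f"(f'={d!r} >= 0); time constant is non-finite"
        )
    return 1.0 / abs(d)


def equilibria(r: float, k) -> np.ndarray:
    """Real equilibria of the cubic for scalar ``r`` and scalar ``k``.

    Returns the real roots sorted ascending (1 or 3 of them).
    """
    roots = np.roots([1.0, 0.0, -A_SCALE * r, -A_SCALE * float(k)])
    real = roots[np.abs(roots.imag) < 1e-9 * max(1.0, np.abs(roots).max())].real
    return np.sort(real)


def _cubic_three_roots(r: float, k: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized real roots of ``z^3 - a z - b = 0`` (a = 1e-3 r, b = 1e-3 k).

    Valid where three real roots exist; entries beyond the folds are NaN.
    Returns (lower, middle, upper) root arrays.
    """
    a = A_SCALE * r
    b = A_SCALE * np.asarray(k, dtype=float)
    # depressed cubic t^3 + p t + q with p = -a, q = -b
    p = -a
    q = -b
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3
    m = 2.0 * np.sqrt(-p / 3.0)
    with np.errstate(invalid="ignore"):
        arg = np.clip(3.0 * b / (a * m), -1.0, 1.0)
        theta = np.arccos(arg)
        roots = np.stack(
            [m * np.cos((theta - 2.0 * np.pi * j) / 3.0) for j in range(3)]
        )
    roots = np.sort(roots, axis=0)
    bad = disc >= 0
    roots[:, bad] = np.nan
    return roots[0], roots[1], roots[2]


def stable_branches(r: float, k) -> tuple[np.ndarray, np.ndarray]:
    """Lower and upper stable equilibrium branches over a drive array.

    Where the lower (upper) branch has been annihilated at a fold, the
    remaining single stable equilibrium is returned for both entries.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    lower, _, upper = _cubic_three_roots(r, k)
    only = np.isnan(lower)
    if np.any(only):
        # single-root regime beyond a fold: Cardano, vectorized
        a = A_SCALE * r
        b = A_SCALE * k[only]
        p, q = -a, -b
        s = np.sqrt((q / 2.0) ** 2 + (p / 3.0) ** 3)
        root = np.cbrt(-q / 2.0 + s) + np.cbrt(-q / 2.0 - s)
        lower[only] = root
        upper[only] = root
    return lower, upper


def unstable_branch(r: float, k) -> np.ndarray:
    """Unstable (middle) branch over a drive array.

    Beyond the folds no unstable equilibrium exists; the fold state value
    is substituted so that upward-crossing detection remains continuous.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    _, middle, _ = _cubic_three_roots(r, k)
    (z_star, k_fold_neg), (z_star_neg, k_fold_pos) = critical_point(r)
    # drive beyond +fold removed the lower branch: threshold -> -z*; beyond
    # -fold removed the upper branch: threshold -> +z*
    middle = np.where(np.isnan(middle) & (k >= 0), z_star_neg, middle)
    middle = np.where(np.isnan(middle) & (k < 0), z_star, middle)
    return middle
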