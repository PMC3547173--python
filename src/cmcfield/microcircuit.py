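"""The four-population canonical microcircuit as a point (neural-mass) model.

The expected depolarisation V of the four populations obeys the second-order
convolution dynamics

    V'' + 2 B V' + B^2 V = A B . D sigma(V) + G u(t),

with A = diag(m_e, m_i, m_e, m_e), B = diag(kappa_1..kappa_4) and a signed
connectivity map D.  The mass model is the delay-free (infinite conduction
speed) limit of the field model, in which the spatial kernels enter only
through their integral over space.
"""

from __future__ import annotations

import numpy as np

from .params import FieldParameters, MicrocircuitParameters

__all__ = [
    "sigmoid",
    "sigmoid_gain",
    "steady_state",
    "mass_transfer",
    "InstabilityError",
    "FixedPointError",
]


class InstabilityError(ArithmeticError):
    """The linearized system matrix is singular on the real frequency axis."""

    def __init__(self, message, omega=None):
        super().__init__(message)
        self.omega = omega


class FixedPointError(ArithmeticError):
    """Damped fixed-point iteration failed to converge."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def sigmoid(v, params: MicrocircuitParameters):
    """Population firing rate in (0, 1) as a function of depolarisation (mV).

    sigma(v) = 1 / (1 + exp(r (eta - v))); strictly increasing, with
    inflection at v = eta.  Evaluated in a saturation-safe form.
    """
    z = params.r * (params.eta - np.asarray(v, dtype=float))
    out = 1.0 / (1.0 + np.exp(np.clip(z, -700.0, 700.0)))
    return out if np.ndim(v) else float(out)


def sigmoid_gain(params: MicrocircuitParameters) -> float:
    """Gain of the depolarisation-to-rate mapping at v = 0 (1/mV).

    gamma = r exp(r eta) / (1 + exp(r eta))^2, the derivative of the sigmoid
    at the origin; for eta = 0 this is r/4.
    """
    e = np.exp(params.r * params.eta)
    return params.r * e / (1.0 + e) ** 2


def sigmoid_slope_at(v, params: MicrocircuitParameters):
    """Derivative of the sigmoid at an arbitrary depolarisation v (1/mV)."""
    s = sigmoid(v, params)
    return params.r * s * (1.0 - s)


def steady_state(params: MicrocircuitParameters,
                 total_connectivity: np.ndarray,
                 damping: float = 0.5,
                 max_iter: int = 10_000,
                 tol: float = 1e-10) -> np.ndarray:
    """Spatially homogeneous fixed point of the mass dynamics (mV).

    Solves V0 = B^-1 A . D0 sigma(V0) by damped fixed-point iteration,
    polished by Newton steps once the iteration is in the basin (the damped
    map alone converges only linearly, with a rate that can approach one for
    strongly coupled circuits).  ``total_connectivity`` D0 is the signed
    spatial integral of the kernels.

    Raises
    ------
    FixedPointError
        If the residual norm does not fall below ``tol``; the exception
        carries the last iterate.
    """
    D0 = np.asarray(total_connectivity, dtype=float)
    gain = params.m / np.asarray(params.kappa)  # B^-1 A diagonal
    v = np.zeros(4)
    for _ in range(max_iter):
        target = gain * (D0 @ sigmoid(v, params))
        v_new = (1.0 - damping) * v + damping * target
        if np.max(np.abs(v_new - v)) < 1e-3 * max(1.0, np.max(np.abs(v_new))):
            v = v_new
            break
        v = v_new
    # Newton polish on  f(v) = v - gain * D0 sigma(v)
    for _ in range(50):
        s = sigmoid(v, params)
        residual = v - gain * (D0 @ s)
        if np.linalg.norm(residual) < 0.1 * tol:
            break
        jac = np.eye(4) - (gain[:, None] * D0) * (params.r * s * (1.0 - s))[None, :]
        try:
            step = np.linalg.solve(jac, residual)
        except np.linalg.LinAlgError:
            break
        v = v - step
    residual = v - gain * (D0 @ sigmoid(v, params))
    if np.linalg.norm(residual) >= tol:
        raise FixedPointError(
            f"fixed point not converged (residual {np.linalg.norm(residual):.3e})",
            last_iterate=v,
        )
    return v


def system_matrix(omega, params: MicrocircuitParameters, D, gamma=None) -> np.ndarray:
    """M(omega) = -omega^2 I - 2 i omega B + B^2 - A B D diag(gamma), broadcasting.

    ``D`` is a (..., 4, 4) signed connectivity map (constant for the mass
    model, a transform evaluated per grid point for the field model).
    ``gamma`` is the firing-rate gain at the linearization point -- the
    sigmoid slope at v = 0 by default, or an explicit scalar / per-population
    4-vector (e.g. the slope at a nonzero steady state).
    """
    omega = np.asarray(omega, dtype=float)
    if gamma is None:
        gamma = sigmoid_gain(params)
    gamma_vec = np.broadcast_to(np.asarray(gamma, dtype=float), (4,))
    B = params.B
    AB = np.diag(params.m * np.asarray(params.kappa))
    D = np.asarray(D, dtype=complex)
    eye = np.eye(4)
    om = omega[..., None, None]
    return (-om ** 2) * eye - 2j * om * B + (B @ B) - AB @ (D * gamma_vec)


def mass_transfer(params: MicrocircuitParameters,
                  omega,
                  total_connectivity: np.ndarray,
                  gamma=None) -> np.ndarray:
    """Neural-mass transfer function T(omega), shape ``omega.shape + (4,)``.

    T(omega) = (-omega^2 I - 2 i omega B + B^2 - A B D0 gamma)^-1 G, the
    delay-free limit of the field transfer function.  ``omega`` is angular
    temporal frequency in rad/ms.

    Raises
    ------
    InstabilityError
        If the system matrix is singular at some frequency; the exception
        carries the offending omega.
    """
    omega = np.asarray(omega, dtype=float)
    M = system_matrix(omega, params, np.asarray(total_connectivity, dtype=complex),
                      gamma=gamma)
    rhs = np.broadcast_to(params.G.astype(complex), M.shape[:-1]).copy()
    try:
        T = np.linalg.solve(M, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        bad = _first_singular_omega(M, omega)
        raise InstabilityError("singular system matrix", omega=bad) from None
    if not np.all(np.isfinite(T)):
        bad = _first_singular_omega(M, omega)
        raise InstabilityError("non-finite transfer values", omega=bad)
    return T


def _first_singular_omega(M, omega):
    dets = np.linalg.det(M)
    bad = np.argmin(np.abs(np.atleast_1d(dets)))
    return np.atleast_1d(omega).ravel()[bad] if np.ndim(omega) else float(omega)


def linear_eigenvalues(params: MicrocircuitParameters,
                       total_connectivity: np.ndarray,
                       gamma=None) -> np.ndarray:
    """Eigenvalues (1/ms) of the linearized mass dynamics.

    Returns the 8 eigenvalues of the first-order companion form of
    V'' + 2 B V' + (B^2 - A B D0 diag(gamma)) V = 0.  The linearization is
    exponentially stable iff all real parts are negative; an unstable point
    still has a well-defined transfer function on the real frequency axis,
    but no stationary time-domain realisation by direct integration.
    """
    if gamma is None:
        gamma = sigmoid_gain(params)
    gamma_vec = np.broadcast_to(np.asarray(gamma, dtype=float), (4,))
    B = params.B
    AB = np.diag(params.m * np.asarray(params.kappa))
    Jlin = AB @ (np.asarray(total_connectivity, dtype=float) * gamma_vec)
    top = np.block([[np.zeros((4, 4)), np.eye(4)],
                    [Jlin - B @ B, -2.0 * B]])
    return np.linalg.eigvals(top)


def simulate_mass_timeseries(params: MicrocircuitParameters,
                             total_connectivity: np.ndarray,
                             duration_ms: float,
                             dt_ms: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Euler-Maruyama integration of the linearized mass dynamics.

    Drives the linearized system (about v = 0) with discretized white noise
    of unit two-sided spectral density (in ms units) through the input gain
    G and returns the 4 x n_steps depolarisation array.  Serves as an
    independent time-domain oracle for the transfer-function spectrum.
    """
    from scipy.signal import lfilter

    n = int(round(duration_ms / dt_ms))
    gamma = sigmoid_gain(params)
    B2 = params.B @ params.B
    AB = np.diag(params.m * np.asarray(params.kappa))
    Jlin = gamma * (AB @ np.asarray(total_connectivity, dtype=float))
    # first-order companion form and explicit-Euler one-step matrix
    A_c = np.block([[np.zeros((4, 4)), np.eye(4)],
                    [Jlin - B2, -2.0 * params.B]])
    Ad = np.eye(8) + dt_ms * A_c
    bd = dt_ms * np.concatenate([np.zeros(4), params.G])
    noise = rng.standard_normal(n) * np.sqrt(1.0 / dt_ms)
    # modal decomposition turns the 8-dim AR(1) recursion into scalar
    # first-order filters, evaluated in compiled code
    lam, W = np.linalg.eig(Ad)
    coef = np.linalg.solve(W, bd)
    out = np.zeros((4, n))
    for i in range(8):
        z = lfilter([0.0, coef[i]], [1.0, -lam[i]], noise)
        out += np.real(W[:4, i:i + 1] * z[None, :])
    return out
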