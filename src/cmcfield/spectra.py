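"""Field transfer function, lead field and predicted single-channel spectra.

The predicted power at a virtual electrode over a bounded cortical patch is
a lead-field-weighted sum over discrete spatial frequencies,

    g(omega) = sum_k |L(k, phi)|^2 |q . T(k, omega)|^2 g_u(omega),

where T(k, omega) is the 4-vector transfer function from endogenous input to
population depolarisations, L a Gaussian lead-field gain and g_u the
(spatially white) input spectrum.  The observed spectrum adds a channel-noise
curve g_n(omega).  Two independent routes to T are provided: a direct 4x4
matrix inversion and an exact closed form obtained by cofactor expansion of
the system matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import kernels, microcircuit
from .params import (FieldParameters, MicrocircuitParameters, ObservationModel,
                     cycles_to_angular, hz_to_angular, with_scaled)

__all__ = [
    "SpectralData",
    "transfer_matrix",
    "closed_form_SR",
    "spatial_grid",
    "lead_field_coefficients",
    "input_and_noise_spectra",
    "sensor_spectrum",
    "predict_observed_spectrum",
    "contribution_sweep",
]


@dataclass
class SpectralData:
    """A single-channel power spectrum: the unit of model fitting.

    ``freqs`` are strictly increasing temporal frequencies in Hz and
    ``power`` the matching non-negative real power values.
    """

    freqs: np.ndarray
    power: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.ndim != 1 or self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and non-negative")

    # -- textual round-trip ------------------------------------------------
    def to_csv(self, path, sep=","):
        df = pd.DataFrame({"frequency_hz": self.freqs, "power": self.power})
        # default float repr is the shortest exact representation
        df.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path, label=None):
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        cols = {c.strip().lower(): c for c in df.columns}
        if "frequency_hz" not in cols or "power" not in cols:
            raise ValueError(
                f"{path}: expected columns frequency_hz, power; got {list(df.columns)}"
            )
        return cls(df[cols["frequency_hz"]].to_numpy(),
                   df[cols["power"]].to_numpy(),
                   label=label if label is not None else path.stem)

    def to_json(self, path):
        payload = {"label": self.label,
                   "frequency_hz": self.freqs.tolist(),
                   "power": self.power.tolist()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path):
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["frequency_hz"]),
                   np.asarray(payload["power"]),
                   label=payload.get("label", ""))


DEFAULT_FREQS_HZ = np.arange(30.0, 81.0, 1.0)


# ---------------------------------------------------------------------------
# Transfer function: matrix route and closed-form route

def transfer_matrix(kappa, omega,
                    params: MicrocircuitParameters,
                    field: FieldParameters,
                    connectivity=None,
                    gamma=None) -> np.ndarray:
    """Field transfer function T(kappa, omega) by direct matrix inversion.

    ``kappa`` (rad/mm) and ``omega`` (rad/ms) broadcast; the result has the
    broadcast shape plus a trailing population axis of length 4.  The signed
    connectivity transform is assembled from the kernels unless an explicit
    ``connectivity`` map of matching shape is supplied.
    """
    kappa, omega = np.broadcast_arrays(
        np.asarray(kappa, dtype=float), np.asarray(omega, dtype=float)
    )
    if connectivity is None:
        D = kernels.connectivity_transform(kappa, omega, params, field)
    else:
        D = np.broadcast_to(np.asarray(connectivity, dtype=complex),
                            kappa.shape + (4, 4))
    M = microcircuit.system_matrix(omega, params, D, gamma=gamma)
    rhs = np.broadcast_to(params.G.astype(complex), M.shape[:-1]).copy()
    try:
        T = np.linalg.solve(M, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        raise microcircuit.InstabilityError(
            "singular system matrix on the (k, omega) grid") from None
    if not np.all(np.isfinite(T)):
        raise microcircuit.InstabilityError("non-finite transfer values")
    return T


def closed_form_SR(kappa, omega,
                   params: MicrocircuitParameters,
                   field: FieldParameters,
                   gamma=None) -> np.ndarray:
    """Field transfer function via the exact closed form T_a = kappa_1 m_e S_a / R.

    R is the determinant of the system matrix and S_a its first-row
    cofactors, written out for the microcircuit's sparsity pattern:

        Q_a  = -kappa_a^2 + gamma (D_aa^i + D_aa^e) kappa_a m_a
               + 2 i kappa_a omega + omega^2          (minus the diagonal of M)
        V_ab = D_ab D_ba gamma^2 kappa_a kappa_b m_a m_b

        R  = -V14 (-V23 + Q2 Q3) + Q4 [-V23 Q1 + Q3 (-V12 + Q1 Q2)]
        S1 = -Q4 (-V23 + Q2 Q3)
        S2 = D21 gamma kappa_2 m_i Q3 Q4
        S3 = -D21 D32 gamma^2 kappa_2 kappa_3 m_e m_i Q4
        S4 = D41 gamma kappa_4 m_e (-V23 + Q2 Q3)

    Every D factor carries the connection sign of the microcircuit (so each
    coupled pair contributes V_ab with a net negative product); under that
    convention this route agrees with :func:`transfer_matrix` to machine
    precision.
    """
    kappa, omega = np.broadcast_arrays(
        np.asarray(kappa, dtype=float), np.asarray(omega, dtype=float)
    )
    ups = field.upsilon
    if gamma is None:
        gamma = microcircuit.sigmoid_gain(params)
    gam = np.broadcast_to(np.asarray(gamma, dtype=float), (4,))
    kap = np.asarray(params.kappa)
    m = params.m

    Di = {
        p: kernels.SIGNS[p] * kernels.intrinsic_ft(
            kappa, omega, params.a[p], field.c[p], ups)
        for p in kernels.INTRINSIC_PAIRS
    }
    De = {i: kernels.extrinsic_ft(kappa, omega, field.c[(i, i)], field.h, ups)
          for i in range(1, 5)}

    Q = {}
    for i in range(1, 5):
        Q[i] = (-kap[i - 1] ** 2
                + gam[i - 1] * (Di[(i, i)] + De[i]) * kap[i - 1] * m[i - 1]
                + 2j * kap[i - 1] * omega + omega ** 2)

    def V(i, j):
        return (Di[(i, j)] * Di[(j, i)] * gam[i - 1] * gam[j - 1]
                * kap[i - 1] * kap[j - 1] * m[i - 1] * m[j - 1])

    V14, V23, V12 = V(1, 4), V(2, 3), V(1, 2)
    core = -V23 + Q[2] * Q[3]
    R = -V14 * core + Q[4] * (-V23 * Q[1] + Q[3] * (-V12 + Q[1] * Q[2]))
    if np.any(np.abs(R) < 1e-300):
        raise microcircuit.InstabilityError("pole of the closed-form transfer (R = 0)")
    S1 = -Q[4] * core
    S2 = Di[(2, 1)] * gam[0] * kap[1] * params.m_i * Q[3] * Q[4]
    S3 = (-Di[(2, 1)] * Di[(3, 2)] * gam[0] * gam[1]
          * kap[1] * kap[2] * params.m_e * params.m_i * Q[4])
    S4 = Di[(4, 1)] * gam[0] * kap[3] * params.m_e * core
    S = np.stack([S1, S2, S3, S4], axis=-1)
    return params.kappa[0] * params.m_e * S / R[..., None]


# ---------------------------------------------------------------------------
# Lead field and spatial grid

def spatial_grid(obs: ObservationModel, field: FieldParameters) -> np.ndarray:
    """Symmetric discrete spatial-frequency grid k_n = n / L_patch (cycles/mm).

    The truncation order is ``obs.k_order`` if set; otherwise the smallest N
    for which the lead-field weight at |k_N| falls below ``obs.k_tol``.
    """
    if obs.k_order is not None:
        N = int(obs.k_order)
    else:
        phi_mm = obs.phi_mm(field)
        # e^{-2 pi^2 phi^2 k^2} < tol  =>  k > sqrt(ln(1/tol) / (2 pi^2)) / phi
        k_max = np.sqrt(np.log(1.0 / obs.k_tol) / (2.0 * np.pi ** 2)) / phi_mm
        N = max(1, int(np.ceil(k_max * field.L_patch)))
    return np.arange(-N, N + 1) / field.L_patch


def lead_field_coefficients(phi_mm: float, k_grid_cycles) -> np.ndarray:
    """Gaussian lead-field gain L(k, phi) = exp(-2 pi^2 phi^2 k^2).

    ``phi_mm`` is the dispersion in mm and ``k_grid_cycles`` the spatial
    frequencies in cycles/mm; the gain is 1 at k = 0 and even in k.
    """
    if phi_mm <= 0:
        raise ValueError("lead-field dispersion must be positive")
    k = np.asarray(k_grid_cycles, dtype=float)
    return np.exp(-2.0 * np.pi ** 2 * phi_mm ** 2 * k ** 2)


# ---------------------------------------------------------------------------
# Input / channel-noise spectra and the predicted sensor spectrum

def input_and_noise_spectra(freqs_hz, obs: ObservationModel):
    """Input spectrum g_u(f) and channel-noise spectrum g_n(f) on the grid.

    Both are mixtures of a white floor and a coloured component; the default
    colour law is ``alpha + beta / f`` and the literal linear-in-omega law
    ``alpha + beta * omega`` (omega in rad/ms) is selectable via
    ``obs.colour``.  Raises if either curve goes negative on the grid.
    """
    f = np.asarray(freqs_hz, dtype=float)
    if obs.colour == "one_over_f":
        with np.errstate(divide="ignore"):
            shape = np.where(f > 0, 1.0 / np.where(f > 0, f, 1.0), 0.0)
        g_u = obs.alpha_u + obs.beta_u * shape
        g_n = obs.alpha_n + obs.beta_n * shape
    else:
        omega = hz_to_angular(f)
        g_u = obs.alpha_u + obs.beta_u * omega
        g_n = obs.alpha_n + obs.beta_n * omega
    if np.any(g_u < 0) or np.any(g_n < 0):
        raise ValueError("input/noise spectral coefficients yield negative power")
    return g_u, g_n


def sensor_spectrum(freqs_hz,
                    params: MicrocircuitParameters,
                    field: FieldParameters,
                    obs: ObservationModel,
                    route: str = "matrix",
                    gamma=None) -> SpectralData:
    """Neural component of the predicted single-channel power spectrum.

    Sums |L|^2 |q . T|^2 g_u over the symmetric spatial-frequency grid.
    ``route`` selects the transfer-function evaluation ("matrix" or
    "closed_form"); the two agree to machine precision.
    """
    f = np.asarray(freqs_hz, dtype=float)
    omega = hz_to_angular(f)
    k_cyc = spatial_grid(obs, field)
    L2 = lead_field_coefficients(obs.phi_mm(field), k_cyc) ** 2
    kap = cycles_to_angular(k_cyc)
    if route == "matrix":
        T = transfer_matrix(kap[:, None], omega[None, :], params, field,
                            gamma=gamma)
    elif route == "closed_form":
        T = closed_form_SR(kap[:, None], omega[None, :], params, field,
                           gamma=gamma)
    else:
        raise ValueError(f"unknown route {route!r}")
    qT = np.einsum("a,kwa->kw", np.asarray(obs.q, dtype=float), T)
    g_u, _ = input_and_noise_spectra(f, obs)
    g = np.einsum("k,kw->w", L2, np.abs(qT) ** 2) * g_u
    return SpectralData(f, g, label="neural")


def mass_spectrum(freqs_hz,
                  params: MicrocircuitParameters,
                  field: FieldParameters,
                  obs: ObservationModel,
                  gamma=None) -> SpectralData:
    """Neural spectrum of the mass (delay-free, point-source) variant.

    Uses the neural-mass transfer function with the spatially integrated
    connectivity; equivalent to the field prediction with upsilon = 0 and
    the lead field concentrated at k = 0.
    """
    f = np.asarray(freqs_hz, dtype=float)
    omega = hz_to_angular(f)
    D0 = kernels.total_connectivity(params, field)
    T = microcircuit.mass_transfer(params, omega, D0, gamma=gamma)
    qT = T @ np.asarray(obs.q, dtype=float)
    g_u, _ = input_and_noise_spectra(f, obs)
    return SpectralData(f, np.abs(qT) ** 2 * g_u, label="neural-mass")


def predict_observed_spectrum(freqs_hz,
                              params: MicrocircuitParameters,
                              field: FieldParameters,
                              obs: ObservationModel,
                              variant: str = "field",
                              route: str = "matrix",
                              gamma=None) -> SpectralData:
    """Noiseless expectation of the observed spectrum: neural + channel noise."""
    if variant == "field":
        neural = sensor_spectrum(freqs_hz, params, field, obs, route=route,
                                 gamma=gamma)
    elif variant == "mass":
        neural = mass_spectrum(freqs_hz, params, field, obs, gamma=gamma)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    _, g_n = input_and_noise_spectra(neural.freqs, obs)
    return SpectralData(neural.freqs, neural.power + g_n, label="predicted")


def contribution_sweep(parameter_name: str,
                       log_scalings,
                       params: MicrocircuitParameters,
                       field: FieldParameters,
                       obs: ObservationModel,
                       freqs_hz=None,
                       variant: str = "field") -> list[SpectralData]:
    """Predicted spectra as one named parameter sweeps a log-scaling range.

    ``parameter_name`` accepts any flat parameter name or the group aliases
    ``c_diag``, ``c_off``, ``c_all``, ``a_all``.  Deterministic; one
    spectrum per scaling, labelled with the scaling value.
    """
    if freqs_hz is None:
        freqs_hz = DEFAULT_FREQS_HZ
    out = []
    for s in log_scalings:
        p2, f2, o2 = with_scaled(params, field, obs, {parameter_name: float(s)})
        spec = predict_observed_spectrum(freqs_hz, p2, f2, o2, variant=variant)
        spec.label = f"{parameter_name}={s:+.3f}"
        out.append(spec)
    return out
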