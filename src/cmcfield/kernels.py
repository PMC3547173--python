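"""Spatial connectivity kernels and their delay-aware Fourier transforms.

Two kernel families couple the cortical sheet.  Interlaminar (intrinsic)
connections decay exponentially with distance,

    k_ab(x) = (1/2) a_ab exp(-c_ab |x|),

while horizontal intra-laminar (extrinsic) connections are patchy, with
non-central peaks at the column separation +-h,

    k_aa(x) = (1/2) c_aa [exp(-c_aa |x - h|) + exp(-c_aa |x + h|)].

The extrinsic kernel is normalised so each displaced exponential integrates
to one (total mass 2), independent of the intrinsic amplitudes.

Spikes propagate laterally with inverse speed ``upsilon`` (ms/mm), so the
spatiotemporal coupling is k(x) delta(t - |x| upsilon).  With the transform
convention  FT[u] = integral u(x, t) exp(-i kappa x + i omega t) dx dt  the
delayed kernels transform to

    D(kappa, omega) = integral k(x) exp(i omega upsilon |x|) exp(-i kappa x) dx,

for which this module provides exact closed forms (``kappa`` in rad/mm,
``omega`` in rad/ms).  All functions broadcast over array arguments.
"""

from __future__ import annotations

import numpy as np

from .params import INTRINSIC_PAIRS, SIGNS, FieldParameters, MicrocircuitParameters

__all__ = [
    "intrinsic_kernel",
    "extrinsic_kernel",
    "intrinsic_ft",
    "extrinsic_ft",
    "connectivity_transform",
    "total_connectivity",
    "ResonanceError",
]


class ResonanceError(ArithmeticError):
    """A kernel transform was evaluated at a (near-)singular point."""


def intrinsic_kernel(x, a_ab, c_ab):
    """Exponential interlaminar kernel (1/2) a exp(-c |x|); even in x."""
    if np.any(np.asarray(c_ab) <= 0):
        raise ValueError("spatial decay must be positive")
    return 0.5 * a_ab * np.exp(-c_ab * np.abs(x))


def extrinsic_kernel(x, c_aa, h_a):
    """Patchy horizontal kernel with peaks at +-h_a; total mass 2."""
    if np.any(np.asarray(c_aa) <= 0):
        raise ValueError("spatial decay must be positive")
    if np.any(np.asarray(h_a) < 0):
        raise ValueError("column separation must be non-negative")
    x = np.asarray(x, dtype=float)
    return 0.5 * c_aa * (np.exp(-c_aa * np.abs(x - h_a)) + np.exp(-c_aa * np.abs(x + h_a)))


def intrinsic_ft(kappa, omega, a_ab, c_ab, upsilon):
    """Transform of the delayed intrinsic kernel.

    D(kappa, omega) = a (c - i upsilon omega) / ((c - i upsilon omega)^2 + kappa^2).

    At ``upsilon = 0, kappa = 0`` this is the kernel mass a/c.
    """
    kappa = np.asarray(kappa, dtype=float)
    omega = np.asarray(omega, dtype=float)
    cm = c_ab - 1j * upsilon * omega
    den = cm * cm + kappa * kappa
    if np.any(np.abs(den) < 1e-12 * (np.abs(cm) ** 2 + kappa * kappa + 1e-300)):
        raise ResonanceError("intrinsic transform evaluated at a resonance")
    return a_ab * cm / den


def extrinsic_ft(kappa, omega, c_aa, h_a, upsilon):
    """Transform of the delayed patchy kernel (exact piecewise closed form).

    Splitting the half-line integral at the kink x = h gives

        D = c [ e^{-c h} I1 + 2 cosh(c h) I2 ],
        I1 = int_0^h cosh(c x) e^{s x} (e^{i kappa x} + e^{-i kappa x})/2 dx,
        I2 = int_h^inf e^{(s - c) x} (e^{i kappa x} + e^{-i kappa x})/2 dx,

    with s = i omega upsilon; both pieces are sums of elementary exponential
    integrals.  At ``upsilon = 0, kappa = 0`` the value is the kernel mass 2.
    """
    kappa, omega = np.broadcast_arrays(
        np.asarray(kappa, dtype=float), np.asarray(omega, dtype=float)
    )
    if c_aa <= 0:
        raise ValueError("spatial decay must be positive")
    s = 1j * upsilon * omega
    shape = kappa.shape
    tot1 = np.zeros(shape, dtype=complex)
    for a_part in (c_aa, -c_aa):
        for b_part in (1j * kappa, -1j * kappa):
            z = s + a_part + b_part
            # z has real part +-c, never zero for c > 0
            tot1 = tot1 + (np.exp(z * h_a) - 1.0) / z
    i1 = 0.5 * tot1
    tot2 = np.zeros(shape, dtype=complex)
    for b_part in (1j * kappa, -1j * kappa):
        z = s - c_aa + b_part  # real part -c < 0: the tail integral converges
        tot2 = tot2 - np.exp(z * h_a) / z
    i2 = 0.5 * tot2
    out = c_aa * (np.exp(-c_aa * h_a) * i1 + 2.0 * np.cosh(c_aa * h_a) * i2)
    return out if out.shape else complex(out)


def connectivity_transform(kappa, omega,
                           params: MicrocircuitParameters,
                           field: FieldParameters,
                           upsilon: float | None = None,
                           signs=None) -> np.ndarray:
    """Signed 4x4 connectivity transform D(kappa, omega).

    Entries are sign_ab * D^(i)_ab plus the extrinsic D^(e)_aa on the
    diagonal.  ``kappa`` (rad/mm) and ``omega`` (rad/ms) broadcast; the
    result has shape ``broadcast(kappa, omega).shape + (4, 4)``.  ``signs``
    overrides the default connection-sign map (e.g. to select a variant
    with inhibitory self-connections).
    """
    kappa, omega = np.broadcast_arrays(
        np.asarray(kappa, dtype=float), np.asarray(omega, dtype=float)
    )
    sgn = SIGNS if signs is None else dict(signs)
    ups = field.upsilon if upsilon is None else upsilon
    D = np.zeros(kappa.shape + (4, 4), dtype=complex)
    for (i, j) in INTRINSIC_PAIRS:
        D[..., i - 1, j - 1] = sgn[(i, j)] * intrinsic_ft(
            kappa, omega, params.a[(i, j)], field.c[(i, j)], ups
        )
    for i in range(1, 5):
        D[..., i - 1, i - 1] += extrinsic_ft(kappa, omega, field.c[(i, i)], field.h, ups)
    return D


def total_connectivity(params: MicrocircuitParameters,
                       field: FieldParameters,
                       signs=None) -> np.ndarray:
    """Signed spatial integral of the full kernel, int K(x) dx.

    Equals sign_ab a_ab / c_ab off and on the diagonal, plus the extrinsic
    mass 2 on the diagonal; identical to the connectivity transform at
    kappa = 0 in the delay-free limit.
    """
    sgn = SIGNS if signs is None else dict(signs)
    D0 = np.zeros((4, 4))
    for (i, j) in INTRINSIC_PAIRS:
        D0[i - 1, j - 1] = sgn[(i, j)] * params.a[(i, j)] / field.c[(i, j)]
    D0 += 2.0 * np.eye(4)
    return D0
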