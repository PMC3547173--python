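"""Parameter sets for the canonical-microcircuit neural field model.

The model describes a cortical patch containing four neuronal populations per
point on the cortical sheet -- spiny stellate input cells (1), inhibitory
interneurons (2), deep pyramidal cells (3) and superficial pyramidal cells
(4) -- coupled through laminar (intrinsic) and patchy horizontal (extrinsic)
connectivity kernels.

Units are fixed throughout the package: time in milliseconds, space in
millimetres, voltages in millivolts.  Temporal frequencies at interfaces are
in Hz (converted internally to rad/ms); spatial frequencies at interfaces are
in cycles/mm (converted internally to rad/mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "POPULATIONS",
    "INTRINSIC_PAIRS",
    "SIGNS",
    "MicrocircuitParameters",
    "FieldParameters",
    "ObservationModel",
    "default_parameters",
    "to_flat_dict",
    "from_flat_dict",
    "load_config",
    "save_config",
    "hz_to_angular",
    "cycles_to_angular",
]

#: Fixed population semantics; the ordering is used everywhere.
POPULATIONS = (
    "spiny_stellate",
    "inhibitory_interneuron",
    "deep_pyramidal",
    "superficial_pyramidal",
)

#: Sparsity pattern of the intrinsic (interlaminar) connectivity, as ordered
#: (target, source) population pairs, 1-based.
INTRINSIC_PAIRS = (
    (1, 1), (1, 2), (1, 4),
    (2, 1), (2, 2), (2, 3),
    (3, 2), (3, 3),
    (4, 1), (4, 4),
)

#: Immutable sign map of the intrinsic connections.  Inputs from the
#: inhibitory population (1<-2, 3<-2) and the 1<-4 connection are negative;
#: every other connection, including all self-connections, is positive.
SIGNS: Mapping[tuple[int, int], int] = {
    pair: (-1 if pair in ((1, 4), (1, 2), (3, 2)) else 1)
    for pair in INTRINSIC_PAIRS
}

#: Default intrinsic amplitudes (dimensionless, analogous to synapse counts).
DEFAULT_AMPLITUDES: Mapping[tuple[int, int], float] = {
    (2, 2): 3200.0, (3, 3): 3200.0, (4, 1): 3200.0,
    (1, 2): 800.0, (4, 4): 800.0, (2, 3): 1600.0, (3, 2): 1600.0,
    (1, 1): 9600.0, (1, 4): 4000.0, (2, 1): 4800.0,
}


def hz_to_angular(freq_hz):
    """Temporal frequency in Hz -> angular frequency in rad/ms."""
    return 2.0 * np.pi * np.asarray(freq_hz, dtype=float) / 1000.0


def cycles_to_angular(k_cycles):
    """Spatial frequency in cycles/mm -> angular spatial frequency in rad/mm."""
    return 2.0 * np.pi * np.asarray(k_cycles, dtype=float)


def _validate_pairs(mapping, name):
    extra = set(mapping) - set(INTRINSIC_PAIRS)
    if extra:
        raise ValueError(f"{name} defined off the sparsity pattern: {sorted(extra)}")
    missing = set(INTRINSIC_PAIRS) - set(mapping)
    if missing:
        raise ValueError(f"{name} missing entries: {sorted(missing)}")


@dataclass(frozen=True)
class MicrocircuitParameters:
    """Synaptic and sigmoid constants of the four-population microcircuit.

    Attributes
    ----------
    m_e, m_i : float
        Maximum postsynaptic depolarisation of excitatory / inhibitory
        synapses (mV).
    kappa : tuple of 4 floats
        Postsynaptic rate constants, one per population (1/ms).
    r : float
        Sigmoid gain (1/mV).
    eta : float
        Sigmoid inflection potential (mV).
    a : mapping (target, source) -> float
        Intrinsic connection amplitudes on the sparsity pattern; >= 0.
    """

    m_e: float = 8.0
    m_i: float = 32.0
    kappa: tuple[float, float, float, float] = (0.5, 0.5, 1.0 / 16.0, 1.0 / 28.0)
    r: float = 0.54
    eta: float = 0.0
    a: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )

    def __post_init__(self):
        if self.m_e <= 0 or self.m_i <= 0:
            raise ValueError("m_e and m_i must be positive")
        if len(self.kappa) != 4 or any(k <= 0 for k in self.kappa):
            raise ValueError("need four positive rate constants")
        if self.r <= 0:
            raise ValueError("sigmoid gain r must be positive")
        _validate_pairs(self.a, "amplitudes")
        if any(v < 0 for v in self.a.values()):
            raise ValueError("amplitudes must be non-negative")

    @property
    def m(self) -> np.ndarray:
        """Per-population maximum depolarisation: (m_e, m_i, m_e, m_e)."""
        return np.array([self.m_e, self.m_i, self.m_e, self.m_e])

    @property
    def B(self) -> np.ndarray:
        """Diagonal matrix of rate constants (1/ms)."""
        return np.diag(self.kappa)

    @property
    def A(self) -> np.ndarray:
        """Diagonal matrix of maximum postsynaptic depolarisations (mV)."""
        return np.diag(self.m)

    @property
    def G(self) -> np.ndarray:
        """Input gain vector: exogenous fluctuations drive the stellate cells."""
        return np.array([self.kappa[0] * self.m_e, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class FieldParameters:
    """Spatial parameters of the connectivity kernels and conduction delays.

    ``c`` holds the spatial decay rates (1/mm) on the intrinsic sparsity
    pattern; the diagonal entries double as the decay of the patchy extrinsic
    kernel.  ``h`` is the separation between macrocolumns (mm), ``upsilon``
    the inverse conduction speed (ms/mm; 0 recovers the neural-mass limit)
    and ``L_patch`` the linear extent of the modelled cortical patch (mm).
    """

    c: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {
            p: (2.0 if p[0] == p[1] else 0.6) for p in INTRINSIC_PAIRS
        }
    )
    h: float = 4.5
    upsilon: float = 0.6
    L_patch: float = 25.0

    def __post_init__(self):
        _validate_pairs(self.c, "spatial decays")
        if any(v <= 0 for v in self.c.values()):
            raise ValueError("spatial decay rates must be positive")
        if self.h < 0:
            raise ValueError("column separation must be non-negative")
        if self.upsilon < 0:
            raise ValueError("inverse conduction speed must be non-negative")
        if self.L_patch <= 0:
            raise ValueError("patch length must be positive")


@dataclass(frozen=True)
class ObservationModel:
    """Single-channel Gaussian lead field and spectral noise model.

    Parameters
    ----------
    phi : float
        Lead-field dispersion as a fraction of the patch length (the default
        0.1 on a 25 mm patch gives a 2.5 mm dispersion).
    q : tuple of 4 floats
        Relative contribution of each population to the sensor signal.
    alpha_u, beta_u : float
        White and coloured coefficients of the endogenous input spectrum.
    alpha_n, beta_n : float
        White and coloured coefficients of the channel-noise spectrum.
    colour : {"one_over_f", "linear"}
        Shape of the coloured component: ``alpha + beta / f`` (default) or
        the literal linear-in-frequency law ``alpha + beta * omega``.
    k_order : int or None
        Truncation order N of the symmetric spatial-frequency grid
        k_n = n / L_patch, n = -N..N.  ``None`` sizes the grid so the
        lead-field weight at the boundary falls below ``k_tol``.
    """

    phi: float = 0.1
    q: tuple[float, float, float, float] = (10.0, 0.0, 10.0, 80.0)
    alpha_u: float = 1.0
    beta_u: float = 0.0
    alpha_n: float = 0.0
    beta_n: float = 0.0
    colour: str = "one_over_f"
    k_order: int | None = None
    k_tol: float = 1e-6

    def __post_init__(self):
        if self.phi <= 0:
            raise ValueError("lead-field dispersion must be positive")
        if len(self.q) != 4:
            raise ValueError("need four layer-contribution weights")
        if self.alpha_u < 0 or self.alpha_n < 0:
            raise ValueError("white spectral coefficients must be non-negative")
        if self.colour not in ("one_over_f", "linear"):
            raise ValueError(f"unknown colour law {self.colour!r}")

    def phi_mm(self, field_params: FieldParameters) -> float:
        """Lead-field dispersion in millimetres."""
        return self.phi * field_params.L_patch


def default_parameters():
    """Return the default (prior-mean) parameter triple."""
    return MicrocircuitParameters(), FieldParameters(), ObservationModel()


# ---------------------------------------------------------------------------
# Flat key-value serialization (config files)

def _pair_key(prefix, pair):
    return f"{prefix}_{pair[0]}{pair[1]}"


def to_flat_dict(params: MicrocircuitParameters,
                 field_params: FieldParameters,
                 obs: ObservationModel) -> dict:
    """Flatten the three parameter sets into symbol-named keys."""
    out = {
        "m_e": params.m_e,
        "m_i": params.m_i,
        **{f"kappa_{i+1}": params.kappa[i] for i in range(4)},
        "r": params.r,
        "eta": params.eta,
        **{_pair_key("a", p): params.a[p] for p in INTRINSIC_PAIRS},
        **{_pair_key("c", p): field_params.c[p] for p in INTRINSIC_PAIRS},
        "h": field_params.h,
        "upsilon": field_params.upsilon,
        "L_patch": field_params.L_patch,
        "phi": obs.phi,
        **{f"q_{i+1}": obs.q[i] for i in range(4)},
        "alpha_u": obs.alpha_u,
        "beta_u": obs.beta_u,
        "alpha_n": obs.alpha_n,
        "beta_n": obs.beta_n,
        "colour": obs.colour,
    }
    if obs.k_order is not None:
        out["k_order"] = obs.k_order
    return out


def from_flat_dict(flat: Mapping) -> tuple[MicrocircuitParameters, FieldParameters, ObservationModel]:
    """Inverse of :func:`to_flat_dict`; unknown keys are rejected."""
    flat = dict(flat)
    known = set(to_flat_dict(*default_parameters())) | {"k_order"}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    defaults = to_flat_dict(*default_parameters())
    merged = {**defaults, **flat}
    params = MicrocircuitParameters(
        m_e=float(merged["m_e"]),
        m_i=float(merged["m_i"]),
        kappa=tuple(float(merged[f"kappa_{i+1}"]) for i in range(4)),
        r=float(merged["r"]),
        eta=float(merged["eta"]),
        a={p: float(merged[_pair_key("a", p)]) for p in INTRINSIC_PAIRS},
    )
    field_params = FieldParameters(
        c={p: float(merged[_pair_key("c", p)]) for p in INTRINSIC_PAIRS},
        h=float(merged["h"]),
        upsilon=float(merged["upsilon"]),
        L_patch=float(merged["L_patch"]),
    )
    obs = ObservationModel(
        phi=float(merged["phi"]),
        q=tuple(float(merged[f"q_{i+1}"]) for i in range(4)),
        alpha_u=float(merged["alpha_u"]),
        beta_u=float(merged["beta_u"]),
        alpha_n=float(merged["alpha_n"]),
        beta_n=float(merged["beta_n"]),
        colour=str(merged["colour"]),
        k_order=None if merged.get("k_order") is None else int(merged["k_order"]),
    )
    return params, field_params, obs


def load_config(path) -> tuple[MicrocircuitParameters, FieldParameters, ObservationModel]:
    """Read a flat JSON or YAML parameter config."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        flat = json.loads(text)
    else:
        flat = yaml.safe_load(text)
    if not isinstance(flat, Mapping):
        raise ValueError(f"config {path} does not contain a mapping")
    return from_flat_dict(flat)


def save_config(path, params, field_params, obs):
    """Write the flat parameter config as JSON or YAML by extension."""
    path = Path(path)
    flat = to_flat_dict(params, field_params, obs)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(flat, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=True))


def with_scaled(params, field_params, obs, scalings: Mapping[str, float]):
    """Apply multiplicative log-scalings to named parameters.

    Each named parameter is replaced by ``value * exp(scaling)``.  Group
    aliases ``c_diag`` (all c_aa), ``c_off`` (all c_ab, a != b), ``a_all``
    and ``c_all`` expand to their members.
    """
    flat = to_flat_dict(params, field_params, obs)
    expanded: dict[str, float] = {}

    def add(name, s):
        expanded[name] = expanded.get(name, 0.0) + s

    for name, s in scalings.items():
        if name == "c_diag":
            for p in INTRINSIC_PAIRS:
                if p[0] == p[1]:
                    add(_pair_key("c", p), s)
        elif name == "c_off":
            for p in INTRINSIC_PAIRS:
                if p[0] != p[1]:
                    add(_pair_key("c", p), s)
        elif name == "c_all":
            for p in INTRINSIC_PAIRS:
                add(_pair_key("c", p), s)
        elif name == "a_all":
            for p in INTRINSIC_PAIRS:
                add(_pair_key("a", p), s)
        elif name in flat and isinstance(flat[name], (int, float)):
            add(name, s)
        else:
            raise KeyError(f"unknown parameter name {name!r}")
    for name, s in expanded.items():
        flat[name] = float(flat[name]) * float(np.exp(s))
    return from_flat_dict(flat)
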