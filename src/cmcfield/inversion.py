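"""Variational-Laplace inversion of power spectra and model comparison.

Free parameters are expressed as multiplicative log-scalings of their prior
means, theta = theta_bar * exp(vartheta), with Gaussian shrinkage priors
vartheta ~ N(0, sigma^2).  The observation model assumes independent
Gaussian error per frequency bin with precision exp(lambda), where lambda
carries its own Gaussian prior (a single noise hyperparameter).

The objective is the variational free energy under the Laplace assumption,

    F = accuracy - complexity
      = [ -(n/2) ln 2 pi + (n/2) lambda - (exp(lambda)/2) r' r ]
        - KL( N(mu, C) || N(0, Sigma_prior) )
        - KL( N(m_lambda, v_lambda) || N(eta_lambda, 1/P_lambda) ),

maximised by Gauss-Newton / Levenberg-Marquardt ascent with numerical
Jacobians of the predicted spectrum; the posterior covariance is the
Laplace curvature C = (exp(lambda) J'J + Pi_prior)^-1.  F approximates the
log model evidence, so differences in F between fitted models are
approximate log Bayes factors (|dF| >= 3 read as strong evidence).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import optimize

from . import microcircuit
from .params import (INTRINSIC_PAIRS, FieldParameters, MicrocircuitParameters,
                     ObservationModel, default_parameters, to_flat_dict,
                     with_scaled)
from .spectra import SpectralData, predict_observed_spectrum

__all__ = [
    "A_NAMES",
    "C_NAMES",
    "DEFAULT_FREE",
    "PriorSpec",
    "ModelSpec",
    "PosteriorFit",
    "FreeEnergy",
    "pack_parameters",
    "free_energy",
    "fit",
    "posterior_correlations",
    "compare_models",
    "ModelComparison",
    "STRONG_EVIDENCE_THRESHOLD",
]

A_NAMES = tuple(f"a_{i}{j}" for (i, j) in INTRINSIC_PAIRS)
C_NAMES = tuple(f"c_{i}{j}" for (i, j) in INTRINSIC_PAIRS)

#: Parameters optimised by default: synaptic (kappa_1, m_e, a_ab), spatial
#: (upsilon, c_ab) and sigmoid (r, eta); everything else is fixed.
DEFAULT_FREE = ("kappa_1", "m_e", *A_NAMES, "upsilon", *C_NAMES, "r", "eta")

#: Relative log evidence treated as strong evidence for one model.
STRONG_EVIDENCE_THRESHOLD = 3.0


def default_log_variance(name: str) -> float:
    """Weakly informative shrinkage variance for a free log-scaling."""
    if name in ("upsilon", "r", "eta") or name.startswith("c_"):
        return 1.0 / 16.0
    return 1.0 / 8.0


@dataclass(frozen=True)
class PriorSpec:
    """Prior means, the free-parameter list and shrinkage variances."""

    params: MicrocircuitParameters
    field: FieldParameters
    obs: ObservationModel
    free: tuple[str, ...] = DEFAULT_FREE
    log_variances: Mapping[str, float] | None = None
    hyper_mean: float = 0.0
    hyper_variance: float = 64.0

    def __post_init__(self):
        flat = to_flat_dict(self.params, self.field, self.obs)
        unknown = [n for n in self.free if n not in flat]
        if unknown:
            raise ValueError(f"free parameters not in the model: {unknown}")
        if self.hyper_variance <= 0:
            raise ValueError("hyperparameter prior variance must be positive")

    def variance_vector(self) -> np.ndarray:
        lv = dict(self.log_variances or {})
        out = np.array([lv.get(n, default_log_variance(n)) for n in self.free])
        if np.any(out <= 0):
            raise ValueError("prior log-variances must be positive")
        return out

    @classmethod
    def default(cls, **overrides) -> "PriorSpec":
        p, f, o = default_parameters()
        return cls(params=p, field=f, obs=o, **overrides)


@dataclass(frozen=True)
class ModelSpec:
    """A fittable model: variant, priors and evaluation options.

    The mass variant is the field model with conduction delays shrunk to
    zero: upsilon is pinned at 0 (zero prior variance, not free) and the
    prediction collapses to the k = 0 point-source spectrum.
    """

    variant: str = "field"
    prior: PriorSpec | None = None
    options: Mapping = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in ("field", "mass"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.prior is None:
            object.__setattr__(self, "prior", PriorSpec.default())
        if self.variant == "mass":
            pinned = replace(self.prior.field, upsilon=0.0)
            free = tuple(n for n in self.prior.free if n != "upsilon")
            object.__setattr__(
                self, "prior", replace(self.prior, field=pinned, free=free)
            )

    def predict(self, freqs_hz, vartheta: np.ndarray) -> np.ndarray:
        """Predicted observed spectrum at the given free log-scalings."""
        names = self.prior.free
        p, f, o = pack_parameters(
            self.prior.params, self.prior.field, self.prior.obs,
            dict(zip(names, np.asarray(vartheta, dtype=float))),
        )
        gamma = None
        if self.options.get("linearization") == "fixed_point":
            from .kernels import total_connectivity
            v0 = microcircuit.steady_state(p, total_connectivity(p, f))
            gamma = microcircuit.sigmoid_slope_at(v0, p)
        spec = predict_observed_spectrum(
            freqs_hz, p, f, o, variant=self.variant,
            route=self.options.get("route", "matrix"), gamma=gamma,
        )
        return spec.power


def pack_parameters(params: MicrocircuitParameters,
                    field: FieldParameters,
                    obs: ObservationModel,
                    vartheta: Mapping[str, float]):
    """Apply multiplicative log-scalings to prior-mean parameters.

    Each named free parameter becomes ``prior mean * exp(log-scaling)``;
    unnamed parameters pass through unchanged.  Unknown names raise.
    """
    return with_scaled(params, field, obs, vartheta)


class FreeEnergy(NamedTuple):
    """Free energy with its accuracy/complexity decomposition (nats)."""

    total: float
    accuracy: float
    complexity_params: float
    complexity_hyper: float


@dataclass
class PosteriorFit:
    """Gaussian posterior over log-scalings plus the evidence bound."""

    names: tuple[str, ...]
    mu: np.ndarray
    C: np.ndarray
    lambda_mean: float
    lambda_var: float
    F: float
    free_energy: FreeEnergy
    trajectory: np.ndarray
    converged: bool
    n_iter: int
    data_checksum: str
    settings_hash: str

    def scaling(self, name: str) -> float:
        """Posterior mean log-scaling of one free parameter."""
        return float(self.mu[self.names.index(name)])

    def scaling_sd(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.C[i, i]))

    def to_json(self, path):
        payload = {
            "names": list(self.names),
            "mu": self.mu.tolist(),
            "C": self.C.tolist(),
            "lambda_mean": self.lambda_mean,
            "lambda_var": self.lambda_var,
            "F": self.F,
            "free_energy": self.free_energy._asdict(),
            "trajectory": self.trajectory.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "data_checksum": self.data_checksum,
            "settings_hash": self.settings_hash,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path):
        d = json.loads(Path(path).read_text())
        return cls(
            names=tuple(d["names"]), mu=np.asarray(d["mu"]),
            C=np.asarray(d["C"]), lambda_mean=d["lambda_mean"],
            lambda_var=d["lambda_var"], F=d["F"],
            free_energy=FreeEnergy(**d["free_energy"]),
            trajectory=np.asarray(d["trajectory"]), converged=d["converged"],
            n_iter=d["n_iter"], data_checksum=d["data_checksum"],
            settings_hash=d["settings_hash"],
        )


def _data_checksum(data: SpectralData) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(data.freqs).tobytes())
    h.update(np.ascontiguousarray(data.power).tobytes())
    return h.hexdigest()


def _settings_hash(model: ModelSpec) -> str:
    flat = to_flat_dict(model.prior.params, model.prior.field, model.prior.obs)
    payload = {
        "variant": model.variant,
        "free": list(model.prior.free),
        "log_variances": model.prior.variance_vector().tolist(),
        "hyper": [model.prior.hyper_mean, model.prior.hyper_variance],
        "means": {k: flat[k] for k in sorted(flat) if not isinstance(flat[k], str)},
        "options": {k: model.options[k] for k in sorted(model.options)},
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _kl_gaussian(mu, C, prior_var) -> float:
    """KL( N(mu, C) || N(0, diag(prior_var)) )."""
    p = mu.size
    pi_p = 1.0 / prior_var
    sign, logdet_c = np.linalg.slogdet(C)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance not positive definite")
    return 0.5 * (np.sum(pi_p * np.diag(C)) + np.sum(pi_p * mu ** 2)
                  - p + np.sum(np.log(prior_var)) - logdet_c)


def _kl_scalar(m, v, eta, var) -> float:
    return 0.5 * (v / var + (m - eta) ** 2 / var - 1.0 + np.log(var) - np.log(v))


def _update_hyper(sum_sq: float, n: int, eta_l: float, var_l: float):
    """Posterior (mean, variance) of the log noise precision given residuals.

    Solves d/dm [ (n/2) m - (e^m / 2) S - (m - eta)^2 / (2 var) ] = 0; the
    derivative is strictly decreasing in m, so the root is unique.
    """
    P = 1.0 / var_l
    S = max(sum_sq, 1e-300)

    def dF(m):
        return 0.5 * n - 0.5 * np.exp(m) * S - P * (m - eta_l)

    lo, hi = -700.0, 700.0
    m = optimize.brentq(dF, lo, hi, xtol=1e-10)
    v = 1.0 / (0.5 * np.exp(m) * S + P)
    return m, v


def free_energy(data: SpectralData,
                model: ModelSpec,
                mu,
                C,
                lambda_mean: float,
                lambda_var: float | None = None) -> FreeEnergy:
    """Evaluate the free-energy bound at a given posterior.

    Accuracy is the Gaussian log-likelihood of the spectral residuals at the
    posterior mean with precision exp(lambda_mean); complexity is the KL
    divergence of the parameter posterior from its prior plus that of the
    hyperparameter posterior (``lambda_var`` defaults to the hyper prior
    variance).
    """
    mu = np.asarray(mu, dtype=float)
    C = np.asarray(C, dtype=float)
    y = _fit_target(data, model)
    g = _predict_target(data, model, mu)
    r = y - g
    if not np.all(np.isfinite(g)):
        raise microcircuit.InstabilityError("non-finite prediction at mu")
    n = y.size
    acc = (-0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * lambda_mean
           - 0.5 * np.exp(lambda_mean) * float(r @ r))
    kl_p = _kl_gaussian(mu, C, model.prior.variance_vector())
    if lambda_var is None:
        lambda_var = model.prior.hyper_variance
    kl_h = _kl_scalar(lambda_mean, lambda_var,
                      model.prior.hyper_mean, model.prior.hyper_variance)
    return FreeEnergy(total=float(acc - kl_p - kl_h), accuracy=float(acc),
                      complexity_params=float(kl_p), complexity_hyper=float(kl_h))


def _fit_target(data, model):
    y = data.power
    if model.options.get("log_power"):
        return np.log(y + 1e-300)
    return y


def _predict_target(data, model, mu):
    g = model.predict(data.freqs, mu)
    if model.options.get("log_power"):
        return np.log(np.maximum(g, 1e-300))
    return g


def _jacobian(data, model, mu, step=1e-3):
    p = mu.size
    cols = []
    for i in range(p):
        up = mu.copy(); up[i] += step
        dn = mu.copy(); dn[i] -= step
        cols.append((_predict_target(data, model, up)
                     - _predict_target(data, model, dn)) / (2.0 * step))
    return np.column_stack(cols)


def fit(data: SpectralData,
        model: ModelSpec,
        max_iter: int = 128,
        f_tol: float = 1e-2,
        n_converged: int = 4,
        jac_step: float = 1e-3,
        max_step_halvings: int = 8) -> PosteriorFit:
    """Invert a power spectrum by Gauss-Newton ascent on the free energy.

    Candidate updates are Levenberg-Marquardt damped Gauss-Newton steps; a
    candidate is accepted only if its fully re-evaluated free energy
    improves on the current one, so the trajectory of accepted F values is
    non-decreasing by construction.  Convergence is declared after
    ``n_converged`` consecutive accepted improvements below ``f_tol`` nats;
    otherwise the best fit so far is returned with ``converged=False``.
    Deterministic given the data and settings.
    """
    prior = model.prior
    names = tuple(prior.free)
    prior_var = prior.variance_vector()
    pi_p = np.diag(1.0 / prior_var)
    y = _fit_target(data, model)
    n = y.size

    def evaluate(mu_vec):
        try:
            g = _predict_target(data, model, mu_vec)
        except (microcircuit.InstabilityError, FloatingPointError):
            return None
        if not np.all(np.isfinite(g)):
            return None
        r = y - g
        J = _jacobian(data, model, mu_vec, step=jac_step)
        if not np.all(np.isfinite(J)):
            return None
        m_l, v_l = _update_hyper(float(r @ r), n, prior.hyper_mean,
                                 prior.hyper_variance)
        H = np.exp(m_l) * (J.T @ J) + pi_p
        try:
            C = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        C = 0.5 * (C + C.T)
        acc = (-0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * m_l
               - 0.5 * np.exp(m_l) * float(r @ r))
        try:
            kl_p = _kl_gaussian(mu_vec, C, prior_var)
        except np.linalg.LinAlgError:
            return None
        kl_h = _kl_scalar(m_l, v_l, prior.hyper_mean, prior.hyper_variance)
        fe = FreeEnergy(total=float(acc - kl_p - kl_h), accuracy=float(acc),
                        complexity_params=float(kl_p),
                        complexity_hyper=float(kl_h))
        return {"mu": mu_vec, "r": r, "J": J, "m_l": m_l, "v_l": v_l,
                "C": C, "H": H, "fe": fe}

    mu = np.zeros(len(names))
    cur = evaluate(mu)
    if cur is None:
        raise microcircuit.InstabilityError(
            "model prediction failed at the prior means")
    trajectory = [cur["fe"].total]
    rho = 1.0
    consec = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        grad = (np.exp(cur["m_l"]) * (cur["J"].T @ cur["r"])
                - (1.0 / prior_var) * cur["mu"])
        accepted = None
        for _ in range(max_step_halvings):
            damp = rho * np.diag(np.diag(cur["H"])) + 1e-12 * np.eye(len(names))
            try:
                step = np.linalg.solve(cur["H"] + damp, grad)
            except np.linalg.LinAlgError:
                rho *= 4.0
                continue
            cand = evaluate(cur["mu"] + step)
            if cand is not None and cand["fe"].total > cur["fe"].total:
                accepted = cand
                rho = max(rho / 2.0, 1e-8)
                break
            rho = min(rho * 4.0, 1e12)
        if accepted is None:
            # no admissible ascent direction: treat as a local optimum
            converged = True
            break
        dF = accepted["fe"].total - cur["fe"].total
        cur = accepted
        trajectory.append(cur["fe"].total)
        consec = consec + 1 if dF < f_tol else 0
        if consec >= n_converged:
            converged = True
            break

    return PosteriorFit(
        names=names, mu=cur["mu"].copy(), C=cur["C"],
        lambda_mean=float(cur["m_l"]), lambda_var=float(cur["v_l"]),
        F=float(cur["fe"].total), free_energy=cur["fe"],
        trajectory=np.asarray(trajectory), converged=converged,
        n_iter=n_iter, data_checksum=_data_checksum(data),
        settings_hash=_settings_hash(model),
    )


def posterior_correlations(fit_result: PosteriorFit):
    """Posterior cross-correlation matrix of the free log-scalings."""
    C = fit_result.C
    d = np.sqrt(np.diag(C))
    if np.any(d <= 0):
        raise ValueError("zero posterior variance on the diagonal")
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return fit_result.names, np.clip(R, -1.0, 1.0)


@dataclass
class ModelComparison:
    """Per-dataset relative log evidence of field vs mass fits."""

    delta_f: np.ndarray            # F_field - F_mass per dataset
    strong_evidence: np.ndarray    # |dF| >= threshold, per dataset
    mean: float
    mean_strong: bool


def compare_models(fit_pairs: Sequence[tuple[PosteriorFit, PosteriorFit]],
                   threshold: float = STRONG_EVIDENCE_THRESHOLD) -> ModelComparison:
    """Relative log evidence dF = F_field - F_mass over datasets.

    Each pair must have been fitted to the same data.  The strong-evidence
    flag is inclusive at the threshold (|dF| >= 3 by default).
    """
    deltas = []
    for field_fit, mass_fit in fit_pairs:
        if field_fit.data_checksum != mass_fit.data_checksum:
            raise ValueError("fits in a pair were obtained on different data")
        deltas.append(field_fit.F - mass_fit.F)
    deltas = np.asarray(deltas, dtype=float)
    strong = np.abs(deltas) >= threshold
    mean = float(np.mean(deltas)) if deltas.size else float("nan")
    return ModelComparison(delta_f=deltas, strong_evidence=strong,
                           mean=mean,
                           mean_strong=bool(abs(mean) >= threshold))
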