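"""Population-level statistics: correlation tests, partial correlations and
maximum-likelihood path analysis (SEM) on a correlation matrix.

These tools operate on summary statistics of a group study -- a labelled
correlation matrix with its sample size -- rather than on raw subject data.
The bundled reference matrix relates four subject-level variables from a
gamma-band MEG study of human visual cortex (N = 32 hemispheric datasets):
retinotopically measured V1 surface area, estimated macrocolumn width
(the dispersion 1/c of horizontal connections), the excitatory drive from
deep pyramidal cells to inhibitory interneurons (a23), and peak gamma
frequency (f).

Tail conventions are never inferred: every significance test takes an
explicit ``tails`` argument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CorrelationMatrix",
    "PathModel",
    "PathFit",
    "pearson_test",
    "partial_correlation",
    "fit_path_model",
    "compare_path_models",
    "reference_study_correlations",
    "MODEL8",
    "model_space",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Labelled symmetric correlation matrix with its sample size."""

    labels: tuple[str, ...]
    values: np.ndarray
    n: int

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        p = len(self.labels)
        if values.shape != (p, p):
            raise ValueError("matrix shape does not match the labels")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have a unit diagonal")
        if np.any(np.abs(values) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n <= p:
            raise ValueError("sample size must exceed the number of variables")

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def sub(self, labels) -> np.ndarray:
        idx = [self.index(l) for l in labels]
        return self.values[np.ix_(idx, idx)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n: int) -> "CorrelationMatrix":
        return cls(tuple(df.columns), df.to_numpy(dtype=float), n)

    @classmethod
    def from_csv(cls, path, n: int) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls.from_dataframe(df, n)

    def to_csv(self, path):
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_json(cls, path) -> "CorrelationMatrix":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["labels"]), np.asarray(d["values"]), int(d["n"]))

    def to_json(self, path):
        Path(path).write_text(json.dumps(
            {"labels": list(self.labels), "values": self.values.tolist(),
             "n": self.n}, indent=2) + "\n")


def reference_study_correlations() -> CorrelationMatrix:
    """The bundled group-study correlation matrix (N = 32).

    Variables: macrocolumn width, V1 surface area, the deep-pyramidal to
    interneuron drive a23, and peak gamma frequency f.
    """
    labels = ("width", "v1_size", "a23", "f")
    values = np.array([
        [1.000, 0.364, -0.320, 0.271],
        [0.364, 1.000, -0.099, 0.286],
        [-0.320, -0.099, 1.000, -0.379],
        [0.271, 0.286, -0.379, 1.000],
    ])
    return CorrelationMatrix(labels, values, 32)


# ---------------------------------------------------------------------------
# Correlation tests

def _t_pvalue(t: float, df: int, tails: str) -> float:
    if tails == "one":
        return float(stats.t.sf(abs(t), df))
    if tails == "two":
        return float(2.0 * stats.t.sf(abs(t), df))
    raise ValueError("tails must be 'one' or 'two'")


def pearson_test(r: float, n: int, tails: str = "two") -> float:
    """p-value for a Pearson correlation of r at sample size n.

    Uses t = r sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.  The
    one-tailed value is half the two-tailed value (the observed direction).
    """
    if not -1.0 < r < 1.0:
        raise ValueError("|r| must be below 1")
    if n <= 2:
        raise ValueError("need n > 2")
    df = n - 2
    if r == 0.0 and tails == "one":
        return 0.5
    t = r * np.sqrt(df / (1.0 - r * r))
    return _t_pvalue(t, df, tails)


def partial_correlation(corr: CorrelationMatrix, x: str, y: str,
                        controls, tails: str = "one"):
    """Partial correlation of x and y controlling for the named variables.

    Computed from the precision matrix of the (x, y, controls) submatrix,
    r_partial = -P_xy / sqrt(P_xx P_yy); the p-value refers
    t = r sqrt(df / (1 - r^2)) to a t distribution with
    df = n - 2 - len(controls).  One-tailed by default, for directional
    hypotheses.
    """
    controls = list(controls)
    names = [x, y, *controls]
    if len(set(names)) != len(names):
        raise ValueError("x, y and controls must be distinct")
    sub = corr.sub(names)
    try:
        P = np.linalg.inv(sub)
    except np.linalg.LinAlgError:
        raise ValueError("correlation submatrix is singular") from None
    rp = float(-P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    df = corr.n - 2 - len(controls)
    if df <= 0:
        raise ValueError("not enough observations for the partial test")
    t = rp * np.sqrt(df / (1.0 - rp * rp))
    return rp, _t_pvalue(t, df, tails)


# ---------------------------------------------------------------------------
# Path analysis (recursive SEM on a correlation matrix)

@dataclass(frozen=True)
class PathModel:
    """A directed acyclic path diagram over named variables.

    ``edges`` are (cause, effect) pairs; ``exogenous`` variables receive no
    edges and have free variances.  Variables not listed as exogenous are
    endogenous with free residual variances.
    """

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "edges",
                           tuple((str(a), str(b)) for a, b in self.edges))
        for a, b in self.edges:
            if a not in self.variables or b not in self.variables:
                raise ValueError(f"edge ({a}, {b}) references unknown variables")
            if a == b:
                raise ValueError("self-loops are not allowed")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        self._toposort()  # raises on cycles

    def _toposort(self) -> tuple[str, ...]:
        remaining = set(self.variables)
        parents = {v: {a for a, b in self.edges if b == v} for v in self.variables}
        order = []
        while remaining:
            free = [v for v in self.variables
                    if v in remaining and not (parents[v] & remaining)]
            if not free:
                raise ValueError("path model contains a cycle")
            for v in free:
                order.append(v)
                remaining.discard(v)
        return tuple(order)

    @property
    def exogenous(self) -> tuple[str, ...]:
        effects = {b for _, b in self.edges}
        return tuple(v for v in self.variables if v not in effects)

    @classmethod
    def from_json(cls, path) -> "PathModel":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["variables"]),
                   tuple((a, b) for a, b in d["edges"]),
                   name=d.get("name", ""))


#: The best-supported structure for the reference study: V1 size constrains
#: columnar width, width sets the inhibitory drive, and peak gamma frequency
#: is driven by that drive plus a direct macroscopic effect of V1 size.
MODEL8 = PathModel(
    variables=("v1_size", "width", "a23", "f"),
    edges=(("v1_size", "width"), ("width", "a23"),
           ("a23", "f"), ("v1_size", "f")),
    name="model8",
)


def model_space() -> list[PathModel]:
    """Candidate structures: v1->width fixed, all subsets of the other edges.

    Enumerates presence/absence of {width->f, a23->f, v1->f, width->a23};
    the full set yields 16 models (model8 is the member with edges
    {v1->width, width->a23, a23->f, v1->f}).
    """
    optional = (("width", "f"), ("a23", "f"), ("v1_size", "f"), ("width", "a23"))
    models = []
    for mask in range(16):
        edges = [("v1_size", "width")]
        edges += [optional[i] for i in range(4) if mask >> i & 1]
        models.append(PathModel(("v1_size", "width", "a23", "f"),
                                tuple(edges), name=f"m{mask:02d}"))
    return models


@dataclass
class PathFit:
    """Maximum-likelihood fit of a path model to a correlation matrix."""

    model: PathModel
    coefficients: dict
    residual_variances: dict
    implied: CorrelationMatrix
    loglik: float
    aic: float
    df: int
    n_params: int
    converged: bool


def _implied_covariance(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Sigma = (I - B)^-1 Psi (I - B)^-T for a recursive path model."""
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    nb = len(model.edges)
    B = np.zeros((p, p))
    for k, (a, b) in enumerate(model.edges):
        B[idx[b], idx[a]] = theta[k]
    psi = np.diag(theta[nb:nb + p])
    A = np.linalg.inv(np.eye(p) - B)
    return A @ psi @ A.T


def _start_values(model: PathModel, corr: CorrelationMatrix) -> np.ndarray:
    """Equation-wise least-squares start: each endogenous variable regressed
    on its parents using the observed correlations."""
    idx = {v: i for i, v in enumerate(model.variables)}
    S = corr.sub(model.variables)
    coeffs = np.zeros(len(model.edges))
    resid = np.ones(len(model.variables))
    for v in model.variables:
        parents = [a for a, b in model.edges if b == v]
        if not parents:
            continue
        pi = [idx[a] for a in parents]
        beta = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, idx[v]])
        for a, w in zip(parents, beta):
            k = model.edges.index((a, v))
            coeffs[k] = w
        resid[idx[v]] = max(1.0 - float(S[pi, idx[v]] @ beta), 1e-3)
    return np.concatenate([coeffs, resid])


def fit_path_model(model: PathModel, corr: CorrelationMatrix) -> PathFit:
    """Fit a recursive standardized path model by maximum likelihood.

    Treats the correlation matrix as a covariance matrix observed on n
    samples and minimises the Wishart discrepancy
    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p over path coefficients and
    residual/exogenous variances.  Implied correlations follow from the
    implied covariance; loglik uses the Wishart form with divisor n - 1 and
    AIC = -2 loglik + 2 k.
    """
    missing = set(model.variables) - set(corr.labels)
    if missing:
        raise ValueError(f"correlation matrix lacks variables {sorted(missing)}")
    S = corr.sub(model.variables)
    p = len(model.variables)
    nb = len(model.edges)
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("observed correlation matrix is not positive definite")

    def discrepancy(theta):
        if np.any(theta[nb:] <= 1e-8):
            return 1e8
        sigma = _implied_covariance(model, theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e8
        try:
            tr = float(np.trace(np.linalg.solve(sigma, S)))
        except np.linalg.LinAlgError:
            return 1e8
        return logdet + tr - logdet_s - p

    x0 = _start_values(model, corr)
    res = optimize.minimize(discrepancy, x0, method="Nelder-Mead",
                            options={"maxiter": 40000, "xatol": 1e-12,
                                     "fatol": 1e-14})
    res2 = optimize.minimize(discrepancy, res.x, method="BFGS",
                             options={"gtol": 1e-10, "maxiter": 2000})
    theta = res2.x if res2.fun <= res.fun else res.x
    converged = bool(res.success or res2.success)

    sigma = _implied_covariance(model, theta)
    d = np.sqrt(np.diag(sigma))
    implied_corr = sigma / np.outer(d, d)
    np.fill_diagonal(implied_corr, 1.0)
    n = corr.n
    sign, logdet = np.linalg.slogdet(sigma)
    tr = float(np.trace(np.linalg.solve(sigma, S)))
    loglik = -0.5 * (n - 1) * (p * np.log(2.0 * np.pi) + logdet + tr)
    k = nb + p  # path coefficients + residual/exogenous variances
    aic = -2.0 * loglik + 2.0 * k

    idx = {v: i for i, v in enumerate(model.variables)}
    coeffs = {}
    for kk, (a, b) in enumerate(model.edges):
        # standardize by the implied standard deviations
        coeffs[(a, b)] = float(theta[kk] * d[idx[a]] / d[idx[b]])
    resid = {v: float(theta[nb + idx[v]]) for v in model.variables}
    return PathFit(
        model=model, coefficients=coeffs, residual_variances=resid,
        implied=CorrelationMatrix(model.variables, implied_corr, n),
        loglik=float(loglik), aic=float(aic),
        df=p * (p + 1) // 2 - k, n_params=k, converged=converged,
    )


def compare_path_models(models, corr: CorrelationMatrix) -> pd.DataFrame:
    """Fit every model and rank by AIC (ties broken by fewer parameters).

    Returns a DataFrame with columns model, aic, loglik, df, n_params,
    sorted best first with a stable order for ties.
    """
    rows = []
    for i, m in enumerate(models):
        f = fit_path_model(m, corr)
        rows.append({"model": m.name or f"model_{i}", "aic": f.aic,
                     "loglik": f.loglik, "df": f.df, "n_params": f.n_params})
    df = pd.DataFrame(rows)
    return (df.sort_values(["aic", "n_params"], kind="stable")
              .reset_index(drop=True))
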