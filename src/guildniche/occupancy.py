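"""Multispecies occupancy model with pairwise interactions.

The latent presence/absence state of S species at site *i* is a vector
``z ∈ {0,1}^S`` modeled with a multivariate Bernoulli distribution whose
log-linear potentials ("natural parameters") are

    ν(z) = Σ_s z_s f_s  +  Σ_{s<t} z_s z_t f_st,        ν(0) = 0,
    ψ(z) = exp(ν(z)) / Σ_z' exp(ν(z')),

so first-order f_s govern single-species log odds and second-order f_st the
log odds of joint occurrence; third and higher orders are fixed at zero
(pairwise interactions only).  Each f may be a linear function of site
covariates.  Detection is imperfect: conditional on occupancy, species s is
recorded in a weekly occasion with probability p_s (logit link, optionally
covariate-dependent), and the observed-data likelihood marginalizes over all
2^S latent states per site.

Estimation is by maximum likelihood with multi-start quasi-Newton
optimization; model comparison uses AICc and Akaike weights.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .detection_history import DetectionHistory

__all__ = [
    "NaturalParameterSpec",
    "LatentStateDistribution",
    "MultiOccuFit",
    "prepare_covariates",
    "psi_from_f",
    "loglik",
    "fit",
    "aicc",
    "model_selection",
    "marginal_occupancy",
    "conditional_occupancy",
]

_P_EPS = 1e-12


class ConvergenceError(RuntimeError):
    """No optimizer start reached convergence."""


# ---------------------------------------------------------------------------
# covariate preparation


def prepare_covariates(
    covariates: pd.DataFrame, r_threshold: float = 0.4
) -> tuple[pd.DataFrame, list[str]]:
    """Z-score covariates and greedily drop collinear ones (|Pearson r| > threshold).

    Standardization uses the sample (n−1) standard deviation.  Dropping is
    greedy in column order: a covariate is removed if it correlates beyond
    the threshold with any earlier *retained* covariate.  Returns the
    standardized retained table and the dropped column names.
    """
    if len(covariates) < 2:
        raise ValueError("need at least 2 sites to standardize covariates")
    std = pd.DataFrame(index=covariates.index)
    for col in covariates.columns:
        x = covariates[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {col!r} has zero variance")
        std[col] = (x - x.mean()) / sd
    kept: list[str] = []
    dropped: list[str] = []
    for col in std.columns:
        r = max((abs(std[col].corr(std[k])) for k in kept), default=0.0)
        (dropped if r > r_threshold else kept).append(col)
    return std[kept], dropped


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class NaturalParameterSpec:
    """Which covariates enter each natural parameter and detection model.

    ``first_order`` maps species -> covariate names (each f_s always has an
    intercept; at most two covariates).  ``second_order`` maps an ordered
    species pair -> covariate names, or ``None`` to fix that f_st ≡ 0
    (independence for the pair).  ``detection`` maps species -> covariate
    names on logit(p); empty list = constant p.
    """

    species: tuple[str, ...]
    first_order: dict[str, list[str]] = field(default_factory=dict)
    second_order: dict[tuple[str, str], list[str] | None] = field(default_factory=dict)
    detection: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ValueError("at least one species required")
        for cov_list in list(self.first_order.values()) + [
            v for v in self.second_order.values() if v is not None
        ]:
            if len(cov_list) > 2:
                raise ValueError("at most two covariates per natural parameter")
        for key in self.second_order:
            if key != tuple(sorted(key)) or key[0] == key[1]:
                raise ValueError(f"second-order key must be a sorted distinct pair, got {key}")

    @classmethod
    def intercept_only(
        cls, species: tuple[str, ...], pairwise: bool = True
    ) -> "NaturalParameterSpec":
        """All-intercept model; ``pairwise=False`` fixes every f_st at 0."""
        pairs = {
            tuple(sorted(p)): ([] if pairwise else None)
            for p in itertools.combinations(species, 2)
        }
        return cls(
            species=tuple(species),
            first_order={s: [] for s in species},
            second_order=pairs,
            detection={s: [] for s in species},
        )

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return sorted(p for p, v in self.second_order.items() if v is not None)

    def covariates_for(self, species: str) -> list[str]:
        return self.first_order.get(species, [])


def _param_layout(spec: NaturalParameterSpec) -> list[tuple[str, str, list[str]]]:
    """Ordered parameter blocks: (block label, kind, covariate names)."""
    blocks = []
    for s in spec.species:
        blocks.append((f"f[{s}]", "first", spec.first_order.get(s, [])))
    for a, b in spec.pairs:
        blocks.append((f"f[{a}:{b}]", "second", spec.second_order[(a, b)]))
    for s in spec.species:
        blocks.append((f"p[{s}]", "detection", spec.detection.get(s, [])))
    return blocks


def param_names(spec: NaturalParameterSpec) -> list[str]:
    names = []
    for label, _, covs in _param_layout(spec):
        names.append(f"{label}:(Intercept)")
        names.extend(f"{label}:{c}" for c in covs)
    return names


# ---------------------------------------------------------------------------
# latent-state distribution


@dataclass
class LatentStateDistribution:
    """ψ(z) over all 2^S presence/absence states at one site."""

    species: tuple[str, ...]
    states: np.ndarray  # (2^S, S) 0/1
    probs: np.ndarray  # (2^S,), sums to 1

    def prob(self, state: tuple[int, ...]) -> float:
        mask = (self.states == np.asarray(state)).all(axis=1)
        return float(self.probs[mask][0])

    def marginal(self, species: str) -> float:
        s = self.species.index(species)
        return float(self.probs[self.states[:, s] == 1].sum())

    def conditional(self, species_a: str, species_b: str, b_state: int) -> float:
        """P(z_a = 1 | z_b = b_state), marginalizing all other species."""
        a = self.species.index(species_a)
        b = self.species.index(species_b)
        cond = self.states[:, b] == b_state
        denom = self.probs[cond].sum()
        if denom < 1e-12:
            raise ZeroDivisionError(
                f"conditioning event z[{species_b}]={b_state} has probability ~0"
            )
        num = self.probs[cond & (self.states[:, a] == 1)].sum()
        return float(num / denom)


def _state_matrix(n_species: int) -> np.ndarray:
    return np.array(list(itertools.product([0, 1], repeat=n_species)), dtype=float)


def psi_from_f(
    f_first: np.ndarray,
    f_second: dict[tuple[int, int], float] | np.ndarray | None = None,
    species: tuple[str, ...] | None = None,
) -> LatentStateDistribution:
    """Occupancy-state distribution from natural-parameter values at one site.

    ``f_first`` holds the S first-order values; ``f_second`` the S(S−1)/2
    second-order values, either as a dict keyed by index pairs (i<j) or as a
    flat array in ``itertools.combinations`` order.  Missing pairs are 0.
    """
    f1 = np.asarray(f_first, dtype=float)
    S = f1.size
    pairs = list(itertools.combinations(range(S), 2))
    f2 = np.zeros(len(pairs))
    if f_second is not None:
        if isinstance(f_second, dict):
            for k, (i, j) in enumerate(pairs):
                f2[k] = f_second.get((i, j), 0.0)
        else:
            f2 = np.asarray(f_second, dtype=float)
            if f2.size != len(pairs):
                raise ValueError(f"expected {len(pairs)} second-order values, got {f2.size}")
    if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(f2))):
        raise ValueError("non-finite natural parameter")
    Z = _state_matrix(S)
    nu = Z @ f1 + np.array([[z[i] * z[j] for (i, j) in pairs] for z in Z]) @ f2
    nu -= nu.max()  # max-subtraction for numerical stability
    probs = np.exp(nu)
    probs /= probs.sum()
    return LatentStateDistribution(
        species=species or tuple(f"sp{k + 1}" for k in range(S)),
        states=Z,
        probs=probs,
    )


# ---------------------------------------------------------------------------
# likelihood


class _ModelData:
    """Precomputed design matrices and detection summaries for one dataset."""

    def __init__(
        self,
        histories: dict[str, DetectionHistory],
        covariates: pd.DataFrame | None,
        spec: NaturalParameterSpec,
    ):
        self.spec = spec
        ref = histories[spec.species[0]]
        self.site_ids = ref.site_ids
        self.n_sites = ref.n_sites
        for s in spec.species:
            if histories[s].site_ids != self.site_ids:
                raise ValueError("histories are not aligned on the same site order")
        if covariates is not None:
            cov = covariates.loc[self.site_ids]
        else:
            cov = pd.DataFrame(index=self.site_ids)
        self.layout = _param_layout(spec)
        self.X = []
        for _, _, covs in self.layout:
            cols = [np.ones(self.n_sites)] + [cov[c].to_numpy(float) for c in covs]
            self.X.append(np.column_stack(cols))
        self.slices = []
        off = 0
        for x in self.X:
            self.slices.append(slice(off, off + x.shape[1]))
            off += x.shape[1]
        self.n_params = off
        S = len(spec.species)
        self.states = _state_matrix(S)  # (2^S, S)
        pairs_idx = [
            (spec.species.index(a), spec.species.index(b)) for a, b in spec.pairs
        ]
        # natural-parameter -> state map: columns follow layout order of f blocks
        n_f = S + len(pairs_idx)
        M = np.zeros((self.states.shape[0], n_f))
        M[:, :S] = self.states
        for k, (i, j) in enumerate(pairs_idx):
            M[:, S + k] = self.states[:, i] * self.states[:, j]
        self.M = M
        self.n_f = n_f
        # detection summaries: counts of 1s and 0s over non-missing occasions
        self.n1 = np.zeros((self.n_sites, S))
        self.n0 = np.zeros((self.n_sites, S))
        for s_idx, s in enumerate(spec.species):
            y = histories[s].matrix
            self.n1[:, s_idx] = np.nansum(y == 1, axis=1)
            self.n0[:, s_idx] = np.nansum(y == 0, axis=1)

    def unpack_f(self, theta: np.ndarray) -> np.ndarray:
        """Per-site natural parameter values F (n_sites × n_f)."""
        F = np.empty((self.n_sites, self.n_f))
        for k in range(self.n_f):
            F[:, k] = self.X[k] @ theta[self.slices[k]]
        return F

    def unpack_p(self, theta: np.ndarray) -> np.ndarray:
        """Per-site detection probabilities (n_sites × S)."""
        S = len(self.spec.species)
        P = np.empty((self.n_sites, S))
        for s in range(S):
            k = self.n_f + s
            P[:, s] = expit(self.X[k] @ theta[self.slices[k]])
        return P


def _loglik_from_theta(theta: np.ndarray, data: _ModelData) -> float:
    F = data.unpack_f(theta)
    nu = F @ data.M.T  # (n_sites, 2^S); state all-zero has nu = 0
    log_psi = nu - logsumexp(nu, axis=1, keepdims=True)
    P = np.clip(data.unpack_p(theta), _P_EPS, 1 - _P_EPS)
    ld_occ = data.n1 * np.log(P) + data.n0 * np.log1p(-P)  # (n_sites, S)
    # unoccupied: detection impossible; a large finite penalty keeps 0·(−inf)
    # out of the matrix product while zeroing those states numerically
    ld_unocc = np.where(data.n1 > 0, -1e10, 0.0)
    Z = data.states  # (2^S, S)
    D = ld_occ @ Z.T + ld_unocc @ (1 - Z).T  # (n_sites, 2^S)
    return float(logsumexp(log_psi + D, axis=1).sum())


def loglik(
    params: np.ndarray,
    histories: dict[str, DetectionHistory],
    covariates: pd.DataFrame | None,
    spec: NaturalParameterSpec,
) -> float:
    """Observed-data log-likelihood, marginalized over the 2^S latent states."""
    data = _ModelData(histories, covariates, spec)
    theta = np.asarray(params, dtype=float)
    if theta.size != data.n_params:
        raise ValueError(f"expected {data.n_params} parameters, got {theta.size}")
    return _loglik_from_theta(theta, data)


# ---------------------------------------------------------------------------
# fitting


def aicc(loglik_value: float, k: int, n: int) -> float:
    """AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1); +inf when the correction blows up."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik_value + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class MultiOccuFit:
    """Maximum-likelihood fit of the multispecies occupancy model."""

    spec: NaturalParameterSpec
    param_names: list[str]
    estimates: np.ndarray
    se: np.ndarray  # NaN where the Hessian was not invertible
    loglik: float
    k: int
    n_sites: int
    aicc: float
    converged: bool
    vcov: np.ndarray | None
    hessian_ok: bool
    covariates: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        """Coefficient table: Estimate, SE, z, p with 10%/5% significance stars."""
        with np.errstate(invalid="ignore", divide="ignore"):
            z = self.estimates / self.se
            p = 2 * norm.sf(np.abs(z))
        stars = np.where(p < 0.05, "**", np.where(p < 0.10, "*", ""))
        return pd.DataFrame(
            {"Estimate": self.estimates, "SE": self.se, "z": z, "p": p, "sig": stars},
            index=self.param_names,
        )

    def coef(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def psi_at(self, cov_row: pd.Series | None) -> LatentStateDistribution:
        """Latent-state distribution at one site's (standardized) covariates."""
        return _psi_at(self.spec, self.param_names, self.estimates, cov_row)


def _psi_at(
    spec: NaturalParameterSpec,
    names: list[str],
    theta: np.ndarray,
    cov_row: pd.Series | None,
) -> LatentStateDistribution:
    val = dict(zip(names, theta))

    def f_value(label: str, covs: list[str]) -> float:
        out = val[f"{label}:(Intercept)"]
        for c in covs:
            out += val[f"{label}:{c}"] * (0.0 if cov_row is None else float(cov_row[c]))
        return out

    f1 = np.array([f_value(f"f[{s}]", spec.first_order.get(s, [])) for s in spec.species])
    f2 = {}
    for a, b in spec.pairs:
        i, j = spec.species.index(a), spec.species.index(b)
        f2[tuple(sorted((i, j)))] = f_value(f"f[{a}:{b}]", spec.second_order[(a, b)])
    return psi_from_f(f1, f2, species=spec.species)


def _numeric_hessian(fun, theta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = theta.size
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            if i == j:
                H[i, i] = (fun(theta + ei) - 2 * f0 + fun(theta - ei)) / eps**2
            else:
                H[i, j] = H[j, i] = (
                    fun(theta + ei + ej)
                    - fun(theta + ei - ej)
                    - fun(theta - ei + ej)
                    + fun(theta - ei - ej)
                ) / (4 * eps**2)
    return H


def fit(
    histories: dict[str, DetectionHistory],
    covariates: pd.DataFrame | None,
    spec: NaturalParameterSpec,
    n_starts: int = 10,
    seed: int | None = 0,
    compute_se: bool = True,
) -> MultiOccuFit:
    """Maximum-likelihood fit via multi-start L-BFGS-B.

    Starts are drawn around zero with N(0, 0.5) jitter (the first start is
    exactly zero); the best converged local optimum wins.  Standard errors
    come from the inverse numerical Hessian; if it is not positive definite
    the fit is returned with SEs flagged NaN.
    """
    data = _ModelData(histories, covariates, spec)
    rng = np.random.default_rng(seed)
    nll = lambda th: -_loglik_from_theta(th, data)
    best = None
    n_converged = 0
    for start in range(max(1, n_starts)):
        x0 = np.zeros(data.n_params) if start == 0 else rng.normal(0.0, 0.5, data.n_params)
        res = minimize(nll, x0, method="L-BFGS-B", options={"ftol": 1e-10, "maxiter": 2000})
        if not np.isfinite(res.fun):
            continue
        n_converged += res.success
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or n_converged == 0:
        raise ConvergenceError(
            f"no start converged ({n_starts} starts, {data.n_params} parameters)"
        )
    theta = best.x
    se = np.full(data.n_params, np.nan)
    vcov = None
    hessian_ok = False
    if compute_se:
        H = _numeric_hessian(nll, theta)
        try:
            vcov = np.linalg.inv(H)
            diag = np.diag(vcov)
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                se = np.sqrt(diag)
                hessian_ok = True
            else:
                vcov = None
        except np.linalg.LinAlgError:
            vcov = None
    ll = -best.fun
    return MultiOccuFit(
        spec=spec,
        param_names=param_names(spec),
        estimates=theta,
        se=se,
        loglik=ll,
        k=data.n_params,
        n_sites=data.n_sites,
        aicc=aicc(ll, data.n_params, data.n_sites),
        converged=True,
        vcov=vcov,
        hessian_ok=hessian_ok,
        covariates=covariates,
    )


def model_selection(fits: dict[str, MultiOccuFit]) -> pd.DataFrame:
    """AICc ranking with ΔAICc and Akaike weights w = exp(−Δ/2)/Σexp(−Δ/2).

    Candidates flagged ``supported`` lie within 2 AICc of the best model.
    Non-converged candidates should be excluded by the caller (fit() raises
    on total non-convergence).
    """
    if len(fits) < 1:
        raise ValueError("no candidate fits")
    rows = pd.DataFrame(
        {
            "model": list(fits),
            "K": [f.k for f in fits.values()],
            "logLik": [f.loglik for f in fits.values()],
            "AICc": [f.aicc for f in fits.values()],
        }
    ).sort_values("AICc", kind="stable", ignore_index=True)
    rows["dAICc"] = rows["AICc"] - rows["AICc"].iloc[0]
    rel = np.exp(-0.5 * rows["dAICc"])
    rows["weight"] = rel / rel.sum()
    rows["supported"] = rows["dAICc"] <= 2.0
    return rows


# ---------------------------------------------------------------------------
# prediction


def marginal_occupancy(
    fit_result: MultiOccuFit, cov_row: pd.Series | None, species: str
) -> float:
    """P(z_s = 1) at the given (standardized) covariate values."""
    return fit_result.psi_at(cov_row).marginal(species)


def conditional_occupancy(
    fit_result: MultiOccuFit,
    cov_row: pd.Series | None,
    species_a: str,
    species_b: str,
    b_state: int,
    n_draws: int = 1000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float] | None]:
    """P(z_a = 1 | z_b = b_state), other species marginalized, with bootstrap CI.

    The CI is a parametric bootstrap: coefficient vectors are drawn from the
    estimated sampling distribution N(θ̂, V̂) and the conditional probability
    recomputed per draw; returns (point, (lower, upper)) or (point, None)
    when no valid covariance matrix is available.
    """
    point = fit_result.psi_at(cov_row).conditional(species_a, species_b, b_state)
    if fit_result.vcov is None or n_draws <= 0:
        return point, None
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit_result.estimates, fit_result.vcov, size=n_draws)
    vals = []
    for th in draws:
        try:
            psi = _psi_at(fit_result.spec, fit_result.param_names, th, cov_row)
            vals.append(psi.conditional(species_a, species_b, b_state))
        except (ZeroDivisionError, ValueError):
            continue
    if not vals:
        return point, None
    alpha = (1 - ci_level) / 2
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return point, (float(lo), float(hi))
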