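"""Time- and paleotemperature-dependent birth-death model fitting.

The likelihood is that of the reconstructed (extant, sampled) tree under a
time-inhomogeneous birth-death process with speciation rate lambda(t) and
extinction rate mu(t), t in Myr before present, and an extant sampling
fraction f.  Writing r(t) = int_0^t (lambda - mu) ds and
F(t) = int_0^t e^{r(s)} lambda(s) ds, the probability that a lineage alive
at time t has no sampled descendant is

    Phi(t) = 1 - e^{r(t)} / (1/f + F(t)),

and the probability that it leaves exactly one sampled descendant lineage
at time s < t is

    Psi(s, t) = e^{r(t) - r(s)} [(1/f + F(s)) / (1/f + F(t))]^2.

The tree likelihood multiplies f per tip, lambda at each branching time,
and Psi over every edge; conditioning is on the crown age and survival of
both crown lineages (divide by lambda(t_crown) (1 - Phi(t_crown))^2).
Rates may depend on time directly or on an interpolated paleotemperature
curve T(t).  Integrals are evaluated by composite Simpson quadrature on a
grid refined to contain every node age and every curve knot.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize

from .simulate import PaleoCurve
from .trees import Phylogeny

__all__ = [
    "RateSpec",
    "ModelFitResult",
    "paleo_prepare",
    "bd_loglik",
    "fit_bd",
    "enumerate_models",
    "model_table",
    "rtt_curve",
    "rtt_temp_regression",
]

_PENALTY = -1e8

LAMBDA_FAMILIES = ("constant", "linear", "exponential")
MU_FAMILIES = ("constant", "linear", "exponential", "zero")

_K_LAMBDA = {"constant": 1, "linear": 2, "exponential": 2}
_K_MU = {"zero": 0, "constant": 1, "linear": 2, "exponential": 2}


@dataclass(frozen=True)
class RateSpec:
    """A birth-death rate model: families, parameters and dependency.

    ``dependency`` is ``time`` (x = age before present) or ``env``
    (x = T(age) from the attached curve).  Families: ``constant`` ->
    base; ``linear`` -> base + slope * x; ``exponential`` ->
    base * exp(slope * x).  Evaluated extinction is clamped at 0 from
    below; speciation must stay positive on the tree's age span.
    """

    dependency: str
    lambda_family: str
    mu_family: str
    lambda0: float = 0.1
    alpha: float = 0.0
    mu0: float = 0.0
    beta: float = 0.0
    curve: PaleoCurve | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.dependency not in ("time", "env"):
            raise ValueError(f"unknown dependency {self.dependency!r}")
        if self.lambda_family not in LAMBDA_FAMILIES:
            raise ValueError(f"unknown speciation family {self.lambda_family!r}")
        if self.mu_family not in MU_FAMILIES:
            raise ValueError(f"unknown extinction family {self.mu_family!r}")
        if self.dependency == "env" and self.curve is None:
            raise ValueError("env dependency requires a paleotemperature curve")

    @property
    def name(self) -> str:
        return f"{self.dependency}:lambda-{self.lambda_family}:mu-{self.mu_family}"

    @property
    def k(self) -> int:
        return _K_LAMBDA[self.lambda_family] + _K_MU[self.mu_family]

    @property
    def free_params(self) -> tuple:
        names = ["lambda0"]
        if self.lambda_family in ("linear", "exponential"):
            names.append("alpha")
        if self.mu_family != "zero":
            names.append("mu0")
            if self.mu_family in ("linear", "exponential"):
                names.append("beta")
        return tuple(names)

    def _x(self, ages: np.ndarray) -> np.ndarray:
        if self.dependency == "time":
            return ages
        return self.curve.interpolator()(ages)

    def lambda_at(self, ages) -> np.ndarray:
        x = self._x(np.asarray(ages, dtype=float))
        if self.lambda_family == "constant":
            return np.full_like(x, self.lambda0)
        if self.lambda_family == "linear":
            return self.lambda0 + self.alpha * x
        with np.errstate(over="ignore"):
            return self.lambda0 * np.exp(self.alpha * x)

    def mu_at(self, ages) -> np.ndarray:
        x = self._x(np.asarray(ages, dtype=float))
        if self.mu_family == "zero":
            return np.zeros_like(x)
        if self.mu_family == "constant":
            raw = np.full_like(x, self.mu0)
        elif self.mu_family == "linear":
            raw = self.mu0 + self.beta * x
        else:
            with np.errstate(over="ignore"):
                raw = self.mu0 * np.exp(self.beta * x)
        return np.maximum(raw, 0.0)  # extinction clamped at zero from below

    def with_params(self, **kw) -> "RateSpec":
        return replace(self, **kw)


@dataclass
class ModelFitResult:
    spec: RateSpec
    loglik: float
    k: int
    aic: float
    converged: bool
    sampling_f: float
    delta_aic: float | None = None
    aw: float | None = None
    crown_age: float | None = None

    @property
    def name(self) -> str:
        return self.spec.name


# ---------------------------------------------------------------------------
# paleotemperature preparation
# ---------------------------------------------------------------------------


def paleo_prepare(
    series: pd.DataFrame,
    mode: str = "temp",
    window: int = 5,
    d18o_coeffs: tuple = (16.5, 4.3),
) -> PaleoCurve:
    """Smooth a paleotemperature (or d18O) series into an interpolable curve.

    ``series`` needs columns ``age_myr`` and ``temp_c`` (mode ``temp``) or
    ``d18o`` (mode ``d18o``; converted by the affine map
    T = a - b * d18o with configurable coefficients -- a convenience
    default, not an asserted calibration).  Smoothing is a centered
    rolling mean of odd width ``window`` whose half-width shrinks
    symmetrically at the series ends.  Queries outside the age range
    clamp to the nearest endpoint value.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    ages = np.asarray(series["age_myr"], dtype=float)
    if mode == "temp":
        vals = np.asarray(series["temp_c"], dtype=float)
    elif mode == "d18o":
        a, b = d18o_coeffs
        vals = a - b * np.asarray(series["d18o"], dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(ages) < window:
        raise ValueError("need at least `window` samples")
    d = np.diff(ages)
    if not (np.all(d < 0) or np.all(d > 0)):
        raise ValueError("ages must be strictly monotone")
    n = len(vals)
    half = window // 2
    smooth = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        smooth[i] = vals[i - h : i + h + 1].mean()
    return PaleoCurve(ages, smooth, provenance="smoothed")


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _branching_structure(tree: Phylogeny):
    """Node ages, parent map and crown age for a binary ultrametric tree."""
    if not tree.is_binary:
        raise ValueError("birth-death likelihood requires a binary tree")
    ages_map = tree.node_ages()
    if not ages_map.ultrametric:
        raise ValueError("birth-death likelihood requires an ultrametric tree")
    a = tree.arrays
    ages = np.array([ages_map.ages[i] for i in range(a.n_nodes)])
    ages[: a.n_tips] = 0.0  # absorb dating jitter at the tips
    return a, ages, ages_map.crown_age


def _quadrature_tables(spec: RateSpec, required_ages: np.ndarray, crown: float, n_grid: int):
    """Cumulative r(t) and F(t) at a grid containing all required ages.

    Composite Simpson per interval; midpoint values of r needed for the
    F integrand come from half-interval Simpson.  Returns (grid, r, F,
    lambda_at_grid, min_lambda_seen).
    """
    pts = [np.linspace(0.0, crown, n_grid + 1), np.asarray(required_ages, dtype=float)]
    if spec.dependency == "env":
        knots = spec.curve.ages
        pts.append(knots[(knots > 0) & (knots < crown)])
    grid = np.unique(np.concatenate(pts))
    grid = grid[(grid >= 0) & (grid <= crown)]
    h = np.diff(grid)
    mids = grid[:-1] + 0.5 * h
    quarters = grid[:-1] + 0.25 * h

    lam_g, mu_g = spec.lambda_at(grid), spec.mu_at(grid)
    lam_m, mu_m = spec.lambda_at(mids), spec.mu_at(mids)
    lam_q, mu_q = spec.lambda_at(quarters), spec.mu_at(quarters)
    min_lambda = float(min(lam_g.min(), lam_m.min(), lam_q.min()))

    net_g, net_m, net_q = lam_g - mu_g, lam_m - mu_m, lam_q - mu_q
    # r at grid points (Simpson per interval) and at interval midpoints
    incr = (h / 6.0) * (net_g[:-1] + 4.0 * net_m + net_g[1:])
    r = np.concatenate([[0.0], np.cumsum(incr)])
    half_incr = (h / 12.0) * (net_g[:-1] + 4.0 * net_q + net_m)
    r_mid = r[:-1] + half_incr
    # F integrand e^{r} lambda, Simpson per interval
    with np.errstate(over="ignore", invalid="ignore"):
        g_g = np.exp(r) * lam_g
        g_m = np.exp(r_mid) * lam_m
        incr_F = (h / 6.0) * (g_g[:-1] + 4.0 * g_m + g_g[1:])
        F = np.concatenate([[0.0], np.cumsum(incr_F)])
    return grid, r, F, lam_g, min_lambda


def bd_loglik(
    tree: Phylogeny,
    spec: RateSpec,
    sampling_f: float = 1.0,
    n_grid: int = 2000,
) -> float:
    """Log-likelihood of the reconstructed tree, crown-conditioned.

    ``sampling_f`` is the probability that an extant species was sampled.
    Returns a large negative penalty (rather than raising) when the
    parameters drive the speciation rate non-positive anywhere on the
    tree's age span or the quadrature overflows, which lets optimisers
    recover.
    """
    if not (0 < sampling_f <= 1):
        raise ValueError("sampling fraction must be in (0, 1]")
    arrays, ages, crown = _branching_structure(tree)
    n = arrays.n_tips
    internal = np.array([i for i in range(arrays.n_nodes) if arrays.children[i]])
    node_ages_int = ages[internal]

    grid, r, F, lam_g, min_lambda = _quadrature_tables(spec, ages, crown, n_grid)
    if min_lambda <= 0:
        return _PENALTY * (1.0 + abs(min_lambda))
    idx = np.searchsorted(grid, ages)
    # required ages are grid members; guard against float fuzz
    idx = np.clip(idx, 0, len(grid) - 1)

    r_at = r[idx]
    F_at = F[idx]
    inv_f = 1.0 / sampling_f
    with np.errstate(over="ignore", invalid="ignore"):
        log_denom = np.log(inv_f + F_at)
        # edges: every non-root node v, from age[v] up to age[parent v]
        nonroot = np.array([i for i in range(arrays.n_nodes) if arrays.parent[i] >= 0])
        pa = arrays.parent[nonroot]
        log_psi = (r_at[pa] - r_at[nonroot]) + 2.0 * (log_denom[nonroot] - log_denom[pa])
        lam_nodes = spec.lambda_at(node_ages_int)
        root = arrays.root
        log_surv = r_at[root] - log_denom[root]  # log(1 - Phi(crown))
        # guard against the extinction-slope degeneracy: when the survival
        # probability underflows, the conditioning term dominates and the
        # conditioned likelihood is numerically meaningless
        if not np.isfinite(log_surv) or log_surv < -30.0:
            return _PENALTY
        ll = (
            n * np.log(sampling_f)
            + np.sum(np.log(lam_nodes))
            - np.log(spec.lambda_at([crown])[0])
            + np.sum(log_psi)
            - 2.0 * log_surv
        )
    if not np.isfinite(ll):
        return _PENALTY
    return float(ll)


# ---------------------------------------------------------------------------
# model enumeration and fitting
# ---------------------------------------------------------------------------


def enumerate_models(dependency: str, curve: PaleoCurve | None = None) -> list:
    """The 12 rate models per dependency: {constant, linear, exponential}
    speciation crossed with {constant, linear, exponential} extinction,
    plus the three pure-birth (zero-extinction) variants."""
    specs = []
    for lf, mf in itertools.product(LAMBDA_FAMILIES, LAMBDA_FAMILIES):
        specs.append(RateSpec(dependency, lf, mf, curve=curve))
    for lf in LAMBDA_FAMILIES:
        specs.append(RateSpec(dependency, lf, "zero", curve=curve))
    return specs


def _pack(spec: RateSpec) -> np.ndarray:
    vals = {
        "lambda0": np.log(max(spec.lambda0, 1e-8)),
        "alpha": spec.alpha,
        "mu0": np.log(max(spec.mu0, 1e-8)),
        "beta": spec.beta,
    }
    return np.array([vals[p] for p in spec.free_params])


def _unpack(spec: RateSpec, theta: np.ndarray) -> RateSpec:
    kw = {}
    for name, val in zip(spec.free_params, theta):
        if name in ("lambda0", "mu0"):
            kw[name] = float(np.exp(val))
        else:
            kw[name] = float(val)
    return spec.with_params(**kw)


# slope bounds of +/-1 per Myr (or per degC) comfortably cover
# biologically plausible rate changes while keeping exp(slope * x) away
# from the overflow/conditioning degeneracies at extreme slopes
_BOUNDS = {
    "lambda0": (np.log(1e-6), np.log(10.0)),
    "mu0": (np.log(1e-8), np.log(10.0)),
    "alpha": (-1.0, 1.0),
    "beta": (-1.0, 1.0),
}


def fit_bd(
    tree: Phylogeny,
    spec: RateSpec,
    sampling_f: float = 1.0,
    n_starts: int = 10,
    seed: int = 0,
    n_grid: int = 2000,
) -> ModelFitResult:
    """Maximum-likelihood fit by bounded multi-start quasi-Newton search.

    Base rates are optimised on the log scale, slopes on the natural
    scale.  The first start is a deterministic moment guess (a Yule-like
    speciation rate from tip count over tree length, one-tenth of it for
    extinction, zero slopes); the rest draw from documented priors
    (log-uniform bases, normal slopes).  The convergence flag is true
    when at least two starts (or the only start) agree with the best
    log-likelihood to within 0.01.
    """
    arrays, ages, crown = _branching_structure(tree)
    n = arrays.n_tips
    lam_guess = float(np.clip((n - 2) / max(tree.total_length, 1e-9), 1e-4, 5.0))
    rng = np.random.default_rng(seed)

    starts = [spec.with_params(lambda0=lam_guess, alpha=0.0, mu0=lam_guess / 10, beta=0.0)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            spec.with_params(
                lambda0=float(np.exp(rng.uniform(np.log(1e-3), np.log(2.0)))),
                alpha=float(rng.normal(0.0, 0.05)),
                mu0=float(np.exp(rng.uniform(np.log(1e-4), np.log(1.0)))),
                beta=float(rng.normal(0.0, 0.05)),
            )
        )
    bounds = [_BOUNDS[p] for p in spec.free_params]

    def nll(theta):
        return -bd_loglik(tree, _unpack(spec, theta), sampling_f, n_grid=n_grid)

    results = []
    for s in starts:
        try:
            res = minimize(nll, _pack(s), method="L-BFGS-B", bounds=bounds)
        except Exception:
            continue
        if np.isfinite(res.fun):
            results.append((float(res.fun), res.x))
    if not results:
        raise RuntimeError(f"all optimisation starts failed for {spec.name}")
    results.sort(key=lambda t: t[0])
    best_nll, best_x = results[0]
    near = sum(1 for f, _ in results if f - best_nll <= 0.01)
    converged = near >= min(2, len(results))
    fitted = _unpack(spec, best_x)
    ll = -best_nll
    k = spec.k
    return ModelFitResult(
        spec=fitted, loglik=ll, k=k, aic=2 * k - 2 * ll,
        converged=converged, sampling_f=sampling_f, crown_age=crown,
    )


def model_table(fits: Sequence[ModelFitResult]) -> pd.DataFrame:
    """Rank fits by AIC; attach delta-AIC and Akaike weights (sum to 1)."""
    if not fits:
        raise ValueError("no fits to tabulate")
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, d, wi in zip(fits, delta, w):
        f.delta_aic = float(d)
        f.aw = float(wi)
    rows = []
    for f in fits:
        row = dict(model=f.name, k=f.k, logL=f.loglik, AIC=f.aic,
                   deltaAIC=f.delta_aic, AW=f.aw, converged=f.converged)
        for p in f.spec.free_params:
            row[p] = getattr(f.spec, p)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)


def rtt_curve(fit: ModelFitResult, n_slices: int = 100) -> pd.DataFrame:
    """Rate-through-time table at equally spaced ages crown -> present."""
    if fit.crown_age is None:
        raise ValueError("fit lacks a crown age")
    t = np.linspace(fit.crown_age, 0.0, n_slices)
    lam = fit.spec.lambda_at(t)
    mu = fit.spec.mu_at(t)
    out = pd.DataFrame({"t": t, "lambda": lam, "mu": mu, "r": lam - mu})
    if fit.spec.dependency == "env":
        out["temp"] = fit.spec.curve.interpolator()(t)
    return out


def rtt_temp_regression(rtt: pd.DataFrame, curve: PaleoCurve) -> dict:
    """Regress net diversification on temperature; pick linear vs exponential.

    Each time slice's r is paired with T at the same age; the linear form
    r = a + b T is fit by least squares, the exponential r = a e^{bT} by
    nonlinear least squares, and the winner chosen by Gaussian-residual
    AIC.  A non-convergent exponential fit falls back to linear with a
    flag.
    """
    T = curve.interpolator()(rtt["t"].to_numpy())
    r = rtt["r"].to_numpy(dtype=float)
    n = len(r)
    X = np.column_stack([np.ones(n), T])
    coef_lin, *_ = np.linalg.lstsq(X, r, rcond=None)
    resid_lin = r - X @ coef_lin
    rss_lin = float(resid_lin @ resid_lin)
    tss = float(((r - r.mean()) ** 2).sum())

    def aic_from_rss(rss, k):
        rss = max(rss, 1e-300)
        return n * np.log(rss / n) + 2 * k

    aic_lin = aic_from_rss(rss_lin, 3)
    fallback = False
    try:
        p0_a = r.mean() if r.mean() != 0 else 1e-3
        popt, _ = curve_fit(
            lambda x, a, b: a * np.exp(b * x), T, r, p0=[p0_a, 0.0], maxfev=10000
        )
        resid_exp = r - popt[0] * np.exp(popt[1] * T)
        rss_exp = float(resid_exp @ resid_exp)
        aic_exp = aic_from_rss(rss_exp, 3)
    except Exception:
        fallback = True
        popt, rss_exp, aic_exp = (np.nan, np.nan), np.inf, np.inf

    if not fallback and aic_exp < aic_lin:
        form, coeff, rss = "exponential", tuple(float(v) for v in popt), rss_exp
    else:
        form, coeff, rss = "linear", (float(coef_lin[0]), float(coef_lin[1])), rss_lin
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return dict(
        form=form, intercept=coeff[0], slope=coeff[1], r2=float(r2),
        aic_linear=float(aic_lin), aic_exponential=float(aic_exp),
        exponential_fallback=fallback,
    )
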