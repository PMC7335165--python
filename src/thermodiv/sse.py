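"""State-dependent speciation/extinction (BiSSE, HiSSE) likelihoods.

The likelihood follows the standard coupled ODE construction: for each
state i, E_i(t) is the probability that a lineage alive at age t leaves
no sampled descendant, and D_i(t) the density of the observed subtree
descending from a lineage in state i.  Along each branch

    dE_i/dt = mu_i - (lambda_i + mu_i + q_i.) E_i + lambda_i E_i^2 + sum_j q_ij E_j
    dD_i/dt = -(lambda_i + mu_i + q_i.) D_i + 2 lambda_i E_i D_i + sum_j q_ij D_j

with tip initial conditions D_i(0) = f_i for states compatible with the
observed tip state and E_i(0) = 1 - f_i.  Daughters combine at nodes as
lambda_i D_i^L D_i^R.  The root is handled by likelihood-weighted
averaging over root states, with survival conditioning dividing each
root state's contribution by lambda_i (1 - E_i)^2 -- the analog of the
crown conditioning used by the birth-death module.

HiSSE doubles the state space with a hidden A/B character; tips are
observed only for the tropicality state, so both hidden states of the
observed value are initialised.  Dual transitions (observed and hidden
flipping together) have rate zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.special import expit, logit

from .bd import ModelFitResult, _branching_structure
from .trees import Phylogeny

__all__ = [
    "bisse_loglik",
    "hisse_loglik",
    "SSEModel",
    "build_model_set",
    "fit_sse",
]

_HIDDEN_ORDER = ("0A", "1A", "0B", "1B")


def _sse_core_loglik(
    tree: Phylogeny,
    tip_D0: np.ndarray,
    lam: np.ndarray,
    mu: np.ndarray,
    Q: np.ndarray,
    f_states: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> float:
    """Shared pruning integrator for k-state SSE models.

    On an ultrametric tree every tip starts from the same extinction
    initial condition, so E(t) is one global function of age, and given
    E the branch equations for D are linear.  A single adaptive solve on
    [0, crown age] therefore integrates E together with a fundamental
    matrix W(t) of the D system (rescaled by exp(phi(t)), phi' =
    mean diagonal, to keep it conditioned); each branch then propagates
    as D(parent) = e^{phi_p - phi_c} W_p W_c^{-1} D(child) with the
    scalar factor accumulated in log space.
    """
    arrays, ages, crown = _branching_structure(tree)
    k = len(lam)
    qrow = Q.sum(axis=1)
    total_rate = lam + mu + qrow
    n_nodes = arrays.n_nodes
    n_tips = arrays.n_tips

    t_eval = np.unique(ages)
    pos = np.searchsorted(t_eval, ages)
    eye = np.eye(k)

    def rhs(t, y):
        E = y[:k]
        W = y[k : k + k * k].reshape(k, k)
        dE = mu - total_rate * E + lam * E**2 + Q @ E
        diagA = 2.0 * lam * E - total_rate
        shift = diagA.mean()
        A = Q + np.diag(diagA - shift)
        dW = A @ W
        return np.concatenate([dE, dW.ravel(), [shift]])

    y0 = np.concatenate([1.0 - f_states, eye.ravel(), [0.0]])
    with np.errstate(over="ignore", invalid="ignore"):
        sol = solve_ivp(rhs, (0.0, crown), y0, t_eval=t_eval, method="DOP853",
                        rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        return -np.inf
    E_at = sol.y[:k, :].T
    W_at = sol.y[k : k + k * k, :].T.reshape(len(t_eval), k, k)
    phi_at = sol.y[-1, :]

    D = np.zeros((n_nodes, k))
    D[:n_tips] = tip_D0
    logscale = 0.0

    def propagate(v: int, parent: int, Dv: np.ndarray):
        nonlocal logscale
        pc, pp = pos[v], pos[parent]
        try:
            base = np.linalg.solve(W_at[pc], Dv)
        except np.linalg.LinAlgError:
            return None
        out = W_at[pp] @ base
        logscale += phi_at[pp] - phi_at[pc]
        return np.maximum(out, 0.0)

    for v in arrays.postorder:
        kids = arrays.children[v]
        if not kids:
            continue
        tops = []
        for c in kids:
            top = propagate(c, v, D[c])
            if top is None:
                return -np.inf
            tops.append(top)
        D[v] = lam * tops[0] * tops[1]
        m = D[v].max()
        if m <= 0 or not np.isfinite(m):
            return -np.inf
        D[v] /= m
        logscale += np.log(m)

    root = arrays.root
    Droot = D[root]
    Eroot = np.clip(E_at[pos[root]], 0.0, 1.0)
    total = Droot.sum()
    if total <= 0 or not np.isfinite(total):
        return -np.inf
    weights = Droot / total
    denom = lam * (1.0 - Eroot) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        lik = np.sum(weights * Droot / denom)
    if not np.isfinite(lik) or lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


def _binary_states_vector(tree: Phylogeny, states: Mapping[str, int]) -> np.ndarray:
    vec = np.array([int(states[l]) for l in tree.tip_labels])
    if not np.all((vec == 0) | (vec == 1)):
        raise ValueError("tip states must be 0/1")
    return vec


def bisse_loglik(
    tree: Phylogeny,
    states: Mapping[str, int],
    params: Mapping[str, float],
    sampling_f: float | Sequence[float] = 1.0,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> float:
    """BiSSE log-likelihood.

    ``params`` keys: lambda0, lambda1, mu0, mu1, q01, q10.
    ``sampling_f`` is a global or per-state extant sampling fraction.
    """
    vec = _binary_states_vector(tree, states)
    lam = np.array([params["lambda0"], params["lambda1"]])
    mu = np.array([params["mu0"], params["mu1"]])
    Q = np.array([[0.0, params["q01"]], [params["q10"], 0.0]])
    f = np.broadcast_to(np.asarray(sampling_f, dtype=float), (2,)).copy()
    n = len(vec)
    D0 = np.zeros((n, 2))
    D0[np.arange(n), vec] = f[vec]
    return _sse_core_loglik(tree, D0, lam, mu, Q, f, rtol=rtol, atol=atol)


def hisse_loglik(
    tree: Phylogeny,
    states: Mapping[str, int],
    params: Mapping[str, float],
    sampling_f: float | Sequence[float] = 1.0,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> float:
    """HiSSE log-likelihood over states (0A, 1A, 0B, 1B).

    ``params`` keys: lambda0A, lambda1A, lambda0B, lambda1B (same pattern
    for mu), q01 (observed flips, both hidden backgrounds), q10, qAB and
    qBA (hidden flips, both observed backgrounds).  Tips observed in
    state s initialise both (s, A) and (s, B).
    """
    vec = _binary_states_vector(tree, states)
    lam = np.array([params[f"lambda{s}"] for s in _HIDDEN_ORDER])
    mu = np.array([params[f"mu{s}"] for s in _HIDDEN_ORDER])
    Q = np.zeros((4, 4))
    # state order 0A, 1A, 0B, 1B; dual transitions stay zero
    Q[0, 1], Q[1, 0] = params["q01"], params["q10"]
    Q[2, 3], Q[3, 2] = params["q01"], params["q10"]
    Q[0, 2], Q[2, 0] = params["qAB"], params["qBA"]
    Q[1, 3], Q[3, 1] = params["qAB"], params["qBA"]
    f_obs = np.broadcast_to(np.asarray(sampling_f, dtype=float), (2,))
    f4 = np.array([f_obs[0], f_obs[1], f_obs[0], f_obs[1]])
    n = len(vec)
    D0 = np.zeros((n, 4))
    for i, s in enumerate(vec):
        D0[i, s] = f_obs[s]
        D0[i, s + 2] = f_obs[s]
    return _sse_core_loglik(tree, D0, lam, mu, Q, f4, rtol=rtol, atol=atol)


# ---------------------------------------------------------------------------
# the four-model comparison set
# ---------------------------------------------------------------------------


class _FitParams:
    """Duck-typed fitted-parameter record compatible with model_table."""

    def __init__(self, name: str, params: dict):
        self.name = name
        self._params = dict(params)
        for key, val in params.items():
            setattr(self, key, val)

    @property
    def free_params(self):
        return tuple(self._params)


@dataclass(frozen=True)
class SSEModel:
    """A named SSE model: packing of free parameters and its likelihood."""

    name: str
    kind: str  # bisse | hisse
    param_names: tuple

    @property
    def k(self) -> int:
        return len(self.param_names)

    def unpack(self, theta: np.ndarray) -> dict:
        raw = dict(zip(self.param_names, theta))
        if self.name == "bisse_null":
            lam, mu = np.exp(raw["log_lambda"]), np.exp(raw["log_mu"])
            return dict(lambda0=lam, lambda1=lam, mu0=mu, mu1=mu,
                        q01=np.exp(raw["log_q01"]), q10=np.exp(raw["log_q10"]))
        if self.name == "bisse_free":
            return dict(
                lambda0=np.exp(raw["log_lambda0"]), lambda1=np.exp(raw["log_lambda1"]),
                mu0=np.exp(raw["log_mu0"]), mu1=np.exp(raw["log_mu1"]),
                q01=np.exp(raw["log_q01"]), q10=np.exp(raw["log_q10"]),
            )
        if self.name == "hisse_cid":
            lamA, lamB = np.exp(raw["log_lambdaA"]), np.exp(raw["log_lambdaB"])
            muA, muB = np.exp(raw["log_muA"]), np.exp(raw["log_muB"])
            q_obs, q_hid = np.exp(raw["log_q_obs"]), np.exp(raw["log_q_hid"])
            return dict(
                lambda0A=lamA, lambda1A=lamA, lambda0B=lamB, lambda1B=lamB,
                mu0A=muA, mu1A=muA, mu0B=muB, mu1B=muB,
                q01=q_obs, q10=q_obs, qAB=q_hid, qBA=q_hid,
            )
        if self.name == "hisse_full":
            eps = expit(raw["logit_eps"])
            q = np.exp(raw["log_q"])
            out = dict(q01=q, q10=q, qAB=q, qBA=q)
            for s in _HIDDEN_ORDER:
                r = np.exp(raw[f"log_r{s}"])
                lam = r / (1.0 - eps)
                out[f"lambda{s}"] = lam
                out[f"mu{s}"] = eps * lam
            return out
        raise ValueError(f"unknown model {self.name!r}")

    def loglik(self, tree, states, theta, sampling_f, **kw) -> float:
        params = self.unpack(theta)
        fn = bisse_loglik if self.kind == "bisse" else hisse_loglik
        return fn(tree, states, params, sampling_f, **kw)


def build_model_set() -> list:
    """The four-model tropicality comparison set.

    * ``bisse_null`` -- diversification shared across observed states
      (k = 4, including two transition rates);
    * ``bisse_free`` -- state-specific speciation and extinction (k = 6);
    * ``hisse_cid`` -- character-independent: diversification varies only
      with the hidden state (k = 6);
    * ``hisse_full`` -- free net diversification across observed x hidden
      states with a single shared transition rate and a single shared
      relative extinction (k = 6).
    """
    return [
        SSEModel("bisse_null", "bisse", ("log_lambda", "log_mu", "log_q01", "log_q10")),
        SSEModel(
            "bisse_free", "bisse",
            ("log_lambda0", "log_lambda1", "log_mu0", "log_mu1", "log_q01", "log_q10"),
        ),
        SSEModel(
            "hisse_cid", "hisse",
            ("log_lambdaA", "log_lambdaB", "log_muA", "log_muB", "log_q_obs", "log_q_hid"),
        ),
        SSEModel(
            "hisse_full", "hisse",
            ("log_r0A", "log_r1A", "log_r0B", "log_r1B", "logit_eps", "log_q"),
        ),
    ]


_LOG_RATE_BOUNDS = (np.log(1e-6), np.log(10.0))


def fit_sse(
    tree: Phylogeny,
    states: Mapping[str, int],
    model: SSEModel,
    sampling_f: float | Sequence[float] = 1.0,
    n_starts: int = 10,
    seed: int = 0,
) -> ModelFitResult:
    """ML fit of one SSE model under its constraint mask.

    Multi-start bounded quasi-Newton on log-scale rates; the first start
    is a moment guess (tip count over tree length for speciation), the
    rest random from log-uniform priors.  Use ``bd.model_table`` to rank
    a set of these fits by AIC.
    """
    arrays, ages, crown = _branching_structure(tree)
    lam_guess = float(np.clip((arrays.n_tips - 2) / max(tree.total_length, 1e-9), 1e-4, 5.0))
    rng = np.random.default_rng(seed)

    def start_vector(random: bool) -> np.ndarray:
        theta = []
        for name in model.param_names:
            if random:
                if name == "logit_eps":
                    theta.append(logit(rng.uniform(0.05, 0.9)))
                elif name.startswith("log_q"):
                    theta.append(rng.uniform(np.log(1e-4), np.log(1.0)))
                else:
                    theta.append(rng.uniform(np.log(1e-3), np.log(2.0)))
            else:
                if name == "logit_eps":
                    theta.append(logit(0.1))
                elif name.startswith("log_q"):
                    theta.append(np.log(0.01))
                elif name.startswith("log_r"):
                    theta.append(np.log(0.9 * lam_guess))
                elif name.startswith("log_mu"):
                    theta.append(np.log(0.1 * lam_guess))
                else:
                    theta.append(np.log(lam_guess))
        return np.array(theta)

    bounds = [
        (-12.0, 12.0) if p == "logit_eps" else _LOG_RATE_BOUNDS
        for p in model.param_names
    ]

    def nll(theta):
        try:
            # slightly looser ODE tolerance inside the search; the final
            # reported likelihood is re-evaluated at full accuracy below
            ll = model.loglik(tree, states, theta, sampling_f, rtol=1e-7, atol=1e-9)
        except RuntimeError:
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    results = []
    for i in range(n_starts):
        res = minimize(nll, start_vector(random=i > 0), method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 300})
        if np.isfinite(res.fun) and res.fun < 1e9:
            results.append((float(res.fun), res.x))
    if not results:
        raise RuntimeError(f"all optimisation starts failed for {model.name}")
    results.sort(key=lambda t: t[0])
    best_nll, best_x = results[0]
    near = sum(1 for f, _ in results if f - best_nll <= 0.01)
    fitted = model.unpack(best_x)
    spec = _FitParams(model.name, fitted)
    ll = model.loglik(tree, states, best_x, sampling_f)  # full accuracy
    return ModelFitResult(
        spec=spec, loglik=ll, k=model.k, aic=2 * model.k - 2 * ll,
        converged=near >= min(2, len(results)), sampling_f=float(np.mean(np.atleast_1d(sampling_f))),
        crown_age=crown,
    )
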