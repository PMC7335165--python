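"""Synthetic data with known truth: trees, traits, occurrences, paleocurves.

Every generator is deterministic given (parameters, seed) and returns the
simulated artifact together with a :class:`SimTruth` record of the
generating model, so downstream estimators can be validated against ground
truth without any external downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import dendropy
import numpy as np
import pandas as pd

from .trees import Phylogeny, TreeError, vcv_matrix

__all__ = [
    "SimTruth",
    "PaleoCurve",
    "simulate_bd_tree",
    "simulate_sse_tree",
    "simulate_timevarying_bd_tree",
    "simulate_bm_trait",
    "simulate_mk_binary",
    "simulate_occurrences",
    "make_paleo_curve",
]


class SimulationError(RuntimeError):
    """Raised when a conditioned simulation exhausts its retry budget."""


@dataclass
class SimTruth:
    """Provenance record attached to every simulated artifact."""

    model: str
    params: dict
    seed: int
    tip_states: dict | None = None
    tip_traits: dict | None = None
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PaleoCurve:
    """Paleotemperature samples, ages in Myr BP strictly decreasing to 0."""

    ages: np.ndarray
    temps: np.ndarray
    provenance: str = "raw"

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        if ages.ndim != 1 or ages.shape != temps.shape:
            raise ValueError("ages and temps must be matching 1-d arrays")
        d = np.diff(ages)
        if not (np.all(d < 0) or np.all(d > 0)):
            raise ValueError("ages must be strictly monotone")
        if not np.all(np.isfinite(temps)):
            raise ValueError("temperatures must be finite")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "temps", temps)

    def interpolator(self) -> Callable[[np.ndarray], np.ndarray]:
        """Linear interpolation T(age); clamped to endpoint values outside."""
        order = np.argsort(self.ages)
        xs, ys = self.ages[order], self.temps[order]

        def T(age):
            return np.interp(age, xs, ys)

        return T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_myr": self.ages, "temp_c": self.temps})


# ---------------------------------------------------------------------------
# birth-death / state-dependent tree simulation (exact, event-driven)
# ---------------------------------------------------------------------------

_REJECTION_CAP = 1000


class _Lineage:
    __slots__ = ("start", "state", "parent", "children", "end", "alive")

    def __init__(self, start, state, parent):
        self.start = start
        self.state = state
        self.parent = parent
        self.children = None
        self.end = None
        self.alive = True


def _gillespie_sse(lam, mu, q, root_state, stop, rng):
    """One attempt at a crown-conditioned state-dependent birth-death tree.

    ``stop`` is ``("n_tips", n)`` (stop at the birth event that reaches n
    extant lineages) or ``("age", T)``.  Returns (root_pair, tip_list) or
    None if the clade died or never reached the target.
    """
    k = len(lam)
    qrow = q.sum(axis=1)
    total_rate = lam + mu + qrow
    mode, target = stop
    t = 0.0
    a = _Lineage(0.0, root_state, None)
    b = _Lineage(0.0, root_state, None)
    active = [a, b]
    while True:
        n = len(active)
        if n == 0:
            return None
        rates = np.array([total_rate[ln.state] for ln in active])
        R = rates.sum()
        if mode == "n_tips" and n >= target:
            # stop the clock at the moment of the next (unexecuted) event so
            # that pendant edges are positive and tip covariances stay
            # non-singular
            if R > 0:
                t = t + rng.exponential(1.0 / R)
            break
        if R <= 0:
            if mode == "age":
                t = target
                break
            return None
        t_next = t + rng.exponential(1.0 / R)
        if mode == "age" and t_next >= target:
            t = target
            break
        t = t_next
        i = rng.choice(n, p=rates / R)
        ln = active[i]
        s = ln.state
        u = rng.random() * total_rate[s]
        if u < lam[s]:
            c1 = _Lineage(t, s, ln)
            c2 = _Lineage(t, s, ln)
            ln.children = (c1, c2)
            ln.end = t
            ln.alive = False
            active[i] = c1
            active.append(c2)
        elif u < lam[s] + mu[s]:
            ln.end = t
            ln.alive = False
            ln.children = ()
            active.pop(i)
        else:
            u -= lam[s] + mu[s]
            for s2 in range(k):
                if s2 == s:
                    continue
                if u < q[s, s2]:
                    ln.state = s2
                    break
                u -= q[s, s2]
    if len(active) < 2:
        return None
    for ln in active:
        ln.end = t
    return (a, b), active


def _build_phylogeny(root_pair, tips, rng=None, sampling_f=1.0):
    """Prune extinct/unsampled lineages and emit a Phylogeny + tip states."""
    if sampling_f < 1.0:
        kept = [ln for ln in tips if rng.random() < sampling_f]
    else:
        kept = list(tips)
    if len(kept) < 2:
        return None
    keep_set = set(id(ln) for ln in kept)

    def reduce(ln):
        # returns (dendropy node, pendant length offset) or None if no
        # sampled descendants below this lineage
        if ln.children is None:  # extant tip
            if id(ln) in keep_set:
                nd = dendropy.Node()
                nd.edge.length = ln.end - ln.start
                nd._sim_lineage = ln
                return nd
            return None
        if ln.children == ():  # extinct
            return None
        subs = [reduce(c) for c in ln.children]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:  # collapse unifurcation, summing lengths
            subs[0].edge.length += ln.end - ln.start
            return subs[0]
        nd = dendropy.Node()
        nd.edge.length = ln.end - ln.start
        for s in subs:
            nd.add_child(s)
        return nd

    a, b = root_pair
    left, right = reduce(a), reduce(b)
    if left is None or right is None:
        return None
    root = dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    states = {}
    for i, leaf in enumerate(tree.leaf_node_iter()):
        label = f"t{i + 1}"
        leaf.taxon = tns.new_taxon(label)
        states[label] = leaf._sim_lineage.state
    return Phylogeny(tree), states


def simulate_sse_tree(
    lambda0: float,
    lambda1: float,
    mu0: float,
    mu1: float,
    q01: float,
    q10: float,
    root_state: int = 0,
    stop: tuple = ("n_tips", 100),
    seed: int = 0,
    sampling_f: float = 1.0,
    max_retries: int = _REJECTION_CAP,
):
    """Binary state-dependent birth-death tree from two crown lineages.

    Exact Gillespie simulation on the growing tip set, conditioned on the
    stop criterion being reached (rejection with a retry cap).  Returns
    ``(Phylogeny, tip_states, SimTruth)`` with states as a label->{0,1} map.
    """
    lam = np.array([lambda0, lambda1])
    mu = np.array([mu0, mu1])
    q = np.array([[0.0, q01], [q10, 0.0]])
    if np.any(lam < 0) or np.any(mu < 0) or q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        out = _gillespie_sse(lam, mu, q, root_state, stop, rng)
        if out is None:
            continue
        built = _build_phylogeny(out[0], out[1], rng, sampling_f)
        if built is None:
            continue
        tree, states = built
        truth = SimTruth(
            model="sse_bd",
            params=dict(
                lambda0=lambda0, lambda1=lambda1, mu0=mu0, mu1=mu1,
                q01=q01, q10=q10, root_state=root_state, stop=stop,
                sampling_f=sampling_f,
            ),
            seed=seed,
            tip_states=states,
        )
        return tree, states, truth
    raise SimulationError(f"no surviving clade in {max_retries} attempts")


def simulate_bd_tree(
    lam: float,
    mu: float,
    stop: tuple = ("n_tips", 100),
    sampling_f: float = 1.0,
    seed: int = 0,
    max_retries: int = _REJECTION_CAP,
):
    """Constant-rate birth-death tree of extant sampled tips (crown start).

    Each extant tip is retained independently with probability
    ``sampling_f``.  Returns ``(Phylogeny, SimTruth)``.
    """
    if lam <= 0 or mu < 0 or not (0 < sampling_f <= 1):
        raise ValueError("need lambda > 0, mu >= 0, 0 < sampling_f <= 1")
    tree, _, truth = simulate_sse_tree(
        lam, lam, mu, mu, 0.0, 0.0,
        root_state=0, stop=stop, seed=seed,
        sampling_f=sampling_f, max_retries=max_retries,
    )
    truth.model = "constant_bd"
    truth.params = dict(lam=lam, mu=mu, stop=stop, sampling_f=sampling_f)
    truth.tip_states = None
    return tree, truth


def simulate_timevarying_bd_tree(
    lambda_of_age: Callable[[float], float],
    mu_of_age: Callable[[float], float],
    crown_age: float,
    seed: int = 0,
    sampling_f: float = 1.0,
    max_tips: int = 20000,
    max_retries: int = _REJECTION_CAP,
):
    """Birth-death tree whose rates vary with absolute age before present.

    Simulated forward from two crown lineages at ``crown_age`` using the
    thinning algorithm, with the rate bound taken as the maximum of
    lambda+mu over a fine age grid.  Returns ``(Phylogeny, SimTruth)``.
    """
    grid = np.linspace(0.0, crown_age, 2001)
    bound = max(float(lambda_of_age(a) + mu_of_age(a)) for a in grid) * 1.05
    if bound <= 0:
        raise ValueError("rates are identically zero on the age span")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        t = 0.0  # time since crown origin
        a0 = _Lineage(0.0, 0, None)
        b0 = _Lineage(0.0, 0, None)
        active = [a0, b0]
        failed = False
        while True:
            n = len(active)
            if n == 0:
                failed = True
                break
            if n > max_tips:
                failed = True
                break
            t_next = t + rng.exponential(1.0 / (bound * n))
            if t_next >= crown_age:
                t = crown_age
                break
            t = t_next
            age = crown_age - t
            lam_t = max(float(lambda_of_age(age)), 0.0)
            mu_t = max(float(mu_of_age(age)), 0.0)
            u = rng.random() * bound
            i = rng.integers(n)
            if u < lam_t:
                ln = active[i]
                c1 = _Lineage(t, 0, ln)
                c2 = _Lineage(t, 0, ln)
                ln.children = (c1, c2)
                ln.end = t
                ln.alive = False
                active[i] = c1
                active.append(c2)
            elif u < lam_t + mu_t:
                ln = active[i]
                ln.end = t
                ln.children = ()
                ln.alive = False
                active.pop(i)
            # else: thinned (no event)
        if failed or len(active) < 2:
            continue
        for ln in active:
            ln.end = t
        built = _build_phylogeny((a0, b0), active, rng, sampling_f)
        if built is None:
            continue
        tree, _ = built
        truth = SimTruth(
            model="timevarying_bd",
            params=dict(crown_age=crown_age, sampling_f=sampling_f),
            seed=seed,
        )
        return tree, truth
    raise SimulationError(f"no surviving clade in {max_retries} attempts")


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------

def simulate_bm_trait(
    tree: Phylogeny,
    sigma2: float,
    root_value: float = 0.0,
    lambda_signal: float = 1.0,
    seed: int = 0,
):
    """Brownian tip values with Pagel-lambda-scaled shared covariance.

    Tip values are multivariate normal with mean ``root_value``, covariance
    ``lambda_signal * sigma2 * C`` off the diagonal and the full
    ``sigma2 * depth`` variance on the diagonal.  Returns
    ``(trait_map, SimTruth)``.
    """
    if sigma2 < 0 or not (0.0 <= lambda_signal <= 1.0):
        raise ValueError("sigma2 >= 0 and lambda_signal in [0, 1] required")
    labels = tree.tip_labels
    n = len(labels)
    if sigma2 == 0:
        vals = np.full(n, root_value)
    else:
        C = vcv_matrix(tree)
        d = np.diag(C).copy()
        Cl = lambda_signal * C
        np.fill_diagonal(Cl, d)
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(sigma2 * Cl + 1e-12 * np.eye(n))
        vals = root_value + L @ rng.standard_normal(n)
    trait = {lbl: float(v) for lbl, v in zip(labels, vals)}
    truth = SimTruth(
        model="bm_trait",
        params=dict(sigma2=sigma2, root_value=root_value, lambda_signal=lambda_signal),
        seed=seed,
        tip_traits=trait,
    )
    return trait, truth


def simulate_mk_binary(tree: Phylogeny, q: float, root_state: int = 0, seed: int = 0):
    """Symmetric two-state Markov character evolved along the tree.

    Flip events occur at rate ``q`` per Myr along every branch (so the
    off-diagonal rate-matrix entries are ``q``); the tip state is the root
    state flipped by the parity of the Poisson event count on its path.
    Returns ``(state_map, SimTruth)``; the truth records the total number
    of simulated flip events.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    a = tree.arrays
    rng = np.random.default_rng(seed)
    state = np.zeros(a.n_nodes, dtype=np.int64)
    n_events = 0
    for v in a.postorder[::-1]:
        p = a.parent[v]
        if p < 0:
            state[v] = root_state
            continue
        flips = rng.poisson(q * a.blen[v])
        n_events += int(flips)
        state[v] = (state[p] + flips) % 2
    states = {lbl: int(state[i]) for i, lbl in enumerate(a.tip_labels)}
    truth = SimTruth(
        model="mk_binary",
        params=dict(q=q, root_state=root_state),
        seed=seed,
        tip_states=states,
        extras=dict(n_events=n_events),
    )
    return states, truth


# ---------------------------------------------------------------------------
# occurrence point clouds
# ---------------------------------------------------------------------------

def _wrap_lon(lon):
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def simulate_occurrences(
    species_spec: pd.DataFrame,
    artifact_rates: Mapping[str, float] | None = None,
    outlier_offset: float = 50.0,
    seed: int = 0,
):
    """Gaussian occurrence clouds per species with injected artifacts.

    ``species_spec`` columns: species, center_lat, center_lon, spread,
    n_records.  ``artifact_rates`` maps
    ``{zero_coord, integer_coord, far_outlier}`` to fractions; the number
    of injected artifacts per species is ``round(rate * n_records)`` (at
    least 1 when the rate is positive), which keeps recall checks sharp.
    Longitudes wrap at +/-180; the spread is isotropic in degrees.

    Returns ``(OccurrenceTable DataFrame, SimTruth)``; the truth carries a
    parallel ``artifact`` column naming each injected record's type.
    """
    rates = dict(zero_coord=0.0, integer_coord=0.0, far_outlier=0.0)
    if artifact_rates:
        unknown = set(artifact_rates) - set(rates)
        if unknown:
            raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
        rates.update(artifact_rates)
    rng = np.random.default_rng(seed)
    rows = []
    for rec in species_spec.itertuples(index=False):
        n = int(rec.n_records)
        lat = rec.center_lat + rng.standard_normal(n) * rec.spread
        lon = _wrap_lon(rec.center_lon + rng.standard_normal(n) * rec.spread)
        lat = np.clip(lat, -89.999, 89.999)
        artifact = np.array(["none"] * n, dtype=object)
        counts = {
            kind: (max(1, round(r * n)) if r > 0 else 0)
            for kind, r in rates.items()
        }
        if sum(counts.values()) > n:
            raise ValueError(f"artifact counts exceed n_records for {rec.species}")
        pool = rng.permutation(n)
        pos = 0
        for kind in ("zero_coord", "integer_coord", "far_outlier"):
            for _ in range(counts[kind]):
                i = pool[pos]
                pos += 1
                artifact[i] = kind
                if kind == "zero_coord":
                    if rng.random() < 0.5:
                        lat[i] = 0.0
                    else:
                        lon[i] = 0.0
                elif kind == "integer_coord":
                    lat[i] = float(np.round(lat[i]))
                    lon[i] = float(np.round(lon[i]))
                else:  # far_outlier: large displacement, kept non-integral
                    theta = rng.random() * 2 * math.pi
                    lat[i] = np.clip(
                        rec.center_lat + outlier_offset * math.sin(theta), -89.5, 89.5
                    )
                    # keep the displaced longitude unwrapped: the degree-space
                    # outlier filter measures raw coordinate distances, so a
                    # dateline-crossing outlier would corrupt its own cut
                    dlon = outlier_offset * math.cos(theta)
                    if abs(rec.center_lon + dlon) > 179.5:
                        dlon = -dlon
                    lon[i] = float(rec.center_lon + dlon)
                    if lat[i] == np.floor(lat[i]):
                        lat[i] += 0.123
                    if lon[i] == np.floor(lon[i]):
                        lon[i] += 0.123
        for j in range(n):
            rows.append((rec.species, float(lon[j]), float(lat[j]), artifact[j]))
    table = pd.DataFrame(rows, columns=["species", "decimalLongitude", "decimalLatitude", "artifact"])
    truth = SimTruth(
        model="occurrence_clouds",
        params=dict(rates=rates, outlier_offset=outlier_offset),
        seed=seed,
        extras=dict(artifact_counts=table["artifact"].value_counts().to_dict()),
    )
    out = table[["species", "decimalLongitude", "decimalLatitude"]].copy()
    truth.extras["artifact_column"] = table["artifact"].to_numpy()
    return out, truth


# ---------------------------------------------------------------------------
# paleotemperature curves
# ---------------------------------------------------------------------------

def make_paleo_curve(kind: str, params: Mapping | None = None, seed: int = 0) -> PaleoCurve:
    """Synthetic paleotemperature series.

    ``constant``: flat at ``temp`` (default 10 degC).
    ``linear_cooling``: linear from ``temp_old`` at ``age_max`` to
    ``temp_young`` at present.
    ``cramer_like``: spans 113 to 0 Myr with long-term cooling from a hot
    Late Cretaceous, an early-Eocene warm peak and a mid-Miocene local
    optimum bump, plus optional small Gaussian noise -- the qualitative
    shape of deep-time global temperature reconstructions.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "constant":
        temp = p.get("temp", 10.0)
        ages = np.linspace(p.get("age_max", 100.0), 0.0, p.get("n", 101))
        return PaleoCurve(ages, np.full_like(ages, temp), provenance="raw")
    if kind == "linear_cooling":
        age_max = p.get("age_max", 100.0)
        t_old = p.get("temp_old", 20.0)
        t_young = p.get("temp_young", 5.0)
        ages = np.linspace(age_max, 0.0, p.get("n", 201))
        temps = t_young + (t_old - t_young) * ages / age_max
        return PaleoCurve(ages, temps, provenance="raw")
    if kind == "cramer_like":
        age_max = p.get("age_max", 113.0)
        n = p.get("n", 227)
        ages = np.linspace(age_max, 0.0, n)
        base = 14.0 + 9.0 * (ages / age_max) ** 1.1
        eocene = 4.0 * np.exp(-0.5 * ((ages - 52.0) / 5.0) ** 2)
        miocene = 2.5 * np.exp(-0.5 * ((ages - 15.0) / 3.0) ** 2)
        noise = p.get("noise_sd", 0.0) * rng.standard_normal(n)
        return PaleoCurve(ages, base + eocene + miocene + noise, provenance="raw")
    raise ValueError(f"unknown curve kind: {kind!r}")
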