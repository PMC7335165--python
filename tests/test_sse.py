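import numpy as np
import pytest

from thermodiv.bd import RateSpec, bd_loglik, model_table
from thermodiv.mk import mk_loglik, mk_ml_q
from thermodiv.simulate import simulate_bd_tree, simulate_mk_binary, simulate_sse_tree
from thermodiv.sse import bisse_loglik, build_model_set, fit_sse, hisse_loglik
from thermodiv.trees import parse_newick

NEUTRAL = dict(lambda0=0.3, lambda1=0.3, mu0=0.1, mu1=0.1, q01=0.05, q10=0.05)
FREE = dict(lambda0=0.25, lambda1=0.4, mu0=0.05, mu1=0.12, q01=0.04, q10=0.07)


def rk4_two_tip_oracle(t1, t2, crown, states, params, h=1e-4):
    """Independent fixed-step RK4 on the coupled BiSSE system for a
    two-tip tree with pendant lengths t1, t2 (= crown for a cherry)."""
    lam = np.array([params["lambda0"], params["lambda1"]])
    mu = np.array([params["mu0"], params["mu1"]])
    Q = np.array([[0.0, params["q01"]], [params["q10"], 0.0]])
    qrow = Q.sum(axis=1)

    def deriv(y):
        E, D = y[:2], y[2:]
        dE = mu - (lam + mu + qrow) * E + lam * E**2 + Q @ E
        dD = -(lam + mu + qrow) * D + 2 * lam * E * D + Q @ D
        return np.concatenate([dE, dD])

    def integrate(span, D0):
        y = np.concatenate([np.zeros(2), D0])
        n = int(round(span / h))
        for _ in range(n):
            k1 = deriv(y)
            k2 = deriv(y + 0.5 * h * k1)
            k3 = deriv(y + 0.5 * h * k2)
            k4 = deriv(y + h * k3)
            y = y + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        return y

    tops = []
    for span, s in zip((t1, t2), states):
        D0 = np.zeros(2)
        D0[s] = 1.0
        tops.append(integrate(span, D0))
    E = tops[0][:2]
    Droot = lam * tops[0][2:] * tops[1][2:]
    w = Droot / Droot.sum()
    return float(np.log(np.sum(w * Droot / (lam * (1 - E) ** 2))))


class TestBisseOracle:
    @pytest.mark.parametrize("states", [(0, 0), (0, 1), (1, 1)])
    def test_two_tip_rk4(self, states):
        tree = parse_newick("(A:2.5,B:2.5);")
        tip_states = dict(zip(("A", "B"), states))
        mine = bisse_loglik(tree, tip_states, FREE)
        oracle = rk4_two_tip_oracle(2.5, 2.5, 2.5, states, FREE)
        assert mine == pytest.approx(oracle, abs=1e-6)


class TestBisseIdentities:
    @pytest.mark.parametrize("seed", range(4))
    def test_neutral_factorisation(self, seed):
        tree, _ = simulate_bd_tree(0.3, 0.1, ("n_tips", 50), seed=40 + seed)
        states, _ = simulate_mk_binary(tree, 0.05, seed=seed)
        lb = bisse_loglik(tree, states, NEUTRAL)
        lbd = bd_loglik(tree, RateSpec("time", "constant", "constant",
                                       lambda0=0.3, mu0=0.1))
        lmk = mk_loglik(tree, states, 0.05, root="fitzjohn")
        assert lb == pytest.approx(lbd + lmk, abs=1e-4)

    def test_label_swap_symmetry(self, bd50):
        states, _ = simulate_mk_binary(bd50, 0.08, seed=2)
        swapped = {k: 1 - v for k, v in states.items()}
        params_sw = dict(lambda0=FREE["lambda1"], lambda1=FREE["lambda0"],
                         mu0=FREE["mu1"], mu1=FREE["mu0"],
                         q01=FREE["q10"], q10=FREE["q01"])
        assert bisse_loglik(bd50, states, FREE) == pytest.approx(
            bisse_loglik(bd50, swapped, params_sw), abs=1e-9
        )

    def test_inert_character_reduces_to_bd(self, bd50):
        states = {l: 0 for l in bd50.tip_labels}
        p = dict(lambda0=0.3, lambda1=0.3, mu0=0.1, mu1=0.1, q01=0.0, q10=0.0)
        lbd = bd_loglik(bd50, RateSpec("time", "constant", "constant",
                                       lambda0=0.3, mu0=0.1))
        assert bisse_loglik(bd50, states, p) == pytest.approx(lbd, abs=1e-6)


class TestHisse:
    def _dup(self, bisse_params, qAB=0.02):
        out = dict(q01=bisse_params["q01"], q10=bisse_params["q10"],
                   qAB=qAB, qBA=qAB)
        for s, obs in [("0A", 0), ("1A", 1), ("0B", 0), ("1B", 1)]:
            out[f"lambda{s}"] = bisse_params[f"lambda{obs}"]
            out[f"mu{s}"] = bisse_params[f"mu{obs}"]
        return out

    def test_identical_hidden_collapses_to_bisse(self, bd50):
        states, _ = simulate_mk_binary(bd50, 0.06, seed=3)
        assert hisse_loglik(bd50, states, self._dup(FREE)) == pytest.approx(
            bisse_loglik(bd50, states, FREE), abs=1e-6
        )

    def test_cid_invariant_under_observed_relabelling(self, bd50):
        # diversification tied to the hidden state only: swapping the
        # observed tip labels must leave the likelihood unchanged when the
        # observed transition rates are symmetric
        states, _ = simulate_mk_binary(bd50, 0.06, seed=4)
        cid = dict(q01=0.05, q10=0.05, qAB=0.02, qBA=0.02)
        for s in ("0A", "1A"):
            cid[f"lambda{s}"] = 0.2
            cid[f"mu{s}"] = 0.05
        for s in ("0B", "1B"):
            cid[f"lambda{s}"] = 0.45
            cid[f"mu{s}"] = 0.1
        swapped = {k: 1 - v for k, v in states.items()}
        assert hisse_loglik(bd50, states, cid) == pytest.approx(
            hisse_loglik(bd50, swapped, cid), abs=1e-8
        )

    def test_sampling_fraction_changes_likelihood(self, bd50):
        states, _ = simulate_mk_binary(bd50, 0.06, seed=5)
        a = hisse_loglik(bd50, states, self._dup(FREE), sampling_f=1.0)
        b = hisse_loglik(bd50, states, self._dup(FREE), sampling_f=0.6)
        assert a != pytest.approx(b)


class TestModelSet:
    def test_four_models_with_expected_k(self):
        models = build_model_set()
        assert [m.name for m in models] == [
            "bisse_null", "bisse_free", "hisse_cid", "hisse_full",
        ]
        assert [m.k for m in models] == [4, 6, 6, 6]

    def test_null_mask_shares_rates(self):
        null = build_model_set()[0]
        p = null.unpack(np.log([0.3, 0.1, 0.04, 0.02]))
        assert p["lambda0"] == p["lambda1"] and p["mu0"] == p["mu1"]

    def test_full_mask_constraints(self):
        full = build_model_set()[3]
        theta = np.array([np.log(0.2), np.log(0.3), np.log(0.25), np.log(0.15),
                          0.0, np.log(0.01)])
        p = full.unpack(theta)
        # single transition rate everywhere, single relative extinction
        assert p["q01"] == p["q10"] == p["qAB"] == p["qBA"]
        eps = p["mu0A"] / p["lambda0A"]
        for s in ("1A", "0B", "1B"):
            assert p[f"mu{s}"] / p[f"lambda{s}"] == pytest.approx(eps)
        # net diversification matches the packed parameters
        assert p["lambda0A"] - p["mu0A"] == pytest.approx(0.2)


@pytest.fixture(scope="module")
def sim():
    tree, states, _ = simulate_sse_tree(
        0.1, 0.2, 0.03, 0.03, 0.01, 0.01, stop=("n_tips", 100), seed=55
    )
    return tree, states


class TestFitSse:
    def test_free_fit_orders_rates_and_nests(self, sim):
        tree, states = sim
        models = build_model_set()
        null = fit_sse(tree, states, models[0], n_starts=2, seed=1)
        free = fit_sse(tree, states, models[1], n_starts=2, seed=1)
        assert free.loglik >= null.loglik - 1e-6  # nesting
        assert free.spec.lambda1 > free.spec.lambda0  # true ratio is 2

    def test_table_weights_sum_to_one(self, sim):
        tree, states = sim
        models = build_model_set()
        fits = [fit_sse(tree, states, m, n_starts=1, seed=2) for m in models]
        tab = model_table(fits)
        assert tab["AW"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (tab["deltaAIC"] >= 0).all()


class TestMkHelpers:
    def test_mk_ml_floor(self, bd50):
        states = {l: 0 for l in bd50.tip_labels}
        states[bd50.tip_labels[0]] = 1
        q = mk_ml_q(bd50, states)
        assert q >= 1.0 / bd50.total_length - 1e-12

    def test_mk_loglik_matches_two_tip_closed_form(self):
        tree = parse_newick("(A:1,B:1);")
        q = 0.3
        same = 0.5 * (1 + np.exp(-2 * q))
        diff = 1 - same
        # stationary root: average over root states of product of branch probs
        expected = np.log(0.5 * (same * diff + diff * same))
        assert mk_loglik(tree, {"A": 0, "B": 1}, q) == pytest.approx(expected, abs=1e-12)
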