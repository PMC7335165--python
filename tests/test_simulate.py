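import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermodiv.simulate import (
    make_paleo_curve,
    simulate_bd_tree,
    simulate_bm_trait,
    simulate_mk_binary,
    simulate_occurrences,
    simulate_sse_tree,
    simulate_timevarying_bd_tree,
)


class TestBdTree:
    def test_pure_birth_reaches_target(self):
        tree, truth = simulate_bd_tree(1.0, 0.0, ("n_tips", 50), seed=1)
        assert tree.n_tips == 50
        assert tree.node_ages().ultrametric
        assert truth.model == "constant_bd"

    def test_yule_age_stop_tip_count_expectation(self):
        # from 2 crown lineages, E[n] at age T is 2 e^{lambda T}
        lam, T, reps = 0.5, 3.0, 300
        counts = []
        for s in range(reps):
            try:
                tree, _ = simulate_bd_tree(lam, 0.0, ("age", T), seed=s, max_retries=1)
                counts.append(tree.n_tips)
            except Exception:
                counts.append(0)  # cannot happen for pure birth from 2 lineages
        expect = 2 * np.exp(lam * T)
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(mean - expect) < 4 * se

    def test_sampling_fraction_binomial(self):
        # retained tip counts over reps should match binomial thinning
        f, n, reps = 0.5, 40, 200
        kept = []
        for s in range(reps):
            tree, _ = simulate_bd_tree(1.0, 0.0, ("n_tips", n), sampling_f=f, seed=s)
            kept.append(tree.n_tips)
        # compare against Binomial(40, 0.5) conditioned on >= 2
        ks = np.arange(0, n + 1)
        pmf = stats.binom.pmf(ks, n, f)
        pmf[:2] = 0
        pmf /= pmf.sum()
        exp_mean = (ks * pmf).sum()
        exp_sd = np.sqrt(((ks - exp_mean) ** 2 * pmf).sum())
        z = (np.mean(kept) - exp_mean) / (exp_sd / np.sqrt(reps))
        assert abs(z) < 4

    def test_determinism(self):
        a, _ = simulate_bd_tree(0.6, 0.1, ("n_tips", 30), seed=99)
        b, _ = simulate_bd_tree(0.6, 0.1, ("n_tips", 30), seed=99)
        assert a.to_newick() == b.to_newick()


class TestSseTree:
    def test_no_transitions_keeps_root_state(self):
        _, states, _ = simulate_sse_tree(0.5, 0.5, 0, 0, 0.0, 0.0,
                                         root_state=0, stop=("n_tips", 30), seed=3)
        assert set(states.values()) == {0}

    def test_neutral_rates_match_plain_bd(self):
        # with identical state rates the tip-count distribution at a fixed
        # age should be indistinguishable from the one-state simulator
        lam, mu, T = 0.6, 0.1, 3.0
        n_sse, n_bd = [], []
        for s in range(120):
            try:
                t1, _, _ = simulate_sse_tree(lam, lam, mu, mu, 0.05, 0.05,
                                             stop=("age", T), seed=s, max_retries=1)
                n_sse.append(t1.n_tips)
            except Exception:
                pass
            try:
                t2, _ = simulate_bd_tree(lam, mu, ("age", T), seed=10000 + s, max_retries=1)
                n_bd.append(t2.n_tips)
            except Exception:
                pass
        p = stats.mannwhitneyu(n_sse, n_bd).pvalue
        assert p > 0.001

    def test_fast_state_overrepresented(self):
        # lambda1 = 2 lambda0: state-1 tips should exceed the 50% Mk
        # stationary share in most replicates
        wins = 0
        reps = 30
        for s in range(reps):
            _, states, _ = simulate_sse_tree(0.1, 0.2, 0.0, 0.0, 0.03, 0.03,
                                             stop=("n_tips", 120), seed=s)
            frac1 = np.mean(list(states.values()))
            wins += frac1 > 0.5
        assert stats.binomtest(wins, reps, 0.5, alternative="greater").pvalue < 0.01


class TestBmTrait:
    def test_zero_rate_degenerate(self, cherry):
        trait, _ = simulate_bm_trait(cherry, 0.0, root_value=3.5, seed=0)
        assert set(trait.values()) == {3.5}

    def test_closed_form_moments_on_cherry(self):
        from thermodiv.trees import parse_newick
        tree = parse_newick("(A:4,B:4);")  # depth 4, no shared path
        reps = 2000
        vals = np.array([
            list(simulate_bm_trait(tree, 0.5, seed=s)[0].values()) for s in range(reps)
        ])
        var = vals.var(axis=0, ddof=1)
        cov = np.cov(vals.T)[0, 1]
        assert np.allclose(var, 0.5 * 4, rtol=0.15)
        assert abs(cov) < 0.3

    def test_lambda_zero_decorrelates(self, three_tip):
        reps = 1500
        vals = np.array([
            list(simulate_bm_trait(three_tip, 1.0, lambda_signal=0.0, seed=s)[0].values())
            for s in range(reps)
        ])
        corr = np.corrcoef(vals.T)
        off = corr[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.1)


class TestMkBinary:
    def test_zero_rate(self, yule100):
        states, _ = simulate_mk_binary(yule100, 0.0, root_state=1, seed=0)
        assert set(states.values()) == {1}

    def test_poisson_event_count(self, yule100):
        q = 0.02
        total = yule100.total_length
        events = [
            simulate_mk_binary(yule100, q, seed=s)[1].extras["n_events"]
            for s in range(300)
        ]
        lam = q * total
        z = (np.mean(events) - lam) / np.sqrt(lam / 300)
        assert abs(z) < 4

    def test_stationary_frequency_on_deep_tree(self):
        tree, _ = simulate_bd_tree(0.3, 0.0, ("n_tips", 60), seed=5)
        fracs = [
            np.mean(list(simulate_mk_binary(tree, 2.0, seed=s)[0].values()))
            for s in range(200)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.05


class TestOccurrences:
    spec = pd.DataFrame(
        dict(species=[f"sp{i}" for i in range(8)],
             center_lat=np.linspace(-40, 40, 8),
             center_lon=np.linspace(-150, 150, 8),
             spread=[1.0] * 8, n_records=[40] * 8)
    )

    def test_no_artifacts_all_clean(self):
        table, truth = simulate_occurrences(self.spec, None, seed=0)
        assert (truth.extras["artifact_column"] == "none").all()
        from thermodiv.occurrences import clean_occurrences
        cleaned = clean_occurrences(table)
        assert (cleaned["status"] == "kept").all()

    def test_outlier_distances(self):
        table, truth = simulate_occurrences(
            self.spec, dict(far_outlier=0.05), outlier_offset=50.0, seed=1
        )
        art = truth.extras["artifact_column"]
        for sp, grp in table.groupby("species"):
            sel = art[grp.index.to_numpy()] == "far_outlier"
            lon = grp["decimalLongitude"].to_numpy()
            lat = grp["decimalLatitude"].to_numpy()
            d = np.hypot(lon - lon[~sel].mean(), lat - lat[~sel].mean())
            assert d[sel].min() > 20  # far outliers really are far

    def test_mean_latitude_matches_center(self):
        table, truth = simulate_occurrences(self.spec, None, seed=2)
        for (sp, grp), center in zip(table.groupby("species", sort=False),
                                     self.spec["center_lat"]):
            se = 1.0 / np.sqrt(len(grp))
            assert abs(grp["decimalLatitude"].mean() - center) < 4 * se


class TestPaleoCurve:
    def test_constant(self):
        c = make_paleo_curve("constant", dict(temp=10.0))
        assert np.allclose(c.temps, 10.0)
        assert c.interpolator()(37.5) == pytest.approx(10.0)

    def test_linear_cooling_midpoint(self):
        c = make_paleo_curve(
            "linear_cooling", dict(age_max=100.0, temp_old=20.0, temp_young=5.0)
        )
        assert c.interpolator()(50.0) == pytest.approx(12.5)

    def test_cramer_like_cools_toward_present(self):
        c = make_paleo_curve("cramer_like")
        T = c.interpolator()
        assert T(0.0) < T(50.0)
        assert c.ages.max() == pytest.approx(113.0)

    def test_interpolator_clamps(self):
        c = make_paleo_curve("linear_cooling", dict(age_max=100.0))
        T = c.interpolator()
        assert T(150.0) == pytest.approx(T(100.0))


class TestTimevaryingBd:
    def test_fixed_crown_age(self):
        tree, _ = simulate_timevarying_bd_tree(
            lambda a: 0.3, lambda a: 0.0, crown_age=8.0, seed=0
        )
        assert tree.node_ages().crown_age == pytest.approx(8.0, rel=1e-9)

    def test_increasing_rate_gives_recent_nodes(self):
        # strongly increasing speciation toward the present should put
        # most branching events in the recent half of the tree
        young = 0
        for s in range(10):
            tree, _ = simulate_timevarying_bd_tree(
                lambda a: 0.8 * np.exp(-0.3 * a), lambda a: 0.0,
                crown_age=10.0, seed=s,
            )
            am = tree.node_ages()
            a = tree.arrays
            ages = [am.ages[i] for i in range(a.n_nodes) if a.children[i]]
            young += np.median(ages) < 5.0
        assert young >= 8
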