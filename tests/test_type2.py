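import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paradiverge import (
    DEFAULT_SCHEME,
    AAGroupScheme,
    SimConfig,
    Type2Params,
    classify_change,
    fit_type2,
    scheme_radical_fraction,
    simulate_family,
)
from paradiverge.simulate import truth_count_table
from paradiverge.type2_model import (
    AA20,
    EarlyChangeProfile,
    discrete_gamma_rates,
    early_profile,
    type2_posteriors,
    type2_site_likelihoods,
)
from tests.test_type1 import make_table


class TestScheme:
    def test_group_sizes(self):
        sizes = sorted(len(g) for g in DEFAULT_SCHEME.groups.values())
        assert sizes == [2, 3, 7, 8]

    def test_partition_total(self):
        letters = [l for g in DEFAULT_SCHEME.groups.values() for l in g]
        assert sorted(letters) == sorted(AA20)

    def test_incomplete_scheme_rejected(self):
        with pytest.raises(ValueError):
            AAGroupScheme({"all_but_one": frozenset(AA20[:-1])})

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("D", "E", "conserved"),  # both negatively charged
            ("F", "S", "radical"),  # hydrophobic -> hydrophilic
            ("K", "Q", "radical"),  # positively charged -> hydrophilic
            ("N", "D", "radical"),  # hydrophilic -> negatively charged
            ("K", "K", "identical"),
        ],
    )
    def test_classify(self, a, b, expected):
        assert classify_change(a, b) == expected

    @given(st.sampled_from(AA20), st.sampled_from(AA20))
    @settings(deadline=None, derandomize=True)
    def test_classify_symmetric(self, a, b):
        assert classify_change(a, b) == classify_change(b, a)

    def test_unknown_letter_rejected(self):
        with pytest.raises(KeyError):
            classify_change("B", "A")

    def test_radical_fraction_brute_force(self):
        # independent enumeration over all 190 unordered pairs
        pairs = list(itertools.combinations(AA20, 2))
        group = {aa: name for name, g in DEFAULT_SCHEME.groups.items() for aa in g}
        n_conserved = sum(1 for a, b in pairs if group[a] == group[b])
        assert len(pairs) == 190
        assert n_conserved == 53
        assert scheme_radical_fraction() == pytest.approx(137 / 190, rel=1e-12)

    def test_degenerate_schemes(self):
        one_group = AAGroupScheme({"all": frozenset(AA20)})
        assert scheme_radical_fraction(one_group) == 0.0
        singletons = AAGroupScheme({aa: frozenset(aa) for aa in AA20})
        assert scheme_radical_fraction(singletons) == 1.0


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 2.0, 10.0])
    def test_category_means_average_to_one(self, alpha):
        rates = discrete_gamma_rates(alpha, k=8)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(rates) > 0)


class TestEarlyProfile:
    def test_identical_ancestors_all_n(self):
        table = make_table([0, 0], [0, 0])
        prof = early_profile(table)
        assert prof.classes.tolist() == ["N", "N"]

    def test_radical_patterns(self):
        from paradiverge.ancestral import SiteCountTable

        data = pd.DataFrame(
            {
                "column_1based": [1, 2, 3],
                "reference_position": [1, 2, 3],
                "x1": [0, 0, 0],
                "x2": [0, 0, 0],
                "a1": ["N", "K", "D"],
                "a2": ["D", "Q", "E"],
                "tie1": [False] * 3,
                "tie2": [False] * 3,
            }
        )
        prof = early_profile(SiteCountTable(data, "c1", "c2"))
        # N->D hydrophilic vs negative: radical; K->Q positive vs
        # hydrophilic: radical; D->E within-group: conserved
        assert prof.classes.tolist() == ["R", "R", "C"]


class TestSiteLikelihoods:
    def params(self, **kw):
        defaults = dict(theta=0.2, alpha=1.0, m1=1.0, m2=1.0, d_e=0.5)
        defaults.update(kw)
        return Type2Params(**defaults)

    def test_f1_zero_for_non_radical(self):
        p = self.params()
        f0, f1 = type2_site_likelihoods(
            np.array(["N", "C", "R"]), np.array([0, 0, 0]), np.array([0, 0, 0]), p
        )
        assert f1[0] == 0.0 and f1[1] == 0.0 and f1[2] > 0.0

    def test_radical_zero_counts_maximize_f1_ratio(self):
        p = self.params()
        counts = np.array([0, 1, 2, 3])
        f0, f1 = type2_site_likelihoods(
            np.array(["R"] * 4), counts, counts, p
        )
        ratio = f1 / f0
        assert np.all(np.diff(ratio) < 0)

    @pytest.mark.parametrize("alpha,d_e", [(1.0, 0.5), (0.5, 1.0)])
    def test_f0_normalization_over_outcome_space(self, alpha, d_e):
        p = self.params(alpha=alpha, d_e=d_e)
        grid = np.arange(0, 120)
        g1, g2 = np.meshgrid(grid, grid, indexing="ij")
        total = 0.0
        for c in "NCR":
            classes = np.full(g1.size, c, dtype="<U1")
            f0, _ = type2_site_likelihoods(classes, g1.ravel(), g2.ravel(), p)
            total += f0.sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_f1_normalization(self):
        p = self.params()
        grid = np.arange(0, 80)
        g1, g2 = np.meshgrid(grid, grid, indexing="ij")
        classes = np.full(g1.size, "R", dtype="<U1")
        _, f1 = type2_site_likelihoods(classes, g1.ravel(), g2.ravel(), p)
        assert f1.sum() == pytest.approx(1.0, abs=1e-6)


class TestPosteriorsAndFit:
    def test_non_radical_posteriors_zero(self):
        table = make_table([0, 1], [0, 2])
        prof = EarlyChangeProfile(
            np.array(["N", "C"]), np.array(["A", "K"]), np.array(["A", "R"]),
            np.zeros(2, bool),
        )
        p = Type2Params(theta=0.3, alpha=1.0, m1=1.0, m2=1.0, d_e=0.5)
        post = type2_posteriors(prof, table, p)
        assert np.all(post.q == 0.0)

    def test_equal_observables_equal_posteriors(self):
        table = make_table([1, 1], [0, 0])
        prof = EarlyChangeProfile(
            np.array(["R", "R"]), np.array(["F", "F"]), np.array(["S", "S"]),
            np.zeros(2, bool),
        )
        p = Type2Params(theta=0.3, alpha=1.0, m1=1.0, m2=1.0, d_e=0.5)
        post = type2_posteriors(prof, table, p)
        assert post.q[0] == pytest.approx(post.q[1], rel=1e-12)

    def test_zero_radical_profile_theta_zero(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(1.0, size=100)
        table = make_table(x, x)
        prof = EarlyChangeProfile(
            np.array(["N"] * 100), np.array(["A"] * 100), np.array(["A"] * 100),
            np.zeros(100, bool),
        )
        est, params = fit_type2(prof, table)
        assert est.theta_hat == 0.0
        assert "no identifiable signal" in est.notes

    def test_recovers_paper_scale_theta(self):
        hats = []
        for seed in range(5):
            cfg = SimConfig(L=1000, theta2=0.236, seed=4000 + seed)
            _, _, _, truth = simulate_family(cfg)
            table = truth_count_table(truth)
            est, _ = fit_type2(early_profile(table), table)
            hats.append(est.theta_hat)
        assert abs(np.mean(hats) - 0.236) <= 0.07

    def test_called_fraction_monotone_in_theta(self):
        fracs = []
        for theta2 in (0.05, 0.2, 0.4):
            cfg = SimConfig(L=800, theta2=theta2, seed=777)
            _, _, _, truth = simulate_family(cfg)
            table = truth_count_table(truth)
            prof = early_profile(table)
            est, params = fit_type2(prof, table)
            post = type2_posteriors(prof, table, params)
            fracs.append(np.mean(post.q > 0.67))
        assert fracs[0] < fracs[1] < fracs[2]
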