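import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb

from paradiverge import (
    Alignment,
    BindingSiteList,
    ClusterPair,
    call_divergent_sites,
    conservation_summary,
    enrichment_from_counts,
    enrichment_test,
    type2_pattern_check,
)
from paradiverge.sitescan import chi2_2x2
from paradiverge.type1_model import SitePosteriorProfile


def profile_from(qs):
    return SitePosteriorProfile("type-II", np.arange(1, len(qs) + 1), np.array(qs))


class TestCallSites:
    def test_strict_inequality_at_cutoff(self):
        called = call_divergent_sites(profile_from([0.66, 0.68]), cutoff=0.67)
        assert called["reference_position"].tolist() == [2]

    def test_ratio_two_equals_q_two_thirds(self):
        qs = [0.5, 2 / 3, 0.7, 0.9]
        by_q = call_divergent_sites(profile_from(qs), cutoff=2 / 3)
        prof = profile_from(qs)
        by_r = prof.to_frame()[prof.r > 2.0]
        assert by_q["reference_position"].tolist() == by_r["reference_position"].tolist()

    def test_all_zero_profile_empty(self):
        assert len(call_divergent_sites(profile_from([0.0, 0.0]))) == 0

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        prof = profile_from(rng.random(50))
        sizes = [len(call_divergent_sites(prof, c)) for c in (0.3, 0.5, 0.7, 0.9)]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            call_divergent_sites(profile_from([0.5]), cutoff=1.5)


class TestConservation:
    def test_modal_fraction(self, tiny_clusters):
        aln = Alignment(
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            ["F", "F", "F", "K", "K", "R"],
        )
        s = conservation_summary(aln, tiny_clusters, np.array([0]))
        row_a = s[s["cluster"] == "A"].iloc[0]
        row_b = s[s["cluster"] == "B"].iloc[0]
        assert row_a["modal"] == "F" and row_a["modal_fraction"] == 1.0
        assert row_b["modal"] == "K" and row_b["modal_fraction"] == pytest.approx(2 / 3)

    def test_composition_fractions_sum_to_one(self, tiny_alignment, tiny_clusters):
        s = conservation_summary(tiny_alignment, tiny_clusters, np.arange(5))
        for _, row in s.iterrows():
            counts = [int(part.split(":")[1]) for part in row["composition"].split(",")]
            assert sum(counts) == 3


class TestPatternCheck:
    def test_f_vs_s_pattern_true(self, tiny_alignment, tiny_clusters):
        ok, report = type2_pattern_check(1, tiny_alignment, tiny_clusters)
        assert ok and report["change_class"] == "radical"

    def test_conserved_group_change_false(self, tiny_alignment, tiny_clusters):
        ok, report = type2_pattern_check(2, tiny_alignment, tiny_clusters)
        assert not ok and report["change_class"] == "conserved"

    def test_unconserved_cluster_false(self, tiny_clusters):
        aln = Alignment(
            ["a1", "a2", "a3", "b1", "b2", "b3"],
            ["F", "F", "S", "S", "S", "S"],
        )
        ok, report = type2_pattern_check(0, aln, tiny_clusters, tau=0.8)
        assert not ok and not report["conserved_both"]


def fisher_two_sided_enum(a, b, c, d):
    """Two-sided Fisher p by enumeration of the hypergeometric tail."""
    n, r1, c1 = a + b + c + d, a + b, a + c

    def p_table(x):
        return (
            comb(r1, x, exact=True)
            * comb(n - r1, c1 - x, exact=True)
            / comb(n, c1, exact=True)
        )

    p_obs = p_table(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = p_table(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestEnrichment:
    def test_chi2_closed_form_matches_scipy(self):
        res = enrichment_from_counts(2, 8, 12, 477)
        a, b, c, d = res.table
        n = a + b + c + d
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.chi2_stat == pytest.approx(stat, rel=1e-12)

    @given(
        st.integers(0, 15), st.integers(0, 15), st.integers(0, 30), st.integers(1, 60)
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_fisher_matches_hypergeometric_enumeration(self, a, b, c, d):
        p_impl = enrichment_from_counts(
            a, a + b, a + c, a + b + c + d, method="fisher"
        ).p_fisher
        p_enum = fisher_two_sided_enum(a, b, c, d)
        assert p_impl == pytest.approx(p_enum, rel=1e-8, abs=1e-12)

    def test_zero_overlap_at_expectation_not_significant(self):
        # 5 divergent, 10 binding, total 1000: expected overlap 0.05 ~ 0
        res = enrichment_from_counts(0, 5, 10, 1000)
        assert res.p_chi2 > 0.4

    def test_binding_subset_of_divergent_fisher(self):
        res = enrichment_from_counts(3, 10, 3, 50, method="fisher")
        assert res.p_fisher == pytest.approx(fisher_two_sided_enum(3, 7, 0, 40), rel=1e-8)

    def test_order_invariance(self):
        div = [345, 34, 405, 150]
        bind = [405, 1, 345, 99]
        r1 = enrichment_test(div, bind, 477)
        r2 = enrichment_test(sorted(div), sorted(bind), 477)
        assert r1.table == r2.table and r1.p_chi2 == r2.p_chi2

    def test_position_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test({500}, {10}, 477)

    def test_chi2_2x2_degenerate_margin(self):
        stat, p = chi2_2x2(0, 0, 5, 10)
        assert stat == 0.0 and p == 1.0


class TestBindingSiteList:
    def test_letter_validated_against_reference(self):
        aln = Alignment(["ref", "o1"], ["FKA-W", "FKAYW"])
        bs = BindingSiteList("ref", [1, 4], ["F", "W"])
        bs.validate_against(aln)  # gap skipped: W is reference position 4

    def test_letter_mismatch_rejected(self):
        aln = Alignment(["ref", "o1"], ["FKAW", "FKAY"])
        bs = BindingSiteList("ref", [2], ["R"])
        with pytest.raises(ValueError, match="coordinate"):
            bs.validate_against(aln)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BindingSiteList("ref", [5, 5], ["F", "F"])
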