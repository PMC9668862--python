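import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossmark.differential import (
    CONTRASTS,
    DifferentialRecord,
    cohort_differential,
    consensus_markers,
    filter_to_detectable,
    phylum_composition_test,
    pooled_differential,
    wilcoxon_rank_sum,
)
from crossmark.profiles import CohortProfile
from crossmark.simulate import default_config, generate_cohorts
from conftest import make_profile


def exact_wilcoxon_oracle(x, y):
    """Full enumeration of the rank-sum null (tie-free): two-sided p as the
    fraction of assignments whose |U - mu| is at least as extreme."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(sorted(ranks.values())[i] for i in combo)
        u = r - n1 * (n1 + 1) / 2
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return count / total


class TestWilcoxon:
    def test_identical_multisets(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_separated_exact(self):
        # 2 of the 20 equally likely assignments are at least this extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_oracle_all_small_sizes(self):
        rng = np.random.default_rng(0)
        for n1 in range(2, 9):
            for n2 in range(2, 11 - n1):
                for _ in range(5):
                    x = rng.normal(size=n1)
                    y = rng.normal(size=n2)
                    p_impl = wilcoxon_rank_sum(x, y)
                    p_oracle = exact_wilcoxon_oracle(x, y)
                    assert p_impl == pytest.approx(p_oracle, abs=1e-10)

    def test_normal_approx_close_to_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            p_approx = mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            assert abs(p_exact - p_approx) < 0.02

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])

    @given(
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8),
        st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_symmetry(self, x, y):
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))


class TestCohortDifferential:
    def test_planted_marker_found_up(self, default_run):
        _, profiles, truth = default_run
        recs = cohort_differential(profiles[0], "CRC_vs_HC")
        by_taxon = {r.taxon: r for r in recs}
        for genus, direction in truth.markers["CRC_vs_HC"][:3]:  # sharp markers
            assert genus in by_taxon
            assert by_taxon[genus].direction == direction

    def test_alpha_one_returns_all(self, two_group_profile):
        recs = cohort_differential(two_group_profile, "CRC_vs_HC", alpha=1.01)
        assert len(recs) == len(two_group_profile.taxa)

    def test_null_type_one_calibration(self):
        """A null genus is flagged in about 5% of seeds at alpha 0.05."""
        from scipy.stats import binom

        hits = 0
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            hits += wilcoxon_rank_sum(x, y) < 0.05
        lo, hi = binom.ppf([0.005, 0.995], 100, 0.05)
        assert lo <= hits <= hi

    def test_missing_group_rejected(self):
        prof = make_profile(np.random.default_rng(0).dirichlet([1, 1], size=6),
                            groups=["HC"] * 6)
        with pytest.raises(ValueError):
            cohort_differential(prof, "CRC_vs_HC")

    def test_direction_invariant_to_joint_renormalization(self, two_group_profile):
        recs1 = cohort_differential(two_group_profile, "CRC_vs_HC", alpha=1.01)
        scaled = CohortProfile(
            "c1", two_group_profile.abundance * 100.0, two_group_profile.metadata
        )
        recs2 = cohort_differential(scaled, "CRC_vs_HC", alpha=1.01)
        assert [r.direction for r in recs1] == [r.direction for r in recs2]
        assert [r.p_value for r in recs1] == pytest.approx([r.p_value for r in recs2])


def _rec(taxon, cohort, direction, contrast="CRC_vs_HC", p=0.01):
    up = direction == "up"
    return DifferentialRecord(taxon, cohort, contrast, p, 0.2 if up else 0.1,
                              0.1 if up else 0.2)


class TestConsensus:
    def test_vote_rule_included(self):
        recs = [_rec("G", f"c{i}", "up") for i in range(3)]
        out = consensus_markers(recs, min_cohorts=3)
        assert len(out) == 1
        assert out[0].direction == "up"
        assert out[0].n_significant_cohorts == 3

    def test_direction_conflict_excluded(self):
        recs = [_rec("G", "c1", "up"), _rec("G", "c2", "up"), _rec("G", "c3", "down")]
        assert consensus_markers(recs, min_cohorts=3) == []

    def test_invariant_to_order_and_duplication(self):
        recs = [_rec("G", f"c{i}", "up") for i in range(4)]
        a = consensus_markers(recs, 3)
        b = consensus_markers(recs[::-1] + [recs[0]], 3)
        assert [(m.taxon, m.n_significant_cohorts, m.direction) for m in a] == [
            (m.taxon, m.n_significant_cohorts, m.direction) for m in b
        ]

    def test_min_cohorts_validated(self):
        with pytest.raises(ValueError):
            consensus_markers([], min_cohorts=1)

    def test_recovers_planted_markers(self, default_run):
        _, profiles, truth = default_run
        recs = []
        for p in profiles:
            recs += cohort_differential(p, "CRC_vs_HC")
        found = {m.taxon: m.direction for m in consensus_markers(recs, 3)}
        planted = dict(truth.markers["CRC_vs_HC"])
        recovered = [g for g in planted if g in found and found[g] == planted[g]]
        assert len(recovered) >= 0.9 * len(planted)


class TestFilterToDetectable:
    def test_passthrough_and_subset(self):
        markers = [
            consensus_markers([_rec(g, f"c{i}", "up") for i in range(3)], 3)[0]
            for g in ["Fusobacterium", "Parvimonas", "Gemella"]
        ]
        kept = filter_to_detectable(markers, ["Fusobacterium", "Gemella"])
        assert [m.taxon for m in kept] == ["Fusobacterium", "Gemella"]

    def test_known_six_genus_panel(self):
        """A 12-genus consensus filtered by a 6-genus 16S-detectable list."""
        twelve = [
            "Anaerostipes", "Porphyromonas", "Fusobacterium", "Parvimonas",
            "Peptostreptococcus", "Gemella", "Eikenella", "Escherichia",
            "Anaerococcus", "Solobacterium", "Morganella", "Eubacterium",
        ]
        six = ["Anaerostipes", "Porphyromonas", "Fusobacterium", "Parvimonas",
               "Peptostreptococcus", "Gemella"]
        markers = [
            consensus_markers([_rec(g, f"c{i}", "up") for i in range(3)], 3)[0]
            for g in twelve
        ]
        kept = filter_to_detectable(markers, six)
        assert sorted(m.taxon for m in kept) == sorted(six)

    def test_empty_intersection_warns(self):
        markers = consensus_markers([_rec("G", f"c{i}", "up") for i in range(3)], 3)
        with pytest.warns(UserWarning):
            assert filter_to_detectable(markers, ["Other"]) == []

    def test_empty_detectable_rejected(self):
        with pytest.raises(ValueError):
            filter_to_detectable([], [])


class TestPhylumComposition:
    def test_identical_composition_p_near_one(self):
        vals = np.tile([0.5, 0.3, 0.2], (12, 1))
        prof = make_profile(vals, groups=["HC"] * 6 + ["CRC"] * 6,
                            taxa=["Firmicutes", "Bacteroidetes", "Fusobacteria"])
        _, p = phylum_composition_test(prof, top_k=3)
        assert p > 0.99

    def test_shifted_composition_detected(self):
        a = np.tile([80.0, 15.0, 5.0], (6, 1)) / 100
        b = np.tile([10.0, 15.0, 75.0], (6, 1)) / 100
        prof = make_profile(np.vstack([a, b]), groups=["HC"] * 6 + ["CRC"] * 6,
                            taxa=["F", "B", "Fu"])
        _, p = phylum_composition_test(prof, top_k=3)
        assert p < 0.05

    def test_statistic_matches_hand_chi_square(self):
        a = np.tile([60.0, 30.0, 10.0], (4, 1)) / 100
        b = np.tile([40.0, 40.0, 20.0], (4, 1)) / 100
        prof = make_profile(np.vstack([a, b]), groups=["HC"] * 4 + ["CRC"] * 4,
                            taxa=["X", "Y", "Z"])
        chi2, _ = phylum_composition_test(prof, top_k=3)
        obs = np.array([[60, 30, 10], [40, 40, 20]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        hand = ((obs - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(hand)


class TestPooledDifferential:
    def test_single_cohort_matches_per_cohort_up_to_transform(self, default_run):
        _, profiles, _ = default_run
        p = profiles[0]
        pooled = pooled_differential([p], "CRC_vs_HC", alpha=1.01, batch_adjust=False)
        single = cohort_differential(p, "CRC_vs_HC", alpha=1.01)
        shared = set(m.taxon for m in pooled) & set(m.taxon for m in single)
        pp = {m.taxon: m.p_value for m in pooled}
        ps = {m.taxon: m.p_value for m in single}
        for t in shared:
            assert pp[t] == pytest.approx(ps[t])

    def test_recovers_planted_markers_in_mixed_data(self, default_run):
        _, profiles, truth = default_run
        recs = pooled_differential(profiles, "CRC_vs_HC", alpha=0.05, batch_adjust=True)
        found = {r.taxon: r.direction for r in recs}
        planted = dict(truth.markers["CRC_vs_HC"])
        hits = [g for g, d in planted.items() if found.get(g) == d]
        assert len(hits) >= 0.9 * len(planted)

    def test_batch_adjustment_removes_confounded_false_positives(self):
        """Unbalanced group composition across strongly batched null cohorts:
        the unadjusted pooled test inflates, the adjusted one does not."""
        cfg = default_config(seed=21, markers=[], ko_links=[], n_cohorts=2,
                            samples_per_group={"HC": 35, "CRC": 35})
        profiles, _ = generate_cohorts(cfg)
        skewed = []
        for i, p in enumerate(profiles):
            g = p.groups()
            hc = g[g == "HC"].index
            crc = g[g == "CRC"].index
            keep = list(hc[:30]) + list(crc[:5]) if i == 0 else list(hc[:5]) + list(crc[:30])
            skewed.append(CohortProfile(p.cohort_id, p.abundance.loc[keep],
                                        p.metadata.loc[keep]))
        n_unadj = len(pooled_differential(skewed, "CRC_vs_HC", 0.05, batch_adjust=False))
        n_adj = len(pooled_differential(skewed, "CRC_vs_HC", 0.05, batch_adjust=True))
        assert n_unadj > n_adj
        assert n_unadj > 0.2 * 130  # unadjusted is grossly inflated
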