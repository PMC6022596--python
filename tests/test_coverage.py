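"""Breadth-of-coverage arithmetic and the lost/conserved classifier."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pavcomp.cluster import OrthoGroupSet
from pavcomp.coverage import (
    CoverageRecord,
    GroupCoverage,
    classify,
    classify_all,
    group_mean_coverage,
    horizontal_coverage,
    union_covered_bases,
)
from pavcomp.io import CdsCatalog, HspRecord


def bitmap_union(intervals, length):
    """Independent per-base oracle for interval-union size."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        s, e = max(s, 1), min(e, length)
        if s <= e:
            mask[s - 1 : e] = True
    return int(mask.sum())


def make_hit(subject, s, e, query="r1"):
    return HspRecord(query, subject, 99.0, e - s + 1, 0, 0, 1, e - s + 1, s, e, 1e-20, 80.0)


class TestUnionCoveredBases:
    @pytest.mark.parametrize(
        "intervals,length,expected",
        [
            ([(1, 50), (41, 90)], 100, 90),
            ([], 100, 0),
            ([(1, 100)], 100, 100),
            ([(10, 20), (10, 20), (10, 20)], 100, 11),  # duplicates are free
            ([(90, 300)], 100, 11),  # clipped to the CDS
            ([(1, 10), (11, 20)], 100, 20),  # adjacent, no overlap
        ],
    )
    def test_known_unions(self, intervals, length, expected):
        assert union_covered_bases(intervals, length) == expected

    def test_order_and_duplication_invariant(self, rng):
        intervals = [
            tuple(sorted(rng.integers(1, 5000, size=2).tolist())) for _ in range(200)
        ]
        base = union_covered_bases(intervals, 5000)
        shuffled = list(intervals)
        rng.shuffle(shuffled)
        assert union_covered_bases(shuffled + intervals, 5000) == base

    def test_random_fixtures_match_bitmap_oracle(self, rng):
        for _ in range(50):
            intervals = [
                tuple(sorted(rng.integers(1, 5001, size=2).tolist()))
                for _ in range(200)
            ]
            assert union_covered_bases(intervals, 5000) == bitmap_union(intervals, 5000)

    def test_negative_length_interval_raises(self):
        with pytest.raises(ValueError):
            union_covered_bases([(10, 5)], 100)

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(1, 200)).map(
                lambda t: (min(t), max(t))
            ),
            max_size=30,
        )
    )
    def test_union_equals_bitmap_property(self, intervals):
        assert union_covered_bases(intervals, 200) == bitmap_union(intervals, 200)


class TestHorizontalCoverage:
    @pytest.fixture()
    def catalog(self):
        cat = CdsCatalog()
        cat.add("SP1", "g1", "A" * 200)
        cat.add("SP1", "g2", "C" * 100)
        return cat

    def test_full_span_hit_is_100(self, catalog):
        (r1, r2) = sorted(
            horizontal_coverage([make_hit("g1", 1, 200)], catalog),
            key=lambda r: r.gene_id,
        )
        assert r1.horizontal_coverage == 100.0
        assert r2.horizontal_coverage == 0.0  # hit-less CDS still reported

    def test_unknown_subject_lists_offenders(self, catalog):
        with pytest.raises(ValueError, match="ghost"):
            horizontal_coverage([make_hit("ghost", 1, 50)], catalog)

    def test_compositional_oracle(self, rng):
        """Each record equals union_covered_bases applied to its own hits."""
        cat = CdsCatalog()
        lengths = {}
        for i in range(10):
            lengths[f"g{i}"] = int(rng.integers(100, 400))
            cat.add("SP1", f"g{i}", "A" * lengths[f"g{i}"])
        hits, per_gene = [], {g: [] for g in lengths}
        for j in range(300):
            g = f"g{int(rng.integers(10))}"
            s, e = sorted(rng.integers(1, lengths[g] + 1, size=2).tolist())
            hits.append(make_hit(g, s, e, query=f"r{j}"))
            per_gene[g].append((s, e))
        for rec in horizontal_coverage(hits, cat):
            expected = union_covered_bases(per_gene[rec.gene_id], lengths[rec.gene_id])
            assert rec.covered_bases == expected
            assert rec.horizontal_coverage == pytest.approx(
                100 * expected / lengths[rec.gene_id]
            )

    def test_monotone_under_added_hits(self, catalog):
        base = {
            r.gene_id: r.covered_bases
            for r in horizontal_coverage([make_hit("g1", 50, 80)], catalog)
        }
        more = {
            r.gene_id: r.covered_bases
            for r in horizontal_coverage(
                [make_hit("g1", 50, 80), make_hit("g1", 100, 150), make_hit("g2", 1, 10)],
                catalog,
            )
        }
        assert all(more[g] >= c for g, c in base.items())


class TestGroupMeanCoverage:
    @pytest.fixture()
    def groups(self):
        return OrthoGroupSet(
            {
                "OG1": {sp: [f"{sp}_a"] for sp in ("ATH", "OSA", "MAC", "PDA", "SPO")},
                "OG2": {"ATH": ["ATH_b"], "OSA": ["OSA_b"]},
            }
        )

    @staticmethod
    def record(sp, gene, pct, length=100):
        covered = round(pct * length / 100)
        return CoverageRecord(sp, gene, covered, length, pct)

    def test_mean_over_species(self, groups):
        vals = {"ATH": 60, "OSA": 40, "MAC": 20, "PDA": 40, "SPO": 40}
        records = [self.record(sp, f"{sp}_a", v) for sp, v in vals.items()]
        gc = {g.group_id: g for g in group_mean_coverage(records, groups)}
        assert gc["OG1"].mean_coverage == pytest.approx(40.0)

    def test_na_species_excluded_from_mean(self, groups):
        records = [self.record("ATH", "ATH_a", 60)]
        gc = {g.group_id: g for g in group_mean_coverage(records, groups)}
        assert gc["OG1"].mean_coverage == pytest.approx(60.0)
        assert gc["OG1"].per_species_coverage["OSA"] is None

    def test_all_na_gives_no_data(self, groups):
        gc = {g.group_id: g for g in group_mean_coverage([], groups)}
        assert gc["OG1"].mean_coverage is None
        assert classify(gc["OG1"]).status == "NO_DATA"

    def test_absent_species_as_zero_switch(self, groups):
        records = [self.record("ATH", "ATH_a", 60)]
        gc = {
            g.group_id: g
            for g in group_mean_coverage(records, groups, absent_species_as_zero=True)
        }
        assert gc["OG1"].mean_coverage == pytest.approx(12.0)  # 60/5

    def test_multicopy_members_average_within_species(self):
        groups = OrthoGroupSet({"OG1": {"ATH": ["a1", "a2"]}})
        records = [self.record("ATH", "a1", 80), self.record("ATH", "a2", 20)]
        (gc,) = group_mean_coverage(records, groups)
        assert gc.mean_coverage == pytest.approx(50.0)


class TestClassify:
    @pytest.mark.parametrize(
        "mean,expected",
        [
            (1.9, "LOST"),
            (55.0, "CONSERVED"),
            (2.0, "INDETERMINATE"),  # strict inequality at the lost bound
            (50.0, "INDETERMINATE"),  # strict inequality at the conserved bound
            (0.0, "LOST"),
            (100.0, "CONSERVED"),
            (None, "NO_DATA"),
        ],
    )
    def test_threshold_semantics(self, mean, expected):
        call = classify(GroupCoverage("OG1", {}, mean))
        assert call.status == expected

    def test_invalid_thresholds_raise(self):
        with pytest.raises(ValueError):
            classify(GroupCoverage("OG1", {}, 10.0), lost_max=60, conserved_min=50)

    def test_adding_coverage_never_flips_conserved_to_lost(self, rng):
        """More hits can only raise the mean, so CONSERVED never degrades."""
        for _ in range(50):
            mean = float(rng.uniform(0, 100))
            bump = float(rng.uniform(0, 100 - mean))
            before = classify(GroupCoverage("g", {}, mean)).status
            after = classify(GroupCoverage("g", {}, mean + bump)).status
            assert not (before == "CONSERVED" and after == "LOST")
            if before == "CONSERVED":
                assert after == "CONSERVED"


def test_recovery_on_synthetic_panel(recovery_run):
    """Planted gene loss is recovered nearly perfectly from read breadth."""
    truth, status = recovery_run
    lost_called = {g for g, s in status.items() if s == "LOST"}
    tp = len(lost_called & truth.lost_groups)
    fp = len(lost_called - truth.lost_groups)
    sensitivity = tp / len(truth.lost_groups)
    specificity = (len(truth.present_groups) - fp) / len(truth.present_groups)
    assert sensitivity >= 0.95
    assert specificity >= 0.95
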