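import itertools
import math
from math import comb

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from polyctx.detect import RepeatRegion
from polyctx.io import AnnotationRow, AnnotationTable, ProteinRecord
from polyctx.position import (
    mann_whitney_u,
    relative_positions,
    start_class,
    stratify_by_location,
    tp_enrichment_table,
)


def pure(pid, start, end):
    return RepeatRegion(pid, start, end, "pure")


class TestRelativePositions:
    def test_midpoint_arithmetic(self):
        prot = [ProteinRecord("p1", "A" * 10 + "L" * 10)]
        (s,) = relative_positions([pure("p1", 1, 10)], prot)
        assert s.rel_pos == pytest.approx(0.275)

    def test_start_mode(self):
        prot = [ProteinRecord("p1", "M" + "A" * 4 + "L" * 15)]
        (s,) = relative_positions([pure("p1", 2, 5)], prot, mode="start")
        assert s.rel_pos == pytest.approx(0.1)

    def test_whole_protein_region_bound(self):
        L = 8
        prot = [ProteinRecord("p1", "A" * L)]
        (s,) = relative_positions([pure("p1", 1, L)], prot)
        assert s.rel_pos == pytest.approx(0.5 + 1 / (2 * L))
        assert s.rel_pos <= 1

    def test_invariant_to_protein_order(self):
        prots = [ProteinRecord("p1", "A" * 20), ProteinRecord("p2", "L" * 5 + "A" * 5)]
        regions = [pure("p1", 3, 6), pure("p2", 6, 10)]
        fwd = [(s.protein_id, s.rel_pos) for s in relative_positions(regions, prots)]
        rev = [(s.protein_id, s.rel_pos) for s in relative_positions(regions, prots[::-1])]
        assert sorted(fwd) == sorted(rev)


def exact_two_sided_p(a, b):
    """Enumeration oracle: distribution of U over all C(n1+n2, n1) position
    assignments of the pooled (distinct) values; p = 2 * min tail."""
    n1, n2 = len(a), len(b)
    pooled = sorted(a + b)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    us = []
    for positions in itertools.combinations(range(n1 + n2), n1):
        chosen = [pooled[i] for i in positions]
        rest = [pooled[i] for i in range(n1 + n2) if i not in positions]
        us.append(sum(1 for x in chosen for y in rest if x > y))
    total = len(us)
    lower = sum(1 for u in us if u <= u_obs)
    upper = sum(1 for u in us if u >= u_obs)
    return u_obs, min(1.0, 2 * min(lower, upper) / total)


class TestMannWhitney:
    def test_spec_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.pvalue == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_samples_symmetric(self):
        a = [1.0, 2.0, 3.0, 4.0] * 5
        res = mann_whitney_u(a, a)
        n = len(a)
        assert res.statistic == pytest.approx(n * n / 2)
        assert res.pvalue > 0.9

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=1, max_value=9),
        st.integers(min_value=1, max_value=9),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_matches_enumeration_for_small_samples(self, n1, n2, seed):
        if n1 + n2 > 10:
            n2 = 10 - n1
        rng = np.random.default_rng(seed)
        a = list(rng.normal(size=n1))
        b = list(rng.normal(size=n2))
        res = mann_whitney_u(a, b)
        u_oracle, p_oracle = exact_two_sided_p(a, b)
        assert res.statistic == pytest.approx(u_oracle)
        assert res.pvalue == pytest.approx(p_oracle)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=9, max_value=40),
        st.integers(min_value=9, max_value=40),
        st.integers(min_value=0, max_value=2**31 - 1),
        st.booleans(),
    )
    def test_asymptotic_matches_scipy(self, n1, n2, seed, with_ties):
        rng = np.random.default_rng(seed)
        if with_ties:
            a = list(rng.integers(0, 5, size=n1).astype(float))
            b = list(rng.integers(0, 5, size=n2).astype(float))
        else:
            a = list(rng.normal(size=n1))
            b = list(rng.normal(size=n2))
        res = mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)

    def test_separated_distributions_highly_significant(self, rng):
        a = rng.normal(0.0, 1.0, size=200)
        b = rng.normal(3.0, 1.0, size=200)
        assert mann_whitney_u(a, b).pvalue < 1e-6


class TestStratify:
    def _annotations(self, assignment):
        t = AnnotationTable()
        for pid, loc in assignment.items():
            t.rows[pid] = AnnotationRow(location=loc)
        return t

    def _samples(self, positions_by_pid, prots):
        regions, proteome = [], []
        for pid, rel in positions_by_pid.items():
            L = 100
            start = max(1, int(rel * L) - 1)
            regions.append(pure(pid, start, start + 3))
            proteome.append(ProteinRecord(pid, "L" * L))
        return relative_positions(regions, proteome)

    def test_planted_group_separation(self, rng):
        positions, annotation = {}, {}
        for i in range(60):
            pid = f"m{i}"
            positions[pid] = float(rng.uniform(0.02, 0.08))
            annotation[pid] = "Mitochondrion"
        for i in range(60):
            pid = f"n{i}"
            positions[pid] = float(rng.uniform(0.3, 0.5))
            annotation[pid] = "Nucleus"
        samples = self._samples(positions, None)
        strat = stratify_by_location(samples, self._annotations(annotation))
        summ = strat.summaries.set_index("group")
        assert summ.loc["Mitochondrion", "median"] < summ.loc["Nucleus", "median"]
        assert strat.pvalues.loc["Mitochondrion", "Nucleus"] < 0.01
        assert "Cytoplasm" in strat.omitted

    def test_single_group_gives_empty_test_matrix(self):
        samples = self._samples({"p1": 0.2, "p2": 0.4}, None)
        strat = stratify_by_location(samples, self._annotations({}))
        assert list(strat.summaries["group"]) == ["Other/Mixed"]
        assert strat.pvalues.shape == (1, 1)
        assert np.isnan(strat.pvalues).all().all()

    def test_holm_adjustment_is_monotone(self, rng):
        positions, annotation = {}, {}
        groups = ["Nucleus", "Cytoplasm", "Mitochondrion"]
        for g, grp in enumerate(groups):
            for i in range(20):
                pid = f"{grp}{i}"
                positions[pid] = float(rng.uniform(0, 0.7)) + 0.05 * g
                annotation[pid] = grp
        samples = self._samples(positions, None)
        raw = stratify_by_location(samples, self._annotations(annotation), holm=False)
        adj = stratify_by_location(samples, self._annotations(annotation), holm=True)
        for a in groups:
            for b in groups:
                if a != b:
                    assert adj.pvalues.loc[a, b] >= raw.pvalues.loc[a, b] - 1e-12


class TestTPTable:
    def _build(self, starts_and_calls, n_extra_no_polya=0):
        prots, regions, ann = [], [], AnnotationTable()
        for i, (start, call) in enumerate(starts_and_calls):
            pid = f"p{i}"
            prots.append(ProteinRecord(pid, "L" * 100))
            if start is not None:
                regions.append(pure(pid, start, start + 3))
            if call:
                ann.rows[pid] = AnnotationRow(peptide_call=call)
        for j in range(n_extra_no_polya):
            prots.append(ProteinRecord(f"x{j}", "L" * 50))
        return prots, regions, ann

    def test_hand_count(self):
        prots, regions, ann = self._build(
            [(2, "mTP"), (5, "SP"), (30, None), (None, None)]
        )
        table = tp_enrichment_table(prots, regions, ann).table
        assert table.loc["no polyA", "proteins"] == 1
        assert list(table.loc["any", ["proteins", "mTP", "SP"]]) == [3, 1, 1]
        assert list(table.loc["2", ["proteins", "mTP", "SP"]]) == [1, 1, 0]
        assert table.loc["2", "pct_mTP"] == pytest.approx(100.0)
        assert list(table.loc["3-20", ["proteins", "mTP", "SP"]]) == [1, 0, 1]
        assert table.loc["3-20", "pct_SP"] == pytest.approx(100.0)
        assert list(table.loc[">20", ["proteins", "mTP", "SP"]]) == [1, 0, 0]

    def test_no_regions_at_all(self):
        prots, regions, ann = self._build([(None, None)], n_extra_no_polya=4)
        table = tp_enrichment_table(prots, [], ann).table
        assert table.loc["any", "proteins"] == 0
        assert table.loc["no polyA", "proteins"] == 5

    def test_start_one_gets_its_own_class(self):
        assert start_class(1) == "1"
        assert start_class(2) == "2"
        assert start_class(20) == "3-20"
        assert start_class(21) == ">20"
        prots, regions, ann = self._build([(1, "mTP"), (2, None)])
        table = tp_enrichment_table(prots, regions, ann).table
        assert table.loc["1", "proteins"] == 1
        assert table.loc["2", "proteins"] == 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(
        st.one_of(st.none(), st.integers(min_value=1, max_value=60)),
        st.sampled_from([None, "mTP", "SP", "other"]),
    ), min_size=1, max_size=30))
    def test_bookkeeping_identities(self, rows):
        prots, regions, ann = self._build(rows)
        table = tp_enrichment_table(prots, regions, ann).table
        classes = ["1", "2", "3-20", ">20"]
        for col in ("proteins", "mTP", "SP"):
            assert table.loc["any", col] == table.loc[classes, col].sum()
        assert table.loc["no polyA", "proteins"] + table.loc["any", "proteins"] == len(prots)
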