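import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conkatseq.linkage import (
    ContingencyTable,
    adjust_fdr_tsbky,
    candidate_pairs,
    contingency,
    detect_links,
    fisher_right_tail,
    fisher_right_tail_many,
    tsbky_reject,
)
from conkatseq.variant_table import OccurrenceMatrix

from _oracles import bky_two_stage_reject, hypergeom_right_tail_exact


def random_matrix(rng, n_variants=20, n_subpools=100, prevalence=(3, 15)):
    counts = np.zeros((n_variants, n_subpools), dtype=np.int64)
    for i in range(n_variants):
        k = int(rng.integers(*prevalence))
        cols = rng.choice(n_subpools, size=k, replace=False)
        counts[i, cols] = rng.integers(1, 10, size=k)
    df = pd.DataFrame(counts, columns=list(range(n_subpools)))
    df.index = [f"v{i:03d}" for i in range(n_variants)]
    meta = pd.DataFrame({"domain_type": "AD", "centroid": "ACGT"}, index=df.index)
    return OccurrenceMatrix(df, meta, min_wells=3)


class TestContingency:
    def test_counted_by_hand(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((2, 10), dtype=np.int64)
        counts[0, [1, 2, 3]] = 1
        counts[1, [2, 3, 4]] = 1
        df = pd.DataFrame(counts, columns=list(range(10)), index=["A", "B"])
        meta = pd.DataFrame({"domain_type": "AD", "centroid": "ACGT"}, index=df.index)
        m = OccurrenceMatrix(df, meta, min_wells=3)
        assert contingency(m, "A", "B") == ContingencyTable(2, 1, 1, 6)

    def test_identical_patterns_have_no_exclusive_cells(self):
        counts = np.zeros((2, 8), dtype=np.int64)
        counts[:, [0, 3, 5]] = 1
        df = pd.DataFrame(counts, columns=list(range(8)), index=["A", "B"])
        meta = pd.DataFrame({"domain_type": "AD", "centroid": "ACGT"}, index=df.index)
        m = OccurrenceMatrix(df, meta, min_wells=3)
        t = contingency(m, "A", "B")
        assert (t.n10, t.n01) == (0, 0)

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(42)
        m = random_matrix(rng, n_variants=10, n_subpools=100)
        presence = m.presence
        for a in m.variants[:5]:
            for b in m.variants[5:]:
                sa = set(presence.columns[presence.loc[a]])
                sb = set(presence.columns[presence.loc[b]])
                expected = ContingencyTable(
                    len(sa & sb),
                    len(sa - sb),
                    len(sb - sa),
                    m.n_subpools - len(sa | sb),
                )
                assert contingency(m, a, b) == expected


class TestFisher:
    def test_zero_overlap_gives_one(self):
        assert fisher_right_tail(ContingencyTable(0, 5, 5, 20)) == 1.0

    def test_closed_form_point_mass(self):
        # A in 3 pools, B in 3 pools, all shared, N=100: p = 1/C(100,3)
        p = fisher_right_tail(ContingencyTable(3, 0, 0, 97))
        assert p == pytest.approx(1 / math.comb(100, 3), rel=1e-12)

    def test_enumerated_tail(self):
        p = fisher_right_tail(ContingencyTable(2, 1, 1, 6))
        assert p == pytest.approx(22 / 120, rel=1e-12)

    def test_monotone_in_overlap_for_fixed_margins(self):
        # margins K=8, n=6, N=40
        for n11 in range(1, 6):
            t_lo = ContingencyTable(n11, 8 - n11, 6 - n11, 40 - 14 + n11)
            t_hi = ContingencyTable(n11 + 1, 7 - n11, 5 - n11, 40 - 13 + n11)
            assert fisher_right_tail(t_hi) < fisher_right_tail(t_lo)

    @given(
        n11=st.integers(0, 8),
        n10=st.integers(0, 8),
        n01=st.integers(0, 8),
        n00=st.integers(0, 10),
    )
    def test_matches_exact_rational_tail(self, n11, n10, n01, n00):
        if n11 + n10 + n01 + n00 == 0:
            return
        t = ContingencyTable(n11, n10, n01, n00)
        expected = float(hypergeom_right_tail_exact(n11, n10, n01, n00))
        assert fisher_right_tail(t) == pytest.approx(expected, rel=1e-12)

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        tables = []
        for _ in range(50):
            n11 = int(rng.integers(0, 6))
            n10 = int(rng.integers(0, 20))
            n01 = int(rng.integers(0, 20))
            n00 = int(rng.integers(0, 300))
            tables.append(ContingencyTable(n11, n10, n01, n00))
        n = max(t.total for t in tables)
        # pad tables to a common N by inflating n00
        tables = [ContingencyTable(t.n11, t.n10, t.n01, t.n00 + n - t.total) for t in tables]
        many = fisher_right_tail_many(
            np.array([t.n11 for t in tables]),
            np.array([t.n11 + t.n10 for t in tables]),
            np.array([t.n11 + t.n01 for t in tables]),
            n,
        )
        for t, p in zip(tables, many):
            assert p == pytest.approx(fisher_right_tail(t), rel=1e-10)


class TestCandidatePairs:
    def test_boundary_inclusion(self):
        counts = np.zeros((3, 20), dtype=np.int64)
        counts[0, [0, 1, 2]] = 1
        counts[1, [0, 1, 2]] = 1  # shares 3 with v0
        counts[2, [1, 2, 19]] = 1  # shares 2 with both
        df = pd.DataFrame(counts, columns=list(range(20)), index=["a", "b", "c"])
        meta = pd.DataFrame({"domain_type": "AD", "centroid": "ACGT"}, index=df.index)
        m = OccurrenceMatrix(df, meta, min_wells=3)
        assert candidate_pairs(m, min_shared=3) == [("a", "b")]

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(17)
        m = random_matrix(rng, n_variants=50, n_subpools=80, prevalence=(3, 25))
        presence = m.presence
        expected = set()
        variants = m.variants
        for i in range(len(variants)):
            for j in range(i + 1, len(variants)):
                shared = int(
                    (presence.loc[variants[i]] & presence.loc[variants[j]]).sum()
                )
                if shared >= 3:
                    expected.add(tuple(sorted((variants[i], variants[j]))))
        assert set(candidate_pairs(m)) == expected


class TestBKY:
    def test_all_ones_reject_nothing(self):
        adjusted, rejected = adjust_fdr_tsbky([1.0, 1.0, 1.0], q=0.05)
        assert not rejected.any()
        assert np.allclose(adjusted, 1.0)

    def test_tiny_uniform_block_all_rejected(self):
        p = [1e-9] * 100
        adjusted, rejected = adjust_fdr_tsbky(p, q=1e-6)
        assert rejected.all()
        assert (adjusted < 1e-6).all()

    def test_flags_match_bruteforce_two_stage(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m) ** rng.integers(1, 6)
            q = float(rng.choice([0.3, 0.05, 0.01, 1e-3]))
            ours = tsbky_reject(p, q)
            oracle = bky_two_stage_reject(list(p), q)
            assert list(ours) == oracle

    def test_adjusted_values_monotone_in_p(self):
        rng = np.random.default_rng(7)
        p = rng.random(50)
        adjusted, _ = adjust_fdr_tsbky(p, q=0.05)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()

    def test_adjusted_consistent_with_rejection(self):
        rng = np.random.default_rng(8)
        for q in (0.05, 1e-3):
            p = rng.random(80) ** 4
            adjusted, rejected = adjust_fdr_tsbky(p, q=q)
            tol = 1e-9
            assert all(
                (adj <= q + tol) == rej or abs(adj - q) <= tol
                for adj, rej in zip(adjusted, rejected)
            )

    def test_matches_statsmodels_reference(self):
        # the same two-stage procedure as the field-standard implementation
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(21)
        for _ in range(50):
            m = int(rng.integers(5, 200))
            p = rng.random(m) ** rng.integers(1, 8)
            q = float(rng.choice([0.2, 0.05, 0.01]))
            reject_sm = multipletests(p, alpha=q, method="fdr_tsbky")[0]
            assert list(tsbky_reject(p, q)) == list(reject_sm)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            adjust_fdr_tsbky([0.5, 1.5])


class TestDetectLinks:
    def test_perfect_cooccurrence_flagged(self):
        rng = np.random.default_rng(31)
        n_subpools = 384
        counts = np.zeros((10, n_subpools), dtype=np.int64)
        counts[0, [5, 6, 7]] = 1
        counts[1, [5, 6, 7]] = 1
        for i in range(2, 10):
            cols = rng.choice(n_subpools, size=6, replace=False)
            counts[i, cols] = 1
        df = pd.DataFrame(counts, columns=list(range(n_subpools)))
        df.index = [f"v{i}" for i in range(10)]
        meta = pd.DataFrame({"domain_type": "AD", "centroid": "ACGT"}, index=df.index)
        m = OccurrenceMatrix(df, meta, min_wells=3)
        links = detect_links(m, alpha=1e-6)
        sig = {(t.variant_a, t.variant_b) for t in links.significant_links()}
        assert ("v0", "v1") in sig
        expected_raw = 1 / math.comb(384, 3)
        found = next(t for t in links.tests if {t.variant_a, t.variant_b} == {"v0", "v1"})
        assert found.p_raw == pytest.approx(expected_raw, rel=1e-10)

    def test_invariant_to_row_and_column_permutation(self):
        rng = np.random.default_rng(41)
        m = random_matrix(rng, n_variants=25, n_subpools=60, prevalence=(3, 20))
        base = detect_links(m, alpha=1e-3)
        perm_rows = rng.permutation(m.n_variants)
        perm_cols = rng.permutation(m.n_subpools)
        counts = m.counts.iloc[perm_rows, perm_cols]
        shuffled = OccurrenceMatrix(counts, m.meta.iloc[perm_rows], min_wells=3)
        other = detect_links(shuffled, alpha=1e-3)

        def norm(links):
            return {
                (tuple(sorted((t.variant_a, t.variant_b)))): (t.table.n11, round(-np.log10(max(t.p_raw, 1e-300)), 6))
                for t in links.tests
            }

        assert norm(base) == norm(other)

    def test_empty_candidate_set(self):
        rng = np.random.default_rng(51)
        m = random_matrix(rng, n_variants=5, n_subpools=200, prevalence=(3, 4))
        links = detect_links(m)
        # with tiny prevalence over 200 subpools, overlaps of >=3 are unlikely
        assert all(t.table.n11 >= 3 for t in links.tests)

    def test_duplicate_variant_id_rejected(self):
        counts = pd.DataFrame(
            np.ones((2, 4), dtype=np.int64), index=["v0", "v0"], columns=range(4)
        )
        meta = pd.DataFrame({"domain_type": "AD", "centroid": "ACGT"}, index=counts.index)
        with pytest.raises(ValueError, match="duplicate"):
            OccurrenceMatrix(counts, meta, min_wells=3)
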