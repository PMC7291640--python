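"""Quality filters, sequence identity, clustering and split plans."""

import numpy as np
import pytest

from tmstruct.datasets import (
    ChainRecord,
    build_folds,
    filter_chains,
    read_cluster_tsv,
    reduce_redundancy,
    sequence_identity,
    stratified_test_split,
)
from tmstruct.structio import MembraneChain


def _chain(seq="ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY", z_span=(-18, 18),
           resolution=2.0, b=None, seqres=None):
    L = len(seq)
    z = np.linspace(*z_span, L)
    rng = np.random.default_rng(0)
    bb = rng.normal(size=(L, 3, 3))
    bb[:, 1, 2] = z
    b = b if b is not None else np.arange(L, dtype=float)
    return MembraneChain(chain_id="A", seqres=seqres or seq, atomseq=seq,
                         backbone=bb, z=z, b_raw=b, resolution=resolution)


def _rec(rid, **kw):
    ch = _chain(**kw)
    return ChainRecord(id=rid, seq=ch.atomseq, n_tms=1, chain=ch)


def identity_oracle(a, b):
    """Exhaustive dynamic-programming global alignment (match 1,
    mismatch 0, gap -1), returning identities / alignment length over the
    best-identity optimal traceback."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        score[i, 0] = -i
    for j in range(1, m + 1):
        score[0, j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0),
                score[i - 1, j] - 1,
                score[i, j - 1] - 1,
            )
    # traceback maximizing identities among optimal paths
    best = {}

    def walk(i, j):
        if (i, j) in best:
            return best[(i, j)]
        if i == 0 and j == 0:
            return 0, 0
        cands = []
        if i > 0 and j > 0 and np.isclose(
                score[i, j], score[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else 0)):
            ident, length = walk(i - 1, j - 1)
            cands.append((ident + (a[i - 1] == b[j - 1]), length + 1))
        if i > 0 and np.isclose(score[i, j], score[i - 1, j] - 1):
            ident, length = walk(i - 1, j)
            cands.append((ident, length + 1))
        if j > 0 and np.isclose(score[i, j], score[i, j - 1] - 1):
            ident, length = walk(i, j - 1)
            cands.append((ident, length + 1))
        best[(i, j)] = max(cands)
        return best[(i, j)]

    ident, length = walk(n, m)
    return ident / length


class TestFilterChains:
    def test_all_pass(self, small_dataset):
        kept, rejected = filter_chains(small_dataset)
        assert len(kept) == len(small_dataset) and not rejected

    def test_min_length(self):
        kept, rej = filter_chains([_rec("r", seq="ACDEFGHIKLMNPQRSTVWYACDEFGHIK")])
        assert rej == [("r", "min_length")]

    def test_constant_bfactor(self):
        rec = _rec("r", b=np.full(40, 30.0))
        assert filter_chains([rec])[1] == [("r", "constant_bfactor")]

    def test_resolution(self):
        assert filter_chains([_rec("r", resolution=3.6)])[1] == [("r", "resolution")]
        assert filter_chains([_rec("r", resolution=None)])[1] == [("r", "resolution")]

    def test_seqres_coverage(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"
        rec = _rec("r", seqres=seq + "G" * 11)  # coverage 40/51 < 0.8
        assert filter_chains([rec])[1] == [("r", "seqres_coverage")]

    def test_no_crossing(self):
        rec = _rec("r", z_span=(2, 20))
        assert filter_chains([rec])[1] == [("r", "no_crossing")]


class TestSequenceIdentity:
    def test_identical(self):
        assert sequence_identity("ACDEFG", "ACDEFG") == 1.0

    def test_disjoint(self):
        assert sequence_identity("AAAA", "TTTT") == 0.0

    def test_against_dp_oracle(self):
        pairs = [("ACDEFG", "ACDEYG"), ("ACACAC", "ACGCAC"),
                 ("MKTAYIAKQR", "MKTAYIAKQR"[::-1]), ("AAAC", "AAC")]
        for a, b in pairs:
            assert sequence_identity(a, b) == pytest.approx(
                identity_oracle(a, b))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sequence_identity("", "ACD")


class TestReduceRedundancy:
    def test_identical_collapse(self):
        recs = [ChainRecord("a", "ACDEFGHIKL", 1),
                ChainRecord("b", "ACDEFGHIKL", 1)]
        assert len(reduce_redundancy(recs, 0.4)) == 1

    def test_all_distinct_kept(self):
        recs = [ChainRecord("a", "AAAAAAAA", 1),
                ChainRecord("b", "CCCCCCCC", 1),
                ChainRecord("c", "DDDDDDDD", 1)]
        assert len(reduce_redundancy(recs, 0.4)) == 3

    def test_greedy_longest_first(self):
        # A~B high, A~C and B~C low, A longest -> representatives {A, C}
        ident = {frozenset(("a", "b")): 0.9, frozenset(("a", "c")): 0.1,
                 frozenset(("b", "c")): 0.1}
        recs = [ChainRecord("a", "A" * 12, 1), ChainRecord("b", "A" * 10, 1),
                ChainRecord("c", "A" * 8, 1)]
        lut = {r.seq: r.id for r in recs}

        def fn(x, y):
            return ident[frozenset((lut[x], lut[y]))]

        reps = reduce_redundancy(recs, 0.4, identity_fn=fn)
        assert sorted(r.id for r in reps) == ["a", "c"]

    def test_no_overlapping_pair_left(self):
        rng = np.random.default_rng(3)
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 30))
        recs = [ChainRecord(f"r{i}", _mutate(base, rng, 0.1 * i), 1)
                for i in range(8)]
        reps = reduce_redundancy(recs, 0.5)
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                assert sequence_identity(a.seq, b.seq) <= 0.5


def _mutate(seq, rng, rate):
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(
        alphabet[rng.integers(20)] if rng.random() < rate else c for c in seq
    )


def make_split_records(n, seed, length=(40, 80)):
    """Lightweight records with seeded sequences, some near-duplicates to
    exercise the identity purging, and varied TMS strata."""
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    records = []
    for i in range(n):
        if records and rng.random() < 0.3:
            seq = _mutate(records[rng.integers(len(records))].seq, rng, 0.05)
        else:
            L = int(rng.integers(*length))
            seq = "".join(alphabet[k] for k in rng.integers(0, 20, L))
        records.append(ChainRecord(f"s{seed}_{i}", seq, int(rng.integers(1, 5))))
    return records


class TestStratifiedTestSplit:
    def test_one_per_stratum(self):
        recs = [ChainRecord(f"a{i}", _mutate("A" * 50, np.random.default_rng(i), 0.9), 1)
                for i in range(10)]
        recs += [ChainRecord(f"b{i}", _mutate("C" * 50, np.random.default_rng(100 + i), 0.9), 2)
                 for i in range(10)]
        cv, test = stratified_test_split(recs, 0.1, seed=0)
        assert len(test) == 2
        assert sorted(r.n_tms for r in test) == [1, 2]

    def test_deterministic(self):
        recs = make_split_records(20, seed=5)
        _, t1 = stratified_test_split(recs, 0.1, seed=3)
        _, t2 = stratified_test_split(recs, 0.1, seed=3)
        assert [r.id for r in t1] == [r.id for r in t2]

    def test_near_duplicate_purged(self):
        rng = np.random.default_rng(0)
        base = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 60))
        recs = [ChainRecord("x", base, 1),
                ChainRecord("y", _mutate(base, rng, 0.05), 1)]
        cv, test = stratified_test_split(recs + make_split_records(8, 1), 0.2, seed=1)
        test_ids = {r.id for r in test}
        if test_ids & {"x", "y"}:
            cv_ids = {r.id for r in cv}
            assert not (cv_ids & {"x", "y"})


class TestBuildFolds:
    def test_plan_invariants(self):
        recs = make_split_records(16, seed=2)
        plan = build_folds(recs, k=5, seed=2)
        seen = []
        by_id = {r.id: r for r in recs}
        for fold in plan.folds:
            train = set(fold["train_ids"])
            val = set(fold["validation_ids"])
            test = set(fold["testbin_ids"])
            assert not (train & val) and not (train & test) and not (val & test)
            seen.extend(fold["testbin_ids"])
            for tid in test:
                for oid in train | val:
                    assert sequence_identity(by_id[oid].seq, by_id[tid].seq) <= 0.3
            for vid in val:
                for tid in train:
                    assert sequence_identity(by_id[tid].seq, by_id[vid].seq) <= 0.3
        # each record is a test-bin member exactly once
        assert sorted(seen) == sorted(r.id for r in recs)

    def test_no_purge_when_all_distinct(self):
        recs = [ChainRecord(f"r{i}", 20 * "ACDEFGHIKLMNPQRSTVWY"[i], 1)
                for i in range(10)]
        plan = build_folds(recs, k=5, seed=0)
        for fold in plan.folds:
            n = len(fold["train_ids"]) + len(fold["validation_ids"])
            assert n == 8
            assert len(fold["validation_ids"]) >= 1


def test_read_cluster_tsv():
    mapping = read_cluster_tsv("rep1\tmem1\nrep1\trep1\n# comment\nrep2\tmem2\n")
    assert mapping == {"mem1": "rep1", "rep1": "rep1", "mem2": "rep2"}
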