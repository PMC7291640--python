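"""Dataset filtering, redundancy reduction and cross-validation splits.

The filtering rules mirror what is needed to obtain clean training chains
from membrane-oriented structures: good X-ray resolution, a minimum
length, informative B-factors, complete backbones, high seqres coverage
with missing residues only at the termini, and at least one membrane
crossing.

Splitting follows a two-step redundancy-reduction scheme: an initial
clustering at 40% identity, a topology-stratified 10% hold-out test set,
then 5 cross-validation folds where every identity above 30% between a
fold's pool and its test bin (and between train and validation) is purged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from .structio import DsspRecord, MembraneChain, MSA
from .targets import TargetBundle

__all__ = [
    "ChainRecord",
    "SplitPlan",
    "filter_chains",
    "sequence_identity",
    "reduce_redundancy",
    "stratified_test_split",
    "build_folds",
    "read_cluster_tsv",
]

#: Strata with this many TMS or more are pooled into one bin (large
#: topologies are sparse).
N_TMS_CAP = 14


@dataclass
class ChainRecord:
    """A chain plus everything the split/training machinery needs.

    Only ``id``, ``seq`` and ``n_tms`` are required by the split builders;
    the structural payload may be absent for lightweight split experiments.
    """

    id: str
    seq: str
    n_tms: int
    chain: MembraneChain | None = None
    dssp: DsspRecord | None = None
    dssp_cplx: DsspRecord | None = None
    msa: MSA | None = None
    bundle: TargetBundle | None = None
    provenance: str = ""

    @property
    def stratum(self) -> int:
        return min(self.n_tms, N_TMS_CAP)


@dataclass
class SplitPlan:
    """Hold-out test ids plus k folds of train/validation/testbin ids."""

    test_ids: list
    folds: list = field(default_factory=list)  # dicts: train_ids/validation_ids/testbin_ids
    identity_threshold: float = 0.3
    seed: int = 0


_REJECT_ORDER = (
    "resolution", "min_length", "single_aa", "constant_bfactor",
    "incomplete_backbone", "seqres_coverage", "interior_gap", "no_crossing",
)


def _first_rejection(rec: ChainRecord, min_length, max_resolution, min_coverage):
    ch = rec.chain
    if ch.resolution is None or ch.resolution > max_resolution:
        return "resolution"
    if len(ch) < min_length:
        return "min_length"
    if len(set(ch.atomseq)) < 2:
        return "single_aa"
    if np.unique(ch.b_raw).size < 2:
        return "constant_bfactor"
    if not np.isfinite(ch.backbone).all():
        return "incomplete_backbone"
    if len(ch.seqres) == 0 or len(ch.atomseq) / len(ch.seqres) < min_coverage:
        return "seqres_coverage"
    obs = np.flatnonzero(ch.observed_mask)
    if obs.size and np.any(np.diff(obs) > 1):
        return "interior_gap"
    if not (np.any(ch.z < 0) and np.any(ch.z > 0)):
        return "no_crossing"
    return None


def filter_chains(records, min_length: int = 30, max_resolution: float = 3.5,
                  min_coverage: float = 0.8):
    """Apply the quality filters in order; returns (kept, rejections).

    Each rejection is ``(record_id, reason_code)`` with the first failing
    rule; reason codes follow ``_REJECT_ORDER``.
    """
    kept, rejected = [], []
    for rec in records:
        reason = _first_rejection(rec, min_length, max_resolution, min_coverage)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec.id, reason))
    return kept, rejected


_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -1.0


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical positions under a simple global alignment
    (match 1, mismatch 0, gap -1), normalized by alignment length.

    A stand-in for an external clustering tool's identity; precomputed
    cluster files can replace it (see :func:`read_cluster_tsv`).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def reduce_redundancy(records, threshold: float = 0.4, identity_fn=sequence_identity):
    """Greedy longest-first clustering; returns the representatives.

    Records are sorted by sequence length (descending, id as tie-break);
    each record joins the first representative it exceeds ``threshold``
    identity with, otherwise it founds a new cluster.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ordered = sorted(records, key=lambda r: (-len(r.seq), r.id))
    reps = []
    for rec in ordered:
        if not any(identity_fn(rec.seq, rep.seq) > threshold for rep in reps):
            reps.append(rec)
    return reps


def _stratified_draw(records, fraction: float, rng):
    """Draw ~fraction of each topology stratum without replacement."""
    by_stratum: dict = {}
    for rec in records:
        by_stratum.setdefault(rec.stratum, []).append(rec)
    drawn = []
    for stratum in sorted(by_stratum):
        members = by_stratum[stratum]
        n = int(math.floor(fraction * len(members)))
        if n == 0 and len(members) >= round(1.0 / fraction):
            n = 1
        idx = rng.choice(len(members), size=n, replace=False) if n else []
        drawn.extend(members[i] for i in sorted(idx))
    return drawn


def _purge(pool, against, threshold, identity_fn):
    """Drop pool records sharing identity above threshold with any record
    in ``against``."""
    return [
        rec for rec in pool
        if all(identity_fn(rec.seq, other.seq) <= threshold for other in against)
    ]


def stratified_test_split(records, test_fraction: float = 0.1, seed: int = 0,
                          identity_threshold: float = 0.3,
                          identity_fn=sequence_identity):
    """Set aside a topology-stratified hold-out test set.

    Returns ``(cv_records, test_records)``; the cross-validation pool is
    purged of anything above ``identity_threshold`` to the test set.
    """
    if not records:
        raise ValueError("no records to split")
    rng = np.random.default_rng(seed)
    test = _stratified_draw(records, test_fraction, rng)
    test_ids = {r.id for r in test}
    cv = [r for r in records if r.id not in test_ids]
    cv = _purge(cv, test, identity_threshold, identity_fn)
    return cv, test


def build_folds(cv_records, k: int = 5, seed: int = 0,
                identity_threshold: float = 0.3,
                validation_fraction: float = 0.1,
                identity_fn=sequence_identity) -> SplitPlan:
    """Build a k-fold plan with stratified bins and identity purging.

    Records are dealt into k bins stratified by TMS count (round-robin
    within shuffled strata, so strata smaller than k still spread out).
    For each fold f: the test bin is bin f; the remaining bins, purged of
    identity > threshold to the test bin, are split 90/10 into train and
    validation (stratified); finally train is purged against validation.
    """
    if not cv_records:
        raise ValueError("no records to fold")
    rng = np.random.default_rng(seed)
    bins: list = [[] for _ in range(k)]
    by_stratum: dict = {}
    for rec in cv_records:
        by_stratum.setdefault(rec.stratum, []).append(rec)
    cursor = 0
    for stratum in sorted(by_stratum):
        members = by_stratum[stratum]
        order = rng.permutation(len(members))
        for j in order:
            bins[cursor % k].append(members[j])
            cursor += 1

    folds = []
    for f in range(k):
        testbin = bins[f]
        pool = [r for g in range(k) if g != f for r in bins[g]]
        pool = _purge(pool, testbin, identity_threshold, identity_fn)
        validation = _stratified_draw(pool, validation_fraction, rng)
        if not validation and len(pool) > 1:
            # tiny strata can round every draw to zero; hold out one record
            validation = [pool[int(rng.integers(len(pool)))]]
        val_ids = {r.id for r in validation}
        train = [r for r in pool if r.id not in val_ids]
        train = _purge(train, validation, identity_threshold, identity_fn)
        folds.append({
            "train_ids": [r.id for r in train],
            "validation_ids": [r.id for r in validation],
            "testbin_ids": [r.id for r in testbin],
        })
    return SplitPlan(test_ids=[], folds=folds,
                     identity_threshold=identity_threshold, seed=seed)


def read_cluster_tsv(text: str) -> dict:
    """Parse a tool-agnostic two-column (representative, member) TSV into a
    member -> representative mapping."""
    mapping = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rep, member = line.split("\t")[:2]
        mapping[member] = rep
    return mapping
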