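"""Bridging chain records to model-ready samples."""

from __future__ import annotations

import numpy as np

from ..features import one_hot, profile_from_msa
from ..structio import MSA

__all__ = ["make_sample", "make_samples"]


def make_sample(record) -> dict:
    """Feature/target/mask dict for one ChainRecord.

    Without an MSA the profile falls back to a single-sequence alignment
    (entirely pseudocount-driven, and a much weaker signal).
    """
    msa = record.msa if record.msa is not None else MSA(record.seq, [record.seq])
    b = record.bundle
    targets = {name: np.asarray(b.target(name), dtype=float)
               for name in b.TARGET_NAMES}
    return {
        "id": record.id,
        "onehot": one_hot(record.seq).values,
        "profile": profile_from_msa(msa).values,
        "targets": targets,
        "masks": {k: np.asarray(v, dtype=bool) for k, v in b.masks.items()},
    }


def make_samples(records) -> list:
    return [make_sample(r) for r in records]
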