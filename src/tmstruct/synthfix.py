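"""Synthetic membrane-protein fixtures with known ground truth.

The generator builds chains segment by segment from a topology
specification: loops sit ~5 A outside the membrane boundary, crossing
segments interpolate linearly through the bilayer, and re-entrant hairpins
descend a seeded depth past the boundary and return on the same side.
Backbone N/CA/C coordinates are laid out along the z-trace with rotating
lateral offsets so every torsion angle is well defined; raw B-factors rise
outside the membrane (loops are floppier than the packed helical core)
plus seeded noise.

Sequences are drawn from depth-dependent amino-acid pools: hydrophobic
inside the bilayer, polar in the loops, with the positive-inside rule
(K/R enrichment on the cytoplasmic side) so that the topology signal is
statistically learnable from composition alone.  Secondary structure and
solvent accessibilities are supplied directly as truth (membrane-crossing
segments are helical; no DSSP run is emulated).

Everything is deterministic given the seed, and each chain's truth bundle
is derived through the same code path as for real structures, so the
generator also doubles as a round-trip test of the target derivations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .datasets import ChainRecord
from .structio import MSA, DsspRecord, MembraneChain, write_membrane_pdb
from .targets import MAX_ASA_TIEN, TargetBundle, count_tms, derive_bundle

__all__ = [
    "TopologySpec", "SyntheticChain",
    "make_chain", "make_msa", "make_learnable_dataset",
    "write_fixture_dir", "load_fixture_dir",
]

_LOOP_KINDS = ("inside", "outside")
_MEM_POOL = list("AILMFVWY")
_LOOP_COMMON = list("GSTNQP")
_INSIDE_EXTRA = list("KR")      # positive-inside rule
_OUTSIDE_EXTRA = list("DE")
_LOOP_SS = np.array(list("CTSE"))
_LOOP_SS_P = np.array([0.5, 0.25, 0.15, 0.10])


@dataclass
class TopologySpec:
    """Segment list of (kind, length) with kind in
    {inside, outside, TMS, RER}; lengths are residue counts (for RER, the
    in-membrane residue count)."""

    segments: list
    half_thickness: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if not self.segments:
            raise ValueError("empty segment list")
        if self.half_thickness <= 3:
            raise ValueError("half_thickness must exceed the 3 A RER immersion")
        side = None
        prev_kind = None
        for i, (kind, n) in enumerate(self.segments):
            if prev_kind == "RER" and kind not in _LOOP_KINDS:
                raise ValueError("RER must return to a loop on its entry side")
            if kind in _LOOP_KINDS:
                this = -1 if kind == "inside" else +1
                if side is not None and this != side:
                    raise ValueError(
                        f"segment {i}: {kind} loop on the wrong membrane side"
                    )
                side = this
                if n < 1:
                    raise ValueError("loop segments need >= 1 residue")
            elif kind == "TMS":
                if side is None:
                    raise ValueError("chain must start with a loop segment")
                if n < 5:
                    raise ValueError("TMS segments need >= 5 residues")
                side = -side
            elif kind == "RER":
                if prev_kind not in _LOOP_KINDS:
                    raise ValueError("RER must follow a loop segment")
                if n < 3:
                    raise ValueError("RER segments need >= 3 residues")
            else:
                raise ValueError(f"unknown segment kind {kind!r}")
            prev_kind = kind
        first, last = self.segments[0][0], self.segments[-1][0]
        if first not in _LOOP_KINDS or last not in _LOOP_KINDS:
            raise ValueError("chain must start and end with a loop segment")


@dataclass
class SyntheticChain:
    """A generated chain plus its derived ground truth."""

    chain: MembraneChain
    dssp_mono: DsspRecord
    dssp_cplx: DsspRecord
    truth: TargetBundle
    msa: MSA
    expected_labels: list


def _z_trace(spec: TopologySpec, rng) -> tuple:
    """Piecewise z-trace plus the expected per-residue topology labels."""
    h = spec.half_thickness
    z: list = []
    expected: list = []
    side = -1 if spec.segments[0][0] == "inside" else +1
    for kind, n in spec.segments:
        if kind in _LOOP_KINDS:
            z.extend(side * (h + 5.0) + rng.uniform(-0.8, 0.8, size=n))
            expected.extend([kind] * n)
        elif kind == "TMS":
            z.extend(np.linspace(side * (h - 0.5), -side * (h - 0.5), n))
            expected.extend(["TMS"] * n)
            side = -side
        else:  # RER
            immersion = rng.uniform(4.0, min(10.0, h - 1.0))
            edge = side * (h - 0.5)
            deep = side * (h - immersion)
            t = np.linspace(0.0, 1.0, n)
            z.extend(edge + (deep - edge) * (1.0 - np.abs(2.0 * t - 1.0)))
            expected.extend(["RER"] * n)
    return np.asarray(z), expected


def _backbone(z, rng) -> np.ndarray:
    """N/CA/C coordinates along the z-trace.

    CA atoms walk the trace with ~3.8 A steps; N and C sit between
    consecutive CAs with rotating lateral offsets so consecutive dihedral
    quadruples are never degenerate and peptide C-N distances stay well
    under the chain-break threshold.
    """
    L = len(z)
    ca = np.zeros((L, 3))
    ca[0] = (0.0, 0.0, z[0])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    for i in range(1, L):
        dz = z[i] - z[i - 1]
        dxy = np.sqrt(max(3.8 ** 2 - dz * dz, 1.0))
        heading += 0.7 + rng.uniform(-0.2, 0.2)
        ca[i] = ca[i - 1] + (dxy * np.cos(heading), dxy * np.sin(heading), dz)

    bb = np.zeros((L, 3, 3))
    for i in range(L):
        prev = ca[i - 1] if i > 0 else 2 * ca[0] - ca[1]
        nxt = ca[i + 1] if i < L - 1 else 2 * ca[-1] - ca[-2]
        th1 = 1.9 * i
        th2 = th1 + 2.1
        off1 = np.array([np.cos(th1), np.sin(th1), 0.5])
        off2 = np.array([np.cos(th2), np.sin(th2), -0.5])
        bb[i, 0] = ca[i] + 0.38 * (prev - ca[i]) + 0.3 * off1 / np.linalg.norm(off1)
        bb[i, 1] = ca[i]
        bb[i, 2] = ca[i] + 0.40 * (nxt - ca[i]) + 0.3 * off2 / np.linalg.norm(off2)
    return np.round(bb, 3)


def _sequence(expected_labels, rng) -> str:
    seq = []
    for lab in expected_labels:
        if lab in ("TMS", "RER"):
            pool = _MEM_POOL if rng.random() < 0.85 else _LOOP_COMMON
        elif lab == "inside":
            pool = _INSIDE_EXTRA if rng.random() < 0.5 else _LOOP_COMMON
        else:
            pool = _OUTSIDE_EXTRA if rng.random() < 0.5 else _LOOP_COMMON
        seq.append(pool[rng.integers(len(pool))])
    return "".join(seq)


def make_chain(spec: TopologySpec, chain_id: str = "A", msa_rows: int = 8,
               mutation_rate: float = 0.15) -> SyntheticChain:
    """Generate one chain (plus MSA and truth) from a topology spec.

    The derived truth bundle is produced by the regular target-derivation
    path, so by construction the topology annotation must recover the
    spec's segment kinds exactly.
    """
    rng = np.random.default_rng(spec.seed)
    z, expected = _z_trace(spec, rng)
    bb = _backbone(z, rng)
    z = bb[:, 1, 2]  # rounded CA z, identical to what a PDB round-trip yields
    seq = _sequence(expected, rng)

    depth_term = 18.0 * np.clip((np.abs(z) - spec.half_thickness) / 8.0, 0.0, 1.0)
    b_raw = np.round(28.0 + depth_term + rng.normal(0.0, 2.5, size=len(z)), 2)
    b_raw = np.clip(b_raw, 2.0, 99.0)

    chain = MembraneChain(
        chain_id=chain_id, seqres=seq, atomseq=seq, backbone=bb, z=z,
        b_raw=b_raw, half_thickness=spec.half_thickness, resolution=2.0,
    )

    in_mem = [lab in ("TMS", "RER") for lab in expected]
    ss8 = "".join(
        "H" if m else rng.choice(_LOOP_SS, p=_LOOP_SS_P) for m in in_mem
    )
    max_asa = np.array([MAX_ASA_TIEN[aa] for aa in seq])
    frac = np.where(in_mem, rng.uniform(0.0, 0.25, len(seq)),
                    rng.uniform(0.15, 0.95, len(seq)))
    asa_mono = frac * max_asa
    buried = rng.random(len(seq)) < 0.25
    burial = np.where(buried, rng.uniform(0.3, 0.7, len(seq)), 0.0)
    asa_cplx = asa_mono * (1.0 - burial)
    dssp_mono = DsspRecord(ss8=ss8, asa=asa_mono)
    dssp_cplx = DsspRecord(ss8=ss8, asa=asa_cplx)

    truth = derive_bundle(chain, dssp_mono, dssp_cplx)
    msa = make_msa(seq, n_rows=msa_rows, mutation_rate=mutation_rate,
                   seed=int(rng.integers(2 ** 31)))
    return SyntheticChain(chain=chain, dssp_mono=dssp_mono,
                          dssp_cplx=dssp_cplx, truth=truth, msa=msa,
                          expected_labels=expected)


def make_msa(sequence: str, n_rows: int, mutation_rate: float, seed: int) -> MSA:
    """Mutated-copy MSA: row 0 is the query, the others carry seeded
    per-site substitutions at the given rate."""
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rows = [sequence]
    for _ in range(max(n_rows - 1, 0)):
        chars = list(sequence)
        hits = np.flatnonzero(rng.random(len(chars)) < mutation_rate)
        for i in hits:
            options = alphabet.replace(chars[i], "")
            chars[i] = options[rng.integers(len(options))]
        rows.append("".join(chars))
    return MSA(query=sequence, rows=rows)


def _random_spec(rng, half_thickness=15.0) -> TopologySpec:
    n_tms = int(rng.integers(1, 5))
    side = "inside" if rng.random() < 0.5 else "outside"
    segments = [(side, int(rng.integers(6, 25)))]
    for _ in range(n_tms):
        if rng.random() < 0.2:
            segments.append(("RER", int(rng.integers(4, 9))))
            segments.append((side, int(rng.integers(4, 12))))
        segments.append(("TMS", int(rng.integers(15, 26))))
        side = "outside" if side == "inside" else "inside"
        segments.append((side, int(rng.integers(6, 25))))
    total = sum(n for _, n in segments)
    if total < 50:
        kind, n = segments[-1]
        segments[-1] = (kind, n + 50 - total)
    return TopologySpec(segments=segments, half_thickness=half_thickness,
                        seed=int(rng.integers(2 ** 31)))


def make_learnable_dataset(n_chains: int, seed: int = 0) -> list:
    """Chain records with varied topologies (1-4 TMS, occasional RER),
    lengths ~50-300, all passing the dataset quality filters."""
    if n_chains < 10:
        raise ValueError("need at least 10 chains for a learnable dataset")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_chains):
        syn = make_chain(_random_spec(rng), chain_id="A")
        records.append(ChainRecord(
            id=f"SYN{i:03d}_A",
            seq=syn.chain.atomseq,
            n_tms=count_tms(syn.truth.topo_labels),
            chain=syn.chain,
            dssp=syn.dssp_mono,
            dssp_cplx=syn.dssp_cplx,
            msa=syn.msa,
            bundle=syn.truth,
            provenance="synthetic",
        ))
    return records


def write_fixture_dir(records, directory) -> Path:
    """Write records as PDB + FASTA + A3M + truth TSV so the real I/O
    paths are exercised; returns the dataset index path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {"chains": []}
    for rec in records:
        (directory / f"{rec.id}.pdb").write_text(write_membrane_pdb(rec.chain))
        (directory / f"{rec.id}.fasta").write_text(f">{rec.id}\n{rec.seq}\n")
        if rec.msa is not None:
            lines = [f">{rec.id}\n{rec.msa.rows[0]}"]
            lines += [f">{rec.id}|hit{j}\n{row}"
                      for j, row in enumerate(rec.msa.rows[1:], 1)]
            (directory / f"{rec.id}.a3m").write_text("\n".join(lines) + "\n")
        rec.bundle.to_frame().to_csv(directory / f"{rec.id}.truth.tsv",
                                     sep="\t", index=False)
        index["chains"].append({
            "id": rec.id,
            "chain_id": rec.chain.chain_id,
            "half_thickness": rec.chain.half_thickness,
            "n_tms": rec.n_tms,
        })
    path = directory / "dataset.json"
    path.write_text(json.dumps(index, indent=2))
    return path


def load_fixture_dir(directory) -> list:
    """Reload a fixture directory written by :func:`write_fixture_dir`."""
    import pandas as pd

    from .structio import read_membrane_pdb, read_msa

    directory = Path(directory)
    index = json.loads((directory / "dataset.json").read_text())
    records = []
    for entry in index["chains"]:
        rid = entry["id"]
        chain = read_membrane_pdb((directory / f"{rid}.pdb").read_text(),
                                  entry["chain_id"], entry["half_thickness"])
        msa_path = directory / f"{rid}.a3m"
        msa = read_msa(msa_path.read_text(), "a3m") if msa_path.exists() else None
        frame = pd.read_csv(directory / f"{rid}.truth.tsv", sep="\t")
        bundle = TargetBundle.from_frame(frame)
        records.append(ChainRecord(
            id=rid, seq=chain.atomseq, n_tms=entry["n_tms"], chain=chain,
            msa=msa, bundle=bundle, provenance=str(directory),
        ))
    return records
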