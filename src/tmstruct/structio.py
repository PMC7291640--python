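"""Readers and writers for the formats the pipeline touches.

Membrane-oriented PDB files follow the OPM convention: the structure is
rotated/translated so that every atom's z-coordinate is its signed depth in
the lipid bilayer (0 = membrane centre, negative = inner side).  Parsing is
done on fixed column ranges, never by whitespace, because PDB is a
fixed-column format and OPM files occasionally contain fused columns.

Also handled here: FASTA and A3M multiple sequence alignments, classic DSSP
tabular output, and per-residue prediction tables (TSV plus a JSON metadata
sidecar).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqUtils import seq1

__all__ = [
    "MembraneChain",
    "MSA",
    "DsspRecord",
    "read_membrane_pdb",
    "write_membrane_pdb",
    "read_msa",
    "parse_dssp",
    "write_predictions",
    "read_predictions",
]

_AA_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}


@dataclass
class MembraneChain:
    """One protein chain in membrane-oriented coordinates.

    Attributes
    ----------
    chain_id : str
        PDB chain identifier.
    seqres : str
        Full sequence as declared by SEQRES records (falls back to the
        ATOM-derived sequence when SEQRES is absent).
    atomseq : str
        Sequence extracted from the ATOM records; only these residues carry
        coordinates.
    backbone : (L, 3, 3) float array
        Per-residue N, CA, C coordinates in Angstrom, in that order.
    z : (L,) float array
        Signed depth of the CA atom in the membrane (negative = inner side).
    b_raw : (L,) float array
        Raw crystallographic B-factor of the CA atom.
    half_thickness : float
        Half of the membrane thickness in Angstrom (an input, not a
        constant: real membranes vary around ~15 A).
    observed_mask : (len(seqres),) bool array
        True at seqres positions covered by atomseq.
    resolution : float or None
        Crystallographic resolution in Angstrom, if stated in the header.
    """

    chain_id: str
    seqres: str
    atomseq: str
    backbone: np.ndarray
    z: np.ndarray
    b_raw: np.ndarray
    half_thickness: float = 15.0
    observed_mask: np.ndarray = field(default=None)
    resolution: float | None = None

    def __post_init__(self):
        self.backbone = np.asarray(self.backbone, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.b_raw = np.asarray(self.b_raw, dtype=float)
        L = len(self.atomseq)
        if not (len(self.z) == len(self.b_raw) == len(self.backbone) == L):
            raise ValueError("atomseq, z, b_raw and backbone lengths differ")
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")
        if self.observed_mask is None:
            self.observed_mask = _align_mask(self.seqres, self.atomseq)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if int(self.observed_mask.sum()) != L:
            raise ValueError("observed_mask must cover exactly the atomseq residues")

    def __len__(self) -> int:
        return len(self.atomseq)


@dataclass
class MSA:
    """A multiple sequence alignment; row 0 is the query."""

    query: str
    rows: list

    def __post_init__(self):
        for r in self.rows:
            if len(r) != len(self.query):
                raise ValueError("all MSA rows must have query length")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DsspRecord:
    """Per-residue 8-state secondary structure and absolute accessibility."""

    ss8: str
    asa: np.ndarray

    def __post_init__(self):
        self.asa = np.asarray(self.asa, dtype=float)
        if len(self.ss8) != len(self.asa):
            raise ValueError("ss8 and asa lengths differ")
        if np.any(self.asa < 0):
            raise ValueError("ASA values must be non-negative")

    def __len__(self) -> int:
        return len(self.ss8)


def _align_mask(seqres: str, atomseq: str) -> np.ndarray:
    """Mark the seqres positions covered by atomseq.

    The common case (residues missing only at the termini) reduces to a
    substring search; interior gaps are resolved with a global alignment.
    """
    mask = np.zeros(len(seqres), dtype=bool)
    if not atomseq:
        return mask
    idx = seqres.find(atomseq)
    if idx >= 0:
        mask[idx:idx + len(atomseq)] = True
        return mask
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -3.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seqres, atomseq)[0]
    for (ts, te), _ in zip(*aln.aligned):
        mask[ts:te] = True
    return mask


def read_membrane_pdb(text: str, chain_id: str, half_thickness: float = 15.0) -> MembraneChain:
    """Parse one chain from a membrane-oriented (OPM-style) PDB string.

    Residues are kept in file order (insertion codes included); of alternate
    locations only blank or 'A' are kept; for multi-model entries only the
    first model is read.  The per-residue z-coordinate and raw B-factor are
    taken from the CA atom.

    Raises
    ------
    ValueError
        If the chain is absent, or an interior residue misses one of the
        N/CA/C backbone atoms ("incomplete backbone").  Residues with an
        incomplete backbone at the termini are silently dropped, mirroring
        how partially resolved chain ends are treated downstream.
    """
    seqres_res: list = []
    residues: dict = {}
    order: list = []
    resolution = None
    for line in text.splitlines():
        rec = line[:6]
        if rec == "REMARK" and "RESOLUTION." in line:
            toks = line.split()
            try:
                i = toks.index("RESOLUTION.")
                resolution = float(toks[i + 1])
            except (ValueError, IndexError):
                pass
        elif rec == "SEQRES":
            if len(line) > 11 and line[11] == chain_id:
                seqres_res.extend(line[19:70].split())
        elif rec == "ATOM  ":
            if len(line) < 66 or line[21] != chain_id:
                continue
            if line[16] not in (" ", "A"):
                continue
            name = line[12:16].strip()
            if name not in ("N", "CA", "C"):
                continue
            key = (int(line[22:26]), line[26])
            if key not in residues:
                residues[key] = {"resname": line[17:20].strip()}
                order.append(key)
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            residues[key][name] = (xyz, float(line[60:66]))
        elif rec == "ENDMDL":
            break
    if not residues:
        raise ValueError(f"no ATOM records for chain {chain_id!r}")

    complete = [all(a in residues[k] for a in ("N", "CA", "C")) for k in order]
    first = complete.index(True) if any(complete) else 0
    last = len(order) - 1 - complete[::-1].index(True) if any(complete) else -1
    if last < first:
        raise ValueError(f"no residue with complete backbone in chain {chain_id!r}")
    kept = []
    for i in range(first, last + 1):
        if not complete[i]:
            num, icode = order[i]
            raise ValueError(
                f"incomplete backbone at residue {num}{icode.strip()} "
                f"({residues[order[i]]['resname']}) of chain {chain_id!r}"
            )
        kept.append(order[i])

    atomseq = "".join(seq1(residues[k]["resname"]) for k in kept)
    backbone = np.array(
        [[residues[k][a][0] for a in ("N", "CA", "C")] for k in kept], dtype=float
    )
    z = np.array([residues[k]["CA"][0][2] for k in kept])
    b_raw = np.array([residues[k]["CA"][1] for k in kept])
    seqres = "".join(seq1(r) for r in seqres_res) if seqres_res else atomseq
    return MembraneChain(
        chain_id=chain_id,
        seqres=seqres,
        atomseq=atomseq,
        backbone=backbone,
        z=z,
        b_raw=b_raw,
        half_thickness=half_thickness,
        observed_mask=_align_mask(seqres, atomseq),
        resolution=resolution,
    )


def write_membrane_pdb(chain: MembraneChain) -> str:
    """Serialize a chain back to fixed-column PDB text.

    The inverse of :func:`read_membrane_pdb` up to coordinate precision
    (3 decimals for coordinates, 2 for B-factors); residue numbers are the
    1-based seqres positions so terminal gaps round-trip through the
    observed mask.
    """
    lines = []
    if chain.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {chain.resolution:7.2f} ANGSTROMS.")
    three = [_AA_1TO3.get(a, "UNK") for a in chain.seqres]
    for i in range(0, len(three), 13):
        lines.append(
            f"SEQRES {i // 13 + 1:>3} {chain.chain_id} {len(three):>4}  "
            + " ".join(three[i:i + 13])
        )
    positions = np.flatnonzero(chain.observed_mask)
    serial = 1
    for ri, pos in enumerate(positions):
        resname = _AA_1TO3.get(chain.atomseq[ri], "UNK")
        for ai, name in enumerate(("N", "CA", "C")):
            x, y, zc = chain.backbone[ri, ai]
            if name == "CA":
                zc = chain.z[ri]
            lines.append(
                f"ATOM  {serial:>5}  {name:<3} {resname:>3} {chain.chain_id}"
                f"{pos + 1:>4}    {x:8.3f}{y:8.3f}{zc:8.3f}{1.0:6.2f}"
                f"{chain.b_raw[ri]:6.2f}          {name[0]:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_msa(text: str, dialect: str = "fasta") -> MSA:
    """Parse an MSA from FASTA or A3M text; the first record is the query.

    For the a3m dialect, lowercase letters are insert states relative to
    the query and are deleted before length checks ('.' insert gaps are
    removed as well); '-' is kept as a deletion gap.
    """
    if dialect not in ("fasta", "a3m"):
        raise ValueError(f"unknown MSA dialect {dialect!r}")
    records = list(SimpleFastaParser(io.StringIO(text)))
    if not records:
        raise ValueError("empty MSA")
    rows = []
    for _, seq in records:
        if dialect == "a3m":
            seq = "".join(c for c in seq if not (c.islower() or c == "."))
        rows.append(seq)
    query = rows[0]
    for i, r in enumerate(rows):
        if len(r) != len(query):
            raise ValueError(
                f"MSA format error: row {i} has length {len(r)}, query has {len(query)}"
            )
    return MSA(query=query, rows=rows)


def parse_dssp(text: str, chain_id: str) -> DsspRecord:
    """Parse classic mkdssp tabular output for one chain.

    Chain breaks ('!' in the amino-acid column) are skipped, and a blank
    structure column maps to coil 'C'.
    """
    ss = []
    asa = []
    in_table = False
    for line in text.splitlines():
        if not in_table:
            if line.startswith("  #  RESIDUE"):
                in_table = True
            continue
        if len(line) < 38:
            continue
        if line[13] == "!":
            continue
        if line[11] != chain_id:
            continue
        s = line[16]
        ss.append("C" if s == " " else s)
        asa.append(float(line[34:38]))
    if not ss:
        raise ValueError(f"no DSSP rows for chain {chain_id!r}")
    return DsspRecord(ss8="".join(ss), asa=np.array(asa))


def write_predictions(
    chain_id: str,
    predictions: dict,
    class_names: dict | None = None,
    sequence: str | None = None,
    metadata: dict | None = None,
) -> tuple:
    """Render per-residue predictions as TSV plus a JSON metadata sidecar.

    ``predictions`` maps target name to a 1-D array (continuous / binary) or
    an (L, K) array of class probabilities; categorical targets emit one
    probability column per class plus an argmax label column.  Returns
    ``(tsv_text, sidecar_json_text)``.
    """
    lengths = {k: np.asarray(v).shape[0] for k, v in predictions.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"prediction arrays differ in length: {lengths}")
    L = next(iter(lengths.values())) if lengths else 0
    data = {"residue": np.arange(1, L + 1)}
    if sequence is not None:
        if len(sequence) != L:
            raise ValueError("sequence length does not match predictions")
        data["aa"] = list(sequence)
    for name, values in predictions.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 1:
            data[name] = arr
        else:
            classes = (class_names or {}).get(name) or [str(i) for i in range(arr.shape[1])]
            for j, cls in enumerate(classes):
                data[f"{name}_p_{cls}"] = arr[:, j]
            data[f"{name}_label"] = [classes[j] for j in arr.argmax(axis=1)] if L else []
    frame = pd.DataFrame(data)
    tsv = frame.to_csv(sep="\t", index=False, float_format="%.6f")
    sidecar = json.dumps(
        {"chain_id": chain_id, "n_residues": int(L), "targets": sorted(predictions),
         **(metadata or {})},
        indent=2,
        sort_keys=True,
    )
    return tsv, sidecar


def read_predictions(tsv_text: str) -> pd.DataFrame:
    """Parse a prediction TSV produced by :func:`write_predictions`."""
    return pd.read_csv(io.StringIO(tsv_text), sep="\t")
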