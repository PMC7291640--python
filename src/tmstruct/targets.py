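"""Derivation of the ten per-residue prediction targets.

From a membrane-oriented chain (plus DSSP output for the monomeric and,
optionally, the complexed form) this module derives:

* ``z``            -- CA depth in the membrane, clipped to [-25, 25] A and
                      scaled to [-1, 1];
* ``topo``         -- four-state topology (inside / TMS / outside / RER);
* ``flex_cont``    -- per-chain z-scored B-factor (B_norm);
* ``flex_bin``     -- two-state flexibility (flexible iff B_norm > 0.03);
* ``phi``, ``psi`` -- backbone torsions in degrees, scaled to [-1, 1];
* ``ss3``          -- three-state secondary structure (helix/sheet/coil);
* ``rsa_mono``, ``rsa_cplx``, ``rsa_change`` -- relative solvent
  accessibilities in [0, 1] and the burial upon complex formation.

Each target carries its own validity mask; masked residues are excluded
from training losses and from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import DsspRecord, MembraneChain

__all__ = [
    "TOPOLOGY_CLASSES",
    "SS3_CLASSES",
    "MAX_ASA_TIEN",
    "TargetBundle",
    "derive_z",
    "annotate_topology",
    "count_tms",
    "encode_topology",
    "normalize_bfactors",
    "binarize_flexibility",
    "dihedral",
    "compute_torsions",
    "scale_angles",
    "collapse_ss",
    "compute_rsa",
    "rsa_change",
    "derive_bundle",
]

TOPOLOGY_CLASSES = ("inside", "TMS", "outside", "RER")
SS3_CLASSES = ("helix", "sheet", "coil")

#: Theoretical maximum solvent accessibility per residue (A^2), Tien et al.
#: 2013 scale.  Overridable wherever it is consumed.
MAX_ASA_TIEN = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Clipping bound for membrane depth (A): the bilayer rarely exceeds 30 A
#: total thickness, so depths beyond +-25 A carry no signal.
Z_CLIP = 25.0

#: B_norm threshold separating flexible (>) from rigid (<=) residues.
FLEX_THRESHOLD = 0.03

_SS8_TO_SS3 = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "sheet", "B": "sheet",
    "T": "coil", "S": "coil", "C": "coil",
}


def derive_z(z_raw) -> np.ndarray:
    """Clip raw depths to [-25, 25] A and scale linearly to [-1, 1]."""
    z = np.asarray(z_raw, dtype=float)
    return np.clip(z, -Z_CLIP, Z_CLIP) / Z_CLIP


def _runs(mask: np.ndarray):
    """Yield (start, stop_inclusive) for maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, stops):
        yield int(idx[s]), int(idx[e])


def _end_sign(z, a, b, step):
    """Sign of z at run end ``a``, falling back to the first non-zero value
    scanning towards the other end."""
    i = a
    while i != b + step and z[i] == 0:
        i += step
    return np.sign(z[i]) if i != b + step else 0.0


def annotate_topology(z_raw, half_thickness: float) -> list:
    """Assign each residue one of four topological states.

    With h = half_thickness, the procedure is:

    1. Maximal runs of residues with \\|z\\| <= h whose two ends lie on
       opposite sides of the membrane centre and within 10 A of their
       respective boundaries (+-h) are membrane-crossing segments (TMS).
       Because the runs are maximal under \\|z\\| <= h this already includes
       the outward extension up to the membrane boundaries.
    2. Remaining in-membrane runs flanked on both sides by residues outside
       the membrane (\\|z\\| > h) on the *same* side, containing at least 3
       residues, and whose deepest residue satisfies \\|z\\| <= h - 3
       (i.e. immersed at least 3 A past the boundary) are re-entrant
       regions (RER).
    3. Everything else is 'inside' if z < 0, else 'outside'.
    """
    z = np.asarray(z_raw, dtype=float)
    L = len(z)
    labels = [None] * L
    h = float(half_thickness)
    in_mem = np.abs(z) <= h

    tms_runs = []
    other_runs = []
    for a, b in _runs(in_mem):
        s_a = _end_sign(z, a, b, +1)
        s_b = _end_sign(z, b, a, -1)
        crossing = s_a * s_b < 0
        near_a = abs(z[a] - s_a * h) <= 10.0
        near_b = abs(z[b] - s_b * h) <= 10.0
        if crossing and near_a and near_b:
            tms_runs.append((a, b))
        else:
            other_runs.append((a, b))
    for a, b in tms_runs:
        for i in range(a, b + 1):
            labels[i] = "TMS"

    for a, b in other_runs:
        if a == 0 or b == L - 1:
            continue
        s = np.sign(z[a - 1])
        if np.sign(z[b + 1]) != s or s == 0:
            continue
        if b - a + 1 < 3:
            continue
        deepest = a + int(np.argmin(s * z[a:b + 1]))
        if abs(z[deepest]) <= h - 3.0:
            for i in range(a, b + 1):
                labels[i] = "RER"

    for i in range(L):
        if labels[i] is None:
            labels[i] = "inside" if z[i] < 0 else "outside"
    return labels


def count_tms(labels) -> int:
    """Number of maximal TMS runs in a topology labelling."""
    n = 0
    prev = None
    for lab in labels:
        if lab == "TMS" and prev != "TMS":
            n += 1
        prev = lab
    return n


def encode_topology(labels) -> np.ndarray:
    """One-hot encode topology labels in the fixed class order
    (inside, TMS, outside, RER)."""
    out = np.zeros((len(labels), len(TOPOLOGY_CLASSES)))
    for i, lab in enumerate(labels):
        try:
            out[i, TOPOLOGY_CLASSES.index(lab)] = 1.0
        except ValueError:
            raise ValueError(f"unknown topology label {lab!r}") from None
    return out


def normalize_bfactors(b_raw, mask=None) -> np.ndarray:
    """Per-chain z-score of raw B-factors: B_norm = (B_raw - mu) / sigma.

    mu and sigma are the population mean and standard deviation over the
    masked residues of *this* chain only -- B-factors are not comparable
    between structures.  Masked-out positions get NaN.
    """
    b = np.asarray(b_raw, dtype=float)
    m = np.ones(len(b), dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    vals = b[m]
    if vals.size < 2 or np.unique(vals).size < 2:
        raise ValueError("constant B-factors: need more than one distinct value")
    mu = vals.mean()
    sigma = vals.std()  # population
    if sigma == 0:
        raise ValueError("constant B-factors: sigma is zero")
    out = np.full(len(b), np.nan)
    out[m] = (b[m] - mu) / sigma
    return out


def binarize_flexibility(b_norm) -> np.ndarray:
    """1 = flexible (B_norm > 0.03), 0 = rigid (B_norm <= 0.03)."""
    return (np.asarray(b_norm, dtype=float) > FLEX_THRESHOLD).astype(int)


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle in degrees, in (-180, 180].

    IUPAC sign convention: looking down the p1->p2 bond, a clockwise
    rotation of the far bond relative to the near bond is positive
    (trans = 180, cis = 0).  Accepts stacked coordinate arrays.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    m1 = np.cross(b1u, n1)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def compute_torsions(backbone, break_distance: float = 2.5):
    """Backbone phi/psi angles in degrees with validity masks.

    phi(i) uses C(i-1), N(i), CA(i), C(i); psi(i) uses N(i), CA(i), C(i),
    N(i+1).  The phi mask is False at the first residue and the psi mask at
    the last; both are False across chain breaks, detected as a C(i)-N(i+1)
    distance exceeding ``break_distance`` A (a peptide bond is ~1.33 A).

    Returns ``(phi, psi, phi_mask, psi_mask)``.
    """
    bb = np.asarray(backbone, dtype=float)
    L = len(bb)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    phi_mask = np.zeros(L, dtype=bool)
    psi_mask = np.zeros(L, dtype=bool)
    if L < 2:
        return phi, psi, phi_mask, psi_mask
    N, CA, C = bb[:, 0], bb[:, 1], bb[:, 2]
    bonded = np.linalg.norm(C[:-1] - N[1:], axis=-1) <= break_distance
    for i in range(1, L):
        if bonded[i - 1]:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
            phi_mask[i] = True
    for i in range(L - 1):
        if bonded[i]:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
            psi_mask[i] = True
    return phi, psi, phi_mask, psi_mask


def scale_angles(angle) -> np.ndarray:
    """Map angles in degrees, (-180, 180], linearly onto [-1, 1]."""
    return np.asarray(angle, dtype=float) / 180.0


def collapse_ss(ss8) -> np.ndarray:
    """Collapse DSSP 8-state letters to a 3-state one-hot matrix.

    {H, G, I} -> helix, {E, B} -> sheet, {T, S, C} -> coil, encoded
    [1,0,0] / [0,1,0] / [0,0,1].
    """
    out = np.zeros((len(ss8), 3))
    for i, letter in enumerate(ss8):
        if letter not in _SS8_TO_SS3:
            raise ValueError(f"unknown DSSP state {letter!r}")
        out[i, SS3_CLASSES.index(_SS8_TO_SS3[letter])] = 1.0
    return out


def compute_rsa(asa, residue, max_asa_table=None) -> float:
    """Relative solvent accessibility: ASA / max-ASA, capped at 1.

    DSSP can report accessibilities above the tabulated theoretical maxima;
    capping keeps the target in [0, 1].
    """
    table = MAX_ASA_TIEN if max_asa_table is None else max_asa_table
    if residue not in table:
        raise KeyError(f"no maximum-ASA entry for residue {residue!r}")
    if asa < 0:
        raise ValueError("ASA must be non-negative")
    return min(float(asa) / table[residue], 1.0)


def rsa_change(rsa_mono, rsa_cplx):
    """Burial upon complex formation: monomer RSA minus complex RSA.

    Floored at 0 -- complex formation can only bury surface.  Returns
    ``(floored, raw)`` so the (rare, numerical) negative differences stay
    available for diagnostics.
    """
    raw = np.asarray(rsa_mono, dtype=float) - np.asarray(rsa_cplx, dtype=float)
    return np.maximum(raw, 0.0), raw


@dataclass
class TargetBundle:
    """The ten per-residue targets in training-ready numeric form.

    Continuous targets are stored on their scaled training range; masks map
    target name to a boolean validity array.  ``diagnostics`` carries
    auxiliary arrays (e.g. the unfloored RSA change).
    """

    z_scaled: np.ndarray
    topo: np.ndarray           # (L, 4) one-hot
    topo_labels: list
    flex_cont: np.ndarray
    flex_bin: np.ndarray
    phi_scaled: np.ndarray
    psi_scaled: np.ndarray
    ss3: np.ndarray            # (L, 3) one-hot
    rsa_mono: np.ndarray
    rsa_cplx: np.ndarray
    rsa_change: np.ndarray
    masks: dict
    diagnostics: dict = field(default_factory=dict)

    TARGET_NAMES = (
        "z", "topo", "flex_cont", "flex_bin", "phi", "psi",
        "ss3", "rsa_mono", "rsa_cplx", "rsa_change",
    )

    def __len__(self) -> int:
        return len(self.z_scaled)

    def target(self, name: str) -> np.ndarray:
        return {
            "z": self.z_scaled, "topo": self.topo, "flex_cont": self.flex_cont,
            "flex_bin": self.flex_bin, "phi": self.phi_scaled,
            "psi": self.psi_scaled, "ss3": self.ss3, "rsa_mono": self.rsa_mono,
            "rsa_cplx": self.rsa_cplx, "rsa_change": self.rsa_change,
        }[name]

    def validate(self):
        L = len(self)
        for name in self.TARGET_NAMES:
            if name not in self.masks or len(self.masks[name]) != L:
                raise ValueError(f"missing or misaligned mask for {name!r}")
        for name, arr in (("topo", self.topo), ("ss3", self.ss3)):
            m = self.masks[name]
            if m.any() and not np.allclose(arr[m].sum(axis=1), 1.0):
                raise ValueError(f"{name} one-hot rows must sum to 1")
        for name, arr in (("z", self.z_scaled), ("phi", self.phi_scaled),
                          ("psi", self.psi_scaled)):
            m = self.masks[name]
            if m.any() and np.max(np.abs(arr[m])) > 1.0 + 1e-12:
                raise ValueError(f"{name} exceeds [-1, 1]")
        m = self.masks["flex_cont"]
        if m.sum() >= 2:
            vals = self.flex_cont[m]
            if abs(vals.mean()) > 1e-6 or abs(vals.std() - 1.0) > 1e-6:
                raise ValueError("flex_cont is not a per-chain z-score")
        bad = self.masks["rsa_change"] & ~(self.masks["rsa_mono"] & self.masks["rsa_cplx"])
        if bad.any():
            raise ValueError("rsa_change mask must imply rsa_mono and rsa_cplx masks")
        return self

    def to_frame(self):
        """Flat per-residue table (TSV-friendly) with one column per scalar
        target, per one-hot class, and per mask."""
        import pandas as pd

        L = len(self)
        data = {"residue": np.arange(1, L + 1)}
        data["z"] = self.z_scaled
        for j, cls in enumerate(TOPOLOGY_CLASSES):
            data[f"topo_{cls}"] = self.topo[:, j]
        data["flex_cont"] = self.flex_cont
        data["flex_bin"] = self.flex_bin
        data["phi"] = self.phi_scaled
        data["psi"] = self.psi_scaled
        for j, cls in enumerate(SS3_CLASSES):
            data[f"ss3_{cls}"] = self.ss3[:, j]
        data["rsa_mono"] = self.rsa_mono
        data["rsa_cplx"] = self.rsa_cplx
        data["rsa_change"] = self.rsa_change
        for name in self.TARGET_NAMES:
            data[f"mask_{name}"] = self.masks[name].astype(int)
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame) -> "TargetBundle":
        topo = frame[[f"topo_{c}" for c in TOPOLOGY_CLASSES]].to_numpy(float)
        ss3 = frame[[f"ss3_{c}" for c in SS3_CLASSES]].to_numpy(float)
        masks = {
            name: frame[f"mask_{name}"].to_numpy(bool) for name in cls.TARGET_NAMES
        }
        labels = [TOPOLOGY_CLASSES[j] for j in topo.argmax(axis=1)]
        return cls(
            z_scaled=frame["z"].to_numpy(float),
            topo=topo,
            topo_labels=labels,
            flex_cont=frame["flex_cont"].to_numpy(float),
            flex_bin=frame["flex_bin"].to_numpy(float),
            phi_scaled=frame["phi"].to_numpy(float),
            psi_scaled=frame["psi"].to_numpy(float),
            ss3=ss3,
            rsa_mono=frame["rsa_mono"].to_numpy(float),
            rsa_cplx=frame["rsa_cplx"].to_numpy(float),
            rsa_change=frame["rsa_change"].to_numpy(float),
            masks=masks,
        )


def derive_bundle(
    chain: MembraneChain,
    dssp_mono: DsspRecord,
    dssp_cplx: DsspRecord | None = None,
    max_asa_table=None,
) -> TargetBundle:
    """Derive all ten targets for one chain.

    ``dssp_mono`` (and optionally ``dssp_cplx`` for the chain within its
    biological assembly) must cover exactly the observed residues of the
    chain, in order.  When the complexed form is absent, the complex-RSA and
    RSA-change targets are fully masked.
    """
    L = len(chain)
    if len(dssp_mono) != L:
        raise ValueError("DSSP record does not cover the chain")
    if dssp_cplx is not None and len(dssp_cplx) != L:
        raise ValueError("complex DSSP record does not cover the chain")
    table = MAX_ASA_TIEN if max_asa_table is None else max_asa_table

    z_scaled = derive_z(chain.z)
    labels = annotate_topology(chain.z, chain.half_thickness)
    topo = encode_topology(labels)
    flex_cont = normalize_bfactors(chain.b_raw)
    flex_bin = binarize_flexibility(flex_cont)
    phi, psi, phi_mask, psi_mask = compute_torsions(chain.backbone)
    ss3 = collapse_ss(dssp_mono.ss8)

    known = np.array([aa in table for aa in chain.atomseq])
    rsa_m = np.zeros(L)
    rsa_c = np.zeros(L)
    for i, aa in enumerate(chain.atomseq):
        if known[i]:
            rsa_m[i] = compute_rsa(dssp_mono.asa[i], aa, table)
            if dssp_cplx is not None:
                rsa_c[i] = compute_rsa(dssp_cplx.asa[i], aa, table)
    change, change_raw = rsa_change(rsa_m, rsa_c)

    always = np.ones(L, dtype=bool)
    cplx_mask = known & (dssp_cplx is not None)
    masks = {
        "z": always.copy(),
        "topo": always.copy(),
        "flex_cont": always.copy(),
        "flex_bin": always.copy(),
        "phi": phi_mask,
        "psi": psi_mask,
        "ss3": always.copy(),
        "rsa_mono": known.copy(),
        "rsa_cplx": cplx_mask.copy(),
        "rsa_change": known & cplx_mask,
    }
    phi_s = np.where(phi_mask, scale_angles(np.nan_to_num(phi)), 0.0)
    psi_s = np.where(psi_mask, scale_angles(np.nan_to_num(psi)), 0.0)
    bundle = TargetBundle(
        z_scaled=z_scaled,
        topo=topo,
        topo_labels=labels,
        flex_cont=flex_cont,
        flex_bin=flex_bin,
        phi_scaled=phi_s,
        psi_scaled=psi_s,
        ss3=ss3,
        rsa_mono=rsa_m,
        rsa_cplx=rsa_c,
        rsa_change=change,
        masks=masks,
        diagnostics={"rsa_change_unfloored": change_raw,
                     "phi_deg": phi, "psi_deg": psi},
    )
    return bundle.validate()
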