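"""Backbone geometry: structures, PDB I/O, torsions, chain building, superposition.

The backbone model keeps only the heavy atoms N, CA, C and (optionally) O per
residue — the coarse representation used throughout fragment-based prediction,
where the backbone torsion angles phi/psi/omega are the only degrees of
freedom and bond lengths/angles are held at ideal values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "BackboneStructure",
    "TorsionTriple",
    "Superposition",
    "read_pdb_backbone",
    "read_pdb_models",
    "write_pdb",
    "read_fasta",
    "compute_torsions",
    "build_backbone_from_torsions",
    "kabsch_superpose",
    "dihedral",
    "CHAIN_BREAK_CA_CA",
    "IDEAL_GEOMETRY",
]

# CA-CA distance above which consecutive residues are treated as a chain break
# (conservative proxy for a broken peptide bond; trans peptide CA-CA ~ 3.8 A).
CHAIN_BREAK_CA_CA = 4.5

#: Ideal backbone covalent geometry used for internal-to-Cartesian building.
IDEAL_GEOMETRY = {
    "n_ca": 1.458,      # N-CA bond (A)
    "ca_c": 1.525,      # CA-C bond (A)
    "c_n": 1.329,       # C-N peptide bond (A)
    "c_o": 1.231,       # C=O carbonyl bond (A)
    "n_ca_c": 111.2,    # backbone angles (degrees)
    "ca_c_n": 116.2,
    "c_n_ca": 121.7,
    "ca_c_o": 120.8,
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "UNK": "X",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items() if k not in ("MSE", "SEC")}
AA1_TO_3["X"] = "UNK"


@dataclass
class TorsionTriple:
    """Backbone torsions of one residue, degrees in (-180, 180].

    ``phi`` is undefined for the first residue, ``psi``/``omega`` for the
    last; an undefined angle is ``None`` (a sentinel, never a fake value).
    ``omega`` describes the peptide bond to the following residue.
    """

    position: int           # 1-based residue index
    phi: float | None
    psi: float | None
    omega: float | None


@dataclass
class Superposition:
    """Optimal rigid superposition: x -> rotation @ x + translation.

    ``rotation`` is a proper rotation (det = +1); ``rmsd`` is the minimal
    CA RMSD over all rigid transforms for the paired point sets.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class BackboneStructure:
    """Protein backbone: per-residue N/CA/C coordinates, optional O, sequence.

    Coordinates are float64 arrays of shape (L, 3) in Angstroms. A missing O
    is a NaN row in ``o``. Residue indexing is 1-based throughout the
    package; fragment windows are inclusive.
    """

    id: str
    chain: str
    sequence: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray | None = None
    skipped_residues: int = 0

    def __post_init__(self) -> None:
        for name in ("n", "ca", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.sequence), 3):
                raise ValueError(
                    f"{name} coordinates have shape {arr.shape}, "
                    f"expected ({len(self.sequence)}, 3)"
                )
            setattr(self, name, arr)
        if self.o is not None:
            self.o = np.asarray(self.o, dtype=float).reshape(len(self.sequence), 3)
        for name in ("n", "ca", "c"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite {name.upper()} coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_o(self) -> bool:
        return self.o is not None and bool(np.all(np.isfinite(self.o)))

    def chain_breaks(self) -> np.ndarray:
        """Boolean array of length L-1; True where CA(i)-CA(i+1) > 4.5 A."""
        d = np.linalg.norm(np.diff(self.ca, axis=0), axis=1)
        return d > CHAIN_BREAK_CA_CA

    def window(self, start: int, length: int) -> "BackboneStructure":
        """Sub-structure of ``length`` residues starting at 1-based ``start``."""
        i = start - 1
        if i < 0 or i + length > len(self):
            raise IndexError(f"window [{start}, {start + length - 1}] out of range")
        sl = slice(i, i + length)
        return BackboneStructure(
            id=self.id, chain=self.chain, sequence=self.sequence[sl],
            n=self.n[sl], ca=self.ca[sl], c=self.c[sl],
            o=None if self.o is None else self.o[sl],
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneStructure":
        def tx(a):
            return None if a is None else a @ np.asarray(rotation).T + translation
        return replace(self, n=tx(self.n), ca=tx(self.ca), c=tx(self.c), o=tx(self.o))


# ---------------------------------------------------------------------------
# PDB I/O


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved first-seen for determinism
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ + 1e-9:
            best = a
    return best


def _model_to_backbone(model: gemmi.Model, chain_id: str | None,
                       struct_id: str) -> BackboneStructure:
    seq: list[str] = []
    coords: dict[str, list[np.ndarray]] = {"N": [], "CA": [], "C": [], "O": []}
    skipped = 0
    used_chain = ""
    for ch in model:
        if chain_id is not None and ch.name != chain_id:
            continue
        used_chain = used_chain or ch.name
        for res in ch:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.name in ("N", "CA", "C", "O"):
                    by_name.setdefault(atom.name, []).append(atom)
            if not all(k in by_name for k in ("N", "CA", "C")):
                if by_name:  # a residue with some backbone atoms but unusable
                    skipped += 1
                continue
            seq.append(AA3_TO_1.get(res.name, "X"))
            for name in ("N", "CA", "C", "O"):
                if name in by_name:
                    pos = _pick_altloc(by_name[name]).pos
                    coords[name].append(np.array([pos.x, pos.y, pos.z]))
                else:
                    coords[name].append(np.full(3, np.nan))
        if chain_id is None and seq:
            break  # first chain only unless a chain id was requested
    if not seq:
        raise ValueError(f"no usable backbone residues in {struct_id!r}")
    o = np.array(coords["O"])
    return BackboneStructure(
        id=struct_id, chain=used_chain, sequence="".join(seq),
        n=np.array(coords["N"]), ca=np.array(coords["CA"]), c=np.array(coords["C"]),
        o=o if np.any(np.isfinite(o)) else None,
        skipped_residues=skipped,
    )


def read_pdb_models(path: str | Path, chain: str | None = None) -> list[BackboneStructure]:
    """Read every MODEL of a PDB file as a separate :class:`BackboneStructure`.

    Altloc duplicates are resolved by highest occupancy, ties first-seen.
    Residues missing any of N/CA/C are skipped and counted in
    ``skipped_residues``.
    """
    st = gemmi.read_pdb(str(path))
    base = Path(path).stem
    out = []
    for i, model in enumerate(st):
        sid = base if len(st) == 1 else f"{base}_m{i + 1}"
        out.append(_model_to_backbone(model, chain, sid))
    if not out:
        raise ValueError(f"no models in {path}")
    return out


def read_pdb_backbone(path: str | Path, chain: str | None = None) -> BackboneStructure:
    """Read the first model of a PDB file (see :func:`read_pdb_models`)."""
    models = read_pdb_models(path, chain)
    if len(models) > 1:
        warnings.warn(f"{path}: {len(models)} models present, returning the first")
    return models[0]


def write_pdb(structures: BackboneStructure | Sequence[BackboneStructure],
              path: str | Path) -> None:
    """Write one or more backbone structures as PDB ATOM records.

    Multiple structures are emitted as consecutive MODEL blocks (a decoy set).
    """
    if isinstance(structures, BackboneStructure):
        structures = [structures]
    lines: list[str] = []
    multi = len(structures) > 1
    for m, s in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL {m:>8}")
        serial = 1
        for i in range(len(s)):
            res3 = AA1_TO_3.get(s.sequence[i], "UNK")
            atoms = [("N", s.n[i], "N"), ("CA", s.ca[i], "C"), ("C", s.c[i], "C")]
            if s.o is not None and np.all(np.isfinite(s.o[i])):
                atoms.append(("O", s.o[i], "O"))
            for name, xyz, elem in atoms:
                name_field = name if len(name) == 4 else f" {name:<3}"
                lines.append(
                    f"ATOM  {serial:>5} {name_field} {res3:>3} {s.chain or 'A':>1}"
                    f"{i + 1:>4}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {elem:>2}"
                )
                serial += 1
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (id, sequence) of the first record in a FASTA file."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Torsions


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention, (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def compute_torsions(s: BackboneStructure) -> list[TorsionTriple]:
    """Phi/psi/omega for every residue; ``None`` at termini and chain breaks."""
    L = len(s)
    if L < 3:
        raise ValueError("torsion computation requires at least 3 residues")
    breaks = s.chain_breaks()
    out = []
    for i in range(L):
        phi = psi = omega = None
        if i > 0 and not breaks[i - 1]:
            phi = dihedral(s.c[i - 1], s.n[i], s.ca[i], s.c[i])
        if i < L - 1 and not breaks[i]:
            psi = dihedral(s.n[i], s.ca[i], s.c[i], s.n[i + 1])
            omega = dihedral(s.ca[i], s.c[i], s.n[i + 1], s.ca[i + 1])
        out.append(TorsionTriple(position=i + 1, phi=phi, psi=psi, omega=omega))
    return out


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement of a new atom bonded to c, given chain a-b-c."""
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    d2 = np.array([
        bond * math.cos(math.pi - ang),
        bond * math.sin(math.pi - ang) * math.cos(tor),
        bond * math.sin(math.pi - ang) * math.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d2


def _check_angle(name: str, value: float) -> float:
    if not (-180.0 < value <= 180.0):
        raise ValueError(f"{name}={value} outside (-180, 180]")
    return value


def build_backbone_from_torsions(sequence: str,
                                 torsions: Sequence[TorsionTriple],
                                 structure_id: str = "built",
                                 chain: str = "A") -> BackboneStructure:
    """Grow a backbone from torsions with ideal bond lengths and angles (NeRF).

    ``phi`` of the first residue and ``psi``/``omega`` of the last are
    ignored (may be ``None``); a missing omega elsewhere defaults to 180
    (trans peptide). Carbonyl O atoms are placed anti to the next residue's N
    so the result is usable for hydrogen-bond based SS assignment.
    """
    L = len(sequence)
    if L == 0:
        raise ValueError("empty sequence")
    if len(torsions) != L:
        raise ValueError(f"{len(torsions)} torsion triples for {L} residues")
    g = IDEAL_GEOMETRY
    for t in torsions:
        for nm in ("phi", "psi", "omega"):
            v = getattr(t, nm)
            if v is not None:
                _check_angle(nm, v)

    n = np.zeros((L, 3))
    ca = np.zeros((L, 3))
    c = np.zeros((L, 3))
    o = np.zeros((L, 3))

    # first residue in a canonical frame
    n[0] = (0.0, 0.0, 0.0)
    ca[0] = (g["n_ca"], 0.0, 0.0)
    ang = math.radians(180.0 - g["n_ca_c"])
    c[0] = ca[0] + g["ca_c"] * np.array([math.cos(ang), math.sin(ang), 0.0])

    for i in range(L - 1):
        t = torsions[i]
        psi = 180.0 if t.psi is None else t.psi
        omega = 180.0 if t.omega is None else t.omega
        phi_next = torsions[i + 1].phi
        phi_next = -120.0 if phi_next is None else phi_next
        n[i + 1] = _place_atom(n[i], ca[i], c[i], g["c_n"], g["ca_c_n"], psi)
        ca[i + 1] = _place_atom(ca[i], c[i], n[i + 1], g["n_ca"], g["c_n_ca"], omega)
        c[i + 1] = _place_atom(c[i], n[i + 1], ca[i + 1], g["ca_c"], g["n_ca_c"], phi_next)
        o[i] = _place_atom(n[i], ca[i], c[i], g["c_o"], g["ca_c_o"], psi - 180.0)
    # terminal carbonyl: trans-like placement (psi is undefined there)
    o[L - 1] = _place_atom(n[L - 1], ca[L - 1], c[L - 1], g["c_o"], g["ca_c_o"], 0.0)

    return BackboneStructure(id=structure_id, chain=chain, sequence=sequence,
                             n=n, ca=ca, c=c, o=o)


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(A: np.ndarray, B: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of point set A onto B (Kabsch, SVD).

    Reflections are excluded: the returned rotation is proper. Degenerate
    (e.g. collinear) point sets are handled by the SVD without special cases.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"point sets differ in shape: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 3:
        raise ValueError("need two (n>=3, 3) coordinate arrays")
    ca_ = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca_).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca_
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)
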