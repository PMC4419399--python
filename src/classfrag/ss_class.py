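"""Secondary-structure assignment and structural-class annotation.

Secondary structure is assigned from backbone coordinates with the
Kabsch-Sander hydrogen-bond scheme (the algorithm DSSP implements), collapsed
to three states H/E/C. Helix and strand content then map a chain to the top
CATH level (mainly alpha / mainly beta / alpha-beta / few secondary
structures) using the 15% helix and 10% strand content thresholds, or to the
classic SCOP classes (all-alpha / all-beta / alpha+beta / alpha/beta / small
proteins), where the alpha/beta-vs-alpha+beta split is decided from the
parallel-vs-antiparallel character of the bridges and the alternation of
helix and strand segments along the chain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import BackboneStructure

__all__ = [
    "SSString",
    "ClassAnnotation",
    "CATH_LABELS",
    "SCOP_LABELS",
    "HELIX_THRESHOLD",
    "STRAND_THRESHOLD",
    "assign_secondary_structure",
    "find_bridges",
    "ss_content",
    "annotate_cath_class",
    "annotate_scop_class",
    "class_agreement",
    "read_dssp_ss",
    "read_ss_string",
    "write_class_table",
]

#: Content thresholds separating the structural classes (fractions).
HELIX_THRESHOLD = 0.15
STRAND_THRESHOLD = 0.10

CATH_LABELS = ("mainly_alpha", "alpha_beta", "mainly_beta", "few_secondary_structures")
SCOP_LABELS = ("all_alpha", "all_beta", "alpha_plus_beta", "alpha_slash_beta",
               "small_protein")

#: Hydrogen-bond electrostatic model: E = Q * (1/rON + 1/rCH - 1/rOH - 1/rCN)
#: in kcal/mol, with a bond called below -0.5 kcal/mol.
_HB_Q = 0.084 * 332.0
_HB_CUTOFF = -0.5


@dataclass
class SSString:
    """Three-state secondary structure, one of H/E/C per residue."""

    letters: str
    source: str = "computed"  # "computed" | "provided"

    def __post_init__(self) -> None:
        bad = set(self.letters) - set("HEC")
        if bad:
            raise ValueError(f"invalid SS letters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters


@dataclass
class ClassAnnotation:
    """Structural class label with the SS-content evidence that produced it."""

    scheme: str                 # "CATH" | "SCOP"
    label: str
    helix_frac: float
    strand_frac: float

    def __post_init__(self) -> None:
        allowed = CATH_LABELS if self.scheme == "CATH" else SCOP_LABELS
        if self.scheme not in ("CATH", "SCOP"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.label not in allowed:
            raise ValueError(f"label {self.label!r} not valid for {self.scheme}")


# ---------------------------------------------------------------------------
# Hydrogen bonds and SS assignment


def _amide_hydrogens(s: BackboneStructure) -> np.ndarray:
    """Amide H positions: 1 A from N along the previous residue's O->C axis.

    NaN rows where no H exists (first residue, after a chain break, proline).
    """
    L = len(s)
    h = np.full((L, 3), np.nan)
    breaks = s.chain_breaks()
    for i in range(1, L):
        if breaks[i - 1] or s.sequence[i] == "P":
            continue
        d = s.c[i - 1] - s.o[i - 1]
        nrm = np.linalg.norm(d)
        if nrm > 0:
            h[i] = s.n[i] + d / nrm
    return h


def _hbond_matrix(s: BackboneStructure) -> np.ndarray:
    """Boolean matrix hb[i, j]: C=O of residue i accepts from N-H of residue j."""
    if not s.has_o:
        raise ValueError(
            "carbonyl O atoms are required for hydrogen-bond SS assignment; "
            "supply a precomputed SSString instead"
        )
    L = len(s)
    h = _amide_hydrogens(s)
    hb = np.zeros((L, L), dtype=bool)
    for j in range(L):            # donor NH(j)
        if not np.all(np.isfinite(h[j])):
            continue
        for i in range(L):        # acceptor CO(i)
            if abs(i - j) < 2:
                continue
            r_on = np.linalg.norm(s.o[i] - s.n[j])
            r_ch = np.linalg.norm(s.c[i] - h[j])
            r_oh = np.linalg.norm(s.o[i] - h[j])
            r_cn = np.linalg.norm(s.c[i] - s.n[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, not a physical bond
            e = _HB_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _HB_CUTOFF:
                hb[i, j] = True
    return hb


def find_bridges(s: BackboneStructure) -> list[tuple[int, int, str]]:
    """Beta-bridge pairs (i, j, kind) with 1-based i < j, kind parallel/antiparallel.

    Kabsch-Sander bridge patterns on the backbone hydrogen-bond matrix;
    partners must be at least 3 residues apart in sequence.
    """
    hb = _hbond_matrix(s)
    L = len(s)

    def bond(i: int, j: int) -> bool:
        return 0 <= i < L and 0 <= j < L and hb[i, j]

    out = []
    for i in range(L):
        for j in range(i + 3, L):
            para = (bond(i - 1, j) and bond(j, i + 1)) or \
                   (bond(j - 1, i) and bond(i, j + 1))
            anti = (bond(i, j) and bond(j, i)) or \
                   (bond(i - 1, j + 1) and bond(j - 1, i + 1))
            if para:
                out.append((i + 1, j + 1, "parallel"))
            elif anti:
                out.append((i + 1, j + 1, "antiparallel"))
    return out


def assign_secondary_structure(s: BackboneStructure) -> SSString:
    """Three-state SS from coordinates (hydrogen-bond based).

    H: residue inside a run of two consecutive i -> i+4 turns (minimal
    alpha-helix). E: residue in a parallel or antiparallel bridge. C
    otherwise. An isolated extended strand with no partner is coil, since a
    bridge needs a partner.
    """
    hb = _hbond_matrix(s)
    L = len(s)
    letters = ["C"] * L

    four_turn = [i + 4 < L and hb[i, i + 4] for i in range(L)]
    for i in range(L - 1):
        if four_turn[i] and four_turn[i + 1]:
            for k in range(i + 1, min(i + 5, L)):
                letters[k] = "H"

    for i, j, _kind in find_bridges(s):
        for k in (i - 1, j - 1):
            if letters[k] != "H":
                letters[k] = "E"
    return SSString("".join(letters), source="computed")


# ---------------------------------------------------------------------------
# Content and class rules


def ss_content(ss: SSString | str) -> tuple[float, float]:
    """(helix_frac, strand_frac) of a 3-state SS string."""
    letters = ss.letters if isinstance(ss, SSString) else ss
    if not letters:
        raise ValueError("empty SS string")
    L = len(letters)
    return letters.count("H") / L, letters.count("E") / L


def _check_fracs(helix_frac: float, strand_frac: float) -> None:
    for name, v in (("helix_frac", helix_frac), ("strand_frac", strand_frac)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")


def annotate_cath_class(helix_frac: float, strand_frac: float,
                        helix_threshold: float = HELIX_THRESHOLD,
                        strand_threshold: float = STRAND_THRESHOLD) -> ClassAnnotation:
    """CATH top-level class from SS content.

    helix >= 15% and strand < 10% -> mainly_alpha; the reverse ->
    mainly_beta; both at or above threshold -> alpha_beta; both below ->
    few_secondary_structures. Values exactly at a threshold count as above.
    """
    _check_fracs(helix_frac, strand_frac)
    a = helix_frac >= helix_threshold
    b = strand_frac >= strand_threshold
    if a and not b:
        label = "mainly_alpha"
    elif b and not a:
        label = "mainly_beta"
    elif a and b:
        label = "alpha_beta"
    else:
        label = "few_secondary_structures"
    return ClassAnnotation("CATH", label, helix_frac, strand_frac)


def annotate_scop_class(s: BackboneStructure, ss: SSString | None = None,
                        parallel_fraction_cut: float = 0.5,
                        small_protein_max: int = 100) -> ClassAnnotation:
    """Classic SCOP class from SS content plus sheet topology.

    Content rules mirror the CATH thresholds. When both helix and strand
    content pass their thresholds, the chain is alpha/beta when the majority
    of its bridges are parallel AND helix/strand segments alternate along the
    sequence (at least two H<->E transitions ignoring coil); otherwise
    alpha+beta — segregated strands forming antiparallel sheets. Chains with
    few secondary structures map to small_protein up to ``small_protein_max``
    residues; longer low-content chains fall back to the dominant pure class.
    """
    if ss is None:
        ss = assign_secondary_structure(s)
    if len(ss) != len(s):
        raise ValueError("SS length does not match structure length")
    helix_frac, strand_frac = ss_content(ss)
    a = helix_frac >= HELIX_THRESHOLD
    b = strand_frac >= STRAND_THRESHOLD
    if a and not b:
        label = "all_alpha"
    elif b and not a:
        label = "all_beta"
    elif a and b:
        bridges = find_bridges(s)
        n_par = sum(1 for *_ij, kind in bridges if kind == "parallel")
        frac_par = n_par / len(bridges) if bridges else 0.0
        segments = [k for k, _g in itertools.groupby(ss.letters) if k != "C"]
        transitions = sum(1 for x, y in zip(segments, segments[1:]) if x != y)
        if frac_par > parallel_fraction_cut and transitions >= 2:
            label = "alpha_slash_beta"
        else:
            label = "alpha_plus_beta"
    else:
        if len(s) <= small_protein_max:
            label = "small_protein"
        else:
            label = "all_alpha" if helix_frac >= strand_frac else "all_beta"
    return ClassAnnotation("SCOP", label, helix_frac, strand_frac)


# ---------------------------------------------------------------------------
# Agreement


def class_agreement(reference: Sequence[ClassAnnotation | str],
                    predicted: Sequence[ClassAnnotation | str],
                    scheme: str | None = None) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (rows: reference, columns: predicted) and accuracy %.

    Accuracy is 100 * trace / total, rounded to one decimal.
    """
    if len(reference) != len(predicted):
        raise ValueError("reference and predicted lists differ in length")
    if not reference:
        raise ValueError("empty annotation lists")

    def norm(x):
        if isinstance(x, ClassAnnotation):
            return x.scheme, x.label
        return None, x

    schemes = {norm(x)[0] for x in list(reference) + list(predicted)} - {None}
    if len(schemes) > 1:
        raise ValueError(f"mixed annotation schemes: {sorted(schemes)}")
    if scheme is None:
        scheme = schemes.pop() if schemes else "CATH"
    elif schemes and scheme not in schemes:
        raise ValueError(f"scheme {scheme!r} does not match annotations")
    labels = CATH_LABELS if scheme == "CATH" else SCOP_LABELS
    mat = pd.DataFrame(0, index=list(labels), columns=list(labels), dtype=int)
    for r, p in zip(reference, predicted):
        mat.loc[norm(r)[1], norm(p)[1]] += 1
    total = int(mat.values.sum())
    accuracy = round(100.0 * np.trace(mat.values) / total, 1)
    return mat, accuracy


# ---------------------------------------------------------------------------
# I/O


_DSSP_COLLAPSE = str.maketrans({"G": "H", "I": "H", "H": "H", "B": "E", "E": "E"})


def collapse_to_3state(letters: str) -> str:
    """Collapse an 8-state DSSP string to H/E/C (G,I -> H; B -> E; rest C)."""
    return "".join(
        c.translate(_DSSP_COLLAPSE) if c in "GIHBE" else "C" for c in letters
    )


def read_dssp_ss(path: str | Path) -> SSString:
    """Read the per-residue SS column of a classic DSSP output file."""
    lines = Path(path).read_text().splitlines()
    started = False
    letters = []
    for line in lines:
        if line.startswith("  #  RESIDUE"):
            started = True
            continue
        if not started or len(line) < 17:
            continue
        if line[13] == "!":  # chain break record
            continue
        letters.append(line[16] if line[16] != " " else "C")
    if not letters:
        raise ValueError(f"no residue records found in DSSP file {path}")
    return SSString(collapse_to_3state("".join(letters)), source="provided")


def read_ss_string(path: str | Path) -> SSString:
    """Read a plain 3-state SS string file (whitespace/newlines ignored)."""
    txt = "".join(Path(path).read_text().split())
    return SSString(txt.upper(), source="provided")


def write_class_table(annotations: dict[str, ClassAnnotation], path: str | Path) -> None:
    """Write id/scheme/label/helix_frac/strand_frac as TSV."""
    rows = [
        {"id": k, "scheme": a.scheme, "label": a.label,
         "helix_frac": round(a.helix_frac, 4), "strand_frac": round(a.strand_frac, 4)}
        for k, a in annotations.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_class_table(path: str | Path) -> dict[str, ClassAnnotation]:
    """Read a class table written by :func:`write_class_table`."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r["id"]): ClassAnnotation(r["scheme"], r["label"],
                                      float(r["helix_frac"]), float(r["strand_frac"]))
        for _, r in df.iterrows()
    }
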