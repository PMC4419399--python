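"""Fragment library construction: scoring, top-N picking, quota, fit analysis.

For every target position and fragment length (3- and 9-mers by default),
every break-free window of every template is scored against the target's
sequence profile and predicted secondary structure; the lowest-scoring
``n_frags`` windows (200 by default) form the library at that position. With
several SS-prediction sources, the per-position budget is split across
sources ("quota" selection for ab initio runs). Fragments are represented by
their torsion angles, so a library can be rebuilt into Cartesian windows and
compared against a native structure (:func:`library_fit`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import geometry
from .geometry import BackboneStructure, TorsionTriple
from .template_select import TemplateDB, TemplateRecord

__all__ = [
    "AA_ORDER",
    "SS_ORDER",
    "SequenceProfile",
    "SSPrediction",
    "FragmentCandidate",
    "FragmentLibrary",
    "profile_score",
    "ss_match_score",
    "pick_fragments",
    "build_fragment_library",
    "library_fit",
    "fragment_to_structure",
    "write_fragment_file",
    "read_fragment_file",
    "read_pssm",
    "write_pssm",
    "read_ss2",
    "write_ss2",
    "DEFAULT_N_FRAGS",
    "DEFAULT_LENGTHS",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"          # fixed alphabetical 1-letter order
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
SS_ORDER = "HEC"
_SS_INDEX = {s: i for i, s in enumerate(SS_ORDER)}

DEFAULT_N_FRAGS = 200
DEFAULT_LENGTHS = (3, 9)

# PSI-BLAST ASCII PSSM column order
_PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class SequenceProfile:
    """Position-specific scores, one row per target residue, columns AA_ORDER."""

    scores: np.ndarray  # (L, 20) log-odds (half-bit convention) or similar

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"profile must be (L, 20), got {self.scores.shape}")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite profile entries")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_sequence(cls, sequence: str) -> "SequenceProfile":
        """Substitution-matrix fallback profile when no real profile exists.

        Each row is the BLOSUM62 row of the target residue. This is a
        documented stand-in for a proper profile from an iterative sequence
        search, not equivalent to one.
        """
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        rows = np.zeros((len(sequence), 20))
        for i, a in enumerate(sequence):
            src = a if a in blosum.alphabet else "X"
            for j, b in enumerate(AA_ORDER):
                rows[i, j] = blosum[src][b]
        return cls(rows)


@dataclass
class SSPrediction:
    """Per-residue 3-state probabilities (columns H, E, C) from one predictor."""

    probs: np.ndarray
    name: str = "pred"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError(f"SS prediction must be (L, 3), got {self.probs.shape}")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("SS probability rows must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)


@dataclass
class FragmentCandidate:
    """One template window proposed for one target position."""

    position: int            # 1-based target position
    length: int
    template_id: str
    chain: str
    template_start: int      # 1-based position within the template
    aa: str
    ss: str
    torsions: list[TorsionTriple]
    score: float             # lower = better
    score_profile: float = math.nan
    score_ss: float = math.nan
    source: str = ""


@dataclass
class FragmentLibrary:
    """Ranked fragment candidates per (target position, fragment length)."""

    target_length: int
    n_frags: int
    entries: dict[tuple[int, int], list[FragmentCandidate]] = field(default_factory=dict)

    @property
    def lengths(self) -> list[int]:
        return sorted({ln for _, ln in self.entries})

    def positions(self, length: int) -> list[int]:
        return sorted(p for p, ln in self.entries if ln == length)

    def get(self, position: int, length: int) -> list[FragmentCandidate]:
        return self.entries.get((position, length), [])


# ---------------------------------------------------------------------------
# Scores


def profile_score(target_window: np.ndarray, template_window: str) -> float:
    """City-block regret of the template residues against the profile.

    For each column, the best attainable profile score minus the score of the
    template's residue, summed over the window. Non-negative; zero iff the
    template residue maximises every column.
    """
    rows = np.asarray(target_window, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != 20 or rows.shape[0] != len(template_window):
        raise ValueError("window shapes disagree")
    total = 0.0
    for row, letter in zip(rows, template_window):
        if letter not in _AA_INDEX:
            raise ValueError(f"unknown residue letter {letter!r}")
        total += float(row.max() - row[_AA_INDEX[letter]])
    return total


def ss_match_score(pred_window: np.ndarray, template_ss: str) -> float:
    """Sum over the window of (1 - P(template SS letter)); in [0, window length]."""
    rows = np.asarray(pred_window, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != 3 or rows.shape[0] != len(template_ss):
        raise ValueError("window shapes disagree")
    total = 0.0
    for row, letter in zip(rows, template_ss):
        if letter not in _SS_INDEX:
            raise ValueError(f"SS letter {letter!r} outside H/E/C")
        total += float(1.0 - row[_SS_INDEX[letter]])
    return total


# ---------------------------------------------------------------------------
# Picking


def _template_arrays(rec: TemplateRecord):
    aa = rec.sequence
    ss = rec.ss
    phi = rec.residues["phi"].to_numpy(dtype=float)
    psi = rec.residues["psi"].to_numpy(dtype=float)
    omg = rec.residues["omega"].to_numpy(dtype=float)
    return aa, ss, phi, psi, omg


def _valid_starts(phi: np.ndarray, psi: np.ndarray, omg: np.ndarray,
                  length: int) -> np.ndarray:
    """0-based starts of windows free of load-bearing torsion sentinels.

    Chain rebuilding never consumes the first residue's phi or the last
    residue's psi/omega, so sentinels there (chain termini) are harmless;
    a sentinel anywhere else marks a chain break and invalidates the window.
    """
    n = len(phi)
    if n < length:
        return np.zeros(0, dtype=int)
    ok_phi = np.isfinite(phi).astype(int)
    ok_po = (np.isfinite(psi) & np.isfinite(omg)).astype(int)
    if length == 1:
        return np.arange(n)
    w = np.ones(length - 1, dtype=int)
    phi_good = np.convolve(ok_phi[1:], w, mode="valid") == length - 1
    po_good = np.convolve(ok_po[:-1], w, mode="valid") == length - 1
    m = min(len(phi_good), len(po_good), n - length + 1)
    return np.nonzero(phi_good[:m] & po_good[:m])[0]


def _quota_split(n_frags: int, k: int) -> list[int]:
    base = n_frags // k
    quotas = [base + (1 if i < n_frags % k else 0) for i in range(k)]
    return quotas


def pick_fragments(sequence: str,
                   profile: SequenceProfile | None,
                   ss_predictions: SSPrediction | Sequence[SSPrediction],
                   templates: TemplateDB,
                   length: int = 9,
                   n_frags: int = DEFAULT_N_FRAGS,
                   w_prof: float = 1.0,
                   w_ss: float = 1.0) -> FragmentLibrary:
    """Top-``n_frags`` template windows per target position for one length.

    With a single SS-prediction source this is a plain top-N by total score
    ``w_prof * profile_score + w_ss * ss_match_score``; with several sources
    the per-position budget is split into per-source quotas (equal shares,
    earlier sources take the remainder) and duplicates are kept by the
    earlier pool. Ties break on (score, template id, template start) so the
    output is deterministic.
    """
    if len(templates) == 0:
        raise ValueError("empty template database")
    if length < 1 or n_frags < 1:
        raise ValueError("length and n_frags must be >= 1")
    if isinstance(ss_predictions, SSPrediction):
        ss_predictions = [ss_predictions]
    if profile is None:
        profile = SequenceProfile.from_sequence(sequence)
    L = len(sequence)
    if len(profile) != L or any(len(p) != L for p in ss_predictions):
        raise ValueError("profile / SS prediction length must match the sequence")

    reg = profile.scores.max(axis=1, keepdims=True) - profile.scores  # (L, 20)

    # per-template cached arrays
    cache = []
    for rec in templates:
        aa, ss, phi, psi, omg = _template_arrays(rec)
        starts = _valid_starts(phi, psi, omg, length)
        if len(starts) == 0:
            continue
        aa_idx = np.array([_AA_INDEX.get(a, -1) for a in aa])
        if np.any(aa_idx[np.concatenate([starts + k for k in range(length)])] < 0):
            bad = sorted({a for a in aa if a not in _AA_INDEX})
            raise ValueError(f"template {rec.id}: unknown residue letters {bad}")
        ss_idx = np.array([_SS_INDEX[c] for c in ss])
        cache.append((rec, aa_idx, ss_idx, starts, phi, psi, omg))
    lib = FragmentLibrary(target_length=L, n_frags=n_frags)

    for p in range(L - length + 1):          # 0-based target start
        pools: list[list[tuple]] = []
        for src_i, pred in enumerate(ss_predictions):
            cands = []
            for rec, aa_idx, ss_idx, starts, phi, psi, omg in cache:
                nwin = len(starts)
                prof = np.zeros(nwin)
                ssc = np.zeros(nwin)
                for k in range(length):
                    cols = aa_idx[starts + k]
                    prof += reg[p + k, cols]
                    ssc += 1.0 - pred.probs[p + k, ss_idx[starts + k]]
                total = w_prof * prof + w_ss * ssc
                for s_i, s in enumerate(starts):
                    cands.append((float(total[s_i]), rec.id, int(s), rec,
                                  float(prof[s_i]), float(ssc[s_i]), pred.name))
            cands.sort(key=lambda c: (c[0], c[1], c[2]))
            pools.append(cands)

        quotas = _quota_split(n_frags, len(pools))
        chosen: list[tuple] = []
        seen: set[tuple[str, int]] = set()
        for pool, quota in zip(pools, quotas):
            taken = 0
            for c in pool:
                if taken >= quota:
                    break
                key = (c[1], c[2])
                if key in seen:
                    continue
                seen.add(key)
                chosen.append(c)
                taken += 1
        chosen.sort(key=lambda c: (c[0], c[1], c[2]))

        frags = []

        def _opt(v: float) -> float | None:
            return float(v) if np.isfinite(v) else None

        for total, tid, s, rec, prof_s, ss_s, src in chosen:
            tt = [TorsionTriple(position=s + k + 1,
                                phi=_opt(rec.residues["phi"].iloc[s + k]),
                                psi=_opt(rec.residues["psi"].iloc[s + k]),
                                omega=_opt(rec.residues["omega"].iloc[s + k]))
                  for k in range(length)]
            frags.append(FragmentCandidate(
                position=p + 1, length=length, template_id=tid, chain=rec.chain,
                template_start=s + 1,
                aa=rec.sequence[s:s + length], ss=rec.ss[s:s + length],
                torsions=tt, score=total, score_profile=prof_s, score_ss=ss_s,
                source=src))
        if not frags:
            warnings.warn(f"no valid fragment window for position {p + 1}")
        lib.entries[(p + 1, length)] = frags
    return lib


def build_fragment_library(sequence: str,
                           profile: SequenceProfile | None,
                           ss_predictions: SSPrediction | Sequence[SSPrediction],
                           templates: TemplateDB,
                           lengths: Sequence[int] = DEFAULT_LENGTHS,
                           n_frags: int = DEFAULT_N_FRAGS,
                           w_prof: float = 1.0,
                           w_ss: float = 1.0) -> FragmentLibrary:
    """Pick fragments for several lengths into one library (3- and 9-mers by default)."""
    lib = FragmentLibrary(target_length=len(sequence), n_frags=n_frags)
    for ln in lengths:
        part = pick_fragments(sequence, profile, ss_predictions, templates,
                              length=ln, n_frags=n_frags, w_prof=w_prof, w_ss=w_ss)
        lib.entries.update(part.entries)
    return lib


# ---------------------------------------------------------------------------
# Fit against a native structure


def fragment_to_structure(frag: FragmentCandidate) -> BackboneStructure:
    """Rebuild the fragment's Cartesian backbone from its torsions."""
    return geometry.build_backbone_from_torsions(
        frag.aa, frag.torsions,
        structure_id=f"{frag.template_id}_{frag.template_start}")


def library_fit(library: FragmentLibrary, native: BackboneStructure) -> pd.DataFrame:
    """Per-position best CA-RMSD of any candidate against the native window.

    Each candidate is rebuilt from torsions and superposed onto the native
    window; the table reports the minimum RMSD, the fraction of candidates
    under 1 A, and the candidate count. Positions with no candidates get NaN.
    """
    rows = []
    for (pos, ln), frags in sorted(library.entries.items()):
        if pos + ln - 1 > len(native):
            raise ValueError("library span exceeds native length")
        native_ca = native.ca[pos - 1: pos - 1 + ln]
        if not frags:
            rows.append({"position": pos, "length": ln, "best_rmsd": np.nan,
                         "frac_under_1A": np.nan, "n_candidates": 0})
            continue
        rmsds = []
        for f in frags:
            frag_ca = fragment_to_structure(f).ca
            rmsds.append(geometry.kabsch_superpose(frag_ca, native_ca).rmsd)
        rmsds = np.array(rmsds)
        rows.append({"position": pos, "length": ln,
                     "best_rmsd": float(rmsds.min()),
                     "frac_under_1A": float(np.mean(rmsds < 1.0)),
                     "n_candidates": len(frags)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fragment file I/O (Rosetta3-style text blocks)


def write_fragment_file(library: FragmentLibrary, path: str | Path) -> None:
    """Write per-position fragment blocks in the classic picker text layout.

    Stable, bit-exact ordering: positions ascending, candidates in rank
    order, one line per fragment residue
    (template id, chain, template position, aa, ss, phi, psi, omega).
    """
    lines: list[str] = []
    for (pos, ln) in sorted(library.entries):
        frags = library.entries[(pos, ln)]
        lines.append(f" position: {pos:12d} neighbors: {len(frags):12d}")
        lines.append("")
        for f in frags:
            for k, t in enumerate(f.torsions):
                phi = math.nan if t.phi is None else t.phi
                psi = math.nan if t.psi is None else t.psi
                omg = math.nan if t.omega is None else t.omega
                lines.append(
                    f" {f.template_id:>5s} {f.chain:1s} {f.template_start + k:5d} "
                    f"{f.aa[k]} {f.ss[k]} "
                    f"{phi:9.3f} {psi:9.3f} {omg:9.3f}"
                )
            lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fragment_file(path: str | Path) -> FragmentLibrary:
    """Parse a fragment file written by :func:`write_fragment_file`.

    Scores are not stored in the text format and come back as NaN.
    """
    lib = FragmentLibrary(target_length=0, n_frags=0)
    pos = None
    block: list[str] = []

    def flush(block_lines: list[str]) -> None:
        if pos is None or not block_lines:
            return
        tid = block_lines[0].split()[0]
        parts = [ln.split() for ln in block_lines]
        length = len(parts)
        tstart = int(parts[0][2])
        frag = FragmentCandidate(
            position=pos, length=length, template_id=tid, chain=parts[0][1],
            template_start=tstart,
            aa="".join(p[3] for p in parts), ss="".join(p[4] for p in parts),
            torsions=[TorsionTriple(
                position=tstart + k,
                phi=None if math.isnan(float(p[5])) else float(p[5]),
                psi=None if math.isnan(float(p[6])) else float(p[6]),
                omega=None if math.isnan(float(p[7])) else float(p[7]))
                for k, p in enumerate(parts)],
            score=math.nan)
        lib.entries.setdefault((pos, length), []).append(frag)

    for line in Path(path).read_text().splitlines():
        if line.strip().startswith("position:"):
            flush(block)
            block = []
            pos = int(line.split()[1])
        elif line.strip():
            block.append(line)
        else:
            flush(block)
            block = []
    flush(block)
    if lib.entries:
        lib.target_length = max(p + ln - 1 for p, ln in lib.entries)
        lib.n_frags = max(len(v) for v in lib.entries.values())
    return lib


# ---------------------------------------------------------------------------
# Profile / SS-prediction file readers and writers


def read_pssm(path: str | Path) -> SequenceProfile:
    """Read the log-odds block of a PSI-BLAST ASCII PSSM.

    Only the first 20 numeric columns (half-bit log-odds) are used; the
    column order is taken from the header line and remapped to AA_ORDER.
    """
    lines = Path(path).read_text().splitlines()
    order = None
    rows = []
    for line in lines:
        parts = line.split()
        if order is None:
            if len(parts) >= 20 and all(p in _PSSM_ORDER for p in parts[:20]):
                order = parts[:20]
            continue
        if len(parts) >= 22 and parts[0].isdigit():
            vals = [float(x) for x in parts[2:22]]
            rows.append(vals)
    if order is None or not rows:
        raise ValueError(f"not a PSI-BLAST ASCII PSSM: {path}")
    mat = np.array(rows)
    remap = [order.index(a) for a in AA_ORDER]
    return SequenceProfile(mat[:, remap])


def write_pssm(sequence: str, profile: SequenceProfile, path: str | Path) -> None:
    """Write a minimal PSI-BLAST-ASCII-dialect PSSM (log-odds block only)."""
    remap = [AA_ORDER.index(a) for a in _PSSM_ORDER]
    lines = ["", "Last position-specific scoring matrix computed",
             "            " + "   ".join(_PSSM_ORDER)]
    for i, a in enumerate(sequence):
        vals = profile.scores[i][remap]
        lines.append(f"{i + 1:5d} {a} " + " ".join(f"{v:5.1f}" for v in vals)
                     + "  " + " ".join("0.00" for _ in range(20)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ss2(path: str | Path, name: str = "ss2") -> SSPrediction:
    """Read a PSIPRED-ss2-like file: index, aa, letter, P(C), P(H), P(E)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) == 6 and parts[0].isdigit():
            p_c, p_h, p_e = (float(x) for x in parts[3:6])
            tot = p_c + p_h + p_e
            rows.append([p_h / tot, p_e / tot, p_c / tot])
    if not rows:
        raise ValueError(f"no prediction rows in {path}")
    return SSPrediction(np.array(rows), name=name)


def write_ss2(sequence: str, pred: SSPrediction, path: str | Path) -> None:
    """Write an ss2-like prediction file (columns: idx, aa, letter, pC, pH, pE)."""
    lines = ["# PSIPRED-like 3-state prediction (synthetic)", ""]
    for i, a in enumerate(sequence):
        ph, pe, pc = pred.probs[i]
        letter = SS_ORDER[int(np.argmax(pred.probs[i]))]
        lines.append(f"{i + 1:4d} {a} {letter}  {pc:6.3f} {ph:6.3f} {pe:6.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
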