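"""Decoy evaluation: GDT_TS / GDT-HA / RMSD, aggregation, bins, convergence.

GDT_TS is the mean over distance cut-offs 1/2/4/8 A of the maximal fraction
of CA atoms that can be superposed within the cut-off; GDT-HA uses
0.5/1/2/4 A. The exact maximisation is combinatorial, so the score is
computed with the usual iterative-superposition heuristic: seed on every
contiguous window of a few lengths, superpose, include CA pairs within the
cut-off, re-superpose on the included set to a fixed point, and keep the
best fraction over seeds. Aggregates follow the common benchmark protocol:
a run's GDT (RMSD) is the mean of its 10 highest GDT_TS (10 lowest RMSD)
decoys, model quality is binned at GDT 40/60/85, and convergence is the
generation index of the first decoy attaining the run's best score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import BackboneStructure, kabsch_superpose

__all__ = [
    "GDT_TS_THRESHOLDS",
    "GDT_HA_THRESHOLDS",
    "DecoySeries",
    "EvalSummary",
    "ConvergenceIndex",
    "gdt_fractions",
    "gdt_score",
    "score_series",
    "top_k_summary",
    "quality_bin",
    "is_informative",
    "convergence_index",
    "compare_runs",
    "convergence_report",
]

GDT_TS_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)
GDT_HA_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)

#: GDT bin edges: Poor < 40 <= Moderate < 60 <= Good < 85 <= HighQuality.
QUALITY_BINS = ((40.0, "Poor"), (60.0, "Moderate"), (85.0, "Good"), (None, "HighQuality"))


@dataclass
class DecoySeries:
    """Per-decoy scores in generation order (1-based contiguous indices)."""

    gdt_ts: np.ndarray
    gdt_ha: np.ndarray
    rmsd: np.ndarray

    def __post_init__(self) -> None:
        self.gdt_ts = np.asarray(self.gdt_ts, dtype=float)
        self.gdt_ha = np.asarray(self.gdt_ha, dtype=float)
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        n = len(self.gdt_ts)
        if len(self.gdt_ha) != n or len(self.rmsd) != n:
            raise ValueError("score arrays differ in length")
        if n == 0:
            raise ValueError("empty decoy series")

    def __len__(self) -> int:
        return len(self.gdt_ts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"index": np.arange(1, len(self) + 1),
                             "gdt_ts": self.gdt_ts, "gdt_ha": self.gdt_ha,
                             "rmsd": self.rmsd})


@dataclass
class EvalSummary:
    """A run's aggregate quality: top-10 means, single best values, bin."""

    target_id: str
    gdt: float          # mean of the 10 highest GDT_TS
    rmsd: float         # mean of the 10 lowest RMSD
    best_gdt: float
    best_rmsd: float
    quality: str = ""
    convergence: "ConvergenceIndex | None" = None


@dataclass
class ConvergenceIndex:
    """1-based generation indices of the run's best decoys (ties -> earliest).

    ``both`` is set when a single decoy attains both the highest GDT and the
    lowest RMSD, else None.
    """

    first_best_gdt: int
    first_best_rmsd: int
    both: int | None


# ---------------------------------------------------------------------------
# GDT


def gdt_fractions(distances: Sequence[float],
                  thresholds: Sequence[float] = GDT_TS_THRESHOLDS
                  ) -> tuple[list[float], float]:
    """Per-threshold included fractions (strict <) and their mean x 100."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if np.any(d < 0):
        raise ValueError("negative distances")
    th = list(thresholds)
    if any(b <= a for a, b in zip(th, th[1:])) or any(t <= 0 for t in th):
        raise ValueError("thresholds must be positive ascending")
    fr = [float(np.mean(d < t)) for t in th]
    return fr, float(100.0 * np.mean(fr))


def _best_fraction(model_ca: np.ndarray, native_ca: np.ndarray,
                   threshold: float, seed_lengths: Sequence[int],
                   max_iter: int = 20) -> float:
    n = len(model_ca)
    best = 0.0
    for L in seed_lengths:
        if L > n:
            continue
        for s in range(n - L + 1):
            include = np.zeros(n, dtype=bool)
            include[s:s + L] = True
            for _ in range(max_iter):
                sup = kabsch_superpose(model_ca[include], native_ca[include])
                dist = np.linalg.norm(sup.apply(model_ca) - native_ca, axis=1)
                new = dist < threshold
                best = max(best, float(np.mean(new)))
                if new.sum() < 3 or np.array_equal(new, include):
                    break
                include = new
            if best >= 1.0:
                return 1.0
    return best


def gdt_score(model: BackboneStructure | np.ndarray,
              native: BackboneStructure | np.ndarray,
              thresholds: Sequence[float] = GDT_TS_THRESHOLDS,
              seed_lengths: Sequence[int] | None = None,
              max_iter: int = 20) -> float:
    """GDT score of a model against a native, in [0, 100], 2 decimals.

    For each cut-off, the included-residue fraction is maximised by iterative
    superposition seeded on contiguous windows; the score is 100 x the mean
    best fraction over cut-offs. Chains of up to 20 residues are seeded on
    every window length (effectively the exhaustive search); longer chains
    use the LGA-style window lengths {3, 5, 7, n}, a heuristic that may
    slightly underestimate the combinatorial optimum.
    """
    mc = model.ca if isinstance(model, BackboneStructure) else np.asarray(model, float)
    nc = native.ca if isinstance(native, BackboneStructure) else np.asarray(native, float)
    if mc.shape != nc.shape:
        raise ValueError(f"CA count mismatch: {mc.shape[0]} vs {nc.shape[0]}")
    n = len(mc)
    if seed_lengths is None:
        if n <= 20:
            seed_lengths = list(range(3, n + 1))
        else:
            seed_lengths = sorted({L for L in (3, 5, 7, n) if L <= n})
    fracs = [_best_fraction(mc, nc, t, seed_lengths, max_iter) for t in thresholds]
    return round(float(100.0 * np.mean(fracs)), 2)


def score_series(decoys: Sequence[BackboneStructure],
                 native: BackboneStructure) -> DecoySeries:
    """GDT_TS, GDT-HA and CA RMSD for every decoy, in generation order."""
    if len(decoys) == 0:
        raise ValueError("no decoys to score")
    ts, ha, rms = [], [], []
    for d in decoys:
        ts.append(gdt_score(d, native, GDT_TS_THRESHOLDS))
        ha.append(gdt_score(d, native, GDT_HA_THRESHOLDS))
        rms.append(kabsch_superpose(d.ca, native.ca).rmsd)
    return DecoySeries(np.array(ts), np.array(ha), np.array(rms))


# ---------------------------------------------------------------------------
# Aggregation


def top_k_summary(series: DecoySeries, k: int = 10,
                  target_id: str = "") -> EvalSummary:
    """Mean of the k highest GDT_TS and k lowest RMSD (all decoys if fewer)."""
    if k <= 0:
        raise ValueError("k must be positive")
    gdt_sorted = np.sort(series.gdt_ts)[::-1]
    rmsd_sorted = np.sort(series.rmsd)
    kk = min(k, len(series))
    gdt = float(np.mean(gdt_sorted[:kk]))
    rmsd = float(np.mean(rmsd_sorted[:kk]))
    return EvalSummary(target_id=target_id, gdt=gdt, rmsd=rmsd,
                       best_gdt=float(gdt_sorted[0]), best_rmsd=float(rmsd_sorted[0]),
                       quality=quality_bin(gdt),
                       convergence=convergence_index(series))


def quality_bin(gdt: float) -> str:
    """Model-quality bin of a GDT value (Poor/Moderate/Good/HighQuality)."""
    for edge, name in QUALITY_BINS:
        if edge is None or gdt < edge:
            return name
    raise AssertionError("unreachable")


def is_informative(gdt: float) -> bool:
    """Whether a model's conformation likely shares the target's shape (GDT >= 40)."""
    return gdt >= 40.0


def convergence_index(series: DecoySeries) -> ConvergenceIndex:
    """Generation index of the first best-GDT and best-RMSD decoys."""
    i_gdt = int(np.argmax(series.gdt_ts)) + 1           # argmax returns first max
    i_rmsd = int(np.argmin(series.rmsd)) + 1
    both = None
    best_g = series.gdt_ts.max()
    best_r = series.rmsd.min()
    attains = (series.gdt_ts == best_g) & (series.rmsd == best_r)
    if np.any(attains):
        both = int(np.argmax(attains)) + 1
    return ConvergenceIndex(i_gdt, i_rmsd, both)


# ---------------------------------------------------------------------------
# Run comparison


def _group_stats(deltas: np.ndarray, baseline: np.ndarray, mask: np.ndarray):
    if not np.any(mask):
        return {"mean_change": 0.0, "mean_change_pct": 0.0}
    d = deltas[mask]
    b = baseline[mask]
    rel = 100.0 * d / np.where(b == 0, np.nan, np.abs(b))
    return {"mean_change": float(np.mean(d)),
            "mean_change_pct": float(np.nanmean(rel))}


def compare_runs(a: Sequence[EvalSummary], b: Sequence[EvalSummary],
                 test: str = "wilcoxon") -> dict:
    """Paired comparison of two runs over the same targets.

    For GDT, improvement in ``b`` means a strictly higher value; for RMSD a
    strictly lower one. Targets equal after rounding to one decimal count as
    unaffected. Reports percentage improved/unaffected/worsened, the mean
    absolute and relative change within each group, and a paired two-sided
    significance p-value (Wilcoxon signed-rank by default, ``test="ttest"``
    for a paired t-test).
    """
    ids_a = [s.target_id for s in a]
    ids_b = [s.target_id for s in b]
    if ids_a != ids_b:
        unpaired = sorted(set(ids_a) ^ set(ids_b)) or ["<order mismatch>"]
        raise ValueError(f"runs are not paired by target id: {unpaired}")
    n = len(a)
    if n == 0:
        raise ValueError("no targets to compare")
    report: dict = {"n_targets": n}
    for metric, higher_better in (("gdt", True), ("rmsd", False)):
        va = np.array([getattr(s, metric) for s in a], dtype=float)
        vb = np.array([getattr(s, metric) for s in b], dtype=float)
        delta = vb - va
        equal = np.round(va, 1) == np.round(vb, 1)
        improved = (~equal) & (delta > 0 if higher_better else delta < 0)
        worsened = (~equal) & ~improved
        entry = {
            "pct_improved": round(100.0 * improved.mean(), 2),
            "pct_unaffected": round(100.0 * equal.mean(), 2),
            "pct_worsened": round(100.0 * worsened.mean(), 2),
            "mean_change": float(np.mean(delta)),
            "improved": _group_stats(delta, va, improved),
            "worsened": _group_stats(delta, va, worsened),
        }
        if np.allclose(delta, 0):
            entry["p_value"] = 1.0
        elif test == "wilcoxon":
            entry["p_value"] = float(stats.wilcoxon(va, vb).pvalue)
        elif test == "ttest":
            entry["p_value"] = float(stats.ttest_rel(va, vb).pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        report[metric] = entry
    return report


def convergence_report(runs: Mapping[str, Sequence[DecoySeries]]) -> pd.DataFrame:
    """Mean (SD) convergence indices per run and pairwise relative speed-ups.

    Rows are runs; columns the three indices (first best GDT, first best
    RMSD, first decoy attaining both — runs lacking any such decoy average
    over the targets that have one). Speed-up of run A over run B is
    100 * (mean_B - mean_A) / mean_B, one decimal, reported in the
    ``speedup_vs_<run>`` columns for the "both" index.
    """
    rows = {}
    for name, series_list in runs.items():
        idx = [convergence_index(s) for s in series_list]
        gdt_i = np.array([c.first_best_gdt for c in idx], dtype=float)
        rmsd_i = np.array([c.first_best_rmsd for c in idx], dtype=float)
        both_i = np.array([c.both for c in idx if c.both is not None], dtype=float)
        rows[name] = {
            "gdt_mean": gdt_i.mean(), "gdt_sd": gdt_i.std(ddof=0),
            "rmsd_mean": rmsd_i.mean(), "rmsd_sd": rmsd_i.std(ddof=0),
            "both_mean": both_i.mean() if both_i.size else np.nan,
            "both_sd": both_i.std(ddof=0) if both_i.size else np.nan,
            "n_both": int(both_i.size),
        }
    df = pd.DataFrame(rows).T
    for other in df.index:
        df[f"speedup_vs_{other}"] = [
            relative_speedup(df.loc[name, "both_mean"], df.loc[other, "both_mean"])
            for name in df.index
        ]
    return df


def relative_speedup(mean_a: float, mean_b: float) -> float:
    """Convergence speed-up of A over B: 100 * (mean_B - mean_A) / mean_B, 1 dp."""
    if not np.isfinite(mean_a) or not np.isfinite(mean_b) or mean_b == 0:
        return float("nan")
    return round(100.0 * (mean_b - mean_a) / mean_b, 1)
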