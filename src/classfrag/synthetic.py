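"""Synthetic fixtures: ideal-SS structures, template databases, decoys, profiles.

Everything the pipeline consumes can be generated here with no external
download: ideal helices/strands/coils built from torsions, class-consistent
template databases with ground-truth labels, noisy decoy sets standing in
for the output of a stochastic fragment-assembly run, and sequence
profiles / SS predictions of controllable sharpness. All randomness is
driven by an explicit integer seed; no global state.

The decoy generator perturbs native torsions with wrapped-Gaussian noise.
This emulates the *statistics* of a decoy set (quality decaying with noise,
generation-order convergence) but not the energy landscape of a real
fragment-assembly simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import geometry, ss_class
from .fragment_picker import AA_ORDER, SSPrediction, SequenceProfile
from .geometry import BackboneStructure, TorsionTriple
from .ss_class import ClassAnnotation, SSString
from .template_select import TemplateDB, TemplateRecord, record_from_structure

__all__ = [
    "SSSpec",
    "IDEAL_TORSIONS",
    "make_ideal_structure",
    "make_template_db",
    "make_decoys",
    "make_profile_and_ss",
    "make_strand_pair",
    "concatenate_structures",
    "class_spec",
    "fit_improvement_experiment",
]

#: Ideal backbone torsions per 3-state SS (degrees).
IDEAL_TORSIONS = {"H": (-57.0, -47.0), "E": (-119.0, 113.0)}

# residues that favour each SS state; proline avoided (no amide H donor)
_SEGMENT_RESIDUES = {"H": "AELKQR", "E": "VIFTYW", "C": "GSNDT"}


@dataclass
class SSSpec:
    """Blueprint of an ideal-SS chain: (state, segment length) list + loop jitter."""

    segments: list[tuple[str, int]]
    loop_jitter_sd: float = 10.0  # degrees, applied to coil torsions only

    def __post_init__(self) -> None:
        for state, ln in self.segments:
            if state not in "HEC" or ln < 1:
                raise ValueError(f"bad segment ({state!r}, {ln})")
        if self.length < 3:
            raise ValueError("total length must be >= 3")

    @property
    def length(self) -> int:
        return sum(ln for _, ln in self.segments)

    @property
    def letters(self) -> str:
        return "".join(state * ln for state, ln in self.segments)


def _wrap_angle(x: float) -> float:
    w = (x + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def make_ideal_structure(spec: SSSpec, seed: int = 0,
                         structure_id: str = "synth") -> BackboneStructure:
    """Build a chain from ideal per-state torsions.

    H segments use (-57, -47), E segments (-119, 113); coil torsions are
    drawn uniformly from a broad allowed region (phi in [-160, -60], psi in
    [-60, 160]) with the blueprint's Gaussian jitter added. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    letters = spec.letters
    L = len(letters)
    seq = "".join(rng.choice(list(_SEGMENT_RESIDUES[c])) for c in letters)
    torsions = []
    for i, c in enumerate(letters):
        if c in IDEAL_TORSIONS:
            phi, psi = IDEAL_TORSIONS[c]
        else:
            phi = float(rng.uniform(-160.0, -60.0))
            psi = float(rng.uniform(-60.0, 160.0))
            phi = _wrap_angle(phi + rng.normal(0.0, spec.loop_jitter_sd))
            psi = _wrap_angle(psi + rng.normal(0.0, spec.loop_jitter_sd))
        torsions.append(TorsionTriple(position=i + 1, phi=phi, psi=psi, omega=180.0))
    return geometry.build_backbone_from_torsions(seq, torsions,
                                                 structure_id=structure_id)


# ---------------------------------------------------------------------------
# Class-consistent template databases


_CATH_TO_SCOP = {
    "mainly_alpha": "all_alpha",
    "mainly_beta": "all_beta",
    "alpha_beta": "alpha_plus_beta",
    "few_secondary_structures": "small_protein",
}
_SCOP_TO_CONTENT = {
    "all_alpha": "mainly_alpha",
    "all_beta": "mainly_beta",
    "alpha_plus_beta": "alpha_beta",
    "alpha_slash_beta": "alpha_beta",
    "small_protein": "few_secondary_structures",
}


def class_spec(label: str, length: int, rng: np.random.Generator) -> SSSpec:
    """A random SS blueprint whose content matches the given class label."""
    content = _SCOP_TO_CONTENT.get(label, label)
    segs: list[tuple[str, int]] = []
    total = 0

    def add(state: str, lo: int, hi: int) -> None:
        nonlocal total
        ln = int(rng.integers(lo, hi + 1))
        segs.append((state, ln))
        total += ln

    add("C", 2, 4)
    # segment ranges keep coil fractions comparable across classes, so that
    # class membership (not coil abundance) is what separates the pools
    if content == "mainly_alpha":
        while total < length:
            add("H", 8, 13)
            add("C", 3, 5)
    elif content == "mainly_beta":
        while total < length:
            add("E", 8, 12)
            add("C", 3, 5)
    elif content == "alpha_beta":
        while total < length:
            add("H", 6, 10)
            add("C", 2, 4)
            add("E", 5, 7)
            add("C", 2, 4)
    elif content == "few_secondary_structures":
        while total < length:
            add("C", 8, 14)
            if rng.random() < 0.4 and total < length - 3:
                add("H", 2, 2)  # stays below the 15% helix threshold
    else:
        raise ValueError(f"unknown class label {label!r}")
    # trim to the requested length
    out: list[tuple[str, int]] = []
    left = length
    for state, ln in segs:
        take = min(ln, left)
        if take > 0:
            out.append((state, take))
            left -= take
    return SSSpec(out)


def make_template_db(n_per_class: Mapping[str, int],
                     lengths: tuple[int, int] = (60, 120),
                     seed: int = 0) -> tuple[TemplateDB, dict[str, str]]:
    """Synthetic class-annotated template database plus ground-truth labels.

    Each template is built from a class-consistent SS blueprint; its recorded
    SS letters come from that blueprint (as a real per-residue template table
    records an assignment made on the full structure). Resolutions are drawn
    uniformly from [1.0, 3.5] A. Keys of ``n_per_class`` may be CATH or SCOP
    labels (not mixed). Returns (db, {template_id: true label}).
    """
    labels = list(n_per_class)
    schemes = {"CATH" if lb in ss_class.CATH_LABELS else "SCOP" for lb in labels}
    if len(schemes) > 1:
        raise ValueError("mixed CATH and SCOP labels")
    scheme = schemes.pop() if schemes else "CATH"
    rng = np.random.default_rng(seed)
    db = TemplateDB()
    truth: dict[str, str] = {}
    for label in labels:
        for k in range(n_per_class[label]):
            L = int(rng.integers(lengths[0], lengths[1] + 1))
            spec = class_spec(label, L, rng)
            tid = "".join(w[0] for w in label.split("_")) + f"{k:03d}"
            s = make_ideal_structure(spec, seed=int(rng.integers(2**31)),
                                     structure_id=tid)
            resolution = float(rng.uniform(1.0, 3.5))
            rec = record_from_structure(s, resolution=resolution,
                                        ss=SSString(spec.letters, source="provided"))
            h, e = ss_class.ss_content(spec.letters)
            rec.annotation = ClassAnnotation(scheme, label, h, e)
            db.records[tid] = rec
            truth[tid] = label
    return db, truth


# ---------------------------------------------------------------------------
# Decoys


def make_decoys(native: BackboneStructure, sigma: float, n: int,
                seed: int = 0) -> list[BackboneStructure]:
    """Decoys from native torsions + wrapped-Gaussian noise (SD sigma, degrees).

    Noise is applied independently to every defined phi/psi; omega is kept.
    The returned list order is the generation order. ``sigma=0`` reproduces
    the native chain (rebuilt with ideal covalent geometry).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    torsions = geometry.compute_torsions(native)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        noisy = []
        for t in torsions:
            phi = None if t.phi is None else _wrap_angle(t.phi + rng.normal(0, sigma))
            psi = None if t.psi is None else _wrap_angle(t.psi + rng.normal(0, sigma))
            noisy.append(TorsionTriple(position=t.position, phi=phi, psi=psi,
                                       omega=t.omega))
        out.append(geometry.build_backbone_from_torsions(
            native.sequence, noisy, structure_id=f"{native.id}_decoy{i + 1}"))
    return out


# ---------------------------------------------------------------------------
# Profiles and SS predictions


def make_profile_and_ss(sequence: str, true_ss: SSString | str,
                        sharpness: float = 0.8,
                        seed: int = 0) -> tuple[SequenceProfile, SSPrediction]:
    """Profile and SS prediction favouring the truth with tunable strength.

    The profile gives the native residue a score of ``10 * sharpness`` per
    column over a noise floor that shrinks as sharpness grows; the SS
    prediction puts probability ``sharpness`` on the true letter with the
    remainder split between the other two states (sharpness 1/3 = uniform).
    """
    if not (0.0 <= sharpness <= 1.0):
        raise ValueError("sharpness must be in [0, 1]")
    letters = true_ss.letters if isinstance(true_ss, SSString) else true_ss
    if len(letters) != len(sequence):
        raise ValueError("SS length must match sequence")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    scores = rng.uniform(-1.0, 1.0, size=(L, 20)) * (1.0 - sharpness)
    for i, a in enumerate(sequence):
        scores[i, AA_ORDER.index(a)] += 10.0 * sharpness
    probs = np.zeros((L, 3))
    for i, c in enumerate(letters):
        j = "HEC".index(c)
        probs[i] = (1.0 - sharpness) / 2.0
        probs[i, j] = sharpness
    return SequenceProfile(scores), SSPrediction(probs, name="synthetic")


# ---------------------------------------------------------------------------
# Paired strands and composites (beta-sheet fixtures)


def _strand_frame(s: BackboneStructure) -> BackboneStructure:
    """Rigidly move a chain so its CA principal axis lies along x, centred."""
    ca = s.ca - s.ca.mean(axis=0)
    u, _sv, vt = np.linalg.svd(ca, full_matrices=False)
    R = vt  # rows: principal axes
    if np.linalg.det(R) < 0:
        R[2] *= -1
    if (ca @ R.T)[-1, 0] < (ca @ R.T)[0, 0]:
        flip = np.diag([-1.0, 1.0, -1.0])  # proper: keep chain running +x
        R = flip @ R
    return s.transformed(R, -R @ s.ca.mean(axis=0))


def _hbond_count_between(a: BackboneStructure, b: BackboneStructure) -> int:
    """Inter-chain backbone H-bonds (both donor directions), vectorised."""
    def hpos(s):
        h = np.full_like(s.n, np.nan)
        d = s.c[:-1] - s.o[:-1]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        h[1:] = s.n[1:] + d
        return h

    def count(donor: BackboneStructure, dh: np.ndarray, acc: BackboneStructure) -> int:
        r = lambda x, y: np.linalg.norm(x[:, None, :] - y[None, :, :], axis=2)
        r_on = r(donor.n, acc.o)
        r_cn = r(donor.n, acc.c)
        r_oh = r(dh, acc.o)
        r_ch = r(dh, acc.c)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        return int(np.nansum(e < -0.5))

    return count(a, hpos(a), b) + count(b, hpos(b), a)


def make_strand_pair(n_res: int = 8, parallel: bool = False,
                     seed: int = 0) -> BackboneStructure:
    """Two ideal strands placed as a hydrogen-bonded beta-sheet pair.

    A synthetic stand-in for a real sheet: the second strand's rigid placement
    is chosen by a deterministic grid search maximising the number of
    inter-strand backbone hydrogen bonds, with the strands ~4.9 A apart. The
    chains are concatenated into a single structure with a chain break
    between them.
    """
    strand = _strand_frame(make_ideal_structure(
        SSSpec([("E", n_res)]), seed=seed, structure_id="strand"))
    if parallel:
        rots = [np.eye(3), _rot("x", 180.0)]
    else:
        rots = [_rot("y", 180.0), _rot("z", 180.0)]

    def search(grids) -> tuple[int, np.ndarray, np.ndarray]:
        top = (-1, rots[0], np.zeros(3))
        for R in rots:
            b0 = strand.transformed(R, np.zeros(3))
            for dy in grids[0]:
                for dx in grids[1]:
                    for dz in grids[2]:
                        t = np.array([dx, dy, dz])
                        nb = _hbond_count_between(strand, b0.transformed(np.eye(3), t))
                        if nb > top[0]:
                            top = (nb, R, t)
        return top

    # coarse grid, then refine around the best placement
    _, R, t = search((np.arange(3.8, 5.81, 0.3), np.arange(-4.0, 4.01, 0.45),
                      np.arange(-2.5, 2.51, 0.5)))
    _, R, t = search((np.arange(t[1] - 0.3, t[1] + 0.31, 0.1),
                      np.arange(t[0] - 0.45, t[0] + 0.46, 0.15),
                      np.arange(t[2] - 0.5, t[2] + 0.51, 0.25)))
    paired = strand.transformed(R, t)
    return concatenate_structures([strand, paired], structure_id="strand_pair")


def _rot(axis: str, deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler(axis, deg, degrees=True).as_matrix()


def concatenate_structures(parts: Sequence[BackboneStructure],
                           structure_id: str = "composite") -> BackboneStructure:
    """Concatenate pre-positioned chains into one structure.

    Coordinates are used as given — the caller is responsible for placing the
    parts (gaps larger than 4.5 A CA-CA read as chain breaks downstream).
    """
    if not parts:
        raise ValueError("no parts")
    return BackboneStructure(
        id=structure_id, chain=parts[0].chain,
        sequence="".join(p.sequence for p in parts),
        n=np.vstack([p.n for p in parts]),
        ca=np.vstack([p.ca for p in parts]),
        c=np.vstack([p.c for p in parts]),
        o=np.vstack([p.o for p in parts]) if all(p.o is not None for p in parts) else None,
    )


# ---------------------------------------------------------------------------
# The central hypothesis at toy scale


def fit_improvement_experiment(n_repeats: int = 20,
                               n_per_class: Mapping[str, int] | None = None,
                               native_length: int = 40,
                               fragment_length: int = 9,
                               n_frags: int = 25,
                               seed: int = 0) -> dict:
    """Class-filtered vs random-template fragment libraries on synthetic data.

    For each repeat: build a mixed-class template database and a
    mainly-alpha native, pick one library from the class-filtered templates
    and one from an equal-size random template subset, and compare the mean
    per-position best-fragment RMSD. Returns per-repeat means, the number of
    repeats where the class-filtered library fits at least as well, and a
    one-sided sign-test p-value.
    """
    from scipy.stats import binomtest

    from . import fragment_picker, template_select

    if n_per_class is None:
        n_per_class = {"mainly_alpha": 5, "mainly_beta": 15}
    rng = np.random.default_rng(seed)
    class_means, random_means = [], []
    for rep in range(n_repeats):
        s_db = int(rng.integers(2**31))
        s_nat = int(rng.integers(2**31))
        db, _truth = make_template_db(n_per_class, lengths=(50, 80), seed=s_db)
        native_spec = class_spec("mainly_alpha", native_length,
                                 np.random.default_rng(s_nat))
        native = make_ideal_structure(native_spec, seed=s_nat, structure_id="native")
        profile, ss_pred = make_profile_and_ss(native.sequence, native_spec.letters,
                                               sharpness=0.9, seed=s_nat)
        target_class = ss_class.annotate_cath_class(
            *ss_class.ss_content(native_spec.letters))
        filtered = template_select.filter_templates(db, target_class,
                                                    max_resolution=None)
        k = len(filtered)
        rand_ids = list(rng.choice(db.ids, size=k, replace=False))
        control = db.subset(rand_ids)

        means = []
        for pool in (filtered, control):
            lib = fragment_picker.pick_fragments(
                native.sequence, profile, ss_pred, pool,
                length=fragment_length, n_frags=n_frags)
            fit = fragment_picker.library_fit(lib, native)
            means.append(float(fit["best_rmsd"].mean()))
        class_means.append(means[0])
        random_means.append(means[1])
    wins = sum(c <= r for c, r in zip(class_means, random_means))
    p = binomtest(wins, n_repeats, 0.5, alternative="greater").pvalue
    return {
        "n_repeats": n_repeats,
        "class_filtered_mean_rmsd": class_means,
        "random_control_mean_rmsd": random_means,
        "wins": wins,
        "sign_test_p": float(p),
        "mean_improvement": float(np.mean(np.array(random_means)
                                          - np.array(class_means))),
    }
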