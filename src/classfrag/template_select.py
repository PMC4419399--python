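"""Template database handling and class-constrained template selection.

The template database is a per-residue flat table in the style of the "vall"
used by fragment pickers: for every template chain, one row per residue with
its amino acid, 3-state SS letter, phi/psi/omega torsions and CA coordinates,
plus the template's crystallographic resolution. Selection for a target
keeps only templates of the target's structural class, at high resolution
(2.5 A cut-off by default), with detectable homologs removed (sequence-search
E-value below 0.05) to emulate ab initio conditions.
"""

from __future__ import annotations

import difflib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from . import geometry, ss_class
from .geometry import BackboneStructure
from .ss_class import ClassAnnotation, SSString

__all__ = [
    "TemplateRecord",
    "TemplateDB",
    "HomologHit",
    "load_template_db",
    "write_template_db",
    "annotate_db",
    "filter_templates",
    "read_homolog_table",
    "write_homolog_table",
    "write_id_list",
    "find_homologs_by_identity",
    "DEFAULT_MAX_RESOLUTION",
    "DEFAULT_E_CUT",
]

DEFAULT_MAX_RESOLUTION = 2.5   # A; resolution cut producing "high quality" templates
DEFAULT_E_CUT = 0.05           # strict: hits with E-value < 0.05 are homologs

_RESIDUE_COLUMNS = ["position", "aa", "ss", "phi", "psi", "omega",
                    "ca_x", "ca_y", "ca_z"]


@dataclass
class HomologHit:
    """A sequence-search hit against the target (template id + E-value)."""

    template_id: str
    e_value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.e_value) or self.e_value < 0:
            raise ValueError(f"invalid E-value {self.e_value}")


@dataclass
class TemplateRecord:
    """One template chain: metadata plus the per-residue torsion/SS table."""

    id: str
    chain: str
    resolution: float | None
    residues: pd.DataFrame
    annotation: ClassAnnotation | None = None

    def __post_init__(self) -> None:
        pos = self.residues["position"].to_numpy()
        if len(pos) and not np.all(np.diff(pos) > 0):
            raise ValueError(f"template {self.id}: positions not strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(self.residues["aa"])

    @property
    def ss(self) -> str:
        return "".join(self.residues["ss"])


@dataclass
class TemplateDB:
    """An ordered collection of template records keyed by id."""

    records: dict[str, TemplateRecord] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TemplateRecord]:
        return iter(self.records.values())

    def __getitem__(self, key: str) -> TemplateRecord:
        return self.records[key]

    def __contains__(self, key: str) -> bool:
        return key in self.records

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def subset(self, ids: Iterable[str]) -> "TemplateDB":
        keep = set(ids)
        return TemplateDB({k: v for k, v in self.records.items() if k in keep})


# ---------------------------------------------------------------------------
# Construction


def record_from_structure(s: BackboneStructure,
                          resolution: float | None = None,
                          ss: SSString | None = None) -> TemplateRecord:
    """Build a per-residue record from a backbone structure.

    Torsions are computed from coordinates; SS is assigned from hydrogen
    bonds unless a precomputed string is supplied.
    """
    torsions = geometry.compute_torsions(s)
    if ss is None:
        ss = ss_class.assign_secondary_structure(s)
    rows = {
        "position": np.arange(1, len(s) + 1),
        "aa": list(s.sequence),
        "ss": list(ss.letters),
        "phi": [t.phi if t.phi is not None else np.nan for t in torsions],
        "psi": [t.psi if t.psi is not None else np.nan for t in torsions],
        "omega": [t.omega if t.omega is not None else np.nan for t in torsions],
        "ca_x": s.ca[:, 0], "ca_y": s.ca[:, 1], "ca_z": s.ca[:, 2],
    }
    return TemplateRecord(id=s.id, chain=s.chain or "A", resolution=resolution,
                          residues=pd.DataFrame(rows))


def load_template_db(path: str | Path) -> TemplateDB:
    """Load a template database from a vall-like TSV or a directory of PDBs.

    Directory mode computes torsions and SS from coordinates and reads the
    resolution from the PDB header when present. Tabular mode trusts the file
    columns. Unusable templates (e.g. non-monotone positions) are dropped and
    reported in ``db.errors``.
    """
    path = Path(path)
    db = TemplateDB()
    if path.is_dir():
        files = sorted(path.glob("*.pdb"))
        for f in files:
            try:
                import gemmi

                st = gemmi.read_pdb(str(f))
                resolution = st.resolution if st.resolution > 0 else None
                s = geometry.read_pdb_backbone(f)
                db.records[s.id] = record_from_structure(s, resolution=resolution)
            except Exception as exc:  # noqa: BLE001 — collect, keep loading
                db.errors.append(f"{f.name}: {exc}")
    else:
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"id": str, "chain": str, "aa": str, "ss": str})
        required = {"id", "chain", "resolution", *_RESIDUE_COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"vall file missing columns: {sorted(missing)}")
        for tid, grp in df.groupby("id", sort=False):
            try:
                res = grp["resolution"].iloc[0]
                resolution = None if pd.isna(res) else float(res)
                db.records[str(tid)] = TemplateRecord(
                    id=str(tid), chain=str(grp["chain"].iloc[0]),
                    resolution=resolution,
                    residues=grp[_RESIDUE_COLUMNS].reset_index(drop=True),
                )
            except Exception as exc:  # noqa: BLE001
                db.errors.append(f"{tid}: {exc}")
    if not db.records:
        raise ValueError(f"no usable templates loaded from {path}")
    return db


def write_template_db(db: TemplateDB, path: str | Path) -> None:
    """Write the database as a flat vall-like TSV (round-trips with load)."""
    frames = []
    for rec in db:
        g = rec.residues.copy()
        g.insert(0, "id", rec.id)
        g.insert(1, "chain", rec.chain)
        g["resolution"] = rec.resolution if rec.resolution is not None else np.nan
        frames.append(g)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.4f")


def annotate_db(db: TemplateDB, scheme: str = "CATH",
                class_table: dict[str, ClassAnnotation] | None = None) -> TemplateDB:
    """Attach class annotations to every record (in place; returns db).

    With a class table, labels are taken from it. Otherwise CATH labels are
    derived from the recorded SS letters via the content thresholds; SCOP
    labels from content alone default the mixed class to alpha+beta (sheet
    topology is not recoverable from a flat SS string).
    """
    for rec in db:
        if class_table is not None:
            if rec.id not in class_table:
                raise KeyError(f"template {rec.id} missing from class table")
            rec.annotation = class_table[rec.id]
            continue
        h, e = ss_class.ss_content(rec.ss)
        if scheme == "CATH":
            rec.annotation = ss_class.annotate_cath_class(h, e)
        else:
            cath = ss_class.annotate_cath_class(h, e)
            label = {
                "mainly_alpha": "all_alpha",
                "mainly_beta": "all_beta",
                "alpha_beta": "alpha_plus_beta",
                "few_secondary_structures": "small_protein",
            }[cath.label]
            rec.annotation = ClassAnnotation("SCOP", label, h, e)
    return db


# ---------------------------------------------------------------------------
# Filtering


def filter_templates(db: TemplateDB,
                     target_class: ClassAnnotation | str,
                     max_resolution: float | None = DEFAULT_MAX_RESOLUTION,
                     homologs: Sequence[HomologHit] | None = None,
                     e_cut: float = DEFAULT_E_CUT) -> TemplateDB:
    """Class-filtered, high-resolution, homolog-free template set.

    Keeps a template iff its class label equals the target's, its resolution
    is at or below ``max_resolution`` (templates without a resolution are
    excluded while a cut is active), and it is not a homolog hit with
    E-value strictly below ``e_cut``.
    """
    if isinstance(target_class, ClassAnnotation):
        label = target_class.label
        scheme = target_class.scheme
    else:
        label = target_class
        scheme = None
    excluded = {h.template_id for h in (homologs or []) if h.e_value < e_cut}
    out = TemplateDB()
    for rec in db:
        if rec.annotation is None:
            raise ValueError(f"template {rec.id} has no class annotation; "
                             "run annotate_db first")
        if scheme is not None and rec.annotation.scheme != scheme:
            raise ValueError(
                f"template {rec.id} annotated under {rec.annotation.scheme}, "
                f"target under {scheme}")
        if rec.annotation.label != label:
            continue
        if max_resolution is not None and (
                rec.resolution is None or rec.resolution > max_resolution):
            continue
        if rec.id in excluded:
            continue
        out.records[rec.id] = rec
    if not out.records:
        warnings.warn("template filter produced an empty set")
    return out


# ---------------------------------------------------------------------------
# Homologs and lists


def read_homolog_table(path: str | Path) -> list[HomologHit]:
    """Read a TSV of (id, e_value) sequence-search hits."""
    df = pd.read_csv(path, sep="\t")
    return [HomologHit(str(r["id"]), float(r["e_value"])) for _, r in df.iterrows()]


def write_homolog_table(hits: Sequence[HomologHit], path: str | Path) -> None:
    pd.DataFrame(
        [{"id": h.template_id, "e_value": h.e_value} for h in hits]
    ).to_csv(path, sep="\t", index=False)


def write_id_list(db_or_ids: TemplateDB | Iterable[str], path: str | Path) -> None:
    """Write template ids one per line (the list handed to a fragment picker)."""
    ids = db_or_ids.ids if isinstance(db_or_ids, TemplateDB) else list(db_or_ids)
    Path(path).write_text("\n".join(ids) + ("\n" if ids else ""))


def find_homologs_by_identity(target_sequence: str, db: TemplateDB,
                              min_identity: float = 0.30,
                              min_coverage: float = 0.50) -> list[HomologHit]:
    """Heuristic homolog detection by sequence identity (no sequence search run).

    A template is flagged when its matched residues cover at least
    ``min_coverage`` of the target and identity over the target length is at
    least ``min_identity``. This is a stand-in for a proper profile search:
    use a real hit table whenever one is available. Flagged hits are given
    E-value 0 so any strict cut excludes them.
    """
    hits = []
    for rec in db:
        sm = difflib.SequenceMatcher(a=target_sequence, b=rec.sequence, autojunk=False)
        matched = sum(b.size for b in sm.get_matching_blocks())
        identity = matched / max(1, len(target_sequence))
        if identity >= min_identity and matched >= min_coverage * len(target_sequence):
            hits.append(HomologHit(rec.id, 0.0))
    return hits
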