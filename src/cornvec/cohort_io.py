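"""Per-eye cohort CSV reading/writing, exclusion rules, and panel decomposition.

The cohort is a flat CSV with one row per eye, carrying biometry (AL, CCT,
ACD, LT), pupil sizes, quality flags, the biometer's (IOLM) front/back/total
keratometry surfaces as radii+axes, the tomographer's (CASIA) pre- and
postoperative front/back surfaces and real power, the implanted toric IOL,
and the postoperative refraction.  Column names follow the device-export
vocabulary (IOLMR1a = IOLM flat front radius, CASIAP1r_pre = CASIA flat real
power preop, ...) and can be remapped via ``column_map``.

Exclusion rules applied before analysis:

* missing or 'Failed'/'Warning'-flagged keratometry, total keratometry, back
  surface, or biometry (AL, CCT, ACD, LT) on the biometer;
* incomplete or flagged pre/postoperative tomography;
* mydriasis (pupil > 5.5 mm, strict) at either visit, or a pupil-size change
  of more than 1.5 mm between visits;
* one eye per patient, chosen at random under a dedicated seed.

``decompose_cohort`` then converts every retained eye into power vectors per
(device, layer) and mirrors left-eye C45 components into right-eye
orientation, producing the wide per-eye panel the downstream statistics use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .power_vectors import (
    BACK_SURFACE,
    FRONT_SURFACE,
    KERATOMETRIC,
    PowerMeridians,
    PowerVector,
    RefractionRecord,
    SurfaceMeasurement,
    TIOLRecord,
    mirror_for_left_eye,
    powers_to_power_vector,
    radii_to_power_vector,
)

__all__ = [
    "EyeRecord",
    "CohortPanel",
    "SchemaError",
    "DEVICES",
    "LAYERS",
    "COMPONENTS",
    "read_cohort_csv",
    "write_cohort_csv",
    "apply_exclusions",
    "decompose_cohort",
    "read_panel_csv",
    "write_exclusion_log",
]

DEVICES = ("IOLM", "CASIA_pre", "CASIA_post")
LAYERS = ("front", "back", "keratometric", "total")
COMPONENTS = ("EQ", "C0", "C45")

#: Quality flags that trigger exclusion (matched case-insensitively).
BAD_FLAGS = frozenset({"failed", "warning"})

#: Flag-group keys and their default CSV columns.
FLAG_COLUMNS = {
    "IOLM_K": "IOLMQualK",
    "IOLM_TK": "IOLMQualT",
    "IOLM_BACK": "IOLMQualP",
    "IOLM_BIO": "IOLMQualBio",
    "CASIA_PRE": "CASIAQual_pre",
    "CASIA_POST": "CASIAQual_post",
}

_SURFACE_COLS = {
    "iolm_front": ("IOLMR1a", "IOLMA1a", "IOLMR2a", "IOLMA2a"),
    "iolm_back": ("IOLMR1p", "IOLMA1p", "IOLMR2p", "IOLMA2p"),
    "iolm_tk": ("IOLMR1t", "IOLMA1t", "IOLMR2t", "IOLMA2t"),
    "casia_front_pre": ("CASIAR1a_pre", "CASIAA1a_pre", "CASIAR2a_pre", "CASIAA2a_pre"),
    "casia_back_pre": ("CASIAR1p_pre", "CASIAA1p_pre", "CASIAR2p_pre", "CASIAA2p_pre"),
    "casia_front_post": ("CASIAR1a_post", "CASIAA1a_post", "CASIAR2a_post", "CASIAA2a_post"),
    "casia_back_post": ("CASIAR1p_post", "CASIAA1p_post", "CASIAR2p_post", "CASIAA2p_post"),
}

_POWER_COLS = {
    "casia_real_pre": ("CASIAP1r_pre", "CASIAA1r_pre", "CASIAP2r_pre", "CASIAA2r_pre"),
    "casia_real_post": ("CASIAP1r_post", "CASIAA1r_post", "CASIAP2r_post", "CASIAA2r_post"),
}

_SCALAR_COLS = ("age", "AL", "CCT", "ACD", "LT", "pupil_pre", "pupil_post")
_TIOL_COLS = ("IOLP", "IOLT", "IOLA")
_REF_COLS = ("REFS", "REFC", "REFA")

#: Columns that must be present in the header (cells may still be empty).
MANDATORY_COLUMNS: tuple[str, ...] = (
    ("patient_id", "eye")
    + _SCALAR_COLS
    + tuple(c for cols in _SURFACE_COLS.values() for c in cols)
    + tuple(c for cols in _POWER_COLS.values() for c in cols)
)

#: Optional columns: quality flags, tIOL, refraction.
OPTIONAL_COLUMNS: tuple[str, ...] = tuple(FLAG_COLUMNS.values()) + _TIOL_COLS + _REF_COLS

ALL_COLUMNS: tuple[str, ...] = MANDATORY_COLUMNS + OPTIONAL_COLUMNS


class SchemaError(ValueError):
    """The CSV header does not contain the mapped mandatory columns."""


@dataclass
class EyeRecord:
    """One eye's full measurement set, ``None`` where data are missing."""

    patient_id: str
    eye: str  # "OD" | "OS"
    age: float | None = None
    AL: float | None = None
    CCT: float | None = None
    ACD: float | None = None
    LT: float | None = None
    pupil_pre: float | None = None
    pupil_post: float | None = None
    flags: dict[str, str] = field(default_factory=dict)
    iolm_front: SurfaceMeasurement | None = None
    iolm_back: SurfaceMeasurement | None = None
    iolm_tk: SurfaceMeasurement | None = None
    casia_front_pre: SurfaceMeasurement | None = None
    casia_back_pre: SurfaceMeasurement | None = None
    casia_front_post: SurfaceMeasurement | None = None
    casia_back_post: SurfaceMeasurement | None = None
    casia_real_pre: PowerMeridians | None = None
    casia_real_post: PowerMeridians | None = None
    tiol: TIOLRecord | None = None
    refraction_post: RefractionRecord | None = None

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ValueError(f"eye must be 'OD' or 'OS', got {self.eye!r}")


@dataclass
class CohortPanel:
    """Wide per-eye frame of power-vector components.

    ``frame`` is indexed by patient_id with an ``eye`` column plus one column
    per ``<device>_<layer>_<component>``; ``mirrored`` records whether OS
    C45 signs have been flipped into right-eye orientation (exactly once).
    """

    frame: pd.DataFrame
    mirrored: bool = True

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="patient_id", float_format="%.6f")

    def device(self, device: str) -> pd.DataFrame:
        """Sub-frame for one device with the device prefix stripped."""
        prefix = device + "_"
        cols = [c for c in self.frame.columns if c.startswith(prefix)]
        if not cols:
            raise KeyError(f"device {device!r} not in panel")
        out = self.frame[cols].copy()
        out.columns = [c[len(prefix):] for c in cols]
        return out


def _mapped(column_map: Mapping[str, str] | None, name: str) -> str:
    return column_map.get(name, name) if column_map else name


def _cell(row: pd.Series, col: str) -> float | None:
    if col not in row.index:
        return None
    v = pd.to_numeric(row[col], errors="coerce")
    return None if pd.isna(v) else float(v)


def read_cohort_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[EyeRecord]:
    """Read a per-eye cohort CSV into :class:`EyeRecord` objects.

    ``column_map`` maps the canonical column vocabulary to the actual header
    names.  Unparseable numeric cells become missing values, never zeros.
    Surface/power groups are only built when all four of their cells parse.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [
        c for c in MANDATORY_COLUMNS if _mapped(column_map, c) not in df.columns
    ]
    if missing:
        raise SchemaError(f"CSV header missing mandatory columns: {missing}")

    records: list[EyeRecord] = []
    for _, row in df.iterrows():
        rec = EyeRecord(
            patient_id=str(row[_mapped(column_map, "patient_id")]),
            eye=str(row[_mapped(column_map, "eye")]).strip(),
        )
        for name in _SCALAR_COLS:
            setattr(rec, name, _cell(row, _mapped(column_map, name)))
        for attr, cols in _SURFACE_COLS.items():
            vals = [_cell(row, _mapped(column_map, c)) for c in cols]
            if all(v is not None for v in vals):
                setattr(rec, attr, SurfaceMeasurement(vals[0], vals[1], vals[2], vals[3]))
        for attr, cols in _POWER_COLS.items():
            vals = [_cell(row, _mapped(column_map, c)) for c in cols]
            if all(v is not None for v in vals):
                p1, a1, p2, _a2 = vals
                # mislabelled flat/steep is normalised (with warning) by the ctor
                setattr(rec, attr, PowerMeridians(p1, p2, a1))
        for grp, col in FLAG_COLUMNS.items():
            mc = _mapped(column_map, col)
            if mc in df.columns and not pd.isna(row[mc]):
                rec.flags[grp] = str(row[mc])
        tv = [_cell(row, _mapped(column_map, c)) for c in _TIOL_COLS]
        if all(v is not None for v in tv):
            rec.tiol = TIOLRecord(tv[0], tv[1], tv[2])
        rv = [_cell(row, _mapped(column_map, c)) for c in _REF_COLS]
        if all(v is not None for v in rv):
            rec.refraction_post = RefractionRecord(rv[0], rv[1], rv[2])
        records.append(rec)
    return records


def write_cohort_csv(records: Sequence[EyeRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical column order (deterministic bytes)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "eye": rec.eye,
        }
        for name in _SCALAR_COLS:
            row[name] = getattr(rec, name)
        for attr, cols in _SURFACE_COLS.items():
            s: SurfaceMeasurement | None = getattr(rec, attr)
            vals = (s.R_flat, s.A_flat, s.R_steep, s.A_steep) if s else (None,) * 4
            row.update(zip(cols, vals))
        for attr, cols in _POWER_COLS.items():
            p: PowerMeridians | None = getattr(rec, attr)
            vals = (p.P_flat, p.A_flat, p.P_steep, p.A_steep) if p else (None,) * 4
            row.update(zip(cols, vals))
        for grp, col in FLAG_COLUMNS.items():
            row[col] = rec.flags.get(grp, "Successful")
        if rec.tiol:
            row.update(zip(_TIOL_COLS, (rec.tiol.IOLP, rec.tiol.IOLT, rec.tiol.IOLA)))
        if rec.refraction_post:
            r = rec.refraction_post
            row.update(zip(_REF_COLS, (r.REFS, r.REFC, r.REFA)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(ALL_COLUMNS))
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# exclusions


def _exclusion_reason(rec: EyeRecord) -> str | None:
    for grp in FLAG_COLUMNS:
        if rec.flags.get(grp, "").strip().lower() in BAD_FLAGS:
            return f"quality flag '{rec.flags[grp]}' on {grp}"
    if rec.iolm_front is None:
        return "missing IOLM keratometry"
    if rec.iolm_tk is None:
        return "missing IOLM total keratometry"
    if rec.iolm_back is None:
        return "missing IOLM back surface"
    for name in ("AL", "CCT", "ACD", "LT"):
        if getattr(rec, name) is None:
            return f"missing {name}"
    if rec.casia_front_pre is None or rec.casia_back_pre is None or rec.casia_real_pre is None:
        return "incomplete preoperative CASIA measurement"
    if rec.casia_front_post is None or rec.casia_back_post is None or rec.casia_real_post is None:
        return "incomplete postoperative CASIA measurement"
    if rec.pupil_pre is None or rec.pupil_post is None:
        return "missing pupil size"
    if rec.pupil_pre > 5.5 or rec.pupil_post > 5.5:
        return "mydriasis (pupil > 5.5 mm)"
    if abs(rec.pupil_post - rec.pupil_pre) > 1.5:
        return "pupil size change > 1.5 mm"
    return None


def apply_exclusions(
    records: Sequence[EyeRecord], seed: int | None = 0
) -> tuple[list[EyeRecord], list[dict[str, str]]]:
    """Apply the exclusion rules; return (retained records, exclusion log).

    The log holds one ``{"patient_id", "eye", "reason"}`` entry per dropped
    eye.  When both eyes of a patient survive the data checks, one is kept at
    random under ``seed`` (a generator dedicated to this choice, so it is
    reproducible independently of any model-fitting seed).  Idempotent:
    re-applying to the retained set excludes nothing further.
    """
    log: list[dict[str, str]] = []
    survivors: list[EyeRecord] = []
    for rec in records:
        reason = _exclusion_reason(rec)
        if reason is None:
            survivors.append(rec)
        else:
            log.append({"patient_id": rec.patient_id, "eye": rec.eye, "reason": reason})

    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[EyeRecord]] = {}
    for rec in survivors:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    retained: list[EyeRecord] = []
    for rec in survivors:
        group = by_patient[rec.patient_id]
        if len(group) == 1:
            retained.append(rec)
    # choose one eye per duplicated patient, in deterministic patient order
    for pid in sorted(p for p, g in by_patient.items() if len(g) > 1):
        group = by_patient[pid]
        keep = group[int(rng.integers(len(group)))]
        retained.append(keep)
        for rec in group:
            if rec is not keep:
                log.append(
                    {"patient_id": pid, "eye": rec.eye, "reason": "fellow eye of included eye"}
                )
    retained.sort(key=lambda r: (r.patient_id, r.eye))
    return retained, log


def write_exclusion_log(log: Sequence[Mapping[str, str]], path: str | Path) -> None:
    """Write the exclusion log as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in log:
            fh.write(json.dumps(dict(entry)) + "\n")


# ---------------------------------------------------------------------------
# decomposition


def _record_vectors(rec: EyeRecord) -> dict[str, PowerVector]:
    """All (device, layer) power vectors of one eye, unmirrored."""
    missing = [
        a
        for a in (
            "iolm_front", "iolm_back", "iolm_tk",
            "casia_front_pre", "casia_back_pre", "casia_real_pre",
            "casia_front_post", "casia_back_post", "casia_real_post",
        )
        if getattr(rec, a) is None
    ]
    if missing:
        raise ValueError(
            f"eye {rec.patient_id}/{rec.eye}: cannot decompose, missing {missing}"
        )
    return {
        "IOLM_front": radii_to_power_vector(rec.iolm_front, FRONT_SURFACE),
        "IOLM_back": radii_to_power_vector(rec.iolm_back, BACK_SURFACE),
        "IOLM_keratometric": radii_to_power_vector(rec.iolm_front, KERATOMETRIC),
        "IOLM_total": radii_to_power_vector(rec.iolm_tk, KERATOMETRIC),
        "CASIA_pre_front": radii_to_power_vector(rec.casia_front_pre, FRONT_SURFACE),
        "CASIA_pre_back": radii_to_power_vector(rec.casia_back_pre, BACK_SURFACE),
        "CASIA_pre_keratometric": radii_to_power_vector(rec.casia_front_pre, KERATOMETRIC),
        "CASIA_pre_total": powers_to_power_vector(rec.casia_real_pre),
        "CASIA_post_front": radii_to_power_vector(rec.casia_front_post, FRONT_SURFACE),
        "CASIA_post_back": radii_to_power_vector(rec.casia_back_post, BACK_SURFACE),
        "CASIA_post_keratometric": radii_to_power_vector(rec.casia_front_post, KERATOMETRIC),
        "CASIA_post_total": powers_to_power_vector(rec.casia_real_post),
    }


def decompose_cohort(records: Sequence[EyeRecord], mirror: bool = True) -> CohortPanel:
    """Decompose every eye into its 3-device x 4-layer power-vector panel.

    Radii-based layers use the front (+0.376), back (-0.040) and keratometric
    (+0.332) index steps; the biometer's total keratometry radii use the
    keratometric index and the tomographer's real power is taken directly in
    dioptres (both reported under the ``total`` layer).  With ``mirror`` on,
    every C45 of an OS eye is sign-flipped once into right-eye orientation.
    """
    rows = []
    index = []
    for rec in records:
        vecs = _record_vectors(rec)
        if mirror and rec.eye == "OS":
            vecs = {k: mirror_for_left_eye(v) for k, v in vecs.items()}
        row: dict[str, object] = {"eye": rec.eye}
        for key, v in vecs.items():
            row[f"{key}_EQ"] = v.EQ
            row[f"{key}_C0"] = v.C0
            row[f"{key}_C45"] = v.C45
        rows.append(row)
        index.append(rec.patient_id)
    cols = ["eye"] + [
        f"{d}_{l}_{c}" for d in DEVICES for l in LAYERS for c in COMPONENTS
    ]
    frame = pd.DataFrame(rows, index=pd.Index(index, name="patient_id"), columns=cols)
    return CohortPanel(frame=frame, mirrored=mirror)


def read_panel_csv(path: str | Path, mirrored: bool = True) -> CohortPanel:
    frame = pd.read_csv(path, index_col="patient_id")
    return CohortPanel(frame=frame, mirrored=mirrored)
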