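"""Synthetic toric-IOL cohort generator.

Emulates the per-eye CSV a clinical centre would export for a cataract
cohort measured with a biometer (IOLM) preoperatively and a tomographer
(CASIA) pre- and postoperatively: paired front/back corneal surfaces across
two devices and two time points, biometry, pupils, quality flags, implanted
toric IOL and postoperative refraction.

The truth model lives in power-vector space, where the analysis is linear:
each eye draws a true front-surface vector (Gaussian EQ, C0, C45 in
right-eye orientation), the back surface follows a front-to-back radius
ratio with jitter plus an extra against-the-rule astigmatism component (so
back astigmatism is correlated with, but not proportional to, the front's —
real corneas carry more back-surface astigmatism than a fixed-ratio
schematic eye implies), and surgery adds a per-eye surgically-induced-
astigmatism (SIA) change.  Device readings are truth + device bias + noise;
derived layers (keratometric, total/real power) are computed from the
device's own front/back readings, total power as the thin-lens sum.
Vectors are converted back to meridional radii/axes by inverting the
decomposition, with left-eye C45 signs un-mirrored into raw axes.

An optional linear teacher overrides the postoperative real-power
astigmatism with ``A x + b + noise`` of the preoperative IOLM keratometric
components, giving a known ground truth for predictor-recovery tests.

Default parameters are the study conditions of the emulated cohort
(marginal means/SDs of the preoperative panels; bias/SIA structure from the
paired difference panels); they are configuration, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cohort_io import EyeRecord
from .power_vectors import (
    BACK_SURFACE,
    FRONT_SURFACE,
    KERATOMETRIC,
    PowerVector,
    RefractionRecord,
    TIOLRecord,
    power_vector_to_polar,
    power_vector_to_radii,
)

__all__ = ["LinearTeacher", "SyntheticConfig", "generate_cohort", "inject_quality_issues"]

_LIOU_BRENNAN_RATIO = 7.77 / 6.4  # front-to-back radius ratio of the schematic eye


@dataclass(frozen=True)
class LinearTeacher:
    """Known linear map from preop IOLM keratometric astigmatism to postop
    real-power astigmatism, for parameter-recovery experiments."""

    matrix: tuple[tuple[float, float], tuple[float, float]]
    intercept: tuple[float, float]
    residual_sd: float = 0.3


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults are the emulated study conditions.

    Power-vector parameters are (mean, SD) pairs in dioptres, biometry in mm,
    all in right-eye orientation.  Device biases/noise are (EQ, C0, C45)
    triples in power-vector space.
    """

    n_eyes: int = 88
    seed: int = 0
    left_eye_fraction: float = 39 / 88
    both_eyes_fraction: float = 0.1  # fraction of patients contributing two eyes

    # biometry (mean, sd)
    age: tuple[float, float] = (72.0, 9.0)
    AL: tuple[float, float] = (24.1154, 1.6258)
    CCT: tuple[float, float] = (0.5574, 0.0368)
    ACD: tuple[float, float] = (3.1882, 0.3936)
    LT: tuple[float, float] = (4.6684, 0.5250)

    # true preoperative front surface, power-vector space
    front_eq: tuple[float, float] = (48.5266, 1.7750)
    front_c0: tuple[float, float] = (0.8859, 1.7477)
    front_c45: tuple[float, float] = (-0.0397, 0.9862)

    # back surface: radius-ratio model plus extra astigmatism
    radius_ratio: tuple[float, float] = (_LIOU_BRENNAN_RATIO, 0.015)
    back_eq_jitter_sd: float = 0.05
    back_extra_c0: tuple[float, float] = (-0.1920, 0.12)
    back_extra_c45: tuple[float, float] = (-0.0327, 0.09)

    # device biases relative to truth (EQ, C0, C45); tomographer anatomically unbiased
    iolm_front_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    iolm_back_bias: tuple[float, float, float] = (0.4778, -0.0078, -0.0147)
    casia_front_bias: tuple[float, float, float] = (0.1392, -0.0745, 0.0715)
    casia_back_bias: tuple[float, float, float] = (0.0865, 0.0, 0.0)

    # measurement noise SDs (EQ, C0, C45), identical pre/post for the tomographer
    iolm_front_noise: tuple[float, float, float] = (0.10, 0.15, 0.12)
    iolm_back_noise: tuple[float, float, float] = (0.03, 0.04, 0.04)
    casia_front_noise: tuple[float, float, float] = (0.10, 0.15, 0.12)
    casia_back_noise: tuple[float, float, float] = (0.03, 0.04, 0.04)

    # surgically induced change of the true surfaces, mean and per-eye SD
    sia_front_mean: tuple[float, float, float] = (-0.0297, -0.0049, -0.0594)
    sia_front_sd: tuple[float, float, float] = (0.187, 0.333, 0.269)
    sia_back_mean: tuple[float, float, float] = (0.0422, 0.0032, 0.0111)
    sia_back_sd: tuple[float, float, float] = (0.053, 0.036, 0.043)

    # pupils (mm)
    pupil_mean: float = 3.2
    pupil_sd: float = 0.6
    pupil_change_sd: float = 0.35
    pupil_clip: tuple[float, float] = (2.0, 5.2)

    # quality-issue injection rates (used by inject_quality_issues)
    flag_rate: float = 0.05
    missing_rate: float = 0.05
    mydriasis_rate: float = 0.05
    pupil_change_rate: float = 0.05

    teacher: LinearTeacher | None = None

    def __post_init__(self) -> None:
        for name in ("left_eye_fraction", "both_eyes_fraction", "flag_rate",
                     "missing_rate", "mydriasis_rate", "pupil_change_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("age", "AL", "CCT", "ACD", "LT", "front_eq", "front_c0",
                     "front_c45", "radius_ratio", "back_extra_c0", "back_extra_c45"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be >= 0")
        for name in ("iolm_front_noise", "iolm_back_noise", "casia_front_noise",
                     "casia_back_noise", "sia_front_sd", "sia_back_sd"):
            if any(s < 0 for s in getattr(self, name)):
                raise ValueError(f"{name} SDs must be >= 0")


def _draw_pv(rng: np.random.Generator, truth: PowerVector,
             bias: Sequence[float], noise: Sequence[float]) -> PowerVector:
    return PowerVector(
        truth.EQ + bias[0] + rng.normal(0.0, noise[0]),
        truth.C0 + bias[1] + rng.normal(0.0, noise[1]),
        truth.C45 + bias[2] + rng.normal(0.0, noise[2]),
    )


def _pv_triplet(v: PowerVector) -> list[float]:
    return [v.EQ, v.C0, v.C45]


def _assign_eyes(cfg: SyntheticConfig, rng: np.random.Generator) -> list[tuple[str, str]]:
    """(patient_id, eye) slots; some patients contribute both eyes."""
    slots: list[tuple[str, str]] = []
    pid = 0
    while len(slots) < cfg.n_eyes:
        pid += 1
        name = f"P{pid:04d}"
        if cfg.n_eyes - len(slots) >= 2 and rng.random() < cfg.both_eyes_fraction:
            slots.append((name, "OD"))
            slots.append((name, "OS"))
        else:
            eye = "OS" if rng.random() < cfg.left_eye_fraction else "OD"
            slots.append((name, eye))
    return slots


def generate_cohort(cfg: SyntheticConfig) -> tuple[list[EyeRecord], dict]:
    """Generate a cohort and its ground-truth sidecar.

    The sidecar carries, per eye, the true (right-eye-oriented) front/back
    preoperative and postoperative power vectors and, with a teacher, the
    teacher parameters — everything a recovery test needs.  Fully
    deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[EyeRecord] = []
    truth_eyes: dict[str, dict] = {}

    for patient_id, eye in _assign_eyes(cfg, rng):
        for _attempt in range(100):
            try:
                rec, truth = _generate_eye(cfg, rng, patient_id, eye)
                break
            except ValueError:  # infeasible radii; redraw
                continue
        else:
            raise RuntimeError("could not generate feasible radii in 100 attempts")
        records.append(rec)
        truth_eyes[f"{patient_id}/{eye}"] = truth

    sidecar = {
        "seed": cfg.seed,
        "n_eyes": cfg.n_eyes,
        "teacher": None
        if cfg.teacher is None
        else {
            "matrix": [list(r) for r in cfg.teacher.matrix],
            "intercept": list(cfg.teacher.intercept),
            "residual_sd": cfg.teacher.residual_sd,
        },
        "eyes": truth_eyes,
    }
    return records, sidecar


def _generate_eye(
    cfg: SyntheticConfig, rng: np.random.Generator, patient_id: str, eye: str
) -> tuple[EyeRecord, dict]:
    # truth, right-eye orientation
    front = PowerVector(
        rng.normal(*cfg.front_eq), rng.normal(*cfg.front_c0), rng.normal(*cfg.front_c45)
    )
    ratio = rng.normal(*cfg.radius_ratio)
    scale = -(abs(BACK_SURFACE.delta_n) / FRONT_SURFACE.delta_n) * ratio
    back = PowerVector(
        front.EQ * scale + rng.normal(0.0, cfg.back_eq_jitter_sd),
        front.C0 * scale + rng.normal(*cfg.back_extra_c0),
        front.C45 * scale + rng.normal(*cfg.back_extra_c45),
    )
    sia_front = PowerVector(*(rng.normal(m, s) for m, s in
                              zip(cfg.sia_front_mean, cfg.sia_front_sd)))
    sia_back = PowerVector(*(rng.normal(m, s) for m, s in
                             zip(cfg.sia_back_mean, cfg.sia_back_sd)))
    front_post = front + sia_front
    back_post = back + sia_back

    # device readings in power-vector space (right-eye orientation)
    iolm_front = _draw_pv(rng, front, cfg.iolm_front_bias, cfg.iolm_front_noise)
    iolm_back = _draw_pv(rng, back, cfg.iolm_back_bias, cfg.iolm_back_noise)
    casia_front_pre = _draw_pv(rng, front, cfg.casia_front_bias, cfg.casia_front_noise)
    casia_back_pre = _draw_pv(rng, back, cfg.casia_back_bias, cfg.casia_back_noise)
    casia_front_post = _draw_pv(rng, front_post, cfg.casia_front_bias, cfg.casia_front_noise)
    casia_back_post = _draw_pv(rng, back_post, cfg.casia_back_bias, cfg.casia_back_noise)

    iolm_tk = iolm_front + iolm_back  # thin-lens total power
    casia_real_pre = casia_front_pre + casia_back_pre
    casia_real_post = casia_front_post + casia_back_post

    if cfg.teacher is not None:
        kerat_scale = KERATOMETRIC.delta_n / FRONT_SURFACE.delta_n
        kx = np.array([iolm_front.C0, iolm_front.C45]) * kerat_scale
        a = np.asarray(cfg.teacher.matrix, dtype=float)
        b = np.asarray(cfg.teacher.intercept, dtype=float)
        astig = a @ kx + b + rng.normal(0.0, cfg.teacher.residual_sd, size=2)
        casia_real_post = PowerVector(casia_real_post.EQ, astig[0], astig[1])

    vectors = {
        "iolm_front": iolm_front,
        "iolm_back": iolm_back,
        "iolm_tk": iolm_tk,
        "casia_front_pre": casia_front_pre,
        "casia_back_pre": casia_back_pre,
        "casia_front_post": casia_front_post,
        "casia_back_post": casia_back_post,
        "casia_real_pre": casia_real_pre,
        "casia_real_post": casia_real_post,
    }
    if eye == "OS":  # un-mirror into raw left-eye axes
        vectors = {k: v.mirror() for k, v in vectors.items()}

    pupil_pre = float(np.clip(rng.normal(cfg.pupil_mean, cfg.pupil_sd), *cfg.pupil_clip))
    pupil_post = float(
        np.clip(pupil_pre + rng.normal(0.0, cfg.pupil_change_sd), *cfg.pupil_clip)
    )

    real_pre_polar = power_vector_to_polar(vectors["casia_real_pre"])
    cyl_pre = real_pre_polar.cylinder
    tiol = TIOLRecord(
        IOLP=float(np.clip(round(rng.normal(21.0, 2.5) * 2.0) / 2.0, 6.0, 34.0)),
        IOLT=float(np.clip(round(1.46 * cyl_pre * 2.0) / 2.0, 1.0, 6.0)),
        IOLA=real_pre_polar.A_steep,
    )
    refraction = RefractionRecord(
        REFS=round(rng.normal(-0.2, 0.3) * 4.0) / 4.0,
        REFC=-abs(round(rng.normal(0.0, 0.3) * 4.0) / 4.0),
        REFA=float(rng.integers(0, 180)),
    )

    rec = EyeRecord(
        patient_id=patient_id,
        eye=eye,
        age=float(rng.normal(*cfg.age)),
        AL=float(rng.normal(*cfg.AL)),
        CCT=float(rng.normal(*cfg.CCT)),
        ACD=float(rng.normal(*cfg.ACD)),
        LT=float(rng.normal(*cfg.LT)),
        pupil_pre=pupil_pre,
        pupil_post=pupil_post,
        iolm_front=power_vector_to_radii(vectors["iolm_front"], FRONT_SURFACE),
        iolm_back=power_vector_to_radii(vectors["iolm_back"], BACK_SURFACE),
        iolm_tk=power_vector_to_radii(vectors["iolm_tk"], KERATOMETRIC),
        casia_front_pre=power_vector_to_radii(vectors["casia_front_pre"], FRONT_SURFACE),
        casia_back_pre=power_vector_to_radii(vectors["casia_back_pre"], BACK_SURFACE),
        casia_front_post=power_vector_to_radii(vectors["casia_front_post"], FRONT_SURFACE),
        casia_back_post=power_vector_to_radii(vectors["casia_back_post"], BACK_SURFACE),
        casia_real_pre=power_vector_to_polar(vectors["casia_real_pre"]),
        casia_real_post=power_vector_to_polar(vectors["casia_real_post"]),
        tiol=tiol,
        refraction_post=refraction,
    )
    truth = {
        "eye": eye,
        "front_pre": _pv_triplet(front),
        "back_pre": _pv_triplet(back),
        "front_post": _pv_triplet(front_post),
        "back_post": _pv_triplet(back_post),
        "sia_front": _pv_triplet(sia_front),
        "sia_back": _pv_triplet(sia_back),
    }
    return rec, truth


def inject_quality_issues(
    records: Sequence[EyeRecord], cfg: SyntheticConfig, seed: int | None = None
) -> tuple[list[EyeRecord], dict[str, list[str]]]:
    """Corrupt a generated cohort with the defects the exclusion filter targets.

    Independently per eye: a 'Warning'/'Failed' quality flag on a random
    measurement group, a missing measurement, a mydriatic pupil (> 5.5 mm),
    or a pre-to-post pupil change > 1.5 mm, each at its configured rate.
    Returns fresh records plus a sidecar listing the affected eye ids per
    issue.  Defaults to a generator derived from ``cfg.seed`` so the
    corruption is reproducible yet independent of the cohort draw.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    flag_groups = ("IOLM_K", "IOLM_TK", "IOLM_BACK", "IOLM_BIO", "CASIA_PRE", "CASIA_POST")
    missing_attrs = (
        "iolm_front", "iolm_back", "iolm_tk", "AL", "CCT", "ACD", "LT",
        "casia_front_pre", "casia_back_pre", "casia_real_pre",
        "casia_front_post", "casia_back_post", "casia_real_post",
    )
    sidecar: dict[str, list[str]] = {
        "flagged": [], "missing": [], "mydriasis": [], "pupil_change": []
    }
    out: list[EyeRecord] = []
    for rec in records:
        rec = replace(rec, flags=dict(rec.flags))
        eid = f"{rec.patient_id}/{rec.eye}"
        if rng.random() < cfg.flag_rate:
            grp = flag_groups[int(rng.integers(len(flag_groups)))]
            rec.flags[grp] = "Warning" if rng.random() < 0.5 else "Failed"
            sidecar["flagged"].append(eid)
        if rng.random() < cfg.missing_rate:
            attr = missing_attrs[int(rng.integers(len(missing_attrs)))]
            rec = replace(rec, **{attr: None})
            sidecar["missing"].append(eid)
        if rng.random() < cfg.mydriasis_rate:
            which = "pupil_pre" if rng.random() < 0.5 else "pupil_post"
            rec = replace(rec, **{which: float(rng.uniform(5.6, 7.5))})
            sidecar["mydriasis"].append(eid)
        if rng.random() < cfg.pupil_change_rate:
            rec = replace(
                rec,
                pupil_post=(rec.pupil_pre or 3.0) + float(rng.uniform(1.6, 2.5)),
            )
            sidecar["pupil_change"].append(eid)
        out.append(rec)
    return out, sidecar
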