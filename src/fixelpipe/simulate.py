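"""Synthetic longitudinal cohort generator with known ground truth.

Emulates a two-visit observational MS imaging study: a shared fixel template
with 20 white-matter tracts, healthy controls (HC) and three patient
phenotypes (RRMS, SPMS, PPMS) with phenotype- and tract-specific fibre
density (FD) and fibre cross-section (FC) deficits at baseline, annual
fractional change between visits, lesion voxel masks with tract-weighted
placement, covariates, normalized brain volumes, EDSS, and seven
cognitive-domain raw scores linked to white-matter damage.

Every random draw flows from one integer seed through named substreams, so
identical (config, seed) pairs give byte-identical cohorts and individual
stages can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .template import TRACT_NAMES, FixelTemplate

GROUPS = ("HC", "RRMS", "SPMS", "PPMS")
PATIENT_GROUPS = ("RRMS", "SPMS", "PPMS")
TREATMENTS = ("IFN", "GA", "NTZ", "other", "none")
N_DOMAINS = 7
DOMAIN_NAMES = (
    "verbal_memory", "verbal_fluency", "processing_speed",
    "visuospatial_memory", "attention", "working_memory", "executive",
)

# Named substreams of the master seed (template, subjects, noise, dropout...).
_STAGE_IDS = {
    "template": 1, "covariates": 2, "fd": 3, "fc": 4, "noise": 5,
    "dropout": 6, "lesions": 7, "cognition": 8, "clinical": 9,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng((int(seed), _STAGE_IDS[stage]))


# Per-tract emphasis of microstructural (FD) damage: cingulum most affected,
# then SLF/ILF; corticospinal least, mirroring the reported spatial pattern.
_FD_TRACT_WEIGHT = {
    "ATR_L": 0.9, "ATR_R": 0.9, "CGC_L": 1.4, "CGC_R": 1.4,
    "CGH_L": 1.45, "CGH_R": 1.45, "CST_L": 0.7, "CST_R": 0.7,
    "Fmajor": 0.95, "Fminor": 0.85, "IFOF_L": 1.0, "IFOF_R": 1.0,
    "ILF_L": 1.1, "ILF_R": 1.1, "SLF_L": 1.2, "SLF_R": 1.2,
    "SLFT_L": 1.15, "SLFT_R": 1.15, "UNC_L": 1.0, "UNC_R": 1.0,
}
# Macrostructural (FC) damage concentrates in CST, cingulum and SLF.
_FC_TRACT_WEIGHT = {
    "ATR_L": 0.8, "ATR_R": 0.8, "CGC_L": 1.3, "CGC_R": 1.3,
    "CGH_L": 1.0, "CGH_R": 1.0, "CST_L": 1.4, "CST_R": 1.4,
    "Fmajor": 0.9, "Fminor": 1.0, "IFOF_L": 0.9, "IFOF_R": 0.9,
    "ILF_L": 0.9, "ILF_R": 0.9, "SLF_L": 1.3, "SLF_R": 1.3,
    "SLFT_L": 1.2, "SLFT_R": 1.2, "UNC_L": 0.8, "UNC_R": 0.8,
}


def _scaled(base: float, weights: dict[str, float]) -> dict[str, float]:
    return {t: base * weights[t] for t in TRACT_NAMES}


@dataclass
class GroupParams:
    """Per-group cohort structure and effect sizes.

    Fractional deficits are applied multiplicatively at baseline
    (``mean_group = mean_HC * (1 - deficit)``); slopes are annual fractional
    change between the two visits.
    """

    size: int
    followup_fraction: float
    interval_mean: float
    interval_sd: float
    age_mean: float
    age_sd: float
    female_fraction: float
    education_high_fraction: float
    fd_deficit: dict[str, float] = field(default_factory=dict)
    fc_deficit: dict[str, float] = field(default_factory=dict)
    fd_slope: dict[str, float] = field(default_factory=dict)
    fc_slope: dict[str, float] = field(default_factory=dict)
    duration_mean: float | None = None  # symptom duration, years (patients)
    duration_sd: float | None = None
    edss_intercept: float | None = None
    edss_annual_change: float = 0.0
    lesion_count_mean: float = 0.0
    lesion_load_per_voxel_ml: float = 0.45  # printed lesion load scale
    # Normalized volume means/SDs (mL): NBV, NWMV, NCGMV, NDGMV.
    volume_means: dict[str, float] = field(default_factory=dict)
    volume_sds: dict[str, float] = field(default_factory=dict)
    volume_annual_pct: float = -0.1  # annual volume change, % of baseline


@dataclass
class CognitionModel:
    """Link from white-matter damage to the 7 cognitive domain raw scores.

    ``score_d = base_d + age_coef*(age-45) + sex_coef*sex + edu_coef*edu
    + loading_d * (meanFDC - ref_mean)/ref_sd + noise``.
    """

    loadings: tuple[float, ...] = (0.44, 0.36, 0.48, 0.40, 0.40, 0.36, 0.40)
    domain_base: tuple[float, ...] = (0.0,) * N_DOMAINS
    domain_noise_sd: float = 0.80
    age_coef: float = -0.02
    sex_coef: float = -0.10   # sex coded 1 = male
    edu_coef: float = 0.30    # education coded 1 = high
    fdc_ref_mean: float = 0.5
    fdc_ref_sd: float = 0.032


@dataclass
class EdssModel:
    """EDSS linear predictor: group intercept + duration + damage + noise."""

    duration_coef: float = 0.03
    damage_coef: float = 0.40  # per SD of FDC damage (positive = worse)
    noise_sd: float = 1.0
    followup_noise_sd: float = 0.3


@dataclass
class SimulationConfig:
    """Full description of the simulated study conditions.

    Defaults emulate the printed cohort structure of the emulated study:
    95 HC / 239 RRMS / 52 SPMS / 36 PPMS at baseline (327 patients), 71% of
    patients and 64% of controls retained at the ~5-year second visit
    (intervals 4.81 +/- 0.85 y patients, 5.43 +/- 1.07 y controls), SPMS
    carrying the heaviest white-matter damage and PPMS ~ RRMS.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 1.25
    streamlines_per_tract: int = 50
    hc_tract_fd_mean: dict[str, float] = field(
        default_factory=lambda: {
            t: 0.5 + 0.05 * (2 * i / (len(TRACT_NAMES) - 1) - 1)
            for i, t in enumerate(TRACT_NAMES)
        }
    )
    between_subject_sd_fd: float = 0.05  # fractional, shared across tracts
    between_subject_sd_fc: float = 0.04
    measurement_sd_fd: float = 0.02      # per-fixel additive, FD units
    measurement_sd_fc: float = 0.02      # per-fixel fractional on FC
    lesion_attenuation: float = 0.6      # pull of lesioned-fixel FD to HC mean
    lesion_tract_weights: dict[str, float] = field(
        default_factory=lambda: dict(_FD_TRACT_WEIGHT)
    )
    groups: dict[str, GroupParams] = field(default_factory=lambda: {
        "HC": GroupParams(
            size=95, followup_fraction=61 / 95,
            interval_mean=5.43, interval_sd=1.07,
            age_mean=45.70, age_sd=10.35,
            female_fraction=55 / 95, education_high_fraction=56 / 95,
            fd_deficit=_scaled(0.0, _FD_TRACT_WEIGHT),
            fc_deficit=_scaled(0.0, _FC_TRACT_WEIGHT),
            fd_slope=_scaled(0.0, _FD_TRACT_WEIGHT),
            fc_slope=_scaled(0.0, _FC_TRACT_WEIGHT),
            volume_means={"NBV": 1517.23, "NWMV": 697.73,
                          "NCGMV": 780.39, "NDGMV": 62.95},
            volume_sds={"NBV": 66.67, "NWMV": 30.82,
                        "NCGMV": 51.65, "NDGMV": 3.73},
            volume_annual_pct=-0.1,
        ),
        "RRMS": GroupParams(
            size=239, followup_fraction=233 / 327,
            interval_mean=4.81, interval_sd=0.85,
            age_mean=47.0, age_sd=10.9,
            female_fraction=0.70, education_high_fraction=0.46,
            fd_deficit=_scaled(0.06, _FD_TRACT_WEIGHT),
            fc_deficit=_scaled(0.030, _FC_TRACT_WEIGHT),
            fd_slope=_scaled(-0.0015, _FD_TRACT_WEIGHT),
            fc_slope=_scaled(-0.0005, _FC_TRACT_WEIGHT),
            duration_mean=13.5, duration_sd=8.0,
            edss_intercept=2.5, edss_annual_change=0.05,
            lesion_count_mean=25.0,
            volume_means={"NBV": 1465.0, "NWMV": 672.0,
                          "NCGMV": 752.0, "NDGMV": 57.0},
            volume_sds={"NBV": 72.0, "NWMV": 33.0,
                        "NCGMV": 50.0, "NDGMV": 6.0},
            volume_annual_pct=-0.25,
        ),
        "SPMS": GroupParams(
            size=52, followup_fraction=233 / 327,
            interval_mean=4.81, interval_sd=0.85,
            age_mean=53.0, age_sd=9.5,
            female_fraction=0.62, education_high_fraction=0.42,
            fd_deficit=_scaled(0.12, _FD_TRACT_WEIGHT),
            fc_deficit=_scaled(0.070, _FC_TRACT_WEIGHT),
            fd_slope=_scaled(-0.005, _FD_TRACT_WEIGHT),
            fc_slope=_scaled(-0.003, _FC_TRACT_WEIGHT),
            duration_mean=19.0, duration_sd=8.0,
            edss_intercept=5.5, edss_annual_change=0.15,
            lesion_count_mean=45.0,
            volume_means={"NBV": 1405.0, "NWMV": 650.0,
                          "NCGMV": 730.0, "NDGMV": 52.0},
            volume_sds={"NBV": 78.0, "NWMV": 35.0,
                        "NCGMV": 52.0, "NDGMV": 6.5},
            volume_annual_pct=-0.4,
        ),
        "PPMS": GroupParams(
            size=36, followup_fraction=233 / 327,
            interval_mean=4.81, interval_sd=0.85,
            age_mean=51.0, age_sd=9.5,
            female_fraction=0.55, education_high_fraction=0.44,
            fd_deficit=_scaled(0.065, _FD_TRACT_WEIGHT),
            fc_deficit=_scaled(0.035, _FC_TRACT_WEIGHT),
            fd_slope=_scaled(-0.004, _FD_TRACT_WEIGHT),
            fc_slope=_scaled(-0.002, _FC_TRACT_WEIGHT),
            duration_mean=13.0, duration_sd=8.0,
            edss_intercept=5.0, edss_annual_change=0.12,
            lesion_count_mean=35.0,
            volume_means={"NBV": 1430.0, "NWMV": 660.0,
                          "NCGMV": 740.0, "NDGMV": 54.0},
            volume_sds={"NBV": 78.0, "NWMV": 35.0,
                        "NCGMV": 52.0, "NDGMV": 6.5},
            volume_annual_pct=-0.35,
        ),
    })
    head_scale_mean: float = 1.0
    head_scale_sd: float = 0.05
    treatment_fractions: dict[str, float] = field(default_factory=lambda: {
        "IFN": 72 / 327, "GA": 16 / 327, "NTZ": 22 / 327,
        "other": 6 / 327, "none": 211 / 327,
    })
    cognition: CognitionModel = field(default_factory=CognitionModel)
    edss: EdssModel = field(default_factory=EdssModel)
    seed: int = 0

    def validate(self) -> None:
        for g, p in self.groups.items():
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group label {g!r}")
            if p.size < 0:
                raise ConfigurationError(f"negative group size for {g}")
            if not 0.0 <= p.followup_fraction <= 1.0:
                raise ConfigurationError(f"followup_fraction out of [0,1] for {g}")
            for d in (p.fd_deficit, p.fc_deficit):
                for t, v in d.items():
                    if not 0.0 <= v < 1.0:
                        raise ConfigurationError(
                            f"fractional deficit {v} for {g}/{t} not in [0,1)"
                        )
        for sd in (self.between_subject_sd_fd, self.between_subject_sd_fc,
                   self.measurement_sd_fd, self.measurement_sd_fc):
            if sd < 0:
                raise ConfigurationError("noise SDs must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SubjectFixelData:
    """Per-subject, per-timepoint fixel data on the shared template."""

    subject_id: str
    timepoint: int
    fd: np.ndarray               # (F,) fibre density, >= 0
    jacobians: np.ndarray        # (F, 3, 3) subject->template warp Jacobians
    fc: np.ndarray | None = None  # optional precomputed FC


@dataclass
class CohortDataset:
    """Simulated study: template, subject table, fixel data and ground truth."""

    template: FixelTemplate
    subjects: pd.DataFrame       # one row per subject x timepoint
    fixel_data: dict[tuple[str, int], SubjectFixelData]
    cognition_raw: pd.DataFrame  # subject_id, timepoint, 7 raw domain scores
    lesions: dict[str, np.ndarray]  # subject_id -> (L, 3) lesioned voxels
    ground_truth: dict
    config: SimulationConfig


# --------------------------------------------------------------------------
# Template generation


def generate_template(config: SimulationConfig | None = None,
                      seed: int = 0) -> FixelTemplate:
    """Build the shared fixel template with 20 labelled bundles.

    Bundles are laid out as axis-aligned voxel paths (7 along x, 7 along y,
    6 along z) with engineered crossings: one two-fixel crossing voxel and
    six three-fixel crossing voxels where an x-, y- and z-bundle meet. Each
    bundle contributes one fixel per voxel along its path; streamlines are
    contiguous sub-paths of the bundle (the first covers the full path).
    """
    config = config or SimulationConfig()
    nx, ny, nz = config.grid_shape
    if min(nx, ny, nz) < 12:
        raise ConfigurationError(
            "grid too small to embed 20 disjoint-labelled bundle paths; "
            "need at least 12 voxels per axis"
        )
    rng = _rng(seed, "template")
    lo = 2
    voxels: list[tuple[int, int, int]] = []
    directions: list[tuple[float, float, float]] = []
    tract_of: list[str] = []
    paths: dict[str, list[int]] = {}

    def add_path(tract: str, vox_list, direction) -> None:
        ids = []
        for v in vox_list:
            ids.append(len(voxels))
            voxels.append(v)
            directions.append(direction)
            tract_of.append(tract)
        paths[tract] = ids

    x_tracts = TRACT_NAMES[:7]
    y_tracts = TRACT_NAMES[7:14]
    z_tracts = TRACT_NAMES[14:]
    for i, t in enumerate(x_tracts):
        a = lo + i
        add_path(t, [(x, a, a) for x in range(lo, nx - 3 + 1)], (1.0, 0.0, 0.0))
    for j, t in enumerate(y_tracts):
        b = lo + j
        add_path(t, [(b, y, b) for y in range(lo, ny - 3 + 1)], (0.0, 1.0, 0.0))
    for k, t in enumerate(z_tracts):
        c = lo + 1 + k
        add_path(t, [(c, c, z) for z in range(lo, nz - 3 + 1)], (0.0, 0.0, 1.0))

    streamlines: list[np.ndarray] = []
    for t in TRACT_NAMES:
        ids = np.asarray(paths[t], dtype=np.int64)
        L = len(ids)
        streamlines.append(ids.copy())  # one full-length streamline
        for _ in range(config.streamlines_per_tract - 1):
            span = int(rng.integers(max(2, (6 * L) // 10), L + 1))
            start = int(rng.integers(0, L - span + 1))
            streamlines.append(ids[start:start + span].copy())

    template = FixelTemplate(
        grid_shape=(nx, ny, nz),
        voxel_size_mm=config.voxel_size_mm,
        voxels=np.asarray(voxels, dtype=np.int64),
        directions=np.asarray(directions, dtype=float),
        tracts=np.asarray(tract_of, dtype=object),
        streamlines=streamlines,
    )
    template.validate()
    return template


# --------------------------------------------------------------------------
# Cohort generation


def _round_half(x: np.ndarray) -> np.ndarray:
    return np.round(x * 2.0) / 2.0


def _jacobians_from_fc(fc: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Affine warps realizing a target FC exactly.

    For each fixel, J = s*I + (1-s)*v v^T with s = sqrt(FC): the fibre axis v
    is preserved (|Jv| = 1) while the perpendicular plane scales by s, so
    det(J)/|Jv| = s^2 = FC in closed form.
    """
    if np.any(fc <= 0):
        raise ConfigurationError("intended FC must be positive")
    s = np.sqrt(fc)                      # (n, F)
    eye = np.eye(3)
    vvt = np.einsum("fi,fj->fij", directions, directions)  # (F, 3, 3)
    return (s[..., None, None] * eye[None, None]
            + (1.0 - s)[..., None, None] * vvt[None])


def generate_cohort(config: SimulationConfig | None = None,
                    seed: int | None = None) -> CohortDataset:
    """Simulate the full two-visit cohort under *config*.

    Returns a :class:`CohortDataset` whose ``ground_truth`` block echoes the
    configured per-tract deficits and slopes for recovery tests.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    template = generate_template(config, seed)
    F = template.n_fixels
    tract_idx = {t: template.tract_fixel_ids(t) for t in TRACT_NAMES}
    fixel_tract_pos = np.empty(F, dtype=np.int64)  # tract index per fixel
    for ti, t in enumerate(TRACT_NAMES):
        fixel_tract_pos[tract_idx[t]] = ti
    hc_mean_by_tract = np.array(
        [config.hc_tract_fd_mean[t] for t in TRACT_NAMES])
    hc_mean_fixel = hc_mean_by_tract[fixel_tract_pos]  # (F,)

    rng_cov = _rng(seed, "covariates")
    rng_fd = _rng(seed, "fd")
    rng_fc = _rng(seed, "fc")
    rng_noise = _rng(seed, "noise")
    rng_drop = _rng(seed, "dropout")
    rng_les = _rng(seed, "lesions")
    rng_cog = _rng(seed, "cognition")
    rng_clin = _rng(seed, "clinical")

    cog = config.cognition
    loadings = np.asarray(cog.loadings, dtype=float)
    base = np.asarray(cog.domain_base, dtype=float)

    lesion_w_by_tract = np.array(
        [config.lesion_tract_weights.get(t, 1.0) for t in TRACT_NAMES])
    lesion_w_fixel = lesion_w_by_tract[fixel_tract_pos]
    # candidate lesion voxels = union of bundle voxels, weighted by the max
    # lesion preference among the fixels sharing that voxel
    vox_keys = [tuple(v) for v in template.voxels]
    vox_weight: dict[tuple[int, int, int], float] = {}
    for kvox, w in zip(vox_keys, lesion_w_fixel):
        vox_weight[kvox] = max(vox_weight.get(kvox, 0.0), float(w))
    cand_voxels = np.array(sorted(vox_weight), dtype=np.int64)
    cand_w = np.array([vox_weight[tuple(v)] for v in cand_voxels])
    cand_p = cand_w / cand_w.sum()

    subject_rows: list[dict] = []
    cog_rows: list[dict] = []
    fixel_data: dict[tuple[str, int], SubjectFixelData] = {}
    lesions: dict[str, np.ndarray] = {}

    for group in GROUPS:
        if group not in config.groups:
            continue
        p = config.groups[group]
        n = p.size
        if n == 0:
            continue
        is_patient = group in PATIENT_GROUPS
        age = rng_cov.normal(p.age_mean, p.age_sd, n).clip(18, 90)
        sex = (rng_cov.random(n) >= p.female_fraction).astype(int)  # 1 = M
        edu = (rng_cov.random(n) < p.education_high_fraction).astype(int)
        head = rng_cov.normal(config.head_scale_mean, config.head_scale_sd, n)
        duration = (rng_cov.normal(p.duration_mean, p.duration_sd, n)
                    .clip(0.5, None) if is_patient else np.full(n, np.nan))
        if is_patient:
            treatment = rng_cov.choice(
                TREATMENTS, size=n,
                p=[config.treatment_fractions[t] for t in TREATMENTS])
        else:
            treatment = np.array(["none"] * n, dtype=object)

        fd_def = np.array([p.fd_deficit.get(t, 0.0) for t in TRACT_NAMES])
        fc_def = np.array([p.fc_deficit.get(t, 0.0) for t in TRACT_NAMES])
        fd_slope = np.array([p.fd_slope.get(t, 0.0) for t in TRACT_NAMES])
        fc_slope = np.array([p.fc_slope.get(t, 0.0) for t in TRACT_NAMES])

        eta_fd = rng_fd.normal(0.0, config.between_subject_sd_fd, n)
        eta_fc = rng_fc.normal(0.0, config.between_subject_sd_fc, n)
        # subject x tract intended means at baseline
        fd_tract_t1 = (hc_mean_by_tract[None] * (1.0 - fd_def)[None]
                       * (1.0 + eta_fd)[:, None])
        fc_tract_t1 = (1.0 - fc_def)[None] * (1.0 + eta_fc)[:, None]
        if np.any(fc_tract_t1 <= 0):
            raise ConfigurationError("intended FC non-positive; lower "
                                     "fc deficits or between-subject SD")

        interval = rng_drop.normal(p.interval_mean, p.interval_sd, n).clip(1.0)
        n_keep = int(round(p.followup_fraction * n))
        keep = np.zeros(n, dtype=bool)
        keep[rng_drop.permutation(n)[:n_keep]] = True

        # lesion masks (patients only)
        lesion_mask_fix = np.zeros((n, F), dtype=bool)
        for i in range(n):
            sid = f"{group}{i + 1:03d}"
            if is_patient and p.lesion_count_mean > 0:
                cnt = min(int(rng_les.poisson(p.lesion_count_mean)),
                          len(cand_voxels))
                sel = rng_les.choice(len(cand_voxels), size=cnt,
                                     replace=False, p=cand_p)
                les_vox = cand_voxels[np.sort(sel)]
            else:
                les_vox = np.empty((0, 3), dtype=np.int64)
            lesions[sid] = les_vox
            if len(les_vox):
                lesion_mask_fix[i] = template.fixels_in_voxels(les_vox)

        lesion_load = np.array([
            len(lesions[f"{group}{i + 1:03d}"]) * p.lesion_load_per_voxel_ml
            for i in range(n)
        ])

        for tp, retained in ((1, np.ones(n, dtype=bool)), (2, keep)):
            if tp == 1:
                fd_tract = fd_tract_t1
                fc_tract = fc_tract_t1
            else:
                fd_tract = fd_tract_t1 * (1.0 + fd_slope[None]
                                          * interval[:, None])
                fc_tract = fc_tract_t1 * (1.0 + fc_slope[None]
                                          * interval[:, None])
                if np.any(fc_tract <= 0):
                    raise ConfigurationError("intended follow-up FC "
                                             "non-positive")
            fd_fix = (fd_tract[:, fixel_tract_pos]
                      + rng_noise.normal(0.0, config.measurement_sd_fd,
                                         (n, F)))
            fd_fix = fd_fix.clip(1e-3)
            # lesioned fixels: group contrast attenuated toward the HC mean
            if config.lesion_attenuation > 0:
                lam = config.lesion_attenuation
                fd_fix = np.where(
                    lesion_mask_fix,
                    fd_fix + lam * (hc_mean_fixel[None] - fd_fix),
                    fd_fix)
            fc_fix = (fc_tract[:, fixel_tract_pos]
                      * (1.0 + rng_noise.normal(0.0, config.measurement_sd_fc,
                                                (n, F))))
            if np.any(fc_fix <= 0):
                raise ConfigurationError("realized FC non-positive; lower "
                                         "measurement_sd_fc")
            jac = _jacobians_from_fc(fc_fix, template.directions)

            mean_fdc = (fd_fix * fc_fix).mean(axis=1)
            z_fdc = (mean_fdc - cog.fdc_ref_mean) / cog.fdc_ref_sd
            age_tp = age if tp == 1 else age + interval
            dom = (base[None]
                   + cog.age_coef * (age_tp - 45.0)[:, None]
                   + cog.sex_coef * sex[:, None]
                   + cog.edu_coef * edu[:, None]
                   + loadings[None] * z_fdc[:, None]
                   + rng_cog.normal(0.0, cog.domain_noise_sd,
                                    (n, N_DOMAINS)))

            if is_patient:
                em = config.edss
                if tp == 1:
                    edss_lin = (p.edss_intercept
                                + em.duration_coef * (duration - 14.0)
                                - em.damage_coef * z_fdc
                                + rng_clin.normal(0.0, em.noise_sd, n))
                    edss = _round_half(edss_lin.clip(0.0, 8.0))
                    edss_t1 = edss
                else:
                    edss_lin = (edss_t1 + p.edss_annual_change * interval
                                + rng_clin.normal(0.0, em.followup_noise_sd,
                                                  n))
                    edss = _round_half(edss_lin.clip(0.0, 8.0))
            else:
                edss = np.full(n, np.nan)

            vols = {}
            for vname in ("NBV", "NWMV", "NCGMV", "NDGMV"):
                if tp == 1:
                    v = rng_clin.normal(p.volume_means[vname],
                                        p.volume_sds[vname], n)
                    # damage-coupled volume loss so cognitive subgroups
                    # reproduce the printed volume gradient
                    v = v + {"NBV": 12.0, "NWMV": 6.0, "NCGMV": 8.0,
                             "NDGMV": 1.2}[vname] * z_fdc.clip(-6, 6)
                    vols[vname] = v
                    if vname == "NBV":
                        vols_t1 = {}
                    vols_t1[vname] = v
                else:
                    v = vols_t1[vname] * (
                        1.0 + p.volume_annual_pct / 100.0 * interval)
                    vols[vname] = v

            for i in range(n):
                if not retained[i]:
                    continue
                sid = f"{group}{i + 1:03d}"
                subject_rows.append({
                    "subject_id": sid, "timepoint": tp, "group": group,
                    "age": float(age_tp[i]), "sex": int(sex[i]),
                    "education_high": int(edu[i]),
                    "head_scale": float(head[i]),
                    "interval_years": float(interval[i]) if tp == 2 else 0.0,
                    "symptom_duration": float(duration[i])
                    if is_patient else np.nan,
                    "treatment": str(treatment[i]),
                    "edss": float(edss[i]) if is_patient else np.nan,
                    "lesion_load": float(lesion_load[i])
                    if is_patient else 0.0,
                    "NBV": float(vols["NBV"][i]),
                    "NWMV": float(vols["NWMV"][i]),
                    "NCGMV": float(vols["NCGMV"][i]),
                    "NDGMV": float(vols["NDGMV"][i]),
                })
                cog_rows.append({
                    "subject_id": sid, "timepoint": tp,
                    **{DOMAIN_NAMES[d]: float(dom[i, d])
                       for d in range(N_DOMAINS)},
                })
                fixel_data[(sid, tp)] = SubjectFixelData(
                    subject_id=sid, timepoint=tp,
                    fd=fd_fix[i].copy(), jacobians=jac[i].copy(),
                    fc=fc_fix[i].copy(),
                )

    subjects = pd.DataFrame(subject_rows)
    cognition_raw = pd.DataFrame(cog_rows)
    ground_truth = {
        "fd_deficit": {g: dict(config.groups[g].fd_deficit)
                       for g in config.groups},
        "fc_deficit": {g: dict(config.groups[g].fc_deficit)
                       for g in config.groups},
        "fd_slope": {g: dict(config.groups[g].fd_slope)
                     for g in config.groups},
        "fc_slope": {g: dict(config.groups[g].fc_slope)
                     for g in config.groups},
        "hc_tract_fd_mean": dict(config.hc_tract_fd_mean),
        "cognition_loadings": list(cog.loadings),
        "seed": int(seed),
    }
    return CohortDataset(
        template=template, subjects=subjects, fixel_data=fixel_data,
        cognition_raw=cognition_raw, lesions=lesions,
        ground_truth=ground_truth, config=config,
    )
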