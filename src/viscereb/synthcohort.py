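"""Synthetic resting-state cohorts with the statistical structure the
analysis assumes.

A cohort is 27 patients and 11 healthy controls.  Each subject carries a
ground-truth 4x4 directed coupling matrix over (PV, SV_L, SV_R, C); latent
neural activity follows the continuous-time linear stochastic system
``dx/dt = A x + w`` integrated by Euler-Maruyama; observed voxel BOLD is the
hemodynamic convolution of the neural state sampled at TR, mixed with
nuisance signals, drift, baseline and white noise.  Patients additionally
carry clinical scores (JOA motor score, ETDRS letter scores per eye) linked
linearly to specific couplings.

Group structure: controls have no coupling between the cerebellum and
either secondary visual cortex; patients have all 12 couplings positive,
with C<->SV_L (both directions) and SV_R->C elevated by a configurable
group effect.  Between-subject variability is Gaussian jitter applied to
the non-zero template entries only, re-drawn until the realized matrix is
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg as sla

from .hemo import HrfParams, hrf
from .regions import (
    N_PARAMS,
    OFFDIAG_PAIRS,
    PARAM_NAMES,
    REGIONS,
    is_stable,
    param_index,
    vector_to_matrix,
)
from .signals import NuisanceMatrix, VoxelBlock


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner-side constants of the emulated acquisition."""

    tr_seconds: float = 2.0
    n_volumes: int = 180
    n_drop: int = 10
    voxels_per_roi: int = 30

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.n_drop < self.n_volumes:
            raise ValueError("need 0 <= n_drop < n_volumes")
        if self.voxels_per_roi < 1:
            raise ValueError("voxels_per_roi must be >= 1")


@dataclass
class EffConnParams:
    """Ground-truth couplings: 12 off-diagonal rates (1/s) in the package's
    fixed order plus 4 unitless self log-scalings."""

    offdiag: np.ndarray
    self_log: np.ndarray
    region_order: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        self.offdiag = np.asarray(self.offdiag, dtype=float)
        self.self_log = np.asarray(self.self_log, dtype=float)
        if self.offdiag.shape != (12,) or self.self_log.shape != (4,):
            raise ValueError("offdiag must be length 12, self_log length 4")
        if len(self.region_order) != 4:
            raise ValueError("region_order must have length 4")

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.offdiag, self.self_log])

    @property
    def matrix(self) -> np.ndarray:
        return vector_to_matrix(self.vector)

    def coupling(self, name: str) -> float:
        return float(self.vector[param_index(name)])


@dataclass
class ClinicalRecord:
    joa_pre: float
    bcva_pre_od: float
    bcva_pre_os: float
    bcva_post_od: float
    bcva_post_os: float
    recovery_od: float
    recovery_os: float

    def __post_init__(self) -> None:
        if not np.isclose(self.recovery_od, self.bcva_post_od - self.bcva_pre_od):
            raise ValueError("recovery_od must equal post - pre")
        if not np.isclose(self.recovery_os, self.bcva_post_os - self.bcva_pre_os):
            raise ValueError("recovery_os must equal post - pre")


@dataclass
class SubjectRecord:
    group: str
    true_params: EffConnParams
    voxel_blocks: dict[str, VoxelBlock]
    nuisance: NuisanceMatrix
    seed: int
    clinical: ClinicalRecord | None = None

    def __post_init__(self) -> None:
        lengths = {b.n_time for b in self.voxel_blocks.values()}
        if len(lengths) > 1:
            raise ValueError("voxel blocks disagree on time-axis length")


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

# Template couplings (1/s).  The visual hierarchy is heterogeneous and
# asymmetric - strong feedforward PV -> SV couplings, weak feedback and
# interhemispheric couplings - matching cortical hierarchies; the wide
# between-subject jitter mirrors the broad subject scatter resting-state
# coupling estimates show in practice.  Controls have 0 on all four
# cerebellum <-> secondary-visual entries; patients have those entries
# positive, with C<->SV_L (both directions) and SV_R->C elevated above any
# control value by the configured group effect.  Self-rates are slow
# (about -0.41 1/s, well within the estimation prior's plausible range,
# and the regime where couplings are most identifiable at TR = 2 s) with a
# stronger (more negative) cerebellar self-connection in patients.
_ELEVATED = ("C->SV_L", "SV_L->C", "SV_R->C")
_PATIENT_ONLY_BASELINE = ("C->SV_R",)
_CEREB_SV = ("C->SV_L", "SV_L->C", "C->SV_R", "SV_R->C")

#: Parameter subset carrying the JOA signal (cerebellum-centred, 7 of 16).
JOA_FEATURES: tuple[str, ...] = (
    "self_C", "C->SV_L", "SV_L->C", "C->SV_R", "SV_R->C", "C->PV", "PV->C",
)


@dataclass(frozen=True)
class ClinicalLinkConfig:
    """Linear links from ground-truth couplings to clinical scores.

    Each score is ``mean + sd * (sqrt(r2) * z + sqrt(1-r2) * noise)`` where
    ``z`` is the standardized planted coupling (or combination) and the
    noise is standard normal.  Marginal moments default to the study's
    printed patient table.
    """

    joa_mean: float = 11.8
    joa_sd: float = 1.5
    joa_r2: float = 0.25
    joa_features: tuple[str, ...] = JOA_FEATURES
    bcva_pre_od_mean: float = 75.9
    bcva_pre_od_sd: float = 3.8
    bcva_pre_os_mean: float = 76.1
    bcva_pre_os_sd: float = 3.2
    bcva_r2: float = 0.25
    recovery_od_mean: float = 2.10
    recovery_od_sd: float = 3.1
    recovery_os_mean: float = 2.12
    recovery_os_sd: float = 3.2
    recovery_r2: float = 0.25

    def __post_init__(self) -> None:
        for r2 in (self.joa_r2, self.bcva_r2, self.recovery_r2):
            if not 0.0 <= r2 <= 1.0:
                raise ValueError("link r2 values must lie in [0, 1]")
        unknown = [f for f in self.joa_features if f not in PARAM_NAMES]
        if unknown:
            raise ValueError(f"unknown joa_features: {unknown}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Every knob of the synthetic cohort, stored with each bundle so a
    cohort regenerates bit-identically from (config, master_seed)."""

    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    ff_coupling: float = 0.28           # 1/s, feedforward PV -> SV_L/SV_R
    fb_coupling: float = 0.03           # 1/s, feedback SV -> PV
    inter_sv_coupling: float = 0.03     # 1/s, SV_L <-> SV_R
    pv_to_c_coupling: float = 0.10      # 1/s, PV -> C (both groups)
    c_to_pv_coupling: float = 0.02      # 1/s, C -> PV (both groups)
    c_to_svr_patient: float = 0.03      # 1/s, C -> SV_R (patients only)
    group_effect: float = 0.15          # 1/s, patient elevation on C<->SV_L, SV_R->C
    self_log_base: float = -0.20        # self-rate -0.41 1/s
    self_log_cereb_patient: float = -0.05  # patient cerebellar self-rate -0.48 1/s
    jitter_sd: float = 0.16             # 1/s, between-subject SD of couplings
    jitter_self_sd: float = 0.10        # between-subject SD of self log-scalings
    dt_seconds: float = 0.1             # Euler-Maruyama step
    innov_sd: float = 1.0               # neural innovation SD per sqrt(s)
    noise_sd: float = 0.8               # voxel white-noise SD (signal units)
    voxel_loading_sd: float = 0.2       # spread of positive voxel loadings
    nuisance_beta_sd: float = 0.15      # voxel coefficients on nuisance columns
    drift_slope: float = 0.5            # per-voxel linear drift scale
    baseline: float = 100.0             # scanner-units baseline intensity
    clinical: ClinicalLinkConfig = field(default_factory=ClinicalLinkConfig)
    stability_margin: float = 0.01      # required -max Re eig of realized A

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortBundle:
    subjects: list[SubjectRecord]
    generator_config: GeneratorConfig
    master_seed: int

    @property
    def patients(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "patient"]

    @property
    def controls(self) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == "control"]

    def true_param_matrix(self, group: str | None = None) -> np.ndarray:
        subs = self.subjects if group is None else [
            s for s in self.subjects if s.group == group
        ]
        return np.array([s.true_params.vector for s in subs])


def template_params(group: str, config: GeneratorConfig = GeneratorConfig()) -> EffConnParams:
    """Noise-free group template (the jitter_sd = 0 connectivity)."""
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group label: {group!r}")
    c = config
    off = np.zeros(12)
    for name, value in (
        ("PV->SV_L", c.ff_coupling), ("PV->SV_R", c.ff_coupling),
        ("SV_L->PV", c.fb_coupling), ("SV_R->PV", c.fb_coupling),
        ("SV_L->SV_R", c.inter_sv_coupling), ("SV_R->SV_L", c.inter_sv_coupling),
        ("PV->C", c.pv_to_c_coupling), ("C->PV", c.c_to_pv_coupling),
    ):
        off[param_index(name)] = value
    self_log = np.full(4, c.self_log_base)
    if group == "patient":
        for name in _ELEVATED:
            off[param_index(name)] = c.group_effect
        for name in _PATIENT_ONLY_BASELINE:
            off[param_index(name)] = c.c_to_svr_patient
        self_log[REGIONS.index("C")] = c.self_log_cereb_patient
    return EffConnParams(off, self_log)


def make_connectivity(group: str, jitter_sd: float, seed: int,
                      config: GeneratorConfig = GeneratorConfig(),
                      jitter_self_sd: float | None = None,
                      max_redraws: int = 100,
                      max_shrinks: int = 10) -> EffConnParams:
    """Draw one subject's ground-truth couplings around the group template.

    Gaussian jitter is applied to the template's non-zero off-diagonal
    entries and to all four self log-scalings; structurally absent
    connections stay exactly zero.  Draws failing the stability margin are
    redrawn up to ``max_redraws`` times, after which the jitter SD is
    halved (keeping the sampler unbiased near the template).
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    tmpl = template_params(group, config)
    if jitter_self_sd is None:
        jitter_self_sd = config.jitter_self_sd if jitter_sd > 0 else 0.0
    rng = np.random.default_rng(seed)
    nz = tmpl.offdiag != 0.0
    sd_off, sd_self = float(jitter_sd), float(jitter_self_sd)
    for _ in range(max_shrinks + 1):
        for _ in range(max_redraws):
            off = tmpl.offdiag.copy()
            off[nz] += sd_off * rng.standard_normal(nz.sum())
            self_log = tmpl.self_log + sd_self * rng.standard_normal(4)
            cand = EffConnParams(off, self_log)
            if is_stable(cand.matrix, margin=config.stability_margin):
                return cand
        sd_off, sd_self = sd_off / 2.0, sd_self / 2.0
    raise RuntimeError("failed to draw a stable coupling matrix")


def stationary_cov(a: np.ndarray, innov_sd: float) -> np.ndarray:
    """Stationary covariance of dx/dt = A x + w: solves A S + S A' + q I = 0."""
    q = float(innov_sd) ** 2
    return sla.solve_lyapunov(a, -q * np.eye(a.shape[0]))


def simulate_neural(params: EffConnParams, duration: float, dt: float = 0.1,
                    innov_sd: float = 1.0, seed: int | None = None,
                    x0: np.ndarray | None = None) -> np.ndarray:
    """Euler-Maruyama integration of the latent linear stochastic system.

    Returns the full (4, n_steps) fine-grid state series; no subsampling is
    done here.  With ``x0=None`` and ``innov_sd>0`` the initial state is a
    stationary draw, so no burn-in is required.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = params.matrix
    if not is_stable(a):
        raise ValueError("coupling matrix is unstable (eigenvalue with Re >= 0)")
    n = int(np.round(duration / dt))
    rng = np.random.default_rng(seed)
    x = np.zeros((4, n))
    if x0 is not None:
        x[:, 0] = np.asarray(x0, dtype=float)
    elif innov_sd > 0:
        x[:, 0] = rng.multivariate_normal(np.zeros(4), stationary_cov(a, innov_sd))
    step = np.eye(4) + dt * a
    scale = innov_sd * np.sqrt(dt)
    noise = scale * rng.standard_normal((4, n - 1)) if innov_sd > 0 else None
    for k in range(n - 1):
        x[:, k + 1] = step @ x[:, k]
        if noise is not None:
            x[:, k + 1] += noise[:, k]
    return x


def _make_nuisance(n_volumes: int, tr: float, rng: np.random.Generator) -> NuisanceMatrix:
    """Six smooth motion-like series plus global/WM/CSF series."""
    t = np.arange(n_volumes) * tr
    cols = []
    for _ in range(6):
        walk = np.cumsum(rng.standard_normal(n_volumes)) * 0.02
        sway = 0.05 * np.sin(2 * np.pi * rng.uniform(0.005, 0.02) * t + rng.uniform(0, 2 * np.pi))
        cols.append(walk + sway)
    for _ in range(3):  # global, WM, CSF: smooth AR(1) fluctuations
        e = rng.standard_normal(n_volumes)
        s = np.empty(n_volumes)
        s[0] = e[0]
        for k in range(1, n_volumes):
            s[k] = 0.9 * s[k - 1] + np.sqrt(1 - 0.9 ** 2) * e[k]
        cols.append(s)
    return NuisanceMatrix(np.column_stack(cols))


def observe_bold(neural: np.ndarray, spec: AcquisitionSpec,
                 hrf_params: HrfParams = HrfParams(),
                 dt: float = 0.1,
                 drift_slope: float = 0.5,
                 noise_sd: float = 1.0,
                 voxel_loading_sd: float = 0.2,
                 nuisance_beta_sd: float = 0.15,
                 baseline: float = 0.0,
                 seed: int | None = None,
                 ) -> tuple[dict[str, VoxelBlock], NuisanceMatrix]:
    """Forward observation model: HRF convolution, TR sampling, voxel mixing.

    Each ROI signal is the hemodynamic convolution of its neural channel
    sampled at the TR grid; each voxel is a positive loading times the ROI
    signal plus a nuisance mixture, a per-voxel linear drift, a baseline and
    white noise.  Returns one VoxelBlock per ROI and the nuisance matrix
    (which covers all ``n_volumes`` acquired volumes).
    """
    neural = np.asarray(neural, dtype=float)
    if neural.ndim != 2 or neural.shape[0] != 4:
        raise ValueError("neural must be (4, n_steps)")
    n_fine = neural.shape[1]
    needed = spec.n_volumes * spec.tr_seconds
    if (n_fine - 1) * dt < needed - spec.tr_seconds:
        raise ValueError(
            f"neural series covers {(n_fine - 1) * dt:.1f}s but "
            f"{needed:.1f}s of acquisition requested"
        )
    rng = np.random.default_rng(seed)
    kernel = hrf(np.arange(0.0, hrf_params.length + dt / 2, dt), hrf_params) * dt
    sample_idx = np.round(np.arange(spec.n_volumes) * spec.tr_seconds / dt).astype(int)
    sample_idx = np.clip(sample_idx, 0, n_fine - 1)

    nuisance = _make_nuisance(spec.n_volumes, spec.tr_seconds, rng)
    tt = np.arange(spec.n_volumes) / spec.n_volumes - 0.5
    blocks: dict[str, VoxelBlock] = {}
    for r, roi in enumerate(REGIONS):
        roi_signal = np.convolve(neural[r], kernel)[:n_fine][sample_idx]
        loadings = np.abs(1.0 + voxel_loading_sd * rng.standard_normal(spec.voxels_per_roi))
        betas = nuisance_beta_sd * rng.standard_normal((spec.voxels_per_roi, 9))
        slopes = drift_slope * rng.standard_normal(spec.voxels_per_roi)
        data = (
            loadings[:, None] * roi_signal[None, :]
            + betas @ nuisance.data.T
            + slopes[:, None] * tt[None, :]
            + baseline
        )
        if noise_sd > 0:
            data = data + noise_sd * rng.standard_normal(data.shape)
        blocks[roi] = VoxelBlock(roi, data, spec.tr_seconds)
    return blocks, nuisance


def _standardized_link(values: np.ndarray, center: np.ndarray, sd: np.ndarray) -> float:
    z = (values - center) / np.where(sd > 0, sd, 1.0)
    return float(z.sum() / np.sqrt(len(z)))


def make_clinical(true_params: EffConnParams,
                  link_config: ClinicalLinkConfig = ClinicalLinkConfig(),
                  seed: int | None = None,
                  config: GeneratorConfig = GeneratorConfig()) -> ClinicalRecord:
    """Clinical scores of one patient, linearly linked to planted couplings.

    Pre-operative acuity of both eyes tracks the cerebellar self parameter;
    left-eye recovery tracks C->SV_L, right-eye recovery tracks C->SV_R;
    the JOA motor score tracks a 7-parameter cerebellum-centred combination.
    Standardization uses the generator's template and jitter SDs, so the
    default marginal moments match the study's patient table.
    """
    lc = link_config
    rng = np.random.default_rng(seed)
    tmpl = template_params("patient", config)
    vec, tvec = true_params.vector, tmpl.vector
    sds = np.concatenate([
        np.full(12, config.jitter_sd), np.full(4, config.jitter_self_sd)
    ])

    def score(mean: float, sd: float, r2: float, z: float) -> float:
        return mean + sd * (np.sqrt(r2) * z + np.sqrt(1.0 - r2) * rng.standard_normal())

    idx = [param_index(f) for f in lc.joa_features]
    z_joa = _standardized_link(vec[idx], tvec[idx], sds[idx])
    i_selfc = param_index("self_C")
    z_selfc = (vec[i_selfc] - tvec[i_selfc]) / sds[i_selfc]
    i_cl = param_index("C->SV_L")
    z_cl = (vec[i_cl] - tvec[i_cl]) / sds[i_cl]
    i_cr = param_index("C->SV_R")
    z_cr = (vec[i_cr] - tvec[i_cr]) / sds[i_cr]

    joa = score(lc.joa_mean, lc.joa_sd, lc.joa_r2, z_joa)
    pre_od = score(lc.bcva_pre_od_mean, lc.bcva_pre_od_sd, lc.bcva_r2, z_selfc)
    pre_os = score(lc.bcva_pre_os_mean, lc.bcva_pre_os_sd, lc.bcva_r2, z_selfc)
    rec_od = score(lc.recovery_od_mean, lc.recovery_od_sd, lc.recovery_r2, z_cr)
    rec_os = score(lc.recovery_os_mean, lc.recovery_os_sd, lc.recovery_r2, z_cl)
    return ClinicalRecord(
        joa_pre=joa,
        bcva_pre_od=pre_od, bcva_pre_os=pre_os,
        bcva_post_od=pre_od + rec_od, bcva_post_os=pre_os + rec_os,
        recovery_od=rec_od, recovery_os=rec_os,
    )


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed: fixed affine counter offset from the
    master seed (never wall clock), kept below 2**31."""
    return int((int(master_seed) * 100003 + 7919 * (index + 1)) % (2 ** 31 - 1))


def make_subject(group: str, seed: int,
                 config: GeneratorConfig = GeneratorConfig()) -> SubjectRecord:
    params = make_connectivity(group, config.jitter_sd, seed, config)
    spec = config.acquisition
    duration = spec.n_volumes * spec.tr_seconds + config.dt_seconds
    neural = simulate_neural(params, duration, config.dt_seconds,
                             config.innov_sd, seed=seed + 1)
    blocks, nuis = observe_bold(
        neural, spec, dt=config.dt_seconds, drift_slope=config.drift_slope,
        noise_sd=config.noise_sd, voxel_loading_sd=config.voxel_loading_sd,
        nuisance_beta_sd=config.nuisance_beta_sd, baseline=config.baseline,
        seed=seed + 2,
    )
    clinical = None
    if group == "patient":
        clinical = make_clinical(params, config.clinical, seed=seed + 3, config=config)
    return SubjectRecord(group=group, true_params=params, voxel_blocks=blocks,
                         nuisance=nuis, seed=seed, clinical=clinical)


def make_cohort(n_patients: int = 27, n_controls: int = 11,
                config: GeneratorConfig = GeneratorConfig(),
                master_seed: int = 0) -> CohortBundle:
    """Generate a full cohort; regeneration from (config, master_seed) is
    bit-identical."""
    if n_patients < 0 or n_controls < 0:
        raise ValueError("group sizes must be >= 0")
    subjects = []
    for i in range(n_patients + n_controls):
        group = "patient" if i < n_patients else "control"
        subjects.append(make_subject(group, subject_seed(master_seed, i), config))
    return CohortBundle(subjects=subjects, generator_config=config,
                        master_seed=int(master_seed))
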