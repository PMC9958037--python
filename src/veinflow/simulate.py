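"""Synthetic cine velocity-map cohorts with known hemodynamic ground truth.

The lower-extremity venous QFlow study setting: each subject contributes one
limb scanned at four venous setpoints — external iliac (EIV), femoral (FV),
popliteal (PV) and great saphenous (GSV) veins.  For each setpoint we build a
parametric one-beat flow waveform, render it into a stack of through-plane
velocity maps with a parabolic lumen profile plus Gaussian pixel noise, and
keep the analytically integrated per-beat volumes as ground truth.

Waveform family (closed-form integrals throughout):

* no reflux: flux(t) = m * (1 + a * sin(2*pi*t/T)), an antegrade baseline
  with weak pulsatile modulation (venous flow is only mildly pulsatile);
  per-beat antegrade volume m*T exactly.
* reflux (fraction f > 0): one antegrade raised-cosine lobe carrying volume
  m*T and one retrograde raised-cosine lobe carrying volume f*m*T, modelling
  valve-incompetence backflow in the GSV.  Raised-cosine (Hann) lobes are C1
  at their boundaries, which keeps trapezoid integration on the coarse phase
  grid accurate to well under 0.5%.

Ground truth: FFV = m*T, BFV = f*m*T, SV = (1-f)*m*T, ASV = (1+f)*m*T.

The default cohort reproduces the study design: 26 reflux-patient limbs and
15 healthy-control limbs, with the between-group shift confined to the GSV
setpoint so that GSV SV/FFV/ASV/MF separate the groups while EIV/FV/PV do
not.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import yaml

from .qflow import QFlowResult, ROIMask, VelocityCine

SETPOINTS = ("EIV", "FV", "PV", "GSV")
GROUP_REFLUX = "reflux_patient"
GROUP_CONTROL = "healthy_control"


class ParameterError(ValueError):
    """Raised for non-finite or out-of-range generator parameters."""


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowTruth:
    """Analytically integrated per-beat volumes (mL)."""

    sv: float
    ffv: float
    bfv: float
    asv: float


@dataclass(frozen=True, eq=False)
class FlowWaveform:
    """One-beat flux waveform sampled on the cine phase grid.

    flux is in mL/s, toward-head positive.
    """

    phase_times: np.ndarray
    flux: np.ndarray
    rr_interval: float
    truth: FlowTruth


@dataclass(frozen=True)
class WaveformParams:
    """Parameters of one setpoint's flow waveform.

    mean_flux : mL/s; per-beat antegrade volume is mean_flux * rr_interval.
    pulsatility : relative sinusoidal modulation amplitude in [0, 1]
        (applies to the reflux-free waveform).
    reflux_fraction : retrograde volume as a fraction of antegrade volume,
        in [0, 1]; > 0 models an incompetent valve.
    reflux_onset, reflux_duration : retrograde lobe placement as fractions
        of the cardiac cycle.
    """

    mean_flux: float
    pulsatility: float = 0.2
    reflux_fraction: float = 0.0
    reflux_onset: float = 0.10
    reflux_duration: float = 0.35

    def __post_init__(self) -> None:
        vals = dataclasses.astuple(self)
        if not np.all(np.isfinite(vals)):
            raise ParameterError(f"non-finite waveform parameter in {self}")
        if self.mean_flux < 0:
            raise ParameterError("mean_flux must be >= 0")
        if not 0.0 <= self.pulsatility <= 1.0:
            raise ParameterError("pulsatility must lie in [0, 1]")
        if not 0.0 <= self.reflux_fraction <= 1.0:
            raise ParameterError("reflux_fraction must lie in [0, 1]")
        if not 0.0 < self.reflux_duration < 1.0:
            raise ParameterError("reflux_duration must lie in (0, 1)")
        if not 0.0 <= self.reflux_onset < 1.0:
            raise ParameterError("reflux_onset must lie in [0, 1)")


def _hann_lobe(x: np.ndarray, length: float, amplitude: float) -> np.ndarray:
    """Raised-cosine lobe of given base length and peak amplitude at x in
    [0, length); zero value and slope at both ends."""
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * x / length))


def waveform_flux(params: WaveformParams, rr_interval: float,
                  t: np.ndarray) -> np.ndarray:
    """Evaluate the parametric flux waveform at times ``t`` (seconds)."""
    T = rr_interval
    m, a, f = params.mean_flux, params.pulsatility, params.reflux_fraction
    if m == 0.0:
        return np.zeros_like(np.asarray(t, dtype=float))
    if f == 0.0:
        return m * (1.0 + a * np.sin(2.0 * np.pi * np.asarray(t) / T))
    L = params.reflux_duration * T
    t0 = params.reflux_onset * T
    phase = np.mod(np.asarray(t, dtype=float) - t0, T)
    retro = phase < L
    # peak amplitudes set so lobe areas are exactly f*m*T and m*T
    amp_b = 2.0 * f * m * T / L
    amp_f = 2.0 * m * T / (T - L)
    out = np.empty_like(phase)
    out[retro] = -_hann_lobe(phase[retro], L, amp_b)
    out[~retro] = _hann_lobe(phase[~retro] - L, T - L, amp_f)
    return out


def generate_waveform(params: WaveformParams, heart_rate: float,
                      n_phases: int = 30) -> FlowWaveform:
    """Build one subject-setpoint flow waveform on a uniform phase grid.

    The R-R interval is 60 / heart_rate seconds; phases sample [0, rr).
    Truth volumes come from the closed-form lobe areas, not from quadrature.
    """
    if n_phases < 8:
        raise ParameterError("n_phases must be >= 8")
    if not (np.isfinite(heart_rate) and heart_rate > 0):
        raise ParameterError("heart_rate must be positive and finite")
    T = 60.0 / heart_rate
    t = np.arange(n_phases) * (T / n_phases)
    flux = waveform_flux(params, T, t)
    ffv = params.mean_flux * T
    bfv = params.reflux_fraction * ffv
    truth = FlowTruth(sv=ffv - bfv, ffv=ffv, bfv=bfv, asv=ffv + bfv)
    return FlowWaveform(phase_times=t, flux=flux, rr_interval=T, truth=truth)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselGeometry:
    """Circular lumen on a square pixel grid.

    lumen_radius in cm, pixel_spacing in cm/pixel; lumen_center in pixel
    coordinates (row, col), defaulting to the grid centre.
    """

    lumen_radius: float
    grid_shape: tuple[int, int] = (64, 64)
    pixel_spacing: float = 0.17
    lumen_center: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pixel_spacing) and self.pixel_spacing > 0):
            raise ParameterError("pixel_spacing must be positive")
        if not (np.isfinite(self.lumen_radius) and self.lumen_radius > 0):
            raise ParameterError("lumen_radius must be positive")
        center = self.lumen_center
        if center is None:
            center = ((self.grid_shape[0] - 1) / 2.0,
                      (self.grid_shape[1] - 1) / 2.0)
        object.__setattr__(self, "lumen_center", (float(center[0]),
                                                  float(center[1])))
        r_pix = self.lumen_radius / self.pixel_spacing
        for c, n in zip(self.lumen_center, self.grid_shape):
            if c - r_pix < -0.5 or c + r_pix > n - 0.5:
                raise ParameterError("lumen does not fit inside the grid")

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing ** 2


def lumen_profile(geometry: VesselGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Unit-peak parabolic (Poiseuille) profile and in-lumen mask."""
    rows, cols = geometry.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cy, cx = geometry.lumen_center
    r = geometry.pixel_spacing * np.hypot(rr - cy, cc - cx)
    profile = np.clip(1.0 - (r / geometry.lumen_radius) ** 2, 0.0, None)
    mask = r < geometry.lumen_radius
    return profile, mask


def render_velocity_cine(waveform: FlowWaveform, geometry: VesselGeometry,
                         noise_sd: float = 0.0,
                         seed=None) -> tuple[VelocityCine, ROIMask]:
    """Render a waveform into per-phase velocity maps plus the lumen ROI.

    The laminar parabolic profile is rescaled per phase so that the in-lumen
    pixel flux sums exactly to the waveform flux at that phase; zero-mean
    Gaussian noise of standard deviation ``noise_sd`` (cm/s) is then added to
    every pixel (lumen and background).
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if geometry.lumen_radius < 2.0 * geometry.pixel_spacing:
        raise ParameterError(
            "lumen radius below 2 pixel spacings: profile unresolvable")
    profile, mask = lumen_profile(geometry)
    denom = profile.sum() * geometry.pixel_area  # mL/s at unit peak velocity
    scale = waveform.flux / denom
    data = scale[:, None, None] * profile[None, :, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    cine = VelocityCine(data=data, phase_times=waveform.phase_times,
                        rr_interval=waveform.rr_interval,
                        pixel_spacing=geometry.pixel_spacing)
    roi = ROIMask(mask=mask, pixel_area=geometry.pixel_area)
    return cine, roi


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SetpointFlowModel:
    """Sampling distribution of one setpoint's waveform parameters.

    mean_flux ~ Normal(loc, scale) truncated below at 0.05 mL/s;
    pulsatility ~ Uniform(range).  lumen_radius in cm.
    """

    mean_flux_loc: float
    mean_flux_scale: float
    pulsatility_range: tuple[float, float] = (0.1, 0.4)
    lumen_radius: float = 0.4


def _default_control_flow() -> dict[str, SetpointFlowModel]:
    return {
        "EIV": SetpointFlowModel(5.0, 1.0, (0.1, 0.4), 0.50),
        "FV": SetpointFlowModel(3.0, 0.7, (0.1, 0.4), 0.45),
        "PV": SetpointFlowModel(1.5, 0.4, (0.1, 0.4), 0.40),
        "GSV": SetpointFlowModel(0.6, 0.15, (0.1, 0.4), 0.35),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-design configuration of the synthetic cohort.

    The default reproduces the study conditions: 26 reflux-patient limbs vs
    15 healthy-control limbs; EIV/FV/PV flow distributions shared between
    groups; the patients' GSV has elevated antegrade volume (dilated,
    refluxing vein) plus a retrograde component of 60-95% of the antegrade
    volume.  ``effect_scale`` linearly interpolates the patients' GSV model
    between the control model (0 => null cohort) and the full effect (1).
    """

    n_reflux: int = 26
    n_control: int = 15
    n_phases: int = 30
    grid_shape: tuple[int, int] = (64, 64)
    pixel_spacing: float = 0.17
    noise_sd: float = 0.5
    heart_rate_loc: float = 70.0
    heart_rate_scale: float = 8.0
    heart_rate_bounds: tuple[float, float] = (40.0, 120.0)
    reflux_gsv_mean_flux_loc: float = 1.4
    reflux_gsv_mean_flux_scale: float = 0.3
    reflux_fraction_range: tuple[float, float] = (0.6, 0.95)
    effect_scale: float = 1.0
    left_limb_prob_reflux: float = 18.0 / 26.0
    control_flow: Mapping[str, SetpointFlowModel] = field(
        default_factory=_default_control_flow)

    def null(self) -> "CohortConfig":
        """Zero-effect variant: patients' GSV drawn from the control model."""
        return dataclasses.replace(self, effect_scale=0.0)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["control_flow"] = {
            k: dataclasses.asdict(v) for k, v in self.control_flow.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "control_flow" in d:
            d["control_flow"] = {
                k: SetpointFlowModel(**{
                    key: tuple(val) if isinstance(val, list) else val
                    for key, val in v.items()})
                for k, v in d["control_flow"].items()}
        for key in ("grid_shape", "heart_rate_bounds",
                    "reflux_fraction_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectSpec:
    """One limb's sampled physiology: group, heart rate and per-setpoint
    waveform parameters."""

    subject_id: str
    group: str
    limb: str
    heart_rate: float
    setpoint_params: Mapping[str, WaveformParams]

    def __post_init__(self) -> None:
        if self.group not in (GROUP_REFLUX, GROUP_CONTROL):
            raise ParameterError(f"unknown group {self.group!r}")
        if not (np.isfinite(self.heart_rate) and self.heart_rate > 0):
            raise ParameterError("heart_rate must be positive")
        if set(self.setpoint_params) != set(SETPOINTS):
            raise ParameterError("subject must carry exactly the four "
                                 f"setpoints {SETPOINTS}")
        for sp, p in self.setpoint_params.items():
            if p.reflux_fraction > 0 and not (
                    sp == "GSV" and self.group == GROUP_REFLUX):
                raise ParameterError(
                    "reflux is only allowed in the GSV of reflux patients")

    @property
    def label(self) -> int:
        """Desired classifier output: reflux patient 1, healthy control 0."""
        return 1 if self.group == GROUP_REFLUX else 0


@dataclass(eq=False)
class ScanRecord:
    """One subject-setpoint scan: rendered cine (optional), ROI and truth."""

    subject_id: str
    group: str
    limb: str
    setpoint: str
    cine: Optional[VelocityCine]
    roi: ROIMask
    truth: QFlowResult


@dataclass(eq=False)
class CohortDataset:
    """A generated cohort: subject specs, per-scan records, provenance."""

    subjects: list[SubjectSpec]
    records: list[ScanRecord]
    seed: int
    config: CohortConfig

    def iter_records(self) -> Iterator[ScanRecord]:
        return iter(self.records)

    def labels(self) -> dict[str, int]:
        return {s.subject_id: s.label for s in self.subjects}

    def truth_table(self):
        """Ground-truth parameter table with the same schema as batch_qflow."""
        import pandas as pd
        from .qflow import QFLOW_COLUMNS
        rows = [{"subject_id": r.subject_id, "group": r.group, "limb": r.limb,
                 "setpoint": r.setpoint, **r.truth.as_dict()}
                for r in self.records]
        return pd.DataFrame(rows, columns=QFLOW_COLUMNS)


def _truncated_normal(rng: np.random.Generator, loc: float, scale: float,
                      low: float, high: float = np.inf) -> float:
    for _ in range(1000):
        x = rng.normal(loc, scale)
        if low <= x <= high:
            return float(x)
    raise RuntimeError("truncated normal sampling failed")


def _truth_qflow(wave: FlowWaveform, roi_area: float,
                 heart_rate: float) -> QFlowResult:
    t = wave.truth
    rf = 100.0 * t.bfv / t.ffv if t.ffv > 0 else None
    mf = t.sv * heart_rate / 60.0
    sd = t.sv / roi_area
    mv = sd * heart_rate / 60.0
    return QFlowResult(sv=t.sv, ffv=t.ffv, bfv=t.bfv, rf=rf, asv=t.asv,
                       mf=mf, sd=sd, mv=mv, roi_area=roi_area,
                       heart_rate=heart_rate)


def _sample_subject(rng: np.random.Generator, config: CohortConfig,
                    subject_id: str, group: str) -> SubjectSpec:
    hr = _truncated_normal(rng, config.heart_rate_loc,
                           config.heart_rate_scale,
                           *config.heart_rate_bounds)
    if group == GROUP_REFLUX:
        limb = "left" if rng.random() < config.left_limb_prob_reflux else "right"
    else:
        limb = "left" if rng.random() < 0.5 else "right"
    es = config.effect_scale
    params = {}
    for sp in SETPOINTS:
        model = config.control_flow[sp]
        loc, scale = model.mean_flux_loc, model.mean_flux_scale
        f_lo = f_hi = 0.0
        if sp == "GSV" and group == GROUP_REFLUX:
            loc = loc + es * (config.reflux_gsv_mean_flux_loc - loc)
            scale = scale + es * (config.reflux_gsv_mean_flux_scale - scale)
            f_lo = es * config.reflux_fraction_range[0]
            f_hi = es * config.reflux_fraction_range[1]
        m = _truncated_normal(rng, loc, scale, 0.05)
        a = float(rng.uniform(*model.pulsatility_range))
        f = float(rng.uniform(f_lo, f_hi)) if f_hi > 0 else 0.0
        params[sp] = WaveformParams(mean_flux=m, pulsatility=a,
                                    reflux_fraction=f)
    return SubjectSpec(subject_id=subject_id, group=group, limb=limb,
                       heart_rate=hr, setpoint_params=params)


def generate_cohort(config: CohortConfig = CohortConfig(), seed: int = 0,
                    render: bool = True) -> CohortDataset:
    """Generate a seeded cohort of subjects with per-setpoint scans.

    All randomness flows from ``seed`` through a spawned seed tree: one
    stream for physiology sampling and one per subject for rendering noise,
    so identical (config, seed) reproduce the cohort bit for bit.  With
    ``render=False`` only ROIs and ground truth are built (fast path for
    statistics at truth level).
    """
    if config.n_reflux < 1 or config.n_control < 1:
        raise ParameterError("group sizes must be >= 1")
    n_total = config.n_reflux + config.n_control
    root = np.random.SeedSequence(seed)
    seqs = root.spawn(n_total + 1)
    param_rng = np.random.default_rng(seqs[0])

    groups = ([GROUP_REFLUX] * config.n_reflux
              + [GROUP_CONTROL] * config.n_control)
    ids = [f"R{i + 1:02d}" for i in range(config.n_reflux)] + \
          [f"H{i + 1:02d}" for i in range(config.n_control)]

    geometries = {
        sp: VesselGeometry(lumen_radius=config.control_flow[sp].lumen_radius,
                           grid_shape=config.grid_shape,
                           pixel_spacing=config.pixel_spacing)
        for sp in SETPOINTS}
    rois = {}
    for sp, geom in geometries.items():
        _, mask = lumen_profile(geom)
        rois[sp] = ROIMask(mask=mask, pixel_area=geom.pixel_area)

    subjects, records = [], []
    for sid, group, seq in zip(ids, groups, seqs[1:]):
        spec = _sample_subject(param_rng, config, sid, group)
        subjects.append(spec)
        render_rng = np.random.default_rng(seq)
        for sp in SETPOINTS:
            wave = generate_waveform(spec.setpoint_params[sp],
                                     spec.heart_rate, config.n_phases)
            roi = rois[sp]
            truth = _truth_qflow(wave, roi.area, spec.heart_rate)
            cine = None
            if render:
                cine, roi = render_velocity_cine(
                    wave, geometries[sp], noise_sd=config.noise_sd,
                    seed=render_rng)
            records.append(ScanRecord(subject_id=sid, group=group,
                                      limb=spec.limb, setpoint=sp,
                                      cine=cine, roi=roi, truth=truth))
    return CohortDataset(subjects=subjects, records=records, seed=seed,
                         config=config)
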