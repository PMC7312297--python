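"""Synthetic inputs with known ground truth for every pipeline stage.

Wet-lab measurements on barrier models (confocal stacks, tracer-flux
tables, impedance traces, ratiometric pH recordings) are emulated here by
forward models whose parameters *are* the quantities the analysis modules
recover: surface geometry and membrane enrichment for the confocal
pipeline, true Papp for the permeability assay, true cell-index
trajectories for the impedance kinetics and true pH plus a known linear
calibration for the BCECF workflow.  Every generator is deterministic for
a fixed seed, and at zero noise the corresponding analysis recovers the
ground truth exactly — the core round-trip property of the package.

Noise is additive Gaussian throughout (multiplicative-relative for the
plate-reader concentrations), the simplest defensible default; intensities
are clipped at zero.  No attempt is made at photorealistic microscopy
(no PSF convolution by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from epibarrier import confocal
from epibarrier.barrier import PermeabilityRecord
from epibarrier.confocal import ApicalMaskSet, ConfocalStack
from epibarrier.impedance import CI_SCALE_OHM, ImpedanceTrace
from epibarrier.ph import CALIBRATION_PH_RANGE, RatioTrace

__all__ = [
    "StackSpec",
    "AssaySpec",
    "TraceSpec",
    "PhExperimentSpec",
    "flat_surface",
    "step_surface",
    "smooth_surface",
    "generate_confocal_stack",
    "generate_junction_image",
    "generate_permeability_experiment",
    "generate_impedance_trace",
    "generate_ph_experiment",
]


# ---------------------------------------------------------------------------
# Surface-height presets (um from the stack top, apical side at z index 0)

def flat_surface(ny: int, nx: int, depth_um: float = 1.0) -> np.ndarray:
    """Flat apical surface at a constant depth below the stack top."""
    return np.full((ny, nx), depth_um, dtype=float)


def step_surface(
    ny: int, nx: int, depth_low_um: float = 0.6, depth_high_um: float = 2.0
) -> np.ndarray:
    """Step profile: left half shallow, right half deep."""
    h = np.full((ny, nx), depth_low_um, dtype=float)
    h[:, nx // 2 :] = depth_high_um
    return h


def smooth_surface(
    ny: int,
    nx: int,
    mean_depth_um: float = 1.2,
    amplitude_um: float = 0.6,
    correlation_px: float = 16.0,
    seed: int = 0,
) -> np.ndarray:
    """Band-limited random surface emulating a gently undulating monolayer.

    White noise is low-pass filtered with a Gaussian of the stated
    correlation length, rescaled to the requested peak amplitude and
    offset to the mean depth.
    """
    rng = np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(
        rng.standard_normal((ny, nx)), sigma=correlation_px, mode="wrap"
    )
    peak = np.abs(field_).max()
    if peak > 0:
        field_ = field_ / peak * amplitude_um
    return np.clip(mean_depth_um + field_, 0.0, None)


# ---------------------------------------------------------------------------
# Confocal stacks

@dataclass(frozen=True)
class StackSpec:
    """Ground-truth description of one synthetic confocal stack.

    The apical surface ``surface_um`` (um below the stack top; generated
    by a preset if omitted) carries a membrane band of
    ``membrane_thickness_um`` below it.  The target channel is drawn at
    ``cytoplasm_intensity * enrichment`` inside the band and
    ``cytoplasm_intensity`` below it, so the true membrane/cytoplasm mean
    ratio equals ``enrichment`` exactly before noise.
    """

    nx: int = 64
    ny: int = 64
    nz: int = 40
    lateral_um: float = 0.2
    axial_um: float = 0.2
    surface_um: np.ndarray | None = None
    membrane_thickness_um: float = 2.4
    enrichment: float = 1.5
    cytoplasm_intensity: float = 100.0
    membrane_stain_intensity: float = 200.0
    background_intensity: float = 2.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.enrichment <= 0:
            raise ValueError("membrane enrichment ratio must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.lateral_um <= 0 or self.axial_um <= 0:
            raise ValueError("voxel sizes must be positive")


def generate_confocal_stack(spec: StackSpec) -> tuple[ConfocalStack, ApicalMaskSet]:
    """Draw a two-channel stack plus its analytic ground-truth masks.

    The membrane-stain channel is bright only inside the membrane band of
    the stated thickness below the surface; the target channel encodes the
    enrichment ratio.  Ground-truth masks are derived from the surface
    height field by index arithmetic, never from image content.
    """
    h = spec.surface_um
    if h is None:
        h = smooth_surface(spec.ny, spec.nx, seed=spec.seed)
    h = np.asarray(h, dtype=float)
    if h.shape != (spec.ny, spec.nx):
        raise ValueError(f"surface field shape {h.shape} != (ny, nx) = {(spec.ny, spec.nx)}")
    depth_um = spec.nz * spec.axial_um
    if h.min() < 0 or h.max() > depth_um:
        raise ValueError("surface height field outside the stack depth")

    z_top = np.rint(h / spec.axial_um).astype(np.int64)
    stripe = int(round(spec.membrane_thickness_um / spec.axial_um))
    if stripe < 1:
        raise ValueError("membrane thickness below one axial voxel")
    if (z_top + stripe > spec.nz).any():
        raise ValueError(
            f"grid too small to contain the membrane band: need z <= {spec.nz}, "
            f"surface reaches voxel {int(z_top.max())} with a {stripe}-voxel band"
        )

    truth = confocal.build_masks(z_top, (spec.nz, spec.ny, spec.nx), stripe)

    membrane = np.full((spec.nz, spec.ny, spec.nx), spec.background_intensity)
    membrane[truth.membrane_mask] = spec.membrane_stain_intensity
    target = np.full((spec.nz, spec.ny, spec.nx), spec.background_intensity)
    target[truth.cytoplasm_mask] = spec.cytoplasm_intensity
    target[truth.membrane_mask] = spec.cytoplasm_intensity * spec.enrichment

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        membrane = membrane + rng.normal(0.0, spec.noise_sd, membrane.shape)
        target = target + rng.normal(0.0, spec.noise_sd, target.shape)
        membrane = np.clip(membrane, 0.0, None)
        target = np.clip(target, 0.0, None)

    stack = ConfocalStack(
        membrane=membrane,
        target=target,
        lateral_um=spec.lateral_um,
        axial_um=spec.axial_um,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Junctional immunostaining images

def generate_junction_image(
    n_cells: int,
    junction_intensity: float = 200.0,
    cytoplasm_intensity: float = 50.0,
    background_intensity: float = 5.0,
    junction_width: int = 2,
    shape: tuple[int, int] = (128, 128),
    margin: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D image of a cell tessellation with bright borders, plus truth mask.

    ``n_cells`` random seed points define a Voronoi tessellation; pixels
    where adjacent tiles meet form the junction mask, dilated to
    ``junction_width``.  With ``margin > 0`` a frame of background pixels
    surrounds the tessellation (for three-class segmentation).  Returns
    ``(image, junction_mask)``.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells for a tessellation")
    if junction_intensity == cytoplasm_intensity:
        warnings.warn(
            "junction and cytoplasm intensities are equal: downstream "
            "segmentation is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    ny, nx = shape
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [
            rng.uniform(margin, ny - margin, n_cells),
            rng.uniform(margin, nx - margin, n_cells),
        ]
    )
    yy, xx = np.mgrid[0:ny, 0:nx]
    _, labels = cKDTree(pts).query(np.column_stack([yy.ravel(), xx.ravel()]))
    labels = labels.reshape(ny, nx)
    border = ndimage.maximum_filter(labels, size=2) != ndimage.minimum_filter(labels, size=2)
    extra = (junction_width - 2) // 2
    if extra > 0:
        border = ndimage.binary_dilation(border, iterations=extra)

    cell_area = np.ones((ny, nx), dtype=bool)
    if margin > 0:
        cell_area[:] = False
        cell_area[margin:-margin, margin:-margin] = True
    mask = border & cell_area

    image = np.full(shape, background_intensity, dtype=float)
    image[cell_area] = cytoplasm_intensity
    image[mask] = junction_intensity
    if noise_sd > 0:
        image = np.clip(image + rng.normal(0.0, noise_sd, shape), 0.0, None)
    return image, mask


# ---------------------------------------------------------------------------
# Permeability assays

@dataclass(frozen=True)
class AssaySpec:
    """Forward model of one tracer-flux experiment on an insert.

    Inverts the Papp definition: ``dC_A = Papp * A * C_D * dt / V_A``.
    Donor depletion is neglected (sink assumption), matching short assays
    where only a ~per-mille fraction of tracer crosses.  ``noise_rel`` is
    the relative sd of the measured acceptor-concentration change.
    """

    papp_cm_s: float = 7.44e-7
    c_donor: float = 10.0
    v_acceptor_ml: float = 1.5
    v_donor_ml: float = 0.5
    area_cm2: float = 1.12
    duration_s: float = 1800.0
    noise_rel: float = 0.0
    tracer: str = "fluorescein"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.c_donor, self.v_acceptor_ml, self.v_donor_ml, self.area_cm2) <= 0:
            raise ValueError("assay geometry and donor concentration must be positive")
        if self.duration_s <= 0:
            raise ValueError("assay duration must be positive")
        if self.papp_cm_s < 0:
            raise ValueError("true Papp must be >= 0")


def generate_permeability_experiment(spec: AssaySpec) -> PermeabilityRecord:
    """One insert's donor/acceptor record consistent with the true Papp."""
    dc = spec.papp_cm_s * spec.area_cm2 * spec.c_donor * spec.duration_s / spec.v_acceptor_ml
    if spec.noise_rel > 0:
        rng = np.random.default_rng(spec.seed)
        dc = max(dc * (1.0 + rng.normal(0.0, spec.noise_rel)), 0.0)
    return PermeabilityRecord(
        c_donor=spec.c_donor,
        dc_acceptor=dc,
        v_acceptor_ml=spec.v_acceptor_ml,
        area_cm2=spec.area_cm2,
        duration_s=spec.duration_s,
        tracer=spec.tracer,
    )


# ---------------------------------------------------------------------------
# Impedance traces

@dataclass(frozen=True)
class TraceSpec:
    """Forward model of one well's impedance kinetics.

    Growth follows a logistic cell-index curve; a treatment at
    ``treatment_h`` multiplies the trajectory by per-window factors
    (hours relative to treatment), emulating transient dips, recovery or
    detergent-induced death (factor 0).  The instrument reading is
    ``Rn(t) = Rb + 15 * CI_true(t) + noise``.
    """

    interval_min: float = 10.0
    duration_h: float = 72.0
    ci_plateau: float = 5.0
    growth_rate_per_h: float = 0.2
    growth_midpoint_h: float = 24.0
    treatment_h: float = 48.0
    effect_windows: tuple = ()  # (start_h, end_h, factor) after treatment
    rb_ohm: float = 20.0
    noise_sd_ohm: float = 0.0
    well: str = ""
    group: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_min <= 0:
            raise ValueError("sampling interval must be positive")
        if self.rb_ohm < 0:
            raise ValueError("background impedance must be >= 0")
        if self.treatment_h > self.duration_h:
            raise ValueError("treatment time lies beyond the end of the trace")
        windows = self.effect_windows
        if np.isscalar(windows):
            windows = ((0.0, np.inf, float(windows)),)
        object.__setattr__(self, "effect_windows", tuple(tuple(w) for w in windows))


def generate_impedance_trace(spec: TraceSpec) -> tuple[ImpedanceTrace, np.ndarray]:
    """Simulate one well; returns the trace and the true cell-index series."""
    t = np.arange(0.0, spec.duration_h + 1e-9, spec.interval_min / 60.0)
    ci = spec.ci_plateau / (
        1.0 + np.exp(-spec.growth_rate_per_h * (t - spec.growth_midpoint_h))
    )
    # windows are (start, end] hours after treatment: the sample taken at
    # the treatment instant itself is still pre-treatment
    for start, end, factor in spec.effect_windows:
        sel = (t - spec.treatment_h > start) & (t - spec.treatment_h <= end)
        ci = np.where(sel, ci * factor, ci)
    rn = spec.rb_ohm + CI_SCALE_OHM * ci
    if spec.noise_sd_ohm > 0:
        rng = np.random.default_rng(spec.seed)
        rn = rn + rng.normal(0.0, spec.noise_sd_ohm, rn.shape)
    trace = ImpedanceTrace(
        time_h=t,
        impedance_ohm=rn,
        rb_ohm=spec.rb_ohm,
        treatment_h=spec.treatment_h,
        well=spec.well,
        group=spec.group,
    )
    return trace, ci


# ---------------------------------------------------------------------------
# Ratiometric pH experiments

@dataclass(frozen=True)
class PhExperimentSpec:
    """Forward model of a BCECF resting-pH experiment.

    ROI traces fluctuate around ``ratio(true_ph)`` under a known linear
    calibration ``ratio = slope * pH + intercept``; the calibration table
    lists one noisy mean ratio per anchor pH.  Default sampling: one
    reading every 2 s, 14 ROIs.
    """

    true_ph: float = 7.4
    anchors_ph: tuple = (6.0, 6.8, 7.6, 8.4)
    slope: float = 0.5
    intercept: float = -2.0
    trace_length_s: float = 120.0
    period_s: float = 2.0
    noise_sd: float = 0.0
    n_rois: int = 14
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.anchors_ph) < 2:
            raise ValueError("need at least 2 calibration anchor points")
        if self.period_s <= 0:
            raise ValueError("sampling period must be positive")
        lo, hi = CALIBRATION_PH_RANGE
        if min(self.anchors_ph) < lo or max(self.anchors_ph) > hi:
            warnings.warn(
                f"calibration anchors outside the standard pH range [{lo}, {hi}]",
                RuntimeWarning,
                stacklevel=2,
            )


def generate_ph_experiment(
    spec: PhExperimentSpec,
) -> tuple[list[RatioTrace], pd.DataFrame]:
    """ROI ratio traces plus a (pH, ratio) calibration table."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.trace_length_s + 1e-9, spec.period_s)
    true_ratio = spec.slope * spec.true_ph + spec.intercept
    traces = []
    for i in range(spec.n_rois):
        ratio = np.full_like(t, true_ratio)
        if spec.noise_sd > 0:
            ratio = ratio + rng.normal(0.0, spec.noise_sd, t.shape)
        traces.append(RatioTrace(roi=f"roi{i:02d}", time_s=t, ratio=ratio))
    anchors = np.asarray(spec.anchors_ph, dtype=float)
    ratios = spec.slope * anchors + spec.intercept
    if spec.noise_sd > 0:
        ratios = ratios + rng.normal(0.0, spec.noise_sd, ratios.shape)
    calibration = pd.DataFrame({"ph": anchors, "ratio": ratios})
    return traces, calibration
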