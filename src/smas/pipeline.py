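"""End-to-end orchestration: raw stacks to deviation maps and study tables.

One eye travels: background removal + normalisation -> right-eye
formatting -> double-shear alignment -> fovea-anchored superpixel grid ->
slab construction per scheme -> superpixel reduction onto the common
lattice window.  Control eyes feed the normative fit (KDE percentiles +
ROI censoring per slab); test eyes are classified against the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation

from . import normative as nm
from .alignment import Landmarks, double_shear, to_right_eye
from .depth import DepthAxis, SCHEME_NAMES, SlabScheme, scheme_catalog
from .grid import (LatticeWindow, RegionParams, SuperpixelGrid, extract_window,
                   grid_from_landmarks, region_pixel_masks, superpixel_reduce)
from .normative import CombinedDeviationMap, DeviationMap, NormativeModel
from .phantom import PhantomEye
from .preprocess import background_threshold, normalize_stack


@dataclass
class RunConfig:
    """Analysis configuration; the defaults are the study conditions."""

    schemes: tuple[str, ...] = SCHEME_NAMES
    axis: DepthAxis = DepthAxis()
    region_params: RegionParams = RegionParams()
    window: LatticeWindow = LatticeWindow()
    n_separating: int = 20          # superpixels between fovea and ONH
    censor_cutoff: float = 2.5      # SD below grand mean for ROI censoring
    visibility_floor: float = 0.5   # ROI seeding: fraction of bright cell mean
    percentile_levels: tuple[float, ...] = nm.PERCENTILE_LEVELS
    min_controls: int = 5
    preprocess: bool = True
    background_window: int = 11     # raphe background sampling window (px)
    background_depth_um: float = 35.0
    min_coverage: float = 0.999     # required valid-pixel fraction per cell
    seed: int = 0

    def catalog(self) -> dict[str, SlabScheme]:
        cat = scheme_catalog()
        return {name: cat[name] for name in self.schemes}


@dataclass
class EyeFeatures:
    """Superpixel lattices of one eye, per scheme, on the common window."""

    eye_id: str
    grid: SuperpixelGrid
    onh_index: tuple[int, int]
    values: dict[str, np.ndarray]   # scheme -> (n_slabs, H, W), NaN = no data
    valid: dict[str, np.ndarray]    # scheme -> (n_slabs, H, W) bool
    truth_cells: np.ndarray | None = None  # (H, W) bool defect footprint


def process_eye(stack: np.ndarray, landmarks: Landmarks, config: RunConfig,
                eye_id: str = "eye", truth: np.ndarray | None = None
                ) -> EyeFeatures:
    """Run one eye from raw stack to per-scheme lattice windows."""
    stack = np.asarray(stack, dtype=float)
    if config.preprocess:
        # sample the background at the central raphe point, ~35 um below the
        # ILM; the window must stay inside the bundle-free raphe gap
        raphe_pt = landmarks.raphe_points[len(landmarks.raphe_points) // 2]
        stack, _ = background_threshold(
            stack, raphe_pt, delta_um=config.axis.pixel_size_um,
            depth_um=config.background_depth_um, window=config.background_window)
        stack, _ = normalize_stack(stack)
    stack, lm = to_right_eye(stack, landmarks)
    aligned = double_shear(stack, lm)
    grid = grid_from_landmarks(aligned.landmarks, stack.shape[1:],
                               n_separating=config.n_separating)
    pixel_masks = region_pixel_masks(grid, config.region_params)

    values: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    from .depth import build_method_slabs
    for name, scheme in config.catalog().items():
        slab_values, slab_valid = [], []
        for img, _, _ in build_method_slabs(aligned.stack, scheme, pixel_masks):
            lattice, cell_ok = superpixel_reduce(
                img, grid, validity=aligned.validity,
                min_coverage=config.min_coverage)
            wv, wok = extract_window(lattice, cell_ok, grid, config.window)
            wv = np.where(wok, wv, np.nan)
            slab_values.append(wv)
            slab_valid.append(wok)
        values[name] = np.stack(slab_values)
        valid[name] = np.stack(slab_valid)

    truth_cells = None
    if truth is not None:
        footprint = np.asarray(truth).any(axis=0).astype(float)
        cover, _ = superpixel_reduce(footprint, grid, min_coverage=0.0)
        wcov, _ = extract_window(cover, np.isfinite(cover), grid, config.window)
        truth_cells = np.nan_to_num(wcov) >= 0.25
    return EyeFeatures(eye_id=eye_id, grid=grid,
                       onh_index=config.window.onh_index(config.n_separating),
                       values=values, valid=valid, truth_cells=truth_cells)


def process_phantom_eye(eye: PhantomEye, config: RunConfig) -> EyeFeatures:
    return process_eye(eye.stack, eye.landmarks, config,
                       eye_id=eye.eye_id, truth=eye.truth)


def fit_normative(controls: list[EyeFeatures], config: RunConfig
                  ) -> dict[str, NormativeModel]:
    """Fit one normative model per scheme from processed control eyes."""
    if len(controls) < config.min_controls:
        raise ValueError(
            f"need >= {config.min_controls} control eyes, got {len(controls)}")
    models: dict[str, NormativeModel] = {}
    for name in config.schemes:
        stacked = np.stack([c.values[name] for c in controls])
        models[name] = nm.fit_normative_model(
            stacked, scheme=name, onh_cell=controls[0].onh_index,
            censor_cutoff=config.censor_cutoff,
            min_controls=config.min_controls,
            levels=config.percentile_levels,
            visibility_floor=config.visibility_floor)
    return models


@dataclass
class DetectionResult:
    eye_id: str
    scheme: str
    maps: list[DeviationMap]
    combined: CombinedDeviationMap | DeviationMap
    proportion_abnormal: float
    median_onh_distance: float


def detect(features: EyeFeatures, model: NormativeModel) -> DetectionResult:
    """Classify one eye against a fitted normative model."""
    if model.scheme not in features.values:
        raise ValueError(f"eye was not processed with scheme {model.scheme!r}")
    vals = features.values[model.scheme]
    maps = model.classify(vals, features.valid[model.scheme])
    combined = nm.combine_maps(maps) if len(maps) > 1 else maps[0]
    return DetectionResult(
        eye_id=features.eye_id, scheme=model.scheme, maps=maps,
        combined=combined,
        proportion_abnormal=nm.proportion_abnormal(combined),
        median_onh_distance=nm.median_onh_distance(combined, model.onh_cell),
    )


@dataclass
class StudyResult:
    """Everything the cohort analysis computes."""

    models: dict[str, NormativeModel]
    detections: dict[str, dict[str, DetectionResult]]  # eye -> scheme -> result
    proportions: pd.DataFrame       # long table (eye, method, y)
    distances: pd.DataFrame
    fp_rates: dict[str, float]      # surrogate false-positive rate per scheme
    localization: float             # abnormal cells inside dilated truth (SMAS)
    config: RunConfig = field(repr=False, default=None)


def run_study(eyes: list[PhantomEye], config: RunConfig | None = None
              ) -> StudyResult:
    """Full study: fit on controls, detect in glaucoma eyes, summarise."""
    config = config or RunConfig()
    features = [process_phantom_eye(e, config) for e in eyes]
    groups = {e.eye_id: e.group for e in eyes}
    controls = [f for f in features if groups[f.eye_id] == "control"]
    glaucoma = [f for f in features if groups[f.eye_id] == "glaucoma"]
    models = fit_normative(controls, config)

    detections: dict[str, dict[str, DetectionResult]] = {}
    prop: dict[str, dict[str, float]] = {}
    dist: dict[str, dict[str, float]] = {}
    for f in glaucoma:
        detections[f.eye_id] = {}
        prop[f.eye_id] = {}
        dist[f.eye_id] = {}
        for name, model in models.items():
            res = detect(f, model)
            detections[f.eye_id][name] = res
            prop[f.eye_id][name] = res.proportion_abnormal
            dist[f.eye_id][name] = res.median_onh_distance

    fp_rates = {
        name: nm.surrogate_fp_rate(
            np.stack([c.values[name] for c in controls]), model,
            np.stack([c.valid[name] for c in controls]))
        for name, model in models.items()
    }

    n_in, n_abn = 0, 0
    if "SMAS" in models:
        for f in glaucoma:
            if f.truth_cells is None:
                continue
            res = detections[f.eye_id]["SMAS"]
            dilated = binary_dilation(f.truth_cells, iterations=1)
            abnormal = res.combined.abnormal
            n_abn += int(abnormal.sum())
            n_in += int((abnormal & dilated).sum())
    localization = n_in / n_abn if n_abn else float("nan")

    from .evaluation import outcome_table
    return StudyResult(
        models=models, detections=detections,
        proportions=outcome_table(prop, "proportion_abnormal"),
        distances=outcome_table(dist, "median_onh_distance"),
        fp_rates=fp_rates, localization=localization, config=config,
    )
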