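"""Synthetic depth-resolved en face phantoms.

The phantom emulates the statistical structure the pipeline assumes, in a
fully parameterised, seeded way: hyper-reflective nerve fiber bundles
whose depth extent varies by retinal region (shallowest at the temporal
raphe, deepest around the optic nerve head), hypo-reflective deeper
layers, a low-reflectance raphe gap temporal to the fovea, a foveal dip
and an ONH disc, an eye-specific multiplicative texture field shared
across depth (bundle reflectance varies together over the depths a bundle
spans), and small independent per-depth noise.  Glaucomatous eyes receive
arcuate or wedge defects: multiplicative reflectance loss over a
configurable angular sector, radial extent and depth-pixel range.

Geometry is parameterised in superpixel-equivalent units so phantoms are
resolution independent: the default cohort uses 256x256 transverse pixels
with superpixel sizes of 5-6 px (a scaled-down retina); instrument-scale
eyes (superpixel sizes 17-23 px) are obtained by raising
``superpixel_px`` and ``image_shape`` together.

Stacks are generated in the aligned frame (raphe, fovea, ONH on one row)
and then mis-aligned by the inverse double shear, so running the
alignment stage recovers the constructed geometry exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .alignment import Landmarks, _shear_stack
from .grid import RegionParams, region_of_offsets
from .depth import REGION_IDS

#: Deepest depth pixel at which bundles are visible, per region.  Mirrors
#: the pattern of real retinae: raphe shallowest, ONH region deepest.
DEFAULT_BUNDLE_EXTENT = {
    "raphe": 8,
    "temporal_macula": 10,
    "inferior_nasal": 12,
    "central": 15,
    "superior_nasal": 15,
    "onh_region": 21,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic eye."""

    image_shape: tuple[int, int] = (256, 256)
    n_depth: int = 50
    superpixel_px: int = 6          # target superpixel size s
    fovea_rc: tuple[float, float] = (128.0, 77.0)
    theta_disc_deg: float = 6.0     # fovea-disc angle
    theta_raphe_deg: float = -7.0   # fovea-raphe angle
    laterality: str = "right"
    bundle_extent: dict = field(default_factory=lambda: dict(DEFAULT_BUNDLE_EXTENT))
    bundle_level: float = 0.55
    deep_level: float = 0.30
    vitreous_level: float = 0.10
    raphe_gap_level: float = 0.15
    fovea_dip_level: float = 0.25
    onh_level: float = 0.50
    rpe_level: float = 0.95         # bright retinal pigment epithelium
    rpe_start_pixel: int = 42       # first depth pixel dominated by the RPE
    gap_halfwidth_sp: float = 1.5   # raphe-gap half height, superpixel units
    fovea_dip_radius_sp: float = 1.2
    onh_disc_radius_sp: float = 2.5
    texture_sd: float = 0.08        # eye-level multiplicative field, depth-shared
    texture_scale_sp: float = 1.0   # correlation length in superpixel units
    noise_sd: float = 0.02          # independent per-depth additive noise
    region_params: RegionParams = RegionParams()
    seed: int = 0

    def __post_init__(self) -> None:
        for region, ext in self.bundle_extent.items():
            if region not in REGION_IDS:
                raise ValueError(f"unknown region {region!r}")
            if not 1 <= ext <= self.n_depth:
                raise ValueError(f"bundle extent {ext} outside 1..{self.n_depth}")
        for lvl in (self.bundle_level, self.deep_level, self.vitreous_level,
                    self.raphe_gap_level, self.fovea_dip_level, self.onh_level,
                    self.rpe_level):
            if not 0 <= lvl <= 1:
                raise ValueError("reflectance levels must be in [0, 1]")

    @property
    def onh_rc(self) -> tuple[float, float]:
        """ONH centre in the aligned frame (same row as the fovea)."""
        return (self.fovea_rc[0], self.fovea_rc[1] + 20.0 * self.superpixel_px)


@dataclass(frozen=True)
class DefectSpec:
    """One reflectance defect, in aligned-frame coordinates around the ONH.

    Angles are measured from the temporal horizontal (the ONH->fovea
    direction), positive superior.  ``radius_sp`` is the radial extent from
    the ONH centre in superpixel units; ``depth_pixels`` the inclusive
    1-based range of affected depth pixels; reflectance inside the
    footprint is multiplied by ``1 - attenuation``.
    """

    kind: str = "arcuate"           # "arcuate" | "wedge"
    angle_deg: float = 45.0
    width_deg: float = 30.0
    radius_sp: tuple[float, float] = (2.5, 8.0)
    depth_pixels: tuple[int, int] = (14, 20)
    attenuation: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("arcuate", "wedge"):
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if not 0 <= self.attenuation < 1:
            raise ValueError("attenuation must be in [0, 1)")
        if self.depth_pixels[0] > self.depth_pixels[1] or self.depth_pixels[0] < 1:
            raise ValueError("invalid depth range")


def _aligned_geometry(spec: PhantomSpec):
    """Per-pixel region labels and landmark distances in the aligned frame."""
    H, W = spec.image_shape
    s = float(spec.superpixel_px)
    fr, fc = spec.fovea_rc
    rows = (np.arange(H) - fr) / s
    cols = (np.arange(W) - fc) / s
    drow = np.broadcast_to(rows[:, None], (H, W))
    dcol = np.broadcast_to(cols[None, :], (H, W))
    labels = region_of_offsets(drow, dcol, onh_dcol=20.0, params=spec.region_params)
    dist_f = np.hypot(drow, dcol)
    dist_o = np.hypot(drow, dcol - 20.0)
    return labels, drow, dcol, dist_f, dist_o


def _aligned_stack(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Noise-textured stack in the aligned frame."""
    H, W = spec.image_shape
    labels, drow, dcol, dist_f, dist_o = _aligned_geometry(spec)
    extent = np.array([spec.bundle_extent[r] for r in REGION_IDS])[labels]
    gap = (labels == REGION_IDS.index("raphe")) \
        & (np.abs(drow) <= spec.gap_halfwidth_sp)
    fovea_dip = dist_f <= spec.fovea_dip_radius_sp
    onh_disc = dist_o <= spec.onh_disc_radius_sp

    depth = np.arange(1, spec.n_depth + 1)[:, None, None]
    level = np.where(depth <= 2, spec.vitreous_level,
                     np.where(depth <= extent[None], spec.bundle_level,
                              spec.deep_level))
    tissue = depth > 2
    level = np.where(tissue & gap[None], spec.raphe_gap_level, level)
    level = np.where(tissue & fovea_dip[None], spec.fovea_dip_level, level)
    level = np.where(depth >= spec.rpe_start_pixel, spec.rpe_level, level)
    # the disc is bright only over the bundle-bearing depths; deeper it
    # blends into the ambient deep-retina reflectance
    onh_depths = tissue & (depth <= spec.bundle_extent["onh_region"])
    level = np.where(onh_disc[None] & onh_depths, spec.onh_level, level)

    texture = gaussian_filter(rng.standard_normal((H, W)),
                              sigma=spec.texture_scale_sp * spec.superpixel_px)
    texture /= max(texture.std(), 1e-12)
    stack = level * (1.0 + spec.texture_sd * texture[None])
    stack += rng.normal(0.0, spec.noise_sd, size=stack.shape)
    return np.clip(stack, 0.0, None)


def defect_footprint(spec: PhantomSpec, defect: DefectSpec) -> np.ndarray:
    """Aligned-frame 2-D boolean footprint of one defect."""
    _, drow, dcol, _, dist_o = _aligned_geometry(spec)
    # angle from the temporal horizontal around the ONH, positive superior
    phi = np.degrees(np.arctan2(-drow, -(dcol - 20.0)))
    dphi = (phi - defect.angle_deg + 180.0) % 360.0 - 180.0
    r0, r1 = defect.radius_sp
    if defect.kind == "wedge":
        r0 = 0.0
    fp = (np.abs(dphi) <= defect.width_deg / 2.0) & (dist_o >= r0) & (dist_o <= r1)
    if not fp.any():
        raise ValueError("defect footprint falls outside the image")
    return fp


def _misalign(spec: PhantomSpec, aligned: np.ndarray
              ) -> tuple[np.ndarray, Landmarks]:
    """Shear the aligned stack into raw geometry and derive raw landmarks."""
    H, W = spec.image_shape
    fr, fc = spec.fovea_rc
    td = np.tan(np.radians(spec.theta_disc_deg))
    tr = np.tan(np.radians(spec.theta_raphe_deg))
    cols = np.arange(W, dtype=float)
    tan = np.where(cols >= fc, td, tr)
    shifts = -tan * (cols - fc)          # inverse of the alignment shear
    raw, _ = _shear_stack(aligned, shifts)

    def to_raw(r: float, c: float) -> tuple[float, float]:
        t = td if c >= fc else tr
        return (r + t * (c - fc), c)

    s = spec.superpixel_px
    raphe_cols = fc - s * np.linspace(10.5, 12.5, 5)
    lm = Landmarks(
        fovea=(fr, fc),
        onh=to_raw(*spec.onh_rc),
        raphe_points=tuple(to_raw(fr, c) for c in raphe_cols),
        laterality="right",
    )
    if spec.laterality == "left":
        flip = lambda p: (p[0], W - 1 - p[1])
        lm = Landmarks(fovea=flip(lm.fovea), onh=flip(lm.onh),
                       raphe_points=tuple(flip(p) for p in lm.raphe_points),
                       laterality="left")
        raw = raw[..., ::-1].copy()
    return raw.astype(np.float32), lm


def generate_control(spec: PhantomSpec, seed: int | None = None
                     ) -> tuple[np.ndarray, Landmarks]:
    """One healthy phantom eye: raw (depth, rows, cols) stack + landmarks."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    aligned = _aligned_stack(spec, rng)
    return _misalign(spec, aligned)


def generate_glaucoma(spec: PhantomSpec, defects: list[DefectSpec],
                      seed: int | None = None
                      ) -> tuple[np.ndarray, Landmarks, np.ndarray]:
    """One glaucomatous phantom eye.

    Returns (raw stack, landmarks, truth) where ``truth`` is the
    aligned-frame per-depth boolean defect mask (depth, rows, cols); with
    zero attenuation the stack is identical to the same-seed control.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    aligned = _aligned_stack(spec, rng)
    truth = np.zeros(aligned.shape, dtype=bool)
    for defect in defects:
        fp = defect_footprint(spec, defect)
        k0, k1 = defect.depth_pixels
        if k1 > spec.n_depth:
            raise ValueError("defect depth range exceeds stack depth")
        aligned[k0 - 1:k1] = np.where(fp[None], aligned[k0 - 1:k1]
                                      * (1.0 - defect.attenuation),
                                      aligned[k0 - 1:k1])
        truth[k0 - 1:k1] |= fp[None]
    raw, lm = _misalign(spec, aligned)
    return raw, lm, truth


@dataclass
class PhantomEye:
    eye_id: str
    group: str                       # "control" | "glaucoma"
    stack: np.ndarray
    landmarks: Landmarks
    spec: PhantomSpec
    defects: tuple[DefectSpec, ...] = ()
    truth: np.ndarray | None = None  # aligned-frame (depth, rows, cols) bool


def generate_cohort(n_controls: int = 19, n_glaucoma: int = 16,
                    seed: int = 0, base: PhantomSpec | None = None,
                    defect_depth: tuple[int, int] = (14, 20),
                    superpixel_sizes: tuple[int, ...] = (5, 6),
                    ) -> list[PhantomEye]:
    """A reproducible study cohort with per-eye anatomy variation.

    Per eye: superpixel size drawn from ``superpixel_sizes`` with the
    fovea-ONH distance set to exactly 20 superpixels, fovea position
    jitter, fovea-disc and fovea-raphe angles drawn around +6 deg and
    -7 deg, random laterality.  Glaucomatous eyes receive one superior and
    one inferior arcuate defect near the ONH over ``defect_depth`` pixels.
    """
    if n_controls < 1 or n_glaucoma < 1:
        raise ValueError("need at least one eye per group")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    eyes: list[PhantomEye] = []

    def sample_spec() -> PhantomSpec:
        s = int(rng.choice(superpixel_sizes))
        fr = base.fovea_rc[0] + rng.uniform(-3, 3)
        fc = base.fovea_rc[1] + rng.uniform(-2, 2)
        return replace(
            base,
            superpixel_px=s,
            fovea_rc=(fr, fc),
            theta_disc_deg=float(np.clip(rng.normal(6.0, 3.0), -15, 15)),
            theta_raphe_deg=float(np.clip(rng.normal(-7.0, 3.0), -15, 15)),
            laterality="left" if rng.random() < 0.5 else "right",
        )

    for i in range(n_controls):
        spec = sample_spec()
        eye_seed = int(rng.integers(0, 2**31 - 1))
        stack, lm = generate_control(spec, seed=eye_seed)
        eyes.append(PhantomEye(eye_id=f"C{i+1:02d}", group="control",
                               stack=stack, landmarks=lm, spec=spec))
    for i in range(n_glaucoma):
        spec = sample_spec()
        defects = (
            DefectSpec(kind="arcuate",
                       angle_deg=float(rng.uniform(25, 60)),
                       width_deg=float(rng.uniform(25, 45)),
                       radius_sp=(float(rng.uniform(2.0, 3.0)),
                                  float(rng.uniform(7.0, 9.0))),
                       depth_pixels=defect_depth,
                       attenuation=float(rng.uniform(0.45, 0.7))),
            DefectSpec(kind="arcuate",
                       angle_deg=float(-rng.uniform(25, 60)),
                       width_deg=float(rng.uniform(25, 45)),
                       radius_sp=(float(rng.uniform(2.0, 3.0)),
                                  float(rng.uniform(7.0, 9.0))),
                       depth_pixels=defect_depth,
                       attenuation=float(rng.uniform(0.45, 0.7))),
        )
        eye_seed = int(rng.integers(0, 2**31 - 1))
        stack, lm, truth = generate_glaucoma(spec, list(defects), seed=eye_seed)
        eyes.append(PhantomEye(eye_id=f"G{i+1:02d}", group="glaucoma",
                               stack=stack, landmarks=lm, spec=spec,
                               defects=defects, truth=truth))
    return eyes
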