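"""Fovea-anchored superpixel lattice and named retinal regions.

After alignment each eye is analysed on a square lattice of superpixels
whose side ``s`` is chosen so that exactly 20 superpixels separate the
fovea from the optic nerve head (ONH): ``s = round(d / 20)`` where ``d``
is the fovea–ONH column distance.  This puts every eye in a common
superpixel coordinate system regardless of its fovea–disc distance.  The
fovea sits at the centre of its cell and the fovea–ONH axis runs along a
lattice row.

Named regions (raphe, temporal macula, central, superior/inferior nasal,
ONH region) are defined in superpixel units relative to the fovea and ONH
cells; they drive the region-dependent slab schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .depth import REGION_IDS


@dataclass(frozen=True)
class RegionParams:
    """Geometry of the named regions, in superpixel units."""

    r_onh: float = 6.0           # radius of the ONH region around the ONH cell
    r_mac: float = 10.0          # radius of the temporal macula around the fovea
    raphe_halfwidth: float = 4.0  # vertical half-extent of the raphe band
    central_halfwidth: float = 4.0  # vertical half-extent of the central band


@dataclass(frozen=True)
class SuperpixelGrid:
    size_px: int                     # superpixel side length s (pixels)
    row0: int                        # image row of the top boundary of cell row 0
    col0: int                        # image col of the left boundary of cell col 0
    n_rows: int
    n_cols: int
    fovea_cell: tuple[int, int]
    onh_cell: tuple[int, int]
    image_shape: tuple[int, int]

    def cell_center_px(self, cell_row: int, cell_col: int) -> tuple[float, float]:
        s = self.size_px
        return (self.row0 + (cell_row + 0.5) * s, self.col0 + (cell_col + 0.5) * s)


def round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def grid_from_landmarks(aligned_landmarks, image_shape: tuple[int, int],
                        n_separating: int = 20) -> SuperpixelGrid:
    """Build the lattice from aligned landmarks (fovea and ONH on one row)."""
    fr, fc = aligned_landmarks.fovea
    _, oc = aligned_landmarks.onh
    d = abs(oc - fc)
    s = round_half_away(d / n_separating)
    if s < 1:
        raise ValueError(f"fovea-ONH distance {d:.1f}px yields superpixel size < 1")
    # fovea at its cell centre: the fovea cell's top-left boundary
    f_top = round_half_away(fr - s / 2)
    f_left = round_half_away(fc - s / 2)
    n_up = int(np.ceil(f_top / s))
    n_left = int(np.ceil(f_left / s))
    row0 = f_top - n_up * s
    col0 = f_left - n_left * s
    n_rows = int(np.ceil((image_shape[0] - row0) / s))
    n_cols = int(np.ceil((image_shape[1] - col0) / s))
    fovea_cell = (n_up, n_left)
    onh_cell = (int((fr - row0) // s), int((oc - col0) // s))
    return SuperpixelGrid(size_px=s, row0=row0, col0=col0,
                          n_rows=n_rows, n_cols=n_cols,
                          fovea_cell=fovea_cell, onh_cell=onh_cell,
                          image_shape=tuple(image_shape))


def superpixel_reduce(image: np.ndarray, grid: SuperpixelGrid,
                      validity: np.ndarray | None = None,
                      min_coverage: float = 0.999,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Reduce an image to per-cell means.

    Returns ``(lattice, valid)``: the mean of each cell's constituent
    pixels (NaN pixels and pixels flagged invalid are excluded) and a
    boolean mask of cells whose valid-pixel coverage reaches
    ``min_coverage`` of the full ``s*s`` cell area.  Partial edge cells
    still carry the mean of their available pixels but are flagged.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    s = grid.size_px
    rows_idx = (np.arange(H) - grid.row0) // s
    cols_idx = (np.arange(W) - grid.col0) // s
    cell_id = rows_idx[:, None] * grid.n_cols + cols_idx[None, :]
    ok = np.isfinite(image)
    if validity is not None:
        ok &= np.asarray(validity, dtype=bool)
    ids = cell_id.ravel()
    n_cells = grid.n_rows * grid.n_cols
    w = ok.ravel().astype(float)
    sums = np.bincount(ids, weights=np.where(ok, image, 0.0).ravel(), minlength=n_cells)
    counts = np.bincount(ids, weights=w, minlength=n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    lattice = means.reshape(grid.n_rows, grid.n_cols)
    coverage = counts.reshape(grid.n_rows, grid.n_cols) / float(s * s)
    valid = coverage >= min_coverage
    return lattice, valid


def region_of_offsets(drow: np.ndarray, dcol: np.ndarray,
                      onh_dcol: float = 20.0,
                      params: RegionParams = RegionParams()) -> np.ndarray:
    """Region index for offsets (in superpixel units) from the fovea.

    Returns an integer array indexing into :data:`smas.depth.REGION_IDS`.
    Temporal is negative ``dcol``; the ONH sits at ``(0, onh_dcol)``.
    """
    drow = np.asarray(drow, dtype=float)
    dcol = np.asarray(dcol, dtype=float)
    out = np.full(np.broadcast(drow, dcol).shape, -1, dtype=int)
    dist_f = np.hypot(drow, dcol)
    dist_o = np.hypot(drow, dcol - onh_dcol)
    idx = {r: i for i, r in enumerate(REGION_IDS)}

    onh = dist_o <= params.r_onh
    out[onh] = idx["onh_region"]
    raphe = (out < 0) & (dcol < 0) & (dist_f > params.r_mac) \
        & (np.abs(drow) <= params.raphe_halfwidth)
    out[raphe] = idx["raphe"]
    mac = (out < 0) & (dcol < 0) & (dist_f <= params.r_mac)
    out[mac] = idx["temporal_macula"]
    central = (out < 0) & (np.abs(drow) <= params.central_halfwidth)
    out[central] = idx["central"]
    sup = (out < 0) & (drow < 0)
    out[sup] = idx["superior_nasal"]
    out[out < 0] = idx["inferior_nasal"]
    return out


def region_masks(grid: SuperpixelGrid,
                 params: RegionParams = RegionParams()) -> dict[str, np.ndarray]:
    """Boolean lattice mask per region; masks partition the lattice."""
    rr, cc = np.meshgrid(np.arange(grid.n_rows), np.arange(grid.n_cols),
                         indexing="ij")
    drow = rr - grid.fovea_cell[0]
    dcol = cc - grid.fovea_cell[1]
    onh_dcol = grid.onh_cell[1] - grid.fovea_cell[1]
    labels = region_of_offsets(drow, dcol, onh_dcol=onh_dcol, params=params)
    return {r: labels == i for i, r in enumerate(REGION_IDS)}


def region_pixel_masks(grid: SuperpixelGrid,
                       params: RegionParams = RegionParams()
                       ) -> dict[str, np.ndarray]:
    """Rasterise the region geometry to image-pixel boolean masks.

    Each image pixel inherits the region of the lattice cell containing
    it, so composite slabs stitched from these masks line up exactly with
    the superpixel analysis.
    """
    H, W = grid.image_shape
    s = grid.size_px
    rows_idx = (np.arange(H) - grid.row0) // s
    cols_idx = (np.arange(W) - grid.col0) // s
    drow = rows_idx[:, None] - grid.fovea_cell[0]
    dcol = cols_idx[None, :] - grid.fovea_cell[1]
    onh_dcol = grid.onh_cell[1] - grid.fovea_cell[1]
    labels = region_of_offsets(
        np.broadcast_to(drow, (H, W)), np.broadcast_to(dcol, (H, W)),
        onh_dcol=onh_dcol, params=params)
    return {r: labels == i for i, r in enumerate(REGION_IDS)}


@dataclass(frozen=True)
class LatticeWindow:
    """A fixed window of cell offsets relative to the fovea cell, shared by
    all eyes so normative statistics can be pooled cell-by-cell."""

    row_extent: int = 10     # rows fovea-10 .. fovea+10
    temporal_extent: int = 13
    nasal_extent: int = 27

    @property
    def shape(self) -> tuple[int, int]:
        return (2 * self.row_extent + 1, self.temporal_extent + self.nasal_extent + 1)

    @property
    def fovea_index(self) -> tuple[int, int]:
        return (self.row_extent, self.temporal_extent)

    def onh_index(self, n_separating: int = 20) -> tuple[int, int]:
        return (self.row_extent, self.temporal_extent + n_separating)


def extract_window(lattice: np.ndarray, valid: np.ndarray,
                   grid: SuperpixelGrid,
                   window: LatticeWindow = LatticeWindow()
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Re-index a per-eye lattice onto the common fovea-centred window.

    Cells outside the eye's lattice are NaN/invalid.
    """
    H, W = window.shape
    out = np.full((H, W), np.nan)
    out_valid = np.zeros((H, W), dtype=bool)
    fr, fc = grid.fovea_cell
    for i, dr in enumerate(range(-window.row_extent, window.row_extent + 1)):
        r = fr + dr
        if not 0 <= r < grid.n_rows:
            continue
        for j, dc in enumerate(range(-window.temporal_extent,
                                     window.nasal_extent + 1)):
            c = fc + dc
            if 0 <= c < grid.n_cols:
                out[i, j] = lattice[r, c]
                out_valid[i, j] = valid[r, c]
    return out, out_valid
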