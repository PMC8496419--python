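"""Axial depth geometry and en face slab construction.

Depth below the inner limiting membrane (ILM) is discretised into
single-pixel slabs of the instrument's axial resolution (3.87 µm by
default, 50 pixels, i.e. ILM to 193.5 µm).  A *slab* is a contiguous band
of depth pixels averaged into one transverse image.  Six slab-construction
schemes are provided:

=========  ==============================================================
SMAS       twelve consecutive 4-pixel bands tiling pixels 3–50; the first
           seven (down to 116.1 µm) enter detection
Hood       pixels 1–13 everywhere (ILM to 50.3 µm)
Ashimatey  region-dependent: ONH 7–13, raphe 5–6, elsewhere 7–9
BestVis    raphe/temporal macula 4–6, elsewhere 5–7
AllVis     region-dependent, 3–8 up to 3–21 (all depths with visible
           bundles in healthy eyes)
Deep       pixels 10–20 everywhere (34.8 to 77.4 µm)
=========  ==============================================================

Depth-pixel indices are 1-based inclusive; pixel ``k`` spans
``((k-1)*delta, k*delta]`` µm below the ILM.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Region identifiers produced by :mod:`smas.grid` and consumed by the
#: region-dependent schemes.  Order is fixed (used for composite assembly).
REGION_IDS = (
    "raphe",
    "temporal_macula",
    "central",
    "superior_nasal",
    "inferior_nasal",
    "onh_region",
)

SCHEME_NAMES = ("SMAS", "Hood", "Ashimatey", "BestVis", "AllVis", "Deep")


@dataclass(frozen=True)
class DepthAxis:
    """Axial sampling: ``n_pixels`` single-pixel slabs of ``pixel_size_um``."""

    pixel_size_um: float = 3.87
    n_pixels: int = 50

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")

    @property
    def total_depth_um(self) -> float:
        """Total depth span below the ILM (193.5 µm at defaults)."""
        return self.pixel_size_um * self.n_pixels


@dataclass(frozen=True)
class SlabBand:
    """Inclusive 1-based band of depth pixels ``pixel_start..pixel_end``."""

    pixel_start: int
    pixel_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.pixel_start <= self.pixel_end:
            raise ValueError(f"invalid band {self.pixel_start}..{self.pixel_end}")

    @property
    def width(self) -> int:
        return self.pixel_end - self.pixel_start + 1

    def depth_range_um(self, axis: DepthAxis = DepthAxis()) -> tuple[float, float]:
        """(anterior, posterior) depth in µm below the ILM."""
        if self.pixel_end > axis.n_pixels:
            raise IndexError(f"band end {self.pixel_end} exceeds {axis.n_pixels} pixels")
        return ((self.pixel_start - 1) * axis.pixel_size_um,
                self.pixel_end * axis.pixel_size_um)


@dataclass(frozen=True)
class SlabScheme:
    """A slab-construction method.

    Region-dependent schemes map each region id to one band; SMAS instead
    carries an ordered list of retina-wide bands of which the first
    ``analyzed_slabs`` enter detection.
    """

    name: str
    bands: dict[str, SlabBand] = field(default_factory=dict)
    smas_bands: tuple[SlabBand, ...] = ()
    analyzed_slabs: int = 0

    @property
    def is_multi_slab(self) -> bool:
        return len(self.smas_bands) > 0

    @property
    def is_region_dependent(self) -> bool:
        """True when different regions use different depth bands."""
        return len(set(self.bands.values())) > 1

    def analyzed_bands(self) -> tuple[SlabBand, ...]:
        if self.is_multi_slab:
            return self.smas_bands[: self.analyzed_slabs]
        return (next(iter(self.bands.values())),) if not self.is_region_dependent \
            else tuple(self.bands.values())


def pixel_depth_range(k: int, axis: DepthAxis = DepthAxis()) -> tuple[float, float]:
    """Depth span (µm below ILM) of 1-based depth pixel ``k``.

    >>> pixel_depth_range(50)
    (189.63, 193.5)
    """
    if not 1 <= k <= axis.n_pixels:
        raise IndexError(f"depth pixel {k} outside 1..{axis.n_pixels}")
    return ((k - 1) * axis.pixel_size_um, k * axis.pixel_size_um)


def smas_band(m: int) -> SlabBand:
    """The ``m``-th (1..12) SMAS band: four pixels starting at pixel 3.

    Band 1 covers pixels 3–6 (7.74–23.22 µm); band 12 ends at pixel 50
    (193.5 µm).  The first two depth pixels are excluded because they
    contain vitreous-interface artefact rather than nerve fiber bundles.
    """
    if not 1 <= m <= 12:
        raise IndexError(f"SMAS slab index {m} outside 1..12")
    start = 4 * (m - 1) + 3
    return SlabBand(start, start + 3)


def scheme_catalog() -> dict[str, SlabScheme]:
    """The six slab-construction schemes, keyed by name."""
    uniform = lambda a, b: {r: SlabBand(a, b) for r in REGION_IDS}
    catalog = {
        "SMAS": SlabScheme(
            name="SMAS",
            smas_bands=tuple(smas_band(m) for m in range(1, 13)),
            analyzed_slabs=7,
        ),
        "Hood": SlabScheme(name="Hood", bands=uniform(1, 13)),
        "Ashimatey": SlabScheme(
            name="Ashimatey",
            bands={
                "onh_region": SlabBand(7, 13),
                "raphe": SlabBand(5, 6),
                "temporal_macula": SlabBand(7, 9),
                "central": SlabBand(7, 9),
                "superior_nasal": SlabBand(7, 9),
                "inferior_nasal": SlabBand(7, 9),
            },
        ),
        "BestVis": SlabScheme(
            name="BestVis",
            bands={
                "raphe": SlabBand(4, 6),
                "temporal_macula": SlabBand(4, 6),
                "central": SlabBand(5, 7),
                "superior_nasal": SlabBand(5, 7),
                "inferior_nasal": SlabBand(5, 7),
                "onh_region": SlabBand(5, 7),
            },
        ),
        "AllVis": SlabScheme(
            name="AllVis",
            bands={
                "raphe": SlabBand(3, 8),
                "temporal_macula": SlabBand(3, 10),
                "inferior_nasal": SlabBand(3, 12),
                "central": SlabBand(3, 15),
                "superior_nasal": SlabBand(3, 15),
                "onh_region": SlabBand(3, 21),
            },
        ),
        "Deep": SlabScheme(name="Deep", bands=uniform(10, 20)),
    }
    return catalog


def average_band(stack: np.ndarray, band: SlabBand,
                 region_mask: np.ndarray | None = None) -> np.ndarray:
    """Mean over the band's depth pixels, per transverse pixel.

    ``stack`` is (depth, rows, cols) with depth pixel 1 at index 0.  Where
    ``region_mask`` is given the output is NaN outside the mask.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (depth, rows, cols)")
    if band.pixel_end > stack.shape[0]:
        raise IndexError(
            f"band {band.pixel_start}..{band.pixel_end} exceeds stack depth {stack.shape[0]}")
    slab = stack[band.pixel_start - 1: band.pixel_end].mean(axis=0)
    if region_mask is not None:
        slab = np.where(region_mask, slab, np.nan)
    return slab


def build_method_slabs(
    stack: np.ndarray,
    scheme: SlabScheme,
    region_masks: dict[str, np.ndarray] | None = None,
) -> list[tuple[np.ndarray, SlabBand | dict[str, SlabBand], str]]:
    """Produce the scheme's slab image(s) from an aligned stack.

    Returns a list of ``(image, band(s), coverage)`` tuples: SMAS yields
    ``analyzed_slabs`` retina-wide images; a region-dependent scheme yields
    one composite image stitched region-by-region (hard boundaries); a
    uniform scheme yields a single retina-wide image.
    """
    if scheme.is_multi_slab:
        return [(average_band(stack, b), b, "retina")
                for b in scheme.smas_bands[: scheme.analyzed_slabs]]
    if not scheme.is_region_dependent:
        band = next(iter(scheme.bands.values()))
        return [(average_band(stack, band), band, "retina")]
    if region_masks is None:
        raise ValueError(f"scheme {scheme.name!r} needs region masks")
    missing = [r for r in scheme.bands if r not in region_masks]
    if missing:
        raise ValueError(f"no mask supplied for region(s) {missing}")
    composite = np.full(stack.shape[1:], np.nan, dtype=float)
    for region, band in scheme.bands.items():
        mask = np.asarray(region_masks[region], dtype=bool)
        composite[mask] = average_band(stack, band)[mask]
    return [(composite, dict(scheme.bands), "composite")]


# -- YAML (de)serialisation of scheme catalogs ------------------------------

def schemes_to_yaml(schemes: dict[str, SlabScheme]) -> str:
    """Serialise a catalog to a ``schemes:`` YAML block."""
    out: dict = {"schemes": {}}
    for name, sc in schemes.items():
        if sc.is_multi_slab:
            out["schemes"][name] = {
                "slabs": [[b.pixel_start, b.pixel_end] for b in sc.smas_bands],
                "analyzed_slabs": sc.analyzed_slabs,
            }
        else:
            out["schemes"][name] = {
                "bands": {r: [b.pixel_start, b.pixel_end] for r, b in sc.bands.items()}
            }
    return yaml.safe_dump(out, sort_keys=False)


def schemes_from_yaml(text: str | io.TextIOBase) -> dict[str, SlabScheme]:
    """Parse a ``schemes:`` YAML block written by :func:`schemes_to_yaml`."""
    doc = yaml.safe_load(text)
    schemes: dict[str, SlabScheme] = {}
    for name, body in doc["schemes"].items():
        if "slabs" in body:
            schemes[name] = SlabScheme(
                name=name,
                smas_bands=tuple(SlabBand(a, b) for a, b in body["slabs"]),
                analyzed_slabs=int(body.get("analyzed_slabs", len(body["slabs"]))),
            )
        else:
            schemes[name] = SlabScheme(
                name=name,
                bands={r: SlabBand(a, b) for r, (a, b) in body["bands"].items()},
            )
    return schemes
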