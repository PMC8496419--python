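"""Standard-format readers and writers.

Stacks are multi-page float32 TIFF (one page per depth pixel, anterior
first); landmarks are JSON; lattices and metrics go to CSV; deviation
maps can be exported as CSV or as a colour-coded PNG using the standard
four-category scheme (grey = within normal limits, yellow / orange / red
= below the 10th / 5th / 1st percentile, white = untested).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .normative import Category, CombinedDeviationMap, DeviationMap

CATEGORY_COLORS = {
    int(Category.UNTESTED): (1.0, 1.0, 1.0),
    int(Category.WNL): (0.65, 0.65, 0.65),
    int(Category.BELOW10): (1.0, 0.85, 0.2),
    int(Category.BELOW5): (1.0, 0.55, 0.1),
    int(Category.BELOW1): (0.85, 0.1, 0.1),
}


def write_stack(path: str | Path, stack: np.ndarray,
                metadata: dict | None = None) -> None:
    """Write a (depth, rows, cols) stack as multi-page float32 TIFF."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 3:
        raise ValueError("stack must be (depth, rows, cols)")
    extra = {"description": json.dumps(metadata)} if metadata else {}
    tifffile.imwrite(Path(path), stack, **extra)


def read_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float32)


def write_lattice_csv(path: str | Path, lattice: np.ndarray,
                      extra_columns: dict[str, np.ndarray] | None = None) -> None:
    """Lattice as long-format CSV (row, col, value [, ...])."""
    rr, cc = np.meshgrid(np.arange(lattice.shape[0]),
                         np.arange(lattice.shape[1]), indexing="ij")
    data = {"row": rr.ravel(), "col": cc.ravel(), "value": lattice.ravel()}
    for name, arr in (extra_columns or {}).items():
        data[name] = np.asarray(arr).ravel()
    pd.DataFrame(data).to_csv(Path(path), index=False)


def deviation_map_to_csv(path: str | Path,
                         dev: DeviationMap | CombinedDeviationMap) -> None:
    if isinstance(dev, CombinedDeviationMap):
        lattice = np.where(dev.tested,
                           np.where(dev.abnormal, int(Category.BELOW1),
                                    int(Category.WNL)),
                           int(Category.UNTESTED))
    else:
        lattice = dev.categories
    write_lattice_csv(path, lattice.astype(int))


def deviation_map_to_png(path: str | Path,
                         dev: DeviationMap | CombinedDeviationMap,
                         cell_px: int = 12) -> None:
    """Colour-coded deviation map image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(dev, CombinedDeviationMap):
        cats = np.where(dev.tested,
                        np.where(dev.abnormal, int(Category.BELOW1),
                                 int(Category.WNL)),
                        int(Category.UNTESTED))
    else:
        cats = dev.categories
    rgb = np.zeros(cats.shape + (3,))
    for value, color in CATEGORY_COLORS.items():
        rgb[cats == value] = color
    h, w = cats.shape
    fig, ax = plt.subplots(figsize=(w * cell_px / 72, h * cell_px / 72))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(Path(path), bbox_inches="tight", dpi=72)
    plt.close(fig)
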