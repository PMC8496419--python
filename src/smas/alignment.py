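"""Anatomic standardisation: right-eye formatting and the double vertical
shear that places raphe, fovea and optic nerve head on one horizontal line.

Coordinates are (row, col) with row increasing downward.  In right-eye
format the ONH lies nasal (larger column) of the fovea and the raphe
temporal (smaller column).  The fovea–disc angle is the signed angle of
the fovea→ONH line; the fovea–raphe angle is the mean signed slope angle
of five fovea→raphe-point lines.  Shearing each side of the fovea
vertically by the negative of its angle brings all three landmarks onto
the fovea's row while leaving every column coordinate unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class Landmarks:
    """Fovea, ONH centre and five raphe-gap points, plus laterality."""

    fovea: tuple[float, float]
    onh: tuple[float, float]
    raphe_points: tuple[tuple[float, float], ...]
    laterality: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        if len(self.raphe_points) != 5:
            raise ValueError("exactly 5 raphe points are required")
        if tuple(self.fovea) == tuple(self.onh):
            raise ValueError("fovea and ONH coincide")

    @classmethod
    def from_json(cls, path: str | Path) -> "Landmarks":
        doc = json.loads(Path(path).read_text())
        return cls(
            fovea=tuple(doc["fovea"]),
            onh=tuple(doc["onh"]),
            raphe_points=tuple(tuple(p) for p in doc["raphe"]),
            laterality=doc["laterality"],
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "fovea": list(self.fovea),
            "onh": list(self.onh),
            "raphe": [list(p) for p in self.raphe_points],
            "laterality": self.laterality,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class AlignedStack:
    """Depth-resolved stack after flip + double shear.

    ``validity`` marks transverse pixels whose value was interpolated from
    inside the original canvas; rows sheared in from outside are zero and
    invalid (they must not be read as real tissue).
    """

    stack: np.ndarray
    landmarks: Landmarks
    validity: np.ndarray
    provenance: dict


def to_right_eye(stack: np.ndarray, landmarks: Landmarks
                 ) -> tuple[np.ndarray, Landmarks]:
    """Mirror left eyes about the vertical axis; right eyes pass through."""
    if landmarks.laterality == "right":
        return stack, landmarks
    stack = np.asarray(stack)
    w = stack.shape[-1]
    flip = lambda p: (p[0], w - 1 - p[1])
    lm = Landmarks(
        fovea=flip(landmarks.fovea),
        onh=flip(landmarks.onh),
        raphe_points=tuple(flip(p) for p in landmarks.raphe_points),
        laterality="right",
    )
    return stack[..., ::-1].copy(), lm


def fovea_disc_angle(landmarks: Landmarks) -> float:
    """Signed angle (degrees) of the fovea→ONH vector vs the horizontal."""
    dr = landmarks.onh[0] - landmarks.fovea[0]
    dc = landmarks.onh[1] - landmarks.fovea[1]
    if dr == 0 and dc == 0:
        raise ValueError("fovea and ONH coincide")
    return float(np.degrees(np.arctan2(dr, dc)))


def fovea_raphe_angle(landmarks: Landmarks) -> float:
    """Mean signed slope angle (degrees) of the five fovea→raphe lines.

    The slope angle lies in (-90, 90) regardless of which side of the
    fovea the point sits on, so the same shear formula applies to the
    temporal half-image.
    """
    if len(landmarks.raphe_points) < 5:
        raise ValueError("need 5 raphe points")
    fr, fc = landmarks.fovea
    angles = []
    for r, c in landmarks.raphe_points:
        if c == fc:
            raise ValueError("raphe point vertically aligned with fovea")
        angles.append(np.degrees(np.arctan((r - fr) / (c - fc))))
    return float(np.mean(angles))


def _shear_stack(stack: np.ndarray, shifts: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Vertical shear: output[r, c] samples input[r + shifts[c], c].

    Bilinear along rows, zero padding; returns (sheared, validity mask).
    """
    stack = np.asarray(stack, dtype=float)
    single = stack.ndim == 2
    if single:
        stack = stack[None]
    n_rows, n_cols = stack.shape[1], stack.shape[2]
    rows = np.arange(n_rows)[:, None]
    src = rows + shifts[None, :]            # (rows, cols) fractional source rows
    lo = np.floor(src).astype(int)
    frac = src - lo
    valid_lo = (lo >= 0) & (lo <= n_rows - 1)
    valid_hi = (lo + 1 >= 0) & (lo + 1 <= n_rows - 1)
    lo_c = np.clip(lo, 0, n_rows - 1)
    hi_c = np.clip(lo + 1, 0, n_rows - 1)
    cols = np.arange(n_cols)[None, :]
    a = stack[:, lo_c, cols] * np.where(valid_lo, 1.0 - frac, 0.0)[None]
    b = stack[:, hi_c, cols] * np.where(valid_hi, frac, 0.0)[None]
    out = a + b
    # valid only if every source row carrying weight lies inside the canvas
    eps = 1e-12
    validity = (valid_lo | (frac >= 1.0 - eps)) & (valid_hi | (frac <= eps))
    out = np.where(validity[None], out, 0.0)
    return (out[0] if single else out), validity


def double_shear(stack: np.ndarray, landmarks: Landmarks,
                 max_angle_deg: float = 45.0) -> AlignedStack:
    """Apply the double vertical shear that aligns raphe, fovea and ONH.

    The nasal half (columns at/right of the fovea) is sheared by the
    negative fovea–disc angle, the temporal half by the negative
    fovea–raphe angle, identically at every depth.  Columns are never
    moved.  Input must already be in right-eye format.
    """
    theta_d = fovea_disc_angle(landmarks)
    theta_r = fovea_raphe_angle(landmarks)
    if abs(theta_d) >= max_angle_deg or abs(theta_r) >= max_angle_deg:
        raise ValueError(f"degenerate shear: angles ({theta_d:.1f}, {theta_r:.1f}) deg")
    fr, fc = landmarks.fovea
    n_cols = np.asarray(stack).shape[-1]
    cols = np.arange(n_cols, dtype=float)
    tan = np.where(cols >= fc, np.tan(np.radians(theta_d)),
                   np.tan(np.radians(theta_r)))
    shifts = tan * (cols - fc)
    sheared, validity = _shear_stack(stack, shifts)

    def move(p: tuple[float, float]) -> tuple[float, float]:
        t = np.tan(np.radians(theta_d if p[1] >= fc else theta_r))
        return (p[0] - t * (p[1] - fc), p[1])

    lm = replace(landmarks,
                 fovea=(fr, fc),
                 onh=move(landmarks.onh),
                 raphe_points=tuple(move(p) for p in landmarks.raphe_points))
    return AlignedStack(
        stack=sheared,
        landmarks=lm,
        validity=validity,
        provenance={"fovea_disc_angle_deg": theta_d,
                    "fovea_raphe_angle_deg": theta_r,
                    "laterality_flipped": False},
    )
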