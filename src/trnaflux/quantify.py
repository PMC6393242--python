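"""Image quantification: ROI intensity ratios and radial profiles.

Reproduces the measurement chain applied to the confocal time-lapses:
small (5x5 px) square ROIs placed just inside and just outside the
nuclear membrane give the nuclear and perinuclear cytoplasmic
intensities whose ratio is the FIR; the cytoplasmic sampling boxes sit
1.5 um outside the membrane.  Radial intensity profiles averaged over
rays from the nucleus centre, normalized by the peak of the first
frame's profile, characterise the perinuclear ring and its decay.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks, peak_widths
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_holes

from .kinetics import FIRSeries
from .synthetic import CYTO_SAMPLING_OFFSET_UM, CellGeometry2D, CellImageStack

__all__ = [
    "RadialProfile",
    "RingStats",
    "segment",
    "roi_fir",
    "mean_cytoplasmic_intensity",
    "radial_profile",
    "ring_stats",
]

ROI_HALF = 2  # 5x5 px boxes
W_TOLERANCE = 1.05  # w above this flags a profile inversion


@dataclass
class RadialProfile:
    """Ray-averaged intensity vs distance from the nucleus centre."""

    r: np.ndarray                      # um, increasing
    intensity: np.ndarray              # normalized a.u.
    normalization_constant: float      # raw peak used for normalization
    t: float = 0.0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.r < 0) or np.any(np.diff(self.r) <= 0):
            raise ValueError("radii must be nonnegative and increasing")
        if self.r.shape != self.intensity.shape:
            raise ValueError("r and intensity must match in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "r": self.r, "intensity": self.intensity})


@dataclass
class RingStats:
    """Location/size of the perinuclear intensity ring, if present."""

    present: bool
    peak_radius: float = float("nan")   # um
    peak_height: float = float("nan")   # normalized a.u.
    ring_width: float = float("nan")    # um, full width at half prominence

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(
    stack: CellImageStack,
    smoothing_sigma_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (nucleus_mask, cell_mask) for a stack.

    Masks supplied on the stack are validated and passed through.
    Otherwise the cell is segmented from the first frame by Otsu
    thresholding of a smoothed image followed by largest-component
    selection and hole filling; the nucleus comes from the stack's
    synthetic geometry when available (it cannot be told apart from
    cytoplasm by intensity alone at early times).
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    if stack.nucleus_mask is not None and stack.cell_mask is not None:
        return stack.nucleus_mask.astype(bool), stack.cell_mask.astype(bool)

    frame = stack.frames[0]
    if not np.any(frame > 0) or np.ptp(frame) == 0:
        raise ValueError("cannot segment a constant image")
    smoothed = gaussian(frame, sigma=smoothing_sigma_px, preserve_range=True)
    mask = smoothed > threshold_otsu(smoothed)
    if not mask.any():
        raise ValueError("segmentation produced an empty cell mask")
    labels = cc_label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    cell = remove_small_holes(labels == largest, max_size=mask.size // 4)

    if stack.geometry is not None:
        nucleus, _ = stack.geometry.masks()
    elif stack.nucleus_mask is not None:
        nucleus = stack.nucleus_mask.astype(bool)
    else:
        raise ValueError(
            "no nucleus mask or geometry available; supply a nucleus mask"
        )
    return nucleus, cell | nucleus


# ---------------------------------------------------------------------------
# ROI-based FIR extraction
# ---------------------------------------------------------------------------

def _nucleus_center_px(nucleus_mask: np.ndarray) -> tuple[float, float]:
    ys, xs = np.nonzero(nucleus_mask)
    return float(ys.mean()), float(xs.mean())


def _box_ok(mask: np.ndarray, cy: int, cx: int) -> bool:
    h, w = mask.shape
    if not (ROI_HALF <= cy < h - ROI_HALF and ROI_HALF <= cx < w - ROI_HALF):
        return False
    return bool(
        mask[cy - ROI_HALF : cy + ROI_HALF + 1, cx - ROI_HALF : cx + ROI_HALF + 1].all()
    )


def _place_boxes(
    mask: np.ndarray, center: tuple[float, float], radius_px: float, n_rois: int
) -> list[tuple[int, int]]:
    """Centres of 5x5 boxes at equal angles, keeping boxes inside ``mask``."""
    cy, cx = center
    out = []
    for ang in np.linspace(0, 2 * np.pi, n_rois, endpoint=False):
        by = int(round(cy + radius_px * np.sin(ang)))
        bx = int(round(cx + radius_px * np.cos(ang)))
        if _box_ok(mask, by, bx):
            out.append((by, bx))
        else:
            warnings.warn(f"ROI at angle {np.degrees(ang):.0f} deg crosses a boundary; dropped")
    return out


def _box_mean(frame: np.ndarray, boxes: list[tuple[int, int]]) -> float:
    vals = [
        frame[y - ROI_HALF : y + ROI_HALF + 1, x - ROI_HALF : x + ROI_HALF + 1].mean()
        for y, x in boxes
    ]
    return float(np.mean(vals))


def roi_fir(
    stack: CellImageStack,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
    cyto_offset_um: float = CYTO_SAMPLING_OFFSET_UM,
    n_rois: int = 8,
    nucleus_radius_um: float | None = None,
) -> FIRSeries:
    """FIR time series from perinuclear 5x5-px ROI averages.

    Per frame, ``n_rois`` boxes are placed at equal angles just inside
    the nuclear boundary (nuclear sample) and ``n_rois`` centred
    ``cyto_offset_um`` outside it (cytoplasmic sample); each set is
    averaged and the ratio of the averages is the FIR.  Boxes that would
    cross a compartment boundary are dropped with a warning; if either
    set empties out, that is an error.
    """
    nucleus, cell = masks if masks is not None else segment(stack)
    cyto = cell & ~nucleus
    center = _nucleus_center_px(nucleus)
    ps = stack.pixel_size
    if nucleus_radius_um is None:
        if stack.geometry is not None:
            nucleus_radius_um = stack.geometry.nucleus_radius
        else:  # equivalent-area radius of the mask
            nucleus_radius_um = ps * np.sqrt(nucleus.sum() / np.pi)
    r_n_px = nucleus_radius_um / ps

    nuc_boxes = _place_boxes(nucleus, center, r_n_px - (ROI_HALF + 2), n_rois)
    cyto_boxes = _place_boxes(cyto, center, r_n_px + cyto_offset_um / ps, n_rois)
    if not nuc_boxes or not cyto_boxes:
        raise ValueError("all ROI boxes were dropped; geometry too tight for 5x5 boxes")

    fir = np.empty(len(stack))
    for i, frame in enumerate(stack.frames):
        c_n = _box_mean(frame, nuc_boxes)
        c_c = _box_mean(frame, cyto_boxes)
        if c_c <= 0:
            raise ZeroDivisionError(f"cytoplasmic ROI intensity is zero at frame {i}")
        fir[i] = c_n / c_c
    return FIRSeries(times=stack.times, fir=np.clip(fir, 0, None), provenance="extracted")


def mean_cytoplasmic_intensity(
    stack: CellImageStack,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
    **roi_kwargs,
) -> pd.DataFrame:
    """Per-frame cytoplasm spatial mean and the uniformity factor w.

    w = Cbar_C / C_C with C_C from the perinuclear ROI sample; values
    above ~1.05 indicate an inverted profile (brighter periphery) and
    are flagged with a warning.
    """
    nucleus, cell = masks if masks is not None else segment(stack)
    cyto = cell & ~nucleus
    if not cyto.any():
        raise ValueError("empty cytoplasm mask")
    center = _nucleus_center_px(nucleus)
    ps = stack.pixel_size
    r_n_px = (
        stack.geometry.nucleus_radius / ps
        if stack.geometry is not None
        else np.sqrt(nucleus.sum() / np.pi)
    )
    offset = roi_kwargs.get("cyto_offset_um", CYTO_SAMPLING_OFFSET_UM)
    boxes = _place_boxes(cyto, center, r_n_px + offset / ps, roi_kwargs.get("n_rois", 8))
    if not boxes:
        raise ValueError("no valid cytoplasmic ROI boxes")

    rows = []
    for t, frame in zip(stack.times, stack.frames):
        c_bar = float(frame[cyto].mean())
        c_c = _box_mean(frame, boxes)
        w = c_bar / c_c if c_c > 0 else np.nan
        rows.append({"t": t, "C_bar_C": c_bar, "C_C": c_c, "w": w})
        if np.isfinite(w) and w > W_TOLERANCE:
            warnings.warn(
                f"w = {w:.3f} > 1 at t = {t}: cytoplasm brighter at the periphery "
                "than perinuclearly (profile inversion)"
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Radial profiles and ring statistics
# ---------------------------------------------------------------------------

def radial_profile(
    frame: np.ndarray,
    center_px: tuple[float, float],
    pixel_size: float,
    n_rays: int = 72,
    r_max_um: float | None = None,
    dr_um: float | None = None,
    normalization_constant: float | None = None,
    t: float = 0.0,
) -> RadialProfile:
    """Ray-averaged radial intensity profile from ``center_px`` (row, col).

    Intensity is sampled by bilinear interpolation along ``n_rays``
    equally spaced rays and averaged over rays at each radius.  The
    profile is divided by ``normalization_constant`` when given; when
    omitted (the t = 0 frame) it is divided by its own maximum, which is
    then stored so later frames share the same scale.
    """
    cy, cx = center_px
    h, w = frame.shape
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("profile centre lies outside the image")
    if r_max_um is None:
        r_max_um = pixel_size * (min(h, w) / 2 - 1)
    if dr_um is None:
        dr_um = pixel_size / 2
    r = np.arange(0.0, r_max_um, dr_um)
    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    rr, aa = np.meshgrid(r / pixel_size, angles)
    rows = cy + rr * np.sin(aa)
    cols = cx + rr * np.cos(aa)
    samples = map_coordinates(frame, [rows.ravel(), cols.ravel()], order=1, mode="nearest")
    prof = samples.reshape(n_rays, r.size).mean(axis=0)

    if normalization_constant is None:
        normalization_constant = float(prof.max())
        if normalization_constant <= 0:
            raise ValueError("profile is nonpositive; cannot normalize")
    return RadialProfile(
        r=r, intensity=prof / normalization_constant,
        normalization_constant=normalization_constant, t=t,
    )


def ring_stats(
    profile: RadialProfile,
    nucleus_radius: float,
    prominence: float = 0.02,
    boundary_margin: float = 0.5,
) -> RingStats:
    """Detect the perinuclear intensity ring in a radial profile.

    Looks for the most prominent local maximum outside the nuclear
    membrane whose height exceeds the cytoplasmic intensity just outside
    it by at least ``prominence`` (in normalized units).  The first
    ``boundary_margin`` um outside the membrane are excluded: pixel
    interpolation across the nucleus/cytoplasm step blends the two
    compartments there and would otherwise fake a local maximum.
    Monotone or flat cytoplasmic profiles yield ``present=False``.
    """
    outside = profile.r >= nucleus_radius + boundary_margin
    if outside.sum() < 5:
        raise ValueError("profile does not extend beyond the nucleus radius")
    r_out = profile.r[outside]
    y_out = profile.intensity[outside]
    at_membrane = y_out[0]

    peaks, props = find_peaks(y_out, prominence=prominence)
    peaks = peaks[y_out[peaks] >= at_membrane + prominence]
    if peaks.size == 0:
        return RingStats(present=False)
    best = peaks[np.argmax(y_out[peaks])]
    widths, *_ = peak_widths(y_out, np.array([best]), rel_height=0.5)
    dr = r_out[1] - r_out[0]
    return RingStats(
        present=True,
        peak_radius=float(r_out[best]),
        peak_height=float(y_out[best]),
        ring_width=float(widths[0] * dr),
    )


def profiles_to_csv(profiles: list[RadialProfile], path: str | Path) -> None:
    """Long-format (t, r, intensity) CSV of a list of radial profiles."""
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(path, index=False)
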