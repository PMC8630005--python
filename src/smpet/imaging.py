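"""From two-channel TIRF image stacks to per-molecule intensity traces.

Stages: local-maximum spot detection with intensity-weighted centroid
refinement, fiducial-bead affine registration of the red channel onto the
green, greedy one-to-one co-localization of spots into molecule ROIs, and
per-frame maximum-pixel trace read-out within each ROI.

Coordinates are (x, y) pixel units, 0-based, pixel centres at integers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter

from .geometry import AffineMap
from .traces import TraceSet

log = logging.getLogger(__name__)


@dataclass
class SpotLocalization:
    frame: int
    x: float
    y: float
    intensity: float            # background-subtracted, integrated over the window
    channel: str = ""


@dataclass
class ChannelTransform:
    """Affine map taking channel-2 (red) coordinates into the channel-1
    (green) frame, with the RMS residual of the fit."""
    affine: AffineMap
    residual_rms_px: float
    n_beads: int = 0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.affine.apply(points)

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls(AffineMap.identity(), 0.0, 0)


@dataclass
class RoiPair:
    molecule_id: int
    center_ch1: tuple
    center_ch2: tuple
    half_width_px: int
    distance_px: float


def detect_spots(image: np.ndarray, threshold_k: float = 5.0,
                 psf_sigma_px: float = 1.3, channel: str = "") -> list[SpotLocalization]:
    """Detect diffraction-limited spots in one frame.

    Local maxima above (background median + threshold_k x robust background
    sigma) are refined to sub-pixel position by an intensity-weighted centroid
    over a (2 ceil(3 sigma_psf) + 1)^2 window; maxima closer than
    4 sigma_psf are merged keeping the brighter one.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a single 2-D frame")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if threshold_k <= 0:
        raise ValueError("threshold_k must be > 0")
    if img.size == 0:
        return []

    background = float(np.median(img))
    sigma_bg = 1.4826 * float(np.median(np.abs(img - background)))
    threshold = background + threshold_k * max(sigma_bg, 1e-12)

    footprint = max(3, 2 * int(math.ceil(2 * psf_sigma_px)) + 1)
    is_max = (img == maximum_filter(img, size=footprint)) & (img > threshold)
    ys, xs = np.nonzero(is_max)
    if xs.size == 0:
        return []

    # merge maxima closer than 4 sigma_psf, keep the brighter
    order = np.argsort(-img[ys, xs])
    keep: list[int] = []
    min_sep = 4.0 * psf_sigma_px
    for i in order:
        if all(math.hypot(float(xs[i] - xs[j]), float(ys[i] - ys[j])) >= min_sep
               for j in keep):
            keep.append(i)

    half = int(math.ceil(3.0 * psf_sigma_px))
    h, w = img.shape
    spots: list[SpotLocalization] = []
    for i in keep:
        x0, y0 = int(xs[i]), int(ys[i])
        xa, xb = max(0, x0 - half), min(w, x0 + half + 1)
        ya, yb = max(0, y0 - half), min(h, y0 + half + 1)
        window = img[ya:yb, xa:xb] - background
        window = np.clip(window, 0.0, None)
        total = window.sum()
        if total <= 0:
            continue
        gx = np.arange(xa, xb)
        gy = np.arange(ya, yb)
        cx = float((window.sum(axis=0) * gx).sum() / total)
        cy = float((window.sum(axis=1) * gy).sum() / total)
        spots.append(SpotLocalization(frame=0, x=cx, y=cy,
                                      intensity=float(total), channel=channel))
    spots.sort(key=lambda s: (-s.intensity,))
    return spots


def _match_mutual_nearest(p1: np.ndarray, p2: np.ndarray,
                          radius: float) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs within a coarse radius."""
    if len(p1) == 0 or len(p2) == 0:
        return []
    d = np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=2)
    nn1 = d.argmin(axis=1)
    nn2 = d.argmin(axis=0)
    return [(i, int(nn1[i])) for i in range(len(p1))
            if nn2[nn1[i]] == i and d[i, nn1[i]] <= radius]


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[1] <= tol * max(sv[0], 1.0)


def register_channels(beads_ch1: np.ndarray, beads_ch2: np.ndarray,
                      match_radius_px: float = 10.0) -> ChannelTransform:
    """Least-squares affine registration of channel 2 onto channel 1 from
    matched fiducial-bead coordinates.

    Beads are paired by mutual nearest neighbour within ``match_radius_px``;
    at least three non-collinear matches are required.  A residual RMS above
    1 px triggers a warning (bad matching or a genuinely non-affine warp).
    """
    p1 = np.atleast_2d(np.asarray(beads_ch1, dtype=float))
    p2 = np.atleast_2d(np.asarray(beads_ch2, dtype=float))
    matches = _match_mutual_nearest(p2, p1, match_radius_px)
    if len(matches) < 3:
        raise ValueError(f"only {len(matches)} matched bead pairs within "
                         f"{match_radius_px} px; need >= 3 for an affine fit")
    src = p2[[i for i, _ in matches]]
    dst = p1[[j for _, j in matches]]
    if _collinear(src):
        raise ValueError("matched beads are collinear; affine fit is degenerate")

    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef[:2, :].T
    offset = coef[2, :]
    affine = AffineMap(matrix, offset)
    resid = affine.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    if rms > 1.0:
        log.warning("channel registration residual RMS %.2f px exceeds 1 px", rms)
    return ChannelTransform(affine=affine, residual_rms_px=rms, n_beads=len(matches))


def colocalize(spots_ch1: list[SpotLocalization], spots_ch2: list[SpotLocalization],
               transform: ChannelTransform | None = None, tol_px: float = 2.0,
               roi_half_width_px: int = 3) -> list[RoiPair]:
    """Greedy one-to-one pairing of spots across channels.

    Channel-2 spots are mapped into the channel-1 frame through ``transform``;
    candidate pairs are matched by ascending distance and kept if the mapped
    distance is at most ``tol_px``.  The pairing is one-to-one, so
    ``len(pairs) <= min(len(spots_ch1), len(spots_ch2))``.
    """
    if tol_px <= 0:
        raise ValueError("tol_px must be > 0")
    if transform is None:
        transform = ChannelTransform.identity()
    if not spots_ch1 or not spots_ch2:
        return []
    p1 = np.array([[s.x, s.y] for s in spots_ch1])
    p2 = np.array([[s.x, s.y] for s in spots_ch2])
    mapped = transform.apply(p2)
    d = np.linalg.norm(p1[:, None, :] - mapped[None, :, :], axis=2)
    cands = [(d[i, j], i, j) for i in range(len(p1)) for j in range(len(p2))
             if d[i, j] <= tol_px]
    cands.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    pairs: list[RoiPair] = []
    for dist, i, j in cands:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append(RoiPair(molecule_id=len(pairs),
                             center_ch1=(spots_ch1[i].x, spots_ch1[i].y),
                             center_ch2=(spots_ch2[j].x, spots_ch2[j].y),
                             half_width_px=roi_half_width_px,
                             distance_px=float(dist)))
    return pairs


def extract_traces(stacks: dict, rois: list[RoiPair], frame_interval_s: float,
                   roi_half_width_px: int | None = None,
                   mode: str = "max") -> TraceSet:
    """Read out per-frame ROI intensity for every co-localized molecule.

    ``stacks`` maps channel name ("green", "red") to a (n_frames, H, W)
    array.  The default read-out is the maximum pixel inside the square ROI
    window per frame; ``mode='sum'`` integrates the window instead.  ROIs
    whose window touches the image border raise an error naming the
    offending molecules.
    """
    if mode not in ("max", "sum"):
        raise ValueError("mode must be 'max' or 'sum'")
    channels = tuple(stacks)
    centers = {"green": lambda r: r.center_ch1, "red": lambda r: r.center_ch2}
    shapes = {np.asarray(s).shape for s in stacks.values()}
    if len({(s[1], s[2]) for s in shapes}) > 1 or len({s[0] for s in shapes}) > 1:
        raise ValueError("channel stacks must share frame count and image size")
    n_frames, h, w = next(iter(shapes))

    bad: list[int] = []
    windows: dict = {}
    for roi in rois:
        half = roi_half_width_px if roi_half_width_px is not None else roi.half_width_px
        for ch in channels:
            cx, cy = centers[ch](roi)
            x0, y0 = int(round(cx)), int(round(cy))
            if x0 - half < 0 or y0 - half < 0 or x0 + half >= w or y0 + half >= h:
                bad.append(roi.molecule_id)
                break
            windows[(roi.molecule_id, ch)] = (slice(y0 - half, y0 + half + 1),
                                              slice(x0 - half, x0 + half + 1))
    if bad:
        raise ValueError(f"ROI window touches the image border for molecule_ids {sorted(set(bad))}")

    intensities: dict = {}
    for roi in rois:
        if roi.molecule_id in {b for b in bad}:
            continue
        per_ch = {}
        for ch in channels:
            sl = windows[(roi.molecule_id, ch)]
            block = np.asarray(stacks[ch])[:, sl[0], sl[1]].astype(float)
            per_ch[ch] = block.max(axis=(1, 2)) if mode == "max" else block.sum(axis=(1, 2))
        intensities[roi.molecule_id] = per_ch
    return TraceSet(frame_interval_s=frame_interval_s, channels=channels,
                    intensities=intensities)


def rois_to_frame(rois: list[RoiPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": r.molecule_id,
        "x1": r.center_ch1[0], "y1": r.center_ch1[1],
        "x2": r.center_ch2[0], "y2": r.center_ch2[1],
        "distance_px": r.distance_px,
    } for r in rois])
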