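"""Two-level idealization of single-molecule intensity traces.

The detector follows the classic recipe for abrupt-step localization in noisy
telegraph-like signals: Gaussian pre-smoothing, then the multiscale product of
first-derivative-of-Gaussian (edge detector) wavelet responses at a small set
of dyadic scales.  A genuine intensity step produces same-sign extrema at
every scale, so the pointwise product grows as amplitude^n_scales at the step
while incoherent noise is suppressed; with an odd number of scales the sign
of the product preserves the step direction.

Candidate steps are thresholded against a robust (MAD-based) noise floor of
the product signal, pruned to a minimum separation, vetted by a relative
amplitude criterion, and finally assembled into a two-level
fluorescent/quenched labeling.  A terminal photobleach level is not treated
specially here: quenched and bleached intensities are one "low" level at
detection time, and bleach classification happens downstream in the kinetics
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import StepDetectionConfig

FLUORESCENT, QUENCHED = "fluorescent", "quenched"


class Step(NamedTuple):
    frame: int            # first frame of the new level
    direction: str        # "down" (fluorescent -> quenched) or "up"
    amplitude: float      # median(after) - median(before), trace units


@dataclass
class IdealizedTrace:
    """Per-frame two-level labeling plus the step list that produced it."""
    labels: np.ndarray                 # array of FLUORESCENT/QUENCHED strings
    steps: list                        # list[Step], frames strictly increasing
    level_means: tuple | None = None   # (fluorescent level, quenched level)
    single_level: bool = False         # True if the two levels were indistinguishable
    product: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)


def gaussian_smooth(trace: np.ndarray, sigma_frames: float) -> np.ndarray:
    """Convolve with a unit-sum Gaussian kernel (truncated at 4 sigma,
    reflective boundary)."""
    x = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if sigma_frames <= 0:
        raise ValueError("sigma_frames must be > 0")
    return gaussian_filter1d(x, sigma_frames, mode="reflect", truncate=4.0)


def _edge_kernel(scale: int) -> np.ndarray:
    """First derivative of a Gaussian of width ``scale``, oriented so that an
    upward step yields a positive response; positive lobe normalized to unit
    sum so a clean step of height h responds with peak ~h."""
    half = int(np.ceil(4.0 * scale))
    j = np.arange(-half, half + 1, dtype=float)
    k = j * np.exp(-0.5 * (j / scale) ** 2)
    pos = k[k > 0].sum()
    return k / pos


def _correlate_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    half = (kernel.size - 1) // 2
    padded = np.pad(x, half, mode="symmetric")
    return np.correlate(padded, kernel, mode="valid")


def multiscale_product(trace: np.ndarray, scales=(1, 2, 4)) -> np.ndarray:
    """Pointwise product of edge-detector responses across scales.

    Requires ``len(trace) > 8 * max(scales)`` so boundary padding cannot
    dominate the response.
    """
    x = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    scales = tuple(int(s) for s in scales)
    min_len = 8 * max(scales)
    if x.size <= min_len:
        raise ValueError(f"trace too short: need more than {min_len} frames "
                         f"for scales {scales}, got {x.size}")
    product = np.ones_like(x)
    for s in scales:
        product *= _correlate_reflect(x, _edge_kernel(s))
    return product


def _local_extrema(mag: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of strict local maxima of ``mag`` above ``threshold``; plateaus
    keep their earliest frame."""
    left = np.r_[True, mag[1:] > mag[:-1]]
    right = np.r_[mag[:-1] >= mag[1:], True]
    return np.nonzero(left & right & (mag > threshold))[0]


def _prune_separation(cands: np.ndarray, score: np.ndarray, min_sep: int) -> list[int]:
    """Greedy non-maximum suppression: keep the larger |product|, earlier frame
    on ties."""
    order = sorted(range(len(cands)), key=lambda i: (-score[i], cands[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(int(cands[i]) - k) >= min_sep for k in kept):
            kept.append(int(cands[i]))
    return sorted(kept)


def _segment_medians(x: np.ndarray, boundaries: list[int]) -> np.ndarray:
    return np.array([np.median(x[a:b]) for a, b in zip(boundaries[:-1], boundaries[1:])])


def _two_level_split(medians: np.ndarray, lengths: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Weighted 2-means on segment medians.  Returns (is_high, m_high, m_low)."""
    m_hi, m_lo = medians.max(), medians.min()
    is_high = medians >= 0.5 * (m_hi + m_lo)
    for _ in range(25):
        w_hi = lengths[is_high].sum()
        w_lo = lengths[~is_high].sum()
        if w_hi == 0 or w_lo == 0:
            break
        m_hi = float(np.average(medians[is_high], weights=lengths[is_high]))
        m_lo = float(np.average(medians[~is_high], weights=lengths[~is_high]))
        new = medians >= 0.5 * (m_hi + m_lo)
        if np.array_equal(new, is_high):
            break
        is_high = new
    return is_high, m_hi, m_lo


def detect_steps(trace: np.ndarray, config: StepDetectionConfig | None = None) -> IdealizedTrace:
    """Idealize a noisy trace into a two-level fluorescent/quenched sequence.

    Candidates are local extrema of the multiscale product exceeding
    ``threshold_c`` times its robust noise floor (1.4826 x MAD); candidates
    within ``min_separation_frames`` are pruned keeping the larger product;
    step amplitudes are measured as differences of flanking level medians and
    must exceed ``min_relative_amplitude`` of the trace's 5-95 percentile
    range.  Levels are assigned fluorescent/quenched against the midpoint of
    the two fitted level means.  Steps within ``max(scales)`` frames of either
    trace end are discarded (wavelet edge artifacts).
    """
    if config is None:
        config = StepDetectionConfig()
    x = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    n = x.size
    max_scale = max(config.scales)

    smoothed = gaussian_smooth(x, config.smooth_sigma_frames)
    min_len = 8 * max_scale
    if n <= min_len:
        raise ValueError(f"trace too short: need more than {min_len} frames "
                         f"for scales {config.scales}, got {n}")
    details = [_correlate_reflect(smoothed, _edge_kernel(s)) for s in config.scales]
    product = np.prod(details, axis=0)
    mag = np.abs(product)

    # noise-calibrated threshold: a step candidate must clear threshold_c
    # times the robust detail noise level (1.4826 x MAD) at every scale, so
    # the product criterion is prod_s (c x sigma_s).  Thresholding the raw
    # MAD of the product signal instead would badly underestimate the tail
    # scale: a product of near-zero detail values is extremely peaked at zero.
    threshold = 1.0
    for d in details:
        threshold *= config.threshold_c * 1.4826 * np.median(np.abs(d - np.median(d)))
    if threshold <= 0:
        # noiseless / degenerate product: admit any genuinely non-zero extremum
        threshold = 1e-12 * max(mag.max(), 1.0)
    cands = _local_extrema(mag, threshold)
    cands = cands[(cands >= max_scale) & (cands < n - max_scale)]

    kept = _prune_separation(cands, mag[cands], config.min_separation_frames)
    # extremum of the product sits half a frame before the first new-level
    # frame; shift so a clean step at frame f is reported at frame f
    step_frames = [f + 1 for f in kept if f + 1 < n]

    # amplitude veto: drop weakest sub-threshold step, re-measure, repeat
    dyn_range = float(np.percentile(x, 95) - np.percentile(x, 5))
    min_amp = config.min_relative_amplitude * dyn_range
    while step_frames:
        boundaries = [0] + step_frames + [n]
        medians = _segment_medians(x, boundaries)
        amps = np.diff(medians)
        weak = np.nonzero(np.abs(amps) < min_amp)[0]
        if weak.size == 0:
            break
        drop = weak[np.argmin(np.abs(amps[weak]))]
        step_frames.pop(int(drop))

    if not step_frames:
        return IdealizedTrace(labels=np.full(n, FLUORESCENT, dtype=object),
                              steps=[], level_means=None, single_level=True,
                              product=product)

    boundaries = [0] + step_frames + [n]
    medians = _segment_medians(x, boundaries)
    lengths = np.diff(boundaries).astype(float)
    is_high, m_hi, m_lo = _two_level_split(medians, lengths)

    # robust per-frame noise after removing the segment structure
    residual = x - np.repeat(medians, np.diff(boundaries))
    sigma = 1.4826 * float(np.median(np.abs(residual - np.median(residual))))
    if abs(m_hi - m_lo) < sigma or np.all(is_high) or not np.any(is_high):
        return IdealizedTrace(labels=np.full(n, FLUORESCENT, dtype=object),
                              steps=[], level_means=None, single_level=True,
                              product=product)

    # merge adjacent same-label segments, keep only label-changing steps
    steps: list[Step] = []
    seg_starts = [0]
    seg_labels = [bool(is_high[0])]
    for i in range(1, len(medians)):
        if bool(is_high[i]) != seg_labels[-1]:
            seg_starts.append(boundaries[i])
            seg_labels.append(bool(is_high[i]))
    seg_bounds = seg_starts + [n]
    seg_medians = _segment_medians(x, seg_bounds)
    labels = np.empty(n, dtype=object)
    for i, (a, b) in enumerate(zip(seg_bounds[:-1], seg_bounds[1:])):
        labels[a:b] = FLUORESCENT if seg_labels[i] else QUENCHED
    for i in range(1, len(seg_labels)):
        direction = "down" if seg_labels[i - 1] else "up"
        steps.append(Step(frame=int(seg_bounds[i]), direction=direction,
                          amplitude=float(seg_medians[i] - seg_medians[i - 1])))

    return IdealizedTrace(labels=labels, steps=steps,
                          level_means=(m_hi, m_lo), single_level=False,
                          product=product)
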