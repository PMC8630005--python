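"""Ground-truthed synthetic data for two-colour smPET analysis.

The generative model is a continuous-time two-state telegraph process on a
shared "clamp" coordinate: closure attempts fire at rate ``k_close`` while the
clamp is open; each attempt either closes the clamp in both reporter channels
(coupled, probability ``1 - p_uncoupled``) for an Exp(1/k_open) sojourn, or is
a failed attempt that quenches a single randomly chosen channel alone
(uncoupled) for an independent Exp(1/k_open) sojourn while the clamp itself
stays open.  Uncoupled events are quench-initiated only; their later
single-channel re-openings are logged as ``uncoupled_open``.  Photobleaching
is an irreversible per-channel Poisson event; a bleached reporter never
recovers.  In the one-colour AMP-PNP mode, closure is irreversible and PET
quenched (but not bleached) reporters recover by dye-sensitized
photo-oxidation (DSPO) after oxygen-rich solution is applied.

Event times are drawn in continuous time and then binned to the acquisition
frame grid; events that fall in the same frame of one channel and cancel
(state unchanged at the frame sampling times) disappear, modelling
frame-rate-limited observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import erf

from .config import CameraModel, SimulationConfig, TraceNoise
from .geometry import AffineMap
from .traces import TraceSet

OPEN, CLOSED, BLEACHED = 0, 1, 2
STATE_NAMES = {OPEN: "open", CLOSED: "closed", BLEACHED: "bleached"}

EVENT_KINDS = ("coupled_close", "coupled_open", "uncoupled_close",
               "uncoupled_open", "bleach", "dspo_recovery")


class Event(NamedTuple):
    """One ground-truth transition, on the frame grid."""
    frame: int
    time_s: float
    channel: str
    kind: str


@dataclass
class ClampTrajectory:
    """Per-molecule hidden state sequences (one per channel) plus event log."""
    molecule_id: int
    frame_interval_s: float
    states: dict          # channel -> np.ndarray of int8 codes (OPEN/CLOSED/BLEACHED)
    events: list = field(default_factory=list)   # list[Event], frame-sorted

    @property
    def n_frames(self) -> int:
        return next(iter(self.states.values())).size

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.states)


class _CtEvent(NamedTuple):
    time_s: float
    channel: str
    kind: str


def _exp(rng: np.random.Generator, rate_per_s: float) -> float:
    """Exponential waiting time; infinite if the rate is zero."""
    if rate_per_s <= 0.0:
        return math.inf
    return float(rng.exponential(1.0 / rate_per_s))


def _dark_intervals_atp(cfg: SimulationConfig, rng: np.random.Generator,
                        channels: tuple[str, ...]):
    """Continuous-time dark (PET-quenched) intervals per channel, ATP cycling."""
    kc = cfg.k_close / 60.0
    ko = cfg.k_open / 60.0
    dt = cfg.frame_interval_s
    j = int(cfg.sync_jitter_frames)
    dark = {ch: [] for ch in channels}
    ct_events: list[_CtEvent] = []
    t = 0.0
    while True:
        w = _exp(rng, kc)
        if not math.isfinite(w) or t + w >= cfg.duration_s:
            break
        t += w
        sojourn = _exp(rng, ko)
        if rng.random() < cfg.p_uncoupled:
            ch = channels[int(rng.integers(len(channels)))]
            dark[ch].append((t, t + sojourn))
            ct_events.append(_CtEvent(t, ch, "uncoupled_close"))
            if t + sojourn < cfg.duration_s:
                ct_events.append(_CtEvent(t + sojourn, ch, "uncoupled_open"))
            # clamp itself stayed open; next attempt re-drawn from t
        else:
            t_end = t + sojourn
            for i, ch in enumerate(channels):
                # coupled transitions land within sync_jitter_frames of each other;
                # the first channel carries the reference time
                off_c = 0.0 if (i == 0 or j == 0) else float(rng.integers(-j, j + 1)) * dt
                off_o = 0.0 if (i == 0 or j == 0) else float(rng.integers(-j, j + 1)) * dt
                a, b = t + off_c, t_end + off_o
                a = max(a, 0.0)
                if b > a:
                    dark[ch].append((a, b))
                ct_events.append(_CtEvent(a, ch, "coupled_close"))
                if b < cfg.duration_s:
                    ct_events.append(_CtEvent(b, ch, "coupled_open"))
            if not math.isfinite(t_end):
                break
            t = t_end
    return dark, ct_events


def _dark_intervals_apo(cfg: SimulationConfig, rng: np.random.Generator,
                        channels: tuple[str, ...]):
    """Apo (no ATP): only rare spontaneous per-channel quench excursions."""
    rate = (cfg.k_close * cfg.p_uncoupled) / 60.0
    ko = cfg.k_open / 60.0
    dark = {ch: [] for ch in channels}
    ct_events: list[_CtEvent] = []
    for ch in channels:
        t = 0.0
        while True:
            w = _exp(rng, rate)
            if not math.isfinite(w) or t + w >= cfg.duration_s:
                break
            t += w
            sojourn = _exp(rng, ko)
            dark[ch].append((t, t + sojourn))
            ct_events.append(_CtEvent(t, ch, "uncoupled_close"))
            if t + sojourn < cfg.duration_s:
                ct_events.append(_CtEvent(t + sojourn, ch, "uncoupled_open"))
            t = t + sojourn if math.isfinite(sojourn) else cfg.duration_s
    return dark, ct_events


def _dark_intervals_ampnp(cfg: SimulationConfig, rng: np.random.Generator,
                          bleach_time: float):
    """One-colour AMP-PNP: a single irreversible closure; DSPO recovery after O2."""
    kc = cfg.k_close / 60.0
    dark = {"green": []}
    ct_events: list[_CtEvent] = []
    t_close = _exp(rng, kc)
    if math.isfinite(t_close) and t_close < cfg.duration_s:
        ct_events.append(_CtEvent(t_close, "green", "coupled_close"))
        t_o2 = cfg.o2_application_s
        recover = max(t_close, t_o2) + float(rng.exponential(cfg.dspo_mean_delay_s))
        if recover < cfg.duration_s and recover < bleach_time:
            dark["green"].append((t_close, recover))
            ct_events.append(_CtEvent(recover, "green", "dspo_recovery"))
        else:
            dark["green"].append((t_close, math.inf))
    return dark, ct_events


def _discretize(cfg: SimulationConfig, dark: dict, bleach: dict,
                ct_events: list[_CtEvent]) -> tuple[dict, list[Event]]:
    """Sample per-channel states at frame times and build the discrete event log.

    State is sampled at t_k = k * dt; a continuous event at time t first shows
    at frame ceil(t / dt).  Pairs of events cancelling inside one frame leave
    no sampled change and are dropped from the log.
    """
    dt = cfg.frame_interval_s
    n = cfg.n_frames
    t_k = np.arange(n) * dt
    states = {}
    for ch, intervals in dark.items():
        s = np.zeros(n, dtype=np.int8)
        for a, b in intervals:
            s[(t_k >= a) & (t_k < b)] = CLOSED
        tb = bleach.get(ch, math.inf)
        s[t_k >= tb] = BLEACHED
        states[ch] = s

    # bleach enters the continuous log too, so discrete kinds can be matched
    full_ct = list(ct_events)
    for ch, tb in bleach.items():
        if math.isfinite(tb) and tb < cfg.duration_s:
            full_ct.append(_CtEvent(tb, ch, "bleach"))
    full_ct.sort(key=lambda e: e.time_s)

    events: list[Event] = []
    for ch, s in states.items():
        change_frames = np.nonzero(np.diff(s))[0] + 1
        ch_ct = [e for e in full_ct if e.channel == ch]
        for f in change_frames:
            lo, hi = (f - 1) * dt, f * dt
            in_frame = [e for e in ch_ct if lo < e.time_s <= hi]
            if s[f] == BLEACHED:
                kind = "bleach"
            elif in_frame:
                kind = in_frame[-1].kind
            else:  # pragma: no cover - defensive; every sampled change has a cause
                kind = "coupled_close" if s[f] == CLOSED else "coupled_open"
            events.append(Event(int(f), float(f * dt), ch, kind))
    events.sort(key=lambda e: (e.frame, e.channel))
    return states, events


def simulate_clamp_trajectory(config: SimulationConfig) -> list[ClampTrajectory]:
    """Draw ground-truth state trajectories for ``config.n_molecules`` molecules.

    Pure function of (config, config.seed): identical inputs give bit-identical
    trajectories and event logs.
    """
    rng = np.random.default_rng(config.seed)
    channels = config.channels
    bleach_rates = {"green": config.k_bleach_green / 60.0,
                    "red": config.k_bleach_red / 60.0}
    out = []
    for mol in range(config.n_molecules):
        bleach = {ch: _exp(rng, bleach_rates[ch]) for ch in channels}
        if config.mode == "atp_cycling":
            dark, ct = _dark_intervals_atp(config, rng, channels)
        elif config.mode == "apo":
            dark, ct = _dark_intervals_apo(config, rng, channels)
        else:  # ampnp_onecolour
            dark, ct = _dark_intervals_ampnp(config, rng, bleach["green"])
        states, events = _discretize(config, dark, bleach, ct)
        out.append(ClampTrajectory(molecule_id=mol,
                                   frame_interval_s=config.frame_interval_s,
                                   states=states, events=events))
    return out


# ---------------------------------------------------------------------------
# trace-level rendering (fast path, bypasses image formation)
# ---------------------------------------------------------------------------

def render_traces(trajectories: list[ClampTrajectory], noise: TraceNoise,
                  seed: int | None = 0) -> TraceSet:
    """Turn state trajectories into noisy two-level intensity traces.

    Open frames sit at ``noise.level_open`` expected counts, quenched and
    bleached frames at ``noise.level_background``; shot noise is Poisson in
    photon number (variance proportional to the level) with additive Gaussian
    read noise.
    """
    if not trajectories:
        raise ValueError("no trajectories to render")
    rng = np.random.default_rng(seed)
    frame_interval = trajectories[0].frame_interval_s
    channels = trajectories[0].channels
    intensities, truth = {}, {}
    for traj in trajectories:
        if traj.frame_interval_s != frame_interval or traj.channels != channels:
            raise ValueError("trajectories must share one frame grid and channel set")
        per_ch, per_ch_truth = {}, {}
        for ch, s in traj.states.items():
            level = np.where(s == OPEN, noise.level_open, noise.level_background)
            if noise.shot_noise:
                photons = rng.poisson(level).astype(float)
            else:
                photons = level.astype(float)
            counts = noise.gain * photons
            if noise.read_noise > 0:
                counts = counts + rng.normal(0.0, noise.read_noise, size=counts.size)
            per_ch[ch] = counts
            per_ch_truth[ch] = s.copy()
        intensities[traj.molecule_id] = per_ch
        truth[traj.molecule_id] = per_ch_truth
    return TraceSet(frame_interval_s=frame_interval, channels=channels,
                    intensities=intensities, true_states=truth)


# ---------------------------------------------------------------------------
# image-level rendering
# ---------------------------------------------------------------------------

def _gaussian_stamp(x0: float, y0: float, amplitude: float, sigma: float,
                    image: np.ndarray) -> None:
    """Add a pixel-integrated 2-D Gaussian of integrated intensity ``amplitude``."""
    h, w = image.shape
    r = int(math.ceil(4.0 * sigma)) + 1
    xi0, xi1 = max(0, int(x0) - r), min(w, int(x0) + r + 1)
    yi0, yi1 = max(0, int(y0) - r), min(h, int(y0) + r + 1)
    if xi0 >= xi1 or yi0 >= yi1:
        return
    xs = np.arange(xi0, xi1)
    ys = np.arange(yi0, yi1)
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x0) / s) - erf((xs - 0.5 - x0) / s))
    fy = 0.5 * (erf((ys + 0.5 - y0) / s) - erf((ys - 0.5 - y0) / s))
    image[yi0:yi1, xi0:xi1] += amplitude * np.outer(fy, fx)


def _place_positions(n: int, shape: tuple[int, int], min_sep: float, margin: float,
                     rng: np.random.Generator, max_attempts: int = 10_000) -> np.ndarray:
    h, w = shape
    if n == 0:
        return np.empty((0, 2))
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} spots with separation >= {min_sep:.1f} px "
                f"in a {w}x{h} image within {max_attempts} attempts")
        attempts += 1
        p = np.array([rng.uniform(margin, w - 1 - margin),
                      rng.uniform(margin, h - 1 - margin)])
        if all(np.hypot(*(p - q)) >= min_sep for q in positions):
            positions.append(p)
    return np.array(positions)


def render_image_stack(trajectories: list[ClampTrajectory], camera: CameraModel,
                       seed: int | None = 0,
                       misalignment: AffineMap | None = None,
                       noise: bool = True,
                       quenched_fraction: float = 0.0,
                       n_frames: int | None = None,
                       channels: tuple[str, ...] = ("green", "red"),
                       min_separation_px: float | None = None):
    """Render two-channel TIRF image stacks with ground-truth spot positions.

    Returns ``(stacks, positions)`` where ``stacks`` maps channel name to a
    ``(n_frames, H, W)`` uint16 array and ``positions`` is a DataFrame with
    the true sub-pixel spot centre per molecule and channel.  Channel-2 (red)
    coordinates are optionally warped by ``misalignment`` to emulate imperfect
    optical alignment between the two cameras.
    """
    rng = np.random.default_rng(seed)
    if trajectories:
        channels = trajectories[0].channels
        n_frames = trajectories[0].n_frames
    elif n_frames is None:
        raise ValueError("n_frames is required when rendering a blank (zero-molecule) stack")
    # sparse fields by default (sub-nM surface densities): spots sit well
    # clear of the localizer's 4-sigma merge radius; 4 sigma is the hard
    # lower bound
    min_sep = 6.0 * camera.psf_sigma_px if min_separation_px is None else float(min_separation_px)
    if min_sep < 4.0 * camera.psf_sigma_px:
        raise ValueError("min_separation_px must be >= 4 x psf_sigma_px")
    margin = math.ceil(4.0 * camera.psf_sigma_px) + 1
    pos1 = _place_positions(len(trajectories), camera.shape, min_sep, margin, rng)
    pos = {channels[0]: pos1}
    if len(channels) > 1:
        pos[channels[1]] = misalignment.apply(pos1) if misalignment is not None else pos1.copy()

    h, w = camera.shape
    stacks = {}
    for ch in channels:
        stack = np.empty((n_frames, h, w), dtype=np.uint16)
        for t in range(n_frames):
            img = np.full((h, w), float(camera.background_photons))
            for traj, (x0, y0) in zip(trajectories, pos[ch]):
                s = traj.states[ch][t]
                if s == OPEN:
                    amp = camera.photons_per_frame_open
                elif s == CLOSED and quenched_fraction > 0:
                    amp = quenched_fraction * camera.photons_per_frame_open
                else:
                    continue
                _gaussian_stamp(x0, y0, amp, camera.psf_sigma_px, img)
            if noise:
                counts = camera.gain * rng.poisson(img).astype(float)
                counts += rng.normal(0.0, camera.read_noise, size=counts.shape)
            else:
                counts = camera.gain * img
            stack[t] = np.clip(np.round(counts), 0, 65535).astype(np.uint16)
        stacks[ch] = stack

    records = {"molecule_id": [traj.molecule_id for traj in trajectories]}
    for ch in channels:
        records[f"x_{ch}"] = pos[ch][:, 0]
        records[f"y_{ch}"] = pos[ch][:, 1]
    return stacks, pd.DataFrame(records)


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    if len(points) < 3:
        return True
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    return sv[1] <= tol * max(sv[0], 1.0)


def make_bead_frames(n_beads: int, camera: CameraModel,
                     misalignment: AffineMap | None = None,
                     seed: int | None = 0, noise: bool = True,
                     positions: np.ndarray | None = None,
                     brightness_factor: float = 5.0):
    """Render a fiducial-bead field in both channels for registration.

    Beads are bright (``brightness_factor`` times the open-state molecule
    budget) and identical in both channels except for the injected
    ``misalignment`` applied to channel 2.  Returns
    ``(image_ch1, image_ch2, true_positions_ch1)``.
    """
    if n_beads < 3:
        raise ValueError("need at least 3 beads for affine registration")
    rng = np.random.default_rng(seed)
    if positions is None:
        margin = math.ceil(4.0 * camera.psf_sigma_px) + 2
        for _ in range(100):
            pos1 = _place_positions(n_beads, camera.shape, 8.0 * camera.psf_sigma_px,
                                    margin, rng)
            if not _collinear(pos1):
                break
        else:  # pragma: no cover
            raise RuntimeError("failed to draw a non-collinear bead layout")
    else:
        pos1 = np.asarray(positions, dtype=float).reshape(-1, 2)
        if len(pos1) != n_beads:
            raise ValueError("positions length does not match n_beads")
        if _collinear(pos1):
            raise ValueError("bead layout is collinear; affine registration is degenerate")
    pos2 = misalignment.apply(pos1) if misalignment is not None else pos1.copy()

    amp = brightness_factor * camera.photons_per_frame_open
    images = []
    for pos in (pos1, pos2):
        img = np.full(camera.shape, float(camera.background_photons))
        for x0, y0 in pos:
            _gaussian_stamp(x0, y0, amp, camera.psf_sigma_px, img)
        if noise:
            counts = camera.gain * rng.poisson(img).astype(float)
            counts += rng.normal(0.0, camera.read_noise, size=counts.shape)
        else:
            counts = camera.gain * img
        images.append(np.clip(np.round(counts), 0, 65535).astype(np.uint16))
    return images[0], images[1], pos1


def event_log_frame(trajectories: list[ClampTrajectory]) -> pd.DataFrame:
    """Flatten ground-truth event logs into one tidy DataFrame."""
    rows = [(traj.molecule_id, ev.frame, ev.time_s, ev.channel, ev.kind)
            for traj in trajectories for ev in traj.events]
    return pd.DataFrame(rows, columns=["molecule_id", "frame", "time_s",
                                       "channel", "kind"])
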