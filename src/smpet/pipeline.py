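"""End-to-end orchestration: simulate -> extract -> detect -> kinetics.

Each stage writes machine-readable artifacts (CSV/TIFF/JSON) into the output
directory, and a run manifest records the config hash, package version,
checksums and wall time per stage, so an identical config + seed reproduces
identical artifacts.

The default path is trace-level (the simulator renders intensity traces
directly); ``render_images=True`` switches to the full image path with
bead-based registration, spot detection, co-localization and ROI read-out.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as smio
from .config import AnalysisConfig, PipelineConfig, StepDetectionConfig
from .geometry import AffineMap
from .imaging import colocalize, detect_spots, extract_traces, register_channels, rois_to_frame
from .kinetics import (DwellRecord, KineticResult, dwells_to_frame, extract_dwells,
                       fit_exponential_cdf, identify_pet_events, mean_rate,
                       pair_synchronous, summarize_synchronicity)
from .simulate import (event_log_frame, make_bead_frames, render_image_stack,
                       render_traces, simulate_clamp_trajectory)
from .stepdetect import detect_steps
from .traces import TraceSet

log = logging.getLogger("smpet")

__version__ = "0.1.0"


@dataclass
class RunManifest:
    config_hash: str
    package_version: str = __version__
    seed: int = 0
    stages: dict = field(default_factory=dict)  # stage -> {files: {name: sha256}, wall_s}

    def record(self, stage: str, files: dict, wall_s: float) -> None:
        self.stages[stage] = {"files": {str(k): smio.sha256_of(v) for k, v in files.items()},
                              "wall_s": round(wall_s, 3)}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def detect_all(traces: TraceSet, config: StepDetectionConfig | None = None) -> dict:
    """Run step detection on every molecule and channel of a trace set.

    Returns molecule_id -> {channel: IdealizedTrace}.
    """
    if config is None:
        config = StepDetectionConfig()
    out: dict = {}
    for mol in traces.molecule_ids:
        out[mol] = {ch: detect_steps(traces.trace(mol, ch), config)
                    for ch in traces.channels}
    return out


def _fit_state(dwells: list[DwellRecord], state: str, config: AnalysisConfig,
               channel: str | None = None):
    """(ExponentialFit, mean rate min^-1) for uncensored dwells in one state,
    or (None, None) when there are too few dwells to fit."""
    durations = [d.duration_s for d in dwells
                 if d.state == state and not d.censored
                 and (channel is None or d.channel == channel)]
    try:
        fit = fit_exponential_cdf(durations, model_selection=config.model_selection)
    except (ValueError, RuntimeError):
        return None, None
    return fit, mean_rate(fit)


def analyze_two_colour(idealized: dict, config: AnalysisConfig | None = None):
    """Classify transitions, extract dwells and fit kinetics for one construct.

    ``idealized`` maps molecule_id -> {channel: IdealizedTrace}.  Returns
    ``(KineticResult, events, dwells, fits)`` where ``fits`` maps
    ('pooled' | channel, state) to the ExponentialFit (or None).
    """
    if config is None:
        config = AnalysisConfig()
    events, dwells = [], []
    for mol, per_ch in idealized.items():
        ev = pair_synchronous(per_ch["green"].steps, per_ch["red"].steps,
                              config, molecule_id=mol)
        events.extend(ev)
        dwells.extend(extract_dwells(per_ch, ev, config, molecule_id=mol))

    result = summarize_synchronicity(events)
    fits: dict = {}
    channels = ("green", "red")
    for state, attr in (("open", "k_c"), ("closed", "k_o")):
        fit, rate = _fit_state(dwells, state, config)
        fits[("pooled", state)] = fit
        setattr(result, attr, rate)
        for ch in channels:
            fit_ch, rate_ch = _fit_state(dwells, state, config, channel=ch)
            fits[(ch, state)] = fit_ch
            result.per_channel.setdefault(ch, {})[attr] = rate_ch
    return result, events, dwells, fits


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame([{
        "molecule_id": e.molecule_id, "channel": e.channel, "frame": e.frame,
        "direction": e.direction, "class": e.klass, "partner_frame": e.partner_frame,
    } for e in events], columns=["molecule_id", "channel", "frame", "direction",
                                 "class", "partner_frame"])


def _kinetics_json(result: KineticResult, fits: dict, config: AnalysisConfig) -> dict:
    def fit_dict(fit):
        if fit is None:
            return None
        return {"n_components": fit.n_components,
                "components": [{"amplitude": a, "tau_s": t} for a, t in fit.components],
                "rss": fit.rss, "bic": fit.bic, "n_dwells": fit.n_points}

    return {
        "counts": {"synchronous": result.n_synchronous,
                   "non_synchronous": result.n_non_synchronous},
        "percent_non_synchronous": {
            "ratio_to_synchronous": result.percent_non_synchronous,
            "fraction_of_total": result.percent_non_synchronous_of_total},
        "mean_rates_per_min": {"k_c": result.k_c, "k_o": result.k_o,
                               "per_channel": result.per_channel},
        "fits": {f"{who}_{state}": fit_dict(fit)
                 for (who, state), fit in fits.items()},
        "sync_window_frames": config.sync_window_frames,
        "frame_interval_s": config.frame_interval_s,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> RunManifest:
    """Execute all stages on synthetic data and write artifacts + manifest.

    The pipeline seed overrides the simulation block's seed so a single
    integer reproduces the whole run.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper()))
    manifest = RunManifest(config_hash=config.config_hash(), seed=config.seed)

    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
    analysis_cfg = dataclasses.replace(config.analysis,
                                       frame_interval_s=sim_cfg.frame_interval_s)

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    log.info("[simulate] %d molecules, mode=%s", sim_cfg.n_molecules, sim_cfg.mode)
    trajectories = simulate_clamp_trajectory(sim_cfg)
    files = {}
    smio.write_event_log(out / "ground_truth_events.json", trajectories)
    files["ground_truth_events.json"] = out / "ground_truth_events.json"

    if config.render_images:
        misalign = AffineMap.identity()
        stacks, positions = render_image_stack(trajectories, config.camera,
                                               seed=config.seed + 1,
                                               misalignment=misalign)
        for ch, stack in stacks.items():
            smio.write_stack(out / f"stack_{ch}.tif", stack)
            files[f"stack_{ch}.tif"] = out / f"stack_{ch}.tif"
        positions.to_csv(out / "true_positions.csv", index=False)
        files["true_positions.csv"] = out / "true_positions.csv"
        bead1, bead2, _ = make_bead_frames(12, config.camera, misalign,
                                           seed=config.seed + 2)
        smio.write_stack(out / "beads_green.tif", bead1)
        smio.write_stack(out / "beads_red.tif", bead2)
        manifest.record("simulate", files, time.perf_counter() - t0)

        # --- extract ------------------------------------------------------
        t0 = time.perf_counter()
        transform = register_channels(
            np.array([[s.x, s.y] for s in detect_spots(bead1, psf_sigma_px=config.camera.psf_sigma_px)]),
            np.array([[s.x, s.y] for s in detect_spots(bead2, psf_sigma_px=config.camera.psf_sigma_px)]))
        smio.write_transform(out / "transform.json", transform)
        ref = {ch: stack[:10].max(axis=0) for ch, stack in stacks.items()}
        spots = {ch: detect_spots(ref[ch], psf_sigma_px=config.camera.psf_sigma_px,
                                  channel=ch) for ch in stacks}
        rois = colocalize(spots["green"], spots["red"], transform)
        rois_to_frame(rois).to_csv(out / "rois.csv", index=False)
        traces = extract_traces(stacks, rois, sim_cfg.frame_interval_s)
        traces.to_csv(out / "traces.csv")
        manifest.record("extract", {"traces.csv": out / "traces.csv",
                                    "rois.csv": out / "rois.csv",
                                    "transform.json": out / "transform.json"},
                        time.perf_counter() - t0)
    else:
        traces = render_traces(trajectories, config.trace_noise, seed=config.seed + 1)
        traces.to_csv(out / "traces.csv")
        files["traces.csv"] = out / "traces.csv"
        manifest.record("simulate", files, time.perf_counter() - t0)

    # --- detect -----------------------------------------------------------
    t0 = time.perf_counter()
    log.info("[detect] idealizing %d traces", len(traces.molecule_ids))
    idealized = detect_all(traces, config.step_detection)
    smio.steps_to_frame(idealized).to_csv(out / "steps.csv", index=False)
    smio.idealization_to_frame(idealized).to_csv(out / "idealization.csv", index=False)
    manifest.record("detect", {"steps.csv": out / "steps.csv",
                               "idealization.csv": out / "idealization.csv"},
                    time.perf_counter() - t0)

    # --- kinetics ---------------------------------------------------------
    t0 = time.perf_counter()
    log.info("[kinetics] window=%d frames", analysis_cfg.sync_window_frames)
    if sim_cfg.mode == "ampnp_onecolour":
        pet = identify_pet_events(idealized, sim_cfg.o2_application_s,
                                  sim_cfg.frame_interval_s)
        pet.to_csv(out / "pet_events.csv", index=False)
        kin_files = {"pet_events.csv": out / "pet_events.csv"}
    else:
        result, events, dwells, fits = analyze_two_colour(idealized, analysis_cfg)
        events_to_frame(events).to_csv(out / "events.csv", index=False)
        dwells_to_frame(dwells).to_csv(out / "dwells.csv", index=False)
        (out / "kinetics.json").write_text(
            json.dumps(_kinetics_json(result, fits, analysis_cfg), indent=1))
        kin_files = {"events.csv": out / "events.csv",
                     "dwells.csv": out / "dwells.csv",
                     "kinetics.json": out / "kinetics.json"}
    manifest.record("kinetics", kin_files, time.perf_counter() - t0)

    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def bootstrap_rate_sd(dwell_df: pd.DataFrame, state: str, channel: str | None,
                      config: AnalysisConfig, n_boot: int = 200,
                      seed: int = 0) -> float | None:
    """Bootstrap s.d. of the amplitude-weighted mean rate over molecules."""
    sel = dwell_df[(dwell_df.state == state)
                   & ~dwell_df.left_censored & ~dwell_df.right_censored]
    if channel is not None:
        sel = sel[sel.channel == channel]
    mols = sel.molecule_id.unique()
    if len(mols) < 2:
        return None
    rng = np.random.default_rng(seed)
    by_mol = {m: g.duration_s.to_numpy() for m, g in sel.groupby("molecule_id")}
    rates = []
    for _ in range(n_boot):
        pick = rng.choice(mols, size=len(mols), replace=True)
        durations = np.concatenate([by_mol[m] for m in pick])
        try:
            fit = fit_exponential_cdf(durations, model_selection=config.model_selection)
            rates.append(mean_rate(fit))
        except (ValueError, RuntimeError):
            continue
    if len(rates) < max(10, n_boot // 4):
        return None
    return float(np.std(rates, ddof=1))


def report(results_dir: str | Path, out_dir: str | Path | None = None,
           n_boot: int = 200, seed: int = 0) -> pd.DataFrame:
    """Summary table + cumulative-sum plots from a pipeline results directory.

    Produces ``summary.csv`` (counts, both non-synchronous percentage
    conventions, k_c and k_o per colour with bootstrap s.d. over molecules)
    and one cumulative-sum plot per state with the fitted curve overlaid.
    Missing dwell sets yield "n/a" cells and a warning, not an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    results_dir = Path(results_dir)
    out = Path(out_dir) if out_dir is not None else results_dir
    out.mkdir(parents=True, exist_ok=True)
    missing = [f for f in ("kinetics.json", "dwells.csv") if not (results_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing kinetics outputs in {results_dir}: {missing}")
    kin = json.loads((results_dir / "kinetics.json").read_text())
    dwell_df = pd.read_csv(results_dir / "dwells.csv")
    config = AnalysisConfig(sync_window_frames=kin["sync_window_frames"],
                            frame_interval_s=kin["frame_interval_s"])

    row: dict = {
        "n_synchronous": kin["counts"]["synchronous"],
        "n_non_synchronous": kin["counts"]["non_synchronous"],
        "pct_nonsync_ratio": kin["percent_non_synchronous"]["ratio_to_synchronous"],
        "pct_nonsync_of_total": kin["percent_non_synchronous"]["fraction_of_total"],
    }
    for ch in ("green", "red"):
        for attr, state in (("k_c", "open"), ("k_o", "closed")):
            val = kin["mean_rates_per_min"]["per_channel"].get(ch, {}).get(attr)
            sd = bootstrap_rate_sd(dwell_df, state, ch, config, n_boot=n_boot, seed=seed)
            row[f"{attr}_{ch}_per_min"] = "n/a" if val is None else round(val, 3)
            row[f"{attr}_{ch}_sd"] = "n/a" if sd is None else round(sd, 3)
            if val is None:
                log.warning("no %s dwells for channel %s; reporting n/a", state, ch)
    table = pd.DataFrame([row])
    table.to_csv(out / "summary.csv", index=False)

    for state, label in (("open", "closure"), ("closed", "opening")):
        sel = dwell_df[(dwell_df.state == state)
                       & ~dwell_df.left_censored & ~dwell_df.right_censored]
        if sel.empty:
            log.warning("no uncensored %s dwells; skipping plot", state)
            continue
        x = np.sort(sel.duration_s.to_numpy())
        y = np.arange(1, x.size + 1)
        fig, ax = plt.subplots(figsize=(4.2, 3.2))
        ax.plot(x, y, ".", ms=3, color="tab:green", label="dwells")
        fit_info = kin["fits"].get(f"pooled_{state}")
        if fit_info:
            tt = np.linspace(0, x.max(), 300)
            model = sum(c["amplitude"] * (1 - np.exp(-tt / c["tau_s"]))
                        for c in fit_info["components"]) * y[-1]
            ax.plot(tt, model, "-", color="black",
                    label=f"{fit_info['n_components']}-exp fit")
        ax.set_xlabel("dwell time (s)")
        ax.set_ylabel("cumulative count")
        ax.set_title(f"kinetics of {label}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"cumsum_{state}.png", dpi=150)
        plt.close(fig)
    return table
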