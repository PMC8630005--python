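# smpet

Analysis of two-colour single-molecule PET (photoinduced electron transfer)
fluorescence microscopy data — and a ground-truthed simulator to validate
every stage of that analysis.

## The problem

A PET reporter turns a local protein conformational change into a binary
fluorescence switch: when a structural element closes, an engineered
tryptophan contacts the dye and quenches it; when it opens, fluorescence
returns. With two spectrally separate dyes on one molecule, two
conformational coordinates are read out simultaneously — one colour per
coordinate — in TIRF image stacks of surface-tethered molecules. The
scientific questions are kinetic: how fast does each element close and
open, and do the two elements move together (synchronous transitions) or
independently?

`smpet` implements the full chain from data to rate constants:

1. **Simulation** (`smpet.simulate`) — a coupled two-state telegraph
   process per molecule: closure attempts at rate `k_close` either quench
   both channels together or, with probability `p_uncoupled`, quench one
   channel alone (a failed closure attempt); sojourns in the quenched state
   relax at `k_open`; irreversible photobleaching per channel; a one-colour
   mode with irreversible closure and oxygen-triggered fluorescence
   recovery (DSPO) that discriminates PET quenching from bleaching. Output:
   state trajectories with event logs, noisy intensity traces, two-channel
   TIFF stacks and fiducial-bead frames.
2. **Image pipeline** (`smpet.imaging`) — local-maximum spot detection with
   sub-pixel centroid refinement, bead-based affine channel registration,
   greedy one-to-one co-localization into molecule ROIs, and per-frame
   maximum-pixel trace read-out.
3. **Step detection** (`smpet.stepdetect`) — Gaussian smoothing followed by
   the multiscale product of derivative-of-Gaussian edge responses at
   scales {1, 2, 4}; noise-calibrated thresholding, minimum-separation
   pruning and a relative-amplitude veto idealize each trace into a
   two-level fluorescent/quenched sequence.
4. **Kinetics** (`smpet.kinetics`) — same-direction steps in the two
   colours within six frames (1.8 s at 0.3 s/frame) form one synchronous
   transition; dwell times in open and closed states are collected with
   censoring at trace boundaries and photobleaches, summarized as
   cumulative-sum curves, and fitted with mono-/bi-exponential models (BIC
   selection). The headline quantities are amplitude-weighted mean rate
   constants

   ```
   k_c = 1 / (Σ aᵢ τᵢ)   from open-state dwells   (closure)
   k_o = 1 / (Σ aᵢ τᵢ)   from closed-state dwells (opening)
   ```

   with `Σ aᵢ = 1`, plus synchronous / non-synchronous transition counts
   and the free-energy conversion `ΔΔG = |−RT ln(k/k′)|`.

See `docs/methods.md` for the models, numerical choices and limitations.

## Worked example

Simulate 100 two-colour molecules (9 min at 0.3 s/frame, `k_close` =
1 min⁻¹, `k_open` = 5 min⁻¹, 12% uncoupled events), run the full
trace-level pipeline, and summarize:

```python
import smpet

config = smpet.PipelineConfig(
    simulation=smpet.SimulationConfig(
        n_molecules=100, duration_s=540.0, frame_interval_s=0.3,
        k_close=1.0, k_open=5.0, p_uncoupled=0.12),
    seed=42)
smpet.run_pipeline(config, "demo_out")
table = smpet.report("demo_out")
```

`demo_out/kinetics.json` then contains (abridged):

```json
{
 "counts": {"synchronous": 1166, "non_synchronous": 163},
 "percent_non_synchronous": {
  "ratio_to_synchronous": 13.98, "fraction_of_total": 12.26},
 "mean_rates_per_min": {
  "k_c": 0.992, "k_o": 4.697,
  "per_channel": {"green": {"k_c": 1.002, "k_o": 4.628},
                  "red":   {"k_c": 0.985, "k_o": 4.780}}}
}
```

Reading it: of 1329 classified transitions, 1166 were synchronous pairs
across the two colours and 163 were single-channel events — a
non-synchronous share of 14.0% relative to the synchronous count, close to
the 12% generative rate of uncoupled events. The recovered closure rate
(0.99 min⁻¹ pooled) matches the generative 1.0 min⁻¹; the opening rate
(4.70 min⁻¹) sits slightly below the generative 5.0 min⁻¹ because closed
dwells shorter than the 3-frame detector resolution are unobservable. The
green- and red-channel estimates agree within their bootstrap standard
deviations (`summary.csv`: k_c = 1.00 ± 0.13 vs 0.98 ± 0.19 min⁻¹), as
they must when both colours watch the same clamp.

The same stages are available from the shell:

```bash
smpet simulate --config sim.yaml --seed 42 --out work/
smpet extract  --green g.tif --red r.tif \
               --beads-green bg.tif --beads-red br.tif \
               --tol-px 2 --out work/traces.csv
smpet detect   --traces work/traces.csv --out work/
smpet kinetics --steps work/steps.csv --idealization work/idealization.csv \
               --frame-interval 0.3 --window 6 --out work/
smpet run      --config pipeline.yaml --seed 42 --out work/
smpet report   --results work/
```

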