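# kymoflux

Single-particle kymograph analysis of chromatin-remodeler dynamics on
stretched DNA: one-dimensional diffusion, remodeler–remodeler collisions,
nucleosome sequestration, and ATP-driven processive nucleosome
translocation — with a ground-truth synthetic trajectory generator so that
every stage of the pipeline is verifiable by parameter recovery.

## Who this is for

Labs imaging DNA-binding proteins on optical-tweezer-stretched tethers with
scanning confocal microscopy. The instrument produces kymographs (position
along the tether vs. time); a particle tracker turns those into per-particle
track tables. `kymoflux` consumes those tables (CSV) and quantifies:

- **1D diffusion** — rolling-window MSD analysis. For each 20-frame window
  the mean squared displacement over the first five lags is fit by least
  squares and `D = slope / 2d` (d = 1). Windows are classified against an
  immobile-control threshold: non-diffusive (`D < 0.01 µm²/s`), low
  (`0.01 ≤ D < 0.04`), high (`D ≥ 0.04`); runs shorter than 10 windows are
  dissolved as spurious, and per-track state durations and fractions are
  reported. Directed motion slower than ~300 bp/s is indistinguishable from
  immobility at this window length — it lands in the non-diffusive class.
- **Dwell times** — single- and double-exponential maximum-likelihood fits,
  `P(t|τ) = ∏ᵢ (1/τ) e^(−tᵢ/τ)`, with AIC model selection, optional
  Kaplan–Meier handling of right-censored events, and survival curves.
- **Two-color colocalization** — a distance threshold `d = x₁ + x₂` with
  `xᵢ = √(2 Dᵢ Δt)` from each molecule's mean diffusion coefficient;
  encounters are classified as short colocalizations (collision + recoil),
  long colocalizations (transient co-diffusion), or bypass (particles cross
  and continue). Remodeler–nucleosome colocalization uses a 500 bp radius
  and a nucleosome position map extended across pulsed-excitation dark gaps
  from the last visible signal.
- **Processive translocation** — penalized piecewise-linear changepoint
  segmentation; each constant-speed segment gets an OLS speed (bp/s via the
  3.2×10⁻⁴ µm/bp tension conversion), and is admitted only if it spans
  ≥ 300 bp, lasts ≥ 5 s and has R² ≥ 0.5 (the filters that separate true
  translocation from no-hydrolysis controls). Admitted segments feed
  direction-change counts, per-frame trace fragmentation (1D search /
  static engagement / translocating) and **push–pull** calls: translocation
  in the same direction as the 1D diffusive approach to the nucleosome is a
  *push* (NDR-widening), opposite is a *pull* (NDR-narrowing).
- **Nucleosome counting** — discrete ~25 nm unwrapping steps in 15–20 pN
  force-clamp distance traces, found by exact changepoint segmentation with
  coincident double steps resolved by size quantization.

## Worked example

```python
import numpy as np
from kymoflux import (SimulationConfig, DiffusionStateModel, simulate_switching_track,
                      diffusion_profile, DwellSample, simulate_dwells, fit_auto)

cfg = SimulationConfig(seed=1)                       # 42.4 ms line time
model = DiffusionStateModel(D_values=(0.002, 0.02, 0.06),
                            mean_lifetimes=(2.0, 1.5, 1.5))
track, truth = simulate_switching_track(model, cfg, duration=120.0)
prof = diffusion_profile(track)
print("mean window D: %.4f um^2/s" % np.nanmean(prof.D_window))
for state in ("non", "low", "high"):
    print("  %-4s fraction: %.2f" % (state, prof.state_fractions.get(state, 0.0)))

dwells = simulate_dwells(2000, taus=[18.0, 2.0], weights=[0.6, 0.4], seed=1)
fit = fit_auto(DwellSample(dwells))
print("AIC-selected components:", fit.n_components)
print("lifetimes: tau_slow = %.1f s, tau_fast = %.2f s (weights %.2f/%.2f)"
      % (fit.taus[0], fit.taus[1], fit.weights[0], fit.weights[1]))
```

Output:

```
mean window D: 0.0193 um^2/s
  non  fraction: 0.60
  low  fraction: 0.28
  high fraction: 0.12
AIC-selected components: 2
lifetimes: tau_slow = 18.4 s, tau_fast = 2.33 s (weights 0.59/0.41)
```

The simulated three-state scanner spends most of its classified time
non-diffusive (its non-diffusive lifetime is longest) with the expected
minority of low- and high-diffusive windows; the dwell fit recovers the
generative 18 s / 2 s mixture and AIC correctly prefers two components.

## Command line

```
kymoflux simulate|diffuse|dwell|coloc|transloc|count-nucs|run|validate
```

`run` drives the full pipeline (tracks → diffusion → dwell → colocalization
→ translocation → JSON/CSV report); `validate` executes the synthetic
parameter-recovery suite. Track CSVs use columns
`track_id, channel, time_s, position_um, observed`; the `dryad` input
dialect additionally maps `track id / time (s) / position (um)` column
names. Force traces are CSVs with `time_s, distance_nm[, force_pN]`.

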