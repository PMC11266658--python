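# burstcycle

Dwell-time analysis of transcriptional bursting at a single gene, for
researchers studying whether the promoter's regulatory cycle operates in or
out of thermodynamic equilibrium.

A gene observed by live-cell imaging switches between transcriptionally
active (ON) and inactive (OFF) periods.  If the hidden promoter dynamics
are a reversible Markov process, the dwell-time density `f(t)` of an
observed mesostate is necessarily monotone; a *peaked* density — and in the
extreme a *maximally peaked* one with `f(0) = 0` — is a model-free
fingerprint of a cyclic, irreversible (entropy-producing) regulatory
process.  `burstcycle` implements both sides of that argument:

- **Theory** (`burstcycle.kinetics`): exact phase-type dwell densities of
  mesostates of small continuous-time Markov chains
  (`f(t) = Σ c_k e^{λ_k t}` from the spectral form of the sub-generator),
  peakedness classification, and the nonequilibrium thermodynamics of the
  3-state promoter clock: `α_eq = (w32 w21 w13 / w12)^{1/2}`, entropy per
  cycle `Δs = 2 k_B ln(α_eq/α)`, cycle current `J+ = w13 p3 − w31 p1`, and
  the Schnakenberg rate `σ = J+ Δs`.
- **Synthetic data** (`burstcycle.simulate`): Gillespie simulation of
  promoter models (including a 4-state graph with short- and long-lived OFF
  states), fluorescence traces with nascent-transcript birth–death signal,
  signal-dependent Gaussian noise, photobleaching and per-cell backgrounds,
  and 7-plane microscope-like image stacks — all seeded, all with ground
  truth.
- **Trace analysis** (`burstcycle.segment`): bleach detrending, KDE-mode
  background subtraction, window-based change-point detection with a
  Gaussian mean+variance cost, ON/OFF labelling, and internal/external
  period extraction — as scikit-learn style estimators
  (`BleachDetrender`, `ModeBackgroundSubtractor`, `ChangePointSegmenter`).
- **Survival statistics** (`burstcycle.survival`): empirical survival
  curves; the biexponential survival model
  `P(T>t) = −a e^{λ1 t} + (1+a) e^{λ2 t}` fitted by least squares on the
  survival curve (free, `f(0) ≥ 0`-constrained, and `f(0) = 0`-pinned
  variants); cell-level bootstrap with peakedness classification;
  memoryless censored-exponential means for window-censored external OFF
  periods; burst-run statistics (`p_long`).
- **Spot quantification** (`burstcycle.spots`): max projection,
  PSF-matched band-pass, 5σ spot calling, nucleus segmentation, tracking
  with carry-forward/fallback, and iterative Gaussian-mask intensities.
- **Pipeline + CLI** (`burstcycle.pipeline`, `burstcycle` command):
  simulate → segment → fit → report from one YAML config and one seed,
  with all intermediates persisted.

## Worked example

```python
from burstcycle.pipeline import RunConfig, run_pipeline

cfg = RunConfig(scenario="wildtype_like", n_cells=60, seed=1,
                fit={"bootstrap": 100, "t_probe": 0.01, "constrained": True},
                out_dir="wt_demo")
print(run_pipeline(cfg).render())
```

prints

```
strain wildtype_like  (60 cells, seed 1, config 13f6395e989a)
  periods: {'internal_ON': 109, 'internal_OFF': 88, 'external_OFF': 81}
  internal ON : mu = 81.0 +/- 24.3 s, class = peaked, f(0.01) = 0.005976 +/- 0.002345
  internal OFF: mean = 139.7 s, class = monotone
  external OFF: mu = 1033 s (n_obs 66, n_cens 30)
  burst runs  : p_long = 0.266 (n 109)
```

Reading it: 60 synthetic cells were segmented into ON/OFF periods; the 109
internal ON periods have a mean length of ~81 s (bootstrap mean ± SD), and
their dwell density classifies *peaked* — the generating clock model is
maximally irreversible (α = 0), so the rise of the density away from
`f(0) = 0` is detected even at this small cohort size.  The external OFF
mean (~1030 s) comes from the censored-exponential estimator, and
`p_long` is the fraction of bursts followed by a long-lived (window-
spanning) OFF period.  The same chain is available from the shell:

```
burstcycle run --config run.yaml
burstcycle segment --traces traces.csv --out periods.csv
burstcycle fit --periods periods.csv --bootstrap 300 --t-probe 0.01
burstcycle report --run-dir out/
```

Four scenario presets (`wildtype_like`, `chd1_like`, `isw2_like`,
`pho4_like`) encode decreasing irreversibility of the promoter cycle and
increasing long-lived OFF occupancy; `compare_strains` tabulates them side
by side.  See `docs/methods.md` for the model, the estimator choices and
their calibration, and known limitations.

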