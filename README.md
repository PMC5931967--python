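# phagelight

Analysis toolkit for light-dependent cyanophage development in marine
*Synechococcus*: how much ATP a lytic infection spends on genome
replication versus translation, and how irradiance reshapes the one-step
growth curve.

Cyanophages carry photosynthesis genes (notably *psbA*, encoding the PSII
D1 protein), and infections under higher light burst earlier without
changing DNA replication — pointing to translation, not nucleotide supply,
as the energetic bottleneck of phage development. `phagelight` packages the
calculations behind that argument for anyone analysing one-step infection
experiments with qPCR, PAM fluorometry and RT-qPCR readouts:

- **energetics** — per-infection ATP budget:
  `E_dna = B(1−s)Σ n_b c_b / N_A` over the duplex base composition, plus
  amino-acid biosynthesis and per-residue polymerisation costs of the
  structural proteome, and their headline translation:replication ratio.
  Cost tables are editable YAML data with documented provenance.
- **kinetics** — standard curves (E = 10^(−1/slope)), absolute
  quantification, latent period (fold-threshold crossing, log-interpolated,
  bootstrap CI), burst size, DNA synthesis rate, condition comparisons.
- **photophysiology** — Fv/Fm = (Fm−F0)/Fm, t₀ normalisation, exponential
  photoinhibition fits.
- **expression** — efficiency-corrected (Pfaffl) ratios, REST-style fixed
  reallocation randomisation tests, splice-isoform ratios under both
  calibrator schemes, Welch coverage comparisons.
- **genome architecture** — intergenic-gap statistics, strand-aware
  upstream distances, a maximal inverted-repeat (hairpin) finder verified
  against brute force, splice-isoform construction and in-frame stop
  detection.
- **synthetic data** — seeded generators for every input (infection time
  series, qPCR plates, RT-qPCR CTs, fluorescence, annotated genomes with
  planted architecture), so the whole pipeline runs and is testable with no
  external data.

## Worked example

The `demo` subcommand simulates a complete experiment (seeded) and runs
every analysis on it:

```sh
phagelight demo --seed 1 --out-dir demo_out
```

prints, among other lines:

```
HL vs LL: latent change -4.99 h (-38.8%), burst ratio 1.01
spliced: ratio=10.83 p=0.08782
median gap 6 bp over 29 gaps
```

Read: against the generating truth (latent 12.5 h LL vs 7.5 h HL, burst 10,
spliced-isoform HL:LL fold change 10.6), the estimators recover a 4.99 h
(38.8%) latent-period reduction with unchanged burst size, a 10.83-fold
spliced-isoform increase (p = 0.088, the resolution floor of a 20-way
reallocation test at n = 3+3), and the planted 6 bp median intergenic gap.
`demo_out/` contains the full TSV outputs — growth parameters per
condition, photoinhibition fits, the energy budget of a toy virion on the
synthetic genome, and the upstream inverted repeat (total paired length
36 bp) — plus a `run_manifest.json` for exact re-execution.

Library use mirrors the CLI:

```python
from phagelight.synthetic import SimulationConfig, simulate_infection
from phagelight.kinetics import estimate_latent_period, estimate_burst_size

cfg = SimulationConfig(seed=1)
ts = simulate_infection(cfg, "HL", n_replicates=3)
latent = estimate_latent_period(ts, "HL")          # ~7.9 h, with bootstrap CI
burst = estimate_burst_size(ts, "HL", cfg.n_infected)  # ~9.4
```

See `docs/methods.md` for the model, estimator definitions, defaults and
their rationale.

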