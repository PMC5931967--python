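# Methods

`phagelight` implements the quantitative core of a one-step cyanophage
infection study under two irradiances (low light, LL, and high light, HL):
ATP cost accounting for phage production, growth-parameter estimation from
qPCR genome-copy time series, PSII photophysiology, efficiency-corrected
relative expression of splice isoforms, and genome-architecture statistics.
Every analysis can be exercised end-to-end on seeded synthetic data.

## Energy budget

The central comparison is the per-infection ATP cost of replicating the
phage genome versus translating its structural proteome.

DNA replication:

    E_dna = B · (1 − s) · Σ_b n_b c_b / N_A

where B is burst size, s an optional salvage fraction (dNTPs recycled from
host DNA rather than made de novo; s = 0 is the upper bound), n_b the base
counts of the *duplex* genome (sequence plus reverse complement, so
Σ n_b = 2L and A = T, C = G by complementarity), c_b the ATP-equivalent
biosynthesis cost of each dNTP, and N_A Avogadro's number. Translation
splits into amino-acid biosynthesis (Σ over virion proteins of copies ×
per-residue costs) and polymerisation, charged at 4 ATP equivalents per
residue: aminoacylation (ATP → AMP, counted as 2 because PPi is
hydrolysed), EF-Tu GTP, and EF-G GTP. Polymerisation is charged per
residue, not per peptide bond, because aminoacylation applies to every
residue; a per-bond variant would differ by one part in the protein length.

Cost tables are data, not code. The shipped YAML tables count only direct
ATP/GTP-hydrolysing steps of the canonical bacterial pathways (PPi release
charged 2; NADPH and precursor opportunity costs excluded, since the
output unit is mol ATP). The per-step breakdown is documented in the YAML
headers and any table with the same keys can be substituted, e.g. one that
converts NADPH at a chosen ATP:NADPH ratio. Reference per-infection totals
of 2.2×10⁻¹⁷ mol ATP (DNA), 7.4×10⁻¹⁹ (amino-acid biosynthesis) and
4.4×10⁻¹⁷ (polymerisation) give a translation:replication ratio of ≈ 2.03;
`energy_budget` reproduces this ratio from the three components and treats
a zero DNA cost as an explicit error rather than an infinite ratio.

## Infection model and kinetics estimation

The synthetic one-step curve assumes: cells at 10⁸ ml⁻¹; phage added at a
virus-to-bacterium ratio (VBR) of 10; a fraction of the added phage adsorb
during the 1 h adsorption window (default 0.5 — marine cyanophage
adsorption is slow and incomplete; the remainder is the extracellular
baseline). Adsorption is Poisson, so the infected fraction is
1 − exp(−VBR·f_ads) ≈ 0.993, consistent with the observed complete lysis.
Per-cell intracellular genome copies rise linearly from 1 (the injected
genome) at the end of the 2 h eclipse to the burst size (10). DNA synthesis
kinetics are deliberately condition-independent — both light treatments
finish replication at min(latent_LL, latent_HL) − σ_lysis = 6.5 h — because
the study's central observation is that irradiance changes lysis timing,
not DNA synthesis. Lysis times are Normal(latent, σ = 1 h) truncated at the
eclipse; the latent period defaults are 12.5 h (LL) and 7.5 h (HL), i.e. a
5 h / 40% reduction. The 1 h lysis dispersion is a free choice; the study
reports a spread but no model. Lysed cells move their genomes from the
intracellular to the extracellular pool (filters capture intact cells
only). Sampling happens at 0, 1, 2, 3, 5, 7, 9, 12, 15, 18 h with
multiplicative lognormal noise (σ = 0.15, unit mean).

Estimators:

- **Standard curve**: ordinary least squares of CT on log₁₀(copies),
  replicates unaveraged; efficiency E = 10^(−1/slope). Unknowns are
  quantified as dilution · 10^((CT − intercept)/slope); missing CT stays
  missing.
- **Latent period**: baseline = geometric mean of the first three sampling
  times (geometric, because the noise is lognormal); the latent period is
  the first crossing of 2× baseline, linearly interpolated in log₁₀ space
  between bracketing samples. The threshold rule is one defensible
  operational definition among several; the fold threshold makes the
  estimate invariant to rescaling all copy numbers. Confidence intervals
  bootstrap the replicates (percentile, seeded).
- **Burst size**: (mean of the last two aggregated time points − baseline)
  / infected cells, with the Poisson-adsorption default for the infected
  count.
- **DNA synthesis rate**: least-squares slope of per-cell copies over the
  window from the first sample above 1.5× the t₀ value to the sample of
  maximum signal. With the coarse 0–18 h sampling grid this window is
  truncated earlier under HL (lysis removes cells near the maximum) than
  under LL (whose window includes plateau samples), so recovered HL and LL
  rates agree only to ~20% at the default noise even though the generating
  kinetics are identical; the tests assert the null result at that
  realistic resolution.

At the defaults the recovered median burst size is within a few percent of
10 and the recovered latent reduction within ~1.5 percentage points of 40%
(20 seeds); the threshold crossing sits near the centre of the lysis-time
distribution, so discretisation bias largely cancels between conditions.

## Photophysiology

Fv/Fm = (Fm − F0)/Fm from dark-adapted PAM fluorescence pairs, bounded in
[0, 1); F0 > Fm is rejected as an instrument artefact. Per-replicate
normalisation to t = 0 is idempotent. Photoinhibition is fitted as
y(t) = y∞ + (y0 − y∞)e^(−kt) by bounded nonlinear least squares,
initialised from the data (k from a log-linear pre-fit). The single
exponential is a modelling choice; the study states only that a decay rate
exists. The generator holds LL constant at Fv/Fm 0.40 (typical for
*Synechococcus*), decays HL uninfected cultures at 0.5 h⁻¹ to 65% of the
LL level, and lets HL infected cultures recover from 2 h post-infection to
90% of LL — the narrative anchor points of the study, used here as
generator defaults, not as claims about real cultures.

## Relative expression and splicing

The Pfaffl ratio E_t^ΔCT_t / E_ref^ΔCT_ref (ΔCT = mean control − mean
treated) is the efficiency-corrected generalisation of 2^ΔΔCT, to which it
reduces exactly at E = 2. Significance uses a fixed-reallocation
randomisation test in the style of REST: sample labels are permuted jointly
for target and reference CTs (a sample's pair moves together), group sizes
preserved, statistic |log ratio|, two-sided p with the (b+1)/(n+1)
correction. The published description of REST's scheme is loose, so this
pinned reimplementation is validated against exhaustive enumeration of all
20 reallocations at n = 3+3 and shown super-uniform under the null. Note
that at n = 3+3 the smallest achievable two-sided p is ≈ 2/20 = 0.1.

The splicing assay supports the study's two calibrator schemes: host 16S
as reference when comparing an isoform between conditions, and the
unspliced isoform as calibrator for the within-sample spliced:unspliced
ratio, computed as E_s^(−CT_s)/E_u^(−CT_u) (equal efficiencies reduce this
to E^(CT_u − CT_s)); the 16S wells are provably unused in that mode. The
CT generator inverts these formulas, so the pipeline recovers the
generating ratios (defaults 10.6 for spliced HL:LL, 3.37 unspliced, 2.0
early spliced:unspliced) exactly at zero CT noise and to < 10% median
error at the default 0.15-cycle noise. The transcriptome coverage
comparison is a Welch t-test on per-replicate mean coverages with the
fold change of group means.

## Genome architecture

Intergenic gaps are strand-agnostic distances between consecutive features
in start order (next.start − prev.end − 1; overlaps clip to 0, are flagged,
and are included in the median). The median uses the lower middle value for
even counts so the statistic stays integer-valued. The strand-aware
upstream distance of a single gene is a separate operation, since a long 5′
region is read in the gene's own orientation. The inverted-repeat finder
enumerates every maximal hairpin (arms exact reverse complements up to a
mismatch budget, loop bounded): maximality means the arms can be extended
neither outward nor inward, and for each innermost pairing exactly one
maximal arm exists, which the finder reaches by greedy outward extension.
It is verified equivalent to a brute-force enumeration of every placement
on random sequences. The finder is quadratic and intended for regions
(upstream gaps, 5′ UTRs), not whole genomes. A "36 bp inverted repeat" is
reported as total paired length (two 18 bp arms); arm length, loop and span
are all exposed so any reading is checkable.

The synthetic genome plants its ground truth by construction: half the
internal gaps are fixed at the 6 bp target median (the rest drawn above
it), one gene sits behind a 232 bp gap containing an 18+8+18 repeat whose
flanks are forced non-pairing so the planted arms are exactly maximal, and
the same gene carries a 212 bp intron with two codon-aligned TAA stops, so
the unspliced transcript cannot encode a full-length product while the
spliced isoform is a clean ORF.

## What the synthetic data does and does not show

The generators reproduce the error structure the estimators assume
(lognormal copy noise, Gaussian CT noise, Poisson adsorption, Normal lysis
dispersion) with known truth, so passing tests demonstrate correctness and
calibration of the estimators under those assumptions — not the biology of
real infections. Real data add plate effects, inhibition, adsorption
kinetics, partial lysis and annotation error that are out of scope here.
Problem sizes in the tests and the acceptance script (20 seeds × 3
replicates × 10 time points; 60-300 bp oracle sequences) were chosen as the
smallest sizes at which the medians are stable.

## Reproducibility

Every stochastic routine takes a seed; generators derive independent
substreams per output kind via `numpy` seed sequences, so adding replicates
of one kind never perturbs another. Same seed ⇒ byte-identical outputs.
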