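"""Synthetic data generators emulating every pipeline input.

The generators reproduce the statistical structure the downstream analyses
assume — a one-step infection curve sampled by qPCR, standard-curve plates,
RT-qPCR CT values with a known generating expression ratio, PSII fluorescence
trajectories, and a phage genome with planted architectural features
(intergenic-gap median, a long upstream gap carrying an inverted repeat, a
group I intron with in-frame stop codons) — so that each estimator can be
tested against known truth without any downloaded data.

Every generator is seeded and byte-reproducible.

Infection model
---------------
Cells at ``cells_per_ml`` are mixed with phage at multiplicity ``vbr``; a
fraction ``adsorbed_fraction`` of the added phage adsorb during the
adsorption window, so the effective Poisson multiplicity is
``vbr * adsorbed_fraction`` and the infected-cell density is
``N_inf = cells * (1 - exp(-vbr * adsorbed_fraction))``. Unadsorbed phage
remain as the extracellular baseline. Per-cell intracellular genome copies
rise linearly from 1 (injected genome) at the end of the eclipse phase to
``burst_size`` at a condition-independent completion time
``min(latent_LL, latent_HL) - lysis_sd_h`` — DNA synthesis kinetics are
shared between light treatments; only lysis timing differs. Each cell's
lysis time is Normal(latent, lysis_sd_h) truncated at the eclipse; lysed
cells move their genomes from the intracellular to the extracellular pool.
Sampled values carry multiplicative lognormal noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    FeatureTable,
    FluorescenceTable,
    GenomeRecord,
    QpcrPlate,
    TimeSeriesTable,
)

__all__ = [
    "SimulationConfig",
    "SyntheticGenomeSpec",
    "GenomePlan",
    "simulate_infection",
    "infection_mean_model",
    "simulate_qpcr_plate",
    "simulate_genome",
    "simulate_expression_ct",
    "simulate_fluorescence",
]

_STOPS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _rng_for(seed: int, *streams: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, label...) pair."""
    return np.random.default_rng([seed] + [zlib.crc32(s.encode()) for s in streams])


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic infection experiment.

    Defaults mirror the experimental design: host at 1e8 cells/ml infected
    at a virus-to-bacterium ratio of 10, burst size 10, latent period 12.5 h
    under low light shortened to 7.5 h under high light, samples at
    0,1,2,3,5,7,9,12,15,18 h. ``adsorbed_fraction`` is the fraction of added
    phage that adsorb during the 1 h adsorption window (marine cyanophage
    adsorption is slow and incomplete; the remainder forms the extracellular
    baseline).
    """

    seed: int = 0
    cells_per_ml: float = 1e8
    vbr: float = 10.0
    burst_size: float = 10.0
    latent_LL_h: float = 12.5
    latent_HL_h: float = 7.5
    eclipse_h: float = 2.0
    lysis_sd_h: float = 1.0
    sample_times_h: tuple[float, ...] = (0, 1, 2, 3, 5, 7, 9, 12, 15, 18)
    noise_cv: float = 0.15
    qpcr_efficiency: float = 1.95
    qpcr_intercept: float = 40.0
    ct_sd: float = 0.15
    adsorbed_fraction: float = 0.5
    fvfm_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if not (self.eclipse_h < self.latent_LL_h and self.eclipse_h < self.latent_HL_h):
            raise ValueError("eclipse_h must precede both latent periods")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 1.0 < self.qpcr_efficiency <= 2.0:
            raise ValueError("qpcr_efficiency must be in (1, 2]")
        if not 0.0 < self.adsorbed_fraction <= 1.0:
            raise ValueError("adsorbed_fraction must be in (0, 1]")

    def latent_for(self, condition: str) -> float:
        try:
            return {"LL": self.latent_LL_h, "HL": self.latent_HL_h}[condition]
        except KeyError:
            raise ValueError(f"unknown condition {condition!r}; expected HL or LL") from None

    @property
    def effective_moi(self) -> float:
        return self.vbr * self.adsorbed_fraction

    @property
    def n_infected(self) -> float:
        """Infected cells per ml under Poisson adsorption at the effective MOI."""
        return self.cells_per_ml * (1.0 - np.exp(-self.effective_moi))

    @property
    def free_phage_0(self) -> float:
        """Unadsorbed phage per ml: the extracellular baseline."""
        return self.cells_per_ml * self.vbr * (1.0 - self.adsorbed_fraction)

    @property
    def dna_done_h(self) -> float:
        """Condition-independent time at which per-cell copies reach burst size."""
        return min(self.latent_LL_h, self.latent_HL_h) - self.lysis_sd_h


def _lysis_cdf(t: np.ndarray, latent: float, sd: float, eclipse: float) -> np.ndarray:
    """P(lysis time <= t) for Normal(latent, sd) truncated below at the eclipse."""
    if sd <= 0:
        return (t >= latent).astype(float)
    a = (eclipse - latent) / sd
    return stats.truncnorm.cdf(t, a=a, b=np.inf, loc=latent, scale=sd)


def _per_cell_copies(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Mean intracellular genome copies per (unlysed) infected cell."""
    t0, t1 = config.eclipse_h, config.dna_done_h
    if t1 <= t0:
        raise ValueError("DNA synthesis window is empty: eclipse_h >= dna_done_h")
    frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return 1.0 + (config.burst_size - 1.0) * frac


def infection_mean_model(
    t: np.ndarray | list[float], config: SimulationConfig, condition: str
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (intracellular, extracellular) copies/ml at times ``t``."""
    t = np.asarray(t, dtype=float)
    latent = config.latent_for(condition)
    n_inf = config.n_infected
    lysed = _lysis_cdf(t, latent, config.lysis_sd_h, config.eclipse_h)
    intracellular = _per_cell_copies(t, config) * (1.0 - lysed) * n_inf
    extracellular = config.free_phage_0 + config.burst_size * n_inf * lysed
    return intracellular, extracellular


def simulate_infection(
    config: SimulationConfig, condition: str, n_replicates: int = 3
) -> TimeSeriesTable:
    """One-step growth time series with multiplicative lognormal noise.

    Noise is lognormal with log-scale sigma ``noise_cv`` and unit mean
    (mu = -sigma^2/2), applied independently per sampled value.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    times = np.asarray(config.sample_times_h, dtype=float)
    intr, extr = infection_mean_model(times, config, condition)
    rng = _rng_for(config.seed, "infection", condition)
    rows = []
    sigma = config.noise_cv
    for rep in range(1, n_replicates + 1):
        for compartment, mean in (("intracellular", intr), ("extracellular", extr)):
            if sigma > 0:
                noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=times.size)
            else:
                noise = np.ones(times.size)
            values = mean * noise
            for t, v in zip(times, values):
                rows.append((t, condition, rep, compartment, float(v)))
    df = pd.DataFrame(
        rows, columns=["time_h", "condition", "replicate", "compartment", "copies_per_ml"]
    )
    return TimeSeriesTable(df)


def simulate_qpcr_plate(
    true_copies: list[float],
    config: SimulationConfig,
    n_standards: int = 9,
    top_standard_copies: float = 2.5e10,
) -> QpcrPlate:
    """A qPCR plate: unknown wells for ``true_copies`` plus a standard ladder.

    CT = intercept + slope*log10(copies) + Normal(0, ct_sd), with
    slope = -1/log10(efficiency). Standards are a triplicate 10-fold
    dilution ladder descending from ``top_standard_copies``.
    """
    copies = np.asarray(true_copies, dtype=float)
    if (copies <= 0).any():
        raise ValueError("true_copies must be positive")
    if n_standards < 3:
        raise ValueError("need at least 3 standard dilution levels")
    rng = _rng_for(config.seed, "qpcr")
    slope = -1.0 / np.log10(config.qpcr_efficiency)

    def ct_for(n: float) -> float:
        ct = config.qpcr_intercept + slope * np.log10(n)
        if config.ct_sd > 0:
            ct += rng.normal(0.0, config.ct_sd)
        return float(ct)

    rows = []
    well = 0
    for level in range(n_standards):
        known = top_standard_copies / 10.0**level
        for rep in range(1, 4):
            well += 1
            rows.append(
                (f"W{well:03d}", f"std_{level + 1}", "gcn", ct_for(known), "standard", known, rep)
            )
    for i, n in enumerate(copies, start=1):
        well += 1
        rows.append((f"W{well:03d}", f"unk_{i}", "gcn", ct_for(n), "unknown", np.nan, 1))
    df = pd.DataFrame(
        rows,
        columns=["well_id", "sample_id", "assay_id", "ct", "role", "known_copies", "replicate"],
    )
    return QpcrPlate(df)


# ---------------------------------------------------------------------------
# Synthetic genome with planted architecture


@dataclass
class SyntheticGenomeSpec:
    """Blueprint for a genome with known architectural ground truth."""

    n_genes: int = 30
    gene_len_bp: int = 300
    target_median_gap_bp: int = 6
    long_gap_bp: int = 232
    ir_arm_bp: int = 18
    ir_loop_bp: int = 8
    intron_len_bp: int = 212
    gc_fraction: float = 0.40

    def __post_init__(self) -> None:
        if self.long_gap_bp < 2 * self.ir_arm_bp + self.ir_loop_bp:
            raise ValueError("long gap too short to host the inverted repeat")
        if self.n_genes < 5:
            raise ValueError("need at least 5 genes")
        if self.gene_len_bp % 3 or self.gene_len_bp < 99:
            raise ValueError("gene_len_bp must be a multiple of 3 and >= 99")
        if self.intron_len_bp < 66:
            raise ValueError("intron must fit two planted stop codons")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GenomePlan:
    """Ground truth of the planted features, for estimator checks."""

    designated_gene_id: str
    intron_start_in_gene: int  # 1-based inclusive, within the unspliced gene
    intron_end_in_gene: int
    intron_genome_start: int
    intron_genome_end: int
    long_gap_genome_start: int  # the 232 bp gap upstream of the designated gene
    long_gap_genome_end: int
    ir_left_arm_start: int  # genome coordinate, 1-based
    ir_arm_bp: int
    ir_loop_bp: int


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _clean_codons(rng: np.random.Generator, n_codons: int, gc: float) -> list[str]:
    out = []
    while len(out) < n_codons:
        codon = _random_bases(rng, 3, gc)
        if codon not in _STOPS:
            out.append(codon)
    return out


def _gene_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    codons = _clean_codons(rng, length // 3 - 2, gc)
    return "ATG" + "".join(codons) + "TAA"


def _ir_cassette(rng: np.random.Generator, arm: int, loop: int, gc: float) -> str:
    left = _random_bases(rng, arm, gc)
    while True:
        loop_seq = _random_bases(rng, loop, gc)
        # the loop ends must not base-pair, or the planted arms would extend inward
        if loop < 2 or loop_seq[0] != _revcomp(loop_seq[-1]):
            break
    return left + loop_seq + _revcomp(left)


def simulate_genome(
    spec: SyntheticGenomeSpec, seed: int = 0
) -> tuple[GenomeRecord, FeatureTable, GenomePlan]:
    """Build a linear genome of same-strand genes with planted ground truth.

    Planted by construction: the median internal intergenic gap equals
    ``target_median_gap_bp`` exactly (half the gaps are fixed at the median,
    the rest drawn above it); one designated gene sits behind a
    ``long_gap_bp`` gap containing an inverted repeat with exact
    reverse-complement arms; the same gene carries an intron with two
    in-frame TAA stop codons at codon-aligned offsets.
    """
    rng = _rng_for(seed, "genome")
    m = spec.n_genes - 1  # internal gaps
    designated = spec.n_genes // 2  # 0-based gene index behind the long gap

    n_median = m // 2 + 1  # enough to pin the lower median
    n_free = m - 1 - n_median
    if n_free < 0:
        raise ValueError("too few genes to plant both the median and the long gap")
    free = rng.integers(spec.target_median_gap_bp + 1, 10 * spec.target_median_gap_bp + 1,
                        size=n_free)
    gap_lengths = [spec.target_median_gap_bp] * n_median + [int(g) for g in free]
    rng.shuffle(gap_lengths)
    gap_lengths.insert(designated - 1, spec.long_gap_bp)  # gap before the designated gene

    # inverted repeat centred in the long gap
    ir_total = 2 * spec.ir_arm_bp + spec.ir_loop_bp
    ir_offset = (spec.long_gap_bp - ir_total) // 2  # 0-based within the gap
    long_gap_seq = list(_random_bases(rng, spec.long_gap_bp, spec.gc_fraction))
    cassette = _ir_cassette(rng, spec.ir_arm_bp, spec.ir_loop_bp, spec.gc_fraction)
    long_gap_seq[ir_offset : ir_offset + ir_total] = cassette
    # block outward extension of the planted arms
    if ir_offset > 0:
        before = long_gap_seq[ir_offset - 1]
        after_idx = ir_offset + ir_total
        if after_idx < spec.long_gap_bp and long_gap_seq[after_idx] == _revcomp(before):
            long_gap_seq[after_idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[
                long_gap_seq[after_idx]
            ]
    long_gap_seq = "".join(long_gap_seq)

    exon1_len = 90  # codon-aligned insertion point for the intron
    intron = list(_random_bases(rng, spec.intron_len_bp, spec.gc_fraction))
    for stop_offset in (30, 60):  # codon-aligned within the gene reading frame
        intron[stop_offset : stop_offset + 3] = "TAA"
    intron = "".join(intron)

    parts: list[str] = []
    rows = []
    pos = 1  # next free 1-based coordinate
    lead = _random_bases(rng, 50, spec.gc_fraction)
    parts.append(lead)
    pos += len(lead)
    plan_fields: dict[str, int] = {}
    for i in range(spec.n_genes):
        if i > 0:
            gap_len = gap_lengths[i - 1]
            if i == designated:
                gap_seq = long_gap_seq
                plan_fields["long_gap_genome_start"] = pos
                plan_fields["long_gap_genome_end"] = pos + gap_len - 1
                plan_fields["ir_left_arm_start"] = pos + ir_offset
            else:
                gap_seq = _random_bases(rng, gap_len, spec.gc_fraction)
            parts.append(gap_seq)
            pos += gap_len
        gene_id = f"gene_{i + 1:03d}"
        if i == designated:
            exon1 = _gene_sequence(rng, spec.gene_len_bp, spec.gc_fraction)[: exon1_len]
            exon2 = "".join(
                _clean_codons(rng, (spec.gene_len_bp - exon1_len) // 3 - 1, spec.gc_fraction)
            ) + "TAA"
            gene_seq = exon1 + intron + exon2
            plan_fields["intron_start_in_gene"] = exon1_len + 1
            plan_fields["intron_end_in_gene"] = exon1_len + spec.intron_len_bp
            plan_fields["intron_genome_start"] = pos + exon1_len
            plan_fields["intron_genome_end"] = pos + exon1_len + spec.intron_len_bp - 1
            attributes = {"ID": gene_id, "Name": "psbA"}
        else:
            gene_seq = _gene_sequence(rng, spec.gene_len_bp, spec.gc_fraction)
            attributes = {"ID": gene_id}
        rows.append((gene_id, pos, pos + len(gene_seq) - 1, "+", "CDS", attributes))
        parts.append(gene_seq)
        pos += len(gene_seq)
    parts.append(_random_bases(rng, 50, spec.gc_fraction))

    genome = GenomeRecord(id="synthetic_phage", sequence="".join(parts))
    features = FeatureTable(pd.DataFrame(rows, columns=FeatureTable.COLUMNS))
    plan = GenomePlan(
        designated_gene_id=f"gene_{designated + 1:03d}",
        ir_arm_bp=spec.ir_arm_bp,
        ir_loop_bp=spec.ir_loop_bp,
        **plan_fields,
    )
    return genome, features, plan


# ---------------------------------------------------------------------------
# RT-qPCR splicing assay


def simulate_expression_ct(
    config: SimulationConfig,
    true_ratio_spliced_HL_LL: float = 10.6,
    true_ratio_unspliced_HL_LL: float = 3.37,
    true_spliced_to_unspliced_early: float = 2.0,
    n_replicates: int = 3,
) -> QpcrPlate:
    """CT values for the spliced/unspliced/16S assays with known true ratios.

    The generating model is the inverse of the efficiency-corrected ratio:
    with amplification efficiency E, a fold change r between two groups is
    encoded as a CT difference of log_E(r) cycles. The 16S reference CT is
    constant across conditions, so reference-normalised ratios equal the
    condition CT differences of the target assay. Two timepoints are
    generated: "early" (both conditions hold the spliced:unspliced ratio at
    its early-infection value) and "late" (the HL:LL fold changes of each
    isoform take their stated values, with LL late at equimolar isoforms).
    Gaussian CT noise with sd ``ct_sd`` is added to every well.
    """
    for name, r in (
        ("true_ratio_spliced_HL_LL", true_ratio_spliced_HL_LL),
        ("true_ratio_unspliced_HL_LL", true_ratio_unspliced_HL_LL),
        ("true_spliced_to_unspliced_early", true_spliced_to_unspliced_early),
    ):
        if r <= 0:
            raise ValueError(f"{name} must be > 0")
    rng = _rng_for(config.seed, "expression")
    log_e = np.log(config.qpcr_efficiency)

    def cycles(ratio: float) -> float:
        return float(np.log(ratio) / log_e)

    ct_u_early = 26.0
    ct_u_late_ll = 25.0
    mean_ct = {
        ("unspliced", "LL", "early"): ct_u_early,
        ("unspliced", "HL", "early"): ct_u_early,
        ("spliced", "LL", "early"): ct_u_early - cycles(true_spliced_to_unspliced_early),
        ("spliced", "HL", "early"): ct_u_early - cycles(true_spliced_to_unspliced_early),
        ("unspliced", "LL", "late"): ct_u_late_ll,
        ("unspliced", "HL", "late"): ct_u_late_ll - cycles(true_ratio_unspliced_HL_LL),
        ("spliced", "LL", "late"): ct_u_late_ll,  # equimolar isoforms at LL late
        ("spliced", "HL", "late"): ct_u_late_ll - cycles(true_ratio_spliced_HL_LL),
    }
    for condition in ("LL", "HL"):
        for timepoint in ("early", "late"):
            mean_ct[("ref16S", condition, timepoint)] = 15.0

    rows = []
    well = 0
    for (assay, condition, timepoint), ct0 in mean_ct.items():
        for rep in range(1, n_replicates + 1):
            well += 1
            ct = ct0 + (rng.normal(0.0, config.ct_sd) if config.ct_sd > 0 else 0.0)
            rows.append(
                (
                    f"W{well:03d}",
                    f"{condition}:{timepoint}:{rep}",
                    assay,
                    float(ct),
                    "unknown",
                    np.nan,
                    rep,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=["well_id", "sample_id", "assay_id", "ct", "role", "known_copies", "replicate"],
    )
    return QpcrPlate(df)


# ---------------------------------------------------------------------------
# PSII fluorescence


def simulate_fluorescence(
    config: SimulationConfig,
    condition: str,
    infected: bool,
    n_replicates: int = 3,
    fvfm_ll: float = 0.40,
    hl_plateau_fraction: float = 0.65,
    infected_recovery_fraction: float = 0.90,
    photoinhibition_rate: float = 0.5,
    recovery_delay_h: float = 2.0,
    recovery_rate: float = 0.5,
) -> FluorescenceTable:
    """(F0, Fm) pairs realising the target Fv/Fm trajectories.

    LL cultures hold a constant Fv/Fm. HL uninfected cultures decay
    first-order (rate ``photoinhibition_rate`` per hour) towards 65% of the
    LL level. HL infected cultures decay identically for the first 2 h, then
    recover towards 90% of the LL level. Multiplicative lognormal noise
    (sigma ``fvfm_noise_cv``) applies to Fm and to the Fv/Fm target.
    """
    if condition not in ("LL", "HL"):
        raise ValueError(f"unknown condition {condition!r}")
    times = np.asarray(config.sample_times_h, dtype=float)

    def target(t: np.ndarray) -> np.ndarray:
        if condition == "LL":
            return np.full_like(t, fvfm_ll)
        plateau = hl_plateau_fraction * fvfm_ll
        decay = plateau + (fvfm_ll - plateau) * np.exp(-photoinhibition_rate * t)
        if not infected:
            return decay
        y_switch = plateau + (fvfm_ll - plateau) * np.exp(
            -photoinhibition_rate * recovery_delay_h
        )
        recovered = infected_recovery_fraction * fvfm_ll
        rec = recovered + (y_switch - recovered) * np.exp(
            -recovery_rate * np.clip(t - recovery_delay_h, 0.0, None)
        )
        return np.where(t < recovery_delay_h, decay, rec)

    y = target(times)
    rng = _rng_for(config.seed, "fluorescence", condition, "inf" if infected else "uninf")
    sigma = config.fvfm_noise_cv
    rows = []
    for rep in range(1, n_replicates + 1):
        if sigma > 0:
            fm = rng.lognormal(mean=0.0, sigma=sigma, size=times.size)
            y_noisy = np.clip(y * rng.lognormal(-sigma**2 / 2, sigma, size=times.size), 0, 0.95)
        else:
            fm = np.ones(times.size)
            y_noisy = y
        f0 = fm * (1.0 - y_noisy)
        for t, a, b in zip(times, f0, fm):
            rows.append((float(t), condition, rep, infected, float(a), float(b)))
    df = pd.DataFrame(rows, columns=["time_h", "condition", "replicate", "infected", "f0", "fm"])
    return FluorescenceTable(df)
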