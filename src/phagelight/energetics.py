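"""Per-infection ATP cost accounting for phage development.

The central comparison: the energetic cost of replicating the phage genome
(de novo dNTP biosynthesis, both strands of the dsDNA duplex, one genome per
progeny particle) versus the cost of building the structural proteome
(amino-acid biosynthesis plus the ATP/GTP spent by the ribosome per residue
polymerised). Costs scale linearly with burst size and are reported in mol
ATP per infected cell.

Cost tables are data, not code: they ship as editable YAML with a provenance
string, and any table with the right keys can be substituted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .io_formats import CompositionTable, GenomeRecord

__all__ = [
    "AVOGADRO",
    "NucleotideCostTable",
    "AminoAcidCostTable",
    "EnergyBudget",
    "load_nucleotide_costs",
    "load_amino_acid_costs",
    "duplex_composition",
    "dna_replication_cost",
    "proteome_cost",
    "energy_budget",
]

AVOGADRO = 6.02214076e23  # mol^-1

_DNTP_KEYS = ("dATP", "dCTP", "dGTP", "dTTP")
_AA_KEYS = tuple("ACDEFGHIKLMNPQRSTVWY")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class NucleotideCostTable:
    """ATP-equivalents per molecule for each dNTP species."""

    costs: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [k for k in _DNTP_KEYS if k not in self.costs]
        if missing:
            raise ValueError(f"nucleotide cost table missing {missing}")
        for key in _DNTP_KEYS:
            if self.costs[key] < 0:
                raise ValueError(f"negative cost for {key}")

    def __getitem__(self, key: str) -> float:
        return self.costs[key]


@dataclass(frozen=True)
class AminoAcidCostTable:
    """Biosynthesis cost per amino acid plus a per-residue polymerisation cost.

    Polymerisation defaults to 4 ATP-equivalents per residue: aminoacylation
    (ATP -> AMP, charged 2) + EF-Tu GTP + EF-G GTP.
    """

    costs: dict[str, float]
    polymerisation_cost_per_residue: float = 4.0
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [k for k in _AA_KEYS if k not in self.costs]
        if missing:
            raise ValueError(f"amino-acid cost table missing {missing}")
        if any(self.costs[k] < 0 for k in _AA_KEYS):
            raise ValueError("amino-acid costs must be non-negative")
        if self.polymerisation_cost_per_residue <= 0:
            raise ValueError("polymerisation cost must be > 0")

    def __getitem__(self, key: str) -> float:
        return self.costs[key]


def _read_yaml(source: str | Path | None, default_name: str) -> dict:
    if source is None:
        text = (resources.files("phagelight") / "data" / default_name).read_text()
    else:
        text = Path(source).read_text()
    return yaml.safe_load(text)


def load_nucleotide_costs(path: str | Path | None = None) -> NucleotideCostTable:
    """Load a dNTP cost table from YAML (the shipped direct-ATP table by default)."""
    doc = _read_yaml(path, "nucleotide_costs_direct_atp.yaml")
    return NucleotideCostTable(
        costs={k: float(v) for k, v in doc["nucleotide_costs"].items()},
        provenance=str(doc.get("provenance", "")).strip(),
    )


def load_amino_acid_costs(path: str | Path | None = None) -> AminoAcidCostTable:
    """Load an amino-acid cost table from YAML (shipped direct-ATP table by default)."""
    doc = _read_yaml(path, "amino_acid_costs_direct_atp.yaml")
    return AminoAcidCostTable(
        costs={str(k): float(v) for k, v in doc["amino_acid_costs"].items()},
        polymerisation_cost_per_residue=float(doc["polymerisation_cost_per_residue"]),
        provenance=str(doc.get("provenance", "")).strip(),
    )


def duplex_composition(genome: GenomeRecord, skip_ambiguous: bool = False) -> dict[str, int]:
    """Base counts of the double-stranded genome (sequence + reverse complement).

    The total is twice the sequence length; by complementarity A == T and
    C == G. Ambiguity codes (N) are an error unless ``skip_ambiguous``.
    """
    counts = Counter(genome.sequence)
    n_ambig = counts.pop("N", 0)
    if n_ambig and not skip_ambiguous:
        raise ValueError(
            f"genome {genome.id!r} contains {n_ambig} ambiguous base(s); "
            "pass skip_ambiguous=True to drop them"
        )
    duplex = {b: 0 for b in "ACGT"}
    for base, n in counts.items():
        duplex[base] += n
        duplex[_COMPLEMENT[base]] += n
    return duplex


def dna_replication_cost(
    genome: GenomeRecord,
    burst_size: float,
    costs: NucleotideCostTable,
    salvage_fraction: float = 0.0,
    skip_ambiguous: bool = False,
) -> float:
    """Mol ATP per infection to replicate ``burst_size`` duplex genome copies.

    E_dna = burst × (1 − salvage) × Σ_b n_b·c_b / N_A, with n_b the duplex
    base counts. salvage_fraction discounts dNTPs recycled from host DNA
    rather than synthesised de novo (an all-de-novo cost is an upper bound).
    """
    if burst_size <= 0:
        raise ValueError("burst_size must be > 0")
    if not 0.0 <= salvage_fraction <= 1.0:
        raise ValueError("salvage_fraction must be in [0, 1]")
    duplex = duplex_composition(genome, skip_ambiguous=skip_ambiguous)
    per_genome = (
        duplex["A"] * costs["dATP"]
        + duplex["C"] * costs["dCTP"]
        + duplex["G"] * costs["dGTP"]
        + duplex["T"] * costs["dTTP"]
    )
    return burst_size * (1.0 - salvage_fraction) * per_genome / AVOGADRO


def proteome_cost(
    composition: CompositionTable,
    burst_size: float,
    costs: AminoAcidCostTable,
) -> tuple[float, float]:
    """(biosynthesis, polymerisation) mol ATP per infection for the virion proteome.

    Each protein contributes copies_per_virion × its residue costs; the whole
    is scaled by burst size. An amino acid absent from the cost table is an
    error naming the residue.
    """
    if burst_size <= 0:
        raise ValueError("burst_size must be > 0")
    total_biosynth = 0.0
    total_residues = 0
    for _, row in composition.df.iterrows():
        seq = row["aa_sequence"]
        copies = int(row["copies_per_virion"])
        counts = Counter(seq)
        for residue, n in counts.items():
            if residue not in costs.costs:
                raise KeyError(
                    f"residue {residue!r} in protein {row['protein_id']!r} "
                    "has no cost entry"
                )
            total_biosynth += copies * n * costs[residue]
        total_residues += copies * len(seq)
    e_aa = burst_size * total_biosynth / AVOGADRO
    e_poly = burst_size * costs.polymerisation_cost_per_residue * total_residues / AVOGADRO
    return e_aa, e_poly


@dataclass(frozen=True)
class EnergyBudget:
    """Per-infection ATP costs of DNA replication vs. protein production."""

    e_dna: float
    e_aa_biosynthesis: float
    e_polymerisation: float
    e_translation: float
    ratio_translation_to_dna: float
    burst_size: float
    avogadro: float = AVOGADRO


def energy_budget(
    e_dna: float,
    e_aa: float,
    e_poly: float,
    burst_size: float = float("nan"),
) -> EnergyBudget:
    """Assemble an :class:`EnergyBudget` from its three cost components.

    The translation cost is the sum of amino-acid biosynthesis and
    polymerisation; the headline statistic is its ratio to the DNA
    replication cost. A zero DNA cost makes the ratio undefined and is an
    explicit error rather than infinity.
    """
    if min(e_dna, e_aa, e_poly) < 0:
        raise ValueError("energy components must be >= 0")
    if e_dna == 0:
        raise ValueError("e_dna is 0: translation-to-DNA ratio is undefined")
    e_translation = e_aa + e_poly
    return EnergyBudget(
        e_dna=e_dna,
        e_aa_biosynthesis=e_aa,
        e_polymerisation=e_poly,
        e_translation=e_translation,
        ratio_translation_to_dna=e_translation / e_dna,
        burst_size=burst_size,
    )
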