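"""Genome-architecture statistics: intergenic gaps, upstream regions,
inverted repeats and splice isoforms.

All coordinates are 1-based inclusive. Intergenic gaps are strand-agnostic
distances between consecutive features in genome order; the strand-aware
upstream distance of a single gene is a separate statistic
(:func:`upstream_length`), since a long 5' intergenic region is read from
the gene's own orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import FeatureTable

__all__ = [
    "IntergenicGap",
    "InvertedRepeat",
    "IsoformPair",
    "intergenic_gaps",
    "median_intergenic",
    "upstream_length",
    "find_inverted_repeats",
    "splice_isoforms",
    "find_inframe_stops",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = {"TAA", "TAG", "TGA"}  # translation table 11


@dataclass(frozen=True)
class IntergenicGap:
    upstream_feature: str
    downstream_feature: str
    length: int
    overlap: bool = False


@dataclass(frozen=True)
class InvertedRepeat:
    """A hairpin-forming repeat: left arm, loop, reverse-complement right arm."""

    left_arm_start: int  # 1-based
    arm_length: int
    loop_length: int
    mismatches: int

    @property
    def total_paired_length(self) -> int:
        return 2 * self.arm_length

    @property
    def span(self) -> int:
        return 2 * self.arm_length + self.loop_length


@dataclass(frozen=True)
class IsoformPair:
    unspliced: str
    spliced: str
    intron_start: int
    intron_end: int

    @property
    def is_degenerate(self) -> bool:
        return len(self.spliced) == 0


def intergenic_gaps(
    features: FeatureTable, genome_length: int, circular: bool = False
) -> list[IntergenicGap]:
    """Gaps between consecutive features in start order, strand-agnostic.

    gap = next.start - prev.end - 1; overlaps clip to 0 and are flagged.
    For a circular genome the wrap gap (last feature to first) is appended.
    """
    if len(features) == 0:
        raise ValueError("feature table is empty")
    df = features.sorted_by_start()
    if (df["end"] > genome_length).any():
        bad = df[df["end"] > genome_length].iloc[0]
        raise ValueError(
            f"feature {bad['feature_id']!r} (end {bad['end']}) exceeds genome length {genome_length}"
        )
    gaps = []
    for prev, nxt in zip(df.itertuples(), df.iloc[1:].itertuples()):
        raw = nxt.start - prev.end - 1
        gaps.append(
            IntergenicGap(
                upstream_feature=prev.feature_id,
                downstream_feature=nxt.feature_id,
                length=max(raw, 0),
                overlap=raw < 0,
            )
        )
    if circular and len(df) > 1:
        last, first = df.iloc[-1], df.iloc[0]
        raw = (genome_length - last["end"]) + (first["start"] - 1)
        gaps.append(
            IntergenicGap(
                upstream_feature=last["feature_id"],
                downstream_feature=first["feature_id"],
                length=max(int(raw), 0),
                overlap=raw < 0,
            )
        )
    return gaps


def median_intergenic(gaps: list[IntergenicGap]) -> int:
    """Median gap length; for even counts the lower of the two middle values."""
    if not gaps:
        raise ValueError("no gaps")
    lengths = sorted(g.length for g in gaps)
    return lengths[(len(lengths) - 1) // 2]


def upstream_length(
    gene_id: str,
    features: FeatureTable,
    genome_length: int | None = None,
    circular: bool = False,
) -> int:
    """Strand-aware distance from a gene's 5' start back to the nearest feature.

    On the + strand: gene.start - nearest_upstream.end - 1; on the - strand:
    nearest_downstream.start - gene.end - 1. With no flanking feature on a
    linear genome the distance runs to the genome edge (position 1, or
    ``genome_length``, which is then required).
    """
    gene = features.get(gene_id)
    df = features.df[features.df["feature_id"] != gene_id]
    if gene["strand"] == "+":
        prev = df[df["end"] < gene["start"]]
        if not prev.empty:
            return max(int(gene["start"] - prev["end"].max() - 1), 0)
        if circular:
            return max(
                int((genome_length - df["end"].max()) + gene["start"] - 1), 0
            )
        return int(gene["start"] - 1)
    nxt = df[df["start"] > gene["end"]]
    if not nxt.empty:
        return max(int(nxt["start"].min() - gene["end"] - 1), 0)
    if genome_length is None:
        raise ValueError("genome_length required for a last-feature upstream distance")
    if circular:
        return max(int((genome_length - gene["end"]) + df["start"].min() - 1), 0)
    return int(genome_length - gene["end"])


def _pairs(a: str, b: str) -> bool:
    return _COMPLEMENT[a] == b


def find_inverted_repeats(
    seq: str,
    min_arm: int = 6,
    max_loop: int = 1000,
    max_mismatch: int = 0,
) -> list[InvertedRepeat]:
    """All maximal inverted repeats (hairpins) in a sequence.

    A repeat is a left arm, a loop of 0..max_loop bases, and a right arm
    whose reverse complement matches the left arm with at most
    ``max_mismatch`` mismatched pairs. Maximality: the arms can be extended
    neither outward nor inward (shrinking the loop by 2) without violating a
    constraint. For each inner pairing there is exactly one maximal arm, so
    repeats are enumerated by scanning all (innermost-pair, loop) centres
    and extending outward greedily within the mismatch budget.

    Results sort by total paired length descending, then leftmost.
    Quadratic in sequence length: intended for regions (upstream gaps,
    5'-UTRs), not whole genomes.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    n = len(seq)
    out: list[InvertedRepeat] = []
    for p in range(n - 1):  # p: innermost left-arm base (0-based)
        max_q = min(n - 1, p + max_loop + 1)
        for q in range(p + 1, max_q + 1):  # q: innermost right-arm base
            loop_len = q - p - 1
            arm = 0
            mismatches = 0
            while p - arm >= 0 and q + arm < n:
                hit = _pairs(seq[p - arm], seq[q + arm])
                if not hit:
                    if mismatches == max_mismatch:
                        break
                    mismatches += 1
                arm += 1
            if arm < min_arm:
                continue
            # inward extension: the loop-end pair joining the arms
            if loop_len >= 2:
                inward_mm = mismatches + (0 if _pairs(seq[p + 1], seq[q - 1]) else 1)
                if inward_mm <= max_mismatch:
                    continue  # extendable inward: not maximal
            out.append(
                InvertedRepeat(
                    left_arm_start=p - arm + 2,  # to 1-based
                    arm_length=arm,
                    loop_length=loop_len,
                    mismatches=mismatches,
                )
            )
    out.sort(key=lambda r: (-r.total_paired_length, r.left_arm_start, r.loop_length))
    return out


def splice_isoforms(unspliced: str, intron_start: int, intron_end: int) -> IsoformPair:
    """Excise the intron [intron_start, intron_end] (1-based inclusive)."""
    n = len(unspliced)
    if not 1 <= intron_start <= intron_end <= n:
        raise ValueError(
            f"intron coordinates [{intron_start}, {intron_end}] out of range for length {n}"
        )
    spliced = unspliced[: intron_start - 1] + unspliced[intron_end:]
    return IsoformPair(
        unspliced=unspliced,
        spliced=spliced,
        intron_start=intron_start,
        intron_end=intron_end,
    )


def find_inframe_stops(seq: str, frame: int = 0) -> list[int]:
    """1-based start positions of stop codons (TAA/TAG/TGA) read in ``frame``."""
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = seq.upper()
    return [
        i + 1
        for i in range(frame, len(seq) - 2, 3)
        if seq[i : i + 3] in _STOPS
    ]
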