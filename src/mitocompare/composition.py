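"""Nucleotide composition and strand-skew statistics.

Insect mitogenomes are strongly A+T biased and compositionally asymmetric
between strands. The two standard asymmetry statistics are

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed from raw counts on the strand of interest. This module reproduces the
genre's standard composition table: one row per region (whole genome, rRNAs,
tRNAs, A+T-rich region, PCGs) and codon-position sub-blocks for the
protein-coding genes pooled per strand class.

Conventions: ambiguity characters (N) are excluded from both numerator and
denominator; region statistics are computed on sense-strand (reading
direction) sequences, so N-strand genes contribute their reverse complement;
report rounding is 1 decimal for percentages and 2 decimals for skews, with
full precision kept internally.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .errors import (
    DegenerateInputError,
    DomainError,
    EmptyInputError,
    FrameError,
    IncompleteAnnotationError,
)
from .genome_model import FeatureTable, MitoGenome, extract_feature_sequence

REGION_NAMES = ("all_genes", "rRNA_genes", "tRNA_genes", "AT_rich", "PCGs")


def skew(x: float, y: float) -> float:
    """(x - y) / (x + y); by convention 0 when x + y == 0."""
    if x < 0 or y < 0:
        raise DomainError("skew arguments must be non-negative")
    total = x + y
    if total == 0:
        return 0.0
    return (x - y) / total


@dataclass(frozen=True)
class CompositionStats:
    """Composition of one region: percentages, size and skews (full precision)."""

    t_pct: float
    c_pct: float
    a_pct: float
    g_pct: float
    size: int
    at_skew: float
    gc_skew: float

    @property
    def at_pct(self) -> float:
        return self.a_pct + self.t_pct

    def rounded(self) -> dict[str, float]:
        """Report-rounding: percentages to 1 decimal, skews to 2."""
        # + 0.0 normalizes -0.0 to 0.0 in the written reports
        return {
            "t_pct": round(self.t_pct, 1) + 0.0,
            "c_pct": round(self.c_pct, 1) + 0.0,
            "a_pct": round(self.a_pct, 1) + 0.0,
            "g_pct": round(self.g_pct, 1) + 0.0,
            "size": float(self.size),
            "at_pct": round(self.at_pct, 1) + 0.0,
            "at_skew": round(self.at_skew, 2) + 0.0,
            "gc_skew": round(self.gc_skew, 2) + 0.0,
        }


def composition_from_counts(counts: Counter, size: int | None = None) -> CompositionStats:
    """Build stats from raw base counts (N and other ambiguity excluded).

    ``size`` is the reported region size in bp; defaults to the number of
    counted A/C/G/T bases.
    """
    a, c, g, t = (counts.get(b, 0) for b in "ACGT")
    total = a + c + g + t
    if total == 0:
        raise DegenerateInputError("no countable A/C/G/T bases")
    return CompositionStats(
        t_pct=100.0 * t / total,
        c_pct=100.0 * c / total,
        a_pct=100.0 * a / total,
        g_pct=100.0 * g / total,
        size=size if size is not None else total,
        at_skew=skew(a, t),
        gc_skew=skew(g, c),
    )


def base_composition(seq: str) -> CompositionStats:
    if len(seq) == 0:
        raise EmptyInputError("empty sequence")
    counts = Counter(seq.upper())
    if counts.get("N", 0) == len(seq):
        raise DegenerateInputError("sequence is all N")
    return composition_from_counts(counts, size=len(seq))


def region_composition(
    genome: MitoGenome, table: FeatureTable
) -> dict[str, CompositionStats]:
    """One composition row per standard region.

    ``all_genes`` is the whole J-strand genome (its size equals the genome
    length, control region included); gene regions concatenate member
    sense-strand sequences in genomic order.
    """
    members = {
        "rRNA_genes": table.rrnas,
        "tRNA_genes": table.trnas,
        "PCGs": table.pcgs,
    }
    expected = {"rRNA_genes": 2, "tRNA_genes": 22, "PCGs": 13}
    for region, feats in members.items():
        if len(feats) != expected[region]:
            raise IncompleteAnnotationError(
                f"{region}: expected {expected[region]} members, got {len(feats)}"
            )
    if table.control_region is None:
        raise IncompleteAnnotationError("no A+T-rich (control) region annotated")

    out = {"all_genes": base_composition(genome.sequence)}
    for region, feats in members.items():
        concat = "".join(extract_feature_sequence(genome, f) for f in feats)
        out[region] = base_composition(concat)
    out["AT_rich"] = base_composition(
        extract_feature_sequence(genome, table.control_region)
    )
    return out


def codon_position_composition(
    genome: MitoGenome, table: FeatureTable, strand_class: str = "all"
) -> dict[str | int, CompositionStats]:
    """Composition pooled per codon position over PCGs of a strand class.

    The reading frame starts at each gene's initiation codon; trailing
    incomplete-stop bases are pooled at their frame positions, which is why
    the three position sizes can differ by a base or two. Keys are 1, 2, 3
    and ``"total"``.
    """
    if strand_class not in ("all", "J", "N"):
        raise DomainError(f"unknown strand class {strand_class!r}")
    pcgs = [
        f for f in table.pcgs if strand_class == "all" or f.strand == strand_class
    ]
    if not pcgs:
        raise IncompleteAnnotationError(f"no PCGs on strand class {strand_class!r}")
    position_counts: dict[int, Counter] = {1: Counter(), 2: Counter(), 3: Counter()}
    for f in pcgs:
        cds = extract_feature_sequence(genome, f)
        if len(cds) < 3:
            raise FrameError(f"{f.name}: CDS shorter than one codon")
        for i, base in enumerate(cds):
            position_counts[i % 3 + 1][base] += 1
    out: dict[str | int, CompositionStats] = {}
    total = Counter()
    for pos in (1, 2, 3):
        counts = position_counts[pos]
        out[pos] = composition_from_counts(counts, size=sum(counts.values()))
        total += counts
    out["total"] = composition_from_counts(total, size=sum(total.values()))
    return out


def composition_report_frame(
    genome: MitoGenome, table: FeatureTable
) -> pd.DataFrame:
    """Full composition report (regions + codon-position blocks), rounded."""
    rows = []
    for region, stats in region_composition(genome, table).items():
        rows.append({"block": "regions", "row": region, **stats.rounded()})
    for label, strand_class in (
        ("all_codons", "all"),
        ("J_strand_PCGs", "J"),
        ("N_strand_PCGs", "N"),
    ):
        for pos, stats in codon_position_composition(genome, table, strand_class).items():
            rows.append({"block": label, "row": str(pos), **stats.rounded()})
    return pd.DataFrame(rows)
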