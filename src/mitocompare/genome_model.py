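"""Data model and I/O for annotated circular mitochondrial genomes.

An insect mitogenome is a circular molecule of ~15-18 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and one non-coding A+T-rich
(control) region. Genes sit on either the major (J) or minor (N) strand; the
deposited sequence is taken as the J strand. Coordinates are 1-based inclusive
throughout, so a feature spanning 1-68 is 68 bp long.

This module provides the containers (:class:`MitoGenome`, :class:`GeneFeature`,
:class:`FeatureTable`) and the accounting operations over them: GenBank and
feature-table input, sense-strand sequence extraction, intergenic-spacer
computation (negative values are overlaps), and per-category/strand gene
tallies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from . import genetics
from .errors import (
    AlphabetError,
    CoordinateError,
    DuplicateFeatureError,
    EmptyTableError,
    OrderingError,
    ParseError,
)

CATEGORIES = ("PCG", "tRNA", "rRNA", "control")
STRANDS = ("J", "N")

TABLE_COLUMNS = (
    "name",
    "category",
    "strand",
    "start",
    "end",
    "anticodon",
    "initiation_codon",
    "termination_codon",
)


@dataclass(frozen=True)
class MitoGenome:
    """One circular annotated mitochondrial genome (J-strand sequence)."""

    identifier: str
    species: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise AlphabetError("genome sequence is empty")
        bad = set(self.sequence.upper()) - genetics.VALID_BASES
        if bad:
            raise AlphabetError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated gene (or the control region) on the genome.

    ``start``/``end`` are 1-based inclusive on the J strand. A wrapping
    feature across the origin has start > end; none occur in the shipped
    fixtures but the model accepts them.
    """

    name: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: Optional[str] = None
    initiation_codon: Optional[str] = None
    termination_codon: Optional[str] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise CoordinateError(f"{self.name}: unknown category {self.category!r}")
        if self.strand not in STRANDS:
            raise CoordinateError(f"{self.name}: strand must be J or N")
        if self.start < 1:
            raise CoordinateError(f"{self.name}: start {self.start} < 1")
        if self.category == "tRNA" and not self.anticodon:
            raise CoordinateError(f"{self.name}: tRNA feature lacks an anticodon")
        if self.category == "PCG" and not (
            self.initiation_codon and self.termination_codon
        ):
            raise CoordinateError(f"{self.name}: PCG lacks start/stop codon annotation")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: Optional[int] = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError(
                f"{self.name}: wrapping feature needs genome_length for its size"
            )
        return genome_length - self.start + 1 + self.end


@dataclass(frozen=True)
class SpacerRecord:
    """Intergenic gap between two consecutive features; negative = overlap."""

    upstream_gene: str
    downstream_gene: str
    spacer_length: int


@dataclass
class FeatureTable:
    """Ordered gene annotation for one genome (genomic order)."""

    features: list[GeneFeature]
    genome_length: int

    def __post_init__(self):
        for f in self.features:
            if not f.wraps and f.end > self.genome_length:
                raise CoordinateError(
                    f"{f.name}: end {f.end} beyond genome length {self.genome_length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.by_category("PCG")

    @property
    def trnas(self) -> list[GeneFeature]:
        return self.by_category("tRNA")

    @property
    def rrnas(self) -> list[GeneFeature]:
        return self.by_category("rRNA")

    @property
    def control_region(self) -> Optional[GeneFeature]:
        ctrl = self.by_category("control")
        return ctrl[0] if ctrl else None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GENBANK_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path) -> tuple[MitoGenome, FeatureTable]:
    """Read a single-record GenBank flat file into the package's model.

    CDS/tRNA/rRNA features become :class:`GeneFeature` entries; a
    misc_feature/D-loop named as control region is used when present,
    otherwise the span from the end of the small rRNA to the genome end is
    taken as the A+T-rich region (the canonical position in this gene order).
    """
    path = Path(path)
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not a single-record GenBank file ({exc})") from exc
    sequence = str(record.seq).upper()
    if not sequence or set(sequence) == {"N"}:
        raise ParseError(f"{path}: record has no usable sequence")
    genome = MitoGenome(
        identifier=record.id, species=record.annotations.get("organism", record.id),
        sequence=sequence,
    )

    features: list[GeneFeature] = []
    control: Optional[GeneFeature] = None
    for feat in record.features:
        if feat.type in _GENBANK_CATEGORY:
            category = _GENBANK_CATEGORY[feat.type]
            name = _feature_name(feat)
            start = int(feat.location.start) + 1  # Biopython is 0-based
            end = int(feat.location.end)
            if end > genome.length or start < 1:
                raise CoordinateError(
                    f"{name}: feature {start}-{end} outside 1-{genome.length}"
                )
            strand = "J" if (feat.location.strand or 1) >= 0 else "N"
            anticodon = None
            init_codon = term_codon = None
            if category == "tRNA":
                anticodon = _anticodon_of(feat) or "NNN"
            if category == "PCG":
                span = sequence[start - 1 : end]
                if strand == "N":
                    span = genetics.reverse_complement(span)
                init_codon = span[:3]
                rem = len(span) % 3
                term_codon = span[-rem:] if rem else span[-3:]
            features.append(
                GeneFeature(name, category, strand, start, end, anticodon,
                            init_codon, term_codon)
            )
        elif feat.type in ("misc_feature", "D-loop"):
            note = " ".join(feat.qualifiers.get("note", [])).lower()
            if "a+t" in note or "control" in note or feat.type == "D-loop":
                control = GeneFeature(
                    "AT_rich", "control", "J",
                    int(feat.location.start) + 1, int(feat.location.end),
                )
    if not features:
        raise ParseError(f"{path}: no gene features found")
    features.sort(key=lambda f: f.start)
    if control is None:
        rrnas = [f for f in features if f.category == "rRNA"]
        if rrnas:
            last_rrna_end = max(f.end for f in rrnas)
            if last_rrna_end < genome.length:
                control = GeneFeature("AT_rich", "control", "J",
                                      last_rrna_end + 1, genome.length)
    if control is not None:
        features.append(control)
        features.sort(key=lambda f: f.start)
    return genome, FeatureTable(features=features, genome_length=genome.length)


def _feature_name(feat) -> str:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return feat.type


def _anticodon_of(feat) -> Optional[str]:
    if "anticodon" in feat.qualifiers:
        text = feat.qualifiers["anticodon"][0]
        # formats like "(pos:..,aa:Ile,seq:gat)" or a bare triplet
        if "seq:" in text:
            return text.split("seq:")[1].strip("() ").upper()[:3]
        if len(text.strip()) == 3:
            return text.strip().upper()
    if "note" in feat.qualifiers:
        note = feat.qualifiers["note"][0]
        if len(note) == 3 and set(note.upper()) <= set("ACGTU"):
            return note.upper().replace("U", "T")
    return None


def read_feature_table(path, sequence: Optional[str] = None):
    """Read the package's tab-separated annotation dialect.

    Columns: name, category, strand, start, end, anticodon, initiation_codon,
    termination_codon (optional fields may be empty). Returns a
    :class:`FeatureTable`; with ``sequence`` given, returns
    ``(MitoGenome, FeatureTable)``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = set(TABLE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    if len(df) == 0:
        raise EmptyTableError(f"{path}: header only, no feature rows")
    features = _rows_to_features(df, str(path))
    genome_length = len(sequence) if sequence is not None else max(
        f.end for f in features
    )
    table = FeatureTable(features=features, genome_length=genome_length)
    if sequence is not None:
        genome = MitoGenome(identifier=path.stem, species=path.stem,
                            sequence=sequence)
        return genome, table
    return table


def _rows_to_features(df: pd.DataFrame, source: str) -> list[GeneFeature]:
    features = []
    for _, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError as exc:
            raise ParseError(f"{source}: non-integer coordinates in row "
                             f"{row['name']!r}") from exc
        if end < start:
            raise CoordinateError(f"{source}: {row['name']} has end < start")
        features.append(
            GeneFeature(
                name=row["name"], category=row["category"], strand=row["strand"],
                start=start, end=end,
                anticodon=row.get("anticodon", "") or None,
                initiation_codon=row.get("initiation_codon", "") or None,
                termination_codon=row.get("termination_codon", "") or None,
            )
        )
    _check_duplicates(features, source)
    return features


def _check_duplicates(features: Iterable[GeneFeature], source: str) -> None:
    seen: dict[str, GeneFeature] = {}
    for f in features:
        if f.name in seen:
            other = seen[f.name]
            if f.start <= other.end and other.start <= f.end:
                raise DuplicateFeatureError(
                    f"{source}: overlapping duplicate feature {f.name!r}"
                )
        seen[f.name] = f


def write_feature_table(table: FeatureTable, path) -> None:
    rows = [
        {
            "name": f.name, "category": f.category, "strand": f.strand,
            "start": f.start, "end": f.end,
            "anticodon": f.anticodon or "",
            "initiation_codon": f.initiation_codon or "",
            "termination_codon": f.termination_codon or "",
        }
        for f in table
    ]
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Accounting operations
# ---------------------------------------------------------------------------

def extract_feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Sense-strand (reading-direction) sequence of a feature.

    J-strand features are the plain slice; N-strand features are the reverse
    complement, so the result always reads 5'->3' in the gene's own direction.
    """
    seq = genome.sequence
    if feature.wraps:
        span = seq[feature.start - 1 :] + seq[: feature.end]
    else:
        if feature.end > genome.length:
            raise CoordinateError(
                f"{feature.name}: end {feature.end} beyond genome length"
            )
        span = seq[feature.start - 1 : feature.end]
    bad = set(span) - genetics.VALID_BASES
    if bad:
        raise AlphabetError(f"{feature.name}: non-ACGTN characters {sorted(bad)}")
    return genetics.reverse_complement(span) if feature.strand == "N" else span


def compute_spacers(table: FeatureTable) -> list[SpacerRecord]:
    """Intergenic spacers between consecutive features, circular wrap included.

    The value attached to a pair is ``next.start - previous.end - 1``;
    negative values are gene overlaps. The final record closes the circle
    from the last feature back to the first.
    """
    feats = table.features
    if len(feats) < 2:
        return []
    starts = [f.start for f in feats]
    if starts != sorted(starts):
        raise OrderingError("feature table is not in genomic order")
    records = []
    for up, down in zip(feats, feats[1:]):
        records.append(SpacerRecord(up.name, down.name, down.start - up.end - 1))
    wrap = feats[0].start + table.genome_length - feats[-1].end - 1
    records.append(SpacerRecord(feats[-1].name, feats[0].name, wrap))
    return records


def summarize_gene_counts(table: FeatureTable) -> dict[str, dict[str, int]]:
    """Tallies per category x strand, e.g. ``counts['PCG']['J'] == 9``."""
    counts = {cat: {s: 0 for s in STRANDS} for cat in CATEGORIES}
    for f in table:
        counts[f.category][f.strand] += 1
    return counts


def annotation_report_frame(genome_or_none, table: FeatureTable) -> pd.DataFrame:
    """Per-gene accounting frame (sizes, spacers, codons) in table layout."""
    spacers = compute_spacers(table)
    gap_after = {s.upstream_gene: s.spacer_length for s in spacers}
    rows = []
    for f in table:
        rows.append(
            {
                "name": f.name, "category": f.category, "strand": f.strand,
                "start": f.start, "end": f.end,
                "size": f.length(table.genome_length),
                "intergenic_length": gap_after.get(f.name, 0),
                "anticodon": f.anticodon or "",
                "initiation_codon": f.initiation_codon or "",
                "termination_codon": f.termination_codon or "",
            }
        )
    return pd.DataFrame(rows)
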