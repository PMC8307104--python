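"""Codon extraction, codon counting, RSCU, and start/stop codon surveys.

Relative synonymous codon usage of a sense codon c with count n_c in a
synonymous family of size k and family total n is

    RSCU(c) = n_c * k / n

i.e. the observed count over the count expected were all synonymous codons
used equally; RSCU sums to k within each used family. Mitochondrial CDSs
often end in incomplete stop codons ("T" or "TA", completed by
polyadenylation); those trailing bases are carried as a remainder and never
enter codon counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from . import genetics
from .errors import IncompleteAnnotationError, TooShortError
from .genome_model import FeatureTable, MitoGenome, extract_feature_sequence

logger = logging.getLogger(__name__)


def extract_codons(cds: str) -> tuple[list[str], str]:
    """Split a reading-direction CDS into triplets plus the 0-2 base remainder."""
    cds = cds.upper()
    if len(cds) < 6:
        raise TooShortError(f"CDS of {len(cds)} bp is too short to be a gene")
    n_codons = len(cds) // 3
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    remainder = cds[3 * n_codons :]
    return codons, remainder


@dataclass
class CodonCountTable:
    """Pooled sense-codon counts; complete stop codons tallied separately."""

    counts: Counter = field(default_factory=Counter)
    stop_counts: Counter = field(default_factory=Counter)
    code_id: int = genetics.INVERTEBRATE_MITO_TABLE_ID

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add_cds(self, cds: str, gene: str = "?") -> None:
        codons, _ = extract_codons(cds)
        for codon in codons:
            if set(codon) - set("ACGT"):
                logger.warning("%s: skipping ambiguous codon %r", gene, codon)
                continue
            if genetics.is_stop(codon):
                self.stop_counts[codon] += 1
            else:
                self.counts[codon] += 1


def count_codons(
    genome_tables: Iterable[tuple[MitoGenome, FeatureTable]]
) -> CodonCountTable:
    """Pool sense codons over all 13 PCGs of each genome."""
    table_out = CodonCountTable()
    for genome, table in genome_tables:
        pcgs = table.pcgs
        if len(pcgs) != 13:
            raise IncompleteAnnotationError(
                f"{genome.identifier}: expected 13 PCGs, found {len(pcgs)}"
            )
        for f in pcgs:
            table_out.add_cds(extract_feature_sequence(genome, f), gene=f.name)
    return table_out


@dataclass
class RSCUTable:
    rscu: dict[str, float]
    family_sizes: dict[str, int]
    counts: Counter

    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "amino_acid": genetics.CODON_TO_AA[c],
                "codon": c,
                "count": self.counts.get(c, 0),
                "rscu": round(self.rscu[c], 2),
            }
            for c in genetics.SENSE_CODONS
        ]
        return pd.DataFrame(rows).sort_values(
            ["amino_acid", "codon"], kind="stable"
        ).reset_index(drop=True)


def rscu(count_table: CodonCountTable) -> RSCUTable:
    """RSCU per sense codon; families with zero usage score 0 throughout."""
    values: dict[str, float] = {}
    for aa, family in genetics.AA_FAMILIES.items():
        k = len(family)
        family_total = sum(count_table.counts.get(c, 0) for c in family)
        for c in family:
            values[c] = (
                count_table.counts.get(c, 0) * k / family_total
                if family_total
                else 0.0
            )
    return RSCUTable(
        rscu=values, family_sizes=dict(genetics.FAMILY_SIZES),
        counts=Counter(count_table.counts),
    )


@dataclass
class StartStopSurvey:
    initiation_codons: dict[str, str]
    termination_codons: dict[str, str]
    modal_initiation: str
    modal_termination: str


def survey_start_stop(table: FeatureTable) -> StartStopSurvey:
    """Tally annotated start/stop codons over the PCGs of one genome.

    Incomplete stops are reported verbatim ("T", "TA"). Modal codons break
    ties alphabetically for determinism.
    """
    inits, terms = {}, {}
    for f in table.pcgs:
        if not f.initiation_codon or not f.termination_codon:
            raise IncompleteAnnotationError(f"{f.name}: missing codon annotation")
        inits[f.name] = f.initiation_codon
        terms[f.name] = f.termination_codon
    if not inits:
        raise IncompleteAnnotationError("table contains no PCGs")
    return StartStopSurvey(
        initiation_codons=inits,
        termination_codons=terms,
        modal_initiation=_modal(inits.values()),
        modal_termination=_modal(terms.values()),
    )


def _modal(values) -> str:
    counts = Counter(values)
    # highest count; alphabetical on ties for determinism
    return min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
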