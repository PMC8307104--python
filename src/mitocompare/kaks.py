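"""Nei-Gojobori (1986) Ka/Ks estimation under the invertebrate mito code.

The NG86 counting method splits each codon's three positions into fractional
synonymous (S) and nonsynonymous (N) *sites* from the effect of the nine
single-base mutants, splits observed codon differences into synonymous and
nonsynonymous *differences* by averaging over all mutational pathways, forms
the proportions pS = Sd / S-bar and pN = Nd / N-bar, and corrects each for
multiple hits with the Jukes-Cantor formula

    d = -3/4 * ln(1 - 4p/3).

Ka/Ks < 1 indicates purifying selection. Conventions in this implementation
(variants of NG86 differ here): mutations that create a stop codon are
excluded and the position's site weights renormalized over the remaining
mutants, so S + N = 3 holds exactly for every sense codon; pathways through
stop codons are dropped from the averaging (if every pathway passes through a
stop, all pathways are used and the result flagged); gapped or ambiguous
codons are deleted pairwise; incomplete-stop remainders are trimmed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional

from . import genetics
from .errors import DomainError, InsufficientDataError, SaturationError

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous/nonsynonymous site counts for one codon."""

    S: float
    N: float


@lru_cache(maxsize=None)
def count_sites(codon: str) -> SiteCounts:
    """NG86 site counts for a sense codon; S + N = 3 by construction."""
    codon = codon.upper()
    if genetics.is_stop(codon):
        raise DomainError(f"{codon} is a stop codon")
    if set(codon) - set(_BASES):
        raise DomainError(f"{codon}: ambiguous codon, skip it pairwise")
    s = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if genetics.is_stop(mutant):
                continue
            viable += 1
            if genetics.is_synonymous(codon, mutant):
                syn += 1
        if viable:
            s += syn / viable
        # a position with no viable mutant (cannot occur under table 5)
        # would count as fully nonsynonymous
    return SiteCounts(S=s, N=3.0 - s)


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are discarded before averaging. sd + nd
    equals the number of differing positions.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    if genetics.is_stop(codon_a) or genetics.is_stop(codon_b):
        raise DomainError("stop codons have no NG86 difference decomposition")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return (0.0, 0.0)
    pathways = []
    stop_free = []
    for order in itertools.permutations(diff_positions):
        current = codon_a
        sd = nd = 0
        passes_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if genetics.is_stop(nxt):
                # a step into a stop counts as nonsynonymous in the
                # all-pathways fallback
                passes_stop = True
                nd += 1
            elif genetics.translate_codon(current) == genetics.translate_codon(nxt) \
                    and not genetics.is_stop(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        pathways.append((sd, nd))
        if not passes_stop:
            stop_free.append((sd, nd))
    used = stop_free if stop_free else pathways
    if not stop_free:
        logger.warning(
            "all pathways %s -> %s pass through stops; averaging over all",
            codon_a, codon_b,
        )
    sd = sum(p[0] for p in used) / len(used)
    nd = sum(p[1] for p in used) / len(used)
    return (sd, nd)


def jukes_cantor(p: float) -> float:
    """JC69 distance for a raw proportion p; undefined at p >= 3/4."""
    if p < 0:
        raise DomainError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: distance undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    """NG86 summary for one sequence pair."""

    S: float          # mean synonymous sites over the pair
    N: float          # mean nonsynonymous sites
    Sd: float         # synonymous differences (pathway-averaged)
    Nd: float         # nonsynonymous differences
    pS: float
    pN: float
    Ks: float
    Ka: float
    n_codons: int     # codon pairs actually compared

    @property
    def ratio(self) -> Optional[float]:
        """Ka/Ks; None when Ks = 0 (undefined)."""
        if self.Ks == 0.0:
            return None
        return self.Ka / self.Ks


def _clean_codon_pairs(a: str, b: str):
    """Codon pairs after remainder trimming and pairwise deletion."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise DomainError("sequences must be equal length (pre-aligned)")
    usable = len(a) - len(a) % 3
    for i in range(0, usable, 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca) - set(_BASES) or set(cb) - set(_BASES):
            continue  # gap or ambiguity: pairwise codon deletion
        if genetics.is_stop(ca) or genetics.is_stop(cb):
            continue  # terminal (or stray) stop codons are not NG86 material
        yield ca, cb


def pairwise_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks between two equal-length, reading-frame-aligned CDSs."""
    S_a = S_b = Sd = Nd = 0.0
    n = 0
    for ca, cb in _clean_codon_pairs(cds_a, cds_b):
        n += 1
        S_a += count_sites(ca).S
        S_b += count_sites(cb).S
        sd, nd = count_differences(ca, cb)
        Sd += sd
        Nd += nd
    if n == 0:
        raise InsufficientDataError("no comparable codons between the sequences")
    S_bar = (S_a + S_b) / 2.0
    N_bar = 3.0 * n - S_bar
    pS = Sd / S_bar if S_bar else 0.0
    pN = Nd / N_bar if N_bar else 0.0
    return KaKsResult(
        S=S_bar, N=N_bar, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        Ks=jukes_cantor(pS), Ka=jukes_cantor(pN), n_codons=n,
    )


@dataclass(frozen=True)
class GeneKaKsSummary:
    gene: str
    mean_ka: float
    mean_ks: float
    mean_ratio: Optional[float]
    n_pairs: int


def gene_mean_kaks(
    gene: str,
    sequences: Mapping[str, str],
    ratio_of_means: bool = False,
) -> GeneKaKsSummary:
    """Mean Ka, Ks and Ka/Ks for one gene over all taxon pairs.

    ``sequences`` maps taxon name -> reading-direction CDS (equal lengths or
    pre-aligned). The default aggregation is the unweighted mean of pairwise
    ratios over pairs where the ratio is defined; ``ratio_of_means=True``
    reports mean(Ka)/mean(Ks) instead.
    """
    taxa = sorted(sequences)
    if len(taxa) < 2:
        raise InsufficientDataError(f"{gene}: need at least two taxa")
    kas, kss, ratios = [], [], []
    n_pairs = 0
    for t1, t2 in itertools.combinations(taxa, 2):
        result = pairwise_kaks(sequences[t1], sequences[t2])
        n_pairs += 1
        kas.append(result.Ka)
        kss.append(result.Ks)
        if result.ratio is not None:
            ratios.append(result.ratio)
    mean_ka = sum(kas) / n_pairs
    mean_ks = sum(kss) / n_pairs
    if ratio_of_means:
        mean_ratio = mean_ka / mean_ks if mean_ks else None
    else:
        mean_ratio = sum(ratios) / len(ratios) if ratios else None
    return GeneKaKsSummary(
        gene=gene, mean_ka=mean_ka, mean_ks=mean_ks,
        mean_ratio=mean_ratio, n_pairs=n_pairs,
    )


def rank_genes(summaries: Iterable[GeneKaKsSummary]) -> list[GeneKaKsSummary]:
    """Genes sorted by mean Ka/Ks, highest first (undefined ratios last)."""
    return sorted(
        summaries,
        key=lambda s: (s.mean_ratio is None, -(s.mean_ratio or 0.0), s.gene),
    )
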