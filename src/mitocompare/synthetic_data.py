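"""Seeded generator of mitogenome-like inputs, plus the packaged fixtures.

Two kinds of data come from this module:

* the study fixtures: fully expanded annotation tables for the five
  grasshopper mitogenomes (one TSV per species, shipped as package data), and
  the published per-region composition table; and

* synthetic genomes with the statistical structure the analysis assumes - a
  circular genome with the canonical 37-gene order, strand assignment and
  per-gene lengths of the reference fixture, strong per-region A+T bias,
  valid open reading frames with the fixture's start/stop codons (incomplete
  stops included), foldable template-consistent tRNAs, and clade-structured
  divergence with a tunable per-gene dN/dS (omega).

The omega control in :func:`evolve_clade` is deliberately simple: proposed
nonsynonymous changes are accepted with probability omega, synonymous ones
always, and stop-creating ones never. That is not a proper codon
substitution model, but it gives monotone control of dN/dS, which is all the
recovery tests require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Union

import dendropy
import numpy as np
import pandas as pd

from . import genetics
from .errors import ConfigError, GenerationError, NameError_
from .genome_model import (
    FeatureTable,
    GeneFeature,
    MitoGenome,
    compute_spacers,
    extract_feature_sequence,
    read_feature_table,
)
from .trna_structure import TrnaDesign, design_trna

FIXTURE_SPECIES = (
    "F_sunanensis",
    "F_amplivertica",
    "F_nigritibia",
    "F_pamphagoides",
    "F_dingxiensis",
)

_DATA = resources.files("mitocompare") / "data"


def emit_fixture(name: str) -> FeatureTable:
    """The fully expanded annotation table for one fixture species."""
    if name not in FIXTURE_SPECIES:
        raise NameError_(
            f"unknown fixture {name!r}; choose from {FIXTURE_SPECIES}"
        )
    with resources.as_file(_DATA / f"annotations_{name}.tsv") as path:
        return read_feature_table(path)


def reference_composition() -> pd.DataFrame:
    """The published per-region composition table for the five species."""
    with resources.as_file(_DATA / "region_composition.tsv") as path:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

def default_clade_tree(
    n_ingroup: int = 12,
    n_outgroup: int = 4,
    branch: float = 0.05,
    stem: float = 0.08,
) -> str:
    """Newick for an ingroup ladder plus an outgroup ladder, as one clade pair."""

    def ladder(names):
        tree = f"({names[0]}:{branch},{names[1]}:{branch})"
        for name in names[2:]:
            tree = f"({tree}:{branch},{name}:{branch})"
        return tree

    ingroup = [f"I{i:02d}" for i in range(1, n_ingroup + 1)]
    outgroup = [f"O{i:02d}" for i in range(1, n_outgroup + 1)]
    left = ladder(ingroup) if n_ingroup > 1 else f"{ingroup[0]}:{branch}"
    right = ladder(outgroup) if n_outgroup > 1 else f"{outgroup[0]}:{branch}"
    return f"({left}:{stem},{right}:{stem});"


DEFAULT_AT_FRACTIONS = {
    "PCG": 0.72,
    "tRNA": 0.70,
    "rRNA": 0.73,
    "control": 0.83,
    "spacer": 0.75,
}


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic clade."""

    seed: int = 0
    template: str = "F_sunanensis"
    at_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AT_FRACTIONS)
    )
    tree: str = field(default_factory=default_clade_tree)
    omega: Union[float, dict[str, float]] = 0.2

    def __post_init__(self):
        for region, frac in self.at_fractions.items():
            if not 0.0 < frac < 1.0:
                raise ConfigError(f"at_fraction[{region}]={frac} not in (0,1)")
        for w in (
            self.omega.values() if isinstance(self.omega, dict) else [self.omega]
        ):
            if w <= 0:
                raise ConfigError("omega must be > 0")

    def omega_for(self, gene: str) -> float:
        if isinstance(self.omega, dict):
            return self.omega[gene]
        return self.omega

    def truth_lines(self) -> list[str]:
        lines = [f"seed={self.seed}", f"template={self.template}"]
        lines += [f"at_fraction.{k}={v}" for k, v in sorted(self.at_fractions.items())]
        if isinstance(self.omega, dict):
            lines += [f"omega.{k}={v}" for k, v in sorted(self.omega.items())]
        else:
            lines.append(f"omega={self.omega}")
        lines.append(f"tree={self.tree}")
        return lines


# ---------------------------------------------------------------------------
# Reference genome generation
# ---------------------------------------------------------------------------

def _declutter_template(table: FeatureTable) -> FeatureTable:
    """Rebuild coordinates with overlaps (negative spacers) clipped to zero.

    Gene order, strands and lengths are preserved; overlapping genes in the
    real annotation would otherwise have to share generated sequence, which
    cannot satisfy two reading frames at once. Genome length grows by the
    total clipped overlap (a few tens of bp).
    """
    spacers = compute_spacers(table)[:-1]  # drop the circular wrap record
    feats = table.features
    new_feats = []
    pos = feats[0].start
    for i, f in enumerate(feats):
        length = f.length(table.genome_length)
        new_feats.append(replace(f, start=pos, end=pos + length - 1))
        if i < len(spacers):
            pos = pos + length + max(spacers[i].spacer_length, 0)
    wrap = compute_spacers(table)[-1].spacer_length
    genome_length = new_feats[-1].end + max(wrap, 0)
    return FeatureTable(features=new_feats, genome_length=genome_length)


def _codon_weights(at_fraction: float) -> np.ndarray:
    p = {b: at_fraction / 2 if b in "AT" else (1 - at_fraction) / 2 for b in "ACGT"}
    w = np.array(
        [p[c[0]] * p[c[1]] * p[c[2]] for c in genetics.SENSE_CODONS]
    )
    return w / w.sum()


def _random_bases(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    if n <= 0:
        return ""
    p_at, p_gc = at_fraction / 2, (1 - at_fraction) / 2
    return "".join(rng.choice(list("ATGC"), size=n, p=[p_at, p_at, p_gc, p_gc]))


def _generate_pcg(rng, feature: GeneFeature, length: int, at_fraction: float) -> str:
    init = feature.initiation_codon
    term = feature.termination_codon
    if len(init) != 3:
        raise GenerationError(f"{feature.name}: initiation codon {init!r}")
    remainder = length % 3
    if len(term) % 3 != remainder % 3 and not (len(term) == 3 and remainder == 0):
        raise GenerationError(
            f"{feature.name}: stop {term!r} incompatible with length {length}"
        )
    n_codons = length // 3
    n_middle = n_codons - 1 - (1 if len(term) == 3 else 0)
    if n_middle < 0:
        raise GenerationError(f"{feature.name}: length {length} too short")
    weights = _codon_weights(at_fraction)
    middle = rng.choice(len(genetics.SENSE_CODONS), size=n_middle, p=weights)
    body = "".join(genetics.SENSE_CODONS[i] for i in middle)
    return init + body + (term if len(term) == 3 else term)


def _trna_design_for(feature: GeneFeature, length: int) -> TrnaDesign:
    """Pick canonical-leaning element lengths that hit the target length."""
    dhu = 0 if "AGN" in feature.name else 4
    base = TrnaDesign(dhu_stem=dhu, dhu_loop=0, variable_loop=0, t_loop=0)
    fixed = base.total_length  # everything except the three loops
    budget = length - fixed
    loop_lo, loop_hi = (2, 12) if dhu == 0 else (3, 11)
    best = None
    for dloop in range(loop_lo, loop_hi + 1):
        for v in range(3, 10):
            tl = budget - dloop - v
            if not 3 <= tl <= 9:
                continue
            penalty = abs(dloop - 7) + abs(v - 4.5) + abs(tl - 7)
            key = (penalty, dloop, v)
            if best is None or key < best[0]:
                best = (key, dloop, v, tl)
    if best is None:
        raise GenerationError(
            f"{feature.name}: no template decomposition at {length} nt"
        )
    _, dloop, v, tl = best
    return replace(base, dhu_loop=dloop, variable_loop=v, t_loop=tl)


def make_reference_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[MitoGenome, FeatureTable]:
    """Generate a synthetic circular genome on the fixture's gene plan."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    template = _declutter_template(emit_fixture(config.template))
    at = config.at_fractions
    chunks: list[str] = []
    pos = 1
    for f in template:
        if f.start > pos:
            chunks.append(_random_bases(rng, f.start - pos, at["spacer"]))
            pos = f.start
        length = f.length(template.genome_length)
        if f.category == "PCG":
            sense = _generate_pcg(rng, f, length, at["PCG"])
        elif f.category == "tRNA":
            sense = design_trna(rng, f.anticodon, _trna_design_for(f, length))
        elif f.category == "rRNA":
            sense = _random_bases(rng, length, at["rRNA"])
        else:
            sense = _random_bases(rng, length, at["control"])
        if len(sense) != length:
            raise GenerationError(f"{f.name}: generated {len(sense)} != {length}")
        chunks.append(
            genetics.reverse_complement(sense) if f.strand == "N" else sense
        )
        pos = f.end + 1
    if pos <= template.genome_length:
        chunks.append(
            _random_bases(rng, template.genome_length - pos + 1, at["spacer"])
        )
    sequence = "".join(chunks)
    genome = MitoGenome(
        identifier=f"synthetic_{config.template}",
        species=f"synthetic_{config.template}",
        sequence=sequence,
    )
    return genome, template


# ---------------------------------------------------------------------------
# Clade evolution
# ---------------------------------------------------------------------------

@dataclass
class SimulatedClade:
    genomes: dict[str, tuple[MitoGenome, FeatureTable]]
    config: SimulationConfig

    @property
    def taxa(self) -> list[str]:
        return list(self.genomes)

    def gene_sequences(self, gene: str) -> dict[str, str]:
        """Sense-strand sequences of one gene across all taxa."""
        return {
            taxon: extract_feature_sequence(genome, table.get(gene))
            for taxon, (genome, table) in self.genomes.items()
        }


def _mutate_neutral(
    seq: list[str], rate: float, rng, protected: frozenset[int] = frozenset()
) -> None:
    L = len(seq)
    if L == 0 or rate <= 0:
        return
    n = rng.binomial(L, min(rate, 1.0))
    if n == 0:
        return
    positions = rng.choice(L, size=n, replace=False)
    for pos in positions:
        if pos in protected:
            continue
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(3)]


def _mutate_pcg(seq: list[str], rate: float, omega: float, rng) -> None:
    """Propose per-site substitutions; filter by synonymy and omega.

    The first codon (initiation) and the terminal stop (complete or
    incomplete remainder) never change, keeping annotations valid.
    """
    L = len(seq)
    remainder = L % 3
    tail = remainder if remainder else 3
    lo, hi = 3, L - tail  # mutable span
    if hi <= lo or rate <= 0:
        return
    span = hi - lo
    n = rng.binomial(span, min(rate, 1.0))
    if n == 0:
        return
    positions = lo + rng.choice(span, size=n, replace=False)
    for pos in positions:
        codon_start = (pos // 3) * 3
        codon = "".join(seq[codon_start : codon_start + 3])
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        new_base = alternatives[rng.integers(3)]
        offset = pos - codon_start
        mutant = codon[:offset] + new_base + codon[offset + 1 :]
        if genetics.is_stop(mutant):
            continue
        if genetics.is_synonymous(codon, mutant) or rng.random() < omega:
            seq[pos] = new_base


def evolve_clade(
    reference: tuple[MitoGenome, FeatureTable], config: SimulationConfig
) -> SimulatedClade:
    """Evolve the reference genome along the configured taxon tree.

    Coding genes evolve codon-aware with per-gene omega; tRNA/rRNA/control
    regions and spacers evolve under plain substitution at the branch rate.
    Branch lengths are expected substitutions per (proposed) site.
    """
    genome, table = reference
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    if len(tree.leaf_nodes()) < 2:
        raise ConfigError("taxon tree needs at least two leaves")
    rng = np.random.default_rng(config.seed + 1)

    # genome state per node: feature sense sequences + inter-feature filler
    def genome_state():
        state = {"__features__": [], "__fillers__": []}
        pos = 1
        for f in table:
            if f.start > pos:
                state["__fillers__"].append(
                    list(genome.sequence[pos - 1 : f.start - 1])
                )
            else:
                state["__fillers__"].append([])
            state["__features__"].append(list(extract_feature_sequence(genome, f)))
            pos = f.end + 1
        state["__tail__"] = list(genome.sequence[pos - 1 :])
        return state

    def copy_state(state):
        return {
            "__features__": [list(s) for s in state["__features__"]],
            "__fillers__": [list(s) for s in state["__fillers__"]],
            "__tail__": list(state["__tail__"]),
        }

    # keep each tRNA's annotated anticodon intact so folds stay anchored
    # (all occurrences: the loop anchor must survive evolution)
    anticodon_spans: dict[str, frozenset[int]] = {}
    for f in table.trnas:
        sense = extract_feature_sequence(genome, f)
        protected: set[int] = set()
        hit = sense.find(f.anticodon)
        while hit >= 0:
            protected.update(range(hit, hit + 3))
            hit = sense.find(f.anticodon, hit + 1)
        anticodon_spans[f.name] = frozenset(protected)

    def mutate(state, branch_length):
        if branch_length < 0:
            raise ConfigError("branch lengths must be >= 0")
        for f, seq in zip(table, state["__features__"]):
            if f.category == "PCG":
                _mutate_pcg(seq, branch_length, config.omega_for(f.name), rng)
            else:
                _mutate_neutral(
                    seq, branch_length, rng,
                    protected=anticodon_spans.get(f.name, frozenset()),
                )
        for filler in state["__fillers__"]:
            _mutate_neutral(filler, branch_length, rng)
        _mutate_neutral(state["__tail__"], branch_length, rng)

    def assemble(state, taxon):
        chunks = []
        for f, filler, seq in zip(
            table, state["__fillers__"], state["__features__"]
        ):
            chunks.append("".join(filler))
            sense = "".join(seq)
            chunks.append(
                genetics.reverse_complement(sense) if f.strand == "N" else sense
            )
        chunks.append("".join(state["__tail__"]))
        sequence = "".join(chunks)
        mg = MitoGenome(identifier=taxon, species=taxon, sequence=sequence)
        return mg, FeatureTable(
            features=list(table.features), genome_length=len(sequence)
        )

    genomes: dict[str, tuple[MitoGenome, FeatureTable]] = {}
    root_state = genome_state()

    def visit(node, state):
        for child in node.child_nodes():
            child_state = copy_state(state)
            mutate(child_state, child.edge.length or 0.0)
            if child.is_leaf():
                taxon = child.taxon.label.replace(" ", "_")
                genomes[taxon] = assemble(child_state, taxon)
            else:
                visit(child, child_state)

    visit(tree.seed_node, root_state)
    return SimulatedClade(genomes=genomes, config=config)
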