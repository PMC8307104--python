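"""Concatenated PCG+rRNA supermatrix assembly, export, and a light NJ tree.

The phylogenetic dataset of this pipeline is the concatenation of the 13
protein-coding genes and the two rRNAs (15 partitions) across taxa, exported
for external maximum-likelihood/Bayesian software (relaxed PHYLIP, NEXUS with
a charset block, FASTA plus RAxML-style partition text). Tree inference
proper is out of scope; the module's internal p-distance + neighbor-joining
tree exists to smoke-test simulated clades (e.g. ingroup monophyly), not to
reproduce published support values.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import (
    AlignmentRequiredError,
    InputError,
    InsufficientDataError,
    MissingDataError,
    NameError_,
    UndefinedDistanceError,
)
from .genome_model import FeatureTable, MitoGenome, extract_feature_sequence

#: canonical concatenation order: the 13 PCGs + 2 rRNAs in genomic order
CANONICAL_GENE_ORDER = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3", "ND5", "ND4",
    "ND4L", "ND6", "CytB", "ND1", "lrRNA", "srRNA",
)


@dataclass
class Supermatrix:
    """Equal-length concatenated sequences with 1-based partition spans."""

    taxa: list[str]
    sequences: dict[str, str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise AlignmentRequiredError("concatenated sequences differ in length")
        (self.length,) = lengths or {0}
        pos = 1
        for name, start, end in self.partitions:
            if start != pos or end < start:
                raise InputError(f"partition {name} does not tile the alignment")
            pos = end + 1
        if self.partitions and pos != self.length + 1:
            raise InputError("partitions do not cover the alignment")


def build_supermatrix(
    gene_blocks: Mapping[str, Mapping[str, str]],
    gene_order: Sequence[str] = CANONICAL_GENE_ORDER,
) -> Supermatrix:
    """Concatenate per-gene blocks (taxon -> gene -> sequence).

    Blocks must be equal-length across taxa (pre-aligned, or alignment-free
    comparable as in the synthetic data); no gap-filling is performed.
    """
    taxa = list(gene_blocks)
    if not taxa:
        raise InsufficientDataError("no taxa supplied")
    for taxon in taxa:
        missing = [g for g in gene_order if g not in gene_blocks[taxon]]
        if missing:
            raise MissingDataError(f"{taxon}: missing gene(s) {missing}")
    partitions = []
    pos = 1
    for gene in gene_order:
        lengths = {len(gene_blocks[t][gene]) for t in taxa}
        if len(lengths) > 1:
            raise AlignmentRequiredError(
                f"{gene}: unequal block lengths {sorted(lengths)}; align first"
            )
        (n,) = lengths
        partitions.append((gene, pos, pos + n - 1))
        pos += n
    sequences = {
        t: "".join(gene_blocks[t][g].upper() for g in gene_order) for t in taxa
    }
    return Supermatrix(taxa=taxa, sequences=sequences, partitions=partitions)


def supermatrix_from_genomes(
    genomes: Mapping[str, tuple[MitoGenome, FeatureTable]],
    gene_order: Sequence[str] = CANONICAL_GENE_ORDER,
) -> Supermatrix:
    """Extract the 15 sense-strand gene blocks from annotated genomes."""
    blocks: dict[str, dict[str, str]] = {}
    for taxon, (genome, table) in genomes.items():
        row = {}
        for f in table:
            if f.name in gene_order:
                row[f.name] = extract_feature_sequence(genome, f)
        blocks[taxon] = row
    return build_supermatrix(blocks, gene_order)


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise InputError("matrix shape does not match taxon count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise InputError("distance matrix is not symmetric")


def p_distance_matrix(sm: Supermatrix) -> DistanceMatrix:
    """Pairwise proportion of differing sites over pairwise-complete columns.

    Columns where either sequence has a gap or ambiguity (anything outside
    A/C/G/T) are excluded for that pair.
    """
    taxa = sm.taxa
    arrays = {
        t: np.frombuffer(sm.sequences[t].encode(), dtype="S1") for t in taxa
    }
    valid = {
        t: np.isin(arrays[t], np.array(list("ACGT"), dtype="S1")) for t in taxa
    }
    n = len(taxa)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[taxa[i]] & valid[taxa[j]]
        total = int(both.sum())
        if total == 0:
            raise UndefinedDistanceError(
                f"no comparable columns between {taxa[i]} and {taxa[j]}"
            )
        diffs = int((arrays[taxa[i]][both] != arrays[taxa[j]][both]).sum())
        out[i, j] = out[j, i] = diffs / total
    return DistanceMatrix(taxa=list(taxa), matrix=out)


@dataclass
class TreeNode:
    """Minimal rooted representation of an (unrooted) phylogeny."""

    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name
        parts = [
            f"{child._newick_inner()}:{length:.6f}"
            for child, length in self.children
        ]
        return "(" + ",".join(parts) + ")"


@dataclass
class Tree:
    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        return self.root.to_newick()

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets under every internal edge (one side of each split)."""
        splits = []

        def visit(node):
            for child, _ in node.children:
                if not child.is_leaf:
                    splits.append(frozenset(child.leaves()))
                visit(child)

        visit(self.root)
        # single leaves are trivial splits; include them for completeness
        for leaf in self.leaves():
            splits.append(frozenset([leaf]))
        return splits


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    On Q-score ties the lowest-index pair (row-major) is joined. Negative
    branch lengths arising from noisy distances are clamped to zero.
    """
    n = len(dm.taxa)
    if n < 3:
        raise InsufficientDataError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()
    active = [TreeNode(name=t) for t in dm.taxa]

    while len(active) > 2:
        m = len(active)
        totals = D.sum(axis=1)
        best = None
        best_q = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - totals[i] - totals[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(active[i], li), (active[j], lj)])
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_new[-1, : m - 2] = new_row[keep]
        D_new[: m - 2, -1] = new_row[keep]
        active = [active[k] for k in keep] + [parent]
        D = D_new

    # join the last two nodes on a single edge
    root = TreeNode(
        children=[(active[0], 0.0), (active[1], max(D[0, 1], 0.0))]
    )
    return Tree(root=root)


def check_monophyly(tree: Tree, ingroup: Iterable[str]) -> bool:
    """True iff one edge bipartition separates exactly the ingroup."""
    ingroup = frozenset(ingroup)
    all_leaves = frozenset(tree.leaves())
    unknown = ingroup - all_leaves
    if unknown:
        raise NameError_(f"unknown taxa: {sorted(unknown)}")
    complement = all_leaves - ingroup
    for split in tree.bipartitions():
        if split == ingroup or split == complement:
            return True
    return False


# ---------------------------------------------------------------------------
# Export formats
# ---------------------------------------------------------------------------

def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: name, two spaces, full sequence on one line."""
    with open(path, "w") as fh:
        fh.write(f" {len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.sequences[t]}\n")


def read_phylip(path) -> Supermatrix:
    lines = Path(path).read_text().splitlines()
    seqs = {}
    taxa = []
    for line in lines[1:]:
        if not line.strip():
            continue
        name, seq = line.split(None, 1)
        taxa.append(name)
        seqs[name] = seq.strip()
    return Supermatrix(taxa=taxa, sequences=seqs, partitions=[])


def write_fasta(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for t in sm.taxa:
            fh.write(f">{t}\n{sm.sequences[t]}\n")


def read_fasta(path) -> Supermatrix:
    taxa, seqs = [], {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].strip()
            taxa.append(name)
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return Supermatrix(taxa=taxa, sequences=seqs, partitions=[])


def write_raxml_partitions(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for name, start, end in sm.partitions:
            fh.write(f"DNA, {name} = {start}-{end}\n")


def read_raxml_partitions(path) -> list[tuple[str, int, int]]:
    partitions = []
    pattern = re.compile(r"DNA,\s*(\S+)\s*=\s*(\d+)-(\d+)")
    for line in Path(path).read_text().splitlines():
        m = pattern.match(line.strip())
        if m:
            partitions.append((m.group(1), int(m.group(2)), int(m.group(3))))
    return partitions


def write_nexus(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.length};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        for t in sm.taxa:
            fh.write(f"    {t}  {sm.sequences[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for name, start, end in sm.partitions:
            fh.write(f"  CHARSET {name} = {start}-{end};\n")
        fh.write("END;\n")


def read_nexus(path) -> Supermatrix:
    text = Path(path).read_text()
    taxa, seqs = [], {}
    in_matrix = False
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if stripped == ";":
                in_matrix = False
                continue
            if stripped:
                name, seq = stripped.split(None, 1)
                taxa.append(name)
                seqs[name] = seq.strip()
    partitions = [
        (m.group(1), int(m.group(2)), int(m.group(3)))
        for m in re.finditer(r"CHARSET\s+(\S+)\s*=\s*(\d+)-(\d+);", text)
    ]
    return Supermatrix(taxa=taxa, sequences=seqs, partitions=partitions)


def write_newick(tree: Tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
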