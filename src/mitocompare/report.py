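"""Report writers and the full-pipeline driver.

All reports are tab-separated text with '#'-prefixed metadata headers
(inputs, seed, package version), so they diff cleanly and re-running on
identical inputs reproduces them byte for byte.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__, composition, codon_usage, kaks, supermatrix, trna_structure
from .errors import MitocompareError, PipelineStageError
from .genome_model import (
    FeatureTable,
    MitoGenome,
    annotation_report_frame,
)

logger = logging.getLogger("mitocompare")


@dataclass
class RunConfig:
    """Run configuration for the full pipeline."""

    output_dir: Path
    seed: int = 0
    code_id: int = 5
    kaks_ratio_of_means: bool = False
    trna_loop_relaxation: bool = False
    percent_decimals: int = 1
    skew_decimals: int = 2


def _header(config: Optional[RunConfig], inputs: str) -> str:
    lines = [
        f"# mitocompare v{__version__}",
        f"# inputs: {inputs}",
    ]
    if config is not None:
        lines.append(f"# seed: {config.seed}")
    return "\n".join(lines) + "\n"


def write_report(df: pd.DataFrame, path, inputs: str,
                 config: Optional[RunConfig] = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(config, inputs))
        df.to_csv(fh, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_full_pipeline(
    genomes: Mapping[str, tuple[MitoGenome, FeatureTable]],
    config: RunConfig,
) -> dict[str, Path]:
    """Run every analysis stage over annotated genomes and write reports.

    Returns a dict of stage name -> written path. Any stage failure aborts
    with a stage-labeled error and removes partial outputs.
    """
    if not genomes:
        raise PipelineStageError("input", "no annotated genomes supplied")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    inputs = ",".join(genomes)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except MitocompareError as exc:
                for path in written.values():
                    path.unlink(missing_ok=True)
                raise PipelineStageError(name, str(exc)) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return wrap

    @stage("annotation")
    def _annotation():
        frames = []
        for taxon, (genome, table) in genomes.items():
            df = annotation_report_frame(genome, table)
            df.insert(0, "taxon", taxon)
            frames.append(df)
        path = out / "annotation_report.tsv"
        write_report(pd.concat(frames, ignore_index=True), path, inputs, config)
        written["annotation"] = path

    @stage("composition")
    def _composition():
        frames = []
        for taxon, (genome, table) in genomes.items():
            df = composition.composition_report_frame(genome, table)
            df.insert(0, "taxon", taxon)
            frames.append(df)
        path = out / "composition_report.tsv"
        write_report(pd.concat(frames, ignore_index=True), path, inputs, config)
        written["composition"] = path

    @stage("rscu")
    def _rscu():
        counts = codon_usage.count_codons(genomes.values())
        df = codon_usage.rscu(counts).frame()
        path = out / "rscu.tsv"
        write_report(df, path, inputs, config)
        written["rscu"] = path

    @stage("trna")
    def _trna():
        rows = []
        for taxon, (genome, table) in genomes.items():
            from .genome_model import extract_feature_sequence

            for f in table.trnas:
                seq = extract_feature_sequence(genome, f)
                structure = trna_structure.fold_trna(
                    seq, f.anticodon,
                    relax_anticodon_loop=config.trna_loop_relaxation,
                )
                pairs = trna_structure.classify_pairs(structure, seq)
                rows.append(
                    {
                        "taxon": taxon, "trna": f.name, "length": len(seq),
                        "dhu_present": structure.dhu_present,
                        "watson_crick": pairs.watson_crick,
                        "gu_wobble": pairs.gu_wobble,
                        "mismatches": len(pairs.mismatches),
                        "dot_bracket": structure.dot_bracket(),
                    }
                )
        path = out / "trna_report.tsv"
        write_report(pd.DataFrame(rows), path, inputs, config)
        written["trna"] = path

    @stage("kaks")
    def _kaks():
        from .genome_model import extract_feature_sequence

        rows = []
        gene_names = [
            f.name for f in next(iter(genomes.values()))[1].pcgs
        ]
        for gene in gene_names:
            seqs = {
                taxon: extract_feature_sequence(genome, table.get(gene))
                for taxon, (genome, table) in genomes.items()
            }
            usable = len(seqs[next(iter(seqs))])
            seqs = {t: s[: usable - usable % 3] for t, s in seqs.items()}
            summary = kaks.gene_mean_kaks(
                gene, seqs, ratio_of_means=config.kaks_ratio_of_means
            )
            rows.append(
                {
                    "gene": gene,
                    "mean_ka": round(summary.mean_ka, 5),
                    "mean_ks": round(summary.mean_ks, 5),
                    "mean_ka_ks": (
                        round(summary.mean_ratio, 5)
                        if summary.mean_ratio is not None else ""
                    ),
                    "n_pairs": summary.n_pairs,
                }
            )
        path = out / "kaks.tsv"
        write_report(pd.DataFrame(rows), path, inputs, config)
        written["kaks"] = path

    @stage("supermatrix")
    def _supermatrix():
        sm = supermatrix.supermatrix_from_genomes(genomes)
        prefix = out / "supermatrix"
        supermatrix.write_phylip(sm, prefix.with_suffix(".phy"))
        supermatrix.write_nexus(sm, prefix.with_suffix(".nex"))
        supermatrix.write_fasta(sm, prefix.with_suffix(".fasta"))
        supermatrix.write_raxml_partitions(sm, prefix.with_suffix(".partitions"))
        written["supermatrix"] = prefix.with_suffix(".nex")
        if len(sm.taxa) >= 3:
            dm = supermatrix.p_distance_matrix(sm)
            tree = supermatrix.nj_tree(dm)
            supermatrix.write_newick(tree, out / "nj_tree.nwk")
            written["nj_tree"] = out / "nj_tree.nwk"

    return written


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.WARNING if quiet else logging.INFO
    logging.basicConfig(
        stream=sys.stderr, level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
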