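"""End-to-end pipeline: preprocess, design, characterize, pair, summarize.

``run_pipeline`` chains the whole design route — duplicate removal, k-mer
based primer design, property calculation, in-silico pairing with optional
off-target specificity, and covered-taxonomy summaries — and writes one
TSV report per stage. Every report embeds the full parameter set as
``#``-prefixed header lines, so outputs are self-describing, and the
analysis path is RNG-free: identical inputs and config give byte-identical
reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .config import PipelineConfig
from .coverage_assessment import PrimerPairReport, evaluate_pair, specificity
from .primer_design import DegeneratePrimer, design_primers
from .primer_properties import FoldingConditions, dG_range, gc_range, tm_range
from .seq_processing import SequenceRecord, dedupe_exact, load_fasta
from .taxonomy_summary import (
    PhenotypeMap,
    breakdown_by_phenotype,
    breakdown_by_rank,
    breakdown_to_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything one run produced, plus where the reports were written."""

    db: list[SequenceRecord]
    primers: list[DegeneratePrimer]
    pair_reports: list[PrimerPairReport]
    outputs: dict[str, Path] = field(default_factory=dict)


def _param_header(config: PipelineConfig) -> str:
    lines = [f"# {k} = {v}" for k, v in sorted(config.to_dict().items())]
    return "\n".join(lines) + "\n"


def _write_primer_report(
    primers: Sequence[DegeneratePrimer], path: Path, config: PipelineConfig
) -> None:
    cond = FoldingConditions(config.fold_temp, config.mg, config.na)
    with open(path, "w") as fh:
        fh.write(_param_header(config))
        fh.write(
            "name\tiupac_seq\tk\tdegeneracy\tcoverage\tseed_occurrences\t"
            "gc_min\tgc_max\ttm_min\ttm_max\tdg_min\tdg_max\n"
        )
        for p in primers:
            gc = gc_range(p)
            tm = tm_range(p)
            dg = dG_range(p, cond, max_degeneracy=max(config.max_degeneracy, 1024))
            fh.write(
                f"{p.name}\t{p.iupac_seq}\t{len(p)}\t{p.degeneracy}\t"
                f"{(p.coverage or 0.0) * 100:.2f}\t{p.seed_occurrences}\t"
                f"{gc.min_val:.2f}\t{gc.max_val:.2f}\t"
                f"{tm.min_val:.2f}\t{tm.max_val:.2f}\t"
                f"{dg.min_val:.2f}\t{dg.max_val:.2f}\n"
            )


def recommend_pairs(
    primers: Sequence[DegeneratePrimer],
    db: Sequence[SequenceRecord],
    config: PipelineConfig,
) -> list[PrimerPairReport]:
    """Evaluate every forward/reverse combination of designed primers.

    Designed primers are sense-strand k-mer consensuses; a pair is formed
    as (primer i forward, reverse complement of primer j as the reverse
    primer), for all ordered i != j. Reports are sorted by pair coverage
    descending and only amplifying pairs (coverage > 0) are kept.
    """
    reports: list[PrimerPairReport] = []
    for f in primers:
        for p in primers:
            if p is f:
                continue
            rev = p.reverse_complement()
            rep = evaluate_pair(
                f,
                rev,
                db,
                config.product_min,
                config.product_max,
                config.max_mismatches,
            )
            rep.fwd, rep.rev = f, rev
            if rep.pair_coverage > 0:
                reports.append(rep)
    reports.sort(
        key=lambda r: (
            -r.pair_coverage,
            r.fwd.name or r.fwd.iupac_seq,
            r.rev.name or r.rev.iupac_seq,
        )
    )
    return reports


def _write_pair_report(
    reports: Sequence[PrimerPairReport],
    offtargets: dict[str, list[SequenceRecord]],
    path: Path,
    config: PipelineConfig,
) -> None:
    with open(path, "w") as fh:
        fh.write(_param_header(config))
        cols = ["forward", "reverse", "pair_coverage", "product_length_mode"]
        cols += [f"specificity_{name}" for name in sorted(offtargets)]
        fh.write("\t".join(cols) + "\n")
        for rep in reports:
            row = [
                rep.fwd.name or rep.fwd.iupac_seq,
                rep.rev.name or rep.rev.iupac_seq,
                f"{rep.pair_coverage * 100:.2f}",
                str(rep.product_length_mode or ""),
            ]
            for name in sorted(offtargets):
                spec = specificity(
                    (rep.fwd, rep.rev),
                    offtargets[name],
                    config.max_mismatches,
                    config.product_min,
                    config.product_max,
                )
                rep.specificity[name] = spec
                row.append(f"{spec * 100:.2f}")
            fh.write("\t".join(row) + "\n")


def run_pipeline(
    target_fasta: str | Path,
    offtarget_fastas: Optional[dict[str, str | Path]] = None,
    config: Optional[PipelineConfig] = None,
    outdir: str | Path = "kmerprimer_out",
    phenotype_tsv: Optional[str | Path] = None,
    rank: str = "phylum",
    name_prefix: str = "primer",
) -> PipelineResult:
    """Run the full design-and-assessment pipeline and write TSV reports.

    Writes ``primers.tsv`` (design + properties), ``pairs.tsv`` (pair
    coverage, product-length mode, per-off-target specificity), and — when
    lineage annotations are present — ``taxonomy_<rank>.tsv`` plus
    phenotype breakdowns for the best pair. An empty design (nothing above
    the coverage floor) is a warning, not an error.
    """
    if config is None:
        config = PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(db=[], primers=[], pair_reports=[])

    db = dedupe_exact(load_fasta(target_fasta))
    result.db = db
    offtargets = {
        name: load_fasta(p) for name, p in (offtarget_fastas or {}).items()
    }

    primers = design_primers(db, config, name_prefix=name_prefix)
    result.primers = primers

    primer_path = outdir / "primers.tsv"
    _write_primer_report(primers, primer_path, config)
    result.outputs["primers"] = primer_path

    pair_path = outdir / "pairs.tsv"
    if len(primers) >= 2:
        reports = recommend_pairs(primers, db, config)
    else:
        reports = []
        if not primers:
            logger.warning("no primers above the coverage floor; reports are empty")
    _write_pair_report(reports, offtargets, pair_path, config)
    result.pair_reports = reports
    result.outputs["pairs"] = pair_path

    has_lineage = any(rec.lineage for rec in db)
    if reports and has_lineage:
        best = reports[0]
        ids = best.covered_ids
        tax_path = outdir / f"taxonomy_{rank}.tsv"
        breakdown_to_tsv(
            breakdown_by_rank(db, ids, rank), tax_path, _param_header(config)
        )
        result.outputs["taxonomy"] = tax_path
        if phenotype_tsv is not None:
            phenomap = PhenotypeMap.from_tsv(phenotype_tsv)
            for axis in ("oxygen", "gram"):
                p = outdir / f"phenotype_{axis}.tsv"
                breakdown_to_tsv(
                    breakdown_by_phenotype(db, ids, phenomap, axis),
                    p,
                    _param_header(config),
                )
                result.outputs[f"phenotype_{axis}"] = p

    return result
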