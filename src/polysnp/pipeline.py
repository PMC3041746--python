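"""Configuration-driven orchestration of the full discovery pipeline.

Stages run in the fixed order: reference self-screen -> record filter
cascade -> sharing classification -> crowded-contig exclusion -> masked
assay-target export.  Every artifact is written to the output directory and
the combined attrition report is rendered both machine-readable (TSV) and in
the narrative "N removed (P%)" style.  Re-running with an identical
configuration and seed produces byte-identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import discovery, io as vio
from .records import CandidateSNP, Contig, MaskedTarget, VariantRecord
from .report import AttritionReport
from .simulate import SimConfig, simulate_variant_tables

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Either ``reference_fasta`` + ``variant_tables`` are given, or a
    ``sim`` block generates record-level synthetic data in their place.
    Threshold defaults are the pipeline's published operating point:
    depth >= 5, frequency exactly 100, 100-bp crowding window, 90 +/- 30 bp
    amplicon size.
    """

    out_dir: str = "polysnp_out"
    reference_fasta: str | None = None
    variant_tables: dict[str, str] = field(default_factory=dict)
    reference_genotype: str = "TAM"
    min_depth: int = 5
    share_requires_identical_alt: bool = True
    window_bp: int = 100
    flank_bp: int = 50
    product_size_opt: int = 90
    product_size_tol: int = 30
    sim: SimConfig | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.window_bp < 1 or self.flank_bp < 1:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim is not None:
            if "expression_ratio" in sim:
                sim["expression_ratio"] = tuple(sim["expression_ratio"])
            cfg.sim = SimConfig(**sim)
        return cfg


@dataclass
class PipelineResult:
    retained_contigs: list[Contig]
    passing_records: list[VariantRecord]
    candidates: list[CandidateSNP]
    assay_candidates: list[CandidateSNP]
    eliminated_contigs: list[str]
    masked_targets: list[MaskedTarget]
    report: AttritionReport
    artifacts: dict[str, Path]


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        tables = simulate_variant_tables(config.sim)
        reference = tables.data.reference
        records = tables.records
        ref_genotype = config.sim.reference_genotype
    else:
        if not config.reference_fasta or not config.variant_tables:
            raise ValueError(
                "need reference_fasta and variant_tables (or a sim block)"
            )
        reference = vio.read_fasta(config.reference_fasta)
        records = {
            g: vio.read_variant_table(p)
            for g, p in sorted(config.variant_tables.items())
        }
        ref_genotype = config.reference_genotype
    return reference, records, ref_genotype


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference, records, ref_genotype = _load_inputs(config)
    self_variants = records.get(ref_genotype, [])
    cross = {g: recs for g, recs in records.items() if g != ref_genotype}
    logger.info(
        "loaded %d reference contigs; %d genotypes; %d self-variants",
        len(reference), len(cross), len(self_variants),
    )

    retained, screen_report = discovery.screen_reference(reference, self_variants)
    passing, filter_report = discovery.filter_candidates(
        cross, retained, min_depth=config.min_depth
    )
    candidates = discovery.classify_candidates(
        passing, require_identical_alt=config.share_requires_identical_alt
    )
    assay, eliminated = discovery.select_assay_targets(
        candidates, window_bp=config.window_bp
    )
    ref_by_id = {c.id: c for c in reference}
    targets = [
        discovery.mask_snp_fasta(c, ref_by_id, flank_bp=config.flank_bp)
        for c in sorted(assay, key=lambda c: (c.contig_id, c.position, c.alt_base))
    ]

    combined = AttritionReport(title="SNP discovery attrition")
    combined.extend(screen_report)
    combined.extend(filter_report)

    artifacts: dict[str, Path] = {}

    def write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        artifacts[name] = p

    vio.write_fasta(retained, out / "retained_contigs.fasta")
    artifacts["retained_contigs.fasta"] = out / "retained_contigs.fasta"
    catalog = ["contig_id\tposition\tref\talt\tclass\tgenotypes\tper_genotype_freq_depth"]
    for c in sorted(candidates, key=lambda c: (c.contig_id, c.position, c.alt_base)):
        pg = ";".join(f"{g}:{f:.1f}/{d}" for g, f, d in c.per_genotype)
        catalog.append(
            f"{c.contig_id}\t{c.position}\t{c.ref_base}\t{c.alt_base}\t"
            f"{c.sharing_class}\t{','.join(sorted(c.supporting_genotypes))}\t{pg}"
        )
    write("candidates.tsv", "\n".join(catalog) + "\n")
    discovery.write_masked_fasta(targets, out / "masked_targets.fasta")
    artifacts["masked_targets.fasta"] = out / "masked_targets.fasta"
    vio.export_vcf(candidates, ref_by_id, out / "candidates.vcf")
    artifacts["candidates.vcf"] = out / "candidates.vcf"
    write("attrition.tsv", combined.to_tsv())
    write("attrition.txt", combined.to_text() + "\n")
    write("eliminated_contigs.txt", "\n".join(eliminated) + ("\n" if eliminated else ""))

    for st in combined.stages:
        logger.info("%s: %s removed", st.name, st.render())
    return PipelineResult(
        retained_contigs=retained,
        passing_records=passing,
        candidates=candidates,
        assay_candidates=assay,
        eliminated_contigs=eliminated,
        masked_targets=targets,
        report=combined,
        artifacts=artifacts,
    )
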