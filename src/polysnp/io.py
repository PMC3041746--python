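"""File formats: FASTA, the variant-table TSV dialect, VCF export, summaries.

The variant table is a TSV with header
``contig_id  start  end  ref  var  freq_pct  depth  genotype`` emulating the
mapper "header report" fields (contig, start/end, reference and polymorphic
base, variation frequency, read depth).  Frequencies are printed with one
decimal; ``-`` denotes a gap allele.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import CandidateSNP, Contig, VariantRecord

VARIANT_TABLE_HEADER = "contig_id\tstart\tend\tref\tvar\tfreq_pct\tdepth\tgenotype"


class VariantTableError(ValueError):
    """Raised for malformed variant-table rows; names the offending line."""


def read_fasta(path: str | Path, genotype: str = "") -> list[Contig]:
    return [
        Contig(id=rec.id, sequence=str(rec.seq).upper(), genotype=genotype)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description=c.genotype)
        for c in contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_variant_table(path: str | Path) -> list[VariantRecord]:
    """Parse a variant table, validating every row.

    Raises :class:`VariantTableError` naming the first offending line and the
    violated invariant.
    """
    records: list[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != VARIANT_TABLE_HEADER:
            raise VariantTableError(
                f"{path}: bad header {header!r}; expected {VARIANT_TABLE_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise VariantTableError(
                    f"{path}:{lineno}: expected 8 fields, got {len(fields)}"
                )
            contig_id, start, end, ref, var, freq, depth, genotype = fields
            try:
                rec = VariantRecord(
                    contig_id=contig_id,
                    start=int(start),
                    end=int(end),
                    ref_allele=ref,
                    var_allele=var,
                    frequency_pct=float(freq),
                    depth=int(depth),
                    genotype=genotype,
                )
            except ValueError as exc:
                raise VariantTableError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(VARIANT_TABLE_HEADER + "\n")
        for r in records:
            fh.write(
                f"{r.contig_id}\t{r.start}\t{r.end}\t{r.ref_allele}\t"
                f"{r.var_allele}\t{r.frequency_pct:.1f}\t{r.depth}\t{r.genotype}\n"
            )


# ---------------------------------------------------------------------------
# Assembly summaries


@dataclass(frozen=True)
class GenotypeAssemblyStats:
    genotype: str
    n_contigs: int
    total_length_mb: float
    mean_len_bp: float
    sd_len_bp: float
    min_len_bp: int
    max_len_bp: int
    total_reads: int | None = None
    assembled_reads: int | None = None


@dataclass(frozen=True)
class AssemblySummary:
    """Per-genotype contig statistics plus pooled derived totals.

    The overall mean contig length is the contig-count-weighted mean of the
    per-genotype means.  Percent assembled is rounded to an integer.
    """

    per_genotype: tuple[GenotypeAssemblyStats, ...]

    @property
    def total_contigs(self) -> int:
        return sum(g.n_contigs for g in self.per_genotype)

    @property
    def mean_contigs_per_genotype(self) -> int:
        return round(self.total_contigs / len(self.per_genotype))

    @property
    def overall_mean_len_bp(self) -> int:
        weighted = sum(g.n_contigs * g.mean_len_bp for g in self.per_genotype)
        return round(weighted / self.total_contigs)

    @property
    def total_reads(self) -> int | None:
        vals = [g.total_reads for g in self.per_genotype]
        return None if any(v is None for v in vals) else sum(vals)

    @property
    def total_assembled_reads(self) -> int | None:
        vals = [g.assembled_reads for g in self.per_genotype]
        return None if any(v is None for v in vals) else sum(vals)

    @property
    def percent_assembled(self) -> int | None:
        tot, asm = self.total_reads, self.total_assembled_reads
        if tot in (None, 0) or asm is None:
            return None
        return round(100 * asm / tot)


def summarize_assembly(
    contig_sets: Mapping[str, Sequence[Contig]],
    read_counts: Mapping[str, tuple[int, int]] | None = None,
) -> AssemblySummary:
    """Summarize per-genotype contig sets.

    ``read_counts`` maps genotype -> (total_reads, assembled_reads); when
    absent the read-derived fields are omitted with a warning.  SDs use the
    population formula.
    """
    if not contig_sets or any(not v for v in contig_sets.values()):
        raise ValueError("need >= 1 genotype, each with >= 1 contig")
    if read_counts is None:
        warnings.warn("no read counts supplied; percent-assembled omitted")
    stats = []
    for genotype, contigs in contig_sets.items():
        lengths = [len(c) for c in contigs]
        n = len(lengths)
        mean = sum(lengths) / n
        sd = math.sqrt(sum((x - mean) ** 2 for x in lengths) / n)
        reads = read_counts.get(genotype) if read_counts else None
        if reads is not None:
            total, assembled = reads
            if assembled > total:
                raise ValueError(
                    f"{genotype}: assembled reads {assembled} > total {total}"
                )
        stats.append(
            GenotypeAssemblyStats(
                genotype=genotype,
                n_contigs=n,
                total_length_mb=sum(lengths) / 1e6,
                mean_len_bp=mean,
                sd_len_bp=sd,
                min_len_bp=min(lengths),
                max_len_bp=max(lengths),
                total_reads=reads[0] if reads else None,
                assembled_reads=reads[1] if reads else None,
            )
        )
    return AssemblySummary(per_genotype=tuple(stats))


# ---------------------------------------------------------------------------
# VCF export

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=polysnp
##INFO=<ID=SC,Number=1,Type=Integer,Description="Genotype-sharing class (number of non-reference genotypes carrying the alt base)">
##INFO=<ID=GTS,Number=.,Type=String,Description="Supporting genotype labels">
##INFO=<ID=DP,Number=.,Type=Integer,Description="Per-supporting-genotype read depth">
##INFO=<ID=AF,Number=.,Type=Float,Description="Per-supporting-genotype alt frequency (fraction)">
"""


def export_vcf(
    candidates: Sequence[CandidateSNP],
    reference: Mapping[str, Contig] | Sequence[Contig],
    path: str | Path,
) -> None:
    """Write classified candidates as VCF 4.2 against the reference contigs."""
    if not isinstance(reference, Mapping):
        reference = {c.id: c for c in reference}
    unknown = sorted({c.contig_id for c in candidates} - set(reference))
    if unknown:
        raise ValueError(f"candidates reference unknown contigs: {unknown}")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for cid in sorted(reference):
            fh.write(f"##contig=<ID={cid},length={len(reference[cid])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(candidates, key=lambda c: (c.contig_id, c.position, c.alt_base)):
            gts = sorted(c.supporting_genotypes)
            by_gt = {g: (f, d) for g, f, d in c.per_genotype}
            dp = ",".join(str(by_gt[g][1]) for g in gts)
            af = ",".join(f"{by_gt[g][0] / 100:.4f}" for g in gts)
            info = f"SC={c.sharing_class};GTS={','.join(gts)};DP={dp};AF={af}"
            fh.write(
                f"{c.contig_id}\t{c.position}\t.\t{c.ref_base}\t{c.alt_base}"
                f"\t.\tPASS\t{info}\n"
            )
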