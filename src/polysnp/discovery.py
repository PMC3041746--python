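"""Pseudo-SNP filtering, genotype-sharing classification, assay targets.

This is the heart of the pipeline.  In a polyploid transcriptome, homoeologous
gene copies that co-assemble into one contig produce apparent within-genotype
polymorphism at every inter-subgenome difference.  Because each homoeolog
contributes only part of a contig's reads, such pseudo-SNPs show variant
frequencies below 100% within a genotype, whereas a true allelic SNP fixed in
a genotype is supported by every read.  The cascade therefore removes, in
order:

1. reference self-screen — contigs polymorphic within the reference
   genotype's own re-assembly (indels first, then ambiguous/N contigs);
2. indel / multi-base / N events in the cross-genotype records;
3. records with read depth <= 4;
4. records with within-genotype frequency below 100% (the conservation
   filter — the key polyploidy screen).

Survivors are single-base, frequency-100, depth >= 5 candidates, grouped into
sharing classes by how many genotypes carry the identical alternative base.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .records import CandidateSNP, Contig, MaskedTarget, VariantRecord, IUPAC_TWO_BASE
from .report import AttritionReport

logger = logging.getLogger(__name__)

FREQ_TOL = 1e-9  # on the percent scale; frequency must equal 100 exactly

DEFAULT_STAGE_ORDER = ("indel", "depth", "conservation")


def _is_indel_stage(rec: VariantRecord) -> bool:
    """Rule: multi-base events, gap alleles, and N calls are all removed here."""
    return rec.is_indel_or_multibase or rec.has_n


def _is_unconserved(rec: VariantRecord) -> bool:
    return abs(rec.frequency_pct - 100.0) > FREQ_TOL


def screen_reference(
    reference: Sequence[Contig],
    self_variants: Sequence[VariantRecord],
) -> tuple[list[Contig], AttritionReport]:
    """Self-screen: drop reference contigs polymorphic within the reference.

    Stage 1 removes contigs with any indel/multi-base self-variant; stage 2
    removes, from the survivors, contigs whose consensus contains an N or
    with any N-allele self-variant.  Both stage percentages are reported
    against the initial contig count.
    """
    by_id = {c.id: c for c in reference}
    unknown = sorted({v.contig_id for v in self_variants} - set(by_id))
    if unknown:
        raise ValueError(f"self-variants reference unknown contigs: {unknown}")

    n0 = len(reference)
    indel_contigs = {
        v.contig_id for v in self_variants if v.is_indel_or_multibase
    }
    survivors1 = [c for c in reference if c.id not in indel_contigs]

    n_contigs = {v.contig_id for v in self_variants if v.has_n}
    ambiguous = {
        c.id for c in survivors1 if "N" in c.sequence or c.id in n_contigs
    }
    survivors2 = [c for c in survivors1 if c.id not in ambiguous]

    report = AttritionReport(title="Reference self-screen")
    report.add_stage("reference_indel", n0, len(indel_contigs & set(by_id)), len(survivors1))
    report.add_stage("reference_ambiguous", n0, len(ambiguous), len(survivors2))
    return survivors2, report


def filter_candidates(
    records: Mapping[str, Sequence[VariantRecord]] | Sequence[VariantRecord],
    retained_contigs: Iterable[str] | Iterable[Contig],
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
    min_depth: int = 5,
) -> tuple[list[VariantRecord], AttritionReport]:
    """Apply the cross-genotype rule cascade; returns survivors + accounting.

    Records on contigs outside the retained set are dropped silently before
    staging.  Stages run sequentially but every stage's percentage is taken
    over the count entering the cascade, matching the published accounting
    convention.  A record passes the depth stage when its depth is at least
    ``min_depth`` (default 5, i.e. depth <= 4 removed).
    """
    if isinstance(records, Mapping):
        flat = [r for g in sorted(records) for r in records[g]]
    else:
        flat = list(records)
    retained_ids = {
        c.id if isinstance(c, Contig) else c for c in retained_contigs
    }
    if not retained_ids:
        raise ValueError("retained contig set is empty")
    if set(stage_order) != set(DEFAULT_STAGE_ORDER):
        raise ValueError(f"stage_order must be a permutation of {DEFAULT_STAGE_ORDER}")

    predicates = {
        "indel": _is_indel_stage,
        "depth": lambda r: r.depth < min_depth,
        "conservation": _is_unconserved,
    }
    current = [r for r in flat if r.contig_id in retained_ids]
    n0 = len(current)
    report = AttritionReport(title="Candidate record filtering")
    for stage in stage_order:
        pred = predicates[stage]
        removed = [r for r in current if pred(r)]
        current = [r for r in current if not pred(r)]
        report.add_stage(stage, n0, len(removed), len(current))
        if removed:
            logger.debug("stage %s removed %d records", stage, len(removed))
    return current, report


def classify_candidates(
    passing: Sequence[VariantRecord],
    require_identical_alt: bool = True,
) -> list[CandidateSNP]:
    """Group filtered records into candidates by (contig, position, alt base).

    A candidate's sharing class is the number of genotypes carrying the
    identical alternative base at the identical coordinate; different alt
    bases at one position remain distinct candidates.  This is the
    conservative default; ``require_identical_alt=False`` groups purely by
    coordinate (any substitution counts as shared), reporting the
    majority alt base.  Two records from one genotype at the same position
    with different alternative bases are kept in their groups but flagged
    as a within-genotype conflict.
    """
    groups: dict[tuple[str, int, str], list[VariantRecord]] = {}
    seen_pos: dict[tuple[str, int, str], set[str]] = {}
    for rec in passing:
        if require_identical_alt:
            key = (rec.contig_id, rec.start, rec.var_allele)
        else:
            key = (rec.contig_id, rec.start, "")
        groups.setdefault(key, []).append(rec)
        seen_pos.setdefault((rec.contig_id, rec.start, rec.genotype), set()).add(
            rec.var_allele
        )
    for (cid, pos, g), alts in seen_pos.items():
        if len(alts) > 1:
            logger.warning(
                "within-genotype conflict: %s carries %s at %s:%d",
                g, sorted(alts), cid, pos,
            )

    out: list[CandidateSNP] = []
    for (cid, pos, alt), recs in sorted(groups.items()):
        if not alt:  # coordinate-only grouping: report the majority alt base
            tally = Counter(r.var_allele for r in recs)
            alt = min(tally, key=lambda a: (-tally[a], a))
        out.append(
            CandidateSNP(
                contig_id=cid,
                position=pos,
                ref_base=recs[0].ref_allele,
                alt_base=alt,
                supporting_genotypes=frozenset(r.genotype for r in recs),
                per_genotype=tuple(
                    (r.genotype, r.frequency_pct, r.depth)
                    for r in sorted(recs, key=lambda r: r.genotype)
                ),
            )
        )
    return out


def class_counts(candidates: Sequence[CandidateSNP]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for c in candidates:
        counts[c.sharing_class] = counts.get(c.sharing_class, 0) + 1
    return counts


def select_assay_targets(
    candidates: Sequence[CandidateSNP],
    window_bp: int = 100,
) -> tuple[list[CandidateSNP], list[str]]:
    """Exclude contigs with multiple SNP targets crowded within a window.

    A contig is eliminated from the assay set when any two candidate
    positions on it are strictly less than ``window_bp`` apart (positions
    exactly ``window_bp`` apart are retained).  Eliminated contigs'
    candidates stay in the catalog; only the assay output excludes them.
    """
    by_contig: dict[str, list[int]] = {}
    for c in candidates:
        by_contig.setdefault(c.contig_id, []).append(c.position)
    eliminated = []
    for cid, positions in by_contig.items():
        positions = sorted(positions)
        if any(b - a < window_bp for a, b in zip(positions, positions[1:])):
            eliminated.append(cid)
    eliminated_set = set(eliminated)
    eligible = [c for c in candidates if c.contig_id not in eliminated_set]
    return eligible, sorted(eliminated)


def mask_snp_fasta(
    candidate: CandidateSNP,
    reference: Mapping[str, Contig] | Sequence[Contig],
    flank_bp: int = 50,
) -> MaskedTarget:
    """Build the dbSNP-style masked window around one candidate.

    The SNP position carries the two-base IUPAC code for {ref, alt}
    (A/G -> R, C/T -> Y, A/C -> M, G/T -> K, A/T -> W, C/G -> S); the window
    extends up to ``flank_bp`` each side and is truncated (and flagged) at
    contig ends.  The 90 +/- 30 bp amplicon-size constraint for primer
    design is carried on the result.
    """
    if not isinstance(reference, Mapping):
        reference = {c.id: c for c in reference}
    contig = reference[candidate.contig_id]
    if not (1 <= candidate.position <= len(contig)):
        raise ValueError(
            f"candidate position {candidate.position} outside contig "
            f"{contig.id!r} (length {len(contig)})"
        )
    start = max(1, candidate.position - flank_bp)
    end = min(len(contig), candidate.position + flank_bp)
    seq = list(contig.sequence[start - 1 : end])
    seq[candidate.position - start] = IUPAC_TWO_BASE[
        frozenset((candidate.ref_base, candidate.alt_base))
    ]
    truncated = (candidate.position - start < flank_bp) or (
        end - candidate.position < flank_bp
    )
    return MaskedTarget(
        candidate=candidate,
        sequence="".join(seq),
        window_start=start,
        window_end=end,
        truncated=truncated,
    )


def write_masked_fasta(
    targets: Sequence[MaskedTarget], path
) -> None:
    """Write masked assay windows in dbSNP-style FASTA for primer design."""
    with open(path, "w") as fh:
        for t in targets:
            c = t.candidate
            fh.write(
                f">{c.contig_id}_{c.position} ref={c.ref_base} alt={c.alt_base} "
                f"class={c.sharing_class} window={t.window_start}-{t.window_end} "
                f"product_size={t.product_size_opt}+/-{t.product_size_tol}"
                f"{' truncated' if t.truncated else ''}\n"
            )
            fh.write(t.sequence + "\n")
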