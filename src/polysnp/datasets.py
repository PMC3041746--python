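"""Published summary inputs from the four-genotype oat 454 EST study.

These are the printed per-genotype sequencing/assembly statistics and the
stage-by-stage candidate counts of the study the pipeline was designed
around.  They are inputs to the report arithmetic (assembly summaries,
attrition accounting, diversity accounting) — the package recomputes every
derived total from them rather than storing the derived values.
"""

from __future__ import annotations

from .io import AssemblySummary, GenotypeAssemblyStats
from .report import AttritionReport

#: Per-genotype cDNA sequencing-run and contig-assembly statistics.
SEQUENCING_RUNS: dict[str, dict] = {
    "Ogle1040": dict(total_reads=283478, assembled_reads=231057, n_contigs=32245,
                     total_length_mb=18.09, mean_len_bp=561, sd_len_bp=205,
                     min_len_bp=41, max_len_bp=2217),
    "TAM O-301": dict(total_reads=381397, assembled_reads=307751, n_contigs=42147,
                      total_length_mb=24.70, mean_len_bp=586, sd_len_bp=217,
                      min_len_bp=40, max_len_bp=4303),
    "Gem": dict(total_reads=180447, assembled_reads=137743, n_contigs=23681,
                total_length_mb=14.20, mean_len_bp=598, sd_len_bp=238,
                min_len_bp=43, max_len_bp=4229),
    "HiFi": dict(total_reads=235589, assembled_reads=188015, n_contigs=29036,
                 total_length_mb=16.40, mean_len_bp=564, sd_len_bp=220,
                 min_len_bp=42, max_len_bp=4416),
}

#: Stage counts of the published SNP-discovery run against the TAM O-301
#: reference assembly (42,147 contigs; 51,405 candidate records entered the
#: cross-genotype filter).
DISCOVERY_COUNTS = dict(
    reference_contigs=42147,
    reference_indel_removed=2179,
    reference_ambiguous_removed=10514,
    candidate_records=51405,
    indel_removed=7041,
    low_depth_removed=6874,
    conservation_removed=28042,
)

#: Published genotype-sharing class sizes (1/2/3 non-reference genotypes).
SHARING_CLASS_COUNTS = {1: 8408, 2: 953, 3: 87}

#: Diversity-panel allele accounting inputs: 36 HRM markers over 34 lines.
DIVERSITY_COUNTS = dict(
    n_markers=36,
    snp_alleles=73,
    insertion_deletion_alleles=51,
    het_alleles=6,
    null_alleles=10,
)


def published_assembly_summary() -> AssemblySummary:
    """The per-genotype assembly statistics as an :class:`AssemblySummary`.

    All pooled totals (total reads, total contigs, percent assembled, the
    contig-count-weighted overall mean length) are derived properties, not
    stored values.
    """
    return AssemblySummary(
        per_genotype=tuple(
            GenotypeAssemblyStats(genotype=g, **stats)
            for g, stats in SEQUENCING_RUNS.items()
        )
    )


def published_attrition_report() -> AttritionReport:
    """Rebuild the published attrition narrative from its stage inputs.

    The reference self-screen stages are reported against the initial contig
    count; the cross-genotype stages against the records entering each
    stage.  Remaining counts are computed, never stored.
    """
    c = DISCOVERY_COUNTS
    report = AttritionReport(title="SNP discovery attrition")
    n0 = c["reference_contigs"]
    rem1 = n0 - c["reference_indel_removed"]
    rem2 = rem1 - c["reference_ambiguous_removed"]
    report.add_stage("reference_indel", n0, c["reference_indel_removed"], rem1)
    report.add_stage("reference_ambiguous", n0, c["reference_ambiguous_removed"], rem2)

    n0 = c["candidate_records"]
    remaining = n0
    for stage, removed in (
        ("indel", c["indel_removed"]),
        ("low_depth", c["low_depth_removed"]),
        ("conservation", c["conservation_removed"]),
    ):
        remaining -= removed
        report.add_stage(stage, n0, removed, remaining)
    return report


def synthetic_diversity_panel():
    """A synthetic diversity-panel call table realizing the published allele
    accounting.

    The original per-line HRM calls are not available, so this builds a
    deterministic stand-in: 36 markers over 34 lines whose distinct observed
    allele states reproduce the published partition (73 single-nucleotide
    alleles, 51 insertion/deletion states, 6 heterozygote states, 10 null
    states; 140 states in total).  Allele *frequencies* across lines are
    arbitrary — only the state inventory is meaningful.
    """
    import pandas as pd

    from .popgen import MISSING, MarkerCallTable

    c = DIVERSITY_COUNTS
    n_markers, n_ind = c["n_markers"], 34
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]
    states_per_marker: list[list[str]] = []
    for i in range(n_markers):
        states = list(pairs[i % len(pairs)])
        states_per_marker.append(states)
    states_per_marker[0].append("T")  # 2 * 36 + 1 = 73 nucleotide states
    # 51 In/Del states: 15 markers carry both, the remaining 21 carry one
    for i in range(n_markers):
        if i < 15:
            states_per_marker[i] += ["In", "Del"]
        else:
            states_per_marker[i].append("In" if i % 2 == 0 else "Del")
    for i in range(c["het_alleles"]):
        states_per_marker[i].append("Het")
    for i in range(n_markers - c["null_alleles"], n_markers):
        states_per_marker[i].append("Null")

    individuals = [f"line{j + 1:02d}" for j in range(n_ind)]
    rows = {}
    for i, states in enumerate(states_per_marker):
        calls = [states[j % len(states)] for j in range(n_ind)]
        if i % 7 == 3:  # sprinkle missing data past the state-coverage prefix
            calls[-1] = MISSING
        rows[f"m{i + 1:02d}"] = calls
    table = pd.DataFrame.from_dict(rows, orient="index", columns=individuals)
    return MarkerCallTable(calls=table, mode="diversity")


def candidate_survivors() -> int:
    """Candidates surviving the cross-genotype cascade, by stage arithmetic."""
    c = DISCOVERY_COUNTS
    return (
        c["candidate_records"]
        - c["indel_removed"]
        - c["low_depth_removed"]
        - c["conservation_removed"]
    )
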