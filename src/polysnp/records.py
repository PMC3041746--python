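"""Core data model for the SNP-discovery pipeline.

Coordinates are 1-based and inclusive of both ends throughout the package,
matching the mapper-style header files the pipeline consumes.  Sequences are
transcript (forward) strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ALLELE_ALPHABET = frozenset("ACGTN-")
SEQ_ALPHABET = frozenset("ACGTN")

#: Two-base IUPAC ambiguity codes used to mask SNP positions for assay design.
IUPAC_TWO_BASE = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
}


@dataclass(frozen=True)
class Contig:
    """A reference or per-genotype transcript contig."""

    id: str
    sequence: str
    genotype: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r}: sequence is empty")
        bad = set(self.sequence) - SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A,C,G,T,N)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One mapper-style candidate difference against the reference assembly.

    ``frequency_pct`` is the percentage of a genotype's reads at this column
    supporting ``var_allele``; ``depth`` is the column read depth
    ("redundancy").  A ``-`` allele denotes a gap (insertion/deletion).
    """

    contig_id: str
    start: int
    end: int
    ref_allele: str
    var_allele: str
    frequency_pct: float
    depth: int
    genotype: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"{self.contig_id}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )
        if self.depth < 1:
            raise ValueError(
                f"{self.contig_id}:{self.start}: depth must satisfy depth >= 1, "
                f"got {self.depth}"
            )
        if not (0 < self.frequency_pct <= 100):
            raise ValueError(
                f"{self.contig_id}:{self.start}: frequency_pct must lie in "
                f"(0, 100], got {self.frequency_pct}"
            )
        for name, allele in (("ref", self.ref_allele), ("var", self.var_allele)):
            if not allele or set(allele) - ALLELE_ALPHABET:
                raise ValueError(
                    f"{self.contig_id}:{self.start}: invalid {name} allele "
                    f"{allele!r} (alphabet is A,C,G,T,N,-)"
                )
        if self.ref_allele == self.var_allele:
            raise ValueError(
                f"{self.contig_id}:{self.start}: ref and var alleles are "
                f"identical ({self.ref_allele!r})"
            )

    @property
    def is_indel_or_multibase(self) -> bool:
        """True for gap alleles and for events longer than one base."""
        return (
            "-" in self.ref_allele
            or "-" in self.var_allele
            or len(self.ref_allele) > 1
            or len(self.var_allele) > 1
        )

    @property
    def has_n(self) -> bool:
        return "N" in self.ref_allele or "N" in self.var_allele


@dataclass(frozen=True)
class CandidateSNP:
    """A filtered single-base SNP locus with its genotype-sharing class.

    ``sharing_class`` counts the non-reference genotypes carrying an
    identical alternative base at this coordinate (the 1/2/3-genotype
    classes of the discovery stage).
    """

    contig_id: str
    position: int
    ref_base: str
    alt_base: str
    supporting_genotypes: frozenset[str]
    per_genotype: tuple[tuple[str, float, int], ...]  # (genotype, freq, depth)

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base equals alt_base")
        if len(self.ref_base) != 1 or len(self.alt_base) != 1:
            raise ValueError("candidate SNPs are single-base")
        if not self.supporting_genotypes:
            raise ValueError("candidate must have >= 1 supporting genotype")

    @property
    def sharing_class(self) -> int:
        return len(self.supporting_genotypes)

    @property
    def iupac(self) -> str:
        return IUPAC_TWO_BASE[frozenset((self.ref_base, self.alt_base))]


@dataclass(frozen=True)
class MaskedTarget:
    """A dbSNP-style masked assay window around one candidate SNP.

    Exactly one position of ``sequence`` carries the two-base IUPAC code for
    {ref, alt}; ``product_size_opt``/``product_size_tol`` record the amplicon
    size constraint handed to downstream primer design (90 +/- 30 bp).
    """

    candidate: CandidateSNP
    sequence: str
    window_start: int  # 1-based, inclusive, on the contig
    window_end: int
    truncated: bool
    product_size_opt: int = 90
    product_size_tol: int = 30


# Ground-truth labels for the synthetic generator.
LABEL_ALLELIC = "allelic_snp"
LABEL_PSEUDO = "homoeolog_pseudo_snp"
LABEL_ERROR = "error"
TRUTH_LABELS = (LABEL_ALLELIC, LABEL_PSEUDO, LABEL_ERROR)


@dataclass(frozen=True)
class TruthVariant:
    """Ground truth for one planted site in the synthetic data."""

    contig_id: str
    position: int
    ref_base: str
    alt_base: str
    genotypes: frozenset[str]
    label: str

    def __post_init__(self) -> None:
        if self.label not in TRUTH_LABELS:
            raise ValueError(f"unknown truth label {self.label!r}")
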