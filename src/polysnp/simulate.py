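"""Synthetic polyploid transcriptomes with ground-truth variant labels.

The generator emulates the situation that makes SNP discovery hard in a
hexaploid transcriptome: each gene family has up to three homoeologous
subgenome copies; with some probability a family's copies co-assemble into a
single collapsed reference contig, so inter-homoeolog differences masquerade
as within-genotype polymorphism (pseudo-SNPs).  True allelic SNPs are
planted between genotypes and are fixed within each carrier genotype.
Everything downstream can therefore be scored against exact truth labels:
``allelic_snp``, ``homoeolog_pseudo_snp`` or ``error``.

Two output modes share one truth model: read-level (FASTQ per genotype, for
the aligner/caller) and record-level (mapper-style variant tables directly,
for fast filter testing).

All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .records import (
    LABEL_ALLELIC,
    LABEL_ERROR,
    LABEL_PSEUDO,
    Contig,
    TruthVariant,
    VariantRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_DEFAULT_GENOTYPES = ("TAM", "Ogle", "Gem", "HiFi")


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic hexaploid-like transcriptome.

    Defaults model the sequencing study the pipeline targets: four
    genotypes, ~4x transcript coverage, 250-bp pyrosequencing-style reads
    with ~0.5% miscalls and homopolymer-associated indels, three subgenome
    copies per gene family with ~2% inter-homoeolog divergence and unequal
    homoeolog expression.
    """

    n_gene_families: int = 40
    n_subgenome_copies: int = 3
    homoeolog_divergence: float = 0.02
    snp_rate: float = 0.005
    collapse_prob: float = 0.3
    expression_ratio: tuple[float, ...] = (0.5, 0.3, 0.2)
    read_length: int = 250
    depth_lambda: float = 4.0
    base_error: float = 0.005
    homopolymer_indel_rate: float = 0.01
    n_genotypes: int = 4
    mean_contig_len: float = 577.0
    sd_contig_len: float = 220.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "homoeolog_divergence": self.homoeolog_divergence,
            "snp_rate": self.snp_rate,
            "collapse_prob": self.collapse_prob,
            "base_error": self.base_error,
            "homopolymer_indel_rate": self.homopolymer_indel_rate,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise SimConfigError(f"{name} must lie in [0,1], got {p}")
        if self.n_gene_families < 1:
            raise SimConfigError("n_gene_families must be >= 1")
        if not (1 <= self.n_subgenome_copies <= 3):
            raise SimConfigError("n_subgenome_copies must be in 1..3")
        if self.depth_lambda <= 0:
            raise SimConfigError("depth_lambda must be > 0")
        if self.read_length < 1:
            raise SimConfigError("read_length must be >= 1")
        if self.n_genotypes < 2:
            raise SimConfigError("need >= 2 genotypes (reference + others)")
        if len(self.expression_ratio) != self.n_subgenome_copies:
            raise SimConfigError(
                "expression_ratio must have one entry per subgenome copy"
            )
        if any(not (0.0 <= w <= 1.0) for w in self.expression_ratio):
            raise SimConfigError("expression_ratio entries must lie in [0,1]")
        if abs(sum(self.expression_ratio) - 1.0) > 1e-9:
            raise SimConfigError("expression_ratio must sum to 1")

    @property
    def genotype_names(self) -> tuple[str, ...]:
        if self.n_genotypes <= len(_DEFAULT_GENOTYPES):
            return _DEFAULT_GENOTYPES[: self.n_genotypes]
        extra = tuple(
            f"G{i}" for i in range(len(_DEFAULT_GENOTYPES), self.n_genotypes)
        )
        return _DEFAULT_GENOTYPES + extra

    @property
    def reference_genotype(self) -> str:
        return self.genotype_names[0]


@dataclass(frozen=True)
class Family:
    """One gene family: homoeolog copies and their reference contig(s)."""

    index: int
    collapsed: bool
    copies: tuple[str, ...]  # one sequence per subgenome copy
    ref_ids: tuple[str, ...]  # one id if collapsed, else one per copy

    def ref_id_for_copy(self, k: int) -> str:
        return self.ref_ids[0] if self.collapsed else self.ref_ids[k]


@dataclass
class SimulatedTranscriptomes:
    config: SimConfig
    reference: list[Contig]  # the reference contig assembly
    transcripts: dict[str, list[Contig]]  # per-genotype transcript copies
    truth: list[TruthVariant]
    families: list[Family]
    #: transcript id -> reference contig id it maps to
    transcript_to_ref: dict[str, str] = field(default_factory=dict)

    def reference_by_id(self) -> dict[str, Contig]:
        return {c.id: c for c in self.reference}


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_bases(
    rng: np.random.Generator, seq: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Substitute masked positions with a uniformly chosen different base."""
    out = seq.copy()
    idx = np.flatnonzero(mask)
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        codes = np.searchsorted(_BASES, out[idx])
        out[idx] = _BASES[(codes + shift) % 4]
    return out


def simulate_transcriptomes(config: SimConfig) -> SimulatedTranscriptomes:
    """Generate reference contigs, per-genotype transcripts and truth labels.

    Collapsed families contribute one reference contig (the first copy's
    consensus); positions where any homoeolog differs from it are labelled
    ``homoeolog_pseudo_snp``.  Allelic SNPs are planted at homoeolog-invariant
    positions, in every copy of the family at once, so that each carrier
    genotype is fixed for the alternative base.  Carrier sets are uniform
    nonempty subsets of the non-reference genotypes.
    """
    rng = np.random.default_rng(config.seed)
    names = config.genotype_names
    non_ref = names[1:]

    families: list[Family] = []
    truth: list[TruthVariant] = []
    reference: list[Contig] = []
    # genotype -> list of (transcript_id, mutable seq array)
    per_gt: dict[str, list[tuple[str, np.ndarray]]] = {g: [] for g in names}
    transcript_to_ref: dict[str, str] = {}

    for i in range(config.n_gene_families):
        length = int(
            np.clip(
                rng.normal(config.mean_contig_len, config.sd_contig_len),
                120,
                3000,
            )
        )
        base = _random_seq(rng, length)
        copies = [base]
        for _ in range(1, config.n_subgenome_copies):
            mask = rng.random(length) < config.homoeolog_divergence
            copies.append(_mutate_bases(rng, base, mask))

        collapsed = (
            config.n_subgenome_copies >= 2
            and rng.random() < config.collapse_prob
        )
        if collapsed:
            ref_ids = (f"c{i:05d}",)
            reference.append(
                Contig(ref_ids[0], base.tobytes().decode(), names[0])
            )
        else:
            ref_ids = tuple(
                f"c{i:05d}_{k}" for k in range(config.n_subgenome_copies)
            )
            for k, rid in enumerate(ref_ids):
                reference.append(
                    Contig(rid, copies[k].tobytes().decode(), names[0])
                )
        fam = Family(i, collapsed, tuple(c.tobytes().decode() for c in copies), ref_ids)
        families.append(fam)

        # pseudo-SNP truth: inter-homoeolog differences in collapsed families
        invariant = np.ones(length, dtype=bool)
        if collapsed:
            for k in range(1, config.n_subgenome_copies):
                diff = copies[k] != base
                invariant &= ~diff
                for p in np.flatnonzero(diff):
                    truth.append(
                        TruthVariant(
                            contig_id=ref_ids[0],
                            position=int(p) + 1,
                            ref_base=chr(base[p][0]),
                            alt_base=chr(copies[k][p][0]),
                            genotypes=frozenset(names),
                            label=LABEL_PSEUDO,
                        )
                    )

        # planted allelic SNPs at homoeolog-invariant reference positions
        snp_mask = (rng.random(length) < config.snp_rate) & invariant
        planted: dict[int, tuple[str, frozenset[str]]] = {}
        for p in np.flatnonzero(snp_mask):
            ref_b = chr(base[p][0])
            alt_b = "ACGT"[("ACGT".index(ref_b) + int(rng.integers(1, 4))) % 4]
            bitmask = int(rng.integers(1, 2 ** len(non_ref)))
            carriers = frozenset(
                g for j, g in enumerate(non_ref) if bitmask >> j & 1
            )
            planted[int(p)] = (alt_b, carriers)

        # emit truth per reference contig coordinate
        for p, (alt_b, carriers) in sorted(planted.items()):
            if collapsed:
                targets = [ref_ids[0]]
            else:
                targets = list(ref_ids)
            for rid in targets:
                truth.append(
                    TruthVariant(
                        contig_id=rid,
                        position=p + 1,
                        ref_base=chr(base[p][0]),
                        alt_base=alt_b,
                        genotypes=carriers,
                        label=LABEL_ALLELIC,
                    )
                )

        # build per-genotype transcript sequences
        for g in names:
            for k in range(config.n_subgenome_copies):
                seq = np.frombuffer(fam.copies[k].encode(), dtype="S1").copy()
                if g != names[0]:
                    for p, (alt_b, carriers) in planted.items():
                        if g in carriers:
                            seq[p] = alt_b.encode()
                rid = fam.ref_id_for_copy(k)
                tid = f"{rid}::copy{k}" if collapsed else rid
                per_gt[g].append((tid, seq))
                transcript_to_ref[tid] = rid

    transcripts = {
        g: [Contig(tid, seq.tobytes().decode(), g) for tid, seq in lst]
        for g, lst in per_gt.items()
    }
    return SimulatedTranscriptomes(
        config=config,
        reference=reference,
        transcripts=transcripts,
        truth=truth,
        families=families,
        transcript_to_ref=transcript_to_ref,
    )


# ---------------------------------------------------------------------------
# Read-level mode


def _copy_weight(config: SimConfig, fam: Family, k: int) -> float:
    return config.expression_ratio[k] if fam.collapsed else 1.0


def _apply_read_errors(
    rng: np.random.Generator, read: np.ndarray, config: SimConfig
) -> np.ndarray:
    if config.base_error > 0:
        mask = rng.random(read.size) < config.base_error
        read = _mutate_bases(rng, read, mask)
    if config.homopolymer_indel_rate > 0 and read.size >= 3:
        out: list[bytes] = []
        i = 0
        s = read.tobytes()
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            run = s[i:j]
            if j - i >= 3 and rng.random() < config.homopolymer_indel_rate:
                run = run + s[i : i + 1] if rng.random() < 0.5 else run[:-1]
            out.append(run)
            i = j
        read = np.frombuffer(b"".join(out), dtype="S1")
    return read


def simulate_reads(
    data: SimulatedTranscriptomes | Mapping[str, Sequence[Contig]],
    config: SimConfig | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Draw shotgun reads per genotype; returns (read id, sequence) lists.

    Coverage per transcript copy is Poisson with mean ``depth_lambda``
    (scaled by ``expression_ratio`` within collapsed families), with uniform
    start positions.  Substitution errors and homopolymer-run indels
    (runs >= 3, one base inserted or deleted) are applied per read.
    """
    if isinstance(data, SimulatedTranscriptomes):
        config = config or data.config
        fam_of = {
            c.id: data.families[int(data.transcript_to_ref[c.id][1:6])]
            for g in data.transcripts
            for c in data.transcripts[g]
        }
        copy_of = {
            c.id: (int(c.id.rsplit("::copy", 1)[1]) if "::copy" in c.id
                   else (int(c.id.rsplit("_", 1)[1]) if "_" in c.id[6:] else 0))
            for g in data.transcripts
            for c in data.transcripts[g]
        }
        transcripts = data.transcripts
    else:
        if config is None:
            raise ValueError("config required with a plain transcript mapping")
        transcripts = {g: list(seqs) for g, seqs in data.items()}
        fam_of, copy_of = {}, {}
    if not transcripts or all(not v for v in transcripts.values()):
        raise ValueError("no sequences to simulate reads from")

    rng = np.random.default_rng(config.seed + 1)
    reads: dict[str, list[tuple[str, str]]] = {}
    for g in transcripts:
        out: list[tuple[str, str]] = []
        for c in transcripts[g]:
            if len(c) == 0:
                raise ValueError(f"zero-length sequence {c.id!r}")
            fam = fam_of.get(c.id)
            weight = (
                _copy_weight(config, fam, copy_of[c.id]) if fam is not None else 1.0
            )
            if weight == 0.0:
                continue
            rlen = min(config.read_length, len(c))
            n_reads = rng.poisson(config.depth_lambda * weight * len(c) / rlen)
            seq = np.frombuffer(c.sequence.encode(), dtype="S1")
            starts = rng.integers(0, len(c) - rlen + 1, size=n_reads)
            for r, s0 in enumerate(sorted(starts.tolist())):
                read = _apply_read_errors(rng, seq[s0 : s0 + rlen], config)
                out.append((f"{g}|{c.id}|{r}", read.tobytes().decode()))
        reads[g] = out
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) reads as FASTQ with a constant quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Record-level mode


@dataclass
class SimulatedTables:
    """Record-level output: mapper-style tables with matching truth."""

    config: SimConfig
    data: SimulatedTranscriptomes
    records: dict[str, list[VariantRecord]]  # per genotype, incl. reference
    truth: list[TruthVariant]

    def truth_label(self, rec: VariantRecord) -> str:
        key = (rec.contig_id, rec.start, rec.var_allele)
        for tv in self._index().get(key, ()):
            if rec.genotype in tv.genotypes:
                return tv.label
        return LABEL_ERROR

    def _index(self):
        if not hasattr(self, "_idx"):
            idx: dict[tuple[str, int, str], list[TruthVariant]] = {}
            for tv in self.truth:
                idx.setdefault((tv.contig_id, tv.position, tv.alt_base), []).append(tv)
            self._idx = idx
        return self._idx


def simulate_variant_tables(config: SimConfig) -> SimulatedTables:
    """Produce per-genotype variant tables directly from the truth model.

    Column depths are Poisson(``depth_lambda``) clipped to >= 1.  A fixed
    allelic SNP yields frequency 100 exactly when ``base_error`` is zero
    (otherwise errors knock individual reads back to reference).  A collapsed
    homoeolog site yields a binomial alt count with success probability equal
    to the summed expression weight of the copies carrying the alternative
    base, so its frequency is typically below 100.  Sequencing-error records
    are planted per column with binomial miscall counts and labelled
    ``error``.
    """
    data = simulate_transcriptomes(config)
    rng = np.random.default_rng(config.seed + 2)
    names = config.genotype_names
    ref_by_id = data.reference_by_id()

    records: dict[str, list[VariantRecord]] = {g: [] for g in names}
    truth_pos: dict[str, set[int]] = {}
    for tv in data.truth:
        truth_pos.setdefault(tv.contig_id, set()).add(tv.position)

    def depth() -> int:
        return max(1, int(rng.poisson(config.depth_lambda)))

    for tv in data.truth:
        if tv.label == LABEL_ALLELIC:
            for g in names:
                if g not in tv.genotypes:
                    continue
                d = depth()
                alt = d if config.base_error == 0 else int(
                    rng.binomial(d, 1.0 - config.base_error)
                )
                if alt == 0:
                    continue
                records[g].append(
                    VariantRecord(
                        tv.contig_id, tv.position, tv.position,
                        tv.ref_base, tv.alt_base,
                        100.0 * alt / d, d, g,
                    )
                )
        elif tv.label == LABEL_PSEUDO:
            fam = data.families[int(tv.contig_id[1:6])]
            w = sum(
                config.expression_ratio[k]
                for k in range(config.n_subgenome_copies)
                if fam.copies[k][tv.position - 1] == tv.alt_base
            )
            for g in names:
                d = depth()
                alt = int(rng.binomial(d, w * (1.0 - config.base_error)))
                if alt == 0:
                    continue
                records[g].append(
                    VariantRecord(
                        tv.contig_id, tv.position, tv.position,
                        tv.ref_base, tv.alt_base,
                        100.0 * alt / d, d, g,
                    )
                )

    if config.base_error > 0:
        for contig in data.reference:
            L = len(contig)
            occupied = truth_pos.get(contig.id, set())
            for g in names:
                d_vec = np.maximum(1, rng.poisson(config.depth_lambda, size=L))
                err = rng.binomial(d_vec, config.base_error)
                for p in np.flatnonzero(err):
                    pos = int(p) + 1
                    if pos in occupied:
                        continue
                    ref_b = contig.sequence[p]
                    if ref_b not in "ACGT":
                        continue
                    alt_b = "ACGT"[("ACGT".index(ref_b) + int(rng.integers(1, 4))) % 4]
                    records[g].append(
                        VariantRecord(
                            contig.id, pos, pos, ref_b, alt_b,
                            100.0 * int(err[p]) / int(d_vec[p]),
                            int(d_vec[p]), g,
                        )
                    )

    for g in names:
        records[g].sort(key=lambda r: (r.contig_id, r.start, r.var_allele))
    return SimulatedTables(config=config, data=data, records=records, truth=data.truth)


# ---------------------------------------------------------------------------
# Truth table serialization

TRUTH_HEADER = "contig_id\tposition\tref\talt\tgenotypes\tlabel"


def write_ground_truth(truth: Sequence[TruthVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_HEADER + "\n")
        for tv in truth:
            gts = ",".join(sorted(tv.genotypes))
            fh.write(
                f"{tv.contig_id}\t{tv.position}\t{tv.ref_base}\t{tv.alt_base}"
                f"\t{gts}\t{tv.label}\n"
            )


def read_ground_truth(path: str | Path) -> list[TruthVariant]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != TRUTH_HEADER:
            raise ValueError(f"{path}: bad ground-truth header")
        for line in fh:
            cid, pos, ref, alt, gts, label = line.rstrip("\n").split("\t")
            out.append(
                TruthVariant(cid, int(pos), ref, alt,
                             frozenset(gts.split(",")) if gts else frozenset(),
                             label)
            )
    return out
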