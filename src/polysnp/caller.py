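"""Read placement and candidate variant calling against the reference assembly.

A minimal, deterministic stand-in for the reference-mapper step: each read is
placed by banded edit-distance alignment (band = 10% of read length) at its
best-scoring contig/offset, ties broken by (contig id, offset).  Every column
where at least one read disagrees with the reference emits one record per
observed non-reference allele, which is exactly the "call all sequence
differences" behaviour the downstream filter cascade assumes.

One record per column and allele is emitted; multi-column events are not
aggregated into single rows.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .records import Contig, VariantRecord

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class Placement:
    """One read placed on a contig; start is 1-based on the contig."""

    read_id: str
    read_seq: str
    contig_id: str
    start: int
    cigar: str  # edlib extended cigar: = X I D (I/D relative to the read)
    edit_distance: int


@dataclass
class PileupColumn:
    contig_id: str
    position: int  # 1-based
    ref_base: str
    counts: Counter  # symbol in {A,C,G,T,N,-} -> read count

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def align_reads(
    reads: Sequence[tuple[str, str]],
    reference: Sequence[Contig] | Mapping[str, Contig],
    band_fraction: float = 0.1,
) -> tuple[list[Placement], list[str]]:
    """Place each read on its best contig; returns (placements, unplaced ids).

    The alignment is semi-global (read fully aligned inside the contig) with
    at most ``ceil(band_fraction * len(read))`` edits allowed.  Among equal
    best scores the lexicographically smallest (contig id, offset) wins.
    """
    if not reads:
        raise ValueError("no reads to align")
    if isinstance(reference, Mapping):
        contigs = [reference[k] for k in sorted(reference)]
    else:
        contigs = sorted(reference, key=lambda c: c.id)
    if not contigs:
        raise ValueError("empty reference")

    placements: list[Placement] = []
    unplaced: list[str] = []
    for rid, seq in reads:
        k = max(0, int(band_fraction * len(seq) + 0.999999))
        best: tuple[int, str, int, str] | None = None  # (dist, cid, start0, cigar)
        for contig in contigs:
            res = edlib.align(seq, contig.sequence, mode="HW", task="path", k=k)
            dist = res["editDistance"]
            if dist < 0:
                continue
            start0 = min(loc[0] for loc in res["locations"])
            cand = (dist, contig.id, start0)
            if best is None or cand < best[:3]:
                if start0 != res["locations"][0][0]:
                    # re-align pinned to the smallest-offset location
                    res = edlib.align(
                        seq,
                        contig.sequence[start0 : start0 + len(seq) + dist],
                        mode="SHW",
                        task="path",
                        k=dist,
                    )
                best = (dist, contig.id, start0, res["cigar"])
                k = dist  # tighten the band: only better or tie-winning hits matter
        if best is None:
            unplaced.append(rid)
        else:
            dist, cid, start0, cigar = best
            # normalize boundary ambiguity: when a same-score global alignment
            # against the equal-length slice exists, prefer it — it trades
            # edge indels for substitutions, keeping columns anchored
            target = next(c for c in contigs if c.id == cid)
            window = target.sequence[start0 : start0 + len(seq)]
            if len(window) == len(seq):
                res_nw = edlib.align(seq, window, mode="NW", task="path")
                if res_nw["editDistance"] == dist:
                    cigar = res_nw["cigar"]
            placements.append(Placement(rid, seq, cid, start0 + 1, cigar, dist))
    return placements, unplaced


def build_pileup(
    placements: Iterable[Placement],
    reference: Sequence[Contig] | Mapping[str, Contig],
) -> dict[tuple[str, int], PileupColumn]:
    """Accumulate per-column base counts from placed reads.

    Read deletions count as the ``-`` symbol at the deleted reference
    column; read insertions count as an insertion-allele at the reference
    column preceding the inserted bases.  N counts toward depth as its own
    allele class.
    """
    if not isinstance(reference, Mapping):
        reference = {c.id: c for c in reference}
    columns: dict[tuple[str, int], PileupColumn] = {}
    inserts: dict[tuple[str, int], Counter] = {}

    def col(cid: str, pos: int) -> PileupColumn:
        key = (cid, pos)
        if key not in columns:
            columns[key] = PileupColumn(
                cid, pos, reference[cid].sequence[pos - 1], Counter()
            )
        return columns[key]

    for pl in placements:
        if pl.contig_id not in reference:
            raise ValueError(f"placement on unknown contig {pl.contig_id!r}")
        rpos = 0  # index into the read
        tpos = pl.start  # 1-based position on the contig
        ops = _CIGAR_RE.findall(pl.cigar)
        for op_idx, (n_str, op) in enumerate(ops):
            n = int(n_str)
            if op == "I" and op_idx in (0, len(ops) - 1):
                # a boundary insertion is alignment-ambiguous (an equal-cost
                # substitution exists just outside the placement); skip it
                rpos += n
                continue
            if op in "=X":
                for j in range(n):
                    col(pl.contig_id, tpos + j).counts[pl.read_seq[rpos + j]] += 1
                rpos += n
                tpos += n
            elif op == "D":  # bases in the contig absent from the read
                for j in range(n):
                    col(pl.contig_id, tpos + j).counts["-"] += 1
                tpos += n
            else:  # 'I': extra bases in the read
                anchor = max(1, tpos - 1)
                inserts.setdefault((pl.contig_id, anchor), Counter())[
                    pl.read_seq[rpos : rpos + n]
                ] += 1
                rpos += n

    # attach insertion alleles to their anchor columns; the '+' prefix keeps
    # them out of the base-depth sum
    for key, ctr in inserts.items():
        if key in columns:
            for ins_seq, n in ctr.items():
                columns[key].counts[f"+{ins_seq}"] = n
    return columns


def call_variants(
    placements: Sequence[Placement],
    reference: Sequence[Contig] | Mapping[str, Contig],
    genotype: str,
) -> list[VariantRecord]:
    """Emit one record per column per observed non-reference allele.

    ``frequency_pct`` = 100 * allele reads / column depth.  Deletions carry
    ``-`` as the variant allele; insertions carry ``-`` as the reference
    allele and the inserted bases as the variant.
    """
    columns = build_pileup(placements, reference)
    out: list[VariantRecord] = []
    for (cid, pos), column in sorted(columns.items()):
        ins_alleles = {
            sym: n for sym, n in column.counts.items() if sym.startswith("+")
        }
        base_counts = {
            sym: n
            for sym, n in column.counts.items()
            if not sym.startswith("+") and n > 0
        }
        depth = sum(base_counts.values())
        if depth == 0:
            continue
        for sym in sorted(base_counts):
            if sym == column.ref_base:
                continue
            n = base_counts[sym]
            out.append(
                VariantRecord(
                    cid, pos, pos, column.ref_base, sym,
                    100.0 * n / depth, depth, genotype,
                )
            )
        for sym in sorted(ins_alleles):
            n = ins_alleles[sym]
            if n == 0:
                continue
            out.append(
                VariantRecord(
                    cid, pos, pos, "-", sym[1:], 100.0 * n / depth, depth, genotype
                )
            )
    return out
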