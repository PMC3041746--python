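"""Downstream marker genetics.

Two kinds of marker call tables are handled:

* RIL mode — bi-allelic calls in {A, B, H} plus missing, scored for
  segregation ratio and distortion against the 1:1 expectation of a
  recombinant-inbred population;
* diversity mode — multi-state melt-curve calls (nucleotide alleles plus
  supplementary states In, Del, Het, Null), coded into a binary presence/
  absence matrix for Dice similarity and UPGMA clustering.

The distortion test (plain 1-df chi-square against 1:1, no continuity
correction) is an extension beyond the published segregation-ratio column
and is labelled as such in the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = "."
SUPPLEMENTARY_STATES = ("In", "Del", "Het", "Null")
NUCLEOTIDES = frozenset("ACGT")


@dataclass
class MarkerCallTable:
    """Markers x individuals call matrix; ``mode`` is 'ril' or 'diversity'."""

    calls: pd.DataFrame  # index = marker ids, columns = individual ids
    mode: str = "ril"

    def __post_init__(self) -> None:
        if self.mode not in ("ril", "diversity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.calls.isna().any().any():
            raise ValueError(f"every (marker, individual) cell needs one call; use {MISSING!r}")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: str = "ril") -> "MarkerCallTable":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        return cls(calls=df, mode=mode)

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t")

    @property
    def markers(self) -> list[str]:
        return list(self.calls.index)

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.columns)


# ---------------------------------------------------------------------------
# Segregation scoring (RIL mode)


@dataclass(frozen=True)
class SegregationResult:
    marker: str
    n_a: int
    n_b: int
    n_h: int
    n_missing: int
    sr: float | None  # parent-A / parent-B allele count ratio; None if n_b == 0
    chi_square: float | None
    p_value: float | None
    distorted: bool
    het_fraction: float
    het_excess: bool


def score_segregation(
    table: MarkerCallTable,
    call_a: str = "A",
    call_b: str = "B",
    call_h: str = "H",
    alpha: float = 0.05,
    het_threshold: float = 0.4,
) -> list[SegregationResult]:
    """Score each marker's segregation in the RIL population.

    SR is oriented parent-A over parent-B (the first-listed parent's allele
    in the numerator).  The chi-square (1 df, vs 1:1 over the homozygous
    classes) flags distortion at ``alpha``; markers whose heterozygous
    fraction reaches ``het_threshold`` are flagged as probable multi-locus
    amplification rather than single Mendelian loci.
    """
    if table.mode != "ril":
        raise ValueError("segregation scoring needs a RIL-mode table")
    out = []
    for marker in table.markers:
        row = table.calls.loc[marker]
        n_a = int((row == call_a).sum())
        n_b = int((row == call_b).sum())
        n_h = int((row == call_h).sum())
        n_missing = len(row) - n_a - n_b - n_h
        scored = n_a + n_b + n_h
        het_fraction = n_h / scored if scored else 0.0
        if n_a + n_b > 0:
            chi2, p = stats.chisquare([n_a, n_b])
            chi2, p = float(chi2), float(p)
        else:
            chi2 = p = None
        out.append(
            SegregationResult(
                marker=marker,
                n_a=n_a, n_b=n_b, n_h=n_h, n_missing=n_missing,
                sr=(n_a / n_b) if n_b > 0 else None,
                chi_square=chi2,
                p_value=p,
                distorted=(p is not None and p < alpha),
                het_fraction=het_fraction,
                het_excess=het_fraction >= het_threshold,
            )
        )
    return out


def segregation_frame(results: Sequence[SegregationResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results]).set_index("marker")
    return df


# ---------------------------------------------------------------------------
# Diversity coding and similarity


def code_binary(
    table: MarkerCallTable,
    het_mode: str = "state",
) -> pd.DataFrame:
    """Code a diversity table into individuals x allele-state indicators.

    One column per observed allele state per marker.  Null scores 0 in all of
    its marker's columns (no amplification = absence everywhere); missing
    scores NaN across the marker's columns and is handled pairwise in the
    similarity step.  Het is its own state column by default (``state``); in
    ``expand`` mode a call like ``A/G`` scores 1 in both constituent allele
    columns, an unresolved ``Het`` falls back to its own column.
    """
    if table.mode != "diversity":
        raise ValueError("binary coding needs a diversity-mode table")
    if het_mode not in ("state", "expand"):
        raise ValueError(f"unknown het_mode {het_mode!r}")
    columns: dict[str, pd.Series] = {}
    for marker in table.markers:
        row = table.calls.loc[marker]
        observed: list[str] = []
        for call in row:
            if call in (MISSING, "Null"):
                continue
            if het_mode == "expand" and "/" in call:
                for part in call.split("/"):
                    if part not in observed:
                        observed.append(part)
            elif call not in observed:
                observed.append(call)
        if not observed:
            import warnings

            warnings.warn(f"marker {marker!r} has no observed states; dropped")
            continue
        for state in observed:
            vals = []
            for call in row:
                if call == MISSING:
                    vals.append(np.nan)
                elif call == "Null":
                    vals.append(0.0)
                elif het_mode == "expand" and "/" in call:
                    vals.append(1.0 if state in call.split("/") else 0.0)
                else:
                    vals.append(1.0 if call == state else 0.0)
            columns[f"{marker}:{state}"] = pd.Series(vals, index=table.individuals)
    return pd.DataFrame(columns)


def dice_similarity(binary: pd.DataFrame) -> pd.DataFrame:
    """Dice's index S = 2a / (2a + b + c) over pairwise-complete columns.

    a = shared presences, b/c = presences unique to either individual.
    Columns where either individual is missing (NaN) are dropped for that
    pair.  When 2a + b + c = 0 the similarity is defined as 0.
    """
    if len(binary) < 2:
        raise ValueError("need >= 2 individuals")
    x = binary.to_numpy(dtype=float)
    n = x.shape[0]
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ok = ~(np.isnan(x[i]) | np.isnan(x[j]))
            a = float(np.nansum(x[i][ok] * x[j][ok]))
            bi = float(x[i][ok].sum())
            bj = float(x[j][ok].sum())
            denom = bi + bj  # = 2a + b + c
            s = 2.0 * a / denom if denom > 0 else 0.0
            sim[i, j] = sim[j, i] = s
    return pd.DataFrame(sim, index=binary.index, columns=binary.index)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    height: float
    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def leaves(self) -> list[str]:
        if self.children is None:
            return [self.label]
        return self.children[0].leaves + self.children[1].leaves


@dataclass
class Dendrogram:
    """Rooted ultrametric UPGMA tree with Newick serialization."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaves)

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.children is None:
                return f"{node.label}:{bl:.10g}"
            left = render(node.children[0], node.height)
            right = render(node.children[1], node.height)
            return f"({left},{right}):{bl:.10g}"

        if self.root.children is None:
            return f"{self.root.label}:0;"
        left = render(self.root.children[0], self.root.height)
        right = render(self.root.children[1], self.root.height)
        return f"({left},{right});"

    def merge_heights(self) -> list[float]:
        out = []

        def walk(node: TreeNode) -> None:
            if node.children is not None:
                out.append(node.height)
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return sorted(out)


def upgma(similarity: pd.DataFrame) -> Dendrogram:
    """Average-linkage clustering of 1 - similarity with deterministic ties.

    Inter-cluster distance is the size-weighted arithmetic mean of member
    distances; a merge is placed at half the merged distance.  Among equal
    minimum distances the pair with the lexicographically smallest
    (smallest-member, smallest-member) label pair is merged first.
    """
    labels = list(similarity.index)
    mat = similarity.to_numpy(dtype=float)
    if list(similarity.columns) != labels or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric with matching labels")
    dist = {
        frozenset((a, b)): 1.0 - float(similarity.loc[a, b])
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
    }
    clusters: dict[str, tuple[TreeNode, int]] = {
        lab: (TreeNode(0.0, label=lab), 1) for lab in labels
    }
    # a cluster is keyed by its lexicographically smallest member label
    while len(clusters) > 1:
        keys = sorted(clusters)
        best_pair = min(
            ((a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]),
            key=lambda p: (dist[frozenset(p)], p),
        )
        a, b = best_pair
        d_ab = dist[frozenset((a, b))]
        node_a, n_a = clusters.pop(a)
        node_b, n_b = clusters.pop(b)
        merged = TreeNode(d_ab / 2.0, children=(node_a, node_b))
        for other in clusters:
            d_new = (
                n_a * dist.pop(frozenset((a, other)))
                + n_b * dist.pop(frozenset((b, other)))
            ) / (n_a + n_b)
            dist[frozenset((a, other))] = d_new
        dist.pop(frozenset((a, b)), None)
        clusters[a] = (merged, n_a + n_b)  # a < b, so the key stays minimal
    (root, _), = clusters.values()
    return Dendrogram(root=root)


# ---------------------------------------------------------------------------
# Allele accounting (diversity mode)


@dataclass(frozen=True)
class AlleleSummary:
    n_markers: int
    total_alleles: int
    mean_alleles_per_marker: float  # rounded to 2 decimals
    snp_alleles: int
    supplementary_alleles: int
    n_insertion_deletion: int
    n_het: int
    n_null: int
    per_marker: tuple[tuple[str, int], ...]


def allele_summary(table: MarkerCallTable) -> AlleleSummary:
    """Count distinct observed allele states per marker and in total.

    Single-nucleotide states (A/C/G/T) count as SNP alleles; In, Del, Het and
    Null count as supplementary (non-SNP) alleles.  Missing is never a state.
    """
    if table.mode != "diversity":
        raise ValueError("allele accounting needs a diversity-mode table")
    per_marker = []
    snp = indel = het = null = 0
    for marker in table.markers:
        states = sorted(set(table.calls.loc[marker]) - {MISSING})
        per_marker.append((marker, len(states)))
        for s in states:
            if s in NUCLEOTIDES:
                snp += 1
            elif s in ("In", "Del"):
                indel += 1
            elif s == "Het" or "/" in s:
                het += 1
            elif s == "Null":
                null += 1
            else:
                raise ValueError(f"marker {marker!r}: unknown allele state {s!r}")
    total = sum(n for _, n in per_marker)
    return AlleleSummary(
        n_markers=len(per_marker),
        total_alleles=total,
        mean_alleles_per_marker=round(total / len(per_marker), 2) if per_marker else 0.0,
        snp_alleles=snp,
        supplementary_alleles=indel + het + null,
        n_insertion_deletion=indel,
        n_het=het,
        n_null=null,
        per_marker=tuple(per_marker),
    )
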