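"""Segregation scoring, binary coding, Dice similarity, UPGMA clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polysnp.popgen import (
    MISSING,
    MarkerCallTable,
    allele_summary,
    code_binary,
    dice_similarity,
    score_segregation,
    upgma,
)


def ril_table(rows: dict[str, str]) -> MarkerCallTable:
    data = {m: list(calls) for m, calls in rows.items()}
    df = pd.DataFrame.from_dict(data, orient="index")
    df.columns = [f"ril{j}" for j in range(df.shape[1])]
    return MarkerCallTable(calls=df, mode="ril")


def div_table(rows: dict[str, list[str]]) -> MarkerCallTable:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"ind{j}" for j in range(df.shape[1])]
    return MarkerCallTable(calls=df, mode="diversity")


# ---------------------------------------------------------------------------
# segregation


def test_balanced_marker_not_distorted():
    (r,) = score_segregation(ril_table({"m1": "A" * 50 + "B" * 50}))
    assert (r.sr, r.chi_square, r.distorted) == (1.0, 0.0, False)


def test_sr_ratio_orientation():
    (r,) = score_segregation(ril_table({"m1": "A" * 45 + "B" * 50}))
    assert round(r.sr, 2) == 0.90


def test_het_excess_flagged_at_half():
    (r,) = score_segregation(ril_table({"m1": "A" * 30 + "B" * 30 + "H" * 60}))
    assert r.het_fraction == 0.5
    assert r.het_excess
    assert not r.distorted  # homozygous classes are still balanced


def test_missing_parent_b_reported_not_crash():
    (r,) = score_segregation(ril_table({"m1": "A" * 20 + "." * 5}))
    assert r.sr is None
    assert r.n_missing == 5


def test_strong_distortion_flagged():
    (r,) = score_segregation(ril_table({"m1": "A" * 90 + "B" * 30}))
    assert r.distorted
    assert round(r.sr, 1) == 3.0


def test_type_i_rate_calibrated_under_true_1_to_1():
    """1,000 markers x 136 RILs at true 1:1: flag rate 0.05 +/- 0.02."""
    rng = np.random.default_rng(77)
    calls = rng.choice(["A", "B"], size=(1000, 136))
    df = pd.DataFrame(calls, index=[f"m{i}" for i in range(1000)],
                      columns=[f"ril{j}" for j in range(136)])
    results = score_segregation(MarkerCallTable(calls=df, mode="ril"))
    rate = sum(r.distorted for r in results) / len(results)
    assert 0.03 <= rate <= 0.07


# ---------------------------------------------------------------------------
# binary coding


def test_two_state_marker_codes_one_hot():
    binary = code_binary(div_table({"m1": ["X", "Y", "X"]}))
    assert list(binary.columns) == ["m1:X", "m1:Y"]
    assert binary.loc["ind0"].tolist() == [1.0, 0.0]


def test_null_codes_all_zero():
    binary = code_binary(div_table({"m1": ["X", "Y", "Null"]}))
    assert binary.loc["ind2"].tolist() == [0.0, 0.0]


def test_column_count_is_total_observed_states():
    binary = code_binary(
        div_table(
            {
                "m1": ["A", "G", "A", "G"],
                "m2": ["A", "C", "In", "A"],
                "m3": ["C", "T", "In", "Del"],
            }
        )
    )
    assert binary.shape[1] == 9


def test_het_expand_mode_sets_both_constituents():
    binary = code_binary(div_table({"m1": ["A", "G", "A/G"]}), het_mode="expand")
    assert list(binary.columns) == ["m1:A", "m1:G"]
    assert binary.loc["ind2"].tolist() == [1.0, 1.0]


def test_het_state_mode_gets_own_column():
    binary = code_binary(div_table({"m1": ["A", "G", "Het"]}))
    assert "m1:Het" in binary.columns


def test_missing_codes_nan():
    binary = code_binary(div_table({"m1": ["A", "G", MISSING]}))
    assert binary.loc["ind2"].isna().all()


# ---------------------------------------------------------------------------
# Dice


def _dice_oracle(u, v):
    """Set-overlap restatement: 2|U & V| / (|U| + |V|)."""
    su = {i for i, x in enumerate(u) if x}
    sv = {i for i, x in enumerate(v) if x}
    if not su and not sv:
        return 0.0
    return 2 * len(su & sv) / (len(su) + len(sv))


def test_dice_trivial_pairs():
    m = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1], [0, 0, 0]], index=list("abc"), dtype=float
    )
    s = dice_similarity(m)
    assert s.loc["a", "b"] == 0.5  # a=1, b=1, c=1
    assert s.loc["a", "a"] == 1.0
    assert s.loc["c", "c"] == 0.0  # no presences: defined as 0
    assert s.loc["a", "c"] == 0.0


def test_dice_equals_set_overlap_oracle_on_all_length6_pairs():
    vectors = list(itertools.product([0, 1], repeat=6))
    m = pd.DataFrame(vectors, dtype=float)
    s = dice_similarity(m)
    for i, u in enumerate(vectors):
        for j, v in enumerate(vectors):
            assert s.iloc[i, j] == pytest.approx(_dice_oracle(u, v))


def test_dice_pairwise_complete_drops_missing_columns():
    m = pd.DataFrame(
        [[1.0, 1.0, 0.0], [1.0, np.nan, 1.0]], index=["a", "b"]
    )
    s = dice_similarity(m)
    # only columns 0 and 2 compared: a=(1,0), b=(1,1) -> 2/3
    assert s.loc["a", "b"] == pytest.approx(2 / 3)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.lists(st.integers(0, 1), min_size=5, max_size=5),
        min_size=2,
        max_size=8,
    )
)
def test_dice_symmetry_range_diagonal(rows):
    m = pd.DataFrame(rows, dtype=float)
    s = dice_similarity(m).to_numpy()
    assert np.allclose(s, s.T)
    assert ((0.0 <= s) & (s <= 1.0)).all()
    for i, row in enumerate(rows):
        assert s[i, i] == (1.0 if any(row) else 0.0)


# ---------------------------------------------------------------------------
# UPGMA


def sim_from_dist(d: pd.DataFrame) -> pd.DataFrame:
    return 1.0 - d


def _upgma_oracle(labels, d0):
    """Brute-force UPGMA: cluster distances recomputed from the original
    matrix as the plain mean over member pairs (no update formula)."""
    clusters = [frozenset([l]) for l in labels]
    heights = []

    def cdist(a, b):
        return float(np.mean([d0.loc[x, y] for x in a for y in b]))

    while len(clusters) > 1:
        best = None
        for i, a in enumerate(clusters):
            for b in clusters[i + 1 :]:
                key = (cdist(a, b), tuple(sorted((min(a), min(b)))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_, a, b) = best
        heights.append(best[0][0] / 2.0)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return sorted(heights)


def test_two_taxa_merge_at_half_distance():
    d = pd.DataFrame([[0, 0.4], [0.4, 0]], index=list("ab"), columns=list("ab"))
    tree = upgma(sim_from_dist(d))
    assert tree.root.height == pytest.approx(0.2)
    assert sorted(tree.root.leaves) == ["a", "b"]


def test_zero_distance_merges_at_height_zero():
    d = pd.DataFrame([[0, 0.0], [0.0, 0]], index=list("ab"), columns=list("ab"))
    assert upgma(sim_from_dist(d)).root.height == 0.0


def test_four_taxon_hand_worked_example():
    # d(a,b)=0.2 merge first at 0.1; d(c,d)=0.3 at 0.15;
    # d({ab},{cd}) = mean(0.6,0.6,0.6,0.6) = 0.6 -> root at 0.3
    labels = list("abcd")
    d = pd.DataFrame(
        [
            [0.0, 0.2, 0.6, 0.6],
            [0.2, 0.0, 0.6, 0.6],
            [0.6, 0.6, 0.0, 0.3],
            [0.6, 0.6, 0.3, 0.0],
        ],
        index=labels,
        columns=labels,
    )
    tree = upgma(sim_from_dist(d))
    assert tree.merge_heights() == pytest.approx([0.1, 0.15, 0.3])
    kids = sorted(sorted(ch.leaves) for ch in tree.root.children)
    assert kids == [["a", "b"], ["c", "d"]]


def test_upgma_matches_brute_force_oracle_on_random_matrices():
    rng = np.random.default_rng(5)
    for n in (3, 4, 5):
        for _ in range(40):
            labels = [f"t{i}" for i in range(n)]
            x = np.round(rng.uniform(0.05, 1.0, size=(n, n)), 3)
            d = pd.DataFrame((x + x.T) / 2, index=labels, columns=labels)
            np.fill_diagonal(d.values, 0.0)
            tree = upgma(sim_from_dist(d))
            assert tree.merge_heights() == pytest.approx(
                _upgma_oracle(labels, d), abs=1e-9
            )


def test_upgma_is_ultrametric():
    rng = np.random.default_rng(6)
    n = 7
    x = rng.uniform(0.1, 1.0, size=(n, n))
    d = pd.DataFrame((x + x.T) / 2, index=[f"t{i}" for i in range(n)],
                     columns=[f"t{i}" for i in range(n)])
    np.fill_diagonal(d.values, 0.0)
    tree = upgma(sim_from_dist(d))

    def check(node):
        if node.children:
            for ch in node.children:
                assert ch.height <= node.height + 1e-12
                check(ch)

    check(tree.root)


def test_upgma_agrees_with_scipy_average_linkage():
    """Independent cross-check against hierarchical average linkage."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    rng = np.random.default_rng(7)
    n = 6
    x = rng.uniform(0.1, 1.0, size=(n, n))
    dmat = (x + x.T) / 2
    np.fill_diagonal(dmat, 0.0)
    labels = [f"t{i}" for i in range(n)]
    d = pd.DataFrame(dmat, index=labels, columns=labels)
    tree = upgma(sim_from_dist(d))
    link = average(squareform(dmat))
    assert tree.merge_heights() == pytest.approx(sorted(link[:, 2] / 2.0))


def test_asymmetric_matrix_rejected():
    d = pd.DataFrame([[1.0, 0.3], [0.4, 1.0]], index=list("ab"), columns=list("ab"))
    with pytest.raises(ValueError):
        upgma(d)


def test_newick_round_trip_preserves_topology_and_heights():
    import dendropy

    labels = list("abcde")
    rng = np.random.default_rng(8)
    x = rng.uniform(0.1, 1.0, size=(5, 5))
    d = pd.DataFrame((x + x.T) / 2, index=labels, columns=labels)
    np.fill_diagonal(d.values, 0.0)
    tree = upgma(sim_from_dist(d))
    parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    # root-to-leaf path lengths equal the root height for every leaf
    for leaf in parsed.leaf_node_iter():
        assert leaf.distance_from_root() == pytest.approx(
            tree.root.height, abs=1e-9
        )
    # internal node ages reproduce the merge heights
    parsed.calc_node_ages(ultrametricity_precision=1e-6)
    ages = sorted(nd.age for nd in parsed.preorder_internal_node_iter())
    assert ages == pytest.approx(tree.merge_heights(), abs=1e-9)


# ---------------------------------------------------------------------------
# allele accounting


def test_biallelic_marker_counts_two():
    s = allele_summary(div_table({"m1": ["A", "G", "A"]}))
    assert (s.total_alleles, s.mean_alleles_per_marker) == (2, 2.0)
    assert s.snp_alleles == 2 and s.supplementary_alleles == 0


def test_supplementary_partition():
    s = allele_summary(
        div_table(
            {
                "m1": ["A", "G", "In", "Null"],
                "m2": ["C", "T", "Del", "Het"],
            }
        )
    )
    assert s.snp_alleles == 4
    assert (s.n_insertion_deletion, s.n_het, s.n_null) == (2, 1, 1)
    assert s.supplementary_alleles == 4
    assert s.mean_alleles_per_marker == 4.0


def test_ril_table_rejected_for_diversity_ops():
    t = ril_table({"m1": "AB"})
    with pytest.raises(ValueError):
        allele_summary(t)
    with pytest.raises(ValueError):
        code_binary(t)
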