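"""Enrichment statistics against independent brute-force oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidont.enrichment import (
    ContingencyTable,
    EnrichmentOptions,
    bh_adjust,
    fisher_enrichment,
    fisher_pvalue,
    ks_dplus,
    ks_enrichment,
    ks_pvalue,
    local_statistic,
    rank_lipids,
    run_enrichment,
)
from lipidont.simulate import PlantedTruth, make_abundance_matrix


# -- oracles -----------------------------------------------------------------


def hypergeom_upper_tail(a, target, annotated, universe):
    """Explicit hypergeometric sum P(X >= a), exact rational arithmetic."""
    num = sum(
        math.comb(annotated, k) * math.comb(universe - annotated, target - k)
        for k in range(a, min(annotated, target) + 1)
    )
    return Fraction(num, math.comb(universe, target))


def ks_permutation_null(n, m):
    """Integer KS statistic T for every m-subset of ranks 1..n."""
    stats_ = []
    for subset in itertools.combinations(range(1, n + 1), m):
        stats_.append(max(i * n - s * m for i, s in enumerate(subset, 1)))
    return stats_


def bh_by_hand(pvalues):
    """Step-up formula applied literally: q_(i) = min_{j>=i} m p_(j) / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * pvalues[j] / (rank + 1) for rank, j in
                list(enumerate(order))[pos - 1:]),
            1.0,
        )
    return q


# -- Fisher ------------------------------------------------------------------


def test_fisher_matches_hypergeometric_oracle_small_tables():
    """Exhaustive over all tables with grand total <= 16."""
    worst = 0.0
    for N in range(1, 17):
        for K in range(N + 1):
            for n in range(1, N + 1):
                for a in range(max(0, n + K - N), min(K, n) + 1):
                    p = fisher_pvalue(a, n, K, N)
                    oracle = float(hypergeom_upper_tail(a, n, K, N))
                    worst = max(worst, abs(p - oracle))
    assert worst <= 1e-12


def test_fisher_specific_table():
    """Universe 100 (10 annotated), target 10 with a=5."""
    oracle = float(hypergeom_upper_tail(5, 10, 10, 100))
    assert fisher_pvalue(5, 10, 10, 100) == pytest.approx(oracle, abs=1e-12)


def test_fisher_target_equals_annotated_is_tail_mass_minimum():
    """With target = annotated set exactly, p equals the probability of the
    single most extreme table for those margins."""
    N, K = 12, 4
    p = fisher_pvalue(K, K, K, N)
    # enumerate all tables with margins (target=K, annotated=K):
    probs = {
        a: float(hypergeom_upper_tail(a, K, K, N) - hypergeom_upper_tail(a + 1, K, K, N))
        for a in range(K + 1)
    }
    assert p == pytest.approx(probs[K], abs=1e-12)
    assert p == pytest.approx(min(
        fisher_pvalue(a, K, K, N) for a in range(K + 1)), abs=1e-15)


def test_fisher_term_annotating_whole_universe_is_never_enriched(toy_ontology):
    universe = set(toy_ontology.species)
    target = set(list(universe)[:10])
    report = fisher_enrichment(target, universe, toy_ontology)
    full = report.frame[report.frame.n_annotated == len(universe)]
    assert len(full) > 0  # branch roots annotate everything
    assert (full.p_raw == 1.0).all()


def test_fisher_target_must_be_subset_of_universe(toy_ontology):
    universe = set(list(toy_ontology.species)[:20])
    target = {"PC(16:0_16:0)", "not-in-universe"}
    with pytest.raises(ValueError):
        fisher_enrichment(target, universe, toy_ontology)


def test_fisher_target_equals_universe_yields_no_enrichment(toy_ontology):
    universe = set(toy_ontology.species)
    report = fisher_enrichment(universe, universe, toy_ontology)
    assert (report.frame.p_raw == 1.0).all()


def test_contingency_table_counts_must_be_nonnegative():
    with pytest.raises(ValueError):
        ContingencyTable(1, -1, 2, 3)


# -- local statistics --------------------------------------------------------


def _matrix(rows):
    return pd.DataFrame(
        rows,
        index=[f"L{i}" for i in range(len(rows))],
        columns=["a1", "a2", "a3", "b1", "b2", "b3"],
    )


LABELS = pd.Series(
    ["A", "A", "A", "B", "B", "B"], index=["a1", "a2", "a3", "b1", "b2", "b3"]
)


def test_welch_identical_groups_gives_half():
    m = _matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
    p = local_statistic(m, LABELS, "welch_t_p")
    assert p.iloc[0] == pytest.approx(0.5)


def test_welch_matches_scipy_per_row():
    rng = np.random.default_rng(0)
    m = _matrix(rng.lognormal(size=(5, 6)))
    p = local_statistic(m, LABELS, "welch_t_p", interest="A", reference="B")
    from scipy import stats

    for i in range(5):
        expected = stats.ttest_ind(
            m.iloc[i, :3], m.iloc[i, 3:], equal_var=False, alternative="greater"
        ).pvalue
        assert p.iloc[i] == pytest.approx(expected)


def test_welch_needs_two_samples_per_group():
    m = _matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
    labels = pd.Series(["A", "B", "B", "B", "B", "B"], index=m.columns)
    with pytest.raises(ValueError):
        local_statistic(m, labels, "welch_t_p")


def test_log2_fold_change_simple_ratio():
    m = _matrix([[4.0, 4.0, 4.0, 2.0, 2.0, 2.0]])
    v = local_statistic(m, LABELS, "log2_fold_change", interest="A")
    assert v.iloc[0] == pytest.approx(1.0)


def test_log2_fold_change_zero_handling():
    m = _matrix([
        [0.0, 0.0, 0.0, 2.0, 2.0, 2.0],   # zero mean of interest: pseudocount
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],   # all-zero: neutral 0
        [4.0, 4.0, 4.0, 2.0, 2.0, 2.0],
    ])
    v = local_statistic(m, LABELS, "log2_fold_change", interest="A")
    pseudo = 0.5 * 2.0  # half the minimum positive value of the matrix
    assert v.iloc[0] == pytest.approx(np.log2(pseudo / (2.0 + pseudo)))
    assert v.iloc[1] == 0.0
    assert v.iloc[2] == pytest.approx(1.0)


def test_anova_flat_groups_give_p_one():
    # same values in every group: between-group SS = 0, F = 0, p = 1
    m = pd.DataFrame(
        [[1.0, 2.0, 1.0, 2.0, 1.0, 2.0]],
        index=["L0"],
        columns=["a1", "a2", "b1", "b2", "c1", "c2"],
    )
    labels = pd.Series(["A", "A", "B", "B", "C", "C"], index=m.columns)
    p = local_statistic(m, labels, "anova_f_p")
    assert p.iloc[0] == pytest.approx(1.0)


def test_custom_statistic_passes_through():
    m = _matrix([[1, 1, 1, 1, 1, 1]] * 3)
    v = local_statistic(m, LABELS, "custom",
                        custom_values={"L0": 3.0, "L1": 1.0, "L2": 2.0})
    assert v.tolist() == [3.0, 1.0, 2.0]


# -- ranking -----------------------------------------------------------------


def test_rank_pvalues_most_significant_first():
    ranked = rank_lipids({"l1": 0.9, "l2": 0.01, "l3": 0.5}, "welch_t_p")
    assert ranked.species == ("l2", "l3", "l1")
    assert ranked.direction == "low_to_high"


def test_rank_fold_change_high_to_low_and_manual_override():
    values = {"l1": -1.0, "l2": 2.0, "l3": 0.5}
    ranked = rank_lipids(values, "log2_fold_change")
    assert ranked.species == ("l2", "l3", "l1")
    flipped = rank_lipids(values, "log2_fold_change",
                          manual_direction="low_to_high")
    assert flipped.species == tuple(reversed(ranked.species))


def test_rank_ties_break_deterministically_by_name():
    values = {"b": 0.5, "a": 0.5, "c": 0.1}
    r1 = rank_lipids(values, "welch_t_p")
    r2 = rank_lipids(dict(reversed(values.items())), "welch_t_p")
    assert r1.species == r2.species == ("c", "a", "b")


def test_rank_nonfinite_values_go_last():
    ranked = rank_lipids({"l1": np.nan, "l2": 0.01}, "welch_t_p")
    assert ranked.species == ("l2", "l1")


# -- KS ----------------------------------------------------------------------


def test_ks_dplus_worked_example():
    """n = 5, annotated at ranks {1, 2}: D+ = max(1/2 - 1/5, 1 - 2/5) = 0.6."""
    d, t = ks_dplus(5, [1, 2])
    assert d == pytest.approx(0.6)
    oracle = ks_permutation_null(5, 2)
    expected = sum(x >= t for x in oracle) / len(oracle)
    assert ks_pvalue(5, 2, t) == pytest.approx(expected, abs=1e-12)


def test_ks_exact_pvalue_matches_permutation_null_exhaustively():
    """All (n <= 12, m <= n) subsets, observed p vs exhaustive tail mass."""
    worst = 0.0
    for n in range(2, 13):
        for m in range(1, n + 1):
            null = ks_permutation_null(n, m)
            total = len(null)
            for subset, t_obs in zip(
                itertools.combinations(range(1, n + 1), m), null
            ):
                p = ks_pvalue(n, m, t_obs)
                oracle = sum(x >= t_obs for x in null) / total
                worst = max(worst, abs(p - oracle))
    assert worst <= 1e-9


def test_ks_term_annotating_everything_gives_p_one(toy_ontology):
    names = sorted(toy_ontology.species)[:30]
    ranked = rank_lipids({n: float(i) for i, n in enumerate(names)}, "custom")
    report = ks_enrichment(ranked, toy_ontology)
    full = report.frame[report.frame.n_annotated == len(names)]
    assert len(full) > 0
    assert np.allclose(full.p_raw, 1.0)


def test_ks_pvalue_monotone_as_ranks_move_up():
    """Moving an annotated lipid one rank higher never increases p."""
    n, m = 10, 3
    for subset in itertools.combinations(range(1, n + 1), m):
        _, t = ks_dplus(n, subset)
        p = ks_pvalue(n, m, t)
        for i, s in enumerate(subset):
            if s - 1 >= 1 and s - 1 not in subset:
                moved = sorted(subset[:i] + (s - 1,) + subset[i + 1:])
                _, t2 = ks_dplus(n, moved)
                assert ks_pvalue(n, m, t2) <= p + 1e-12


def test_ks_large_m_uses_smirnov_tail():
    # m > 50 falls back to the one-sided Smirnov distribution
    from scipy import stats

    n, m = 200, 60
    ranks = list(range(1, m + 1))  # all at the top
    d, t = ks_dplus(n, ranks)
    assert ks_pvalue(n, m, t) == pytest.approx(float(stats.ksone.sf(d, m)))


# -- BH ----------------------------------------------------------------------


def test_bh_step_up_worked_example():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_tied_pvalues():
    assert bh_adjust([0.2]) == pytest.approx([0.2])
    assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_matches_hand_oracle_and_is_order_invariant(pvals):
    q = bh_adjust(pvals)
    assert np.allclose(q, bh_by_hand(pvals), atol=1e-12)
    perm = list(reversed(pvals))
    q_perm = bh_adjust(perm)
    assert np.allclose(q_perm, list(reversed(q.tolist())), atol=1e-12)
    # monotone: smaller p never gets a larger q
    for i in range(len(pvals)):
        for j in range(len(pvals)):
            if pvals[i] <= pvals[j]:
                assert q[i] <= q[j] + 1e-12


def test_bh_cross_checked_against_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.random(40)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(bh_adjust(p), q_sm)


# -- orchestration -----------------------------------------------------------


@pytest.fixture(scope="module")
def planted_run():
    from lipidont.simulate import make_toy_ontology

    ontology = make_toy_ontology(n_classes=4)
    planted = PlantedTruth("diacylglycerophosphocholines", 4.0, "treated", seed=42)
    matrix, labels, _ = make_abundance_matrix(
        ontology, 3, ("treated", "control"), planted
    )
    return ontology, matrix, labels, planted


def test_restriction_changes_family_never_praw(planted_run):
    ontology, matrix, labels, _ = planted_run
    base = run_enrichment("ranking", ontology, matrix=matrix, group_labels=labels)
    restricted = run_enrichment(
        "ranking", ontology, matrix=matrix, group_labels=labels,
        options=EnrichmentOptions(term_subset=("contains fatty acid",)),
    )
    sub = set(restricted.frame.term_id)
    root = ontology.resolve_term("contains fatty acid")
    allowed = set(ontology.descendants(root)) | {root}
    assert sub <= allowed
    joined = restricted.frame.merge(base.frame, on="term_id", suffixes=("_r", "_b"))
    assert np.allclose(joined.p_raw_r, joined.p_raw_b)
    assert not np.allclose(joined.q_value_r, joined.q_value_b)  # family differs


def test_restriction_unknown_term_is_an_error(planted_run):
    ontology, matrix, labels, _ = planted_run
    from lipidont.ontology import LipidOntologyError

    with pytest.raises(LipidOntologyError):
        run_enrichment(
            "ranking", ontology, matrix=matrix, group_labels=labels,
            options=EnrichmentOptions(term_subset=("no such term",)),
        )


def test_pruned_report_drops_redundant_ancestor(planted_run):
    ontology, matrix, labels, _ = planted_run
    pruned = run_enrichment(
        "ranking", ontology, matrix=matrix, group_labels=labels,
        options=EnrichmentOptions(prune_redundant=True),
    )
    base = run_enrichment("ranking", ontology, matrix=matrix, group_labels=labels)
    dropped = set(base.frame.term_id) - set(pruned.frame.term_id)
    assert dropped  # e.g. glycerophosphocholines == diacylglycerophosphocholines
    child = ontology.resolve_term("diacylglycerophosphocholines")
    parent = ontology.resolve_term("glycerophosphocholines")
    assert parent in dropped
    assert child in set(pruned.frame.term_id)
    # pruning never changes surviving rows' statistics
    joined = pruned.frame.merge(base.frame, on="term_id", suffixes=("_p", "_b"))
    assert np.allclose(joined.q_value_p, joined.q_value_b)


def test_planted_term_recovered_in_both_modes(planted_run):
    ontology, matrix, labels, planted = planted_run
    tid = ontology.resolve_term(planted.planted_term)

    ranking = run_enrichment("ranking", ontology, matrix=matrix,
                             group_labels=labels, local_stat="welch_t_p")
    row = ranking.frame[ranking.frame.term_id == tid].iloc[0]
    assert row.q_value < 0.05

    hits = sorted(ontology.species_of_term(tid) & set(matrix.index))
    target = run_enrichment(
        "target_list", ontology, target_names=hits,
        universe_names=sorted(matrix.index),
    )
    row = target.frame[target.frame.term_id == tid].iloc[0]
    assert row.q_value < 0.05
    # the planted term is tied for the smallest p in the report (other class
    # terms sharing the identical species set tie with it)
    assert row.p_raw == pytest.approx(target.frame.p_raw.min())


def test_report_csv_is_stable_across_runs(planted_run, tmp_path):
    ontology, matrix, labels, _ = planted_run
    paths = []
    for i in range(2):
        report = run_enrichment("ranking", ontology, matrix=matrix,
                                group_labels=labels)
        path = tmp_path / f"run{i}.csv"
        report.to_csv(path)
        paths.append(path.read_bytes())
    assert paths[0] == paths[1]


def test_significance_labels_but_never_filters(planted_run):
    ontology, matrix, labels, _ = planted_run
    report = run_enrichment("ranking", ontology, matrix=matrix,
                            group_labels=labels,
                            options=EnrichmentOptions(alpha=1e-30))
    assert len(report) > 0
    assert not report.frame.significant.any()
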