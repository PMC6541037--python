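"""Ontology term enrichment statistics for lipidomic datasets.

Two modes are supported, mirroring gene-set enrichment practice:

* **Target-list mode** — a lipid subset of interest (from thresholding or
  clustering) is compared against the full background of matched lipids.
  For every candidate term a 2x2 contingency table is built and tested with
  a one-tailed Fisher exact test (over-representation only: the upper
  hypergeometric tail ``P(X >= a)``).

* **Ranking mode** — all matched lipids are ordered by a per-lipid "local"
  statistic (one-tailed Welch t-test p-value, log2 fold change, one-way
  ANOVA F-test p-value, or user-supplied values).  Each term is then tested
  with a one-sided Kolmogorov-Smirnov comparison of the ranks of its
  annotated lipids against uniform placement; enrichment means
  over-representation of highly ranked lipids.

Every term is tested independently against its full closed annotation set
("classic" algorithm semantics — no parent/child decorrelation), raw
p-values are Benjamini-Hochberg adjusted over the family of terms actually
tested, and the most generic term of ancestor/descendant pairs annotating
identical lipid sets can optionally be pruned from the report.

The KS null here is the *rank permutation* null: the annotated lipids occupy
a uniformly random size-m subset of the n ranks.  The p-value is computed
exactly for m <= 50 by an integer dynamic program over subsets (the
statistic ``D+ = max_i(i/m - r_i/n)`` scaled by ``m*n`` is an integer), and
by the one-sided Smirnov distribution for larger m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import MatchReport, match_names
from .ontology import Ontology

__all__ = [
    "ContingencyTable",
    "RankedList",
    "EnrichmentOptions",
    "EnrichmentReport",
    "fisher_enrichment",
    "fisher_pvalue",
    "local_statistic",
    "rank_lipids",
    "ks_enrichment",
    "ks_dplus",
    "ks_pvalue",
    "bh_adjust",
    "run_enrichment",
    "LOCAL_STATISTICS",
]

LOCAL_STATISTICS = ("welch_t_p", "log2_fold_change", "anova_f_p", "custom")

#: Largest annotated-set size for which the exact permutation-null KS
#: p-value is computed; beyond this the one-sided Smirnov distribution
#: (continuous-sample approximation) is used.
KS_EXACT_MAX_M = 50


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table for one term: target/background vs annotated/not."""

    a: int  # target and annotated
    b: int  # target, not annotated
    c: int  # background (non-target) and annotated
    d: int  # background, not annotated

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class RankedList:
    """Lipid node names in rank order with the local values that ordered them."""

    species: tuple[str, ...]
    local_values: tuple[float, ...]
    statistic_name: str
    direction: str  # "high_to_low" or "low_to_high"

    def __post_init__(self) -> None:
        if len(self.species) != len(set(self.species)):
            raise ValueError("ranked list contains duplicate species")
        if self.direction not in ("high_to_low", "low_to_high"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class EnrichmentOptions:
    """Knobs shared by both enrichment modes.

    term_subset restricts testing (and the BH family) to the listed terms
    plus their descendants; min_term_size drops terms annotating fewer
    matched lipids; alpha only labels rows as significant, it never filters.
    """

    term_subset: tuple[str, ...] | None = None
    prune_redundant: bool = False
    min_term_size: int = 1
    alpha: float = 0.05


class EnrichmentReport:
    """Per-term enrichment results, sorted by q-value."""

    COLUMNS = ["term_id", "term_name", "branch", "n_annotated", "statistic",
               "p_raw", "q_value", "significant"]

    def __init__(self, frame: pd.DataFrame, mode: str,
                 match_report: MatchReport | None = None,
                 universe_size: int | None = None) -> None:
        self.frame = frame.reset_index(drop=True)
        self.mode = mode
        self.match_report = match_report
        self.universe_size = universe_size

    def __len__(self) -> int:
        return len(self.frame)

    def summary(self) -> pd.DataFrame:
        return self.frame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def significant_terms(self) -> list[str]:
        return list(self.frame.loc[self.frame["significant"], "term_id"])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped at 1, mapped back to the
    input order; invariant under permutation of the input.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# -- candidate-term bookkeeping ---------------------------------------------


def _term_species_map(
    ontology: Ontology,
    universe: Sequence[str],
    options: EnrichmentOptions,
) -> dict[str, frozenset[str]]:
    """Map candidate term id -> universe species annotated to it (closed)."""
    term_sets: dict[str, set[str]] = {}
    for name in universe:
        for tid in ontology.closed_annotations(name):
            term_sets.setdefault(tid, set()).add(name)
    candidates = set(term_sets)
    if options.term_subset is not None:
        allowed: set[str] = set()
        for key in options.term_subset:
            tid = ontology.resolve_term(key)
            allowed.add(tid)
            allowed |= ontology.descendants(tid)
        candidates &= allowed
    min_size = max(1, options.min_term_size)
    return {
        tid: frozenset(term_sets[tid])
        for tid in sorted(candidates)
        if len(term_sets[tid]) >= min_size
    }


def _prune_rows(
    ontology: Ontology,
    term_sets: Mapping[str, frozenset[str]],
) -> set[str]:
    """Terms to drop: ancestors annotating the same species set as a tested
    descendant (only the most specific term is kept)."""
    dropped: set[str] = set()
    candidates = set(term_sets)
    for tid in term_sets:
        for anc in ontology.ancestors(tid) & candidates:
            if term_sets[anc] == term_sets[tid]:
                dropped.add(anc)
    return dropped


def _finish_report(
    ontology: Ontology,
    rows: list[dict],
    term_sets: Mapping[str, frozenset[str]],
    options: EnrichmentOptions,
    mode: str,
    match_report: MatchReport | None,
    universe_size: int,
) -> EnrichmentReport:
    frame = pd.DataFrame(rows, columns=EnrichmentReport.COLUMNS[:-2])
    frame["q_value"] = bh_adjust(frame["p_raw"].to_numpy()) if len(frame) else []
    frame["significant"] = frame["q_value"] < options.alpha
    if options.prune_redundant and len(frame):
        dropped = _prune_rows(ontology, term_sets)
        frame = frame[~frame["term_id"].isin(dropped)]
    frame = frame.sort_values(
        ["q_value", "p_raw", "term_id"], kind="stable"
    ).reset_index(drop=True)
    return EnrichmentReport(frame, mode, match_report, universe_size)


# -- target-list mode --------------------------------------------------------


def fisher_pvalue(a: int, target_size: int, annotated: int, universe: int) -> float:
    """One-tailed Fisher exact p for over-representation.

    Probability of drawing at least ``a`` annotated lipids when sampling
    ``target_size`` lipids without replacement from a universe of
    ``universe`` lipids of which ``annotated`` carry the term:
    the hypergeometric upper tail ``P(X >= a)``.
    """
    if not 0 <= a <= min(target_size, annotated):
        raise ValueError("inconsistent contingency counts")
    return float(min(stats.hypergeom.sf(a - 1, universe, annotated, target_size), 1.0))


def fisher_enrichment(
    target: set[str],
    universe: set[str],
    ontology: Ontology,
    options: EnrichmentOptions | None = None,
    match_report: MatchReport | None = None,
) -> EnrichmentReport:
    """One-tailed Fisher exact over-representation test per candidate term.

    ``target`` and ``universe`` are canonical species-node names;
    ``target`` must be a subset of ``universe``.  The p-value for a term
    annotating K of N universe lipids, a of them in the size-n target, is
    the hypergeometric upper tail ``P(X >= a)``.
    """
    options = options or EnrichmentOptions()
    if not target:
        raise ValueError("target set is empty")
    extra = target - universe
    if extra:
        raise ValueError(f"target is not a subset of the universe: {sorted(extra)[:5]}")
    term_sets = _term_species_map(ontology, sorted(universe), options)
    N, n_target = len(universe), len(target)
    rows = []
    for tid, annotated in term_sets.items():
        a = len(target & annotated)
        K = len(annotated)
        table = ContingencyTable(a, n_target - a, K - a, N - K - (n_target - a))
        term = ontology.terms[tid]
        rows.append(
            {"term_id": tid, "term_name": term.name, "branch": term.branch,
             "n_annotated": K, "statistic": table.odds_ratio,
             "p_raw": fisher_pvalue(a, n_target, K, N)}
        )
    return _finish_report(ontology, rows, term_sets, options, "target_list",
                          match_report, N)


# -- local statistics and ranking -------------------------------------------


def _split_groups(
    matrix: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
) -> dict[str, list[str]]:
    labels = pd.Series(dict(group_labels)) if not isinstance(group_labels, pd.Series) \
        else group_labels
    missing = [s for s in matrix.columns if s not in labels.index]
    if missing:
        raise ValueError(f"samples without condition label: {missing}")
    groups: dict[str, list[str]] = {}
    for sample in matrix.columns:  # preserve listing order of conditions
        groups.setdefault(str(labels[sample]), []).append(sample)
    return groups


def local_statistic(
    matrix: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    method: str,
    interest: str | None = None,
    reference: str | None = None,
    custom_values: Mapping[str, float] | pd.Series | None = None,
) -> pd.Series:
    """Per-lipid local statistic used to rank the lipids of a dataset.

    ``matrix`` is lipids x samples.  For the two-condition statistics the
    condition of interest defaults to the first-listed condition; the Welch
    p-value is one-tailed for "interest greater than reference" with
    Welch-Satterthwaite degrees of freedom.  ``log2_fold_change`` applies a
    half-minimum-positive pseudocount to zero means; all-zero lipids get the
    neutral value 0.
    """
    if method not in LOCAL_STATISTICS:
        raise ValueError(f"unknown local statistic {method!r}")
    if method == "custom":
        if custom_values is None:
            raise ValueError("custom statistic requires custom_values")
        return pd.Series(dict(custom_values), dtype=float).reindex(matrix.index)

    groups = _split_groups(matrix, group_labels)
    names = list(groups)
    if method in ("welch_t_p", "log2_fold_change"):
        if len(names) != 2:
            raise ValueError(f"{method} needs exactly 2 conditions, got {names}")
        interest = interest or names[0]
        if interest not in groups:
            raise ValueError(f"unknown condition {interest!r}")
        reference = reference or next(n for n in names if n != interest)
        x = matrix[groups[interest]].to_numpy(float)
        y = matrix[groups[reference]].to_numpy(float)
        if method == "welch_t_p":
            if x.shape[1] < 2 or y.shape[1] < 2:
                raise ValueError("Welch t-test needs >= 2 samples per condition")
            res = stats.ttest_ind(x, y, axis=1, equal_var=False,
                                  alternative="greater", nan_policy="omit")
            return pd.Series(res.pvalue, index=matrix.index)
        mx = np.nanmean(x, axis=1)
        my = np.nanmean(y, axis=1)
        values = np.asarray(matrix.to_numpy(float))
        positive = values[np.isfinite(values) & (values > 0)]
        pseudo = 0.5 * positive.min() if positive.size else 0.0
        out = np.zeros(len(matrix))
        both_zero = (mx == 0) & (my == 0)
        needs_pc = ((mx == 0) | (my == 0)) & ~both_zero
        plain = ~both_zero & ~needs_pc
        out[plain] = np.log2(mx[plain] / my[plain])
        out[needs_pc] = np.log2((mx[needs_pc] + pseudo) / (my[needs_pc] + pseudo))
        return pd.Series(out, index=matrix.index)

    # one-way ANOVA F-test
    if len(names) < 2:
        raise ValueError("ANOVA needs >= 2 conditions")
    arrays = []
    for name in names:
        arr = matrix[groups[name]].to_numpy(float)
        if arr.shape[1] < 2:
            raise ValueError(f"condition {name!r} has < 2 samples")
        arrays.append(arr)
    res = stats.f_oneway(*arrays, axis=1)
    return pd.Series(res.pvalue, index=matrix.index)


#: Default ranking direction per local statistic: p-values put the most
#: significant lipid first; fold changes put the largest increase first.
_DEFAULT_DIRECTION = {
    "welch_t_p": "low_to_high",
    "anova_f_p": "low_to_high",
    "log2_fold_change": "high_to_low",
    "custom": "high_to_low",
}


def rank_lipids(
    values: Mapping[str, float] | pd.Series,
    statistic_name: str,
    manual_direction: str | None = None,
) -> RankedList:
    """Order lipids by a local statistic into a :class:`RankedList`.

    Ties (and non-finite values, which are placed last) are broken
    deterministically by canonical name, making downstream KS p-values
    reproducible across runs.
    """
    if statistic_name not in LOCAL_STATISTICS:
        raise ValueError(f"unknown local statistic {statistic_name!r}")
    series = values if isinstance(values, pd.Series) else pd.Series(dict(values))
    direction = manual_direction or _DEFAULT_DIRECTION[statistic_name]
    if direction not in ("high_to_low", "low_to_high"):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == "low_to_high" else -1.0

    def key(item):
        name, v = item
        finite = np.isfinite(v)
        return (not finite, sign * v if finite else 0.0, name)

    ordered = sorted(series.items(), key=key)
    return RankedList(
        species=tuple(name for name, _ in ordered),
        local_values=tuple(float(v) for _, v in ordered),
        statistic_name=statistic_name,
        direction=direction,
    )


# -- one-sided KS under the rank-permutation null ----------------------------


def ks_dplus(n: int, ranks: Sequence[int]) -> tuple[float, int]:
    """One-sided KS statistic of m annotated ranks within a list of n.

    Returns ``(D+, T)`` where ``D+ = max_i (i/m - r_i/n)`` over the sorted
    annotated ranks and ``T = D+ * m * n`` is the equivalent integer
    statistic used for exact p-value computation.
    """
    s = sorted(ranks)
    m = len(s)
    if m == 0:
        raise ValueError("no annotated ranks")
    if s[0] < 1 or s[-1] > n:
        raise ValueError("ranks must lie in 1..n")
    t = max(i * n - si * m for i, si in enumerate(s, start=1))
    return t / (m * n), t


def ks_pvalue(n: int, m: int, t: int) -> float:
    """P(T >= t) for the integer one-sided KS statistic under the null that
    the m annotated lipids occupy a uniformly random subset of the n ranks.

    Exact (integer dynamic program over rank subsets) for m <= 50; the
    one-sided Smirnov distribution is used as the large-m approximation.
    """
    if m < 1 or m > n:
        raise ValueError("need 1 <= m <= n")
    if t <= 0:
        return 1.0
    if m > KS_EXACT_MAX_M:
        return float(stats.ksone.sf(t / (m * n), m))
    # Count subsets with T < t: for all i, s_i >= L_i with
    # L_i = floor((i*n - t)/m) + 1  (from s_i * m > i*n - t).
    lower = [((i * n - t) // m) + 1 for i in range(1, m + 1)]
    prev = [0] * (n + 1)
    prev[0] = 1
    for i in range(1, m + 1):
        lo = max(lower[i - 1], i)
        cur = [0] * (n + 1)
        run = 0
        for j in range(1, n + 1):
            run += prev[j - 1]
            if j >= lo:
                cur[j] = run
        prev = cur
    count_below = sum(prev)
    total = math.comb(n, m)
    return float(Fraction(total - count_below, total))


def ks_enrichment(
    ranked: RankedList,
    ontology: Ontology,
    options: EnrichmentOptions | None = None,
    match_report: MatchReport | None = None,
) -> EnrichmentReport:
    """One-sided KS enrichment of every candidate term over a ranked list.

    For each term the empirical distribution of its annotated lipids' ranks
    is compared against uniform placement; the statistic is ``D+`` (maximal
    excess of annotated lipids near the top of the list).
    """
    options = options or EnrichmentOptions()
    n = len(ranked.species)
    if n < 2:
        raise ValueError("ranked list needs at least 2 lipids")
    rank_of = {name: i for i, name in enumerate(ranked.species, start=1)}
    term_sets = _term_species_map(ontology, ranked.species, options)
    rows = []
    for tid, annotated in term_sets.items():
        ranks = [rank_of[name] for name in annotated]
        m = len(ranks)
        dplus, t = ks_dplus(n, ranks)
        p = ks_pvalue(n, m, t)
        term = ontology.terms[tid]
        rows.append(
            {"term_id": tid, "term_name": term.name, "branch": term.branch,
             "n_annotated": m, "statistic": dplus, "p_raw": p}
        )
    return _finish_report(ontology, rows, term_sets, options, "ranking",
                          match_report, n)


# -- orchestration -----------------------------------------------------------


def run_enrichment(
    mode: str,
    ontology: Ontology,
    target_names: Sequence[str] | None = None,
    universe_names: Sequence[str] | None = None,
    matrix: pd.DataFrame | None = None,
    group_labels: Mapping[str, str] | pd.Series | None = None,
    local_stat: str = "welch_t_p",
    custom_values: Mapping[str, float] | None = None,
    manual_direction: str | None = None,
    interest: str | None = None,
    reference: str | None = None,
    options: EnrichmentOptions | None = None,
) -> EnrichmentReport:
    """Match input lipid names against the ontology and run one enrichment.

    In ``"target_list"`` mode, ``target_names`` and ``universe_names`` are raw
    lipid names; unmatched names are excluded and reported, never fatal.  In
    ``"ranking"`` mode the row names of ``matrix`` are matched; rows that
    collapse onto the same ontology node are summed before the local
    statistic is computed.
    """
    options = options or EnrichmentOptions()
    if mode == "target_list":
        if not target_names or not universe_names:
            raise ValueError("target-list mode needs target_names and universe_names")
        uni_map, uni_report = match_names(list(universe_names), ontology)
        tgt_map, _ = match_names(list(target_names), ontology)
        universe = set(uni_map.values())
        target = {node for raw, node in tgt_map.items()} & universe
        missing = set(tgt_map.values()) - universe
        if missing:
            raise ValueError(
                f"target lipids outside the universe: {sorted(missing)[:5]}"
            )
        if not target:
            raise ValueError("no target lipid matched the ontology")
        return fisher_enrichment(target, universe, ontology, options, uni_report)

    if mode == "ranking":
        if matrix is None:
            raise ValueError("ranking mode needs an abundance matrix")
        mapping, report = match_names(list(matrix.index), ontology)
        matched = matrix.loc[[r for r in matrix.index if r in mapping]].copy()
        matched.index = [mapping[r] for r in matched.index]
        collapsed = matched.groupby(level=0).sum(min_count=1)
        if local_stat == "custom":
            if custom_values is None:
                raise ValueError("custom statistic requires custom_values")
            mapped_values: dict[str, float] = {}
            for raw, v in dict(custom_values).items():
                node = mapping.get(raw, raw if raw in ontology.species else None)
                if node is not None:
                    mapped_values[node] = float(v)
            values = pd.Series(mapped_values).reindex(collapsed.index)
        else:
            values = local_statistic(collapsed, group_labels, local_stat,
                                     interest=interest, reference=reference)
        ranked = rank_lipids(values, local_stat, manual_direction)
        return ks_enrichment(ranked, ontology, options, report)

    raise ValueError(f"unknown mode {mode!r}")
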