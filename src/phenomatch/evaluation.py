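"""Benchmark evaluation: confusion curves, lift, enrichment and proximity.

A score table is benchmarked against labeled positive gene–drug pairs.  The
benchmark universe follows the construction used for curated drug–target
sets: the positives plus *all* combinations of the drugs and genes that
appear in at least one positive (so every drug and gene in the universe has
some supporting evidence).  Sweeping a threshold over the scores yields one
confusion point per distinct score — tied pairs cross the threshold together
— from which precision, TPR, FPR, accuracy and lift derive:

    lift = precision / prevalence,   prevalence = P / (P + N)

Also here: the binned enrichment profile, the causal side-effect fraction
(how many of a pair's contributing side effects are independently known to
be caused through the gene's protein), the one-sided rank-sum comparison of
high- vs low-scoring pairs, shortest-hop PPI proximity to known targets, and
the frequency-binned mapping-coverage analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkSet",
    "EvaluationCurve",
    "build_benchmark",
    "confusion_curve",
    "lift_at",
    "threshold_at_precision",
    "binned_lift",
    "causal_se_fraction",
    "compare_high_low",
    "ppi_min_distance",
    "mapping_coverage_by_frequency",
    "GENE_FREQUENCY_BIN_EDGES",
    "DRUG_FREQUENCY_BIN_EDGES",
]

# frequency-of-occurrence bins: 1, ]1,5], ]5,10], ]10,50], ]50,100], >100;
# drug-side terms recur so much that two extra bins ]100,500], >500 are added
GENE_FREQUENCY_BIN_EDGES = (1, 5, 10, 50, 100)
DRUG_FREQUENCY_BIN_EDGES = (1, 5, 10, 50, 100, 500)


@dataclass
class BenchmarkSet:
    """Labeled pairs over an explicit universe."""

    positives: frozenset[tuple[str, str]]
    universe: tuple[tuple[str, str], ...]
    scores: dict[tuple[str, str], float]

    @property
    def labels(self) -> np.ndarray:
        pos = self.positives
        return np.array([pair in pos for pair in self.universe], dtype=bool)

    @property
    def score_array(self) -> np.ndarray:
        return np.array([self.scores[pair] for pair in self.universe])

    @property
    def n_positive(self) -> int:
        return len(self.positives)

    @property
    def n_negative(self) -> int:
        return len(self.universe) - len(self.positives)


def build_benchmark(
    positives: Iterable[tuple[str, str]],
    score_table: pd.DataFrame,
    universe_mode: str = "cross_product",
) -> BenchmarkSet:
    """Assemble a benchmark from positive (drug_id, gene_id) pairs and scores.

    ``cross_product`` (default) sets the universe to all combinations of the
    drugs and genes appearing in at least one usable positive; ``scored``
    uses every scored pair.  Positives referencing entities absent from the
    score table are dropped (their count is logged on the result as
    ``n_unmatched``).
    """
    scores = {
        (d, g): s
        for d, g, s in zip(
            score_table["drug_id"], score_table["gene_id"], score_table["normalized"]
        )
    }
    scored_drugs = set(score_table["drug_id"])
    scored_genes = set(score_table["gene_id"])

    usable, unmatched = set(), 0
    for d, g in positives:
        if d in scored_drugs and g in scored_genes:
            usable.add((d, g))
        else:
            unmatched += 1
    if not usable:
        raise ValueError("no positive pair matches the scored entities")

    if universe_mode == "cross_product":
        drugs = sorted({d for d, _ in usable})
        genes = sorted({g for _, g in usable})
        universe = tuple((d, g) for d in drugs for g in genes)
    elif universe_mode == "scored":
        universe = tuple(sorted(scores))
    else:
        raise ValueError(f"unknown universe mode: {universe_mode!r}")

    bench = BenchmarkSet(
        positives=frozenset(usable), universe=universe, scores=scores
    )
    bench.n_unmatched = unmatched  # type: ignore[attr-defined]
    return bench


@dataclass
class EvaluationCurve:
    """Threshold-ordered confusion counts with derived rates and ROC AUC.

    ``points`` has one row per distinct score, thresholds descending, with
    columns threshold, TP, FP, TN, FN, precision, tpr, fpr, accuracy, lift.
    """

    points: pd.DataFrame
    auc: float
    n_positive: int
    n_negative: int

    @property
    def prevalence(self) -> float:
        return self.n_positive / (self.n_positive + self.n_negative)


def confusion_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> EvaluationCurve:
    """Build the full evaluation curve for scored, labeled pairs.

    The classifier at threshold t calls every pair with score >= t positive;
    equal scores enter together, so tie ordering cannot influence any rate.
    AUC is the trapezoid area under (FPR, TPR) including the (0, 0) origin.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    P = int(labels.sum())
    N = int(len(labels) - P)
    if P == 0 or N == 0:
        raise ValueError("need at least one positive and one negative label")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    cum_tp = np.cumsum(l_sorted)
    cum_fp = np.cumsum(~l_sorted)
    # last index of each tie block = counts with all tied pairs included
    distinct_mask = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    idx = np.flatnonzero(distinct_mask)

    tp = cum_tp[idx]
    fp = cum_fp[idx]
    fn = P - tp
    tn = N - fp
    thr = s_sorted[idx]
    precision = tp / (tp + fp)
    tpr = tp / P
    fpr = fp / N
    accuracy = (tp + tn) / (P + N)
    prevalence = P / (P + N)
    lift = precision / prevalence

    points = pd.DataFrame(
        {
            "threshold": thr,
            "TP": tp,
            "FP": fp,
            "TN": tn,
            "FN": fn,
            "precision": precision,
            "tpr": tpr,
            "fpr": fpr,
            "accuracy": accuracy,
            "lift": lift,
        }
    )
    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    return EvaluationCurve(points=points, auc=auc, n_positive=P, n_negative=N)


def lift_at(curve: EvaluationCurve, threshold: float) -> float:
    """Lift of the classifier calling score >= threshold positive."""
    pts = curve.points
    eligible = pts[pts["threshold"] >= threshold]
    if eligible.empty:
        # nothing classified positive: lift of an empty call set is undefined
        return float("nan")
    return float(eligible["lift"].iloc[-1])


def threshold_at_precision(
    curve: EvaluationCurve, min_precision: float
) -> float | None:
    """Lowest threshold whose precision still reaches ``min_precision``.

    Scanning thresholds from the top, returns the smallest score at which
    precision >= min_precision, i.e. the score splitting high- from
    low-scoring pairs; ``None`` if no threshold qualifies.
    """
    if not 0 < min_precision <= 1:
        raise ValueError("min_precision must lie in (0, 1]")
    pts = curve.points
    ok = pts[pts["precision"] >= min_precision]
    if ok.empty:
        return None
    return float(ok["threshold"].min())


def binned_lift(
    scores: Sequence[float],
    labels: Sequence[bool],
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Per-score-bin precision, lift and ln(pair count).

    Bins are half-open-left, closed-right between consecutive edges (the
    first edge is an inclusive lower bound).  Empty bins are flagged and
    carry NaN lift — at high scores pairs get sparse, so single bins can be
    empty.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    prevalence = labels.mean()
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo == edges[0]:
            mask = (scores >= lo) & (scores <= hi)
        else:
            mask = (scores > lo) & (scores <= hi)
        n = int(mask.sum())
        n_pos = int(labels[mask].sum())
        if n:
            prec = n_pos / n
            lift = prec / prevalence if prevalence > 0 else float("nan")
        else:
            prec = float("nan")
            lift = float("nan")
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_pairs": n,
                "n_positive": n_pos,
                "precision": prec,
                "lift": lift,
                "ln_n_pairs": math.log(n) if n else float("nan"),
                "is_empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


def causal_se_fraction(
    gene_id: str,
    contributing_side_effects: Sequence[str],
    known_gene_se: Iterable[tuple[str, str]],
) -> float:
    """Fraction of a pair's contributing side effects with a known causal link.

    ``known_gene_se`` holds (gene_id, term_id) pairs from an independent
    catalogue of side effects caused through the gene's protein.  The
    contributing side effects are the (at most 20) terms behind the pair's
    drug-direction score.
    """
    contributing = list(contributing_side_effects)
    if not contributing:
        raise ValueError("contributing side-effect set is empty")
    known_terms = {t for g, t in known_gene_se if g == gene_id}
    hits = sum(1 for t in contributing if t in known_terms)
    return hits / len(contributing)


def compare_high_low(
    values_high: Sequence[float], values_low: Sequence[float]
) -> tuple[float, float]:
    """One-sided rank-sum test that the high-scoring group exceeds the low.

    Mann–Whitney U with normal approximation and tie correction; returns
    (U statistic, one-sided p for high > low).  Fully degenerate samples
    (every value identical) yield p = 0.5 with a warning.
    """
    high = np.asarray(values_high, dtype=float)
    low = np.asarray(values_low, dtype=float)
    if len(high) < 3 or len(low) < 3:
        raise ValueError("both samples need at least 3 values")
    pooled = np.r_[high, low]
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; rank-sum p set to 0.5", stacklevel=2)
        return float(len(high) * len(low) / 2.0), 0.5
    res = stats.mannwhitneyu(high, low, alternative="greater", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def ppi_min_distance(
    network: nx.Graph | Iterable[tuple[str, str]],
    gene_id: str,
    target_ids: Iterable[str],
) -> int | None:
    """Minimum hop distance from a gene to any known drug target in a PPI net.

    Distance 0 means the gene *is* a known target; 1 a direct interactor;
    2 a shared neighbour.  ``None`` when no target is reachable.
    """
    targets = set(target_ids)
    if not targets:
        raise ValueError("target set is empty")
    if gene_id in targets:
        return 0
    g = network if isinstance(network, nx.Graph) else nx.Graph(network)
    if gene_id not in g:
        return None
    dists = nx.single_source_shortest_path_length(g, gene_id)
    reachable = [d for t, d in dists.items() if t in targets]
    return min(reachable) if reachable else None


def mapping_coverage_by_frequency(
    term_annotation_counts: Mapping[str, int],
    mapped_flags: Mapping[str, bool],
    bin_edges: Sequence[int] = GENE_FREQUENCY_BIN_EDGES,
) -> pd.DataFrame:
    """Fraction of terms successfully mapped, per frequency-of-occurrence bin.

    The first bin holds terms occurring exactly ``bin_edges[0]`` times (once,
    with the default edges); intermediate bins are half-open-left,
    closed-right; a final open bin catches counts above the last edge.
    """
    edges = list(bin_edges)
    counts = {t: int(c) for t, c in term_annotation_counts.items()}
    if any(c < 1 for c in counts.values()):
        raise ValueError("annotation counts must be >= 1")

    bounds: list[tuple[float, float]] = [(edges[0], edges[0])]
    bounds += list(zip(edges[:-1], edges[1:]))
    bounds.append((edges[-1], math.inf))

    rows = []
    for lo, hi in bounds:
        if lo == hi:
            members = [t for t, c in counts.items() if c == lo]
            label = str(int(lo))
        elif math.isinf(hi):
            members = [t for t, c in counts.items() if c > lo]
            label = f">{int(lo)}"
        else:
            members = [t for t, c in counts.items() if lo < c <= hi]
            label = f"]{int(lo)},{int(hi)}]"
        n = len(members)
        n_mapped = sum(1 for t in members if mapped_flags.get(t, False))
        rows.append(
            {
                "bin": label,
                "n_terms": n,
                "n_mapped": n_mapped,
                "fraction_mapped": n_mapped / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
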