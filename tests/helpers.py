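"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain dict/loop code, deliberately sharing
no machinery with the package, so that agreement between the two is a real
cross-check and not a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def ancestor_set(parents: dict[str, set[str]], term: str) -> set[str]:
    """Self-inclusive ancestors by naive recursive closure."""
    out = {term}
    for p in parents.get(term, set()):
        out |= ancestor_set(parents, p)
    return out


def descendant_count(parents: dict[str, set[str]], term: str) -> int:
    terms = set(parents)
    return sum(1 for u in terms if u != term and term in ancestor_set(parents, u))


def ic_table(parents: dict[str, set[str]]) -> dict[str, float]:
    n = len(parents)
    return {
        t: 1.0 - math.log(descendant_count(parents, t) + 1) / math.log(n)
        for t in parents
    }


def mica_brute(parents: dict[str, set[str]], a: str, b: str) -> tuple[str | None, float]:
    """Exhaustive MICA: max-IC common ancestor, ties to smallest id."""
    common = ancestor_set(parents, a) & ancestor_set(parents, b)
    if not common:
        return None, 0.0
    ic = ic_table(parents)
    best = sorted(common, key=lambda t: (-ic[t], t))[0]
    return best, ic[best]


def _invert(annotations: dict[str, set[str]]) -> dict[str, set[str]]:
    inv: dict[str, set[str]] = {}
    for e, terms in annotations.items():
        for t in terms:
            inv.setdefault(t, set()).add(e)
    return inv


def _weight_product(
    inv: dict[str, set[str]], n_entities: int, focal: str, other: str
) -> float:
    """f*c of the focal term vs a partner, with cap and identity conventions."""
    a = inv.get(focal, set())
    if not a:
        return 0.0
    f = -math.log(len(a) / n_entities)
    if focal == other:
        c = math.log(n_entities + 1)
    else:
        b = inv.get(other, set())
        union = a | b
        inter = a & b
        c = -math.log(len(inter) / len(union)) if inter else math.log(len(union) + 1)
    return f * c


def pair_score_brute(
    parents: dict[str, set[str]],
    drug_ann: dict[str, set[str]],
    gene_ann: dict[str, set[str]],
    se: str,
    trait: str,
) -> float:
    _, mica_ic = mica_brute(parents, se, trait)
    dp = _weight_product(_invert(drug_ann), len(drug_ann), se, trait)
    gp = _weight_product(_invert(gene_ann), len(gene_ann), trait, se)
    return mica_ic * min(dp, gp)


def score_table_brute(
    parents: dict[str, set[str]],
    drug_ann: dict[str, set[str]],
    gene_ann: dict[str, set[str]],
    top_k: int | None = 20,
    combine: str = "pooled",
    gene_scale_mode: str = "ln_n",
    burden_weights: tuple[float, float, float] = (1.0, 0.66, 0.33),
) -> dict[tuple[str, str], dict[str, float]]:
    """Quadruple-loop reference for the all-pairs similarity table."""
    counts = np.array([len(ts) for _, ts in sorted(drug_ann.items())])
    q33, q66 = np.quantile(counts, [0.33, 0.66])
    burden = {}
    for d, ts in drug_ann.items():
        n = len(ts)
        burden[d] = (
            burden_weights[0]
            if n <= q33
            else burden_weights[1] if n <= q66 else burden_weights[2]
        )

    out: dict[tuple[str, str], dict[str, float]] = {}
    for d, ses in drug_ann.items():
        for g, traits in gene_ann.items():
            gene_vals = []
            for t in sorted(traits):
                gene_vals.append(
                    max(pair_score_brute(parents, drug_ann, gene_ann, se, t) for se in ses)
                )
            per_se = []
            for se in sorted(ses):
                per_se.append(
                    (
                        -max(
                            pair_score_brute(parents, drug_ann, gene_ann, se, t)
                            for t in traits
                        ),
                        se,
                    )
                )
            per_se.sort()
            k = len(per_se) if top_k is None else min(top_k, len(per_se))
            drug_vals = [-v for v, _ in per_se[:k]]
            if combine == "pooled":
                raw = float(np.mean(gene_vals + drug_vals))
            else:
                raw = (float(np.mean(gene_vals)) + float(np.mean(drug_vals))) / 2.0
            n_tr = len(traits)
            if gene_scale_mode == "ln_n":
                gs = math.log(n_tr) if n_tr > 1 else 0.0
            else:
                gs = math.log(n_tr + 1)
            out[(d, g)] = {
                "raw": raw,
                "gene_scale": gs,
                "burden_weight": burden[d],
                "scaled": raw * gs * burden[d],
            }
    max_scaled = max(v["scaled"] for v in out.values())
    for v in out.values():
        v["normalized"] = v["scaled"] / max_scaled if max_scaled > 0 else 0.0
    return out


def auc_pairwise_probability(scores, labels) -> float:
    """AUC as P(score+ > score-) + 0.5 P(tie), by exhaustive enumeration."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def mannwhitney_u_brute(high, low) -> float:
    """Exhaustive U statistic: count of (high, low) wins with half for ties."""
    u = 0.0
    for h in high:
        for l in low:
            u += 1.0 if h > l else 0.5 if h == l else 0.0
    return u


def shortest_hops_brute(edges, source: str, targets: set[str]) -> int | None:
    """All-paths breadth search on an explicit adjacency dict."""
    if source in targets:
        return 0
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    if source not in adj:
        return None
    seen = {source}
    frontier = {source}
    dist = 0
    while frontier:
        dist += 1
        frontier = {n for f in frontier for n in adj.get(f, set())} - seen
        if frontier & targets:
            return dist
        seen |= frontier
    return None
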