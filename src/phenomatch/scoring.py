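"""Gene–drug phenotypic similarity with the polypharmacology correction.

The similarity of one side effect *i* (drug corpus) and one phenotypic trait
*j* (gene corpus) is

    s_ij = IC(MICA(i, j)) * min(f_i * c_i,  f_j * c_j)

where f is the frequency weight and c the co-occurrence weight of the pair,
each evaluated inside its own corpus (c_i = co-occurrence of (i, j) among
drugs, c_j among genes).  A gene–drug comparison aggregates term-pair scores
by best-match:

* gene direction — for every gene trait, the best-scoring side effect; the
  mean is taken over all traits;
* drug direction — for every side effect, the best-scoring trait; because
  drugs hit multiple targets (polypharmacology) and so carry far more side
  effects than a single-gene perturbation produces phenotypes, only the
  top-K (default 20) side-effect best matches enter the mean; a drug with
  fewer side effects contributes them all.

The combined raw score (default: mean of the pooled best-match values of the
two directions) is scaled by ln(#gene terms) to downweight genes with little
phenotypic information, multiplied by a tertile burden weight (1 / 0.66 /
0.33) that penalises drugs with many side effects, and finally divided by
the maximum scaled score in the run, yielding a value in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import AnnotationCorpus, UndefinedWeightError
from .ontology import MicaResult, Ontology

__all__ = [
    "ScoringConfig",
    "TermPairScore",
    "BestMatchRow",
    "PairSimilarity",
    "PairScorer",
    "term_pair_score",
    "best_matches",
    "gene_to_drug_similarity",
    "drug_to_gene_similarity",
    "combine_directions",
    "drug_burden_weights",
    "score_all_pairs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringConfig:
    """Tunables of the similarity scheme.

    top_k:
        Number of highest-scoring side-effect best matches entering the drug
        direction (the polypharmacology correction).  ``None`` disables the
        cutoff (all side effects are used).
    combine_mode:
        ``"pooled"`` (default) averages the concatenated best-match values of
        both directions; ``"mean_of_means"`` averages the two directional
        means.
    burden_weights:
        Weights of the low / medium / high side-effect-count tertiles.
    gene_scale_mode:
        ``"ln_n"`` multiplies by ln(#gene terms) — a single-term gene scores
        0; ``"ln_n_plus_1"`` uses ln(n+1) to retain such genes.
    cooccurrence_mode:
        ``"per_corpus"`` (default) evaluates each term's co-occurrence weight
        inside its own corpus; ``"pooled"`` uses one Jaccard over the union
        of both corpora's entity sets, shared by both sides.
    """

    top_k: int | None = 20
    combine_mode: str = "pooled"
    burden_weights: tuple[float, float, float] = (1.0, 0.66, 0.33)
    gene_scale_mode: str = "ln_n"
    descendant_mode: str = "transitive"
    cooccurrence_mode: str = "per_corpus"

    def __post_init__(self):
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1 (or None for no cutoff)")
        if self.combine_mode not in ("pooled", "mean_of_means"):
            raise ValueError(f"unknown combine mode: {self.combine_mode!r}")
        if self.gene_scale_mode not in ("ln_n", "ln_n_plus_1"):
            raise ValueError(f"unknown gene scale mode: {self.gene_scale_mode!r}")
        if self.cooccurrence_mode not in ("per_corpus", "pooled"):
            raise ValueError(f"unknown cooccurrence mode: {self.cooccurrence_mode!r}")
        if not all(0 < w <= 1 for w in self.burden_weights):
            raise ValueError("burden weights must lie in (0, 1]")


@dataclass(frozen=True)
class TermPairScore:
    """Score of one side-effect / trait term pair with its components."""

    se_term: str
    trait_term: str
    mica: MicaResult
    drug_side_product: float
    gene_side_product: float

    @property
    def s(self) -> float:
        return self.mica.ic_value * min(self.drug_side_product, self.gene_side_product)


@dataclass(frozen=True)
class BestMatchRow:
    """Best partner of one anchor term and the score it achieves."""

    anchor_term: str
    best_partner: str
    best_score: float


@dataclass(frozen=True)
class PairSimilarity:
    """One scored gene–drug comparison."""

    drug_id: str
    gene_id: str
    gene_direction_mean: float
    drug_direction_values: tuple[float, ...]
    contributing_side_effects: tuple[str, ...]
    raw: float
    gene_scale: float
    burden_weight: float
    n_gene_terms: int
    n_drug_terms: int

    @property
    def scaled(self) -> float:
        return self.raw * self.gene_scale * self.burden_weight


class PairScorer:
    """Caches the term-pair score matrix for one ontology + corpus pair."""

    def __init__(
        self,
        ontology: Ontology,
        drug_corpus: AnnotationCorpus,
        gene_corpus: AnnotationCorpus,
        config: ScoringConfig | None = None,
    ):
        self.ontology = ontology
        self.drug_corpus = drug_corpus
        self.gene_corpus = gene_corpus
        self.config = config or ScoringConfig()
        self._cache: dict[tuple[str, str], float] = {}
        if self.config.cooccurrence_mode == "pooled":
            # entity ids are namespaced by class so a drug and a gene that
            # happen to share an id cannot collapse into one entity
            pooled: dict[str, set[str]] = {}
            for cls, corpus in (("d", drug_corpus), ("g", gene_corpus)):
                for ent, terms in corpus.annotations.items():
                    for t in terms:
                        pooled.setdefault(t, set()).add(f"{cls}:{ent}")
            self._pooled_inverted = pooled
        else:
            self._pooled_inverted = None

    def _cooccurrence(self, corpus: AnnotationCorpus, focal: str, other: str) -> float:
        # Identity convention: the co-occurrence weight penalises redundant
        # term pairs *within* a profile corpus; a side effect compared with
        # the literally identical trait term is a perfect cross-corpus match,
        # not a redundant pair, so its weight is the supremum of the capped
        # co-occurrence weight in that corpus, -ln(1/(n+1)).  The within-
        # corpus self-Jaccard (J = 1, c = 0) would zero out every exact match
        # — and with it the whole true signal — and any smaller cap would let
        # a never-co-occurring sibling pair outweigh a perfect match.
        if self._pooled_inverted is None:
            if focal == other:
                if not corpus.entities_with(focal):
                    raise UndefinedWeightError(focal)
                return math.log(corpus.n_entities + 1)
            return corpus.cooccurrence_weight(focal, other)
        a = self._pooled_inverted.get(focal, set())
        if not a:
            raise UndefinedWeightError(focal)
        if focal == other:
            n_pooled = self.drug_corpus.n_entities + self.gene_corpus.n_entities
            return math.log(n_pooled + 1)
        b = self._pooled_inverted.get(other, set())
        union = a | b
        inter = a & b
        if inter:
            return -math.log(len(inter) / len(union))
        return -math.log(1.0 / (len(union) + 1))

    def term_pair_score(self, se_term: str, trait_term: str) -> TermPairScore:
        """Full score decomposition of one side-effect / trait pair."""
        mica = self.ontology.mica(se_term, trait_term)
        try:
            f_se = self.drug_corpus.frequency_weight(se_term)
            c_se = self._cooccurrence(self.drug_corpus, se_term, trait_term)
            drug_prod = f_se * c_se
        except UndefinedWeightError:
            logger.debug("undefined drug-side weight for %s; score 0", se_term)
            drug_prod = 0.0
        try:
            f_tr = self.gene_corpus.frequency_weight(trait_term)
            c_tr = self._cooccurrence(self.gene_corpus, trait_term, se_term)
            gene_prod = f_tr * c_tr
        except UndefinedWeightError:
            logger.debug("undefined gene-side weight for %s; score 0", trait_term)
            gene_prod = 0.0
        return TermPairScore(
            se_term=se_term,
            trait_term=trait_term,
            mica=mica,
            drug_side_product=drug_prod,
            gene_side_product=gene_prod,
        )

    def score(self, se_term: str, trait_term: str) -> float:
        key = (se_term, trait_term)
        s = self._cache.get(key)
        if s is None:
            s = self.term_pair_score(se_term, trait_term).s
            self._cache[key] = s
        return s

    def score_matrix(
        self, se_terms: Sequence[str], trait_terms: Sequence[str]
    ) -> np.ndarray:
        """Dense s_ij matrix (rows: side effects, columns: traits)."""
        out = np.empty((len(se_terms), len(trait_terms)))
        for i, se in enumerate(se_terms):
            for j, tr in enumerate(trait_terms):
                out[i, j] = self.score(se, tr)
        return out


def term_pair_score(
    ontology: Ontology,
    drug_corpus: AnnotationCorpus,
    gene_corpus: AnnotationCorpus,
    se_term: str,
    trait_term: str,
    config: ScoringConfig | None = None,
) -> TermPairScore:
    """Convenience wrapper: score one term pair without keeping a scorer."""
    return PairScorer(ontology, drug_corpus, gene_corpus, config).term_pair_score(
        se_term, trait_term
    )


def best_matches(
    anchor_profile: Iterable[str],
    partner_profile: Iterable[str],
    scorer: PairScorer,
    anchor_side: str = "drug",
) -> list[BestMatchRow]:
    """Best partner term for every anchor term.

    ``anchor_side`` says which corpus the anchor terms come from ("drug":
    anchors are side effects matched against traits; "gene": the reverse).
    Ties between partners break to the lexicographically smallest term id;
    rows are ordered by descending best score, then anchor term id.
    """
    anchors = sorted(set(anchor_profile))
    partners = sorted(set(partner_profile))
    if not anchors or not partners:
        raise ValueError("profiles must be non-empty")
    rows = []
    for a in anchors:
        if anchor_side == "drug":
            best = max(partners, key=lambda p: (scorer.score(a, p), _neg_str(p)))
            score = scorer.score(a, best)
        else:
            best = max(partners, key=lambda p: (scorer.score(p, a), _neg_str(p)))
            score = scorer.score(best, a)
        rows.append(BestMatchRow(anchor_term=a, best_partner=best, best_score=score))
    rows.sort(key=lambda r: (-r.best_score, r.anchor_term))
    return rows


class _neg_str(str):
    """Inverts string ordering so max() tie-breaks to the smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


def gene_to_drug_similarity(
    gene_profile: Iterable[str],
    drug_profile: Iterable[str],
    scorer: PairScorer,
) -> float:
    """Mean best-match score over ALL gene traits (no cutoff)."""
    rows = best_matches(gene_profile, drug_profile, scorer, anchor_side="gene")
    return float(np.mean([r.best_score for r in rows]))


def drug_to_gene_similarity(
    drug_profile: Iterable[str],
    gene_profile: Iterable[str],
    scorer: PairScorer,
    top_k: int | None = 20,
) -> tuple[float, list[float], list[str]]:
    """Mean of the top-K side-effect best matches (polypharmacology correction).

    Returns the mean, the selected best-match values and the contributing
    side-effect ids.  Selection is per gene comparison: the same drug may
    contribute different side effects against different genes.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    rows = best_matches(drug_profile, gene_profile, scorer, anchor_side="drug")
    if top_k is not None:
        rows = rows[: min(top_k, len(rows))]
    values = [r.best_score for r in rows]
    terms = [r.anchor_term for r in rows]
    return float(np.mean(values)), values, terms


def combine_directions(
    gene_direction_values: Sequence[float],
    drug_direction_values: Sequence[float],
    mode: str = "pooled",
) -> float:
    """Symmetric combination of the two directional best-match value lists."""
    if mode == "pooled":
        pooled = list(gene_direction_values) + list(drug_direction_values)
        return float(np.mean(pooled))
    if mode == "mean_of_means":
        return float(
            (np.mean(gene_direction_values) + np.mean(drug_direction_values)) / 2.0
        )
    raise ValueError(f"unknown combine mode: {mode!r}")


def drug_burden_weights(
    drug_corpus: AnnotationCorpus,
    config: ScoringConfig | None = None,
) -> dict[str, float]:
    """Tertile burden weight per drug from its side-effect count.

    Tertile boundaries are the 33% / 66% linear-interpolation quantiles of
    the per-drug counts; a count at a boundary falls in the lower bin.
    """
    config = config or ScoringConfig()
    counts = drug_corpus.annotation_counts()
    values = np.array(list(counts.values()))
    q33, q66 = np.quantile(values, [0.33, 0.66], method="linear")
    w_low, w_mid, w_high = config.burden_weights
    out = {}
    for drug, n in counts.items():
        if n <= q33:
            out[drug] = w_low
        elif n <= q66:
            out[drug] = w_mid
        else:
            out[drug] = w_high
    return out


def score_all_pairs(
    ontology: Ontology,
    drug_corpus: AnnotationCorpus,
    gene_corpus: AnnotationCorpus,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Score every (drug, gene) pair; returns one row per pair.

    Columns: drug_id, gene_id, raw, gene_scale, burden_weight, scaled,
    normalized, n_gene_terms, n_drug_terms, contributing_side_effects
    (pipe-separated).  ``normalized`` is ``scaled`` divided by the maximum
    scaled score of the run (0 everywhere if that maximum is 0).  Rows are
    ordered by (drug_id, gene_id).
    """
    config = config or ScoringConfig()
    scorer = PairScorer(ontology, drug_corpus, gene_corpus, config)

    drug_terms = sorted(drug_corpus.terms)
    gene_terms = sorted(gene_corpus.terms)
    se_idx = {t: i for i, t in enumerate(drug_terms)}
    tr_idx = {t: j for j, t in enumerate(gene_terms)}
    smat = scorer.score_matrix(drug_terms, gene_terms)

    burden = drug_burden_weights(drug_corpus, config)
    single_term_genes = [
        g for g, ts in gene_corpus.annotations.items() if len(ts) == 1
    ]
    if single_term_genes and config.gene_scale_mode == "ln_n":
        logger.warning(
            "%d gene(s) with a single annotation scale to 0 under ln(n) "
            "(e.g. %s); use gene_scale_mode='ln_n_plus_1' to retain them",
            len(single_term_genes),
            single_term_genes[0],
        )

    records = []
    for drug in sorted(drug_corpus.annotations):
        ses = sorted(drug_corpus.profile(drug))
        rows = np.array([se_idx[t] for t in ses])
        for gene in sorted(gene_corpus.annotations):
            traits = sorted(gene_corpus.profile(gene))
            cols = np.array([tr_idx[t] for t in traits])
            sub = smat[np.ix_(rows, cols)]

            gene_vals = sub.max(axis=0)  # best side effect per trait
            drug_best = sub.max(axis=1)  # best trait per side effect
            order = np.lexsort((np.array(ses), -drug_best))
            k = len(ses) if config.top_k is None else min(config.top_k, len(ses))
            sel = order[:k]
            drug_vals = drug_best[sel]
            contributing = [ses[i] for i in sel]

            raw = combine_directions(gene_vals, drug_vals, config.combine_mode)
            n_gene = len(traits)
            if config.gene_scale_mode == "ln_n":
                gene_scale = math.log(n_gene) if n_gene > 1 else 0.0
            else:
                gene_scale = math.log(n_gene + 1)
            bw = burden[drug]
            records.append(
                {
                    "drug_id": drug,
                    "gene_id": gene,
                    "raw": raw,
                    "gene_scale": gene_scale,
                    "burden_weight": bw,
                    "scaled": raw * gene_scale * bw,
                    "n_gene_terms": n_gene,
                    "n_drug_terms": len(ses),
                    "contributing_side_effects": "|".join(contributing),
                }
            )

    table = pd.DataFrame.from_records(records)
    max_scaled = table["scaled"].max()
    if max_scaled > 0:
        table["normalized"] = table["scaled"] / max_scaled
    else:
        table["normalized"] = 0.0
    table.attrs["max_scaled"] = float(max_scaled)
    table.attrs["config"] = config
    cols = [
        "drug_id",
        "gene_id",
        "raw",
        "gene_scale",
        "burden_weight",
        "scaled",
        "normalized",
        "n_gene_terms",
        "n_drug_terms",
        "contributing_side_effects",
    ]
    return table[cols]
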