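"""Synthetic desk-scale studies with planted gene–drug signal.

The generator emulates the statistical structure the similarity method
assumes, without any licensed vocabulary:

* a complete layered term hierarchy standing in for the adapted four-level
  side-effect ontology (optionally with extra cross-links playing the role
  of SMQ-style groupings);
* gene trait profiles drawn uniformly from leaf terms — leaf-only sampling
  keeps the IC of exact matches maximal, so planted signal is analytically
  predictable;
* drug side-effect profiles built by polypharmacology: each drug targets
  1..T genes, echoes a fraction of each target's traits (occasionally
  blurred to a sibling term, modelling the imperfect correspondence between
  mouse phenotypes and human side-effect vocabulary), and adds unrelated
  noise side effects from leaves outside its targets' trait sets;
* the implied planted positive pairs, a small PPI graph around the targets,
  and a causal gene–side-effect set drawn from the echoed terms.

All randomness flows through one seeded generator with per-artifact
sub-streams, so e.g. adding drugs does not perturb gene sampling, and
identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .corpus import AnnotationCorpus
from .ontology import Ontology, TermNode

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_ontology",
    "generate_study",
    "polypharmacology_stress_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    Defaults give a 40-term hierarchy (27 leaves), 50 genes with 4–6 leaf
    traits each and 30 single-target drugs; drugs echo 95% of their target's
    traits, blur 5% of echoed traits to a sibling, and top the profile up to
    a fixed budget of 7 side effects with popularity-skewed unrelated noise.
    The fixed budget keeps profile size from carrying accidental signal at
    this vocabulary scale; drug-size variation (and with it the burden
    tertiles) is exercised by :func:`polypharmacology_stress_config`.
    """

    seed: int = 0
    depth: int = 4
    branching: int = 3
    cross_link_rate: float = 0.0
    n_genes: int = 50
    n_drugs: int = 30
    traits_per_gene: tuple[int, int] = (4, 6)
    targets_per_drug: tuple[int, int] = (1, 1)
    copy_fraction: float = 0.95
    sibling_swap_prob: float = 0.05
    noise_side_effects: tuple[int, int] = (3, 8)
    total_side_effects: int | None = 7
    noise_popularity_exponent: float = 1.5
    n_decoy_proteins: int = 20
    ppi_extra_edge_prob: float = 0.08
    causal_pair_fraction: float = 0.5

    def __post_init__(self):
        if self.depth < 2 or self.branching < 2:
            raise ValueError("need depth >= 2 and branching >= 2")
        if not (0 <= self.copy_fraction <= 1 and 0 <= self.sibling_swap_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        for lo, hi in (
            self.traits_per_gene,
            self.targets_per_drug,
            (1, self.n_genes),
            (1, self.n_drugs),
        ):
            if lo < 1 or hi < lo:
                raise ValueError("count ranges must be positive and ordered")
        if self.noise_side_effects[0] < 0:
            raise ValueError("noise range must be non-negative")


def polypharmacology_stress_config(seed: int = 0) -> SimConfig:
    """Heavy-polypharmacology conditions: 3 targets/drug, noise dominating.

    A broader hierarchy (branching 4: 85 terms, 64 leaves) keeps the noise
    pool large enough that each drug can carry at least twice as many
    unrelated side effects as echoed ones.
    """
    return SimConfig(
        seed=seed,
        branching=4,
        targets_per_drug=(3, 3),
        copy_fraction=0.6,
        noise_side_effects=(20, 30),
        total_side_effects=None,
        noise_popularity_exponent=1.2,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Planted positives and the terms through which they were planted."""

    planted_pairs: frozenset[tuple[str, str]]
    drug_targets: dict[str, tuple[str, ...]]
    echoed_terms: dict[tuple[str, str], tuple[str, ...]]


@dataclass(frozen=True)
class SyntheticStudy:
    """One generated study: the inputs every other module consumes."""

    config: SimConfig
    ontology: Ontology
    drug_corpus: AnnotationCorpus
    gene_corpus: AnnotationCorpus
    truth: GroundTruth
    ppi_edges: tuple[tuple[str, str], ...]
    causal_gene_se: frozenset[tuple[str, str]]


def _term_id(level: int, index: int) -> str:
    return f"T{level}.{index:04d}"


def generate_ontology(config: SimConfig) -> Ontology:
    """Complete ``depth``-level tree with ``branching`` children per node.

    Term count is the geometric sum 1 + b + b^2 + ... + b^(depth-1).  With
    ``cross_link_rate`` > 0, terms additionally acquire a second parent from
    the level above with that probability (SMQ-like cross links).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    nodes = [TermNode(term_id=_term_id(1, 0), label="root", level=1)]
    prev_level = [_term_id(1, 0)]
    for level in range(2, config.depth + 1):
        level_ids = []
        n_this = config.branching ** (level - 1)
        for i in range(n_this):
            tid = _term_id(level, i)
            parents = {prev_level[i // config.branching]}
            if config.cross_link_rate > 0 and rng.random() < config.cross_link_rate:
                extra = prev_level[int(rng.integers(len(prev_level)))]
                parents.add(extra)
            nodes.append(
                TermNode(
                    term_id=tid,
                    label=f"term level {level} #{i}",
                    level=level,
                    parent_ids=frozenset(parents),
                )
            )
            level_ids.append(tid)
        prev_level = level_ids
    return Ontology(nodes)


def _sample_range(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    lo, hi = lohi
    return int(rng.integers(lo, hi + 1))


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate the full synthetic study for one config."""
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_genes = np.random.default_rng(streams[0])
    rng_drugs = np.random.default_rng(streams[1])
    rng_ppi = np.random.default_rng(streams[2])
    rng_causal = np.random.default_rng(streams[3])

    ontology = generate_ontology(config)
    leaves = sorted(ontology.leaves)
    leaf_index = {t: i for i, t in enumerate(leaves)}
    if config.traits_per_gene[1] > len(leaves):
        raise ValueError("ontology too small for requested gene profile sizes")

    # siblings: leaves sharing a parent, for the cross-species blur
    sibling_pool = {
        leaf: sorted(
            {
                s
                for p in ontology.parents(leaf)
                for s in ontology.children(p)
                if s != leaf and s in ontology.leaves
            }
        )
        for leaf in leaves
    }

    # Unrelated noise side effects are popularity-skewed, like real adverse
    # events: a few common terms (headache, nausea) recur across many drugs
    # while the tail is rare.  A Zipf profile over a seed-fixed leaf ranking
    # reproduces that; the frequency weight is what neutralises the common
    # head at scoring time.  Exponent 0 recovers uniform noise.
    rng_rank = np.random.default_rng(streams[4])
    popularity_rank = rng_rank.permutation(len(leaves))
    noise_p = 1.0 / (popularity_rank + 1.0) ** config.noise_popularity_exponent
    noise_p /= noise_p.sum()

    genes = [f"G{i:03d}" for i in range(config.n_genes)]
    gene_profiles = {}
    for g in genes:
        n = _sample_range(rng_genes, config.traits_per_gene)
        gene_profiles[g] = set(
            rng_genes.choice(leaves, size=n, replace=False).tolist()
        )

    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    drug_profiles: dict[str, set[str]] = {}
    drug_targets: dict[str, tuple[str, ...]] = {}
    echoed: dict[tuple[str, str], tuple[str, ...]] = {}
    planted: set[tuple[str, str]] = set()
    for d in drugs:
        n_targets = _sample_range(rng_drugs, config.targets_per_drug)
        targets = rng_drugs.choice(genes, size=n_targets, replace=False).tolist()
        drug_targets[d] = tuple(targets)
        profile: set[str] = set()
        for g in targets:
            traits = sorted(gene_profiles[g])
            picked = [t for t in traits if rng_drugs.random() < config.copy_fraction]
            if not picked and config.copy_fraction > 0:
                # a planted pair must leave at least one trace in the profile
                picked = [traits[int(rng_drugs.integers(len(traits)))]]
            echoes = []
            for t in picked:
                if (
                    sibling_pool[t]
                    and rng_drugs.random() < config.sibling_swap_prob
                ):
                    t = sibling_pool[t][int(rng_drugs.integers(len(sibling_pool[t])))]
                echoes.append(t)
            profile.update(echoes)
            echoed[(d, g)] = tuple(sorted(set(echoes)))
            planted.add((d, g))
        if config.total_side_effects is not None:
            # fixed per-drug side-effect budget: noise tops the profile up to
            # a constant size, so the burden tertiles are degenerate (all
            # drugs weight 1) and profile size carries no accidental signal
            n_noise = max(config.total_side_effects - len(profile), 0)
        else:
            n_noise = _sample_range(
                rng_drugs,
                (max(config.noise_side_effects[0], 0), config.noise_side_effects[1]),
            )
        # noise avoids only the echoed terms themselves: excluding whole
        # target trait sets would make the copy_fraction = 0 control
        # anti-correlated rather than signal-free
        pool = [t for t in leaves if t not in profile]
        if n_noise > len(pool):
            raise ValueError(
                f"insufficient leaf pool for {n_noise} noise side effects "
                f"({len(pool)} leaves available outside target traits)"
            )
        if n_noise:
            pool_p = np.array([noise_p[leaf_index[t]] for t in pool])
            pool_p /= pool_p.sum()
            profile.update(
                rng_drugs.choice(pool, size=n_noise, replace=False, p=pool_p).tolist()
            )
        if not profile:  # copy_fraction 0 and zero noise drawn
            profile.update(rng_drugs.choice(pool, size=1).tolist())
        drug_profiles[d] = profile

    # PPI: targets sit in a graph with decoy proteins; each target links to a
    # couple of decoys, decoys link sparsely among themselves
    decoys = [f"P{i:03d}" for i in range(config.n_decoy_proteins)]
    edges: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    all_targets = sorted({t for ts in drug_targets.values() for t in ts})
    for g in all_targets:
        for _ in range(int(rng_ppi.integers(1, 3))):
            add_edge(g, decoys[int(rng_ppi.integers(len(decoys)))])
    nodes = all_targets + decoys
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            if rng_ppi.random() < config.ppi_extra_edge_prob:
                add_edge(a, b)

    # causal catalogue: echoed side effects of a random subset of planted pairs
    causal: set[tuple[str, str]] = set()
    for (d, g), terms in sorted(echoed.items()):
        if terms and rng_causal.random() < config.causal_pair_fraction:
            causal.update((g, t) for t in terms)

    return SyntheticStudy(
        config=config,
        ontology=ontology,
        drug_corpus=AnnotationCorpus(drug_profiles, entity_class="drug"),
        gene_corpus=AnnotationCorpus(gene_profiles, entity_class="gene"),
        truth=GroundTruth(
            planted_pairs=frozenset(planted),
            drug_targets=drug_targets,
            echoed_terms=echoed,
        ),
        ppi_edges=tuple(sorted(edges)),
        causal_gene_se=frozenset(causal),
    )
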