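"""Gene-list enrichment: ORA, proximity-extended pathway analysis, and
phenotype enrichment by t-test or random-list resampling.

Classic over-representation analysis (ORA) tests a query list against curated
term memberships with a one-sided Fisher exact test.  Proximity-extended
pathway analysis (PPA) first widens each pathway's membership with proteins
that are significantly close to it in the causal network, then applies the
same Fisher test -- crediting regulators that curators never assigned to the
pathway.  Phenotype enrichment works on proximity Z-scores: either a Welch
t-test comparing the query's Z-values against all other scored proteins, or
an empirical p-value from random protein lists of matched size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from causalprox.graph_model import CausalGraph, GeneSetCollection
from causalprox.proxpath import (
    ProxConfig,
    ProximityRecord,
    ProximityResult,
    _paths_to_target,
    proximity_scores,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for Fisher: k query hits in term, n query size, K background
    hits in term, N background size."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid table: k={self.k}, n={self.n}, K={self.K}")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"invalid table: n={self.n}, K={self.K}, N={self.N}")


@dataclass
class EnrichmentResult:
    """One tested term with raw and adjusted p and a direction call."""

    term: str
    p_raw: float
    p_adj: float
    method: str  # ora | ppa | ttest | random_lists
    direction: str = "na"  # up | down | mixed | na
    table: ContingencyTable | None = None
    statistic: float | None = None  # t statistic or observed count
    df: float | None = None
    n_curated_hits: int | None = None
    n_extended_hits: int | None = None


def _adjust(p_raw: Sequence[float], correction: str) -> list[float]:
    if not len(p_raw):
        return []
    if correction == "bonferroni":
        m = len(p_raw)
        return [min(1.0, m * p) for p in p_raw]
    if correction == "bh":
        return list(multipletests(p_raw, method="fdr_bh")[1])
    raise ValueError(f"unknown correction {correction!r}; use 'bonferroni' or 'bh'")


def fisher_enrichment_p(table: ContingencyTable) -> float:
    """One-sided Fisher exact p: upper hypergeometric tail P(X >= k)."""
    return float(stats.hypergeom.sf(table.k - 1, table.N, table.K, table.n))


def ora(
    query: Iterable[str],
    term_sets: GeneSetCollection | Mapping[str, set[str]],
    background: Iterable[str],
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Over-representation of a query list in each term, Fisher one-sided.

    Query members outside the background are dropped with a warning; an empty
    query after filtering is an error.  Default correction is Bonferroni.
    """
    bg = set(background)
    q = set(query)
    dropped = q - bg
    if dropped:
        logger.warning("%d query ids outside background dropped", len(dropped))
        q &= bg
    if not q:
        raise ValueError("query empty after background filtering")
    sets = term_sets.sets if isinstance(term_sets, GeneSetCollection) else term_sets
    if not sets:
        raise ValueError("term_sets is empty")
    results = []
    for term in sets:
        members = sets[term] & bg
        table = ContingencyTable(
            k=len(q & members), n=len(q), K=len(members), N=len(bg)
        )
        results.append(
            EnrichmentResult(
                term=term,
                p_raw=fisher_enrichment_p(table),
                p_adj=math.nan,
                method="ora",
                table=table,
            )
        )
    for r, p in zip(results, _adjust([r.p_raw for r in results], correction)):
        r.p_adj = p
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.term))
    return results


@dataclass
class ExtendedMembership:
    """Curated members plus proteins significantly close to the pathway."""

    members: set[str]
    added: set[str] = field(default_factory=set)
    degenerate: bool = False


def extend_pathway_membership(
    graph: CausalGraph,
    pathway_members: Iterable[str],
    config: ProxConfig = ProxConfig(),
) -> ExtendedMembership:
    """Widen a pathway with proteins proximity-significant to its members.

    All bounded paths into any member are pooled into one distance
    distribution; a non-member source is added when the Z of its best path
    falls below ``config.z_threshold``.  A degenerate pooled distribution
    (fewer than 2 paths or zero spread) returns the curated set unchanged,
    flagged.
    """
    members = {m for m in pathway_members if m in graph}
    paths = []
    for m in sorted(members):
        paths.extend(_paths_to_target(graph, m, config))
    dists = np.array([p.distance for p in paths])
    if len(paths) < 2 or float(np.std(dists, ddof=1)) == 0.0:
        return ExtendedMembership(members=set(members), degenerate=True)
    mean = float(np.mean(dists))
    sd = float(np.std(dists, ddof=1))
    best: dict[str, float] = {}
    for p in paths:
        if p.source not in members:
            d = best.get(p.source)
            if d is None or p.distance < d:
                best[p.source] = p.distance
    added = {
        src for src, d in best.items() if (d - mean) / sd < config.z_threshold
    }
    return ExtendedMembership(members=members | added, added=added)


def ppa(
    query: Iterable[str],
    pathways: GeneSetCollection | Mapping[str, set[str]],
    graph: CausalGraph,
    background: Iterable[str] | None = None,
    correction: str = "bonferroni",
    config: ProxConfig = ProxConfig(),
) -> list[EnrichmentResult]:
    """Pathway-proximity analysis: ORA on proximity-extended memberships.

    Background defaults to all protein-type nodes of the graph.  Each result
    reports how many query hits were curated members vs proximity-added.
    """
    bg = set(background) if background is not None else set(graph.proteins)
    sets = pathways.sets if isinstance(pathways, GeneSetCollection) else pathways
    q = set(query) & bg
    if not q:
        raise ValueError("query empty after background filtering")
    extended: dict[str, ExtendedMembership] = {
        term: extend_pathway_membership(graph, sets[term], config) for term in sets
    }
    results = ora(q, {t: e.members for t, e in extended.items()}, bg, correction)
    for r in results:
        e = extended[r.term]
        r.method = "ppa"
        curated = e.members - e.added
        r.n_curated_hits = len(q & curated)
        r.n_extended_hits = len(q & e.added)
    return results


def _direction_from_signs(signs: Iterable[int | str]) -> str:
    s = {x for x in signs if x not in (0, "mixed")}
    if s == {1}:
        return "up"
    if s == {-1}:
        return "down"
    return "mixed" if s else "na"


def phenotype_enrichment_ttest(
    proximity_records: Sequence[ProximityRecord] | ProximityResult,
    query: Iterable[str],
    correction: str = "bh",
    min_group: int = 3,
) -> list[EnrichmentResult]:
    """Per phenotype: Welch one-sided t-test, query Z-scores vs the rest.

    The alternative is "query closer" (lower Z).  Phenotypes with fewer than
    ``min_group`` records in either group are skipped with a warning.
    Direction is the consensus of the query members' net path signs.
    """
    q = set(query)
    by_target: dict[str, list[ProximityRecord]] = {}
    for r in proximity_records:
        by_target.setdefault(r.target, []).append(r)
    results = []
    skipped = []
    for target in sorted(by_target):
        recs = by_target[target]
        qz = [r.z for r in recs if r.source in q]
        bz = [r.z for r in recs if r.source not in q]
        if len(qz) < min_group or len(bz) < min_group:
            skipped.append(target)
            continue
        t, p = stats.ttest_ind(qz, bz, equal_var=False, alternative="less")
        results.append(
            EnrichmentResult(
                term=target,
                p_raw=float(p),
                p_adj=math.nan,
                method="ttest",
                statistic=float(t),
                direction=_direction_from_signs(
                    r.net_sign for r in recs if r.source in q
                ),
            )
        )
    if skipped:
        logger.warning("skipped %d phenotypes with too few records", len(skipped))
    for r, p in zip(results, _adjust([r.p_raw for r in results], correction)):
        r.p_adj = p
    return results


def phenotype_enrichment_random_lists(
    graph: CausalGraph,
    query: Iterable[str],
    phenotypes: Iterable[str] | None = None,
    n_lists: int = 1000,
    seed: int = 0,
    config: ProxConfig = ProxConfig(),
    correction: str = "bh",
    records: Sequence[ProximityRecord] | None = None,
) -> list[EnrichmentResult]:
    """Empirical phenotype enrichment from random protein lists.

    For each phenotype, count how many query proteins are proximity-
    significant to it, then draw ``n_lists`` uniform random protein lists of
    the same size and report the add-one empirical p of seeing a count at
    least as large: ``(#{count >= observed} + 1) / (n_lists + 1)``.

    ``records`` may supply precomputed proximity scores to avoid re-running
    path enumeration.
    """
    if n_lists < 100:
        raise ValueError("n_lists must be >= 100")
    proteins = graph.proteins
    q = sorted(set(query))
    if len(q) > len(proteins):
        raise ValueError("query larger than the protein universe")
    targets = sorted(phenotypes) if phenotypes is not None else graph.phenotypes
    if records is None:
        records = proximity_scores(graph, targets, config).records
    sig: dict[str, set[str]] = {t: set() for t in targets}
    for r in records:
        if r.significant and r.target in sig:
            sig[r.target].add(r.source)
    rng = np.random.default_rng(seed)
    prot_arr = np.array(proteins)
    random_lists = [
        set(prot_arr[rng.choice(len(prot_arr), size=len(q), replace=False)])
        for _ in range(n_lists)
    ]
    results = []
    qset = set(q)
    for t in targets:
        observed = len(qset & sig[t])
        count_ge = sum(1 for rl in random_lists if len(rl & sig[t]) >= observed)
        results.append(
            EnrichmentResult(
                term=t,
                p_raw=(count_ge + 1) / (n_lists + 1),
                p_adj=math.nan,
                method="random_lists",
                statistic=float(observed),
            )
        )
    for r, p in zip(results, _adjust([r.p_raw for r in results], correction)):
        r.p_adj = p
    return results
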