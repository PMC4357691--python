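"""Path-consistency network inference driven by CMI2 (or a plug-in measure).

The engine starts from the complete graph over all genes and deletes edges
by conditional-independence tests of increasing order L.  At order 0 each
pair is scored by mutual information; at order L >= 1 each surviving pair
(i, j) is tested against every size-L subset K of the genes adjacent to
both i and j, the per-subset scores are aggregated (maximum by default, or
geometric mean), and the edge is deleted when the aggregate falls below
the dependence threshold theta.  Deletions within an order are batched:
every test at order L sees the graph as it stood when the order began, so
the result does not depend on pair iteration order.  The graph sequence is
a nested chain G0 ⊇ G1 ⊇ ... and the engine stops when an order L >= 1
removes nothing, when no surviving pair has enough common neighbours, or
when the configured maximum order is reached.  Because tests at order L
condition on exactly L variables, a converged order-L network needs only
L + 2 independent samples' worth of covariance information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations

from .errors import InputError
from .estimators import (
    GaussianModel,
    TripleQuery,
    cmi,
    cmi2,
    fit_gaussian,
    mi,
    partial_correlation,
)

__all__ = [
    "InferenceConfig",
    "Network",
    "pair_conditioning_candidates",
    "aggregate_condition_score",
    "infer_network",
    "edge_ranking",
]

MEASURES = ("cmi2", "cmi", "pcor")
AGGREGATIONS = ("max", "geometric-mean")


@dataclass(frozen=True)
class InferenceConfig:
    """Knobs of the path-consistency engine.

    theta
        Dependence threshold in nats (for pcor: correlation units); an
        aggregated score below theta deletes the edge.  Default 0.03, a
        threshold commonly used for expression compendia of moderate
        sample size; sparser data warrant a larger value.
    max_order
        Cap on the conditioning order L; ``None`` runs until convergence.
        Order 1 is a pragmatic cap for networks beyond ~100 genes.
    aggregation
        How the per-conditioning-set scores of one pair are combined:
        ``"max"`` (default) or ``"geometric-mean"``.
    measure
        ``"cmi2"`` (default), ``"cmi"`` (plain conditional mutual
        information, PCA-CMI style), or ``"pcor"`` (absolute partial
        correlation, pcalg style).
    """

    theta: float = 0.03
    max_order: int | None = None
    aggregation: str = "max"
    measure: str = "cmi2"
    log_transform: bool = False
    pseudocount: float = 0.0
    standardize: bool = False
    strict: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise InputError("theta must be nonnegative")
        if self.max_order is not None and self.max_order < 0:
            raise InputError("max_order must be >= 0 (or None for unlimited)")
        if self.aggregation not in AGGREGATIONS:
            raise InputError(f"aggregation must be one of {AGGREGATIONS}")
        if self.measure not in MEASURES:
            raise InputError(f"measure must be one of {MEASURES}")


@dataclass
class Network:
    """Undirected network with a per-pair score ledger.

    ``edges`` holds the surviving adjacency as unordered pairs
    (frozensets).  ``edge_scores`` records, for every pair ever tested,
    the last aggregated measure value computed for it; ``decision_order``
    the conditioning order at which the pair was removed (or last
    retained).  Removed-pair scores are kept, not zeroed, so a ROC curve
    can be drawn from a single run by ranking all pairs.
    """

    genes: tuple[str, ...]
    edges: set = field(default_factory=set)
    edge_scores: dict = field(default_factory=dict)
    decision_order: dict = field(default_factory=dict)
    final_order: int = 0

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        for pair in self.edges:
            if len(pair) != 2:
                raise InputError(f"invalid edge {set(pair)}: self-loops not allowed")

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def neighbors(self, gene: str) -> list[str]:
        return [g for g in self.genes if g != gene and self.has_edge(gene, g)]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for pair in self.edges:
            a, b = sorted(pair)
            g.add_edge(a, b, score=self.edge_scores.get(pair))
        return g


def pair_conditioning_candidates(net: Network, i: str, j: str) -> list[str]:
    """Genes adjacent to both i and j (excluding i and j themselves), in
    the network's gene order.  Its length is the T of the order-L test."""
    if not net.has_edge(i, j):
        raise InputError(f"({i}, {j}) is not an edge of the network")
    return [g for g in net.genes if g not in (i, j) and net.has_edge(i, g) and net.has_edge(j, g)]


def aggregate_condition_score(values, mode: str = "max") -> float:
    """Combine the scores of one pair across its conditioning sets.

    ``max`` keeps an edge alive if any conditioning set still shows
    dependence; ``geometric-mean`` is the softer alternative (zero if any
    individual score is zero).
    """
    values = list(values)
    if not values:
        raise InputError("cannot aggregate an empty score list")
    if any(v < 0 for v in values):
        raise InputError("scores must be nonnegative")
    if mode == "max":
        return float(max(values))
    if mode == "geometric-mean":
        if any(v == 0 for v in values):
            return 0.0
        return float(math.exp(sum(math.log(v) for v in values) / len(values)))
    raise InputError(f"unknown aggregation mode {mode!r}")


def _measure_fn(cfg: InferenceConfig):
    def score(model: GaussianModel, i: str, j: str, k: tuple[str, ...]) -> float:
        q = TripleQuery(i, j, tuple(k)) if k else None
        if cfg.measure == "pcor":
            return partial_correlation(
                model, q or TripleQuery(i, j), strict=cfg.strict
            )
        if not k:
            return mi(model, i, j, strict=cfg.strict)  # order 0: MI for both modes
        if cfg.measure == "cmi2":
            return cmi2(model, q, strict=cfg.strict)
        return cmi(model, q, strict=cfg.strict)

    return score


def infer_network(expr, cfg: InferenceConfig = InferenceConfig()) -> Network:
    """Run the path-consistency loop on an expression matrix.

    Returns a :class:`Network` whose ``final_order`` is the highest order
    at which any pair was actually tested.
    """
    model = fit_gaussian(
        expr,
        log_transform=cfg.log_transform,
        pseudocount=cfg.pseudocount,
        standardize=cfg.standardize,
    )
    genes = model.variables
    if len(genes) < 2:
        raise InputError("at least 2 genes are required for inference")
    score = _measure_fn(cfg)

    net = Network(genes, edges={frozenset(p) for p in combinations(genes, 2)})

    # order 0: plain pairwise dependence on the complete graph
    removals = set()
    for a, b in combinations(genes, 2):
        pair = frozenset((a, b))
        val = score(model, a, b, ())
        net.edge_scores[pair] = val
        net.decision_order[pair] = 0
        if val < cfg.theta:
            removals.add(pair)
    net.edges -= removals
    net.final_order = 0
    if cfg.max_order == 0:
        return net

    order = 0
    while True:
        order += 1
        start_edges = set(net.edges)  # all tests at this order see the order-start graph
        start_net = replace(net, edges=start_edges)
        removals = set()
        tested = False
        for pair in sorted(start_edges, key=lambda p: tuple(sorted(p))):
            a, b = sorted(pair)
            candidates = pair_conditioning_candidates(start_net, a, b)
            if len(candidates) < order:
                continue
            tested = True
            vals = [score(model, a, b, k) for k in combinations(candidates, order)]
            agg = aggregate_condition_score(vals, cfg.aggregation)
            net.edge_scores[pair] = agg
            net.decision_order[pair] = order
            if agg < cfg.theta:
                removals.add(pair)
        if not tested:
            break
        net.final_order = order
        net.edges -= removals
        if not removals:
            break
        if cfg.max_order is not None and order >= cfg.max_order:
            break
    return net


def edge_ranking(net: Network) -> list[tuple[str, str, float]]:
    """All pairs ever scored, ranked by score descending (ties broken by
    gene names).  Retained edges carry their final-order score, removed
    edges the score at removal — the ranking a ROC sweep consumes."""
    rows = [(*sorted(pair), s) for pair, s in net.edge_scores.items()]
    return sorted(rows, key=lambda r: (-r[2], r[0], r[1]))
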