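"""Linear-Gaussian DAG simulator and canonical three-gene fixtures.

Expression is generated from a structural equation model on a directed
acyclic graph: each gene is a weighted sum of its parents plus independent
Gaussian noise.  The implied joint distribution is exactly multivariate
normal with covariance (I - W)^{-T} D (I - W)^{-1}, where W[p, c] is the
weight of edge p -> c and D the diagonal of noise variances — so every
information measure has an analytically known population value and the
estimators can be validated against closed-form ground truth.  This is a
deliberate idealization of the nonlinear ODE simulators used by community
benchmarks: it matches the Gaussian assumption of the estimators, which
is exactly the regime where ground truth is computable.

The three fixture scenarios cover the canonical behaviours of the
measures on a gene triple:

* ``independent-pair`` — X regulates Y, Z unrelated: MI, CMI and CMI2 all
  agree.
* ``mediated-chain`` — X -> Z -> Y with no direct X–Y edge: X and Y are
  conditionally independent given Z, so CMI and CMI2 both vanish and the
  indirect edge is correctly removable.
* ``redundant-conditioner`` — X regulates Y while Z is a near-copy of Y
  (correlation 0.999): conditioning on Z destroys plain CMI (it
  underestimates a genuinely direct edge towards zero) while CMI2 stays
  well away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .estimators import GaussianModel
from .io import ExpressionMatrix

__all__ = [
    "DagModel",
    "random_dag",
    "simulate_expression",
    "population_covariance",
    "population_model",
    "fixture_triples",
    "SCENARIOS",
]

SCENARIOS = ("independent-pair", "mediated-chain", "redundant-conditioner")


@dataclass(frozen=True)
class DagModel:
    """A linear-Gaussian structural equation model on a DAG.

    ``parent_weights`` maps (parent, child) gene-name pairs to edge
    coefficients; ``noise_sd`` gives each gene's noise standard
    deviation; ``topological_order`` is a permutation of ``genes``
    consistent with the edges.
    """

    genes: tuple[str, ...]
    parent_weights: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    topological_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.topological_order:
            object.__setattr__(self, "topological_order", self.genes)
        object.__setattr__(self, "topological_order", tuple(self.topological_order))
        if sorted(self.topological_order) != sorted(self.genes):
            raise InputError("topological_order must be a permutation of genes")
        if not self.noise_sd:
            object.__setattr__(self, "noise_sd", {g: 1.0 for g in self.genes})
        pos = {g: i for i, g in enumerate(self.topological_order)}
        for (p, c), w in self.parent_weights.items():
            if p not in pos or c not in pos:
                raise InputError(f"edge ({p}, {c}) references unknown gene")
            if pos[p] >= pos[c]:
                raise InputError(
                    f"edge ({p}, {c}) violates the topological order (cycle?)"
                )
        for g in self.genes:
            if self.noise_sd.get(g, 0.0) <= 0:
                raise InputError(f"noise_sd for {g!r} must be positive")

    @property
    def skeleton(self) -> set:
        """The undirected edge set — the object the inference engine recovers."""
        return {frozenset((p, c)) for p, c in self.parent_weights}

    def weight_matrix(self) -> np.ndarray:
        """W with W[p, c] = weight of p -> c, genes indexed as in ``genes``."""
        idx = {g: i for i, g in enumerate(self.genes)}
        w = np.zeros((len(self.genes),) * 2)
        for (p, c), val in self.parent_weights.items():
            w[idx[p], idx[c]] = val
        return w


def random_dag(
    n: int, edge_density: float, seed: int | np.random.Generator
) -> DagModel:
    """Sample a random DAG: genes are ordered and each forward pair becomes
    an edge with probability ``edge_density``; weights are uniform on
    ±[0.5, 1.0] (bounded away from zero so every edge is detectable),
    noise standard deviations 1."""
    if n < 2:
        raise InputError("need at least 2 genes")
    if not 0 <= edge_density <= 1:
        raise InputError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = tuple(f"G{i+1}" for i in range(n))
    weights = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_density:
                mag = rng.uniform(0.5, 1.0)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                weights[(genes[i], genes[j])] = sign * mag
    return DagModel(genes, weights, {g: 1.0 for g in genes}, genes)


def population_covariance(dag: DagModel) -> np.ndarray:
    """Exact covariance (I - W)^{-T} D (I - W)^{-1} of the implied joint."""
    w = dag.weight_matrix()
    d = np.diag([dag.noise_sd[g] ** 2 for g in dag.genes])
    inv = np.linalg.inv(np.eye(len(dag.genes)) - w)
    cov = inv.T @ d @ inv
    return 0.5 * (cov + cov.T)


def population_model(dag: DagModel) -> GaussianModel:
    """The exact (zero-mean) Gaussian model implied by the SEM."""
    return GaussianModel(dag.genes, np.zeros(len(dag.genes)), population_covariance(dag))


def simulate_expression(
    dag: DagModel, m: int, seed: int | np.random.Generator
) -> ExpressionMatrix:
    """Draw m samples from the SEM, evaluating genes in topological order."""
    if m < 2:
        raise InputError("need at least 2 samples")
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(dag.genes)}
    values = np.zeros((len(dag.genes), m))
    parents: dict = {g: [] for g in dag.genes}
    for (p, c), wv in dag.parent_weights.items():
        parents[c].append((p, wv))
    for g in dag.topological_order:
        row = rng.normal(0.0, dag.noise_sd[g], size=m)
        for p, wv in parents[g]:
            row += wv * values[idx[p]]
        values[idx[g]] = row
    samples = tuple(f"S{j+1}" for j in range(m))
    return ExpressionMatrix(dag.genes, samples, values)


def _chain_weight_for_corr(r: float) -> tuple[float, float]:
    """Weight and child noise sd so that a unit-variance parent yields a
    unit-variance child with correlation r."""
    return r, float(np.sqrt(1.0 - r * r))


def fixture_triples(scenario: str) -> tuple[GaussianModel, DagModel]:
    """Exact population model + generating DAG for the three canonical
    triple-gene scenarios (all variables unit variance, zero mean):

    * ``independent-pair``: Y = 0.8·X + e, Z independent
      (rho_xy = 0.8, rho_xz = rho_yz = 0).
    * ``mediated-chain``: Z = 0.8·X + e, Y = 0.8·Z + e
      (rho_xz = rho_zy = 0.8, rho_xy = 0.64 — Markov).
    * ``redundant-conditioner``: Y = 0.8·X + e, Z = 0.999·Y + e
      (rho_xy = 0.8, rho_yz = 0.999, rho_xz = 0.7992).
    """
    if scenario not in SCENARIOS:
        raise InputError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    genes = ("X", "Y", "Z")
    if scenario == "independent-pair":
        w, sd = _chain_weight_for_corr(0.8)
        dag = DagModel(genes, {("X", "Y"): w}, {"X": 1.0, "Y": sd, "Z": 1.0}, genes)
    elif scenario == "mediated-chain":
        w, sd = _chain_weight_for_corr(0.8)
        dag = DagModel(
            ("X", "Z", "Y"),
            {("X", "Z"): w, ("Z", "Y"): w},
            {"X": 1.0, "Z": sd, "Y": sd},
            ("X", "Z", "Y"),
        )
    else:  # redundant-conditioner
        w, sd = _chain_weight_for_corr(0.8)
        wz, sdz = _chain_weight_for_corr(0.999)
        dag = DagModel(
            ("X", "Y", "Z"),
            {("X", "Y"): w, ("Y", "Z"): wz},
            {"X": 1.0, "Y": sd, "Z": sdz},
            ("X", "Y", "Z"),
        )
    model = population_model(dag)
    # fixtures are reported over (X, Y, Z) regardless of generation order
    return model.submodel(["X", "Y", "Z"]), dag
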