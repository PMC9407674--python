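"""Binding-similarity kernel, thermodynamic conversions, and ordinariness.

The central object is the pairwise binding similarity between two CDR3
sequences,

    Z_ij = s ** m,

where ``m`` is the edit distance between the sequences and ``s`` is the
average ratio of dissociation constants (Kd1/Kd2, smaller over larger) for
a single amino-acid substitution. The default ``s = 0.30`` is the value
implied by the mean |ddG| of large-scale experimental binding data for
single substitutions (see :mod:`classdiv.ddg`), via

    s = exp(-|ddG| / RT),    |ddG| = -RT ln(Kd1/Kd2),

with R = 1.99e-3 kcal/(mol*K) and T = 298 K.

The *ordinariness* of sequence i in a repertoire is the similarity-weighted
frequency mass around it,

    Z_i = sum_j Z_ij p_j,

the inner sum of the Leinster-Cobbold similarity-sensitive diversity; the
diversity measures in :mod:`classdiv.diversity` need only this vector, so
the full N x N similarity matrix is never required for large repertoires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import edlib
import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .repertoire import Repertoire

__all__ = [
    "ThermoConstants",
    "STANDARD_THERMO",
    "SimilarityModel",
    "OrdinarinessVector",
    "ClusterResult",
    "edit_distance",
    "pair_similarity",
    "ddg_from_ratio",
    "ratio_from_ddg",
    "pairwise_distances",
    "similarity_matrix",
    "ordinariness",
    "cluster_at_threshold",
]


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant (kcal/(mol*K)) and temperature (K) used throughout."""

    R: float = 1.99e-3
    T: float = 298.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0:
            raise ValidationError("R and T must be positive")

    @property
    def RT(self) -> float:
        """Thermal energy scale, ~0.593 kcal/mol at standard temperature."""
        return self.R * self.T


STANDARD_THERMO = ThermoConstants()


@dataclass(frozen=True)
class SimilarityModel:
    """Per-substitution similarity kernel ``Z_ij = s**m``.

    Parameters
    ----------
    s
        Similarity per amino-acid difference, in (0, 1). Default 0.30.
    distance
        ``"levenshtein"`` (default; finite similarity for unequal-length
        pairs) or ``"hamming"`` (equal lengths only).
    m_cap
        Optional distance cap: pairs farther than ``m_cap`` contribute 0 to
        ordinariness, with the truncation error bounded by ``s**(m_cap+1)``
        per entry. ``None`` (default) means exact computation.
    epsilon
        Optional similarity floor: pair similarities below ``epsilon`` are
        set to 0. ``None`` (default) applies no floor.
    """

    s: float = 0.30
    distance: str = "levenshtein"
    m_cap: int | None = None
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.s < 1.0:
            raise ValidationError(f"s must be in (0, 1), got {self.s}")
        if self.distance not in ("levenshtein", "hamming"):
            raise ValidationError(f"unknown distance {self.distance!r}")
        if self.m_cap is not None and self.m_cap < 0:
            raise ValidationError("m_cap must be >= 0 when set")
        if self.epsilon is not None and not 0.0 <= self.epsilon < 1.0:
            raise ValidationError("epsilon must be in [0, 1) when set")

    def similarity(self, a: str, b: str) -> float:
        return pair_similarity(a, b, self)


@dataclass
class OrdinarinessVector:
    """Z_i = sum_j Z_ij p_j per unique sequence, plus truncation metadata."""

    values: np.ndarray
    exact: bool = True
    error_bound: float = 0.0


@dataclass
class ClusterResult:
    """Edit-distance-threshold clustering of a repertoire's unique sequences."""

    labels: np.ndarray
    n_clusters: int
    threshold: int
    method: str


# -- distances and kernel ------------------------------------------------


def edit_distance(a: str, b: str, metric: str = "levenshtein") -> int:
    """Unit-cost edit distance between two sequences.

    ``levenshtein`` allows substitutions, insertions and deletions;
    ``hamming`` counts mismatched positions and requires equal lengths.
    """
    if not a or not b:
        raise ValidationError("edit_distance requires non-empty sequences")
    if metric == "levenshtein":
        if a == b:
            return 0
        return edlib.align(a, b, task="distance")["editDistance"]
    if metric == "hamming":
        if len(a) != len(b):
            raise ValidationError(
                "hamming distance requires equal-length sequences "
                f"(got {len(a)} and {len(b)})"
            )
        return sum(x != y for x, y in zip(a, b))
    raise ValidationError(f"unknown metric {metric!r}")


def _bounded_distance(a: str, b: str, metric: str, k: int | None) -> int | None:
    """Distance, or None if it provably exceeds ``k`` (banded search)."""
    if metric == "hamming":
        d = edit_distance(a, b, "hamming")
        return None if (k is not None and d > k) else d
    if k is not None and abs(len(a) - len(b)) > k:
        return None
    if a == b:
        return 0
    d = edlib.align(a, b, task="distance", k=-1 if k is None else int(k))[
        "editDistance"
    ]
    return None if d < 0 else d


def pair_similarity(a: str, b: str, model: SimilarityModel | None = None) -> float:
    """Binding similarity ``s**m`` for a sequence pair; 1 for identical pairs."""
    if model is None:
        model = SimilarityModel()
    m = edit_distance(a, b, model.distance)
    if model.m_cap is not None and m > model.m_cap:
        return 0.0
    z = model.s**m
    if model.epsilon is not None and z < model.epsilon:
        return 0.0
    return z


# -- thermodynamic conversions ------------------------------------------


def ddg_from_ratio(
    kd_ratio: float, constants: ThermoConstants = STANDARD_THERMO
) -> float:
    """|ddG| in kcal/mol for a Kd ratio in (0, 1]: ``-RT ln(ratio)``."""
    if not 0.0 < kd_ratio <= 1.0:
        raise ValueError(f"kd_ratio must be in (0, 1], got {kd_ratio}")
    return -constants.RT * math.log(kd_ratio)


def ratio_from_ddg(ddg: float, constants: ThermoConstants = STANDARD_THERMO) -> float:
    """Kd ratio in (0, 1] for an absolute ddG >= 0: ``exp(-ddg/RT)``."""
    if ddg < 0.0:
        raise ValueError(f"ddg must be >= 0, got {ddg}")
    return math.exp(-ddg / constants.RT)


# -- repertoire-scale computation ---------------------------------------


def pairwise_distances(
    seqs: Sequence[str],
    metric: str = "levenshtein",
    m_cap: int | None = None,
) -> np.ndarray:
    """Dense pairwise distance matrix over ``seqs``.

    When ``m_cap`` is set, entries whose distance exceeds the cap hold the
    sentinel ``m_cap + 1`` (the search is banded, so capped computation is
    cheaper on long, dissimilar pairs).
    """
    n = len(seqs)
    sentinel = None if m_cap is None else m_cap + 1
    out = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        a = seqs[i]
        for j in range(i + 1, n):
            d = _bounded_distance(a, seqs[j], metric, m_cap)
            out[i, j] = out[j, i] = sentinel if d is None else d
    return out


def similarity_matrix(
    seqs: Sequence[str], model: SimilarityModel | None = None
) -> np.ndarray:
    """Dense ``Z_ij = s**d(i,j)`` matrix (small/medium N only)."""
    if model is None:
        model = SimilarityModel()
    d = pairwise_distances(seqs, model.distance, model.m_cap)
    z = model.s ** d.astype(float)
    if model.m_cap is not None:
        z[d > model.m_cap] = 0.0
    if model.epsilon is not None:
        z[z < model.epsilon] = 0.0
    np.fill_diagonal(z, 1.0)
    return z


def ordinariness(
    rep: Repertoire,
    model: SimilarityModel | None = None,
    matrix_limit: int = 4000,
) -> OrdinarinessVector:
    """Ordinariness ``Z_i = sum_j s**d(i,j) p_j`` for every unique sequence.

    Exact by default. With ``model.m_cap`` set, pairs beyond the cap are
    dropped and the reported ``error_bound = s**(m_cap+1)`` bounds the
    per-entry underestimate (the dropped similarity mass is at most
    ``s**(m_cap+1)`` times a frequency total of at most 1). Repertoires up
    to ``matrix_limit`` unique sequences use a dense matrix product; larger
    ones stream row by row in O(N^2) time but O(N) memory.
    """
    if model is None:
        model = SimilarityModel()
    n = rep.n_unique
    p = rep.frequencies
    if n <= matrix_limit:
        z = similarity_matrix(rep.sequences, model) @ p
    else:
        z = p.astype(float).copy()  # diagonal terms Z_ii p_i = p_i
        seqs = rep.sequences
        s, metric, cap, eps = model.s, model.distance, model.m_cap, model.epsilon
        for i in range(n):
            a = seqs[i]
            for j in range(i + 1, n):
                d = _bounded_distance(a, seqs[j], metric, cap)
                if d is None:
                    continue
                zij = s**d
                if eps is not None and zij < eps:
                    continue
                z[i] += zij * p[j]
                z[j] += zij * p[i]
    exact = model.m_cap is None and model.epsilon is None
    if exact:
        bound = 0.0
    else:
        bound = 0.0 if model.m_cap is None else model.s ** (model.m_cap + 1)
        if model.epsilon is not None:
            bound = max(bound, model.epsilon)
    return OrdinarinessVector(values=z, exact=exact, error_bound=bound)


# -- edit-distance-threshold clustering baselines ------------------------


def cluster_at_threshold(
    rep: Repertoire, t: int, method: str = "components"
) -> ClusterResult:
    """Cluster unique sequences by edit-distance threshold ``t``.

    ``components``: connected components of the graph whose edges join
    pairs at distance <= t (deterministic, merges maximally).

    ``greedy``: repeatedly seed a cluster from the highest-degree
    unassigned node of that graph (ties broken by lexicographically
    smallest sequence), assign the seed and every unassigned sequence
    within distance t of it, and continue until all sequences are
    assigned. This mirrors the common "start from the biggest hub"
    clustering heuristic; its result depends on the seeding rule, which is
    why it is pinned deterministically here.
    """
    if t < 0:
        raise ValidationError("threshold must be >= 0")
    if method not in ("components", "greedy"):
        raise ValidationError(f"unknown clustering method {method!r}")
    seqs = rep.sequences
    n = len(seqs)
    d = pairwise_distances(seqs, "levenshtein", m_cap=t)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(d <= t, k=1))
    graph.add_edges_from(zip(ii.tolist(), jj.tolist()))

    labels = np.full(n, -1, dtype=np.int64)
    if method == "components":
        for c, comp in enumerate(nx.connected_components(graph)):
            labels[list(comp)] = c
        n_clusters = labels.max() + 1
    else:
        degree = dict(graph.degree())
        unassigned = set(range(n))
        c = 0
        while unassigned:
            seed = min(unassigned, key=lambda i: (-degree[i], seqs[i]))
            members = {seed} | (set(graph[seed]) & unassigned)
            labels[list(members)] = c
            unassigned -= members
            c += 1
        n_clusters = c
    return ClusterResult(
        labels=labels, n_clusters=int(n_clusters), threshold=int(t), method=method
    )
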