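"""Synthetic repertoires and binding tables with known ground truth.

Everything the test suite and worked examples need is generated here:

* clonal repertoires — single-substitution lineage networks (a stand-in
  for a somatically hypermutated B cell clonotype) with skewed clone
  sizes;
* the four-repertoire validity panel: one clone, two unrelated clones
  with an isomorphic lineage network, a set of mutually unrelated
  CDR3-like sequences, and uniformly random k-mers, all sharing one count
  multiset so their Hill (sequence) diversity is identical at every q
  while class diversity increases strictly along the panel;
* SKEMPI-like |ddG| tables drawn from truncated-exponential core/noncore
  mixtures, with the generator's implied per-substitution similarity
  recorded as ground truth.

All generators are deterministic under a fixed seed and return their
ground-truth parameters alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .repertoire import CANONICAL_AA, Repertoire
from .similarity import STANDARD_THERMO, ThermoConstants, edit_distance

__all__ = [
    "CloneNetworkSpec",
    "DdgGeneratorSpec",
    "SyntheticRepertoire",
    "reference_counts",
    "make_clone_network",
    "make_two_clone",
    "make_unrelated_set",
    "make_random_kmers",
    "make_validity_quartet",
    "make_clonal_repertoire",
    "make_ddg_table",
    "truncated_exponential_mean",
]

_ALPHABET = np.array(list(CANONICAL_AA))


@dataclass(frozen=True)
class CloneNetworkSpec:
    """Parameters of a synthetic single-clone lineage network.

    Defaults mirror a small somatically hypermutated clonotype: 34 unique
    CDR3s carrying 752 total cells, CDR3 length 17. ``n_mutable_positions``
    optionally confines substitutions to a fixed random subset of interior
    positions; ``None`` allows any interior position.
    """

    n_unique: int = 34
    total_count: int = 752
    cdr3_length: int = 17
    seed: int | None = None
    count_decay: float = 0.85
    n_mutable_positions: int | None = None

    def __post_init__(self) -> None:
        if self.cdr3_length < 3:
            raise ValidationError("cdr3_length must be >= 3")
        if self.n_unique < 1 or self.n_unique > self.total_count:
            raise ValidationError("need 1 <= n_unique <= total_count")
        if not 0.0 < self.count_decay <= 1.0:
            raise ValidationError("count_decay must be in (0, 1]")


@dataclass(frozen=True)
class DdgGeneratorSpec:
    """Parameters of the synthetic |ddG| table generator.

    Core substitutions have a 13-fold geometric mean effect on binding and
    noncore a 4-fold effect by default; |ddG| per region is exponential
    with mean ``RT ln(fold)``, truncated at the extreme-value cutoff.
    """

    core_fold: float = 13.0
    noncore_fold: float = 4.0
    core_weight: float = 0.15
    cutoff: float = 3.2
    n_records: int = 1328
    n_multi: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.core_fold < 1.0 or self.noncore_fold < 1.0:
            raise ValidationError("fold effects must be >= 1")
        if not 0.0 <= self.core_weight <= 1.0:
            raise ValidationError("core_weight must be in [0, 1]")
        if self.cutoff <= 0:
            raise ValidationError("cutoff must be > 0")
        if self.n_records < 1:
            raise ValidationError("n_records must be >= 1")


@dataclass
class SyntheticRepertoire:
    """A generated repertoire with its lineage edges and ground truth."""

    repertoire: Repertoire
    edges: list[tuple[str, str]] | None
    ground_truth: dict


# -- counts -------------------------------------------------------------


def reference_counts(
    n_unique: int, total_count: int, decay: float = 0.85
) -> np.ndarray:
    """Skewed (geometrically decaying) clone counts summing to ``total_count``.

    One dominant ancestor plus geometrically decaying descendant counts,
    each at least 1 — a simple stand-in for the clone-size skew of real
    lineages. Deterministic; used as the shared count multiset of the
    validity panel.
    """
    if n_unique < 1 or total_count < n_unique:
        raise ValidationError("need 1 <= n_unique <= total_count")
    weights = decay ** np.arange(n_unique, dtype=float)
    counts = np.maximum(1, np.floor(weights * total_count / weights.sum())).astype(
        np.int64
    )
    diff = total_count - counts.sum()
    i = 0
    while diff != 0:
        j = i % n_unique
        if diff > 0:
            counts[j] += 1
            diff -= 1
        elif counts[j] > 1:
            counts[j] -= 1
            diff += 1
        i += 1
    return counts


# -- sequence helpers ---------------------------------------------------


def _random_cdr3(rng: np.random.Generator, length: int) -> str:
    """CDR3-like sequence: conserved C ... F flanks, random interior."""
    middle = rng.choice(_ALPHABET, size=length - 2)
    return "C" + "".join(middle) + "F"


def _grow_clone(
    rng: np.random.Generator,
    seed_seq: str,
    n_nodes: int,
    positions: Sequence[int],
) -> tuple[list[str], list[tuple[int, int, str]]]:
    """Grow a lineage by successive single substitutions of random nodes.

    Returns the node list (seed first) and the operations
    ``(parent_index, position, new_residue)``; each child is at distance 1
    from its parent, so the distance-1 graph is connected.
    """
    length = len(seed_seq)
    if n_nodes > 20 ** max(1, len(positions)):
        raise ValidationError("n_unique exceeds the sequence space of the spec")
    nodes = [seed_seq]
    seen = {seed_seq}
    ops: list[tuple[int, int, str]] = []
    attempts = 0
    max_attempts = 1000 * n_nodes
    while len(nodes) < n_nodes:
        attempts += 1
        if attempts > max_attempts:
            raise ValidationError("clone growth failed; spec too constrained")
        parent_idx = int(rng.integers(len(nodes)))
        parent = nodes[parent_idx]
        pos = int(positions[rng.integers(len(positions))])
        residue = str(rng.choice(_ALPHABET))
        if residue == parent[pos]:
            continue
        child = parent[:pos] + residue + parent[pos + 1 :]
        if child in seen:
            continue
        nodes.append(child)
        seen.add(child)
        ops.append((parent_idx, pos, residue))
    assert len(nodes) == n_nodes and length == len(seed_seq)
    return nodes, ops


def _distance1_edges(nodes: Sequence[str]) -> list[tuple[str, str]]:
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if edit_distance(a, b) == 1:
                edges.append((a, b))
    return edges


def _derangement(rng: np.random.Generator, letters: str) -> dict[str, str]:
    """Random fixed-point-free permutation of the alphabet."""
    arr = list(letters)
    while True:
        perm = rng.permutation(len(arr))
        if all(perm[i] != i for i in range(len(arr))):
            return {arr[i]: arr[perm[i]] for i in range(len(arr))}


def _confinement_budget(length: int) -> int:
    """Largest interior position budget that keeps a derangement copy of a
    confined clone at distance >= ceil(length/2) from the original."""
    return max(1, (length - 2) - math.ceil(length / 2))


# -- the validity panel -------------------------------------------------


def make_clone_network(spec: CloneNetworkSpec) -> SyntheticRepertoire:
    """Single-clone lineage network with skewed counts.

    The seed sequence plus successive single-substitution mutants form a
    graph that is connected through distance-1 edges; counts follow
    :func:`reference_counts`.
    """
    rng = np.random.default_rng(spec.seed)
    interior = np.arange(1, spec.cdr3_length - 1)
    if spec.n_mutable_positions is not None:
        if not 1 <= spec.n_mutable_positions <= interior.size:
            raise ValidationError("n_mutable_positions out of range")
        interior = np.sort(
            rng.choice(interior, size=spec.n_mutable_positions, replace=False)
        )
    seed_seq = _random_cdr3(rng, spec.cdr3_length)
    nodes, _ = _grow_clone(rng, seed_seq, spec.n_unique, interior)
    counts = reference_counts(spec.n_unique, spec.total_count, spec.count_decay)
    rep = Repertoire.from_pairs(zip(nodes, counts), label="one-clone")
    return SyntheticRepertoire(
        repertoire=rep,
        edges=_distance1_edges(nodes),
        ground_truth={
            "kind": "one-clone",
            "seed_sequence": seed_seq,
            "n_unique": spec.n_unique,
            "total_count": spec.total_count,
            "mutable_positions": [int(p) for p in interior],
            "seed": spec.seed,
        },
    )


def make_two_clone(spec: CloneNetworkSpec) -> SyntheticRepertoire:
    """Two-clone repertoire with an isomorphic second lineage.

    A reference clone is grown with substitutions confined to a small
    interior position subset; the second half of its nodes is replaced by
    an alphabet-derangement copy (a fixed-point-free residue relabelling
    of the interior). Relabelling preserves all pairwise distances, so the
    replaced half's induced subgraph is reproduced exactly and the count
    multiset is unchanged, while every cross-clone pair differs at all
    unconfined interior positions — distance >= ceil(length/2), i.e.
    negligible cross-clone similarity.
    """
    budget = _confinement_budget(spec.cdr3_length)
    if spec.n_mutable_positions is not None and spec.n_mutable_positions > budget:
        raise ValidationError(
            f"two-clone construction needs n_mutable_positions <= {budget}"
        )
    confined = CloneNetworkSpec(
        n_unique=spec.n_unique,
        total_count=spec.total_count,
        cdr3_length=spec.cdr3_length,
        seed=spec.seed,
        count_decay=spec.count_decay,
        n_mutable_positions=spec.n_mutable_positions or budget,
    )
    rng = np.random.default_rng(spec.seed)
    interior = np.sort(
        rng.choice(
            np.arange(1, spec.cdr3_length - 1),
            size=confined.n_mutable_positions,
            replace=False,
        )
    )
    seed_seq = _random_cdr3(rng, spec.cdr3_length)
    nodes, _ = _grow_clone(rng, seed_seq, spec.n_unique, interior)
    counts = reference_counts(spec.n_unique, spec.total_count, spec.count_decay)

    half = spec.n_unique // 2
    mapping = _derangement(rng, CANONICAL_AA)

    def relabel(seq: str) -> str:
        return seq[0] + "".join(mapping[c] for c in seq[1:-1]) + seq[-1]

    replaced = [relabel(s) for s in nodes[half:]]
    final_nodes = nodes[:half] + replaced
    rep = Repertoire.from_pairs(zip(final_nodes, counts), label="two-clone")
    return SyntheticRepertoire(
        repertoire=rep,
        edges=_distance1_edges(final_nodes),
        ground_truth={
            "kind": "two-clone",
            "seed_sequence": seed_seq,
            "second_seed_sequence": relabel(nodes[half]) if half < len(nodes) else None,
            "block_a": nodes[:half],
            "block_b": replaced,
            "replaced_nodes": nodes[half:],
            "n_unique": spec.n_unique,
            "total_count": spec.total_count,
            "mutable_positions": [int(p) for p in interior],
            "clone_sizes": [half, spec.n_unique - half],
            "seed": spec.seed,
        },
    )


def make_unrelated_set(
    n: int = 34,
    length: int = 17,
    min_pairwise_distance: int = 2,
    seed: int | None = None,
    counts: Sequence[int] | None = None,
) -> SyntheticRepertoire:
    """CDR3-like sequences with every pair at distance >= the minimum.

    Emulates CDR3s sampled from unrelated clones across many repertoires
    (conserved C/F flanks, otherwise random), rejection-sampled so no two
    look like lineage relatives.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValidationError("rejection sampling failed; constraints too tight")
        cand = _random_cdr3(rng, length)
        if all(
            edit_distance(cand, other) >= min_pairwise_distance for other in accepted
        ):
            accepted.append(cand)
    if counts is None:
        counts = np.ones(n, dtype=np.int64)
    rep = Repertoire.from_pairs(zip(accepted, counts), label="unrelated")
    return SyntheticRepertoire(
        repertoire=rep,
        edges=None,
        ground_truth={
            "kind": "unrelated",
            "n": n,
            "length": length,
            "min_pairwise_distance": min_pairwise_distance,
            "seed": seed,
        },
    )


def make_random_kmers(
    n: int = 34,
    length: int = 17,
    seed: int | None = None,
    counts: Sequence[int] | None = None,
) -> SyntheticRepertoire:
    """Uniformly random amino-acid k-mers (no CDR3 flanks), unique."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        cand = "".join(rng.choice(_ALPHABET, size=length))
        if cand not in seen:
            seen.add(cand)
            seqs.append(cand)
    if counts is None:
        counts = np.ones(n, dtype=np.int64)
    rep = Repertoire.from_pairs(zip(seqs, counts), label="random-kmers")
    return SyntheticRepertoire(
        repertoire=rep,
        edges=None,
        ground_truth={"kind": "random", "n": n, "length": length, "seed": seed},
    )


def make_validity_quartet(
    spec: CloneNetworkSpec | None = None,
) -> dict[str, SyntheticRepertoire]:
    """The four-repertoire validity panel sharing one count multiset.

    All four repertoires have identical clone-count multisets (hence
    identical Hill sequence diversity at every q), but class diversity
    increases strictly: one tight clone < two unrelated clones < unrelated
    CDR3-like sequences <= fully random k-mers. The one- and two-clone
    members are built from the *same* confined lineage (the two-clone
    variant relocates half the nodes to an unrelated region of sequence
    space), so their ordering is structural.
    """
    if spec is None:
        spec = CloneNetworkSpec()
    budget = _confinement_budget(spec.cdr3_length)
    confined = CloneNetworkSpec(
        n_unique=spec.n_unique,
        total_count=spec.total_count,
        cdr3_length=spec.cdr3_length,
        seed=spec.seed,
        count_decay=spec.count_decay,
        n_mutable_positions=min(spec.n_mutable_positions or budget, budget),
    )
    counts = reference_counts(spec.n_unique, spec.total_count, spec.count_decay)
    base = 0 if spec.seed is None else spec.seed
    return {
        "one-clone": make_clone_network(confined),
        "two-clone": make_two_clone(confined),
        "unrelated": make_unrelated_set(
            n=spec.n_unique,
            length=spec.cdr3_length,
            seed=base + 1,
            counts=counts,
        ),
        "random": make_random_kmers(
            n=spec.n_unique,
            length=spec.cdr3_length,
            seed=base + 2,
            counts=counts,
        ),
    }


# -- generic clonal repertoires -----------------------------------------


def make_clonal_repertoire(
    n_clones: int,
    n_unique_per_clone: int = 20,
    total_count: int | None = None,
    length: int = 17,
    clone_size_decay: float = 1.0,
    within_clone_decay: float = 0.7,
    n_mutable_positions: int = 2,
    min_seed_distance: int | None = None,
    seed: int | None = None,
) -> SyntheticRepertoire:
    """Union of independent lineage networks with configurable skew.

    Clone seeds are rejection-sampled to pairwise distance
    ``min_seed_distance`` (default ``ceil(length/2) + 2*n_mutable_positions``)
    and each clone mutates only a small private position subset, so every
    cross-clone pair is at distance
    ``>= min_seed_distance - 2*n_mutable_positions >= ceil(length/2)`` and
    cross-clone similarity is negligible. Clone totals decay geometrically
    with ``clone_size_decay``; counts within a clone follow
    :func:`reference_counts` with ``within_clone_decay``.
    """
    if n_clones < 1:
        raise ValidationError("n_clones must be >= 1")
    if min_seed_distance is None:
        min_seed_distance = min(
            length - 2, math.ceil(length / 2) + 2 * n_mutable_positions
        )
    if total_count is None:
        total_count = 20 * n_clones * n_unique_per_clone
    rng = np.random.default_rng(seed)
    interior = np.arange(1, length - 1)
    if n_mutable_positions > interior.size:
        raise ValidationError("n_mutable_positions exceeds interior length")

    seeds: list[str] = []
    attempts = 0
    while len(seeds) < n_clones:
        attempts += 1
        if attempts > 1000 * n_clones:
            raise ValidationError("could not place clone seeds far enough apart")
        cand = _random_cdr3(rng, length)
        if all(edit_distance(cand, s) >= min_seed_distance for s in seeds):
            seeds.append(cand)

    clone_weights = clone_size_decay ** np.arange(n_clones, dtype=float)
    clone_totals = reference_counts(
        n_clones,
        total_count - n_clones * (n_unique_per_clone - 1),
        clone_size_decay,
    ) + (n_unique_per_clone - 1)
    # each clone must hold at least one cell per unique sequence
    del clone_weights

    pairs: list[tuple[str, int]] = []
    all_nodes: list[str] = []
    for c in range(n_clones):
        positions = np.sort(
            rng.choice(interior, size=n_mutable_positions, replace=False)
        )
        nodes, _ = _grow_clone(rng, seeds[c], n_unique_per_clone, positions)
        counts = reference_counts(
            n_unique_per_clone, int(clone_totals[c]), within_clone_decay
        )
        pairs.extend(zip(nodes, counts))
        all_nodes.extend(nodes)
    if len(set(all_nodes)) != len(all_nodes):  # pragma: no cover - far seeds
        raise ValidationError("clone sequence collision; retry with another seed")
    rep = Repertoire.from_pairs(pairs, label=f"clonal-{n_clones}")
    return SyntheticRepertoire(
        repertoire=rep,
        edges=None,
        ground_truth={
            "kind": "clonal",
            "n_clones": n_clones,
            "n_unique_per_clone": n_unique_per_clone,
            "total_count": total_count,
            "clone_seeds": seeds,
            "min_seed_distance": min_seed_distance,
            "n_mutable_positions": n_mutable_positions,
            "min_cross_clone_distance_bound": min_seed_distance
            - 2 * n_mutable_positions,
            "seed": seed,
        },
    )


# -- synthetic binding tables -------------------------------------------


def truncated_exponential_mean(mean: float, cutoff: float) -> float:
    """Mean of an Exp(mean) variable truncated to [0, cutoff]."""
    z = math.exp(-cutoff / mean)
    return mean - cutoff * z / (1.0 - z)


def _sample_truncated_exponential(
    rng: np.random.Generator, mean: float, cutoff: float, size: int
) -> np.ndarray:
    u = rng.random(size)
    return -mean * np.log1p(-u * (1.0 - np.exp(-cutoff / mean)))


_NONCORE_CODES = np.array(["RIM", "SUP", "INT", "SUR"])


def make_ddg_table(
    spec: DdgGeneratorSpec,
    constants: ThermoConstants = STANDARD_THERMO,
) -> tuple[pd.DataFrame, dict]:
    """SKEMPI-like CSV rows from a truncated-exponential core/noncore mix.

    |ddG| per region is exponential with mean ``RT ln(fold)``, truncated
    at ``spec.cutoff``; Kd pairs are reconstructed so that parsing the
    table recovers the generated |ddG| exactly (kd_wt fixed at 1e-9 M).
    The returned ground truth includes the truncated mixture mean and the
    implied per-substitution similarity ``exp(-mean/RT)``. Optional
    multi-substitution rows (``spec.n_multi``) are exactly multiplicative
    in the implied s, for kernel-consistency checks.
    """
    rng = np.random.default_rng(spec.seed)
    rt = constants.RT
    n_core = int(round(spec.core_weight * spec.n_records))
    n_noncore = spec.n_records - n_core

    def region_values(fold: float, size: int) -> np.ndarray:
        if size == 0:
            return np.empty(0)
        mean = rt * math.log(fold)
        if mean == 0.0:
            return np.zeros(size)
        return _sample_truncated_exponential(rng, mean, spec.cutoff, size)

    core_vals = region_values(spec.core_fold, n_core)
    noncore_vals = region_values(spec.noncore_fold, n_noncore)

    def mutation_token(rng: np.random.Generator) -> str:
        wt = str(rng.choice(_ALPHABET))
        mut = str(rng.choice([a for a in CANONICAL_AA if a != wt]))
        pos = int(rng.integers(1, 18))
        return f"{wt}{pos}{mut}"

    rows = []
    kd_wt = 1e-9
    for i, (ddg, region) in enumerate(
        [(v, "COR") for v in core_vals]
        + [(v, str(rng.choice(_NONCORE_CODES))) for v in noncore_vals]
    ):
        rows.append(
            {
                "complex_id": f"SYN{i:04d}",
                "mutation": mutation_token(rng),
                "region_code": region,
                "kd_wt": kd_wt,
                "kd_mut": kd_wt * math.exp(ddg / rt),
                "receptor_class": "IG" if rng.random() < 0.6 else "TR",
            }
        )

    def trunc_mean(fold: float) -> float:
        mean = rt * math.log(fold)
        return 0.0 if mean == 0.0 else truncated_exponential_mean(mean, spec.cutoff)

    mixture_mean = spec.core_weight * trunc_mean(spec.core_fold) + (
        1.0 - spec.core_weight
    ) * trunc_mean(spec.noncore_fold)
    implied_s = math.exp(-mixture_mean / rt)

    for j in range(spec.n_multi):
        m = int(rng.integers(2, 5))
        ddg = -m * rt * math.log(implied_s)
        rows.append(
            {
                "complex_id": f"SYNM{j:04d}",
                "mutation": ",".join(mutation_token(rng) for _ in range(m)),
                "region_code": str(rng.choice(_NONCORE_CODES)),
                "kd_wt": kd_wt,
                "kd_mut": kd_wt * math.exp(ddg / rt),
                "receptor_class": "IG",
            }
        )

    ground_truth = {
        "core_fold": spec.core_fold,
        "noncore_fold": spec.noncore_fold,
        "core_weight": spec.core_weight,
        "cutoff": spec.cutoff,
        "n_records": spec.n_records,
        "n_core": n_core,
        "n_noncore": n_noncore,
        "core_mean_untruncated": rt * math.log(spec.core_fold),
        "noncore_mean_untruncated": rt * math.log(spec.noncore_fold),
        "core_mean_truncated": trunc_mean(spec.core_fold),
        "noncore_mean_truncated": trunc_mean(spec.noncore_fold),
        "mixture_mean_truncated": mixture_mean,
        "implied_s": implied_s,
        "seed": spec.seed,
    }
    return pd.DataFrame(rows), ground_truth
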