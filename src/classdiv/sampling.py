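"""Subsampling, rarefaction, discovery rates, and ordering robustness.

Sequence diversity is notoriously sensitive to sample size (most unique
CDR3s are singletons, so new sequences keep appearing with every
additional cell sampled), whereas class diversity saturates once the main
similarity neighborhoods are represented. The tools here quantify both
behaviors and test whether the *relative ordering* of two repertoires'
class diversities survives subsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diversity import class_diversity, hill_diversity
from .exceptions import EmptyRepertoireError, ValidationError
from .repertoire import Repertoire
from .similarity import SimilarityModel, similarity_matrix

__all__ = [
    "RarefactionCurve",
    "OrderingReport",
    "subsample",
    "metarepertoire",
    "rarefaction",
    "discovery_rate",
    "ordering_robustness",
]


@dataclass
class RarefactionCurve:
    """Diversity (mean +/- SD over replicate subsamples) vs sample size."""

    sizes: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    kind: str  # "sequence" | "class"
    q: float
    n_replicates: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "q": "inf" if math.isinf(self.q) else self.q,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "sizes": [int(s) for s in self.sizes],
            "means": [float(v) for v in self.means],
            "sds": [float(v) for v in self.sds],
        }


@dataclass
class OrderingReport:
    """Per-size agreement of subsampled diversity ratios with full data."""

    sizes: np.ndarray
    fraction_correct: np.ndarray
    ratio_mean: np.ndarray
    ratio_sd: np.ndarray
    full_values: tuple[float, float]
    q: float
    n_replicates: int
    seed: int | None

    @property
    def full_ratio(self) -> float:
        return self.full_values[0] / self.full_values[1]

    def to_dict(self) -> dict:
        return {
            "q": "inf" if math.isinf(self.q) else self.q,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "full_values": [float(v) for v in self.full_values],
            "full_ratio": float(self.full_ratio),
            "sizes": [int(s) for s in self.sizes],
            "fraction_correct": [float(v) for v in self.fraction_correct],
            "ratio_mean": [float(v) for v in self.ratio_mean],
            "ratio_sd": [float(v) for v in self.ratio_sd],
        }


def subsample(
    rep: Repertoire,
    n: int,
    mode: str = "by_frequency",
    seed: int | None = None,
    with_replacement: bool = False,
) -> Repertoire:
    """Random subsample of a repertoire.

    ``by_frequency`` draws ``n`` cells without replacement from the count
    multiset (multivariate hypergeometric; set ``with_replacement`` for
    bootstrap-style multinomial draws). ``uniform_singletons`` draws ``n``
    distinct sequences, each assigned count 1, ignoring clone sizes.
    """
    rng = np.random.default_rng(seed)
    if mode == "by_frequency":
        if not 1 <= n <= rep.total_count:
            raise ValidationError(
                f"n must be in [1, {rep.total_count}] for by_frequency, got {n}"
            )
        if with_replacement:
            drawn = rng.multinomial(n, rep.frequencies)
        else:
            drawn = rng.multivariate_hypergeometric(rep.counts, n)
        keep = drawn > 0
        return Repertoire(
            [s for s, k in zip(rep.sequences, keep) if k],
            drawn[keep],
            label=f"{rep.label}|n={n}",
        )
    if mode == "uniform_singletons":
        if not 1 <= n <= rep.n_unique:
            raise ValidationError(
                f"n must be in [1, {rep.n_unique}] for uniform_singletons, got {n}"
            )
        idx = np.sort(rng.choice(rep.n_unique, size=n, replace=False))
        return Repertoire(
            [rep.sequences[i] for i in idx],
            np.ones(n, dtype=np.int64),
            label=f"{rep.label}|singletons n={n}",
        )
    raise ValidationError(f"unknown subsample mode {mode!r}")


def metarepertoire(reps: Sequence[Repertoire]) -> Repertoire:
    """Pool repertoires into an all-singleton metarepertoire.

    The pooled unique sequence set with every count set to 1 is a
    conservative diversity upper bound: all-singleton repertoires are more
    diverse than any repertoire with larger clone sizes over the same
    sequences.
    """
    if len(reps) < 2:
        raise ValidationError("need at least 2 repertoires to pool")
    pooled = sorted({s for rep in reps for s in rep.sequences})
    if not pooled:
        raise EmptyRepertoireError("empty pool")
    return Repertoire(pooled, np.ones(len(pooled), dtype=np.int64), label="meta")


class _ClassDiversityEngine:
    """Class diversity for subsamples of one parent repertoire.

    For parents of moderate richness the parent's similarity matrix is
    computed once and subsample ordinariness obtained by slicing; larger
    parents fall back to per-subsample ordinariness.
    """

    def __init__(
        self,
        parent: Repertoire,
        model: SimilarityModel,
        matrix_limit: int = 4000,
    ) -> None:
        self.model = model
        if parent.n_unique <= matrix_limit:
            self.index = {s: i for i, s in enumerate(parent.sequences)}
            self.matrix = similarity_matrix(parent.sequences, model)
        else:
            self.index = None
            self.matrix = None

    def value(self, rep: Repertoire, q: float) -> float:
        if self.matrix is None:
            return class_diversity(rep, q, model=self.model)
        idx = np.fromiter(
            (self.index[s] for s in rep.sequences), dtype=np.int64, count=len(rep)
        )
        zi = self.matrix[np.ix_(idx, idx)] @ rep.frequencies
        return class_diversity(rep, q, zi=zi)


def rarefaction(
    rep: Repertoire,
    sizes: Sequence[int],
    n_replicates: int = 10,
    kind: str = "sequence",
    model: SimilarityModel | None = None,
    q: float = 0.0,
    seed: int | None = None,
    mode: str = "by_frequency",
) -> RarefactionCurve:
    """Mean +/- SD diversity over replicate subsamples at each size.

    ``kind="sequence"`` rarefies the Hill number at ``q`` (richness by
    default); ``kind="class"`` rarefies ``qD_S`` under ``model``
    (default kernel if None).
    """
    sizes_arr = np.asarray(sorted(sizes), dtype=np.int64)
    if sizes_arr.size == 0:
        raise ValidationError("sizes must be non-empty")
    if np.any(np.diff(sizes_arr) <= 0):
        raise ValidationError("sizes must be strictly increasing")
    if kind not in ("sequence", "class"):
        raise ValidationError(f"unknown rarefaction kind {kind!r}")
    engine = None
    if kind == "class":
        engine = _ClassDiversityEngine(rep, model or SimilarityModel())
    rng = np.random.default_rng(seed)
    means = np.empty(sizes_arr.size)
    sds = np.empty(sizes_arr.size)
    limit = rep.total_count if mode == "by_frequency" else rep.n_unique
    for k, size in enumerate(sizes_arr):
        if size > limit:
            raise ValidationError(f"size {size} exceeds repertoire ({limit})")
        vals = np.empty(n_replicates)
        for r in range(n_replicates):
            sub = subsample(rep, int(size), mode=mode, seed=rng.integers(2**31))
            if kind == "sequence":
                vals[r] = hill_diversity(sub, q)
            else:
                vals[r] = engine.value(sub, q)
        means[k] = vals.mean()
        sds[k] = vals.std(ddof=1) if n_replicates > 1 else 0.0
    return RarefactionCurve(
        sizes=sizes_arr,
        means=means,
        sds=sds,
        kind=kind,
        q=q,
        n_replicates=n_replicates,
        seed=seed,
    )


def discovery_rate(curve: RarefactionCurve, delta: float = 0.1) -> np.ndarray:
    """Marginal rate of new-diversity discovery per additional cell.

    Estimated by a backward finite difference on the (interpolated)
    rarefaction curve: ``(value(n) - value(n(1-delta))) / (n*delta)``. The
    curve is anchored at (0, 0). For sequence richness the rate lies in
    [0, 1] (each cell adds at most one new sequence).
    """
    if curve.sizes.size < 2:
        raise ValidationError("discovery rate needs a curve with >= 2 sizes")
    if not 0.0 < delta < 1.0:
        raise ValidationError("delta must be in (0, 1)")
    xs = np.concatenate([[0.0], curve.sizes.astype(float)])
    ys = np.concatenate([[0.0], curve.means])
    n = curve.sizes.astype(float)
    lower = np.interp(n * (1.0 - delta), xs, ys)
    return (curve.means - lower) / (n * delta)


def ordering_robustness(
    rep1: Repertoire,
    rep2: Repertoire,
    q: float = 0.0,
    model: SimilarityModel | None = None,
    sizes: Sequence[int] = (100, 300, 1000, 3000),
    n_replicates: int = 20,
    seed: int | None = None,
) -> OrderingReport:
    """How reliably subsamples reproduce the full-data diversity ordering.

    Both repertoires are subsampled ``n_replicates`` times at each size;
    ``qD_S`` is computed per subsample and ratios are formed over all
    replicate pairs. Reports, per size, the fraction of pairs agreeing
    with the full-data ordering and the ratio mean +/- SD. For
    repertoires with genuinely different diversity the fraction tends to 1
    as the sample size grows; for identical repertoires it hovers at
    chance (~0.5).
    """
    model = model or SimilarityModel()
    sizes_arr = np.asarray(sorted(sizes), dtype=np.int64)
    max_size = int(sizes_arr.max())
    if rep1.total_count < max_size or rep2.total_count < max_size:
        raise ValidationError("both repertoires must exceed the largest size")
    engine1 = _ClassDiversityEngine(rep1, model)
    engine2 = _ClassDiversityEngine(rep2, model)
    full1 = engine1.value(rep1, q)
    full2 = engine2.value(rep2, q)
    first_larger = full1 > full2
    rng = np.random.default_rng(seed)
    fraction = np.empty(sizes_arr.size)
    ratio_mean = np.empty(sizes_arr.size)
    ratio_sd = np.empty(sizes_arr.size)
    for k, size in enumerate(sizes_arr):
        d1 = np.array(
            [
                engine1.value(
                    subsample(rep1, int(size), seed=rng.integers(2**31)), q
                )
                for _ in range(n_replicates)
            ]
        )
        d2 = np.array(
            [
                engine2.value(
                    subsample(rep2, int(size), seed=rng.integers(2**31)), q
                )
                for _ in range(n_replicates)
            ]
        )
        ratios = d1[:, None] / d2[None, :]
        agree = (d1[:, None] > d2[None, :]) == first_larger
        fraction[k] = agree.mean()
        ratio_mean[k] = ratios.mean()
        ratio_sd[k] = ratios.std(ddof=1)
    return OrderingReport(
        sizes=sizes_arr,
        fraction_correct=fraction,
        ratio_mean=ratio_mean,
        ratio_sd=ratio_sd,
        full_values=(float(full1), float(full2)),
        q=q,
        n_replicates=n_replicates,
        seed=seed,
    )
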