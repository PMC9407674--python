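"""Hill (sequence) diversity and similarity-sensitive (class) diversity.

Both families are "effective numbers" parameterized by the viewpoint
parameter q >= 0 (larger q up-weights dominant clones):

* sequence diversity, Hill numbers over clone frequencies p_i:

      qD   = (sum_i p_i**q) ** (1/(1-q)),            q not in {1, inf}
      1D   = exp(-sum_i p_i ln p_i)                  (Shannon limit)
      infD = 1 / max_i p_i                           (Berger-Parker limit)

* class diversity, the Leinster-Cobbold similarity-sensitive version,
  with Z_i = sum_j Z_ij p_j the ordinariness of sequence i:

      qD_S   = (sum_i p_i Z_i**(q-1)) ** (1/(1-q)),  q not in {1, inf}
      1D_S   = prod_i (1/Z_i)**p_i
      infD_S = 1 / max_i Z_i

With the identity kernel (Z = I) class diversity reduces exactly to the
Hill numbers. Because Z_ii = 1 and Z_ij >= 0 imply p_i <= Z_i <= 1,
1 <= qD_S <= qD <= richness for every q, and both profiles are
non-increasing in q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError
from .repertoire import Repertoire
from .similarity import OrdinarinessVector, SimilarityModel, ordinariness

__all__ = [
    "DiversityProfile",
    "effective_number",
    "block_ordinariness",
    "hill_diversity",
    "class_diversity",
    "class_bpi",
    "diversity_profile",
    "off_diagonal_report",
]

#: |q - 1| below which the Shannon-limit closed form is used.
Q_ONE_TOL = 1e-9


def _check_q(q: float) -> float:
    q = float(q)
    if math.isnan(q) or q < 0:
        raise ValueError(f"viewpoint parameter q must be >= 0 or inf, got {q}")
    return q


def effective_number(p: np.ndarray, zi: np.ndarray, q: float) -> float:
    """Evaluate the effective-number formula for frequencies ``p`` and
    ordinariness ``zi`` at viewpoint ``q``.

    Zero-frequency entries are excluded from all sums and from the q=inf
    maximum (the measure is defined on the support). The q=1 product form
    is evaluated in log space for numerical stability.
    """
    q = _check_q(q)
    p = np.asarray(p, dtype=float)
    zi = np.asarray(zi, dtype=float)
    support = p > 0
    p, zi = p[support], zi[support]
    if p.size == 0:
        raise ValidationError("no support: all frequencies are zero")
    if math.isinf(q):
        return float(1.0 / zi.max())
    if abs(q - 1.0) < Q_ONE_TOL:
        return float(np.exp(-np.sum(p * np.log(zi))))
    return float(np.sum(p * zi ** (q - 1.0)) ** (1.0 / (1.0 - q)))


def block_ordinariness(p: np.ndarray, labels: Sequence) -> np.ndarray:
    """Ordinariness under an idealized block kernel: similarity 1 within a
    block, 0 across blocks, so ``Z_i`` is the total frequency of i's block.

    This is the kernel behind the textbook worked example of a repertoire
    whose sequences all bind one of a few completely unrelated antigens:
    at q = 0 the class diversity is exactly the number of blocks,
    independent of the frequency split.
    """
    p = np.asarray(p, dtype=float)
    labels = np.asarray(labels)
    if p.shape != labels.shape:
        raise ValidationError("p and labels must align")
    zi = np.empty_like(p)
    for lab in np.unique(labels):
        mask = labels == lab
        zi[mask] = p[mask].sum()
    return zi


def hill_diversity(rep: Repertoire, q: float) -> float:
    """Hill sequence diversity ``qD`` of a repertoire."""
    q = _check_q(q)
    p = rep.frequencies
    if math.isinf(q):
        return float(1.0 / p.max())
    if abs(q - 1.0) < Q_ONE_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def class_diversity(
    rep: Repertoire,
    q: float,
    model: SimilarityModel | None = None,
    zi: OrdinarinessVector | np.ndarray | None = None,
) -> float:
    """Similarity-sensitive class diversity ``qD_S``.

    ``model=None`` means the identity kernel (Z_i = p_i), under which the
    result equals :func:`hill_diversity`. A precomputed ordinariness
    vector ``zi`` short-circuits the kernel computation (used by batch and
    subsampling code paths).
    """
    q = _check_q(q)
    if zi is None:
        if model is None:
            zi_values = rep.frequencies
        else:
            zi_values = ordinariness(rep, model).values
    elif isinstance(zi, OrdinarinessVector):
        zi_values = zi.values
    else:
        zi_values = np.asarray(zi, dtype=float)
    return effective_number(rep.frequencies, zi_values, q)


def class_bpi(
    rep: Repertoire,
    model: SimilarityModel | None = None,
    zi: OrdinarinessVector | np.ndarray | None = None,
) -> float:
    """Class Berger-Parker index, ``1 / infD_S = max_i Z_i``.

    High class BPI means the repertoire holds a large mass of mutually
    similar sequences, regardless of whether any single clone is large.
    With the identity kernel this is the ordinary BPI, ``max_i p_i``.
    """
    return 1.0 / class_diversity(rep, math.inf, model=model, zi=zi)


@dataclass
class DiversityProfile:
    """Diversity as a function of the viewpoint parameter q."""

    q_values: tuple[float, ...]
    values: np.ndarray
    kind: str  # "sequence" or "class"
    s: float | None = None  # kernel s for class profiles, None for sequence

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "s": self.s,
            "q": ["inf" if math.isinf(q) else q for q in self.q_values],
            "values": [float(v) for v in self.values],
        }


def diversity_profile(
    rep: Repertoire,
    q_values: Iterable[float],
    model: SimilarityModel | None = None,
    kinds: Sequence[str] = ("sequence", "class"),
) -> dict[str, DiversityProfile]:
    """Evaluate sequence and/or class diversity over a grid of q values.

    The ordinariness vector is computed once and reused across q. Returns
    a dict keyed by kind.
    """
    q_tuple = tuple(_check_q(q) for q in q_values)
    if not q_tuple:
        raise ValidationError("q_values must be non-empty")
    out: dict[str, DiversityProfile] = {}
    if "sequence" in kinds:
        vals = np.array([hill_diversity(rep, q) for q in q_tuple])
        out["sequence"] = DiversityProfile(q_tuple, vals, kind="sequence")
    if "class" in kinds:
        zi = None if model is None else ordinariness(rep, model)
        vals = np.array(
            [class_diversity(rep, q, model=model, zi=zi) for q in q_tuple]
        )
        out["class"] = DiversityProfile(
            q_tuple, vals, kind="class", s=None if model is None else model.s
        )
    return out


def off_diagonal_report(
    rep: Repertoire, model: SimilarityModel | None = None
) -> dict[str, float]:
    """Summarize the off-diagonal similarity mass ``Z_i - p_i`` per sequence.

    q-sensitivity of the class profile requires most of this mass to be
    small; the report states it without imposing a criterion.
    """
    zi = ordinariness(rep, model if model is not None else SimilarityModel())
    off = zi.values - rep.frequencies
    return {
        "mean": float(off.mean()),
        "median": float(np.median(off)),
        "max": float(off.max()),
    }
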