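"""Repertoire container and I/O.

A repertoire is the multiset of antibody or TCR CDR3 amino-acid sequences
recovered from one sample, stored as unique sequences with clone counts.
All downstream measures operate on the normalized clone frequencies
``p_i = count_i / sum(counts)``.

Supported on-disk dialects:

* AIRR Rearrangement TSV with columns ``junction_aa`` and
  ``duplicate_count`` (a missing ``duplicate_count`` column, or cell, is
  treated as 1);
* plain two-column TSV, ``sequence<TAB>count``, with or without the header
  line ``sequence\\tcount``;
* FASTA, with the clone count parsed from a ``count=N`` token in the record
  description (default 1).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import EmptyRepertoireError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

FORMATS = ("airr-tsv", "tsv", "fasta")

_COUNT_TOKEN = re.compile(r"\bcount=(\d+)\b")


class Repertoire:
    """Unique CDR3 sequences with clone counts and frequencies.

    Parameters
    ----------
    sequences
        Unique, uppercase sequences over the 20 canonical amino acids.
    counts
        Positive integer clone count per sequence.
    label
        Free-text identifier carried through analyses and outputs.

    Use :meth:`from_pairs` (or :func:`read_repertoire`) to build a
    repertoire from raw, possibly duplicated rows; the constructor itself
    requires already-collapsed input.
    """

    __slots__ = ("sequences", "counts", "label", "_frequencies")

    def __init__(
        self,
        sequences: Sequence[str],
        counts: Sequence[int],
        label: str = "",
    ) -> None:
        sequences = tuple(sequences)
        if len(sequences) == 0:
            raise EmptyRepertoireError("repertoire has no sequences")
        counts_arr = np.asarray(counts)
        if counts_arr.shape != (len(sequences),):
            raise ValidationError("counts must align one-to-one with sequences")
        if not np.issubdtype(counts_arr.dtype, np.integer):
            if not np.all(counts_arr == np.floor(counts_arr)):
                raise ValidationError("counts must be integers")
            counts_arr = counts_arr.astype(np.int64)
        else:
            counts_arr = counts_arr.astype(np.int64)
        if np.any(counts_arr < 1):
            raise ValidationError("counts must be >= 1")
        seen = set()
        for s in sequences:
            _validate_sequence(s)
            if s in seen:
                raise ValidationError(f"duplicate sequence {s!r}; collapse first")
            seen.add(s)
        self.sequences = sequences
        self.counts = counts_arr
        self.counts.setflags(write=False)
        self.label = label
        self._frequencies: np.ndarray | None = None

    # -- construction ----------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[Tuple[str, int]],
        label: str = "",
        strict: bool = True,
    ) -> "Repertoire":
        """Collapse raw ``(sequence, count)`` rows into a repertoire.

        Sequences are uppercased and compared case-insensitively; duplicate
        rows have their counts summed; the result is stored in lexicographic
        sequence order (so collapsing is order-independent). In strict mode
        a sequence containing a non-canonical residue (X, B, Z, ``*``, ...)
        raises :class:`ValidationError`; in lenient mode the row is dropped
        with a logged warning.
        """
        agg: dict[str, int] = {}
        n_dropped = 0
        for seq, count in pairs:
            seq = str(seq).strip().upper()
            count = _as_count(count)
            if not seq or not _CANONICAL_SET.issuperset(seq):
                if strict:
                    _validate_sequence(seq)  # raises with a precise message
                n_dropped += 1
                continue
            agg[seq] = agg.get(seq, 0) + count
        if n_dropped:
            logger.warning(
                "dropped %d row(s) with empty or non-canonical sequences", n_dropped
            )
        if not agg:
            raise EmptyRepertoireError("no valid sequences after collapsing")
        seqs = sorted(agg)
        return cls(seqs, [agg[s] for s in seqs], label=label)

    # -- basic protocol --------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequences)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Repertoire(label={self.label!r}, n_unique={self.n_unique}, "
            f"total_count={self.total_count})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Repertoire):
            return NotImplemented
        return self.sequences == other.sequences and np.array_equal(
            self.counts, other.counts
        )

    def __hash__(self) -> int:
        return hash((self.sequences, self.counts.tobytes()))

    # -- derived quantities ----------------------------------------------

    @property
    def n_unique(self) -> int:
        """Number of unique sequences (species richness at the sequence level)."""
        return len(self.sequences)

    @property
    def total_count(self) -> int:
        """Total number of cells/reads represented."""
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Clone frequencies ``p_i = count_i / total``; sums to 1."""
        if self._frequencies is None:
            freqs = self.counts / self.counts.sum()
            freqs.setflags(write=False)
            self._frequencies = freqs
        return self._frequencies

    def to_pairs(self) -> list[Tuple[str, int]]:
        return [(s, int(c)) for s, c in zip(self.sequences, self.counts)]


def _as_count(count) -> int:
    try:
        as_float = float(count)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"count {count!r} is not a number") from exc
    if as_float != int(as_float):
        raise ValidationError(f"count {count!r} is not an integer")
    value = int(as_float)
    if value < 1:
        raise ValidationError(f"count must be >= 1, got {value}")
    return value


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise ValidationError("empty sequence")
    bad = set(seq) - _CANONICAL_SET
    if bad:
        raise ValidationError(
            f"sequence {seq!r} contains non-canonical residues {sorted(bad)}"
        )


def collapse_and_normalize(
    raw: Iterable[Tuple[str, int]], label: str = "", strict: bool = True
) -> Repertoire:
    """Collapse duplicate sequences, sum counts, normalize frequencies."""
    return Repertoire.from_pairs(raw, label=label, strict=strict)


# -- reading ------------------------------------------------------------


def read_repertoire(
    path,
    format: str | None = None,
    strict: bool = True,
    label: str | None = None,
) -> Repertoire:
    """Read a repertoire from ``path`` in one of the supported dialects.

    ``format`` is one of ``airr-tsv``, ``tsv``, ``fasta``; when omitted it
    is inferred from the file suffix and, for TSV, from the header line.
    """
    path = Path(path)
    if format is None:
        format = _infer_format(path)
    if format not in FORMATS:
        raise FormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    if label is None:
        label = path.stem
    if format == "fasta":
        pairs = _read_fasta(path)
    elif format == "airr-tsv":
        pairs = _read_airr(path)
    else:
        pairs = _read_tsv(path)
    return Repertoire.from_pairs(pairs, label=label, strict=strict)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fasta", ".fa", ".faa"):
        return "fasta"
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if first.startswith(">"):
        return "fasta"
    if "junction_aa" in first.split("\t"):
        return "airr-tsv"
    return "tsv"


def _read_airr(path: Path) -> list[Tuple[str, int]]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyRepertoireError(f"{path} is empty") from exc
    if "junction_aa" not in df.columns:
        raise FormatError(f"{path}: AIRR TSV lacks required column 'junction_aa'")
    if df.empty:
        raise EmptyRepertoireError(f"{path} has no rearrangement rows")
    if "duplicate_count" in df.columns:
        counts = df["duplicate_count"].fillna("1")
    else:
        counts = pd.Series(["1"] * len(df))
    return list(zip(df["junction_aa"].fillna(""), counts))


def _read_tsv(path: Path) -> list[Tuple[str, int]]:
    pairs: list[Tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and [f.strip().lower() for f in fields[:2]] == [
                "sequence",
                "count",
            ]:
                continue
            if len(fields) < 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 'sequence<TAB>count', got {line!r}"
                )
            try:
                count = int(fields[1])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: count {fields[1]!r} is not an integer"
                ) from exc
            pairs.append((fields[0], count))
    if not pairs:
        raise EmptyRepertoireError(f"{path} contains no sequence rows")
    return pairs


def _read_fasta(path: Path) -> list[Tuple[str, int]]:
    pairs: list[Tuple[str, int]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        match = _COUNT_TOKEN.search(record.description)
        count = int(match.group(1)) if match else 1
        pairs.append((str(record.seq), count))
    if not pairs:
        raise EmptyRepertoireError(f"{path} contains no FASTA records")
    return pairs


# -- writing ------------------------------------------------------------


def write_repertoire(rep: Repertoire, path, format: str = "airr-tsv") -> Path:
    """Write ``rep`` to ``path``; round-trips losslessly through
    :func:`read_repertoire` (sequence set and counts)."""
    path = Path(path)
    if format == "airr-tsv":
        df = pd.DataFrame(
            {"junction_aa": rep.sequences, "duplicate_count": rep.counts}
        )
        df.to_csv(path, sep="\t", index=False)
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("sequence\tcount\n")
            for seq, count in rep.to_pairs():
                fh.write(f"{seq}\t{count}\n")
    elif format == "fasta":
        records = [
            SeqRecord(Seq(seq), id=f"seq{i + 1}", description=f"count={count}")
            for i, (seq, count) in enumerate(rep.to_pairs())
        ]
        SeqIO.write(records, str(path), "fasta")
    else:
        raise FormatError(f"unknown format {format!r}; expected one of {FORMATS}")
    return path
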