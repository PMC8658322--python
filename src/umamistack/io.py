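"""Peptide sequence I/O and the labeled-dataset container.

Peptides are short sequences over the 20 standard amino-acid letters
(A, C, D, E, F, G, H, I, K, L, M, N, P, Q, R, S, T, V, W, Y). Labels are
binary: 1 for umami (positive), 0 for non-umami (negative). Labels can be
supplied either as a two-column tab-separated table (``id<TAB>label``) or
as a FASTA header suffix ``|1`` / ``|0``; when both are present the table
wins.

Non-standard residues (B, J, O, U, X, Z, gaps, ...) are rejected rather
than imputed: every downstream encoder assumes the 20-letter alphabet.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._tables import ALPHABET

logger = logging.getLogger(__name__)

_ALPHABET_SET = frozenset(ALPHABET)


class SequenceError(ValueError):
    """A sequence violates the 20-letter amino-acid alphabet."""


class DatasetError(ValueError):
    """A dataset violates its structural invariants."""


def validate_sequence(raw: str) -> str:
    """Canonicalize a peptide sequence to uppercase and validate it.

    Returns the uppercased sequence iff every residue is one of the 20
    standard amino-acid letters. Idempotent.

    Raises
    ------
    SequenceError
        If the sequence is empty or contains a character outside the
        alphabet; the message names the 1-based position and character.
    """
    if raw is None:
        raise SequenceError("sequence is None")
    seq = raw.strip().upper()
    if not seq:
        raise SequenceError("empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _ALPHABET_SET:
            raise SequenceError(
                f"invalid residue {ch!r} at position {pos} "
                f"(allowed: {ALPHABET})"
            )
    return seq


@dataclass(frozen=True)
class Peptide:
    """A validated amino-acid sequence with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[Peptide]:
    """Read peptides from a FASTA file, preserving record order.

    Sequence characters are uppercased and whitespace-stripped; a header
    suffix ``|0`` / ``|1`` (label convention) is kept as part of the id
    here and interpreted by :func:`load_dataset`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    peptides: list[Peptide] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).replace(" ", "")
        if not raw:
            raise SequenceError(f"record {rec.id!r}: empty sequence")
        try:
            peptides.append(Peptide(id=rec.id, sequence=raw))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    if not peptides:
        raise DatasetError(f"no FASTA records found in {path}")
    return peptides


def write_fasta(peptides: Iterable[Peptide], path: str | Path) -> None:
    """Write peptides to FASTA (canonical uppercase, one line per seq)."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def read_label_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of ``id<TAB>label`` with labels in {0, 1}."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetError(
                    f"{path}:{lineno}: expected 'id<TAB>label', got {line!r}"
                )
            pid, lab = parts
            if lab not in ("0", "1"):
                raise DatasetError(
                    f"{path}:{lineno}: label must be 0 or 1, got {lab!r}"
                )
            labels[pid] = int(lab)
    return labels


@dataclass
class LabeledDataset:
    """An ordered collection of unique peptides with binary labels."""

    peptides: list[Peptide]
    labels: np.ndarray
    name: str = "dataset"

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def __len__(self) -> int:
        return len(self.peptides)

    def subset(self, indices: Sequence[int], name: str | None = None) -> "LabeledDataset":
        """Row-subset preserving order of ``indices``."""
        idx = list(indices)
        return LabeledDataset(
            peptides=[self.peptides[i] for i in idx],
            labels=self.labels[idx],
            name=name or self.name,
        )


def make_dataset(
    peptides: Sequence[Peptide],
    labels: Sequence[int],
    name: str = "dataset",
    require_both_classes: bool = False,
) -> LabeledDataset:
    """Assemble a labeled dataset, enforcing uniqueness of sequences.

    Raises
    ------
    DatasetError
        On length mismatch, duplicate sequence, a label outside {0, 1},
        or (if ``require_both_classes``) a single-class label vector.
    """
    if len(peptides) != len(labels):
        raise DatasetError(
            f"{len(peptides)} peptides but {len(labels)} labels"
        )
    y = np.asarray(labels)
    if y.size and not np.isin(y, (0, 1)).all():
        bad = y[~np.isin(y, (0, 1))][0]
        raise DatasetError(f"labels must be in {{0, 1}}, got {bad!r}")
    seen: dict[str, str] = {}
    for p in peptides:
        if p.sequence in seen:
            raise DatasetError(
                f"duplicate sequence {p.sequence!r} "
                f"(ids {seen[p.sequence]!r} and {p.id!r})"
            )
        seen[p.sequence] = p.id
    if require_both_classes and len(set(y.tolist())) < 2:
        raise DatasetError("training dataset needs both classes present")
    n_pos = int(y.sum())
    logger.info(
        "%s: %d peptides (%d positive, %d negative)",
        name, len(peptides), n_pos, len(peptides) - n_pos,
    )
    return LabeledDataset(list(peptides), y.astype(np.int64), name)


def load_dataset(
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    name: str | None = None,
) -> LabeledDataset:
    """Load a labeled dataset from FASTA plus either a label table or
    ``|0`` / ``|1`` header suffixes (table takes precedence)."""
    peptides = read_fasta(fasta_path)
    table = read_label_table(labels_path) if labels_path else None
    labels: list[int] = []
    clean: list[Peptide] = []
    for p in peptides:
        base, _, suffix = p.id.rpartition("|")
        has_suffix = base != "" and suffix in ("0", "1")
        pid = base if has_suffix else p.id
        if table is not None:
            if pid in table:
                lab = table[pid]
            elif p.id in table:
                pid, lab = p.id, table[p.id]
            else:
                raise DatasetError(f"no label for record {p.id!r}")
        elif has_suffix:
            lab = int(suffix)
        else:
            raise DatasetError(
                f"record {p.id!r} has no '|0'/'|1' suffix and no label table"
            )
        clean.append(Peptide(id=pid, sequence=p.sequence))
        labels.append(lab)
    ds = make_dataset(clean, labels, name=name or Path(fasta_path).stem)
    n_pos = int(ds.labels.sum())
    print(
        f"{ds.name}: {len(ds)} peptides ({n_pos} positive / "
        f"{len(ds) - n_pos} negative)",
        file=sys.stderr,
    )
    return ds
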