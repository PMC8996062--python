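"""Reading, validating and writing pre-miRNA sequence data.

All external sequence data enters through this module. FASTA records are
canonicalized on input — uppercased, with T mapped to U — so DNA-alphabet
files, which are common in miRNA databases, load transparently. Any residue
outside {A, C, G, U} after canonicalization is a hard error rather than a
silent skip: every downstream feature encoder assumes a clean four-letter
alphabet in its denominators.

Labels are binary essentiality marks: 1 = essential (the positive class
throughout the package), 0 = non-essential.
"""

from __future__ import annotations

import dataclasses
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")


class SequenceError(ValueError):
    """A sequence record violates the RNA-alphabet or identity contract."""


class LabelError(ValueError):
    """A label table is inconsistent with the sequence collection."""


def canonicalize(raw: str) -> str:
    """Uppercase and map T to U. Idempotent; does not validate the alphabet."""
    return raw.upper().replace("T", "U")


@dataclasses.dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence over the alphabet {A, C, G, U}.

    Parameters
    ----------
    id : str
        Non-empty identifier (FASTA header up to the first whitespace).
    residues : str
        Canonical residue string; validated on construction.
    description : str
        Remainder of the FASTA header; metadata only, never part of identity.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            ch = sorted(bad)[0]
            raise SequenceError(
                f"sequence {self.id!r} contains invalid character {ch!r}; "
                "the alphabet is A, C, G, U (T is converted to U on input)"
            )

    @classmethod
    def from_raw(cls, id: str, raw: str, description: str = "") -> "RnaSequence":
        """Build from a raw (possibly DNA-alphabet, lowercase) string."""
        return cls(id=id, residues=canonicalize(raw), description=description)

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclasses.dataclass(frozen=True)
class LabeledDataset:
    """Index-aligned sequences and binary essentiality labels."""

    sequences: tuple[RnaSequence, ...]
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise LabelError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        bad = sorted({l for l in self.labels if l not in (0, 1)})
        if bad:
            raise LabelError(f"labels must be 0 or 1; found {bad}")

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=int)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def read_fasta(path: str | os.PathLike) -> list[RnaSequence]:
    """Read a FASTA file into validated, canonicalized :class:`RnaSequence`.

    Record order is preserved. The id is the header up to the first
    whitespace; the remainder is kept as ``description``. Duplicate ids and
    non-{A,C,G,U,T} residues are hard errors.
    """
    path = Path(path)
    out: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(RnaSequence.from_raw(rec.id, str(rec.seq), desc))
    return out


def write_fasta(sequences: Iterable[RnaSequence], path: str | os.PathLike) -> None:
    """Write sequences as FASTA (60-column wrapped), atomically."""
    lines: list[str] = []
    for seq in sequences:
        header = f">{seq.id}" + (f" {seq.description}" if seq.description else "")
        lines.append(header)
        for i in range(0, len(seq), 60):
            lines.append(seq.residues[i : i + 60])
    _atomic_write(path, "\n".join(lines) + "\n")


def read_labels(path: str | os.PathLike, sequences: Sequence[RnaSequence]) -> LabeledDataset:
    """Read a two-column (id, label) table and align it to *sequences*.

    The delimiter (tab or comma) is auto-detected per line. A single header
    row whose id matches no sequence and whose label is not 0/1 is skipped.
    Every sequence must receive exactly one label; missing or extra ids are
    errors listing the offenders.
    """
    path = Path(path)
    table: dict[str, int] = {}
    ids = {s.id for s in sequences}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split(",")
            if len(parts) != 2:
                raise LabelError(
                    f"{path}:{lineno}: expected two columns (id, label), got {len(parts)}"
                )
            name, value = parts[0].strip(), parts[1].strip()
            if value not in ("0", "1"):
                if lineno == 1 and name not in ids:
                    continue  # header row
                raise LabelError(
                    f"{path}:{lineno}: label for {name!r} must be 0 or 1, got {value!r}"
                )
            if name in table:
                raise LabelError(f"{path}:{lineno}: duplicate label for id {name!r}")
            table[name] = int(value)

    missing = [s.id for s in sequences if s.id not in table]
    extra = sorted(set(table) - ids)
    if missing:
        raise LabelError(f"missing labels for sequence ids: {', '.join(missing)}")
    if extra:
        raise LabelError(f"labels for unknown sequence ids: {', '.join(extra)}")
    return LabeledDataset(
        sequences=tuple(sequences), labels=tuple(table[s.id] for s in sequences)
    )


def write_labels(dataset: LabeledDataset, path: str | os.PathLike) -> None:
    """Write a two-column tab-delimited label table with a header row."""
    lines = ["id\tlabel"]
    lines += [f"{s.id}\t{l}" for s, l in zip(dataset.sequences, dataset.labels)]
    _atomic_write(path, "\n".join(lines) + "\n")


def write_predictions(
    records: Iterable[tuple[str, float, int]], path: str | os.PathLike
) -> None:
    """Write (id, score, predicted label) rows as a 3-column TSV.

    Scores must lie in [0, 1]; row order equals input order; a header row is
    always present (an empty input yields a header-only file).
    """
    lines = ["id\tscore\tlabel"]
    for name, score, label in records:
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"score for {name!r} is {score}, outside [0, 1]")
        if label not in (0, 1):
            raise ValueError(f"predicted label for {name!r} must be 0 or 1, got {label}")
        lines.append(f"{name}\t{score:.6f}\t{label}")
    _atomic_write(path, "\n".join(lines) + "\n")


def _atomic_write(path: str | os.PathLike, text: str) -> None:
    """Write text to *path* via a temp file + rename, never leaving partials."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
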