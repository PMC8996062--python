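"""Secondary structures, per-residue pairing status, and pseudo-energies.

A pre-miRNA folds into a hairpin; its minimum-free-energy (MFE) secondary
structure is written in dot-bracket notation, where matched ``(`` ``)``
denote base-paired positions and ``.`` unpaired ones. Structures come either
from the ViennaRNA folding engine (:func:`fold`) or from user-supplied
dot-bracket files (:func:`read_dotbracket`) — the latter makes every
structural feature computable without a folding engine.

From a (sequence, structure) pair we derive the per-residue *structural
status*: one of ten categories — the four unpaired nucleotides A, C, G, U,
or the six ordered canonical/wobble pair types A-U, U-A, G-C, C-G, G-U,
U-G (first letter = the residue itself, second = its partner). Each status
carries a pseudo-free-energy from a configurable ten-entry lookup table;
the distance-structure-status-pair features consume only squared
differences of these energies, so any fixed, documented table yields a
well-defined feature. The shipped default assigns 0 to unpaired statuses
and negative values ordered |G-C| > |A-U| > |G-U| to the paired ones.

Positions are reported 1-based in all error messages; internal storage is
0-based.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io import RnaSequence

STATUS_CATEGORIES: tuple[str, ...] = (
    "A", "C", "G", "U", "A-U", "U-A", "G-C", "C-G", "G-U", "U-G",
)
PAIRED_STATUSES: frozenset[str] = frozenset(
    s for s in STATUS_CATEGORIES if "-" in s
)

#: Default per-status pseudo-energy (arbitrary units): unpaired residues
#: contribute nothing; paired ones are stabilizing, with Watson–Crick G-C
#: strongest, A-U intermediate, and the G-U wobble weakest.
DEFAULT_ENERGY_TABLE: Mapping[str, float] = {
    "A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0,
    "G-C": -3.0, "C-G": -3.0,
    "A-U": -2.0, "U-A": -2.0,
    "G-U": -1.0, "U-G": -1.0,
}


class StructureError(ValueError):
    """A dot-bracket string or predicted pairing violates the contract."""


class FoldingEngineError(RuntimeError):
    """The MFE folding engine is unavailable or failed."""


@dataclasses.dataclass(frozen=True)
class SecondaryStructure:
    """A validated dot-bracket structure with its pairing map.

    ``paired_with[i]`` is the 0-based partner index of position *i*, or
    ``None`` when position *i* is unpaired (``.``). The map is a symmetric
    involution consistent with the brackets by construction.
    """

    brackets: str
    paired_with: tuple[int | None, ...]

    @classmethod
    def from_brackets(cls, brackets: str) -> "SecondaryStructure":
        """Parse and validate a dot-bracket string.

        Only the three-symbol alphabet ``( ) .`` is accepted; pseudoknot
        bracket dialects are rejected. Unbalanced brackets are an error.
        """
        partner: list[int | None] = [None] * len(brackets)
        stack: list[int] = []
        for i, ch in enumerate(brackets):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                if not stack:
                    raise StructureError(
                        f"unbalanced ')' at position {i + 1} in {brackets!r}"
                    )
                j = stack.pop()
                partner[i], partner[j] = j, i
            elif ch != ".":
                raise StructureError(
                    f"invalid structure character {ch!r} at position {i + 1}; "
                    "only '(', ')' and '.' are supported"
                )
        if stack:
            raise StructureError(
                f"unbalanced '(' at position {stack[-1] + 1} in {brackets!r}"
            )
        return cls(brackets=brackets, paired_with=tuple(partner))

    def __len__(self) -> int:
        return len(self.brackets)

    @property
    def n_pairs(self) -> int:
        return self.brackets.count("(")


def fold(seq: RnaSequence) -> SecondaryStructure:
    """Predict the minimum-free-energy dot-bracket structure of *seq*.

    Uses the ViennaRNA programmatic interface with its default model
    parameters (temperature, dangles); the engine version is available via
    :func:`fold_engine_info`. Deterministic for a fixed engine version.
    """
    RNA = _require_vienna()
    brackets, _mfe = RNA.fold(seq.residues)
    return SecondaryStructure.from_brackets(brackets)


def fold_engine_info() -> dict[str, str]:
    """Name and version of the folding engine, for provenance records."""
    RNA = _require_vienna()
    return {"engine": "ViennaRNA", "version": RNA.__version__}


def _require_vienna():
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FoldingEngineError(
            "the ViennaRNA Python bindings are not installed; either install "
            "the 'ViennaRNA' package or supply dot-bracket structures via "
            "read_dotbracket() instead of folding"
        ) from exc
    return RNA


def read_dotbracket(
    path: str | os.PathLike, sequences: Sequence[RnaSequence]
) -> dict[str, SecondaryStructure]:
    """Read a Vienna-style dot-bracket file keyed to *sequences*.

    Each record is a ``>id`` line followed by one bracket line (an optional
    sequence line between them is tolerated and checked). Unknown ids,
    length mismatches and unbalanced brackets are errors naming the record.
    """
    path = Path(path)
    by_id = {s.id: s for s in sequences}
    out: dict[str, SecondaryStructure] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current not in by_id:
                    raise StructureError(
                        f"structure record {current!r} matches no sequence id"
                    )
                continue
            if current is None:
                raise StructureError(f"structure line before any '>' header: {line!r}")
            if set(line) <= {"A", "C", "G", "U", "T", "a", "c", "g", "u", "t"}:
                continue  # optional sequence line, Vienna output style
            struct = SecondaryStructure.from_brackets(line)
            seq = by_id[current]
            if len(struct) != len(seq):
                raise StructureError(
                    f"structure for {current!r} has length {len(struct)} but the "
                    f"sequence has length {len(seq)}"
                )
            if current in out:
                raise StructureError(f"duplicate structure record for {current!r}")
            out[current] = struct
            current = None
    return out


@dataclasses.dataclass(frozen=True)
class StatusTrack:
    """Per-residue structural status and pseudo-energy series."""

    status: tuple[str, ...]
    energy: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.status)

    @property
    def energy_array(self) -> np.ndarray:
        return np.asarray(self.energy, dtype=float)


def status_energy(status: str, table: Mapping[str, float] | None = None) -> float:
    """Pseudo-energy of one structural-status category (table lookup)."""
    table = DEFAULT_ENERGY_TABLE if table is None else table
    if status not in STATUS_CATEGORIES:
        raise StructureError(
            f"unknown structural status {status!r}; expected one of "
            f"{', '.join(STATUS_CATEGORIES)}"
        )
    return float(table[status])


def assign_status(
    seq: RnaSequence,
    struct: SecondaryStructure,
    energy_table: Mapping[str, float] | None = None,
) -> StatusTrack:
    """Derive the 10-category status track of a (sequence, structure) pair.

    Unpaired positions take their own nucleotide as status; paired positions
    take ``X-Y`` with X the residue itself and Y its partner. Only the six
    canonical/wobble pair categories are legal — an MFE engine never emits
    others, so a violation indicates a corrupt file-supplied structure.
    """
    if len(struct) != len(seq):
        raise StructureError(
            f"structure length {len(struct)} does not match sequence "
            f"{seq.id!r} length {len(seq)}"
        )
    table = DEFAULT_ENERGY_TABLE if energy_table is None else energy_table
    statuses: list[str] = []
    for i, partner in enumerate(struct.paired_with):
        if partner is None:
            statuses.append(seq.residues[i])
        else:
            cat = f"{seq.residues[i]}-{seq.residues[partner]}"
            if cat not in PAIRED_STATUSES:
                raise StructureError(
                    f"non-canonical pair {cat} between positions {i + 1} and "
                    f"{partner + 1} of sequence {seq.id!r}"
                )
            statuses.append(cat)
    energies = tuple(status_energy(s, table) for s in statuses)
    return StatusTrack(status=tuple(statuses), energy=energies)
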