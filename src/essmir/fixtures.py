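"""Deterministic synthetic pre-miRNA data for testing and benchmarking.

Three generators cover what the rest of the package needs without any
download or folding engine:

* :func:`random_rna` — i.i.d. residues at a chosen GC content;
* :func:`hairpin_rna` — a stem-loop whose 3' arm is the reverse complement
  of the 5' arm, returned *with* its ground-truth dot-bracket structure,
  so the structural encoders are exercisable engine-free and every
  predicted pair is canonical by construction;
* :func:`planted_motif_dataset` — a labeled two-class set in which
  positives carry a short planted motif and negatives are guaranteed
  motif-free by rejection sampling. The planted signal is a sufficiency
  probe for the learning pipeline, not a model of miRNA biology.

Default scale (100 + 100 sequences of 60–90 nt) mimics the size regime of
curated mouse pre-miRNA essentiality benchmarks (~170 hairpins of
60–110 nt) while keeping leave-one-out runtimes small. All generation is a
pure function of its spec: a fixed seed reproduces byte-identical FASTA.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np

from .io import LabeledDataset, RnaSequence, write_fasta, write_labels
from .structure import SecondaryStructure

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


class FixtureError(ValueError):
    """A fixture spec is invalid or rejection sampling was exhausted."""


def _draw(rng: np.random.Generator, length: int, gc_content: float) -> str:
    p_gc = gc_content / 2.0
    p_au = (1.0 - gc_content) / 2.0
    return "".join(
        rng.choice(np.array(["A", "U", "G", "C"]), size=length, p=[p_au, p_au, p_gc, p_gc])
    )


def random_rna(
    length: int, gc_content: float = 0.5, seed: int = 0, id: str = "random"
) -> RnaSequence:
    """A random RNA with P(G)=P(C)=gc/2 and P(A)=P(U)=(1−gc)/2."""
    if length < 1:
        raise FixtureError(f"length must be >= 1, got {length}")
    if not (0.0 < gc_content < 1.0):
        raise FixtureError(f"gc_content must lie in (0, 1), got {gc_content}")
    rng = np.random.default_rng(seed)
    return RnaSequence(id=id, residues=_draw(rng, length, gc_content))


def hairpin_rna(
    stem_len: int,
    loop_len: int,
    seed: int = 0,
    gc_content: float = 0.5,
    id: str = "hairpin",
) -> tuple[RnaSequence, SecondaryStructure]:
    """A perfect stem-loop with its ground-truth dot-bracket structure.

    The 5' stem and loop are random; the 3' stem is the reverse complement
    of the 5' stem (A↔U, G↔C), so every pair in the returned structure is
    a canonical Watson–Crick pair.
    """
    if stem_len < 1:
        raise FixtureError(f"stem_len must be >= 1, got {stem_len}")
    if loop_len < 3:
        raise FixtureError(f"loop_len must be >= 3 (a hairpin loop), got {loop_len}")
    rng = np.random.default_rng(seed)
    stem5 = _draw(rng, stem_len, gc_content)
    loop = _draw(rng, loop_len, gc_content)
    stem3 = "".join(_COMPLEMENT[c] for c in reversed(stem5))
    seq = RnaSequence(id=id, residues=stem5 + loop + stem3)
    brackets = "(" * stem_len + "." * loop_len + ")" * stem_len
    return seq, SecondaryStructure.from_brackets(brackets)


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a planted-motif labeled dataset."""

    n_pos: int = 100
    n_neg: int = 100
    length: tuple[int, int] = (60, 90)
    motif: str = "GGGCCC"
    insertion_rate: float = 1.0
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length
        if not (1 <= lo <= hi):
            raise FixtureError(f"invalid length range {self.length}")
        if not self.motif or set(self.motif) - set("ACGU"):
            raise FixtureError(f"motif must be a non-empty A/C/G/U string, got {self.motif!r}")
        if len(self.motif) >= lo:
            raise FixtureError("motif must be shorter than the shortest sequence")
        if not (0.0 <= self.insertion_rate <= 1.0):
            raise FixtureError("insertion_rate must lie in [0, 1]")
        if not (0.0 < self.gc_content < 1.0):
            raise FixtureError("gc_content must lie in (0, 1)")

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)


_MAX_REJECTIONS = 1000


def planted_motif_dataset(spec: FixtureSpec) -> LabeledDataset:
    """Generate the two-class planted-motif dataset described by *spec*.

    Positives receive the motif overwritten at a uniform-random position
    with probability ``insertion_rate``; negatives are redrawn until they
    do not contain the motif (bounded retries). Deterministic under seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length
    sequences: list[RnaSequence] = []
    labels: list[int] = []

    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        residues = _draw(rng, length, spec.gc_content)
        if rng.random() < spec.insertion_rate:
            pos = int(rng.integers(0, length - len(spec.motif) + 1))
            residues = residues[:pos] + spec.motif + residues[pos + len(spec.motif):]
        sequences.append(RnaSequence(id=f"pos{i:04d}", residues=residues))
        labels.append(1)

    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        for _attempt in range(_MAX_REJECTIONS):
            residues = _draw(rng, length, spec.gc_content)
            if spec.motif not in residues:
                break
        else:
            raise FixtureError(
                f"could not draw a motif-free negative in {_MAX_REJECTIONS} "
                f"attempts; use a longer or rarer motif than {spec.motif!r}"
            )
        sequences.append(RnaSequence(id=f"neg{i:04d}", residues=residues))
        labels.append(0)

    return LabeledDataset(sequences=tuple(sequences), labels=tuple(labels))


def write_dataset(dataset: LabeledDataset, out_dir: str | os.PathLike,
                  spec: FixtureSpec | None = None) -> dict[str, Path]:
    """Emit FASTA + label TSV (+ spec JSON) into *out_dir*; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "sequences.fasta",
        "labels": out_dir / "labels.tsv",
    }
    write_fasta(dataset.sequences, paths["fasta"])
    write_labels(dataset, paths["labels"])
    if spec is not None:
        paths["spec"] = out_dir / "fixture_spec.json"
        paths["spec"].write_text(spec.to_json(indent=2) + "\n")
    return paths
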