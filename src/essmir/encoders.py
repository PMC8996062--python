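"""Feature encoders mapping pre-miRNA sequences to fixed-length vectors.

Five encoding schemes are provided, each as a scikit-learn transformer:

``KmerEncoder``
    Frequencies of the 4^k contiguous k-mers (counts over the l−k+1
    windows, normalized to sum to 1).
``MismatchEncoder``
    For each of the 4^k k-mer types, the number of length-k windows within
    Hamming distance m of that type (raw counts; the spectrum kernel with
    inexact matching).
``SubsequenceEncoder``
    The gap-weighted subsequence kernel feature map: for each k-mer type,
    the sum over all ordered (possibly gapped) index tuples matching the
    type of δ^span, where a contiguous match weighs δ^0 = 1 and a gapped
    match weighs δ raised to its span (last − first + 1).
``TripletEncoder``
    The 32-bin local structure composition: for every interior position,
    the pairing pattern of its 3-window (bracket direction collapsed to
    paired/unpaired — 8 patterns) combined with the center nucleotide,
    normalized over the l−2 windows.
``PseDsspcEncoder``
    Pseudo distance-structure-status-pair composition: frequencies of the
    10 per-residue structural statuses, frequencies of ordered status pairs
    at each distance 1..d, and λ pseudo-energy autocorrelation tiers
    (mean squared energy difference at each lag), jointly normalized with
    a balance weight w so the full vector sums to 1.

Feature dimensions are 4^k, 4^k, 4^k, 32 and 10 + 100·d + λ respectively.
All k-mer-type orderings are lexicographic with A < C < G < U.

Transformers accept raw strings, :class:`~essmir.io.RnaSequence` objects,
or ``(sequence, SecondaryStructure)`` pairs. Structural encoders fold
sequences on the fly (ViennaRNA) when no structure is supplied, so plain
sequence lists work in sklearn pipelines; supplying structures keeps the
computation engine-free and is what the test fixtures do.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import os
from typing import ClassVar, Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RnaSequence, canonicalize
from .structure import (
    STATUS_CATEGORIES,
    SecondaryStructure,
    StatusTrack,
    assign_status,
    fold,
)

BASES = "ACGU"
_CODE = {b: i for i, b in enumerate(BASES)}


class EncodingError(ValueError):
    """A sequence violates an encoder precondition (e.g. shorter than k)."""


class BatchEncodingError(EncodingError):
    """One or more sequences in a batch failed to encode."""

    def __init__(self, failures: list[tuple[str, Exception]]):
        self.failures = failures
        detail = "; ".join(f"{sid}: {err}" for sid, err in failures)
        super().__init__(f"{len(failures)} sequence(s) failed to encode: {detail}")


def _codes(residues: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in residues), dtype=np.int64, count=len(residues))


def kmer_names(k: int) -> list[str]:
    """All 4^k k-mer strings in lexicographic order (A < C < G < U)."""
    return ["".join(p) for p in itertools.product(BASES, repeat=k)]


def _window_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts of each of the 4^k contiguous k-mer types (lexicographic)."""
    l = codes.size
    idx = np.zeros(l - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j : l - k + 1 + j]
    return np.bincount(idx, minlength=4**k).astype(float)


def _as_seq(item, fallback_id: str) -> RnaSequence:
    if isinstance(item, RnaSequence):
        return item
    if isinstance(item, str):
        return RnaSequence(id=fallback_id, residues=canonicalize(item))
    raise TypeError(f"cannot interpret {type(item).__name__} as an RNA sequence")


def _split_item(item, fallback_id: str) -> tuple[RnaSequence, SecondaryStructure | None]:
    if isinstance(item, tuple) and len(item) == 2:
        seq, struct = item
        return _as_seq(seq, fallback_id), struct
    return _as_seq(item, fallback_id), None


class BaseRnaEncoder(TransformerMixin, BaseEstimator):
    """Common transformer surface shared by the five encoding schemes."""

    scheme: ClassVar[str]
    requires_structure: ClassVar[bool] = False

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X=None, y=None):
        """Stateless: validates parameters and returns self."""
        self._check_params()
        self.n_features_out_ = self.dim
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        """Encode an iterable of sequences into an (n, dim) float array."""
        self._check_params()
        rows = [self.encode_item(item, fallback_id=f"seq{i}") for i, item in enumerate(X)]
        if not rows:
            return np.empty((0, self.dim), dtype=float)
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        self._check_params()
        return np.asarray(self.feature_names(), dtype=object)

    # -- scheme surface ----------------------------------------------------
    @property
    def dim(self) -> int:
        raise NotImplementedError

    def feature_names(self) -> list[str]:
        raise NotImplementedError

    def encode(self, seq: RnaSequence, structure: SecondaryStructure | None = None) -> np.ndarray:
        raise NotImplementedError

    def encode_item(self, item, fallback_id: str = "seq") -> np.ndarray:
        seq, struct = _split_item(item, fallback_id)
        if self.requires_structure and struct is None:
            struct = fold(seq)
        return self.encode(seq, struct)

    def provenance(self) -> dict:
        """Scheme + parameters + dimension, for feature-matrix provenance."""
        return {"scheme": self.scheme, "dim": self.dim, **self.get_params()}

    def _check_params(self) -> None:
        pass


def _check_k(k: int) -> None:
    if not (isinstance(k, (int, np.integer)) and 1 <= k <= 6):
        raise ValueError(f"k must be an integer in [1, 6], got {k!r}")


class KmerEncoder(BaseRnaEncoder):
    """Contiguous k-mer frequency vector (4^k dimensions, sums to 1)."""

    scheme = "kmer"

    def __init__(self, k: int = 3):
        self.k = k

    def _check_params(self) -> None:
        _check_k(self.k)

    @property
    def dim(self) -> int:
        return 4**self.k

    def feature_names(self) -> list[str]:
        return kmer_names(self.k)

    def encode(self, seq: RnaSequence, structure=None) -> np.ndarray:
        self._check_params()
        k = self.k
        if len(seq) < k:
            raise EncodingError(
                f"sequence {seq.id!r} has length {len(seq)} < k={k}"
            )
        counts = _window_counts(_codes(seq.residues), k)
        return counts / (len(seq) - k + 1)


class MismatchEncoder(BaseRnaEncoder):
    """Inexact-matching spectrum counts: windows within Hamming distance m.

    Entry i is the number of length-k windows of the sequence whose Hamming
    distance to the i-th k-mer type is at most m. Raw counts (m = 0 gives
    exactly the contiguous k-mer counts).
    """

    scheme = "mismatch"

    def __init__(self, k: int = 2, m: int = 1):
        self.k = k
        self.m = m

    def _check_params(self) -> None:
        _check_k(self.k)
        if not (isinstance(self.m, (int, np.integer)) and 0 <= self.m <= self.k - 1):
            raise ValueError(
                f"m must be an integer in [0, k-1] = [0, {self.k - 1}], got {self.m!r}"
            )

    @property
    def dim(self) -> int:
        return 4**self.k

    def feature_names(self) -> list[str]:
        return kmer_names(self.k)

    def encode(self, seq: RnaSequence, structure=None) -> np.ndarray:
        self._check_params()
        k, m = self.k, self.m
        if len(seq) < k:
            raise EncodingError(f"sequence {seq.id!r} has length {len(seq)} < k={k}")
        codes = _codes(seq.residues)
        weights = [4 ** (k - 1 - j) for j in range(k)]
        counts = np.zeros(4**k, dtype=float)
        cache: dict[tuple[int, ...], list[int]] = {}
        for start in range(len(seq) - k + 1):
            window = tuple(int(c) for c in codes[start : start + k])
            idxs = cache.get(window)
            if idxs is None:
                idxs = _neighborhood_indices(window, m, weights)
                cache[window] = idxs
            counts[idxs] += 1.0
        return counts


def _neighborhood_indices(
    window: tuple[int, ...], m: int, weights: list[int]
) -> list[int]:
    """Feature indices of all k-mer types within Hamming distance m of *window*."""
    k = len(window)
    base = sum(c * w for c, w in zip(window, weights))
    out: list[int] = []

    def rec(pos: int, budget: int, idx: int) -> None:
        if pos == k:
            out.append(idx)
            return
        rec(pos + 1, budget, idx)
        if budget > 0:
            c, w = window[pos], weights[pos]
            for alt in range(4):
                if alt != c:
                    rec(pos + 1, budget - 1, idx + (alt - c) * w)

    rec(0, m, base)
    return out


class SubsequenceEncoder(BaseRnaEncoder):
    """Gap-weighted subsequence feature map with decay δ.

    For each k-mer type, sums δ^span over every ordered index tuple
    p₁ < … < p_k whose residues spell the type, where a contiguous tuple
    (span k) contributes δ⁰ = 1 and a gapped tuple contributes δ raised to
    its span p_k − p₁ + 1. At δ = 0 this reduces exactly to the contiguous
    k-mer counts. Computed by a dynamic program over prefix positions in
    O(l · 4^k); the exhaustive tuple enumeration serves as its test oracle.
    """

    scheme = "subsequence"

    def __init__(self, k: int = 2, delta: float = 0.9):
        self.k = k
        self.delta = delta

    def _check_params(self) -> None:
        _check_k(self.k)
        if not (0.0 <= float(self.delta) <= 1.0):
            raise ValueError(f"delta must lie in [0, 1], got {self.delta!r}")

    @property
    def dim(self) -> int:
        return 4**self.k

    def feature_names(self) -> list[str]:
        return kmer_names(self.k)

    def encode(self, seq: RnaSequence, structure=None) -> np.ndarray:
        self._check_params()
        k, delta = self.k, float(self.delta)
        if len(seq) < k:
            raise EncodingError(f"sequence {seq.id!r} has length {len(seq)} < k={k}")
        codes = _codes(seq.residues)
        l = codes.size
        contig = _window_counts(codes, k)

        # D holds, per position p, the sum over length-j tuples ending at p of
        # delta^(p - p_1); the cumulative array carries the decayed prefix sums.
        D = np.zeros((l, 4), dtype=float)
        D[np.arange(l), codes] = 1.0
        for j in range(2, k + 1):
            newD = np.zeros((l, 4**j), dtype=float)
            cum = np.zeros(4 ** (j - 1), dtype=float)
            for p in range(l):
                newD[p].reshape(-1, 4)[:, codes[p]] = delta * cum
                cum = cum * delta + D[p]
            D = newD
        gapped = delta * D.sum(axis=0)  # extra delta: span = p_k - p_1 + 1
        # contiguous tuples entered the DP with weight delta^k; re-weight to 1
        return gapped + contig * (1.0 - delta**k)


_TRIPLET_PATTERNS = ["".join(p) for p in itertools.product(".(", repeat=3)]


class TripletEncoder(BaseRnaEncoder):
    """32-bin local-structure triplet composition.

    Each interior position i contributes one observation: the
    paired/unpaired pattern of positions (i−1, i, i+1) — bracket direction
    collapsed, so 8 patterns — crossed with the center nucleotide r_i.
    Frequencies are normalized over the l − 2 interior windows.
    """

    scheme = "triplet"
    requires_structure = True

    @property
    def dim(self) -> int:
        return 32

    def feature_names(self) -> list[str]:
        return [f"{b}{pat}" for b in BASES for pat in _TRIPLET_PATTERNS]

    def encode(self, seq: RnaSequence, structure: SecondaryStructure | None = None) -> np.ndarray:
        if structure is None:
            raise EncodingError(f"triplet encoding of {seq.id!r} requires a structure")
        if len(structure) != len(seq):
            raise EncodingError(
                f"structure length {len(structure)} != sequence {seq.id!r} "
                f"length {len(seq)}"
            )
        l = len(seq)
        if l < 3:
            raise EncodingError(f"sequence {seq.id!r} has length {l} < 3")
        paired = np.array([ch != "." for ch in structure.brackets], dtype=int)
        codes = _codes(seq.residues)
        counts = np.zeros(32, dtype=float)
        for i in range(1, l - 1):
            pattern = paired[i - 1] * 4 + paired[i] * 2 + paired[i + 1]
            counts[codes[i] * 8 + pattern] += 1.0
        return counts / (l - 2)


class PseDsspcEncoder(BaseRnaEncoder):
    """Pseudo distance-structure-status-pair composition.

    Three blocks, jointly normalized to unit sum:

    1. frequencies of the 10 structural statuses (count / l);
    2. for each distance d' = 1..d, frequencies of the 100 ordered status
       pairs (status at i, status at i+d'), normalized by l − d';
    3. for each lag 1..λ, the pseudo-energy correlation tier — the mean
       squared difference of the per-residue energies at that lag.

    The final vector divides blocks 1–2 by Z and block 3 by Z/w, where
    Z = Σ(blocks 1–2) + w·Σ(block 3); since block 1 sums to 1 and block 2
    to d, Z = 1 + d + w·Σ(tiers). Dimension: 10 + 100·d + λ.
    """

    scheme = "psedsspc"
    requires_structure = True

    def __init__(
        self,
        d: int = 5,
        lam: int = 5,
        w: float = 0.5,
        energy_table: Mapping[str, float] | None = None,
    ):
        self.d = d
        self.lam = lam
        self.w = w
        self.energy_table = energy_table

    def _check_params(self) -> None:
        if not (isinstance(self.d, (int, np.integer)) and self.d >= 1):
            raise ValueError(f"d must be an integer >= 1, got {self.d!r}")
        if not (isinstance(self.lam, (int, np.integer)) and self.lam >= 1):
            raise ValueError(f"lam must be an integer >= 1, got {self.lam!r}")
        if not (0.0 < float(self.w) <= 1.0):
            raise ValueError(f"w must lie in (0, 1], got {self.w!r}")

    @property
    def dim(self) -> int:
        return 10 + 100 * self.d + self.lam

    def feature_names(self) -> list[str]:
        names = list(STATUS_CATEGORIES)
        for dist in range(1, self.d + 1):
            for x in STATUS_CATEGORIES:
                for y in STATUS_CATEGORIES:
                    names.append(f"{x}|{y}@{dist}")
        names += [f"tier{k}" for k in range(1, self.lam + 1)]
        return names

    def encode(self, seq: RnaSequence, structure: SecondaryStructure | None = None) -> np.ndarray:
        self._check_params()
        if structure is None:
            raise EncodingError(f"psedsspc encoding of {seq.id!r} requires a structure")
        track = assign_status(seq, structure, self.energy_table)
        return self.encode_track(track, seq_id=seq.id)

    def encode_track(self, track: StatusTrack, seq_id: str = "seq") -> np.ndarray:
        """Encode directly from a precomputed status track."""
        self._check_params()
        d, lam, w = self.d, self.lam, float(self.w)
        l = len(track)
        if l <= max(d, lam):
            raise EncodingError(
                f"sequence {seq_id!r} has length {l} <= max(d={d}, lam={lam}); "
                "every block needs at least one term"
            )
        sidx = {s: i for i, s in enumerate(STATUS_CATEGORIES)}
        codes = np.array([sidx[s] for s in track.status], dtype=np.int64)
        energy = track.energy_array

        g_status = np.bincount(codes, minlength=10).astype(float) / l
        g_pairs = np.zeros((d, 100), dtype=float)
        for dist in range(1, d + 1):
            pair_idx = codes[:-dist] * 10 + codes[dist:]
            g_pairs[dist - 1] = np.bincount(pair_idx, minlength=100) / (l - dist)
        g_tiers = np.array(
            [np.mean((energy[:-k] - energy[k:]) ** 2) for k in range(1, lam + 1)]
        )

        z = g_status.sum() + g_pairs.sum() + w * g_tiers.sum()
        return np.concatenate([g_status, g_pairs.ravel(), w * g_tiers]) / z


_SCHEMES: dict[str, type[BaseRnaEncoder]] = {
    cls.scheme: cls
    for cls in (KmerEncoder, MismatchEncoder, SubsequenceEncoder, TripletEncoder, PseDsspcEncoder)
}


def make_encoder(scheme: str, **params) -> BaseRnaEncoder:
    """Instantiate an encoder by scheme name with keyword parameters."""
    try:
        cls = _SCHEMES[scheme]
    except KeyError:
        raise ValueError(
            f"unknown scheme {scheme!r}; choose from {sorted(_SCHEMES)}"
        ) from None
    enc = cls(**params)
    enc._check_params()
    return enc


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """A single named, provenance-carrying feature vector."""

    values: np.ndarray
    names: tuple[str, ...]
    provenance: dict

    @property
    def dim(self) -> int:
        return int(self.values.size)


@dataclasses.dataclass(frozen=True)
class FeatureMatrix:
    """Homogeneous per-sequence feature rows with shared provenance."""

    values: np.ndarray
    ids: tuple[str, ...]
    names: tuple[str, ...]
    provenance: dict

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count does not match id count")
        if self.values.shape[1] != len(self.names):
            raise ValueError("column count does not match feature-name count")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.names))

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write id + named feature columns as TSV, provenance as a # header."""
        from .io import _atomic_write

        lines = ["# provenance: " + json.dumps(self.provenance, sort_keys=True)]
        lines.append("id\t" + "\t".join(self.names))
        for sid, row in zip(self.ids, self.values):
            lines.append(sid + "\t" + "\t".join(format(v, ".12g") for v in row))
        _atomic_write(path, "\n".join(lines) + "\n")


def batch_encode(
    sequences: Sequence[RnaSequence],
    encoder: BaseRnaEncoder,
    structures: Mapping[str, SecondaryStructure] | None = None,
) -> FeatureMatrix:
    """Encode a sequence collection into a provenance-carrying matrix.

    For structural schemes, *structures* maps sequence id to structure; any
    sequence without one is folded on the fly. Per-sequence failures are
    collected and reported together; the batch never emits a partial matrix.
    """
    encoder._check_params()
    rows: list[np.ndarray] = []
    failures: list[tuple[str, Exception]] = []
    for seq in sequences:
        struct = structures.get(seq.id) if structures else None
        try:
            if encoder.requires_structure and struct is None:
                struct = fold(seq)
            rows.append(encoder.encode(seq, struct))
        except (EncodingError, ValueError) as err:
            failures.append((seq.id, err))
    if failures:
        raise BatchEncodingError(failures)
    values = (
        np.vstack(rows) if rows else np.empty((0, encoder.dim), dtype=float)
    )
    return FeatureMatrix(
        values=values,
        ids=tuple(s.id for s in sequences),
        names=tuple(encoder.feature_names()),
        provenance=encoder.provenance(),
    )


# -- thin functional wrappers -------------------------------------------------

def _vector(enc: BaseRnaEncoder, seq: RnaSequence, struct=None) -> FeatureVector:
    return FeatureVector(
        values=enc.encode(seq, struct),
        names=tuple(enc.feature_names()),
        provenance=enc.provenance(),
    )


def encode_kmer(seq: RnaSequence, k: int) -> FeatureVector:
    return _vector(make_encoder("kmer", k=k), seq)


def encode_mismatch(seq: RnaSequence, k: int, m: int) -> FeatureVector:
    return _vector(make_encoder("mismatch", k=k, m=m), seq)


def encode_subsequence(seq: RnaSequence, k: int, delta: float) -> FeatureVector:
    return _vector(make_encoder("subsequence", k=k, delta=delta), seq)


def encode_triplet(seq: RnaSequence, struct: SecondaryStructure) -> FeatureVector:
    return _vector(TripletEncoder(), seq, struct)


def encode_psedsspc(
    seq: RnaSequence,
    track_or_struct: StatusTrack | SecondaryStructure,
    d: int,
    lam: int,
    w: float,
) -> FeatureVector:
    enc = PseDsspcEncoder(d=d, lam=lam, w=w)
    if isinstance(track_or_struct, StatusTrack):
        values = enc.encode_track(track_or_struct, seq_id=seq.id)
    else:
        values = enc.encode(seq, track_or_struct)
    return FeatureVector(
        values=values, names=tuple(enc.feature_names()), provenance=enc.provenance()
    )
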