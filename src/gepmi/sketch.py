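"""Read handling, k-mer extraction and bottom-n MinHash sketching.

The pipeline mirrors the standard reference-free workflow for comparing
shotgun metagenomes: reads are down-sampled to a common base budget,
decomposed into canonical k-mers, low-abundance k-mers (mostly sequencing
errors) are removed, and the surviving k-mer set is summarised by the n
smallest values of a seeded 64-bit hash.  Two such bottom-n sketches yield
an estimate of the Jaccard similarity of the underlying k-mer sets.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import _kmers
from .errors import SketchCompatibilityError, UndefinedSimilarityError

DEFAULT_K = 18
DEFAULT_N = 10_000
DEFAULT_S_BASES = 1_000_000_000
DEFAULT_HASH_SEED = 42
DEFAULT_ABUNDANCE_CUTOFF = 2


@dataclass
class SequenceSample:
    """One sample's reads plus its sample/individual identity."""

    sample_id: str
    individual_id: str | None
    reads: list[str]

    @property
    def total_bases(self) -> int:
        return sum(len(r) for r in self.reads)


class KmerCountTable(Mapping):
    """Multiset of canonical k-mers, stored packed for speed.

    Behaves as a read-only mapping from canonical k-mer string to count.
    """

    def __init__(self, k: int, packed: np.ndarray, counts: np.ndarray):
        self.k = int(k)
        self._packed = np.asarray(packed, dtype=np.uint64)
        self._counts = np.asarray(counts, dtype=np.int64)

    def __len__(self) -> int:
        return int(self._packed.size)

    def __iter__(self):
        for v in self._packed:
            yield _kmers.decode_kmer(int(v), self.k)

    def __getitem__(self, kmer: str) -> int:
        idx = np.searchsorted(self._packed, _kmers.encode_kmer(kmer))
        if idx < self._packed.size and self._packed[idx] == _kmers.encode_kmer(kmer):
            return int(self._counts[idx])
        raise KeyError(kmer)

    def as_dict(self) -> dict[str, int]:
        return {k: int(c) for k, c in zip(self, self._counts)}

    @property
    def packed(self) -> np.ndarray:
        return self._packed

    @property
    def counts(self) -> np.ndarray:
        return self._counts


@dataclass
class KmerSet:
    """A set of canonical k-mers (2-bit packed, sorted ascending)."""

    k: int
    packed: np.ndarray

    def __len__(self) -> int:
        return int(self.packed.size)

    def to_strings(self) -> set[str]:
        return {_kmers.decode_kmer(int(v), self.k) for v in self.packed}


@dataclass
class KmerSketch:
    """Bottom-n MinHash sketch: the n smallest distinct hash values."""

    sample_id: str
    k: int
    n: int
    hashes: np.ndarray
    hash_seed: int = DEFAULT_HASH_SEED

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)

    def compatible_with(self, other: "KmerSketch") -> bool:
        return (
            self.k == other.k
            and self.n == other.n
            and self.hash_seed == other.hash_seed
        )

    def to_json(self) -> str:
        doc = {
            "sample_id": self.sample_id,
            "k": self.k,
            "n": self.n,
            "hash_seed": self.hash_seed,
            "hashes": [int(h) for h in self.hashes],
        }
        return json.dumps(doc, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "KmerSketch":
        doc = json.loads(text)
        return cls(
            sample_id=doc["sample_id"],
            k=int(doc["k"]),
            n=int(doc["n"]),
            hashes=np.asarray(doc["hashes"], dtype=np.uint64),
            hash_seed=int(doc["hash_seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "KmerSketch":
        return cls.from_json(Path(path).read_text())


@dataclass
class SimilarityMatrix:
    """Symmetric all-vs-all estimated Jaccard similarities."""

    sample_ids: list[str]
    values: np.ndarray
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def get(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def to_csv(self, path: str | Path) -> None:
        """Write in the sourmash ``compare --csv`` dialect.

        First row holds the sample identifiers; subsequent rows hold the
        similarity values, row order equal to column order.  Floats are
        written with ``repr`` so that a write -> read -> write cycle is
        bit-identical.
        """
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.sample_ids)
            for row in self.values:
                w.writerow([repr(float(v)) for v in row])

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityMatrix":
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            ids = next(r)
            rows = [[float(v) for v in row] for row in r]
        values = np.asarray(rows, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError(
                f"similarity CSV is not square: {values.shape} vs {len(ids)} ids"
            )
        return cls(sample_ids=ids, values=values)


# ---------------------------------------------------------------------------
# operations


def _open_maybe_gzip(path: str | Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_sequences(
    path: str | Path,
    format: str | None = None,
    sample_id: str | None = None,
    individual_id: str | None = None,
) -> SequenceSample:
    """Load a FASTA/FASTQ file (plain or gzipped) into a SequenceSample.

    ``format`` is inferred from the file name when omitted.  Reads are
    upper-cased and kept in file order.
    """
    path = Path(path)
    if format is None:
        name = path.name.removesuffix(".gz")
        suffix = name.rsplit(".", 1)[-1].lower()
        format = {"fa": "fasta", "fasta": "fasta", "fna": "fasta",
                  "fq": "fastq", "fastq": "fastq"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer sequence format from {path.name!r}")
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    reads: list[str] = []
    with _open_maybe_gzip(path) as fh:
        iterator = SeqIO.parse(fh, format)
        index = 0
        while True:
            try:
                record = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed {format} record #{index}: {exc}") from exc
            reads.append(str(record.seq).upper())
            index += 1
    return SequenceSample(
        sample_id=sample_id if sample_id is not None else path.name.split(".")[0],
        individual_id=individual_id,
        reads=reads,
    )


def downsample_bases(sample: SequenceSample, s_bases: int, seed: int) -> SequenceSample:
    """Randomly retain reads until the cumulative base count reaches s_bases.

    Reads are selected uniformly at random without replacement under a
    seeded generator; selection stops at the first read whose inclusion
    makes the cumulative base count >= ``s_bases``.  If the sample holds no
    more than ``s_bases`` bases it is returned unchanged.
    """
    if s_bases <= 0:
        raise ValueError(f"s_bases must be positive, got {s_bases}")
    if sample.total_bases <= s_bases:
        return sample
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sample.reads))
    lengths = np.fromiter((len(sample.reads[i]) for i in order), dtype=np.int64)
    cumulative = np.cumsum(lengths)
    stop = int(np.searchsorted(cumulative, s_bases, side="left")) + 1
    kept = order[:stop]
    return SequenceSample(
        sample_id=sample.sample_id,
        individual_id=sample.individual_id,
        reads=[sample.reads[i] for i in kept],
    )


def extract_kmers(sample: SequenceSample, k: int = DEFAULT_K) -> KmerCountTable:
    """Count canonical k-mers across all reads.

    Windows containing any non-ACGT character are skipped.  Reads shorter
    than k contribute nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    # join reads with an 'N' separator so windows never span two reads
    blob = "N".join(sample.reads)
    codes = _kmers.encode_sequence(blob)
    packed = _kmers.canonical_window_codes(codes, k)
    if packed.size == 0:
        return KmerCountTable(k, np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64))
    uniq, counts = np.unique(packed, return_counts=True)
    return KmerCountTable(k, uniq, counts)


def trim_low_abundance(table: KmerCountTable, cutoff_C: int = DEFAULT_ABUNDANCE_CUTOFF) -> KmerSet:
    """Keep k-mers with count >= cutoff_C; abundances are then discarded."""
    if cutoff_C <= 0:
        raise ValueError(f"cutoff_C must be positive, got {cutoff_C}")
    keep = table.counts >= cutoff_C
    return KmerSet(k=table.k, packed=table.packed[keep])


def minhash_sketch(
    kmers: KmerSet | Iterable[str],
    n: int = DEFAULT_N,
    hash_seed: int = DEFAULT_HASH_SEED,
    sample_id: str = "",
) -> KmerSketch:
    """Bottom-n MinHash sketch of a canonical k-mer set.

    Each k-mer is mapped through a seeded 64-bit hash; the sketch keeps the
    n smallest distinct hash values (all of them if fewer exist).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if isinstance(kmers, KmerSet):
        k = kmers.k
        packed = kmers.packed
    else:
        strings = sorted(set(kmers))
        if not strings:
            raise ValueError("cannot infer k from an empty k-mer collection")
        k = len(strings[0])
        if any(len(s) != k for s in strings):
            raise ValueError("k-mers have inconsistent lengths")
        packed = np.fromiter(
            (int(_kmers.encode_kmer(s)) for s in strings), dtype=np.uint64
        )
    hashes = np.unique(_kmers.hash_kmers(packed, seed=hash_seed))
    return KmerSketch(
        sample_id=sample_id, k=k, n=n, hashes=hashes[:n], hash_seed=hash_seed
    )


def estimate_jaccard(a: KmerSketch, b: KmerSketch) -> float:
    """Merged bottom-n Jaccard estimate between two compatible sketches.

    Takes the min(n, |union|) smallest values of the merged hash sets and
    returns the fraction of them present in both sketches.  Exact whenever
    both original k-mer sets have at most n elements.
    """
    if not a.compatible_with(b):
        raise SketchCompatibilityError(
            f"sketch parameters differ: (k={a.k}, n={a.n}, seed={a.hash_seed}) "
            f"vs (k={b.k}, n={b.n}, seed={b.hash_seed})"
        )
    if a.hashes.size == 0 and b.hashes.size == 0:
        raise UndefinedSimilarityError(
            f"both sketches empty: {a.sample_id!r}, {b.sample_id!r}"
        )
    union = np.union1d(a.hashes, b.hashes)
    bottom = union[: min(a.n, union.size)]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    hits = np.intersect1d(bottom, shared, assume_unique=True).size
    return float(hits / bottom.size)


def pairwise_similarity(sketches: list[KmerSketch]) -> SimilarityMatrix:
    """All-vs-all estimated Jaccard similarities (diagonal = 1)."""
    if len(sketches) < 2:
        raise ValueError("need at least two sketches")
    ids = [s.sample_id for s in sketches]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among sketches")
    m = len(sketches)
    values = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            sim = estimate_jaccard(sketches[i], sketches[j])
            values[i, j] = values[j, i] = sim
    first = sketches[0]
    return SimilarityMatrix(
        sample_ids=ids,
        values=values,
        parameters={"k": first.k, "n": first.n, "hash_seed": first.hash_seed},
    )


def sketch_sample(
    sample: SequenceSample,
    k: int = DEFAULT_K,
    n: int = DEFAULT_N,
    s_bases: int | None = DEFAULT_S_BASES,
    abundance_cutoff: int = DEFAULT_ABUNDANCE_CUTOFF,
    hash_seed: int = DEFAULT_HASH_SEED,
    seed: int = 0,
) -> KmerSketch:
    """Full per-sample pipeline: down-sample, count, trim, sketch."""
    if s_bases is not None:
        sample = downsample_bases(sample, s_bases, seed=seed)
    table = extract_kmers(sample, k=k)
    kept = trim_low_abundance(table, cutoff_C=abundance_cutoff)
    return minhash_sketch(kept, n=n, hash_seed=hash_seed, sample_id=sample.sample_id)
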