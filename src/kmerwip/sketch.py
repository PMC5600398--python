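"""Canonical k-mer counting into fixed-size, prime-length sketches.

Reads are decomposed into overlapping words of length k.  Each word is
canonicalized (the lexicographically smaller of the word and its reverse
complement, under A<C<G<T), packed into a 2-bit integer code, and counted
in the bin given by the code modulo the prime sketch length.  Bins are
saturating 8-bit counters: they clamp at 255 and never wrap.  A prime
sketch length spreads collisions uniformly across bins; collisions can
only inflate similarity and do so uniformly over sample pairs, which is
why a lossy fixed-size table is acceptable for relatedness estimation.

Windows containing any non-ACGT character (N, IUPAC ambiguity codes) are
skipped entirely.  Lowercase input is uppercased before windowing.  FASTQ
quality strings are ignored.
"""

from __future__ import annotations

import gzip
import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import sympy

__all__ = [
    "KmerConfig",
    "Sketch",
    "SketchFormatError",
    "reverse_complement",
    "canonical_kmer",
    "encode_kmer",
    "bin_index",
    "count_files",
    "next_prime",
    "save_sketch",
    "load_sketch",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Base -> 2-bit code lookup (A=0, C=1, G=2, T=3); -1 marks ambiguous bases.
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_MAGIC = b"KWS1"
_VERSION = 1


class SketchFormatError(ValueError):
    """Raised when a sketch file is malformed or of the wrong version."""


def _validate_dna(seq: str, what: str = "sequence") -> None:
    for ch in seq:
        if ch not in "ACGT":
            raise ValueError(
                f"{what} contains non-ACGT character {ch!r}; "
                "callers must uppercase and pre-filter ambiguous bases"
            )


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of an uppercase ACGT string.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    Raises ``ValueError`` on any non-ACGT character.
    """
    _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Return the lexicographically smaller of a k-mer and its reverse
    complement (A < C < G < T), making counting strand-independent."""
    return min(kmer, reverse_complement(kmer))


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string into a big-endian 2-bit integer code.

    A=0, C=1, G=2, T=3; the first base occupies the most significant
    position.  Injective for fixed k; values lie in ``[0, 4**k)``.
    """
    if len(kmer) > 32:
        raise ValueError(f"k-mer longer than 32 bases ({len(kmer)})")
    _validate_dna(kmer, "k-mer")
    code = 0
    for ch in kmer:
        code = (code << 2) | int(_CODE[ord(ch)])
    return code


def next_prime(n: int) -> int:
    """Smallest prime >= n (n must be >= 2)."""
    if n < 2:
        raise ValueError(f"next_prime requires n >= 2, got {n}")
    if sympy.isprime(n):
        return n
    return int(sympy.nextprime(n))


@dataclass(frozen=True)
class KmerConfig:
    """Word length and sketch geometry.

    k
        k-mer length in bases, 1..32 (32 keeps the packed code in a
        64-bit integer; 19-21 is the usual sweet spot for eukaryote-scale
        specificity).
    sketch_length
        number of bins; must be prime so that the modulo hash distributes
        codes evenly.
    """

    k: int
    sketch_length: int

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError(f"k must be in [1, 32], got {self.k}")
        if self.sketch_length < 2 or not sympy.isprime(self.sketch_length):
            raise ValueError(
                f"sketch_length must be a prime >= 2, got {self.sketch_length}"
                " (use next_prime to round up)"
            )


def bin_index(kmer: str, config: KmerConfig) -> int:
    """Sketch bin of a k-mer: encode(canonical(kmer)) mod sketch_length."""
    if len(kmer) != config.k:
        raise ValueError(f"expected a {config.k}-mer, got length {len(kmer)}")
    return encode_kmer(canonical_kmer(kmer)) % config.sketch_length


def _canonical_codes(seq: str, k: int) -> np.ndarray:
    """Vectorized canonical 2-bit codes of every unambiguous window.

    Windows containing any non-ACGT character are dropped.  Returns a
    uint64 array, one entry per counted window, in sequence order.
    """
    if len(seq) < k:
        return np.empty(0, dtype=np.uint64)
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    invalid = codes < 0
    c = codes.astype(np.uint64)
    c[invalid] = 0  # placeholder; these windows are masked out below
    n_win = codes.size - k + 1
    # a window is valid iff it contains no ambiguous base
    bad_cumsum = np.concatenate(([0], np.cumsum(invalid, dtype=np.int64)))
    valid = (bad_cumsum[k:] - bad_cumsum[:-k]) == 0
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    # Horner over the k base positions: O(k) passes, no (n, k) temporaries.
    two = np.uint64(2)
    three = np.uint64(3)
    fwd = np.zeros(n_win, dtype=np.uint64)
    rev = np.zeros(n_win, dtype=np.uint64)
    for i in range(k):
        fwd = (fwd << two) | c[i:i + n_win]
    for i in range(k - 1, -1, -1):
        rev = (rev << two) | (three - c[i:i + n_win])
    return np.minimum(fwd, rev)[valid]


@dataclass
class Sketch:
    """Per-sample vector of saturating 8-bit k-mer bin counts.

    ``counts`` has one uint8 entry per bin, clamped at 255.
    ``n_kmers_consumed`` totals counting events before saturation, so it
    can exceed the sum of the clamped counts.
    """

    sample_name: str
    k: int
    length: int
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_kmers_consumed: int = 0

    def __post_init__(self) -> None:
        KmerConfig(self.k, self.length)  # validate geometry
        if self.counts is None:
            self.counts = np.zeros(self.length, dtype=np.uint8)
        else:
            self.counts = np.asarray(self.counts, dtype=np.uint8)
            if self.counts.shape != (self.length,):
                raise ValueError(
                    f"counts shape {self.counts.shape} != ({self.length},)"
                )

    @classmethod
    def empty(cls, config: KmerConfig, sample_name: str = "") -> "Sketch":
        return cls(sample_name=sample_name, k=config.k, length=config.sketch_length)

    @property
    def config(self) -> KmerConfig:
        return KmerConfig(self.k, self.length)

    @property
    def n_nonzero_bins(self) -> int:
        return int(np.count_nonzero(self.counts))

    def count_sequence(self, seq: str) -> "Sketch":
        """Count every unambiguous k-length window of ``seq`` into its bin.

        Saturates at 255 per bin.  Short or fully ambiguous input
        degrades to fewer (or zero) counted windows; never an error.
        Returns self for chaining.
        """
        canon = _canonical_codes(seq.upper(), self.k)
        if canon.size:
            self._accumulate(canon)
        return self

    def count_sequences(self, seqs: Iterable[str], batch_bases: int = 1 << 20) -> "Sketch":
        """Count many reads, batching them for vectorization.

        Reads are joined with 'N' separators before windowing, so no
        window ever spans two reads; the result is identical to counting
        each read individually.
        """
        buf: list[str] = []
        size = 0
        for seq in seqs:
            buf.append(seq)
            size += len(seq) + 1
            if size >= batch_bases:
                self.count_sequence("N".join(buf))
                buf, size = [], 0
        if buf:
            self.count_sequence("N".join(buf))
        return self

    def _accumulate(self, canonical_codes: np.ndarray) -> None:
        bins = canonical_codes % np.uint64(self.length)
        batch = np.bincount(bins.astype(np.int64), minlength=self.length)
        total = self.counts.astype(np.int64) + batch
        np.minimum(total, 255, out=total)
        self.counts = total.astype(np.uint8)
        self.n_kmers_consumed += int(canonical_codes.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sketch):
            return NotImplemented
        return (
            self.sample_name == other.sample_name
            and self.k == other.k
            and self.length == other.length
            and self.n_kmers_consumed == other.n_kmers_consumed
            and bool(np.array_equal(self.counts, other.counts))
        )


# ---------------------------------------------------------------------------
# Read-file parsing (FASTA / FASTQ, optionally gzipped; auto-detected)

def _open_maybe_gzip(path: Path) -> io.TextIOBase:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def _iter_reads(path: Path) -> Iterator[str]:
    """Yield read sequences from a FASTA or FASTQ file.

    The format is auto-detected from the first non-whitespace character
    after decompression ('>' FASTA, '@' FASTQ).  Uses Biopython's
    SeqIO parser; malformed records raise with file and record index.
    """
    from Bio import SeqIO

    with _open_maybe_gzip(path) as handle:
        first = ""
        while True:
            ch = handle.read(1)
            if not ch:
                return  # empty file: zero reads
            if not ch.isspace():
                first = ch
                break
        handle.seek(0)
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(
                f"{path}: cannot detect read format (first character {first!r},"
                " expected '>' or '@')"
            )
        record_idx = 0
        try:
            for record in SeqIO.parse(handle, fmt):
                yield str(record.seq)
                record_idx += 1
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed {fmt.upper()} record at index {record_idx}: {exc}"
            ) from exc


def count_files(
    paths: Sequence[str | Path],
    sample_name: str,
    config: KmerConfig,
) -> Sketch:
    """Count all reads of all files into one sketch for a sample.

    Files may be FASTA or FASTQ, plain or gzip-compressed, in any mix.
    The result is deterministic and independent of file order.
    """
    sketch = Sketch.empty(config, sample_name=sample_name)
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"read file not found: {path}")
        sketch.count_sequences(_iter_reads(path))
    return sketch


# ---------------------------------------------------------------------------
# KWS1 sketch serialization (little-endian):
#   magic "KWS1" | version u8 | k u8 | sketch_length u64 |
#   n_kmers_consumed u64 | name_len u16 | sample_name utf-8 |
#   sketch_length bytes of counts
# The whole file may be gzip-wrapped; the loader sniffs the gzip magic.

def save_sketch(sketch: Sketch, path: str | Path, compress: bool = False) -> None:
    """Write a sketch in the KWS1 binary format (byte-deterministic)."""
    name = sketch.sample_name.encode("utf-8")
    header = _MAGIC + struct.pack(
        "<BBQQH", _VERSION, sketch.k, sketch.length, sketch.n_kmers_consumed,
        len(name),
    )
    payload = header + name + sketch.counts.tobytes()
    if compress:
        # mtime pinned so repeated saves are byte-identical
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)


def load_sketch(path: str | Path) -> Sketch:
    """Read a KWS1 sketch file (plain or gzip-wrapped)."""
    with open(path, "rb") as raw:
        if raw.read(2) == b"\x1f\x8b":
            raw.seek(0)
            data = gzip.decompress(raw.read())
        else:
            raw.seek(0)
            data = raw.read()
    if data[:4] != _MAGIC:
        raise SketchFormatError(
            f"{path}: bad magic {data[:4]!r}, expected {_MAGIC!r}"
        )
    try:
        version, k, length, n_consumed, name_len = struct.unpack_from(
            "<BBQQH", data, 4
        )
    except struct.error as exc:
        raise SketchFormatError(f"{path}: truncated header") from exc
    if version != _VERSION:
        raise SketchFormatError(
            f"{path}: unsupported sketch version {version} (expected {_VERSION})"
        )
    offset = 4 + struct.calcsize("<BBQQH")
    name_end = offset + name_len
    if len(data) < name_end + length:
        raise SketchFormatError(
            f"{path}: truncated payload ({len(data)} bytes, "
            f"expected {name_end + length})"
        )
    name = data[offset:name_end].decode("utf-8")
    counts = np.frombuffer(data[name_end:name_end + length], dtype=np.uint8).copy()
    return Sketch(
        sample_name=name, k=k, length=length, counts=counts,
        n_kmers_consumed=n_consumed,
    )
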