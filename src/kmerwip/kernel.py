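"""Entropy weighting and inner-product kernels over k-mer sketches.

Given sketches S_i (one per sample), the population frequency sketch F
records, per bin b, the fraction of samples with a non-zero count.  The
weight vector H is the binary Shannon entropy of F,

    H_b = -(F_b log2 F_b + (1 - F_b) log2 (1 - F_b)),

with the 0*log(0) = 0 convention, so bins absent from all samples or
present in all samples get weight 0 and bins present in exactly half the
samples get weight 1.  The weighted inner product (WIP) kernel is

    K_ij = sum_b S_ib S_jb H_b,

the unweighted inner product (IP) kernel drops H.  K is normalized to
unit diagonal with the Euclidean (cosine) norm,

    K'_ij = K_ij / sqrt(K_ii K_jj),

and converted to a Euclidean distance with the kernel trick,

    D_ij = sqrt(K'_ii + K'_jj - 2 K'_ij).

Because H depends on F, WIP distances are relative to the analysis set:
the distance between two fixed samples changes when other samples are
added or removed.  Positive semi-definiteness of K (all eigenvalues
non-negative) guarantees D embeds in Euclidean space; it holds by
construction for both kernels and is verified numerically.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from kmerwip.sketch import Sketch, SketchFormatError

__all__ = [
    "FrequencySketch",
    "WeightVector",
    "KernelMatrix",
    "DistanceMatrix",
    "population_frequency",
    "entropy_weights",
    "wip_kernel",
    "ip_kernel",
    "normalize_kernel",
    "kernel_to_distance",
    "check_psd",
    "save_matrix",
    "load_matrix",
    "save_weights",
    "load_weights",
]

#: relative eigenvalue tolerance below which a kernel is not considered PSD
PSD_TOL = 1e-8
#: gross violation threshold at which downstream steps should abort
PSD_ABORT_TOL = 1e-4

_CHUNK_BINS = 1 << 20  # bins per accumulation chunk; order fixed, ascending

_KWV_MAGIC = b"KWV1"
_KWV_VERSION = 1


@dataclass
class FrequencySketch:
    """Per-bin fraction of samples with a non-zero count."""

    length: int
    freqs: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (self.length,):
            raise ValueError("freqs length mismatch")


@dataclass
class WeightVector:
    """Per-bin binary Shannon entropy of the population frequency."""

    length: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (self.length,):
            raise ValueError("weights length mismatch")


@dataclass
class KernelMatrix:
    """Symmetric n x n matrix of pairwise (weighted) inner products."""

    sample_names: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_names)
        if self.values.shape != (n, n):
            raise ValueError(
                f"kernel shape {self.values.shape} != ({n}, {n})"
            )


@dataclass
class DistanceMatrix:
    """Symmetric n x n matrix of pairwise distances with zero diagonal."""

    sample_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.sample_names)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance shape {self.values.shape} != ({n}, {n})"
            )

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries in row-major order."""
        idx = np.tril_indices(self.values.shape[0], k=-1)
        return self.values[idx]


def _check_conformable(sketches: Sequence[Sketch]) -> tuple[int, int]:
    if len(sketches) < 2:
        raise ValueError(f"need at least 2 sketches, got {len(sketches)}")
    k, length = sketches[0].k, sketches[0].length
    bad = [
        s.sample_name
        for s in sketches
        if s.k != k or s.length != length
    ]
    if bad:
        raise ValueError(
            f"sketches disagree on k or length (expected k={k}, "
            f"length={length}); offenders: {', '.join(bad)}"
        )
    return k, length


def population_frequency(sketches: Sequence[Sketch]) -> FrequencySketch:
    """Fraction of samples with a non-zero count, per bin.

    Presence/absence only: the magnitude of a count is ignored.  The
    frequency is computed over ALL samples in the analysis set,
    including any pair later compared.
    """
    _, length = _check_conformable(sketches)
    n = len(sketches)
    present = np.zeros(length, dtype=np.int64)
    for s in sketches:
        present += s.counts > 0
    return FrequencySketch(length=length, freqs=present / n, n_samples=n)


def entropy_weights(freq: FrequencySketch) -> WeightVector:
    """Binary Shannon entropy of each bin's population frequency.

    Endpoints are handled explicitly (0 * log2(0) = 0) so frequencies of
    exactly 0 or 1 give weight exactly 0 with no NaN.
    """
    f = freq.freqs
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    w = np.zeros_like(f)
    interior = (f > 0) & (f < 1)
    fi = f[interior]
    w[interior] = -(fi * np.log2(fi) + (1.0 - fi) * np.log2(1.0 - fi))
    return WeightVector(length=freq.length, weights=w)


def _weighted_gram(sketches: Sequence[Sketch], weights: np.ndarray | None) -> np.ndarray:
    """Accumulate sum_b w_b S_ib S_jb in fixed ascending-bin chunk order.

    Sketch counts stay uint8 until each chunk is lifted to float64, so
    memory is one chunk's worth of floats, not the full count matrix.
    """
    n = len(sketches)
    length = sketches[0].length
    gram = np.zeros((n, n), dtype=np.float64)
    for start in range(0, length, _CHUNK_BINS):
        stop = min(start + _CHUNK_BINS, length)
        block = np.empty((n, stop - start), dtype=np.float64)
        for i, s in enumerate(sketches):
            block[i] = s.counts[start:stop]
        if weights is None:
            gram += block @ block.T
        else:
            gram += (block * weights[start:stop]) @ block.T
    # enforce exact symmetry (BLAS gemm does not guarantee it bitwise)
    lower = np.tril(gram)
    return lower + np.tril(gram, -1).T


def wip_kernel(sketches: Sequence[Sketch], weights: WeightVector) -> KernelMatrix:
    """Weighted inner-product kernel: K_ij = sum_b S_ib S_jb H_b."""
    _, length = _check_conformable(sketches)
    if weights.length != length:
        raise ValueError(
            f"weight vector length {weights.length} != sketch length {length}"
        )
    values = _weighted_gram(sketches, weights.weights)
    return KernelMatrix(
        sample_names=[s.sample_name for s in sketches], values=values
    )


def ip_kernel(sketches: Sequence[Sketch]) -> KernelMatrix:
    """Unweighted inner-product kernel: K_ij = sum_b S_ib S_jb."""
    _check_conformable(sketches)
    values = _weighted_gram(sketches, None)
    return KernelMatrix(
        sample_names=[s.sample_name for s in sketches], values=values
    )


def normalize_kernel(kernel: KernelMatrix) -> KernelMatrix:
    """Scale to unit diagonal: K'_ij = K_ij / sqrt(K_ii K_jj).

    A zero (or negative) self-similarity cannot be normalized; this is
    what an all-zero or entirely down-weighted sketch produces, and such
    samples should be excluded from the analysis set.
    """
    diag = np.diag(kernel.values)
    bad = np.flatnonzero(diag <= 0)
    if bad.size:
        names = ", ".join(kernel.sample_names[i] for i in bad)
        raise ValueError(
            f"cannot normalize kernel: zero or negative self-similarity for "
            f"sample(s) {names}; exclude empty or fully down-weighted samples"
        )
    root = np.sqrt(diag)
    values = kernel.values / np.outer(root, root)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(
        sample_names=list(kernel.sample_names), values=values, normalized=True
    )


def kernel_to_distance(kernel: KernelMatrix) -> DistanceMatrix:
    """Kernel-trick Euclidean distance D_ij = sqrt(K_ii + K_jj - 2 K_ij).

    Tiny negative radicands (> -1e-9, floating-point jitter) clamp to
    zero; anything more negative means the kernel is not a valid
    similarity and is an error.
    """
    diag = np.diag(kernel.values)
    radicand = diag[:, None] + diag[None, :] - 2.0 * kernel.values
    if radicand.min() < -1e-9:
        raise ValueError(
            f"negative squared distance {radicand.min():g}: kernel is not a "
            "valid (PSD) similarity matrix"
        )
    values = np.sqrt(np.clip(radicand, 0.0, None))
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(
        sample_names=list(kernel.sample_names), values=values
    )


def check_psd(kernel: KernelMatrix, tol: float = PSD_TOL) -> tuple[bool, float]:
    """Positive semi-definiteness check via the eigenvalue spectrum.

    Returns ``(flag, smallest_eigenvalue)``; the flag is true iff the
    smallest eigenvalue is >= -tol * max(1, largest |eigenvalue|), i.e.
    negative eigenvalues within floating-point jitter of zero pass.
    """
    values = kernel.values
    if not np.allclose(values, values.T, rtol=0.0, atol=1e-12):
        raise ValueError("kernel matrix is not symmetric")
    eigenvalues = np.linalg.eigvalsh(values)
    smallest = float(eigenvalues[0])
    scale = max(1.0, float(np.abs(eigenvalues).max()))
    return smallest >= -tol * scale, smallest


# ---------------------------------------------------------------------------
# Matrix text formats

def save_matrix(
    names: Sequence[str],
    values: np.ndarray,
    path: str | Path,
    fmt: str = "tsv",
) -> None:
    """Write a labelled square matrix as TSV (default) or square PHYLIP.

    TSV: first line is a tab followed by sample names; each following
    row is the sample name then the values.  Values are printed with 10
    significant digits.
    """
    values = np.asarray(values, dtype=np.float64)
    with open(path, "w", encoding="utf-8") as fh:
        if fmt == "tsv":
            fh.write("\t" + "\t".join(names) + "\n")
            for name, row in zip(names, values):
                fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        elif fmt == "phylip":
            fh.write(f"{len(names)}\n")
            for name, row in zip(names, values):
                fh.write(name + " " + " ".join(f"{v:.10g}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown matrix format {fmt!r}")


def load_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labelled square matrix written by :func:`save_matrix` (TSV)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in parts[1:]])
    return header, np.asarray(rows, dtype=np.float64)


def save_weights(weights: WeightVector, path: str | Path, compress: bool = False) -> None:
    """Write a weight vector in the KWV1 binary format.

    Same header scheme as the KWS1 sketch format; payload is one little-
    endian float64 per bin.
    """
    header = _KWV_MAGIC + struct.pack("<BQ", _KWV_VERSION, weights.length)
    payload = header + weights.weights.astype("<f8").tobytes()
    if compress:
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write(payload)
    else:
        with open(path, "wb") as fh:
            fh.write(payload)


def load_weights(path: str | Path) -> WeightVector:
    """Read a KWV1 weight-vector file (plain or gzip-wrapped)."""
    with open(path, "rb") as raw:
        data = raw.read()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    if data[:4] != _KWV_MAGIC:
        raise SketchFormatError(
            f"{path}: bad magic {data[:4]!r}, expected {_KWV_MAGIC!r}"
        )
    version, length = struct.unpack_from("<BQ", data, 4)
    if version != _KWV_VERSION:
        raise SketchFormatError(f"{path}: unsupported weights version {version}")
    offset = 4 + struct.calcsize("<BQ")
    expected = offset + 8 * length
    if len(data) < expected:
        raise SketchFormatError(
            f"{path}: truncated payload ({len(data)} bytes, expected {expected})"
        )
    weights = np.frombuffer(data[offset:expected], dtype="<f8").copy()
    return WeightVector(length=length, weights=weights)
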