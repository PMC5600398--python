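import gzip
from pathlib import Path

import numpy as np
import pytest

from kmerwip import KmerConfig, Sketch

BASES = "ACGT"


def random_reads(rng: np.random.Generator, n_reads: int, length: int) -> list[str]:
    """Uniform random ACGT reads."""
    codes = rng.integers(0, 4, size=(n_reads, length))
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [lookup[row].tobytes().decode("ascii") for row in codes]


def random_sketches(
    rng: np.random.Generator,
    n_samples: int,
    length: int = 97,
    k: int = 11,
    sparsity: float = 0.5,
) -> list[Sketch]:
    """Random sketch sets with realistic sparsity, for kernel properties."""
    sketches = []
    for i in range(n_samples):
        counts = rng.integers(0, 30, size=length)
        counts[rng.random(length) < sparsity] = 0
        sketches.append(
            Sketch(
                sample_name=f"s{i}",
                k=k,
                length=length,
                counts=counts.astype(np.uint8),
                n_kmers_consumed=int(counts.sum()),
            )
        )
    return sketches


def write_fastq(path: Path, reads: list[str], compress: bool = False) -> Path:
    chunks = [f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n" for i, seq in enumerate(reads)]
    data = "".join(chunks).encode("ascii")
    if compress:
        with open(path, "wb") as raw:
            with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                fh.write(data)
    else:
        path.write_bytes(data)
    return path


def write_fasta(path: Path, reads: list[str]) -> Path:
    data = "".join(f">r{i}\n{seq}\n" for i, seq in enumerate(reads)).encode("ascii")
    path.write_bytes(data)
    return path


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170905)


@pytest.fixture
def small_config() -> KmerConfig:
    # prime length >= 4^5: bin_index is injective on canonical 5-mers
    return KmerConfig(k=5, sketch_length=1031)
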