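"""Population and read simulator for validating the similarity estimator.

The generator produces the whole chain needed to score the estimator
against known truth, with no external tools:

1. a Kingman-coalescent genealogy for ``n`` haploid individuals
   (exponential inter-coalescence times with rate C(j, 2) at j lineages,
   uniformly chosen pairs);
2. branch lengths rescaled so the population's mean pairwise nucleotide
   diversity — the expected fraction of differing sites between two
   sampled genomes — equals a target pi;
3. Jukes-Cantor substitutions dropped on each branch (Poisson number of
   events, uniform sites, uniform alternative base), yielding aligned
   leaf genomes whose exact pairwise Hamming distances are the truth;
4. uniform-position, uniform-strand short reads per individual and
   sequencing run, with the run's read count drawn from a truncated
   normal (coefficient of variation ``cv_reads``) to emulate run-to-run
   yield variation, and independent per-base substitution errors.

Substitutions only — no indels — so genomes stay aligned and truth is an
exact per-site Hamming distance.  Because multiple substitutions can hit
one site, expected Hamming distance saturates below the raw substitution
load; the rescaling in step 2 inverts the Jukes-Cantor saturation so the
realized diversity targets pi itself rather than the substitution rate.

All randomness flows from one user seed through named independent
streams (genealogy, mutations, reads), so each stage is independently
reproducible.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from kmerwip.kernel import (
    DistanceMatrix,
    entropy_weights,
    ip_kernel,
    kernel_to_distance,
    normalize_kernel,
    population_frequency,
    wip_kernel,
)
from kmerwip.sketch import KmerConfig, Sketch

__all__ = [
    "SimulationParams",
    "Genealogy",
    "SimulatedPopulation",
    "simulate_genealogy",
    "scale_to_pi",
    "drop_mutations",
    "simulate_population",
    "simulate_reads",
    "spearman_rho",
    "tile_truth",
    "benchmark_replicate",
    "run_benchmark",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the simulated re-sequencing experiment.

    Defaults mirror a small population re-sequencing design: 12
    individuals, 1 Mbp genomes, diversity pi = 0.005, three replicate
    sequencing runs per individual at 8-fold mean coverage with a 0.3
    coefficient of variation in read counts, 100 bp reads with a 0.1%
    per-base error rate.
    """

    n_individuals: int = 12
    genome_length: int = 1_000_000
    pi: float = 0.005
    coverage: float = 8.0
    runs_per_individual: int = 3
    read_length: int = 100
    error_rate: float = 0.001
    cv_reads: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 0.75:
            raise ValueError(f"pi must be in (0, 0.75), got {self.pi}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.cv_reads < 0:
            raise ValueError("cv_reads must be >= 0")
        if self.n_individuals < 3:
            raise ValueError("need at least 3 individuals")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")

    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "genome_length": self.genome_length,
            "pi": self.pi,
            "coverage": self.coverage,
            "runs_per_individual": self.runs_per_individual,
            "read_length": self.read_length,
            "error_rate": self.error_rate,
            "cv_reads": self.cv_reads,
            "seed": self.seed,
        }


def _streams(seed: int | np.random.SeedSequence) -> dict[str, np.random.Generator]:
    """Independent, named RNG streams derived from one seed."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    return {
        "genealogy": np.random.default_rng(children[0]),
        "mutations": np.random.default_rng(children[1]),
        "reads": np.random.default_rng(children[2]),
    }


@dataclass
class Genealogy:
    """Rooted binary coalescent tree over n leaves.

    Nodes 0..n-1 are leaves; internal nodes follow in coalescence order,
    node 2n-2 is the root.  ``branch_lengths[v]`` is the length of the
    branch above node v (0 for the root).
    """

    n_leaves: int
    parent: np.ndarray
    branch_lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes - 1):
            kids[int(self.parent[v])].append(v)
        return kids

    def scaled(self, factor: float) -> "Genealogy":
        return Genealogy(
            n_leaves=self.n_leaves,
            parent=self.parent.copy(),
            branch_lengths=self.branch_lengths * factor,
        )

    def pairwise_path_lengths(self) -> np.ndarray:
        """Sum of branch lengths along the path between each leaf pair."""
        n = self.n_leaves
        ancestors: list[dict[int, float]] = []
        for leaf in range(n):
            anc: dict[int, float] = {}
            v, d = leaf, 0.0
            while v >= 0:
                anc[v] = d
                d += self.branch_lengths[v]
                v = int(self.parent[v])
            ancestors.append(anc)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                # lowest common ancestor = shared ancestor closest to i
                lca_depth = min(
                    ancestors[i][a] + ancestors[j][a]
                    for a in ancestors[i]
                    if a in ancestors[j]
                )
                dist[i, j] = dist[j, i] = lca_depth
        return dist


@dataclass
class SimulatedPopulation:
    """Aligned leaf genomes with their exact pairwise distances.

    ``genomes`` holds 2-bit base codes, one row per individual;
    ``true_distances`` is the per-site Hamming distance between rows.
    """

    genomes: np.ndarray
    true_distances: np.ndarray
    genealogy: Genealogy

    @property
    def n_individuals(self) -> int:
        return self.genomes.shape[0]

    @property
    def genome_length(self) -> int:
        return self.genomes.shape[1]

    def genome_strings(self) -> list[str]:
        return [codes_to_string(row) for row in self.genomes]


def codes_to_string(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Draw a Kingman coalescent tree for n lineages.

    While j lineages remain, wait an Exponential(rate C(j,2)) time (in
    coalescent units of 2N generations) and merge two lineages chosen
    uniformly at random.  E[TMRCA] for n=2 is 1.
    """
    if n < 2:
        raise ValueError("need at least 2 lineages")
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    next_node = n
    while len(active) > 1:
        j = len(active)
        rate = j * (j - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        a_idx, b_idx = rng.choice(j, size=2, replace=False)
        a, b = active[a_idx], active[b_idx]
        parent[a] = parent[b] = next_node
        node_time[next_node] = t
        for x in sorted((a_idx, b_idx), reverse=True):
            active.pop(x)
        active.append(next_node)
        next_node += 1
    branch_lengths = np.zeros(n_nodes)
    for v in range(n_nodes - 1):
        branch_lengths[v] = node_time[int(parent[v])] - node_time[v]
    return Genealogy(n_leaves=n, parent=parent, branch_lengths=branch_lengths)


def _expected_hamming(path_length: np.ndarray | float) -> np.ndarray | float:
    """Expected per-site Hamming distance after a Jukes-Cantor path.

    With substitution rate 1 per site per unit branch length, multiple
    hits saturate the observable distance at 3/4.
    """
    return 0.75 * (1.0 - np.exp(-4.0 * np.asarray(path_length) / 3.0))


def implied_pi(genealogy: Genealogy) -> float:
    """Mean expected pairwise Hamming distance implied by the tree."""
    paths = genealogy.pairwise_path_lengths()
    tri = paths[np.triu_indices(genealogy.n_leaves, k=1)]
    return float(np.mean(_expected_hamming(tri)))


def scale_to_pi(genealogy: Genealogy, pi: float) -> Genealogy:
    """Rescale branch lengths so the tree implies mean diversity pi.

    Solves for the single multiplicative constant c such that the mean
    over leaf pairs of the Jukes-Cantor expected Hamming distance along
    the scaled path equals pi.  Inverting the saturation here means the
    realized diversity of the mutated genomes converges to pi itself as
    the genome grows, not to the (larger) substitution load.
    """
    if not 0.0 < pi < 0.75:
        raise ValueError(f"pi must be in (0, 0.75), got {pi}")
    paths = genealogy.pairwise_path_lengths()
    tri = paths[np.triu_indices(genealogy.n_leaves, k=1)]
    if tri.max() <= 0:
        raise ValueError("genealogy has zero total path length")

    def gap(c: float) -> float:
        return float(np.mean(_expected_hamming(c * tri))) - pi

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"cannot reach pi={pi} by rescaling")
    c = optimize.brentq(gap, 0.0, hi, xtol=1e-15, rtol=1e-14)
    return genealogy.scaled(c)


def drop_mutations(
    genealogy: Genealogy,
    genome_length: int,
    rng: np.random.Generator,
) -> SimulatedPopulation:
    """Drop Jukes-Cantor substitutions on every branch.

    The ancestral genome is uniform over ACGT.  Each branch receives a
    Poisson(branch_length * genome_length) number of substitution
    events; each event hits a uniform site and replaces the current base
    with a uniform choice of the three alternatives.  Events are applied
    in order, so repeated hits on one site compound (and may revert).
    """
    n = genealogy.n_leaves
    kids = genealogy.children()
    ancestral = rng.integers(0, 4, size=genome_length, dtype=np.int8)
    genomes = np.empty((n, genome_length), dtype=np.int8)
    # iterative preorder DFS; genome copied per tree edge
    stack: list[tuple[int, np.ndarray]] = [(genealogy.root, ancestral)]
    while stack:
        node, genome = stack.pop()
        if node != genealogy.root:
            genome = genome.copy()
            n_events = rng.poisson(
                genealogy.branch_lengths[node] * genome_length
            )
            if n_events:
                sites = rng.integers(0, genome_length, size=n_events)
                shifts = rng.integers(1, 4, size=n_events, dtype=np.int8)
                for s, d in zip(sites, shifts):
                    genome[s] = (genome[s] + d) % 4
        if node < n:
            genomes[node] = genome
        else:
            for child in kids[node]:
                stack.append((child, genome))
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.count_nonzero(genomes[i] != genomes[j])) / genome_length
            dist[i, j] = dist[j, i] = d
    return SimulatedPopulation(
        genomes=genomes, true_distances=dist, genealogy=genealogy
    )


def simulate_population(
    params: SimulationParams,
    seed: int | np.random.SeedSequence | None = None,
) -> SimulatedPopulation:
    """Genealogy, rescaling, and mutation drop in one call."""
    streams = _streams(params.seed if seed is None else seed)
    tree = simulate_genealogy(params.n_individuals, streams["genealogy"])
    tree = scale_to_pi(tree, params.pi)
    return drop_mutations(tree, params.genome_length, streams["mutations"])


# ---------------------------------------------------------------------------
# Read simulation

def _draw_read_count(
    mean_reads: float, cv: float, rng: np.random.Generator
) -> int:
    """Truncated-normal run yield: Normal(mean, cv*mean), floored at 0."""
    if cv == 0:
        return int(round(mean_reads))
    return max(0, int(round(rng.normal(mean_reads, cv * mean_reads))))


def _run_read_codes(
    genome: np.ndarray,
    n_reads: int,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample reads as a (n_reads, read_length) matrix of base codes.

    Positions uniform over valid starts, strand uniform, then i.i.d.
    per-base substitution errors (uniform over the three alternatives).
    """
    length = genome.size
    starts = rng.integers(0, length - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    offsets = np.arange(read_length)
    reads = genome[starts[:, None] + offsets[None, :]].copy()
    if n_reads:
        rev = strands == 1
        # reverse complement in code space: complement is 3 - code
        reads[rev] = 3 - reads[rev, ::-1]
        if error_rate > 0:
            err = rng.random(reads.shape) < error_rate
            shifts = rng.integers(1, 4, size=int(err.sum()), dtype=np.int8)
            reads[err] = (reads[err] + shifts) % 4
    return reads


def iter_run_reads(
    population: SimulatedPopulation,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Iterator[tuple[int, int, np.ndarray]]:
    """Yield (individual, run, read code matrix) for every sequencing run.

    Ordering is individual-major then run, and the draw sequence is
    fixed, so results are deterministic for a given generator state.
    """
    mean_reads = params.coverage * params.genome_length / params.read_length
    for ind in range(population.n_individuals):
        for run in range(params.runs_per_individual):
            n_reads = _draw_read_count(mean_reads, params.cv_reads, rng)
            reads = _run_read_codes(
                population.genomes[ind], n_reads, params.read_length,
                params.error_rate, rng,
            )
            yield ind, run, reads


def simulate_reads(
    population: SimulatedPopulation,
    params: SimulationParams,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
    compress: bool = True,
) -> list[Path]:
    """Write per-run FASTQ files (gzip by default) and return their paths.

    File names are ``ind{i}_run{r}.fastq[.gz]``; quality strings are
    constant ('I') since counting ignores quality.  Byte-deterministic
    for a fixed generator state.
    """
    if rng is None:
        rng = _streams(params.seed)["reads"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    suffix = ".fastq.gz" if compress else ".fastq"
    for ind, run, reads in iter_run_reads(population, params, rng):
        path = out_dir / f"ind{ind:02d}_run{run}{suffix}"
        qual = "I" * params.read_length
        chunks = []
        for r, row in enumerate(reads):
            seq = codes_to_string(row)
            chunks.append(f"@ind{ind:02d}_run{run}_read{r}\n{seq}\n+\n{qual}\n")
        payload = "".join(chunks).encode("ascii")
        if compress:
            with open(path, "wb") as raw:
                with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                    fh.write(payload)
        else:
            path.write_bytes(payload)
        paths.append(path)
    return paths


def write_population(
    population: SimulatedPopulation,
    params: SimulationParams,
    out_dir: str | Path,
) -> None:
    """Write genomes (FASTA), the truth matrix (TSV), and a JSON sidecar."""
    from kmerwip.kernel import save_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "genomes.fasta", "w", encoding="ascii") as fh:
        for i, seq in enumerate(population.genome_strings()):
            fh.write(f">ind{i:02d}\n")
            for start in range(0, len(seq), 80):
                fh.write(seq[start:start + 80] + "\n")
    names = [f"ind{i:02d}" for i in range(population.n_individuals)]
    save_matrix(names, population.true_distances, out_dir / "true_distances.tsv")
    with open(out_dir / "params.json", "w", encoding="utf-8") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Scoring

def tile_truth(true_distances: np.ndarray, runs_per_individual: int) -> np.ndarray:
    """Expand an n x n sample truth to run level.

    Each sample's distances are replicated for each of its sequencing
    runs (individual-major run ordering); runs of the same individual
    are at distance zero.
    """
    block = np.ones((runs_per_individual, runs_per_individual))
    return np.kron(np.asarray(true_distances), block)


def rank_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman's rho between two vectors (average ranks for ties).

    A constant vector leaves the correlation undefined and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("constant distances: rank correlation is undefined")
    return float(stats.spearmanr(a, b).statistic)


def spearman_rho(d_est: DistanceMatrix, d_true: DistanceMatrix) -> float:
    """Spearman's rank correlation between two distance matrices.

    Computed over the strictly-lower-triangle entries.  Requires
    identical sample ordering and n >= 3.
    """
    if d_est.sample_names != d_true.sample_names:
        raise ValueError("distance matrices have different sample orderings")
    if len(d_est.sample_names) < 3:
        raise ValueError("need at least 3 samples for a rank correlation")
    return rank_correlation(d_est.condensed(), d_true.condensed())


# ---------------------------------------------------------------------------
# Benchmark driver

def _sketches_for_replicate(
    population: SimulatedPopulation,
    params: SimulationParams,
    config: KmerConfig,
    rng: np.random.Generator,
) -> list[Sketch]:
    sketches = []
    for ind, run, reads in iter_run_reads(population, params, rng):
        sketch = Sketch.empty(config, sample_name=f"ind{ind:02d}_run{run}")
        if reads.size:
            # join with 'N' separators: windows never span two reads
            joined = "N".join(codes_to_string(row) for row in reads)
            sketch.count_sequence(joined)
        sketches.append(sketch)
    return sketches


def distances_from_sketches(
    sketches: Sequence[Sketch], metric: str
) -> DistanceMatrix:
    """Full similarity pipeline: kernel -> normalize -> distance."""
    if metric == "wip":
        weights = entropy_weights(population_frequency(sketches))
        kern = wip_kernel(sketches, weights)
    elif metric == "ip":
        kern = ip_kernel(sketches)
    else:
        raise ValueError(f"unknown metric {metric!r} (expected 'wip' or 'ip')")
    return kernel_to_distance(normalize_kernel(kern))


def benchmark_replicate(
    params: SimulationParams,
    config: KmerConfig,
    metrics: Sequence[str] = ("wip", "ip"),
    seed: int | np.random.SeedSequence | None = None,
) -> dict[str, float]:
    """One simulate -> count -> estimate -> score pass.

    Returns Spearman's rho against run-level truth for each metric, on
    the same simulated reads and sketches.
    """
    streams = _streams(params.seed if seed is None else seed)
    tree = simulate_genealogy(params.n_individuals, streams["genealogy"])
    tree = scale_to_pi(tree, params.pi)
    population = drop_mutations(tree, params.genome_length, streams["mutations"])
    sketches = _sketches_for_replicate(
        population, params, config, streams["reads"]
    )
    names = [s.sample_name for s in sketches]
    truth = DistanceMatrix(
        sample_names=names,
        values=tile_truth(
            population.true_distances, params.runs_per_individual
        ),
    )
    result = {}
    for metric in metrics:
        est = distances_from_sketches(sketches, metric)
        result[metric] = spearman_rho(est, truth)
    return result


def run_benchmark(
    coverages: Sequence[float],
    pis: Sequence[float],
    *,
    n_individuals: int = 12,
    genome_length: int = 100_000,
    runs_per_individual: int = 3,
    read_length: int = 100,
    error_rate: float = 0.001,
    cv_reads: float = 0.3,
    k: int = 20,
    sketch_size: int = 1_000_003,
    metrics: Sequence[str] = ("wip", "ip"),
    replicates: int = 10,
    seed: int = 1,
) -> pd.DataFrame:
    """Accuracy sweep over a (coverage, pi) grid.

    For every grid point and replicate: simulate a population, generate
    replicate sequencing runs, count sketches, compute the distance
    matrix under each metric, and score it against the known truth by
    Spearman's rho.  Returns a tidy frame with one row per (replicate,
    coverage, pi, metric).  Deterministic for a given seed; each
    replicate of each grid point has its own independent seed stream.
    """
    config = KmerConfig(k=k, sketch_length=sketch_size)
    rows = []
    for gi, (coverage, pi) in enumerate(
        (c, p) for c in coverages for p in pis
    ):
        for rep in range(replicates):
            params = SimulationParams(
                n_individuals=n_individuals,
                genome_length=genome_length,
                pi=pi,
                coverage=coverage,
                runs_per_individual=runs_per_individual,
                read_length=read_length,
                error_rate=error_rate,
                cv_reads=cv_reads,
                seed=seed,
            )
            ss = np.random.SeedSequence([seed, gi, rep])
            rhos = benchmark_replicate(params, config, metrics, seed=ss)
            for metric, rho in rhos.items():
                rows.append(
                    {
                        "replicate": rep,
                        "coverage": coverage,
                        "pi": pi,
                        "metric": metric,
                        "rho": rho,
                    }
                )
    return pd.DataFrame(rows)
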