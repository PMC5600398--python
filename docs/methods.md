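# Methods

## Sketching

Reads are uppercased and decomposed into overlapping k-length windows;
any window containing a non-ACGT character is skipped whole. Each window
is canonicalized to the lexicographic minimum of itself and its reverse
complement (A < C < G < T), packed big-endian into a 2-bit integer
(A=0, C=1, G=2, T=3), and counted at bin `code mod L`, where `L` is the
sketch length. The packing is a reversible hash: it is injective for
fixed k, bit-exact across platforms, and — because `L` is required to be
prime — provably injective on canonical k-mers whenever `L >= 4^k`,
which is what the exact-counting oracle in the test suite exploits
(k = 5, L = 1031). `k` is capped at 32 so the code fits a 64-bit
integer; 19–21 is the practical default range for distinguishing
genomic context in eukaryote-scale data.

Bins are saturating 8-bit counters: an increment at 255 is a no-op, so
counts never wrap. Since all increments are +1, batch accumulation
(exact bincount per read batch, then clamp) is equivalent to per-event
saturating increments. `n_kmers_consumed` records pre-saturation
counting events and is therefore invariant to the sketch length, which
the collision-monotonicity test relies on.

Collisions between distinct canonical k-mers sharing a bin are tolerated
by design: they only ever inflate similarity, and they do so uniformly
over sample pairs, so the *ordering* of distances — which is what the
estimator is scored on — is robust at sensible fill fractions. Choose
`L` a few times larger than the expected number of distinct k-mers; the
`count` command logs the realized fill.

## Weighting and distances

The population frequency `F_b` is the fraction of samples whose bin `b`
is non-zero, computed over all samples in the run (including any pair
later compared; there is no leave-one-out variant). The weight is the
binary Shannon entropy `H_b = -(F log2 F + (1-F) log2 (1-F))`, with the
endpoints handled explicitly so `F in {0, 1}` gives exactly 0 with no
NaN. Entropy weighting is assumption-free: it needs no genome model,
only the presence/absence pattern itself, and it down-weights — without
zeroing — both ubiquitous k-mers (fixed, repetitive) and near-private
ones (rare variants, sequencing errors).

Kernels accumulate `sum_b w_b S_ib S_jb` in float64 over fixed
ascending-bin chunks of 2^20 bins (counts stay uint8 until a chunk is
lifted), so results are independent of how work is scheduled, and the
lower triangle is mirrored afterwards to make the matrix exactly
symmetric. Normalization divides by `sqrt(K_ii K_jj)` and fails loudly,
naming the sample, when a self-similarity is zero — the signature of an
empty or entirely down-weighted sketch, which should be excluded from
the set rather than silently propagated.

The distance is the kernel-trick form `D_ij = sqrt(K'_ii + K'_jj -
2 K'_ij)` — with the square root, so `D` is a genuine Euclidean metric;
the `--squared-distance` flag emits the radicand for users who want the
squared form. Radicands in `(-1e-9, 0)` are clamped to zero as
floating-point jitter; anything more negative is an error. Positive
semi-definiteness is verified on the eigenvalue spectrum with a relative
tolerance of 1e-8 (jitter-sized negative eigenvalues must not fail valid
Gram matrices); the CLI warns on a marginal failure and aborts only
below -1e-4 relative, since both kernels are Gram matrices of
(weighted) inner products and a gross violation can only mean corrupted
inputs.

## The validation simulator

The simulator exists to answer one question reproducibly: how well does
each metric's distance ordering recover the true ordering, as a function
of coverage and diversity? It generates:

1. **Genealogy** — a Kingman coalescent over `n` lineages (exponential
   waiting times with rate C(j,2), uniform pair merges). Checked against
   closed-form properties: E[TMRCA] = 1 for n = 2, uniform labeled
   topologies for n = 3.
2. **Diversity scaling** — all branch lengths are multiplied by the one
   constant for which the tree-implied *expected Hamming distance*,
   averaged over leaf pairs, equals the target π. Under Jukes–Cantor
   with substitution rate 1/site/unit length, a path of length t yields
   an expected per-site Hamming distance of `3/4 (1 - exp(-4t/3))`;
   the scaling constant is found by bracketed root-finding on the mean
   of this expression. Inverting the saturation here (rather than
   scaling the raw substitution load linearly) makes the realized
   diversity of the emitted genomes converge to π itself — the quantity
   π actually denotes — which matters at π ≳ 0.05 where multiple hits
   otherwise bias realized diversity several percent low. π must lie in
   (0, 0.75), the Jukes–Cantor ceiling.
3. **Genomes** — a uniform-ACGT ancestral sequence; per branch, a
   Poisson(branch length × genome length) number of substitution events
   at uniform sites, each replacing the current base with a uniform
   choice of the three alternatives (events compound and may revert).
   Substitutions only — no indels — so leaf genomes stay aligned and the
   truth matrix is the exact per-site Hamming distance.
4. **Reads** — per individual and run, a read count drawn from
   Normal(coverage × genome length / read length, cv × mean), truncated
   at zero and rounded, emulating run-to-run yield variation (default
   coefficient of variation 0.3). Reads are uniform-position,
   uniform-strand substrings with i.i.d. substitution errors (default
   0.1% per base, a typical short-read scale) and constant quality
   strings, since counting ignores quality.

All randomness flows from one seed through three named `SeedSequence`
streams (genealogy, mutations, reads), so each stage is independently
reproducible and FASTQ output is byte-identical under a fixed seed.

**What the simulator does not emulate:** recombination (each population
has a single genealogy), indels and structural variation, GC- or
context-dependent error profiles, quality-score structure, duplicate
reads, and contamination. Passing benchmarks therefore demonstrate that
the estimator recovers relatedness orderings under idealized neutral
evolution and uniform noise — not that it is robust to every artifact of
real libraries. Conversely, none of these omissions favor the weighted
over the unweighted metric: both are scored on identical reads.

## Benchmark design and expected behaviour

`run_benchmark` scores mean Spearman ρ between estimated and true
pairwise distances over a (coverage, π) grid. Truth at run level tiles
the sample-level matrix across each individual's runs (zeros within an
individual). Default problem size is 12 individuals × 3 runs, 100 kbp
genomes, k = 20, 1,000,003 bins, 10 replicates — large enough that the
weighting signal is unambiguous and small enough that a full sweep runs
in minutes on one CPU.

Two behaviours are the headline checks: at low coverage (4x) the
entropy-weighted metric ranks distances significantly closer to truth
than the unweighted one (paired one-sided test over replicates), and at
high coverage the two metrics approach each other as sampling noise on
the common-k-mer baseline averages out. Note that the coverage at which
they meet grows as genomes shrink: with 100 kbp genomes the informative
fraction of each sketch is ten times smaller than with 1 Mbp genomes at
equal π, so the unweighted metric still trails by a few hundredths of ρ
at 32x at this scale, and replicate-to-replicate spread is substantial
(star-like genealogies produce many near-tied true distances whose
ordering no estimator can resolve from finite genomes).

## Numerical and interface choices

* Sketch files (KWS1) and weight files (KWV1) are little-endian binary
  with a magic/version header; saves are byte-deterministic (gzip mtime
  pinned to 0).
* Matrices are TSV (tab + names header, 10 significant digits) or
  square PHYLIP.
* The CLI is single-process; `--threads` is accepted for workflow
  compatibility and never affects results. At the sketch sizes this
  package targets (≤ 10^7 bins) the chunked BLAS accumulation is
  seconds per matrix, so reproducibility was priced above parallelism.
* Sample order in every output matrix equals the command-line argument
  order; sample names come from the sketch header unless
  `--name-from-filename` overrides them.
* `--sketch-size` requests that are not prime are rounded up to the next
  prime with a logged notice.
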