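# Methods

## 1. Library generation

A library is fully determined by `(seed, count, length_spec, alphabet)`.
One seeded `numpy.random.Generator` (PCG64) drives every draw in a run:
length draws (uniform integers on the inclusive range [j, k]) and residue
draws (`floor(r · |alphabet|)` over uniform `r ∈ [0, 1)`, vectorized per
sequence). Bit-compatibility with any other generator (e.g. a
Mersenne-Twister stream) is not promised — only statistical equivalence
and exact run-to-run reproducibility within this implementation.

Uniqueness is enforced by whole-sequence rejection: a colliding sequence
is discarded and redrawn. Expected cost stays O(m·n) while the requested
count is a vanishing fraction of the 4^n (or Σ 4^n) sequence space; a
requested count exceeding the space raises a feasibility error before any
generation, and a hard cap of 1000 × count attempts converts pathological
near-exhaustion into an explicit error instead of an endless loop.
Sequences are named `aptamer1 … aptamerM` in emission order. The alphabet
defaults to the order (A, U, G, C); order affects only enumeration order
and reproducibility bookkeeping, not statistics.

Default library shapes are the two benchmark datasets: 1100 × 22 nt
(fixed) and 20,000 × [16, 60] nt (randomized). The randomized range is
inclusive on both ends.

## 2. Composition statistics and the mean predictions

Per-base counts, overlapping-window dinucleotide counts (no wrap-around;
length-1 sequences give an all-zero record with a warning so imported
degenerate entries do not abort a batch) and k-mer counts up to k = 3.
Dataset summaries use ANOVA-style bookkeeping: Count, Sum, Average and
sample variance (denominator Count − 1). Frequencies are reported in
percent.

The closed-form mean predictions are E[count of x] = N/4 per sequence at
fixed length N, and M/4 with M = (j + k)/2 under uniform integer lengths.
`proposition_check` compares observed dataset means against these
predictions with a 3-standard-error pass flag, the standard error
estimated from the per-sequence count variance. With a fair generator the
fixed-22 prediction is 5.5 and the [16, 60] prediction 9.5.

## 3. Statistical battery

One-way ANOVA is computed from the classical sum-of-squares decomposition
(asserted additive to 1e-8 relative tolerance on every call) with p and
F-critical from scipy's F distribution; the result object carries the full
spreadsheet-style table, not just p. Shapiro–Wilk and Anderson–Darling
run through scipy; constant samples return a flagged "degenerate" verdict
instead of a numeric statistic (reference implementations disagree on this
edge, a flag is auditable). Samples above 5000 values are subsampled with
a fixed seed for Shapiro–Wilk only — the classical test was not calibrated
for such sizes — while Anderson–Darling always uses the full sample.
Two-sample Kolmogorov–Smirnov uses the asymptotic two-sided p-value.
p-values are written to CSV with four decimals ("0.0000" rather than 0).
No multiple-testing correction is applied across the battery.

## 4. Folding

### 4.1 Engine

`folding.zuker` implements the standard minimum-free-energy recursions:
`V(i,j)` (best structure closed by pair i·j: hairpin, stack/bulge/internal
loop to an inner pair, or multiloop), `M`/`M1` (multiloop segments), and
`F` (exterior loop). Interior loops are capped at 30 unpaired nucleotides;
hairpin loops must enclose ≥ 3 residues; legal pairs are AU/UA/GC/CG/GU/UG;
pseudoknots are out of model. Energies are integers in 0.01 kcal/mol.
Kernels are numba-compiled (O(n³) fill); the traceback re-derives each
decision in Python by exact integer equality against the filled tables.
Dangling ends follow the "d2" convention: every helix in the exterior loop
or inside a multiloop collects both a 5' and a 3' dangle from its flanking
nucleotides whenever those positions exist, and multiloop closing pairs
collect the mirrored terms on their inner side.

A structure is reported only if its energy is strictly negative; otherwise
the open chain with MFE exactly 0 is returned ("does not fold"). Backends
reporting small positive optima are clamped the same way.

### 4.2 Parameterization and its approximations

The tables in `folding.params` are a Turner-type 37 °C set. Transcribed
from the published nearest-neighbor literature: the 10 Watson–Crick stack
free energies, G·U wobble stacks, hairpin initiations (sizes 3–9), bulge
initiations (1–6), internal-loop initiations, the Jacobson–Stockmayer
ln-extrapolation (1.75·RT), the ±0.5 terminal AU/GU helix-end penalty, the
0.6 kcal/mol·nt asymmetry penalty capped at 3.0, and the affine multiloop
model (3.4 closing + 0.4 per branch, unpaired free).

Approximated, because the full published tables are not reproducible here:

* hairpin terminal mismatches collapse to closing-pair-class values
  (−1.2 for C·G/G·C, −0.6 otherwise) plus the published first-mismatch
  bonuses (G·A −0.9, U·U −0.9, G·G −0.8);
* internal-loop mismatches use unordered-identity bonuses (G·A −0.9,
  U·U −0.7), suppressed for 1×n loops; 1×1 loops use a base value of 0.8
  with a G·G bonus instead of the published 1×1 table; no 1×2/2×2 special
  tables;
* no special tetraloop/triloop bonus sequences;
* dangle tables carry representative published magnitudes, with G·U rows
  reusing A·U/U·A values.

Consequences, measured against the four reference folds whose RNAfold
structures and MFEs are printed in the source study: all four dot-bracket
structures are reproduced exactly; MFEs deviate by 0.1 %, 4.0 %, 1.7 % and
3.3 %. Engine output is therefore "Turner-style", suitable for population
statistics (non-folding fractions, length–MFE correlation) and structure
identification, but not bit-identical to RNAfold energies. Parameters were
frozen after this single evaluation; fitting the handful of class-level
constants to four reference values would have been overfitting. Every
output records the engine name and parameter-set descriptor, since third
decimals of MFE are parameter-set-specific.

### 4.3 Correctness oracle

`structure.enumerate_structures` yields every legal structure of a short
sequence; `structure_energy` scores an explicit structure by loop
decomposition (exterior + hairpin/interior/multiloop terms), sharing the
energy primitives but not the DP recursions. The test suite asserts that
the DP minimum equals the brute-force minimum over all structures for
seeded samples of sequences up to length 10, for both the Turner-style
engine and the simplified engine, and that every traced structure
re-scores exactly to its DP value.

### 4.4 Simplified backend

`"nussinov"` (alias `"builtin"`) scores −1 per stacked pair adjacency and
+3 per hairpin loop, everything else free. It is a pseudo-energy for
pipeline and invariant testing, not kcal/mol; a hairpin needs five
stacked pairs before the score turns negative. A `"viennarna"` wrapper
(alias `"vienna"`) delegates to the ViennaRNA Python bindings when they
are importable and otherwise raises an environment error naming
`"turner"` as the fallback.

### 4.5 Length threshold scan

For each length the scan folds either the full 4^n space (when it fits the
cap, default 65,536) or a seeded uniform sample (with-replacement draws
de-duplicated; the sampled total may fall slightly below the cap). The
`arrangements` column is always the exact power. The ζ indicator encodes
the threshold claim: ζ = 0 for n ≤ 7 (no sequence folds), 1 above.
Exhaustive folding of all 21,844 sequences of lengths 1–7 finds zero
negative-MFE sequences; the first folders appear at length 8.

## 5. Features and embedding

The registry holds 110 named features per sequence: 4 mononucleotide
percentages, 16 dinucleotide and 64 trinucleotide overlapping-window
frequencies, 16 raw adjacency counts, paired/unpaired counts, stem density
(paired/length), GC skew (G−C)/(G+C) and AU skew (defined 0 when the
denominator vanishes, so homopolymers stay embeddable), Wallace-rule
melting temperature 2(A+U)+4(G+C) °C (appropriate for short oligos),
Shannon entropy of base usage in bits (0 for homopolymers, 2 at uniform
usage), MFE, length, and the GC pair count within the predicted structure.
The registry is versioned and emitted with every matrix; the source study
quotes a larger total ("161") that its text does not decompose, so this
package defines its own explicit registry rather than chasing that count.

Columns are z-scored; zero-variance columns (e.g. `length` in a
fixed-length library) are dropped with a logged list. PCA is centered with
a deterministic sign convention (each component's largest-magnitude
loading is made positive). t-SNE uses perplexity 30 by default, PCA
initialization and auto learning rate, requires rows > 3 × perplexity, and
is deterministic for a fixed seed within one library version.

## 6. What the generated data does and does not establish

The generator *is* the object of study — a uniform null model of aptamer
sequence space — so there is no separate synthetic-data module: the
benchmark libraries are the stated 1100 × 22 nt and 20,000 × [16, 60] nt
draws. Green tests establish properties of this uniform model and of the
implementation (uniqueness, unbiasedness, closed-form means, folding
invariants). They say nothing about experimentally selected aptamers,
which show strong base biases, multimodal count distributions and far
lower MFEs; such sets can be imported via FASTA for side-by-side tables,
but no curated database ships with the package.

## 7. Numerical conventions

Integer centi-kcal energies throughout the DP (no float ties); traceback
by exact equality. MFE printed to two decimals in Vienna output.
Percentages on 0–100. Sample variance everywhere (ddof = 1) except
z-scoring (population, ddof = 0). Chi-square uniformity checks in the
test suite use p > 0.001 at n = 10,000. Seeds are plain integers; every
CLI run can emit its resolved configuration as JSON alongside results.

## 8. Known limitations

* MFEs are Turner-style approximations (§4.2), not RNAfold-identical;
  deterministic reference-fold checks carry a 2 % band and two of the four
  printed references currently sit just outside it (4.0 %, 3.3 %).
* No partition function, suboptimal structures, pseudoknots or 3D
  prediction; no DNA energy model (alphabet is configurable, energies are
  RNA).
* The length–MFE relationship is characterized empirically (correlation,
  threshold scan); no closed form for the composition/arrangement factor
  is attempted.
* Shapiro–Wilk above 5000 samples is a seeded-subsample approximation by
  design.
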