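# aptabench

Virtual RNA aptamer library generation and benchmarking.

Aptamer discovery by SELEX screens enormous random oligonucleotide pools in
vitro; curated aptamer sequence databases remain scarce. `aptabench` builds
the in-silico counterpart of such a pool — a seeded, uniqueness-filtered
library of uniformly random RNA sequences — and quantifies how such a
library behaves: base and adjacent-base composition, a statistical test
battery (one-way ANOVA, Shapiro–Wilk, Anderson–Darling, Kolmogorov–Smirnov),
minimum-free-energy secondary-structure characterization, exhaustive
short-length enumeration, and k-mer/structure feature extraction with
PCA/t-SNE embedding. It is aimed at computational chemists and
bioinformaticians who want a reproducible null model of aptamer sequence
space before committing to selection experiments or docking studies.

## The core method

Each residue is drawn independently and uniformly from the alphabet
X = {A, U, G, C}: a uniform variate r ∈ [0, 1) maps to the residue with
index ⌊r·|X|⌋. A library of m sequences is built either at fixed length n
or with lengths uniform on an inclusive integer range [j, k] (study
defaults: 1100 sequences at n = 22, and 20,000 sequences on [16, 60]);
duplicate sequences are rejected and redrawn, so all m sequences are
distinct. The sequence space at length n holds exactly 4^n sequences,
computed in arbitrary precision.

Under this model the expected per-base count is E[k_x] = P(x)·N with
P(x) = 1/4 for fixed length N, and P(x)·M with M = (j+k)/2 for randomized
lengths — predictions the `proposition_check` table tests against any
generated or imported library.

Folding uses a Zuker-style dynamic program over a Turner-type
nearest-neighbor model (hairpin/bulge/internal loop initiations, stacking
including G·U wobbles, affine multiloops, both-side dangles), authored
in-package because no external folding engine is assumed; see
`docs/methods.md` for the exact parameterization and its approximations.
MFE = 0 denotes the open chain ("does not fold"). No sequence of length
≤ 7 can attain MFE < 0 — the minimal stable motif needs two base pairs and
a three-residue hairpin loop — which the package verifies by exhaustively
folding all 21,844 sequences of lengths 1–7.

## Worked example

```bash
aptabench bench --scale 0.1 --seed 0 --out-dir bench_out
```

prints (backend `turner`, the in-package engine):

```
fixed22: n=110 zero-MFE 30.91% min -8.41 ANOVA p=0.6047
random16_60: n=2000 zero-MFE 9.75% min -23.44 ANOVA p=0.7375
random16_60: length-MFE Pearson r = -0.7306
```

Reading: at one tenth of the study scale, 30.9 % of the 110 fixed-length
(22 nt) sequences do not fold, versus 9.8 % of the 2000 randomized-length
(16–60 nt) sequences — shorter uniform sequences often lack a stabilizing
motif. The ANOVA p-values (≫ 0.05) confirm the generator introduces no
detectable bias among A/U/G/C mean counts, and length correlates strongly
and negatively with MFE (r ≈ −0.73): longer random sequences fold more
stably. `bench_out/` holds the FASTA libraries, Vienna dot-bracket
triplets, composition/ANOVA/scan CSV tables and PCA coordinates, each with
a provenance sidecar.

Individual steps are available as `generate`, `characterize`, `stats`,
`fold`, `scan` and `embed` subcommands (`aptabench --help`), or directly
from Python:

```python
from aptabench.generator import GeneratorConfig, LengthSpec, generate_library
from aptabench.folding import fold_library, mfe_summary

lib = generate_library(GeneratorConfig(seed=0, count=1100,
                                       length_spec=LengthSpec.fixed(22)))
print(mfe_summary(lib, "turner").zero_percent)
```

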