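# Methods

## The model and its assumptions

The pipeline estimates, per academic field, the proportion of pairwise
comparisons that the field's tools win across a corpus of benchmark
rankings, and tests it against the null value 0.5.

The win-counting rule: within a benchmark of *n* tools, a tool contributes
exactly *n − 1* comparisons; it wins each comparison against a tool with a
strictly larger rank number. A tied pair is counted as a comparison without
a win for either side — the most conservative tie rule, and the one under
which the worked "second of 11 → 9 wins, 10 comparisons" arithmetic is
exact. Curated rank corpora are usually tie-free, so this choice rarely
binds.

The bootstrap resamples **tools**, not benchmarks: replicates draw
`sample_size` tools uniformly with replacement; each draw independently
picks one benchmark uniformly among the benchmarks ranking that tool
(repeated draws of the same tool get fresh picks). This weights every tool
equally regardless of how many benchmarks cover it, at the cost of mixing
benchmark-choice noise into the replicate distribution (see *Calibration*
below). A draw's wins and comparisons are credited in full to **each**
field the tool carries — a dual-affiliation tool is evidence about both of
its fields, not half-evidence about each. Tools in fields below the
reporting threshold still participate as opponents and in sampling; they
are simply not reported.

Summaries per field: mean μ and standard deviation σ (sample sd, ddof = 1;
at 1000 replicates the ddof choice is immaterial) of the replicate
proportions, a percentile 95% CI (2.5th/97.5th percentiles of the replicate
distribution — chosen over normal-theory intervals because replicate
distributions of small fields are visibly skewed), and

    Z = (0.5 − μ) / σ.

Negative Z means the field wins more often than chance. The p-value is the
one-sided standard-normal upper tail at |Z|; a `two_sided` flag doubles it.
Because the tail is taken at the *absolute* Z, the one-sided default folds
both tails and its realized size is up to twice the nominal level; the FDR
step inherits this. FDR correction is Benjamini–Hochberg, applied within
one hierarchy level at a time (specific, general and expertise fields are
separate families — each level is a separate forest panel and a separate
set of hypotheses).

Degenerate cases: a field whose replicate proportions are all identical has
σ = 0; its Z is reported as ±∞ (sign of 0.5 − μ, 0 if exactly null) with
p = 0, and a warning is logged. Fields never drawn in any replicate are
dropped with a warning rather than imputed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `sample_size` | 200 tools | tools drawn with replacement per replicate |
| `n_replicates` | 1000 | bootstrap replicates |
| `min_field_size` | 10 tools | reporting threshold, counted once on the full corpus before any resampling |
| `null_value` | 0.5 | win proportion of an arbitrarily grouped set of tools |
| `two_sided` | off | p-value sidedness (the default matches the folded one-sided convention above) |

The field-size filter is monotone (adding tools never removes eligibility)
and deliberately applied pre-bootstrap: eligibility is a property of the
corpus, not of a replicate.

## The synthetic-corpus generator

`benchfield.simulate` generates corpora with known ground truth. Tool *t*
with field set *F(t)* has latent quality

    q_t = mean{δ_f : f ∈ F(t)} + e_t,   e_t ~ N(0, 1);

benchmark *b* ranks a uniform random subset (3–50 tools by default) by
`q_t + ε_bt` with `ε_bt ~ N(0, noise_sd)`, rank 1 best. Ties occur with
probability zero. Defaults mirror a realistic curated corpus: 498 tools,
128 benchmarks, 1–2 affiliations per tool (second affiliation with
probability 0.2, drawn from the renormalised field distribution), and
`noise_sd = 1` — equal parts persistent tool quality and per-benchmark
noise, i.e. a cross-benchmark score correlation of 0.5 for the same tools,
which matches the moderate rank consistency seen across real benchmarks.
Dual-affiliation tools average their fields' δ so expected quality stays
bounded. If the random benchmark subsets leave a tool uncovered, it is
placed into one random benchmark before ranking, preserving the corpus
contract that every tool is ranked somewhere.

What the generator does **not** emulate: metric heterogeneity beyond
per-benchmark noise (no metric-specific biases), non-independence between
benchmarks from the same publication, redundant near-identical tools
(parameter variants of one program), or any correlation between field and
benchmark coverage. Passing calibration and recovery tests on synthetic
corpora therefore demonstrates the estimator's mechanics, not the absence
of such structure in real data.

## Calibration

Two distinct noise sources separate a null field's estimate from 0.5:

1. **Bootstrap/Monte-Carlo error** of the mean over replicates — at 500
   replicates, about 0.002 and negligible.
2. **Grouping noise** — which tools happen to carry the field. With ~30
   tools per field (150 tools, 5 fields) the corpus-level win proportion of
   a randomly composed field has a standard deviation near 0.034, from
   persistent tool-quality differences (~0.035 at `noise_sd = 1`) plus the
   finite number of realized comparisons (~0.023, irreducible by the noise
   scale).

So at that scale a ±0.05 band around 0.5 is only a ~1.5σ statement per
field: measured over 60 independent null corpora, all five fields stay
inside it for about 45% of corpora. Averaging the five interchangeable null
fields' means (as `scripts/acceptance.py` does for its null-calibration
quantity) shrinks the spread to ~0.015 and is the stable estimator of the
null expectation. The Z-test itself is conservative: σ includes per-draw
benchmark-choice noise that averages out of μ, so the realized type-I
fraction at p < 0.05 measured across null ensembles was ~0.005, well below
the folded nominal 0.10.

## Problem sizes used in the shipped tests

Unit and property tests run on corpora of 2–100 tools with 60–500
replicates; the acceptance checks use the 150-tool/30-benchmark/5-field
null corpus with 500 replicates of 150 draws, and a 150-tool/3-field
recovery corpus (δ = +2/+1/0, `noise_sd = 1`) with 400 replicates — sizes
at which every statistical assertion above is resolvable in seconds.

## Design choices where the design was open

- **Benchmark pick per draw**: uniform over the benchmarks containing the
  tool; no weighting by benchmark size or metric.
- **CI**: percentile bootstrap, not normal-theory or BCa.
- **FDR family**: per hierarchy level.
- **Entry canonicalisation**: benchmark entries are stored sorted by
  (rank, tool id), making corpus equality and TSV round-trips exact and
  byte-stable (fixed column order, lexicographic row order).
- **Unknown affiliations fail loudly**: an unmapped department string
  raises (carrying the raw string) instead of being bucketed into an
  "Other" field, which would contaminate tallies silently. The taxonomy
  file is user-editable; "Medical Informatics" ships under the
  "Technologies" general field and is flagged inherently interdisciplinary,
  a seat users can change in one line.
- **Benchmark size bounds (3–50) warn, don't reject**: they describe
  typical curated corpora, not a structural requirement.

## Known limitations

- The bootstrap treats benchmarks as exchangeable evidence; correlated
  benchmarks (same publication, same test data) overstate the effective
  sample size.
- The shipped taxonomy covers the fields named in the analyses it was
  built for; applying the pipeline to a new corpus will usually require
  extending `taxonomy.tsv` (unmapped names are reported explicitly).
- Per-field inference at the default threshold of 10 tools is fragile:
  grouping noise alone moves a 10–30 tool field's win proportion by several
  points (see *Calibration*), which is precisely why corrected p-values,
  not point estimates, should be read.
- Rank-based wins discard margin information; alternative paired-comparison
  models (Bradley–Terry, Plackett–Luce) are deliberately out of scope.
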