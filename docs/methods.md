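# Methods

Exact definitions of every quantity the pipeline computes, the default
parameters and why they were chosen, and known limitations.

## Data model

A `SequenceRecord` is one specimen × marker sequence: IUPAC nucleotide
codes only (`ACGT` plus ambiguity codes `RYSWKMBDHVN`), no gap characters,
with optional per-base Phred quality values and coverage (contig depth),
both required to match the sequence length when present.  A
`BarcodeLibrary` is a collection of records keyed by (specimen, marker); a
**complete sample** is a specimen with a sequence at every marker under
study (`select_complete_samples`).  Discrimination and gap statistics are
computed on the complete sample so every species is scored on the same
marker panel, but the query reference is built from *all* records —
identification in practice runs against everything available, and
restricting the reference to complete samples would overstate success.

## Quality control

**Quality index** (`quality_index`, defaults `q=30`, `x=2`): the mean over
positions of `1[QV_i >= q] * min(coverage_i, x) / x`.  A position scores 1
only when its Phred quality is at least `q` and it is covered by at least
`x` reads; single-read positions with high quality score 1/2.  `q=30`
(0.001 error probability) and `x=2` (double-stranded confirmation) are the
conventional thresholds for barcode-grade sequence.

**Linguistic complexity** (`linguistic_complexity`, defaults `window=100`,
`step=1`, k from 3 to 6): for each window `w`, the product over k of
(number of distinct k-mers observed in `w`) / `min(4^k, |w| - k + 1)`, the
maximum possible count.  Sequences no longer than the window form a single
window; otherwise the windows slide by `step` and the reported value is
the arithmetic mean (`aggregate="min"` gives the most repetitive window
instead).  Repetitive, primer-slippage-prone sequence scores low.

**Homopolymers** (`find_homopolymers`, default `min_length=8`): maximal
single-nucleotide runs of at least 8 bases, reported as (base, length,
1-based start).  Runs of 8+ are where single-pass reads accumulate indel
errors.

## Distances and alignment

Pairwise global alignment (Biopython `PairwiseAligner`) with match +1,
mismatch −1, gap open −2, gap extension −0.5, and **free end gaps**
(terminal gaps cost nothing), so fragments of different lengths are not
penalized for incomplete overlap.  A gap of length L costs
`open + (L-1) * extend`.

The **uncorrected p-distance** of an aligned pair is (columns where both
sequences have unambiguous, different nucleotides) / (total aligned
columns); columns with a gap or an ambiguity code count in the denominator
only.  Multilocus distances pool counts across markers
(`sum(diffs) / sum(columns)`), weighting each marker by its aligned
length.  No substitution-model correction is applied: identification and
gap analysis depend on distance ranks at very small divergences, where
p-distance is monotone in any standard correction.

The `Aligner` class memoizes diff/column counts per sequence pair and
short-circuits identical strings, which makes repeated matrix and query
computations on deduplicated libraries cheap.

**Simple indel coding** (`simple_indel_coding`): from an MSA, every
distinct internal gap span becomes a binary character; a sequence whose
gap strictly contains another's span is scored inapplicable (`-`); leading
and trailing gaps are missing data, not events.

**Neighbour joining** (`nj_tree`, via scikit-bio) with input ids sorted
for determinism; requires at least three taxa.

## Species discrimination

A query sequence returns the set of species owning at least one reference
sequence at minimal p-distance, **ties included**.  Marker combinations
intersect the per-marker species sets.  A species is scored `+` for a
marker set when every query of every one of its complete samples returns
exactly that species and nothing else; otherwise the species it was
confused with are listed, ordered by how often they were returned (ties
alphabetical).  By default each query's own record stays in the reference
(its self-match guarantees a non-empty intersection and distance 0);
`leave_one_out=True` removes it, which is the stricter "new specimen"
protocol but is undefined for singleton species, whose nearest remaining
neighbour is necessarily heterospecific.

Because combining markers intersects species sets, adding a marker can
never turn a discriminated species into a failure (monotone synergy); the
test suite verifies this exhaustively on synthetic libraries.

**Least inclusive clade** (`least_inclusive_clade`): on a specimen tree, a
species with two or more samples is `+` when the smallest clade containing
all of its samples contains no other species' samples; singletons are not
applicable (`None`).

## Barcode gap

For each species: `max_intra` is the largest distance among its specimen
pairs (0 for singletons), `min_inter` the smallest distance from any of
its specimens to any heterospecific specimen.  The species has a gap when
`min_inter > max_intra` — strictly, so a tie is no gap, and a singleton
whose genotype also occurs in another species has `min_inter = 0` and no
gap.  Frequencies are reported per marker and multilocus with Wilson
intervals.  Adding specimens can only raise `max_intra` and lower
`min_inter`, so gaps can be lost but never gained as sampling deepens (the
suite checks this by incremental insertion).

**Concordance** with discrimination: species are cross-classified by
(gap, discriminated) and the discordant cells compared with McNemar's
test, exact binomial by default.

## Statistics

- **Wilson score interval** for binomial proportions (via statsmodels);
  preferred over the Wald interval at the small counts and extreme
  proportions typical here.
- **Scheffé simultaneous contrasts**: all pairwise contrasts judged
  against the Scheffé criterion, valid at the family level for any number
  of post-hoc comparisons.  Gaussian groups use the pooled within-group
  mean square and the criterion `(g-1) F_{1-alpha}(g-1, N-g)`; binomial
  `(k, n)` groups use the large-sample form with variance `p(1-p)/n`
  against chi-square with `g-1` degrees of freedom.  Zero-variance
  contrasts are flagged degenerate rather than silently given p-values.
- **Spearman** rank and **point-biserial** correlations (SciPy), with
  errors instead of NaNs on constant or single-class inputs.
- **McNemar's test** on discordant counts (b, c): exact mode doubles the
  smaller binomial(b+c, 1/2) tail and caps at 1 (p = 1 when b + c = 0);
  `chi2` mode uses `(b-c)^2/(b+c)` against chi-square(1) and is undefined
  without discordant pairs.

## Synthetic libraries

`generate_library(SyntheticConfig)` emulates the sampling design of a
multi-genus barcode library: a few genera, up to a few individuals per
species, several unlinked markers a few hundred bases long, small
interspecific divergence (default 0.02 substitutions/site), near-zero
intraspecific divergence (default 0.002), and the two empirically
important failure modes — multilocus genotypes shared across species
boundaries (`shared_genotype_pairs`; pairs chain, so A~B plus B~C puts all
three species on one genotype) and absence of variation.  Substitutions
hit uniformly chosen sites with a uniform replacement base (Jukes–Cantor
style); nothing finer is needed because downstream distances are
uncorrected.  Homopolymer insertions are applied at the same position to
every sequence of a marker, keeping sequences equal length.

Consequently the ground truth is exact, not simulated: identification
truth is string-equality set logic (`expected_discrimination`), and gap
truth is Hamming counting (`expected_gap`).  Quality values and coverage
are injected separately (`inject_quality`) from a profile (fraction of
positions at QV ≥ 30, coverage distribution), giving a binomial oracle
for the quality index.

The generator does **not** emulate alignment-relevant indel variation
between species, ambiguity codes, contamination, or mislabelled
specimens; configurations whose interspecific divergence rounds to zero
substitutions on some marker are rejected as infeasible rather than
silently producing identical species.

## Numerical and convention notes

- All randomness flows from explicit integer seeds through NumPy
  `default_rng`; derived seeds stay below 2^31.
- Equal-length, low-divergence sequence pairs are normally aligned without
  gaps, but the aligner can return an equally scoring gapped alignment,
  which inflates the column count slightly; distances may therefore differ
  from exact Hamming values by a few parts per thousand without affecting
  distance ranks or gap flags in practice.
- Percentages are kept at full precision; rounding to one decimal is a
  display concern.
- The packaged results table is scored with the same conventions
  (`+`/`-` indicators, 0/1 gap flags, semicolon-separated conflated
  species, `conflated_truncated` marking lists the source shortened).
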