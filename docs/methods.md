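# Methods

## Over-representation model

A microbe set is a named group of normalized microbe names annotated either
with a disease (microbes reported significantly increased or decreased in
that disease) or with a body position (microbes colonizing it). Sets may
overlap. The background universe defaults to the union of all set members;
a user-supplied background is first intersected with that universe, since
microbes unknown to the database can never match a set and would only
dilute the test.

For background size N, set size n (after intersection with the background),
query size M (after normalization, de-duplication and intersection with the
background) and overlap m, the p-value is the inclusive hypergeometric
upper tail P(X ≥ m), evaluated through the exact survival function in
log-space — no normal approximation is used anywhere, and the test suite
checks agreement with an exact rational binomial-coefficient enumeration to
relative error 10⁻¹⁰ over every valid configuration with N ≤ 12. The
inclusive tail (summation starting at the observed m) is the standard
over-representation convention; depletion is out of scope.

Query names absent from the background are dropped with a warning and
excluded from M rather than silently counted: counting them would deflate
every percent and fold, and erroring out would make mixed-provenance query
lists unusable.

Two quantities in the report have conventional rather than prescribed
definitions, and this package adopts the usual ones:

* **percent** = m/M, the fraction of the query matching the set;
* **fold of over-representation** = (m/M)/(n/N), observed over expected
  overlap. It is 0 when m = 0 and exactly 1 when the query equals the
  background.

Bonferroni (min(1, p·k)) and Benjamini–Hochberg step-up FDR are applied
with k equal to the number of sets actually tested — i.e. those with at
least `min_size` (default 2) members inside the background, after any
category restriction. Correcting over sets that were never tested would be
needlessly conservative. Both corrections are implemented directly (they
are a few lines of array arithmetic); BH is cross-checked against
statsmodels in the test suite. Results are sorted by p ascending with ties
broken by set name, so output is byte-stable.

Singleton sets are excluded by default because a one-member set cannot
distinguish enrichment from the mere presence of one name, and the default
follows the curated tool's behaviour.

## Disease similarity

Signed association records (disease i, microbe j, direction ±1) are kept as
a multiset: the record count W_ij for a pair is its evidence weight — the
number of independent curated reports. The weight vector entry for disease
i and microbe j is

    w_ij = s_ij · log(N / n_j)

where s_ij is the *signed record sum* (equal to E_ij·W_ij when all records
for the pair agree in direction), N the number of distinct diseases in the
table, and n_j the number of diseases with at least one record for microbe
j regardless of direction. The log term is the inverse-document-frequency
idea transplanted from text retrieval: a microbe perturbed in every disease
carries no discriminative information and gets weight exactly zero.

Two deliberate choices where the formulation is open:

* **Mixed directions net out.** A microbe reported both increased and
  decreased in the same disease contributes the signed sum of its records,
  so perfectly contradictory evidence cancels to zero rather than being
  rejected. This reduces to the plain E·W product whenever the literature
  agrees, which is the described case.
* **Natural logarithm.** The base is provably immaterial: changing it
  rescales all weights by one positive constant that cancels in the
  cosine. The test suite asserts ln/log₂ agreement to 10⁻¹².

Similarity is the cosine of two disease vectors, reported signed in
[−1, 1]; negative values are meaningful (two diseases moving the same
microbes in opposite directions) and are not clamped to zero. A disease
whose vector has zero norm — every associated microbe ubiquitous, or all
signs cancelled — has similarity 0 to everything, with a warning, rather
than NaN. The matrix is symmetrized against floating-point rounding and its
diagonal is 1 for every nonzero vector.

## Synthetic data generator

The curated database behind the original application (47 sets built from
483 signed records over 39 diseases and 292 microbes) is not
redistributable, so the generator emulates its shape in miniature. All
generators are pure functions of a `FixtureSpec`; identical specs produce
byte-identical files.

Defaults, chosen to mirror the curated database at test scale:

| parameter | default | rationale |
|---|---|---|
| `n_sets` | 40 | close to the curated 47, small enough for seconds-fast suites |
| `size_bins` | 77% of sets sized 1–5, 11% 6–10, 2% 11–15, 4% 16–20, 6% 21–40 | the curated size distribution is dominated by tiny sets with a few large position sets |
| `position_set_fraction` | 0.2 | ≈10 of 47 curated sets are body-position sets |
| `n_diseases`, `n_microbes` | 10, 60 | miniature of 39 × 292 |
| `records_per_disease` | 3–12 distinct microbes | 483 records / 39 diseases ≈ 12, minus repeats |
| `pair_repeat_rate` | 0.2 | some pairs curated from several studies (W_ij > 1) |
| planted query overlap | 0.8 of the target set + 5 noise names | strong but not total signal |
| planted pair `shared_fraction` | 0.8 over an 8-microbe profile | same signal strength as the enrichment benchmark |

Microbe names are synthetic latinate binomials from a fixed token pool; no
real taxonomy is implied. The packaged diet-study query list is real,
transcribed from the published table (29 species-rank plus 22 genus-rank
names, 51 distinct after normalization).

What the generator does **not** emulate: taxonomic structure (no
genus/species nesting, so name matching cannot be confounded by rank),
correlated set membership (real disease sets share gut commensals far more
than uniform sampling does), and literature biases (well-studied diseases
accumulate more records). Passing the planted-recovery benchmarks therefore
shows the pipeline detects a strong known signal under clean conditions; it
does not certify performance on real curated data, and published P/FDR
values for the original case study cannot be reproduced without the
original database.

## Benchmarks and problem sizes

The acceptance benchmarks run 100 seeded replicates each: planted
enrichment (40-set database, 80% of the largest set planted into the
query) must put the planted set at rank 1 by FDR in ≥95% of replicates;
planted similarity (concordant pair, defaults above) must make the pair the
off-diagonal maximum in ≥95%. Both finish in seconds at these sizes, and
the exact-oracle sweep over all hypergeometric configurations with N ≤ 12
covers a few thousand cases.

## Numerical and I/O details

* Name normalization is purely lexical (lowercase, underscores to spaces,
  whitespace collapsed); no synonym or taxonomy resolution is attempted, so
  name variants across sources count as different microbes.
* The set-database file is GMT-like with the category occupying standard
  GMT's description column, letting disease and position sets share one
  file; members are written sorted, and read∘write is the identity.
* Duplicate association rows are preserved on read (they encode W_ij);
  duplicate members within one set line are collapsed.
* p-values are validated to [0, 1] before correction; inconsistent
  hypergeometric counts (m > min(n, M), n > N, M > N) raise instead of
  returning nonsense.
* CLI outputs are written to a temporary file and renamed, so a failing
  run never leaves a partial TSV; p/Bonferroni/FDR are printed with six
  significant digits, percent and fold with four decimals.

## Known limitations

* Lexical name matching under-counts overlap whenever the query and the
  database spell a taxon differently.
* The hypergeometric null assumes the background is the correct sampling
  frame; with the default universe (union of set members) the test is
  conditional on the database's coverage.
* Similarity is undefined (reported 0) for degenerate zero-norm diseases.
* Only over-representation is tested; depletion would need the lower tail.
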