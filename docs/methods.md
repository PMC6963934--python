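# Methods

This note documents the models and numerical choices behind `senslex`, what
the synthetic generators do and do not emulate, and the package's known
limitations.

## Lexicon mining

Documents are tokenized by Unicode word boundaries after NFKC
normalization and lowercasing; tokens containing digits, punctuation and
stopwords are removed. The stopword list is a fixed English list shipped
with the package (`data/stopwords_en.txt`) so results never depend on an
external toolkit's version. Hyphenated tuples ("green-apple") survive as
single tokens by default, and an explicit bigram list can merge adjacent
token pairs; there is no automatic collocation detection. Suffix
lemmatization exists behind `lemmatize=True` but is off by default —
rule-based stemming can destroy sensory descriptors (flowery → flow), and
the expert fusion map is the better tool for collapsing inflected forms.

The sparsity filter keeps a term present in at least
`ceil(min_doc_fraction × n_docs)` documents (default fraction 0.10):
"at least 10% of documents" must round up to remain a whole document
count. Term correlations are Pearson coefficients on raw per-document
count vectors (not binary presence); zero-variance terms are excluded and
flagged rather than yielding silent NaNs. Automatic fusion builds a graph
with an edge for every pair strictly above the threshold (default 0.50)
and proposes each connected component as one entry, represented by its
highest-frequency member (lexicographic tie-break). The proposal is a
starting point: expert-curated `FusionMap`s override it, which is also the
only mechanism for dropping non-descriptive or affective terms — no
automatic semantic filter is attempted. Column fusion conserves total
token mass; the pipeline is deterministic byte-for-byte at fixed inputs.

## Sensory wheel

The wheel is a validated hierarchy with globally unique descriptors. The
selectable set is the outer ring plus any subcategory flagged selectable,
ordered by category then ring position. The bundled apple-juice wheel is a
**synthetic fixture**: the published wheel figure it emulates is not
machine-readable, so the file collects every descriptor named in the
source study's text and normalization table and pads with generic
apple-lexicon terms to exactly 42 outer descriptors + 4 selectable
odor/aroma subcategories = 46. Whether the published d = 46 counts the
four subcategories inside or on top of the ring is not decidable from the
text; this fixture fixes 42 + 4 and all downstream numbers follow from
d = 46, which reproduces the published checkpoints.

## MFA of projective mapping

Each assessor's (x, y) columns form one active group. Columns are
centered but not standardized — the sheet coordinates share a unit, and a
factor method still requires centering even when no scaling is applied.
Group g is weighted by 1/σ₁(g)², the inverse squared first singular value
of its centered block, so every assessor contributes at most unit inertia
to the first axis; a degenerate block (all products at one point) raises
an error naming the assessor. The weighted concatenation additionally
carries a 1/√G factor (G = number of groups), which makes the solution
invariant under duplicating the entire panel — group weights renormalize
instead of inflating the inertia — without changing explained-variance
ratios or any identity below. The global solution is the SVD of this
matrix; axis signs are fixed by making the largest-magnitude score on each
axis positive. Eigenvalues are squared singular values; ranks below
`σ₁ × 1e-12` are truncated.

Partial coordinates are `G × (weighted group block projected on the
axes)`; their mean over assessors equals the global coordinate exactly
(asserted in tests). With identical groups the concatenated matrix has
rank ≤ 2, so the first plane carries 100% of inertia.

Supplementary descriptors are projected as Pearson correlations between
their per-product citation frequencies and the global axis scores, which
sidesteps the scale mismatch between centimetre coordinates and small
counts; zero-variance columns are excluded with a warning. This treats the
frequency table as individual supplementary columns rather than as an
MFA-weighted contingency group — the method operates on continuous
coordinate groups throughout, not on the strict contingency-table variant.

Confidence ellipses use the partial bootstrap: each of `n_boot` (default
500) replicates resamples assessors with replacement and averages their
partial coordinates per product; the ellipse is the bivariate-normal
contour of the replicate cloud at the χ²(2 df) quantile of the coverage
level (default 0.95). Resampling partial coordinates in the fixed global
space deliberately excludes between-assessor variability: the regions
compare products. Covariances are symmetrized and eigenvalue-clipped at
zero; a degenerate cloud yields a zero-area ellipse, and the membership
test adds 1e-15 to the diagonal to stay defined there. All resampling is
driven by an explicit seed.

## Descriptor validation

The chance model: an assessor picks a uniformly random non-empty subset of
at most n_max attributes from the d selectable ones. TC counts all such
subsets, C those containing one fixed attribute (`Σ C(d−1, k−1)`), and
P = C/TC, held as an exact `Fraction`. The alternative numerator
`Σ C(d−1, k)` — the form the source literature prints — counts subsets of
the *other* d − 1 attributes and gives P ≈ 0.89 at d = 46, inconsistent
with every published checkpoint; it remains available behind
`verbatim_eq8=True` strictly for audit. E = P·J rounds half-up (the
convention "rounded" leaves open; half-up is the everyday reading).

Each (product, descriptor) cell gets the exact upper tail
Pr(X ≥ obs), X ~ Binomial(J, P), computed by rational summation of the pmf
(floats only at the end) — no normal approximation, which matters at
E ≈ 1.6. Significance is strict p < α with α = 0.05 and no
multiple-testing correction by default, matching the practice the package
reproduces; Holm or Bonferroni can be applied downstream on the p-value
table. The significance count c* is the smallest c with Pr(X ≥ c) < α;
since Pr(X ≥ 0) = 1, c* = 0 is unattainable and the floor is 1. Heatmap
bins follow the grayscale gradation darkest < 10⁻⁶ … lightest < 10⁻².

An open modeling question: if the number of picks K were treated as
random (uniform on 1..5), the marginal citation probability would be
E[K]/d ≈ 6.5% rather than 10.6%. The subset-combinatorics P is the
definition used throughout because it is what the published checkpoints
fix; the synthetic generator, which *does* draw K randomly, therefore
produces null citation rates slightly below P — making the type-I
calibration conservative (observed false-flag rate ≈ 0.2% against an
analytic ceiling of ≈ 1.6%).

## Quality indices

BrimA = TSS − k·TA with k = 10 for apples; negative values are allowed.
The ratio classification is strict: sweet iff TSS/TA > 20; exactly 20 is
classed sour (the "over 20" rule leaves the boundary unassigned; assigning
it to sour keeps "sweet" a strict claim). TA = 0 is an error rather than
an infinite ratio. Hue uses the two-argument arctangent mapped to
[0, 360) because the one-argument form is quadrant-ambiguous for a* < 0;
the achromatic point a* = b* = 0 raises. Ranks are descending competition
ranks (ties share the smaller rank). No ANOVA or measurement-error
modeling is included — inputs are taken as the per-sample values to index.

## Synthetic generators

`gen_corpus` draws per-term document presence from stated rates with
counts 1 + Poisson; planted pairs copy counts exactly, so their dtm
columns correlate at 1.0 and any threshold fusion must link them. It does
not emulate real prose: no syntax, no stopword load, no Zipfian tail, so
lexicon tests show pipeline correctness, not retrieval quality on real
articles.

`gen_mapping` passes a true 2-D configuration (default: an ellipse well
inside the sheet) through a per-assessor similarity transform — rotation
optional, scale uniform in [0.8, 1.2], reflection optional and off by
default — plus iid Gaussian noise (default sd 2 cm), then clips to the
physical 60 × 40 cm sheet, warning on every clipped placement. Clipping
mirrors the tabletop constraint but distorts geometry near edges;
exactness tests use compact configurations. Perceptual structure beyond
geometry (attribute-driven placement, fatigue, serving order) is not
modeled.

`gen_citations` draws K per record from a distribution on {1..5} (uniform
by default — the protocol fixes only the range) and then K distinct
attributes without replacement, weighted by the product's propensity row.
The documented planted-effect condition for the power analyses is a 10×
weight on one (product, descriptor) cell at J = 15, d = 46, which yields
recovery power ≈ 0.85; at 5× the effect is too small for 15 assessors
(power ≈ 0.3), a genuine sensitivity limit of the exact test at this
panel size, not an implementation artifact.

Default scenario sizes follow the study design throughout: 6 products, 15
assessors, 46 attributes, 2 cm placement noise.

## Verification problem sizes

The test suite and the acceptance script verify: subset-combinatorics
against exhaustive enumeration for every d ≤ 12; MFA scores against a
direct SVD oracle on random panels; binomial tails against definitional
pmf summation and an independent scipy route; ellipse coverage on 200
simulated panels × 300 bootstrap replicates (observed ≈ 93% at nominal
95%, the similarity-Procrustes alignment of the truth being itself
estimated); null false-flag rate on 200 panels; planted recovery power on
200 panels; configuration recovery (Procrustes correlation > 0.9) on 20
panels. These sizes keep Monte-Carlo error a few times smaller than the
asserted margins.

## Known limitations

- The published explained-variance figures (84.12% total, 70.09% on the
  first dimension) and product-specific descriptor calls depend on the
  original raw panel data, which are not published; they are not
  reproduction targets. The package reproduces the method and its
  checkpoints, and validates behavior on synthetic truth.
- Expert judgment (term filtering, wheel membership) is represented only
  as explicit override structures; nothing semantic is automated.
- The colorimeter's reflectance-mode confound between lightness and
  cloudiness is an instrument limitation; no correction is attempted.
- Rendering (wheel graphics, maps, heatmaps) is out of scope; every
  analysis emits plot-ready tables instead.
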