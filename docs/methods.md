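# Methods

## Free-list standardization

Respondents name depicted objects freely, so the first analysis step maps
raw terms onto a closed roster of canonical objects. The mapping is
explicit data (a lexicon file), not code: every raw term maps to exactly
one canonical, every canonical to exactly one macro-category (`plant`,
`animal`, `human_nonliving`), and plant canonicals carry a
`general`/`specific` flag separating growth-form and habitat words
("tree", "field") from taxa ("sunflower", "spruce"). Terms too vague to
assign to one depicted species land on collective canonicals ("bird",
"beetle"); terms absent from the lexicon become their own canonical with
macro-category `unknown` and are flagged, so the lexicon can be curated
iteratively. Normalization before lookup is case folding, accent
stripping and whitespace collapsing only — no fuzzy matching, so results
are deterministic. Ranks are 1-based throughout.

Duplicate canonicals within one list (e.g., "tree … fir … tree") are not
meaningful for a salience index based on first recall; the default policy
keeps the earliest mention and closes the rank gap, which preserves the
order of everything else and lets the earliest rank dominate. A strict
policy that raises instead is available for data-entry auditing.

The shipped lexicon and identification key are best-effort
reconstructions for the 71-object scene (their filenames carry a
`_synthetic` suffix); any real deployment should substitute its own
curated files in the same format.

## Salience

Smith's salience and the personal (per-respondent, per-category) variant
are implemented exactly as defined in the package docstrings:
`S = (1/N) Σ (L − R_j + 1)/L` per object, and
`S_p(c) = [Σ_{j∈c} (L − R_j + 1)/L]/L` per respondent. One reading issue
is worth recording: the printed form of the adapted formula carries a
`/N` inside the per-respondent quantity, yet group-level values in the
0.2–0.3 range with hundreds of respondents are only possible if the 1/N
step happens once, at group averaging. The implementation therefore
treats `S_p` as the per-respondent statistic and divides by N only when
averaging; a `literal_formula` flag reproduces the double-normalized
variant for audit. Reported dispersions use the sample (n−1) standard
deviation.

Two exact identities are asserted in tests at 1e−12: the salience-table
total equals the mean over lists of (L+1)/2, and `Σ_c S_p(c) =
(L+1)/(2L)` on fully categorized lists (items with `unknown`
macro-category count toward L but toward no category, so the identity
degrades to ≤). Objects never mentioned get S = 0 only when a reference
roster is supplied — without a domain roster, "not mentioned" is not
well-defined. Top-k selection breaks salience ties by mention count, then
lexicographically, so it is deterministic.

## Identification scoring

The 0–3 rubric (correct species / wrong species but correct higher group
/ higher group only / blank-unrecognized) is driven entirely by the
answer key: each taxon lists its accepted strings per level, and the
scorer does case/whitespace-insensitive set membership in level order.
The three per-taxon answer sets must be pairwise disjoint, which makes
scoring unambiguous and the generator round-trip exact. Kingdom-level
averages default to the unweighted mean of per-taxon means (matching a
per-taxon results table); a cell-mean variant exists and coincides on
balanced data. A separate proportion-correct summary (no partial credit)
covers expert-validation style reporting.

## Object areas

Each object mask is an RGB PNG of the scene's exact dimensions with the
object isolated on exact black. A pixel is foreground iff any channel is
strictly positive; no tolerance is applied because lossless PNG makes
exact zero well-defined. Masks are processed in a fixed order against a
shared claim bitmap: per-object raw counts are order-invariant, while
`overlap_pixels` records how many of an object's pixels were already
claimed by earlier masks, so both the raw and deduplicated conventions
are recoverable downstream. Alpha-channel or wrong-size images are
rejected rather than silently converted, since silent conversion risks
count drift. Percentages use the raw count over width × height; totals
use claimed pixels so they can never exceed the image.

## Fixation statistics

Fixation records are respondent × AOI rows with time to first fixation
(TTFF; missing when never fixated), total fixation duration and fixation
count; average fixation time is the derived ratio. Missing TTFF is
excluded pairwise, never imputed — a never-fixated object still
contributes its zero count to the count mean. Category-level means
average over a category's objects rather than raw rows, so a category is
not dominated by its most fixated object.

For the omnibus category comparisons both a parametric path (one-way
ANOVA, Welch pairwise post-hocs) and a rank path (Kruskal–Wallis, Dunn's
pairwise z tests with tie correction) are implemented, both with
Bonferroni adjustment `min(1, m·p)`. The two paths exist because the two
named procedures come from different families: Dunn's test pairs
naturally with Kruskal–Wallis, not with ANOVA. The recommended default is
the rank path for bounded, skewed personal-salience scores and plain
ANOVA for the roughly continuous eye metrics. Dunn's test is implemented
in-package (mean-rank z statistic with the standard tie-correction term);
with two groups it reduces to the normal-approximation rank test, which a
unit test checks against `scipy`'s Mann–Whitney implementation.

Salience regression is OLS with intercept on the four eye metrics plus
object size, with listwise deletion and automatic dropping of constant
predictors; salience–identification association is Spearman's rho with
mid-ranked ties. The general- vs. specific-plant-term comparison is a
paired t-test by default, because the same respondents contribute both
class weights; an unpaired Welch option exists.

## Synthetic data generator

The generator exists so every stage can be exercised, and parameter
recovery demonstrated, without any field data. Its design mirrors the
study conditions it stands in for:

* **Recall.** Each group g has category attention weights `w_g(c) ≥ 0`
  summing to 1; each roster object a positive prominence `p_o`,
  normalized within its category (so the rank-1 category probabilities
  equal `w_g` exactly). A list of length L — truncated Poisson,
  `1 ≤ L ≤` roster size — is drawn by successive sampling without
  replacement with weight `w_g(cat(o))·p_o` (Plackett–Luce). This is the
  simplest generative story under which both mention frequency and early
  position increase with prominence, making Smith's salience a consistent
  estimator of within-category prominence order — verified by a recovery
  test (Spearman ρ ≥ 0.9 at 500 lists). Raw strings are emitted through
  the lexicon's synonym sets, so standardization is genuinely exercised
  and exactly invertible.
* **Group defaults.** The default scenario has five groups with the
  sample sizes of the emulated designs (427 urban middle-school students,
  388 Naturparkschule students, 66 botanical experts, a 218-respondent
  piloting sample, an 80-respondent eye-tracking sample). Attention
  weights were set once from the first-order relation
  `mean S_p(c) ≈ w_g(c)·(λ+1)/(2λ)` against the emulated group-level
  category saliences, with mean list length λ = 8 for students and 12
  for experts. Expert lists are additionally tilted toward specific plant
  taxa by a ×2 within-plant prominence boost, which reproduces the
  qualitative specificity pattern: students' general-term salience
  exceeds their specific-term salience (large paired t), experts are
  balanced, and the groups differ on specific-term salience but not
  general-term salience.
* **Identification.** Per-taxon rubric levels are drawn from a
  Binomial(3, m/3) family, a one-parameter distribution over {0,…,3}
  whose expectation is exactly the target mean m; targets for the 20
  species are the emulated per-taxon means. Emitted answer strings come
  from the key, so rescoring recovers the drawn levels exactly.
* **Fixations.** Per respondent, a Poisson total number of fixations
  (30 s exposure × 3 fixations/s) is allocated multinomially over objects
  proportional to the same attention weights; individual fixation
  durations are lognormal (mean 0.25 s, σ = 0.6) scaled per category
  (animals ×1.6, emulating the longer fixations small animals require);
  TTFF is the minimum of the object's uniform arrival times over the
  exposure window, missing when never fixated; total viewing time is
  capped at the exposure by proportional rescaling (with a 1e−12
  under-scale so the cap is strict in floating point).
* **Masks.** Filled rectangles and ellipses on black with exact
  ground-truth counts (analytic for rectangles, rasterized for ellipses).

What the generator does **not** emulate: memory dynamics (no primacy
decay beyond the Plackett–Luce mechanism), inter-item semantic clustering
in recall order, respondent-level heterogeneity in attention weights
beyond group membership, correlated identification errors across taxa,
gaze trajectories or saccade dynamics, and visual realism of the scene.
Passing tests therefore show the *analysis* is correct under a plausible
data-generating process, not that the process captures everything real
respondents do.

## Numerical choices and degenerate inputs

All conservation identities are asserted at 1e−12 (float accumulation
over short lists is well within that). Probability vectors must sum to 1
within 1e−9. Empty samples, empty groups, lists with blank terms,
constant vectors in a correlation, and categories with fewer than two
values all raise immediately rather than propagating NaNs; a paired
t-test on identical vectors returns t = 0, p = 1 (where the naive
formula is 0/0). Randomness flows from one integer seed through separate
`numpy` Generator streams per stage, so adding a stage never perturbs
another's draws; a fixed seed gives byte-identical CSV output, which the
CLI test verifies.

## Problem sizes

The default scenario generates 1,179 free lists, 1,600 identification
responses and 5,680 fixation rows; the full test suite plus the
acceptance script run in well under a minute. Monte-Carlo tests use 200
respondents per group for the known-groups recovery check and 500 lists
for prominence-rank recovery — sizes at which the tested effects are
decisively powered.

## Known limitations

* The lexicon/key reconstructions are illustrative; conclusions about any
  real dataset require the study's own standardization dictionary.
* The "salience count" sometimes used for eye-tracked objects is treated
  as identical to Smith's S; no alternative salience indices (Sutrop,
  cognitive salience index B) are provided.
* Expert-validation proportions are simple percent-correct; whether
  partial credit should apply there is a key-design question, not a
  scoring-code question.
* The regression treats objects as independent observations; spatial
  autocorrelation between neighbouring AOIs is not modelled.
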