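# Methods

## The problem

Microbial culture media are published as semi-structured recipes whose final
compound concentrations require unit conversion, volume resolution and
recursive unpacking of submedium cross-references ("trace element solution",
"vitamin mix") before they can be compared or mined. Growth records are
positive-only: a collection lists which organisms grow on which media, never
which fail. `mediarec` implements (i) a compiler from a tagged recipe dialect
to standardized compositions and (ii) predictors that propose new
organism–media pairings from the positive-only relation: transitive-pattern
mining with a binomial evaluation, phylogeny-weighted collaborative
filtering with salt/oxygen filters, and media-richness preference
prediction.

## Recipe compilation

**Units.** All raw units map to five standard kinds: g/l, l/l, mol/l, and
the `trace` / `gas_substrate` flags (which carry no numeric concentration).
The shipped unit map covers ~30 common spellings (mg, µl, mM, %, mg/l, ...);
mass/volume percent is 10 g/l per percent. The map is user-extensible; an
unknown unit is an error, never a silent drop.

**Volumes.** A recipe either `fill`s (declared volume ignored, composition
read per litre) or `scale`s (composition multiplied by 1 l / declared
volume). The general rule — fill when no volume is declared or the declared
volume is 1 l ± 1%, scale otherwise — is a reconstruction from prose
conventions in the source catalogues, and a per-medium override table is
authoritative, mirroring curated practice. This reconstruction is the one
deliberately under-specified part of the compiler.

**References.** Submedium references multiply nested volume factors through
(100 ml of a submedium at 5 g/l contributes 0.5 g/l). The 1 g = 1 ml density
convention applies only to volumes of *individual compounds*, never to
volumes of submedia. Identical components met at several nesting levels are
summed after conversion. Reference cycles are an error listing the cycle.

**Moles.** Defined compounds convert grams to moles via a molecular weight
that includes hydrate waters; each constituent ion/molecule contributes
`moles x molar ratio` (e.g. CaCl2·2H2O at 10 mg gives 6.80e-5 mol/l Ca2+ and
1.36e-4 mol/l Cl-). Full dissociation is assumed; no chemical speciation.
Complex components (peptone, extracts) stay in g/l under a category tag.
Mass is conserved to 1e-9 relative, and compilation is deterministic and
invariant to ingredient line order.

## Similarity

Phylogenetic distance between two organisms is the leaf count beneath their
lowest common ancestor divided by total leaves — a value in (0, 1], equal to
1/total for an organism with itself. Ecological similarity is the Jaccard
index of shared environments (undefined, not zero, when both sets are
empty). Media similarity compares post-compilation constituent IDs, so
spelling variants of one compound always match and complex components match
by category. Partial organism matching supports union and best-match modes;
matching by raw component count is restricted to media with ≥ 15 components
and thresholds ≤ 15, below which counts are not comparable across media.

The binned association analysis bins all usable organism pairs by distance
(equal-width by default; the source analysis does not state its binning),
computes the fraction sharing a medium per bin, and reports Spearman rho of
bin *similarity* (1 − distance) against that fraction, so positive rho means
closer organisms share media more often. Pairs where either organism has no
media are excluded and counted. A constant sharing fraction is reported as
degenerate (rho = NaN) rather than a number.

## Transitivity

A pattern is AB|m1, BC|m2, C|m3 with distinct organisms and distinct media;
it implies the pairing (A, m3). Media with fewer than 3 or more than 100
organisms are excluded before mining. Patterns are sampled **exactly
uniformly** over all valid tuples: the sampler enumerates (B, m1, m2)
bridges with exact completion counts and samples proportionally, falling
back to full enumeration when the requested sample approaches the pattern
universe. Plain rejection sampling over the raw tuple product space is
astronomically inefficient on realistic databases, which is why the
sequential exact sampler is used; duplicates are rejected, and if fewer than
n distinct patterns exist all are returned with a warning.

Evaluation tests, per pattern, whether (A, m3) is documented, against a
control replacing A with a random organism (excluding A, B, C). The binomial
upper tail of the test successes is computed in log space (finite log10 far
below the 1e-308 underflow threshold) under a null rate of
max(control successes, 1)/n — conservative, and equal to 1/1000 when the
control shows a single success in 1000. The rate is a parameter for users
with a better-calibrated null. Predicted pairings are deduplicated at the
pair level with a witness count equal to the number of distinct
(B, C, m1, m2, m3) combinations implying them.

## Collaborative filtering

The collaborative score of (test organism, medium) is

    score = sum over neighbors o with d(test, o) <= cutoff and (o, medium) documented
            of cutoff / max(d(test, o), floor)

with cutoff 0.04 on phylogenetic subtree distance (weighting cutoff/d) and
0.15 on ecological Jaccard distance (uniform weights). The floor (default
1/total leaves) bounds the weight of a near-identical strain, since the raw
cutoff/d weight is otherwise unbounded; every neighbor weight then lies in
[1, cutoff/floor]. The test organism's own pairings never enter the sum, so
scoring organisms already in the database is leave-one-out by construction
(verified by deleting an organism's rows and observing identical scores).
Ranked predictions break score ties by medium ID for determinism.

The popularity null pairs organisms with media sampled independently, each
proportional to its number of known pairings, restricted to organisms in
the phylogenetic (or ecological) set. The enrichment test draws K null
prediction sets of matched size (K = 1000 by default; 199 in the test
suite, where the smallest attainable p is 1/200) and reports
p = (1 + #{null TP ≥ observed TP}) / (K + 1).

Score-binned evaluation uses logarithmic bins (scores are heavy-tailed) and
reports Spearman of bin score vs true-positive fraction plus the partial
Spearman controlling for mean medium popularity, computed as the Pearson
correlation of rank residuals after regressing out the ranked control (and
cross-checked against an independent implementation in the tests).

## Filters and richness

An organism is aerobic/anaerobic when its documented media are unanimous
under a per-medium oxygen annotation, facultative when mixed, unknown when
unannotated; the annotation is a metadata column because a medium's oxygen
status is not derivable from composition alone (a keyword heuristic would
be guesswork, so none is applied by default). A medium is salty at ≥ 15 g/l
NaCl-equivalent or when its name contains "sea"; NaCl-equivalent is
reconstructed from the compiled composition as min(mol Na+, mol Cl-) x 58.44
plus complex sea-salts g/l — an approximation, since other sodium and
chloride salts contribute their ions. Filters remove oxygen-mismatched
pairs in both directions and salt-mismatched pairs (high-salt organism with
non-salty medium and vice versa); facultative and unknown always pass.
Because profiles derive from an organism's own media, a documented pairing
can never contradict them — filters provably never remove a true pairing.

Richness is a weighted g/l sum of complex components plus a configurable
list of rich defined compounds (default: common sugars, converted from
mol/l via their molar mass). Default weights are 1.0 per g/l; the canonical
weight table is not public, so weights are configuration with documented
defaults. Classes: low ≤ 5 g/l < medium ≤ 15 g/l < high, with boundary
scores assigned to the lower class (a choice; the boundary assignment is
unstated in the source). An organism's preference is the class with the
largest summed collaborative score over its (filtered) predictions; ties
break toward the lower class, conservative toward minimal media. Category
enrichment uses a two-sided Wilcoxon rank-sum on scores of media containing
vs lacking a category — exact null for combined n ≤ 20 without ties,
tie-corrected normal approximation otherwise.

## Synthetic study systems

The generator emulates the statistical structure the predictors assume: a
balanced binary taxonomy of 128 organisms, clades of 8 leaves, 64 media of
which each clade prefers 4 realizing the clade's planted oxygen, salt and
richness classes, and 3 pairings per organism drawn from the clade
preference with probability `signal` and uniformly from all media
otherwise. At signal 1 organism classes derived from observed media equal
the planted clade classes exactly; at signal 0 pairings are independent of
the taxonomy, so recovery statistics are null-distributed. Defaults were
chosen once as realistic-but-testable study conditions: real collections
average closer to 1 medium per organism, which is too sparse for any
neighbor-based predictor to be measurable at this scale, so 3 per organism
keeps the positive-only under-sampled character while giving neighbors
votes. Environments are clade-level habitat sets with 10% noise. Everything
planted is recorded in a ground-truth ledger sufficient to compute exact
expected values; generation is byte-for-byte reproducible under the seed.

What the generator does **not** emulate: the power-law popularity structure
of real collections, realistic chemical compositions, shared media between
clades, or curator biases. Passing recovery tests therefore demonstrates
correctness of the machinery under controlled signal, not field accuracy on
real catalogues.

Planted transitivity uses two fully-analyzed block types: 3-organism x
3-media cliques, whose 36 patterns are all positive, and 7-organism chains
(m1 = {A, A2, B}, m2 = {B, C, Q}, m3 = {C, R, S}) contributing exactly 4
patterns — two forward, two backward by symmetry — all negative. Block
counts come from the rational approximation of the requested fraction f, so
the positive fraction of the pattern universe equals f exactly and any
uniform miner recovers it within hypergeometric sampling error.

## Numerical choices and degenerate inputs

- Binomial tail: log-sum-exp over log-pmf terms (scipy gammaln); the linear
  probability underflows to 0.0 below ~1e-300 while log10 stays finite.
- A saturated control (every control draw positive) clamps the null rate to
  1 − 0.5/n so the test stays defined.
- Spearman on constant vectors returns NaN and is reported as degenerate,
  never silently coerced.
- Volume 0 with scale mode, cyclic references, unknown units, unknown tags,
  missing molecular weights, empty environment unions and empty rank-sum
  groups are errors naming the offending entity.
- All samplers take explicit seeds (numpy Generator); database iteration is
  over sorted keys so results are order-independent.

## Problem sizes

The test and acceptance workloads use 128-organism synthetic systems, 20
seeds for the signal-recovery checks with 199-permutation null
distributions, and 1000 mined patterns against planted pools of ≥ 2400;
these sizes give sub-percent standard errors on every recovered quantity
while the full suite runs in well under a minute.

## Known limitations

- The fill/scale general rule and the unit multiplier table are best-effort
  reconstructions; both are overridable configuration.
- Richness weights and the rich defined-compound list are non-canonical
  defaults.
- NaCl-equivalent salt scoring over-counts media rich in non-NaCl sodium or
  chloride salts.
- `predict_transitive` enumerates bridge triples and is intended for
  databases up to a few thousand pairings.
- Subtree distance ignores branch lengths by design; trees must place every
  organism of interest as a leaf.
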