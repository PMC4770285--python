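# Methods

## Model

The package treats a protein's proteolytic fragment-mass distribution as a
fingerprint of how its residues are arranged. If a residue that specifies a
cleavage site were allocated at random positions along the chain, the
intervals between consecutive sites would be geometric (exponential in the
continuum limit), and so — up to the residue-mass lattice — would the
fragment masses. The working statistic is therefore the maximum discrepancy
between the empirical exceedance distribution of mean-normalized fragment
masses and the exponential null e^(−x):

* **signed mode** takes `max_i [R_emp(x_i) − exp(−x_i)]`, the convention of
  a plain tabular computation (sort masses, tabulate the empirical and
  theoretical exceedance in two columns, take the largest difference);
* **absolute mode** takes the maximum absolute discrepancy, the classical
  one-sample Kolmogorov statistic.

Both are first class. `R_emp` is evaluated at the observed points only,
`R_emp(x) = #{values > x}/N`, not at both sides of each step as in the
textbook two-sided KS evaluation; the difference is O(1/N) and is
deliberate, matching the tabular definition.

### Which mode measures "breadth"

The two modes are not interchangeable, and the difference matters for
in-silico digests. Real digests contain single-residue fragments, so the
smallest normalized mass x_min = m_min/M is well above 0 while
R_emp(x_min) ≈ 1; the signed statistic therefore contains an irreducible
"left-edge" term ≈ 1 − exp(−x_min) ≈ x_min. Distributions that are *broader*
than exponential inflate M, which *shrinks* x_min and hence this term: the
signed maximum can decrease as the distribution broadens. The absolute
statistic additionally captures the deep negative deviation that a
broad (bimodal small-fragment/large-fragment) distribution carves into the
body of the curve, and is the quantity that tracks breadth monotonically.
Group-separation analyses in this package therefore default to the signed
mode at the single-spectrum level (the tabular convention) but use the
absolute mode for breadth-driven classification benchmarks; every fitted
classifier records the mode it was trained with.

### Null calibration and the estimated scale

The classical critical values (e.g. 1.358/√N at the 5% level, computed from
the asymptotic Kolmogorov tail Q(λ) = 2 Σ (−1)^(k−1) e^(−2k²λ²)) apply when
the null is fully specified. Normalizing by the *sample* mean fits the null
scale to the data and makes the test conservative — the same phenomenon the
Lilliefors correction addresses; simulation at N = 1000 puts the actual
exceedance rate of the 5% critical value near 0.5% rather than 5%.
`kstat(..., scale=...)` accepts an externally known scale for calibration
work; the null-calibration acceptance test draws i.i.d. Exp(1) spectra and
evaluates the statistic at the known scale 1, where the classical threshold
is exact (measured exceedance rate 0.046 over 10⁴ replicates of N = 1000).
`kolmogorov_pvalue` always refers to the known-scale null and should be read
as conservative for mean-normalized statistics.

## Digestion engine

Sixteen cleavage rules are built in, keyed by their residue shorthand
(`KR` trypsin, `AFILMV` thermolysin, `DK` AspN/LysC with its mixed
N-/C-terminal sides, …). Each rule is a set of (residue, side) site
specifications plus contextual exceptions that suppress a cut when a stated
neighbour flanks the site residue (e.g. a following proline for trypsin and
chymotrypsin; a preceding aspartate/glutamate for thermolysin; the
preceding-proline exception of chymotrypsin applies to tyrosine sites only).
Exceptions are evaluated per site before cut positions are merged across
site residues, so a boundary is cut if any non-suppressed site produces it.
Cuts at the chain termini are discarded.

Missed cleavages use augmentation semantics: at ceiling k, every
concatenation of up to k+1 consecutive fully cleaved fragments is reported
alongside the fully cleaved set (the behaviour of standard peptide-mass web
services), and all levels pool into one spectrum. Fragment masses are
residue-mass sums plus one water; the residue tables are the standard
published monoisotopic and average values (average is the default, matching
linear-mode MALDI-TOF practice). N-terminal methionine excision and
post-translational modifications are not modelled. `decomposable_mass`
implements the peak-sanity filter — whether a mass can be written as a
non-empty residue-mass combination plus water — by a reachability dynamic
program on a grid of bin width ≤ tolerance/2; grid rounding accumulates for
very large peptides, so the filter is intended for peak-level screening, not
exact composition search.

## Interval distributions

For one residue, intervals are the differences between consecutive
occurrence positions (adjacent occurrences give 1; no boundary intervals).
Group curves pool per-protein scaled intervals l/L̂ by default, because
compositions differ across proteins; raw pooling with a single scale is
available and preferable when compositions are homogeneous. Two systematic
effects bound what agreement with e^(−x) can be expected:

* scaling by a per-protein sample mean L̂ estimated from m intervals adds a
  broadening bias of order 1/m to the pooled curve, so the 5% Kolmogorov
  band (which covers sampling noise only) holds only while the pooled
  protein count stays well below m;
* i.i.d. intervals are geometric, not exponential; at residue frequency
  0.05 the deterministic KS distance between the two laws is ≈ 0.009.

The shuffling control (randomly permuting each sequence) removes all
arrangement structure while conserving composition, and restores
exponential-band agreement under the conditions above.

## Synthetic generator

`random_protein` draws residues i.i.d. from a given composition.
`patchy_protein` emulates structure-associated compositional patchiness with
a symmetric two-state Markov chain: at each position the state is kept with
probability `persistence` and otherwise redrawn uniformly, so persistence 0
is exactly the i.i.d. state mixture, the stationary occupancy is 1/2 per
state for every persistence, and the marginal composition is the mean of the
two emission compositions — persistence can be varied at fixed marginal
composition. Expected patch length is 2/(1 − persistence).

Defaults (the study conditions of the test benchmarks): groups of 100
proteins of 300–600 residues; persistence 0.99 (expected patch length 200);
enriched state with the thermolysin site set A, F, I, L, M, V at 2.5× a
uniform background, depleted state at 0.05×, the contrast calibrated so that
the absolute thermolysin-rule K_stat separates patchy from
composition-matched i.i.d. groups at AUC ≥ 0.9 across seeds (measured
0.93–0.99). The i.i.d. control group defaults to the state-mixture marginal
composition: matching compositions isolates the arrangement effect and makes
the shuffled-patchy group statistically indistinguishable from the control
(AUC ≈ 0.5), whereas unmatched compositions would bias the comparison
through fragment counts alone.

What the generator does *not* emulate: real transmembrane architectures have
nearly fixed helix lengths and multi-scale (long-range-correlated) interval
structure, while the Markov mechanism produces geometrically distributed
patches with exactly two interval scales. Passing benchmarks therefore show
that the pipeline detects compositional patchiness; they do not certify
accuracy levels on real membrane proteomes.

## Classifiers

* **ROC.** The decision rule is "score > threshold ⇒ positive"; the curve
  sweeps all observed scores (plus a below-minimum threshold, so it runs
  from (1,1) to (0,0)); the AUC is computed by the Mann–Whitney rank
  identity with half-credit for ties. AUC < 0.5 marks inverted-rule
  predictors; `efficacy = max(AUC, 1 − AUC)`.
* **Logistic regression.** Maximum likelihood by IRLS (tolerance 1e-8 on the
  log-likelihood, ≤ 100 iterations, 1e-10 ridge floor on the normal
  equations). Complete separation — diverging coefficients or a likelihood
  at its supremum — caps coefficients at |b| ≤ 30 and sets a flag; Wald
  statistics are (b/SE)² from the observed information; Nagelkerke R² is
  R²_CS/(1 − L0^(2/n)) against the intercept-only fit.
* **Stepwise logistic.** Mann–Whitney prescreen at α = 0.05 (scipy; exact
  null for small tie-free samples, tie-corrected normal approximation
  otherwise), entry in descending single-predictor Wald order, stop when the
  training-ROC AUC gain falls below 0.005 (the operationalization of "no
  significant enhancement of the ROC curve"; configurable) or at 4
  predictors. Coefficient signs absorb inverted-rule directions
  automatically.
* **Stepwise LDA.** Equal-prior linear discriminants with pooled
  within-class covariance (ridge jitter 1e-8 × trace when singular); entry
  by the predictor maximizing the minimum pairwise Mahalanobis distance
  between class means; stop on a training-accuracy gain below 0.5
  percentage points. Ties in discriminant scores break to the first class
  in declared order.
* **Validation.** Stratified 70/30 splitting with a mandatory seed;
  single-member labels go to the training side with a warning.

## Numerical choices and problem sizes

Test and acceptance simulations use: 1000 random sequences of 30–200
residues × 16 rules for the digestion-oracle and mass-conservation checks
(mass additivity to 1e-6 Da via cumulative sums); 10⁴ spectra of N = 1000
for the null calibration; 10⁴ proteins per group for the random-guess AUC;
100 seeded runs for coefficient recovery (n = 5000) and stepwise-entry
sanity (n = 1000); 100 + 100 proteins for the patchy benchmark. Seeds are
explicit arguments everywhere; identical configurations reproduce outputs
byte for byte.

## Known limitations

* The exponential null ignores the residue-mass lattice; for dense cleavage
  rules (mean fragment length ≲ 3 residues) the discreteness itself
  contributes a K_stat baseline of ~0.1–0.2 that both groups share.
* The decomposability filter is grid-based (see above).
* Multi-class discriminant analysis assumes equal priors and a shared
  covariance; no calibration for unequal group frequencies is attempted.
* Classifier accuracies quoted anywhere in this repository are properties of
  the synthetic benchmark conditions stated above, not of real proteomes.
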