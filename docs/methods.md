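# Methods

This note documents the statistical procedures, default constants, and
design decisions behind `soldissect`, in the spirit of a model-description
vignette: what is computed, under which assumptions, and what the bundled
synthetic data can and cannot certify.

## Descriptors

All 36 descriptors are *global*: they depend only on the residue multiset
(and, for the aggregation proxy alone, on residue order). No positional
profiles, windows, or predicted structure are used.

**Ambiguity handling.** Ambiguity codes (X, B, Z, U, O) are accepted on
input and preserved in the sequence, but excluded uniformly from every
computation: the effective length `L` counts canonical residues only and is
both the `length` feature and the denominator of every frequency and ratio.
This single rule keeps the identities `Σ_a f_a = 1` and
`r_G = Σ_{a∈G} f_a` exact, and it is the only self-consistent way to make
mass, hydropathy and propensity means ignore residues that have no table
entry. An ambiguous residue also breaks a hydrophobic run, which makes the
aggregation proxy conservative. A sequence with zero canonical residues is a
hard error.

**Charge model.** Net charge is the Henderson–Hasselbalch sum over the
ionizable side chains (acidic D, E, C, Y; basic H, K, R) plus both termini:

    Q(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH)).

Termini are included: a peptide is modelled as a free chain with one
α-amino and one α-carboxyl group, which also guarantees Q is strictly
decreasing with at least one sign change, so the isoelectric point — the
root of Q on [0, 14] — exists and is unique. It is found by bisection (40
iterations, final pH uncertainty ≪ 10⁻⁴; vectorized across sequences). The
default pKa set is the EMBOSS one (D 3.9, E 4.1, C 8.5, Y 10.1, H 6.5,
K 10.8, R 12.5, N-term 8.6, C-term 3.6). Absolute pI values shift by a few
tenths of a pH unit under alternative classical sets (Bjellqvist,
Lehninger); rank-based downstream statistics are much less sensitive than
the absolute values. The set is fully overridable via the tables config.

**Other scales.** Masses are Expasy *average* residue masses with one water
added per chain (the conventional protein molecular weight; the water term
matters only for very short peptides). Hydropathy is Kyte–Doolittle (1982);
structural propensities are the classical Chou–Fasman (1978) parameters,
averaged over the sequence per class (helix/sheet/turn). The disorder ratio
is the fraction of residues whose residue-level disorder propensity strictly
exceeds a threshold τ; the default scale is TOP-IDP with τ = 0. This default
is deliberately provisional — residue-level disorder scales differ
substantially in their zero point, so absolute disorder-ratio levels are
only meaningful relative to a stated scale, and any scale/τ pair can be
supplied in the YAML tables config. Every scale carries a provenance string
that the pipeline copies into its run log.

## Univariate statistics

Soluble is always group 1 / the positive class; this orientation is what
makes δ(length) negative and its AUC < 0.5 (AUCs are reported
unoriented, as-is).

* **U, δ, AUC.** One shared mid-rank computation yields
  U = #{x>y} + ½#{x=y}, δ = 2U/(n₁n₂) − 1 and AUC = U/(n₁n₂); the identity
  AUC = (δ+1)/2 therefore holds to machine precision including ties, and is
  asserted as an invariant.
* **p-values.** Exact Mann–Whitney null when n₁+n₂ ≤ 50 and there are no
  ties; otherwise the normal approximation with tie-corrected variance and
  continuity correction. Jointly constant groups return p = 1 by convention.
  (Exact tie-aware enumeration at 50 observations would require summing over
  ~10¹⁴ arrangements and is not implemented.)
* **δ confidence interval.** Percentile bootstrap, default B = 2,000,
  resampling within each group. B = 0 disables the bootstrap (CI reported as
  NaN) for large simulation studies where only point estimates are needed.
* **Hodges–Lehmann shift.** The median of all n₁n₂ pairwise differences is
  found by k-th-element selection: binary search over the value range with
  O((n₁+n₂) log) rank counting per step, snapping the bracket to realized
  difference values (with a fallback to interval halving when float rounding
  would stall the bracket). Memory is O(n₁+n₂). The CI inverts the rank-sum
  test with the large-sample critical value
  k = ⌊n₁n₂/2 − z₀.₉₇₅ √(n₁n₂(n₁+n₂+1)/12)⌋, taking the (k+1)-th and
  (N−k)-th ordered differences — the classical distribution-free companion
  of the estimator. (The bootstrap CI used for δ is statistically valid here
  too; the rank-inversion interval was chosen because it is deterministic
  and exact at the same level as the test.)
* **Youden's J.** All distinct observed values are scanned as thresholds in
  both decision orientations (positive if ≥ T, positive if ≤ T); ties are
  broken toward the smallest achieving threshold for determinism.
* **Multiplicity.** Benjamini–Hochberg step-up across the 36 features
  jointly; q-values are reported for all features, and the pipeline's
  redundancy stage only admits features with q below `fdr_alpha`
  (default 0.05).
* **Quantiles** are linear-interpolation sample quantiles throughout
  (medians, quartiles, robust-scaling constants).
* **Seeding.** A single pipeline seed fans out to per-feature substreams
  keyed by a hash of the feature name, so per-feature results do not depend
  on the order features are analyzed in.

## Redundancy and the composite-δ index

Spearman ρ (tie-aware) is computed over the significant features with
|δ| ≥ 0.1 (the `delta_floor`; the floor keeps near-null features from
inflating the correlation stage). Pairs with |ρ| ≥ 0.85 are redundant;
clusters are connected components of the thresholded graph — deterministic
and parameter-free, at the cost of possible chaining, which is acceptable at
so high a threshold. One representative survives per cluster: a
preference-listed feature if present (default preference: `length`, the most
interpretable member of the size axis), else the member with largest |δ|,
ties broken alphabetically.

The composite index robust-scales each retained feature by the *pooled*
median and IQR (both classes together — the scaling must not peek at
labels), weights it by its δ, and sums. Classification is by sign, with
S = 0 assigned to insoluble. There is deliberately no fitting: the index is
a descriptive summary of distributional separation, not a trained model, and
all reported metrics (tie-aware AUC, accuracy, F1, MCC with the
0-by-convention rule for degenerate margins, precision, sensitivity,
specificity at soluble-positive) are in-sample descriptions.

## Synthetic data generator

The generator emulates the benchmark's class-conditional structure from its
published summary statistics; defaults are fixed from those summaries and
are not free knobs.

* **Lengths** are log-normal per class, rounded, floored at 30 residues.
  Log-medians are ln 209 (soluble) and ln 277 (insoluble); log-sigmas come
  from the upper-quartile ratio, σ = ln(Q3/median)/Φ⁻¹(0.75), giving 0.713
  and 0.638. The soluble quartiles are nearly symmetric on the log scale
  (ln(338/209) ≈ ln(209/129)), which motivates the family; the insoluble
  class is slightly asymmetric and the approximation absorbs it.
* **Composition**: per protein, a residue distribution is drawn from a
  Dirichlet centered on the class's published median frequencies
  (renormalized to the simplex; the 20 medians sum to ≈0.95 per class
  because medians are not means), then residue counts are multinomial at the
  drawn length, then order is a uniform shuffle. The shared concentration
  c = 500 was derived once, before any end-to-end runs, from a variance
  budget: the within-class variance of the negative-charge proportion is
  p(1−p)/(c+1) (Dirichlet) plus p(1−p)·E[1/L] (multinomial ≈ 6.8 × 10⁻⁴ at
  the soluble length model), and c = 500 makes the total match the published
  soluble IQR of 0.0406 (≈0.038 realized).
* **Null variant**: 2n sequences from the soluble model with labels
  shuffled independently of the sequences, for type-I/FDR checks.

Under these defaults the generator reproduces the direction and approximate
size of the published effects — δ(length) ≈ −0.23 ± 0.01 vs −0.215
published, δ(neg_ratio) ≈ +0.19 vs +0.150 (the renormalization of median
compositions slightly widens the class gap), two-feature composite
AUC ≈ 0.63–0.64 vs 0.624 — while remaining unfaithful in ways that bound
what passing tests mean: sequences are exchangeable multinomials with no
motifs, domains or homology; length and composition are independent within
class (in real data they are weakly coupled); aggregation-run statistics are
whatever a random shuffle implies; and the soluble/insoluble imbalance of
the real benchmark (46,450/31,581) is not reproduced at the default
5,000/5,000. Tests passing on synthetic data certify the statistical
machinery and calibration, not feature biology.

## Problem sizes used in the test suite

Self-contained statistical checks run at 5,000 sequences per class
(parameter recovery, five seeds) and 2,000 sequences per replicate over 50
replicates (null behaviour); oracle-equivalence checks compare the fast rank
paths against exhaustive O(n²) references on 220 random instances with group
sizes up to 30. These sizes give quantile/effect-size sampling error well
inside the asserted tolerance bands. The full-benchmark reproduction check
needs the deposited dataset on disk and fails with instructions when absent.

## Known limitations

* The disorder scale/threshold and pKa set are defaults, not reproductions
  of any specific study's choices; absolute pI, net-charge and
  disorder-ratio levels move with these constants (rank statistics move far
  less). Both are config-overridable.
* Whether published molecular weights include the water term, and whether
  termini entered published net-charge values, is generally unknowable from
  summary tables; this package states its own convention (water included,
  termini included) and keeps it fixed.
* The Mann–Whitney "exact" path is limited to small tie-free samples.
* Composite metrics are in-sample descriptions by construction; the package
  intentionally offers no train/test machinery.
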