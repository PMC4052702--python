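# Methods

## Model and procedure

The pipeline treats two-group differential expression as a supervised
projection problem. The predictors are autoscaled log2 expression
profiles (one column per probe, centered and divided by the ddof-1
standard deviation); the response is the 0/1 disease status, centered.
Zero-variance probes cannot be scaled and are excluded from the model
(they are retained in the input table and reported in the preprocessing
record). Scaling is optional (`scale=False` centers only); autoscaling
is the default because the VIP normalization identity and the customary
"VIP > 1" reading both presuppose unit-variance columns.

With a single response, the NIPALS inner iteration collapses to a
closed-form step per component, so the implementation is the exact PLS1
recursion (weights from the covariance X'y, scores, loadings, then
deflation of both X and y). The sequential-projection structure gives an
exact decomposition ||y||² = Σ_a SSY_a + ||residual||², which the tests
assert. Extraction stops early, with a warning, if the remaining
covariance norm falls below 1e-12 (response exhausted or rank
deficient). Three components are fitted by default; no automatic
component selection is offered, and the number is a config knob.

VIP aggregates squared weights across components, weighted by each
component's explained response sum of squares SSY_a = q_a²·t_a't_a. The
weights, not the rotated weights, enter the formula — the standard
definition under NIPALS deflation — and the identity Σ_j VIP_j² = p
holds to floating-point accuracy because each weight column is
unit-norm. Ties in VIP are left intact; the FDR's closed (≥) tail
counting handles them conservatively.

## Permutation FDR

The null distribution is built by shuffling the centered response
uniformly (class sizes are automatically preserved) and refitting the
full A-component model plus VIP on the unchanged X; X's scaling does not
depend on y, so it is not recomputed. One seeded NumPy generator drives
all shuffles. A permutation in which the model explains no response
variance contributes an all-zero VIP row and is counted in the run log
(conservative; it inflates no tail).

For a probe with observed VIP v, the estimate is

    FDR(v) = min(1, mean over permutations of #{null VIPs ≥ v}
                    / #{observed VIPs ≥ v})

with null counts pooled over the whole probe axis within each
permutation, followed by the q-value-style running minimum over all
thresholds at or below v, which makes FDR non-increasing in VIP. The
pooled construction uses every permutation's full VIP vector, so 200
permutations of a 1000-probe matrix already give a 200 000-point null;
the package default is 10 000 permutations, and the test suite and
acceptance script use 200, which the calibration results below show is
ample at these problem sizes. Selection is strict (FDR < threshold,
default 0.05); regulation direction is the sign of the patient-minus-
control mean difference on the raw log2 scale, with exact ties labeled
"down" and logged — group means, not PLS loadings, because that is the
directly interpretable reading of over-/under-expression.

### Power characteristics of the pooled estimator

Two empirical properties of this estimator are worth knowing, both
measured by the test suite and the acceptance script:

* Under a global null it is very conservative: across 20 replicate null
  datasets (1000 probes, 10 vs 10 samples, 200 permutations) the mean
  fraction of probes selected at FDR < 0.05 is about 1e-4, and realized
  false-discovery proportions on signal datasets are typically 0.
* When a non-negligible fraction of probes carries true signal, the
  observed weight normalizer ||X'y|| is inflated relative to the
  permutation null's, which shrinks observed VIPs toward the null and
  costs sensitivity. At the default study design (50 planted probes of
  ±1.0 log2 among 1000, noise sd 0.5, 23 vs 11 samples) measured
  sensitivity is roughly 0.5–0.75 depending on seed and scaling, with
  zero false positives, whereas a per-probe t-test with
  Benjamini–Hochberg reaches ~0.95 on the same data. The trade-off
  reverses under confounding: with a class-correlated array-wide latent
  factor the t-test's selections are heavily contaminated (false-
  discovery proportions approaching 0.9) while the PLS-VIP selection
  remains clean — the multivariate null absorbs the factor that the
  per-probe error model cannot. At realistic whole-array scale, where
  selected genes are ~1% of probes, the normalizer inflation is
  negligible and the estimator is nearly unbiased.

## Enrichment and network

The enrichment universe is the set of genes present on the input matrix
that carry at least one annotation; selected genes without annotation
are dropped with a logged count. A gene counts as selected if any of
its probes is selected. P-values are exact upper-tail hypergeometric
probabilities (scipy's survival function, stable in log space) and are
reported raw, matching the convention of reporting unadjusted
over-representation P values; an optional Benjamini–Hochberg column is
available. Ranking is by ascending p, ties broken by larger overlap
then term id. Annotations are flat pairs; ontology ancestor
propagation is deliberately out of scope.

The interaction network is the induced subgraph of the edge list on the
selected genes: an interaction is kept only when both partners are
selected, isolated selected genes stay as degree-0 nodes, and edge
records are canonicalized (sorted pair, self-loops removed, duplicates
collapsed) because public interaction extracts are directional and
redundant. Degree counts distinct partners; hubs are nodes with degree
strictly greater than 10. Exports are a SIF edge file and a node table
with degree, direction, and hub columns for Cytoscape styling.

## Synthetic data

The generator emulates the target study design: x_js = μ_j + δ_j·c_s +
γ_j·b_s + ε_js with baselines μ_j ~ U(6, 12) log2 units (the bulk of an
RMA intensity distribution), planted shifts δ_j = ±1.0 for 50 of 1000
probes (25% positive — patients over-expressing — mirroring a
predominantly depressed signature), Gaussian noise sd 0.5 (a typical
post-normalization within-group spread), and 23 patients vs 11
controls. The optional confounder b_s ~ N(0, sd) loads on every probe
with γ_j ~ N(0,1); a class-correlated mode shifts it by class to stress
comparisons against per-probe tests. Annotation fixtures plant one term
drawing 80% of its members from the differential genes against a ~5%
base rate; edge fixtures plant two hub genes at degrees 20 and 14
within the differential-gene subgraph (comfortably above the hub
threshold) over a sparse random background kept at degree ≤ 10.

What the generator does not emulate: probe-level effects (RNA
degradation, GC bias), correlated co-expression blocks, heavy-tailed or
heteroscedastic noise, and many-to-one probe/gene maps (synthetic
probes map 1:1 to genes). Passing tests therefore demonstrate the
statistical machinery under an idealized independent-Gaussian regime,
not performance on raw array data.

## Numerical and design choices

* ddof-1 standard deviations in autoscaling; 0/1 response coding minus
  the class proportion.
* NIPALS early-stop tolerance 1e-12 on ||X'y||; score orthogonality and
  weight normality asserted to 1e-8/1e-10 in tests.
* The FDR's raw tail-ratio values are exposed (`monotonize=False`) for
  inspection; the pipeline always reports the monotonized version.
* Group-label coding in label files is explicit (`case_label`), never
  inferred from file order or alphabet.
* Missing expression values are rejected by default; per-probe mean
  imputation is opt-in and logged.
* Probes without a gene mapping stay in the DE analysis and drop out,
  with a logged count, only at the enrichment/network stages.
* All randomness (generator, permutations) flows from explicit integer
  seeds; reports contain no timestamps, so a rerun with the same config
  is byte-identical.

## Problem sizes

The test suite and the acceptance script run the full design at 1000
probes and 200 permutations, null calibration over 20 replicates, exact
hypergeometric enumeration up to N = 12, and 50-graph network oracles —
sizes chosen so the whole suite completes in well under a minute while
still exercising the study-scale sample design. The pipeline itself
handles whole-array matrices (tens of thousands of probes) with the
10 000-permutation default in minutes, since each permutation costs a
handful of matrix–vector products.

## Known limitations

Single binary response only (no multi-class or continuous phenotypes);
no cross-validated component selection; the pooled permutation FDR's
conservatism under dense signal (see above); flat annotation semantics;
degree is the only centrality; no plotting — scores and network
attributes are exported as tables for external tools.
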