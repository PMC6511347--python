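# Methods

`radargate` implements a flow-cytometric screening protocol for acute
promyelocytic leukemia (APL) built on multidimensional radar (star-
coordinate) dot-plots.  This note records the model, the numerical choices,
and the design decisions that were genuinely open, together with what the
synthetic-data experiments do and do not demonstrate.

## The screening model

APL is a hematologic emergency: the diagnosis is confirmed genetically
(PML-RARA), but treatment must start on the strength of morphology and
immunophenotype.  The protocol screens a standard four-tube, 8-color AML
panel (plus FSC/SSC) as follows.

**Projection.** Within each tube, K selected channels are placed on equally
spaced radar axes (axis *i* at angle θᵢ = 2π(i−1)/K, axis 1 at angle 0,
counter-clockwise).  An event with channel values x₁..x_K, each scaled to
[0, 1], projects to

    p = (1/K) Σᵢ xᵢ (cos θᵢ, sin θᵢ),

the unweighted star-coordinate map; all events land in the unit disc.  The
shipped per-tube layouts are the published parameter orders (tube 1: SSC,
CD4, CD64, CD11b, CD13, HLA-DR, CD14, CD300e, CD45; tube 2: CD15, CD123,
SSC, CD34, CD13, HLA-DR, CD45; tube 3: CD34, CD117, CD56, CD45, CD33, SSC;
tube 4: cyFXIII-A, cyMPO, HLA-DR, SSC, CD117, CD45).  A layout optimizer is
provided that searches circular orderings (exhaustively up to K = 9,
(K−1)!/2 orderings after removing rotations and reflections; greedy
insertion beyond) for the order maximizing the minimum pairwise standardized
centroid distance ‖c_a − c_b‖ / √(σ²_a + σ²_b) between labelled reference
populations, where σ² is a population's mean squared distance to its own
centroid.  Maximizing the worst-separated pair reflects the protocol's goal
that all morphology groups look distinct simultaneously.  Because the
projection is linear, orderings are scored from per-population channel
means and covariances (on a seeded ≤20,000-event subsample per population),
which reproduces the point-wise score exactly.

**Scaling.** Fluorescence channels are transformed with asinh(x/150)
(cofactor configurable); scatter channels stay linear.  Each channel is
mapped affinely to [0, 1] between its 0.001 and 0.999 quantiles on the
template-building reference events, then clipped.  The anchors are frozen
into the template so screened cases land on exactly the display scale the
gates were drawn on — the analogue of running a daily-calibrated instrument.
Spillover compensation (solving the linear mixing model from the FCS
`$SPILLOVER` keyword or a user matrix) is available upstream; the convention
is S[i, j] = fraction of true signal j read by detector i.

**Blast gating.** Blasts are selected per tube on the CD45/SSC plot.  The
default gate is the CD45-dim window 0.15–0.55 (scaled units) at any SSC,
overridable per case; points on the gate boundary count as inside
(even–odd rule on simple polygons).

**Gate construction.** For each tube and APL type (hypergranular,
microgranular), the blasts of the merged reference cases are projected and
enclosed in the smallest highest-density region containing ≥95% of them:
a Gaussian KDE (Scott's rule bandwidth, evaluated by binned convolution on
a 256×256 grid), the density level set at the empirical (1−0.95) quantile
of the per-point densities, and the outer contour polygonized at 128
vertices.  A disconnected region falls back to the convex hull of its
contours (flagged).  Achieved containment is verified by exact
point-in-polygon recount and the polygon dilated about its centroid (2%
steps) if short.

**Predictive calibration.** A raw 95% HDR hugs the training cases, so an
exchangeable *new* case would reach the 95% level only on average, while
the protocol's defining claim is that essentially every APL case clears the
cutoff in every tube.  The template therefore calibrates a single uniform
dilation factor: leave-one-out dilation requirements (rebuild the gate
without one reference case; find the dilation it needs to reach 95%) are
pooled across all tubes and both types — a dilation factor is dimensionless,
and the case-to-case variation it measures (staining efficiency, day
effects, biological intensity spread) is a property of cases, not tubes —
and the log of the pooled maximum is inflated by
√(ln(1/α) / ln(n+1)) with α = 0.001, targeting the ~99.9th-percentile
future case rather than the ~n/(n+1) quantile the plain maximum estimates.
In-sample per-case containment (each reference case ≥95% in its own gate)
is enforced on top.  On simulated validation cohorts disjoint from every
test cohort (90 APL cases), all cases exceeded the cutoff in all tubes with
the calibrated gates, and 80 non-APL validation cases produced no false
positives — the conjunctive rule leaves ample specificity headroom because a
mimic must match the reference phenotype in all four tubes at once.

**Screening call.** A case is scaled with the frozen anchors, blasts gated
and projected per tube, and the percentage of blasts inside each gate
polygon computed (boundary inside).  The hypergranular call requires the
percentage ≥ cutoff (default 95) in *all four* tubes; microgranular
analogous; the case is APL-positive if either call holds, indeterminate
(never negative) if a tube is missing or contains no gateable blasts.  A
"k-of-4" relaxation is available for sensitivity analysis.  Raising the
cutoff can only flip calls positive→negative.

**Pattern dissimilarity.** Each gate stores a 64×64 histogram of its
reference blasts over the polygon's bounding box.  A screened case's
in-gate points are histogrammed on the same grid and compared by the base-2
Jensen–Shannon distance after light Gaussian smoothing (1.5 cells) of both
histograms; the smoothing removes the sparse-binning noise floor of a
few-thousand-event histogram.  Identical patterns score 0; well-separated
supports score ~1; the score is undefined below 50 in-gate events.  The
check is disabled by default; when enabled it vetoes a tube whose score
exceeds `pattern_max` (default 0.80).  The threshold is deliberately
conservative: on validation cohorts true APL scores reach ~0.70 (case-level
brightness shifts translate the cloud within the gate) while the
CD34⁻/CD117⁺ mimic that can sneak over the tube-3 percentage cutoff
concentrates at the gate edge and scores ~0.73–0.93; the tails touch, so
the default is set above the APL tail — enabling the check never costs
sensitivity and still flags gross deviations.

## The synthetic cohort generator

No list-mode data from the underlying study is deposited, so the package
ships a seeded generator emulating its three groups: hypergranular APL
(CD117⁺, CD33/CD13/cyMPO bright, CD34⁻, HLA-DR⁻, high SSC), microgranular
APL (additionally CD34⁺, CD123⁺, CD2⁺, medium SSC), and the non-APL mimic
(NPM1-type AML: CD117⁺, CD33 bright, CD34⁻, variable HLA-DR/monocytic
markers/CD123, medium-low SSC).

* **Case-level statuses.** Each case draws one status per marker, shared
  across tubes.  0%/100% group rates are hard constraints; intermediate
  rates are Bernoulli in `simulate_case`.  `simulate_cohort` instead
  allocates statuses so the within-cohort counts match the rates exactly
  (round(p·n) positives, seeded assignment): the published rates describe a
  concrete cohort's composition (17% of 6 cases = exactly one positive
  case), and a reference cohort that is to stand in for the study must
  contain each variant.
* **Intensities.** Log-normal per marker status: negatives median 40
  (log-sd 0.7), dim 500, moderate 4,000, bright 15,000 (log-sd 0.5).
  Constraint markers express on all blasts at their characteristic level;
  intermediate-rate (LAIP-type) markers express dimly on a per-case
  fraction of blasts drawn uniformly from 0.25–0.65, the way partial dim
  aberrancies (CD56, CD2, CD7, CD64…) present in real AML.  A per-case
  log-normal factor (log-sd 0.25; 0.15 for SSC) adds case-to-case
  biological/technical variation.
* **Background.** The non-blast compartment is lymphocytes (35%, CD45
  bright/SSC low), monocytes (20%), granulocytes (35%) and CD45-negative
  erythroid precursors (10%, CD71 bright) at canonical CD45/SSC positions
  with realistic marker profiles; the erythroid fraction anchors the bottom
  of the CD45 display scale as it does in real marrow.
* **Blast fraction.** Uniform over the study groups' bone-marrow blast
  ranges (APL 26.6–87.5%, non-APL 20.7–82.9%); the blast count is an exact
  allocation, not a binomial draw.  Default acquisition 100,000 events per
  tube; the tests and the acceptance script use 10,000 for runtime, which
  leaves ≥2,600 blasts per tube — comfortably above every estimator's needs.
* **Determinism.** One integer seed per case (cohort seeds derived as
  (master·100003 + 7919·i + 1) mod 2³¹) drives every draw; identical seeds
  give bit-identical FCS output.

What passing tests show — and do not.  The generator reproduces the study's
*population structure*: marker positivity patterns, SSC separation of the
morphologic types, CD45/SSC geography, case-level heterogeneity.  It does
not simulate doublets, debris, spillover artifacts, autofluorescence,
instrument drift, or subclonal blast structure, and its intensity magnitudes
for positives are stated conventions, not fitted to data.  Results on it
demonstrate that the pipeline's mathematics and decision logic behave as
claimed under realistic population geometry; they are not evidence about
any particular instrument's raw data.

## Numerical and degenerate-input choices

* FCS is written as 3.1, float32, little-endian; 3.0/3.1 integer, float and
  double list-mode data are read.  Truncated files and malformed offsets
  raise format errors rather than returning partial data.
* Constant channels are flagged degenerate at scaling time and their
  anchors widened by an epsilon margin; values outside the anchors clip to
  0/1.
* All-identical gate points yield a minimal square gate with containment 1.
* Gate dilation searches in multiplicative 2% steps, capped at 5×.
* Ties in the layout search are broken by the lexicographically smallest
  canonical (rotation/reflection-normalized) channel sequence, so the
  optimizer is deterministic.
* Template JSON serialization is key-sorted with full float precision;
  builds are pure functions of their inputs, so identical inputs give
  byte-identical templates.
* Zero-blast tubes make a case indeterminate, never negative; the pattern
  score is reported as missing below 50 in-gate events, and a case whose
  in-gate points all miss the stored reference footprint scores 1.

## Known limitations

* The radar projection is this package's own (unweighted, 1/K-normalized)
  star-coordinate map; commercial analysis software does not document its
  display math, so gates live in this projection space and are internally
  consistent rather than byte-compatible with any vendor display.
* The microgranular gate can rest on as few as one or two reference cases;
  the template records per-gate reference sizes in its provenance so users
  can see how thin the evidence is.  The predictive calibration partly
  compensates by pooling leave-one-out information across tubes and types.
* Templates do not transfer across instruments or laboratories; scaling
  anchors are frozen per template and assume a consistently calibrated
  cytometer.
* The screen is exactly that — a screen.  A positive call motivates urgent
  genetic confirmation; it is not a diagnosis.
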