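# Methods

This note records the models and procedures phytonet implements, the
conventions and numerical choices behind them, what the synthetic
generators do and do not emulate, and known limitations.

## Retention indices and composition tables

Retention indices use the van den Dool–Kratz formulation for
temperature-programmed GC: the analyte's retention time is located between
the bracketing n-alkanes and interpolated linearly,
`RI = 100·(n_i + (n_j − n_i)·(t − t_i)/(t_j − t_i))`. Calibration is exact
at ladder points (the C_n alkane maps to 100·n) and strictly monotone in
retention time between them. Analytes outside the ladder span raise an
error rather than extrapolate — extrapolated indices on a temperature ramp
are not meaningful.

Identity confirmation compares experimental against literature indices
within a tolerance window, default **10 index units**. This is a common
working window for RI confirmation on 5%-phenyl (DB-5/Rtx-5-class)
columns; it is configurable because laboratories differ and no single
value is authoritative.

Class subtotals use a controlled five-class vocabulary (monoterpene
hydrocarbon, oxygenated monoterpene, sesquiterpene hydrocarbon, oxygenated
sesquiterpene, other). Free-text class descriptors collapse onto it:
skeleton adjectives (bicyclic, aromatic, monocyclic, tricyclic, acyclic)
are ignored, so *aromatic* monoterpene hydrocarbons count with the
monoterpene hydrocarbons — the bundled oil table's subtotal of 34.95% only
reconciles under this rule — and oxygen-bearing descriptors (alcohol,
oxide, …) map to the oxygenated classes. Non-terpene constituents (the
fatty acid ester in the bundled table) fall in "other": they are excluded
from the four terpene subtotals (which sum to 98.05% for the bundled
profile) but included in the grand identified total (98.09%). Both totals
are reported because chromatography tables are printed both ways and the
bundled table itself is internally ambiguous between them.

Report values are rounded half-up at 2 decimals from full-precision sums;
comparisons and invariants always use full precision.

Profile comparison matches compound names case-insensitively after
normalizing dashes and stripping trailing parenthetical synonyms
("1,8-Cineole (Eucalyptol)" ≡ "1,8-cineole"). Stereo-descriptors are *not*
stripped (cis/trans isomers stay distinct); enantiomer pairs that a report
sums jointly are handled explicitly through group definitions, producing a
"grouped" row whose current value is the members' sum.

## Drug-likeness

Lipinski violations are strict exceedances of MW > 500 Da, logP > 5,
HBD > 5, HBA > 10; a compound exactly on a limit complies. The screen
passes a compound with at most **1 violation** (Lipinski's original
allowance; configurable to 0) and an Abbott bioavailability score of at
least 0.5. Descriptors are ingested, not computed — the score in
particular is assay-calibrated and not derivable from structure here — but
`descriptor_from_smiles` can populate the physicochemical fields via RDKit
when it is installed.

## PPI network and hub screen

Edge lists carry confidences either as fractions in [0, 1] or in the
STRING 0–1000 integer dialect; the dialect is auto-detected (any score
above 1) and rescaled. Filtering keeps edges with confidence strictly
above the threshold (default 0.4); a non-strict mode exists because
"threshold of 0.4" is stated both ways in common usage. Self-loops are
dropped, parallel edges keep the highest confidence, and isolated nodes
are removed. "Disconnected nodes" is read as *isolated* nodes only;
restriction to the largest component is available as an option, since
either reading appears in practice.

Centralities are computed on the unweighted simple graph (confidence is a
filter, not a path weight, matching how Cytoscape-style analyses treat
STRING imports):

- **DC**: plain degree.
- **BC**: Brandes' algorithm, undirected, endpoints excluded, each
  unordered pair counted once, **no normalization**. Raw pair counts are
  the convention under which published hub tables of ~300-node networks
  show values in the thousands.
- **CC**: closeness normalized to [0, 1] with the component-size
  correction `(r/Σd)·(r/(n−1))` where `r` is the number of reachable
  nodes; on a connected graph this is the standard `(n−1)/Σd`.

The hub screen is two-tiered. Tier 1 keeps nodes with DC at least
`multiplier × median(DC)` (default multiplier 2) and induces the subgraph
on them, dropping newly isolated nodes. Tier 2 **recomputes** centralities
on that subnetwork and keeps nodes at or above the median of BC, CC and DC
simultaneously, ranked by DC descending (ties by BC, then name). The
recomputation choice matters: medians taken on the original network's
values restricted to the survivors would be systematically different; the
published threshold sequence this design follows (a tier-2 DC threshold
above the tier-1 one) is consistent with recomputation, and recomputation
is also the natural reading of "filtering the subnetwork". Both screens
are deterministic and idempotent at fixed thresholds.

Compound ranking in the bipartite compound–target network uses degree =
number of distinct targets, a median cutoff with ≥ semantics, and
degree-descending, name-tiebroken order.

## Enrichment statistics

Over-representation uses the hypergeometric upper tail P[X ≥ k] evaluated
through the survival function (log-space internals), exact against
combinatorial enumeration for small backgrounds. The EASE variant
(evaluating at k − 1, as annotation portals do) is available as an option
but is not the default: it is a deliberate conservative bias, not the
exact test. The background defaults to the union of catalog genes — the
only choice reproducible from the catalog alone. BH correction is applied
within each annotation category (BP/CC/MF/KEGG) separately, mirroring how
category-blocked reports are produced, with a pooled mode by flag.
Adjusted values follow the step-up rule `adj_(i) = min_{j≥i} p_(j)·m/j`,
capped at 1. Note the full BH map is not idempotent (re-adjusting adjusted
values inflates them); only weak order preservation holds and is what the
tests assert.

## Dose–response and cytotoxicity

The 4PL model `V(c) = bottom + (top − bottom)/(1 + (c/IC50)^h)` is fitted
by bounded least squares on log10 concentration, parameterized by
log10(IC50) for stability. Initialization is multi-start over Hill slopes
{0.5, 1, 2, 4} in both signs with top/bottom started at the data extremes;
bounds default to bottom ∈ [0, 50], top ∈ [50, 120] (viability per cent,
allowing modest >100% plateaus from plate noise) and log10(IC50) within
±2 decades of the tested range. The best converged start by SSE wins;
flat responses and universal non-convergence raise errors rather than
return a degenerate fit. Standard errors come from the Gauss–Newton
covariance; the IC50 interval is formed on the log scale and
back-transformed. Any inhibition level is solved analytically:
`IC_q = IC50·(q/(100 − q))^(1/h)`.

Viability is `100·OD_treated/OD_control`. One published statement of this
formula inverts the ratio (control over treated), which would exceed 100%
for any toxic treatment; the treated/control form is the one that
reproduces sigmoid dose–response curves and is implemented, with the
printed form treated as an erratum. Likewise the selectivity index is
implemented as **SI = CC50/IC50** (normal-line tolerance over cancer-line
potency): the printed inverse contradicts the accompanying text and the
tabulated values (77.76/18.09 = 4.30). NCI activity uses IC50 ≤ 30 µg/mL;
selectivity uses SI strictly > 3.

Apoptosis quadrants gate two log10 fluorescence channels; events exactly
on a gate count as positive. Fractions are exact partitions (summing to
100), total death = early + late + necrotic, and the fold induction is
reported at 1 decimal. Cell-cycle gating excludes sub-G1 events from the
three-phase normalization and reports them separately, as FlowJo-style
analyses do; gates are inputs, never estimated. Wound closure is
`100·(A0 − A_t)/A0` per arm; both the treated-relative-to-control ratio
and the percentage-point difference are emitted because "closure
reduction" is stated both ways in the literature. Two-group comparisons
use Welch's t with Satterthwaite degrees of freedom; the degenerate
zero-variance/equal-means case returns (t = 0, p = 1) by convention.

IC25 deserves a caveat: for the bundled A-549 panel a published IC25 of
0.70 µg/mL is not reconcilable with an IC50 of 18.09 µg/mL under any 4PL
with a plausible Hill slope (it would require h ≈ 0.34). `icq()` computes
the analytic value from fitted parameters; reproducing that particular
printed number is out of scope without the raw optical densities.

## Docking summaries

Best-per-target reports the minimum (most negative) energy with a full
tie list; relevance uses score ≤ −5.00 kcal/mol, the conventional cutoff
for biologically meaningful poses, anti-monotone in the cutoff by
construction. Pose selection takes the lowest energy among poses with
RMSD ≤ 2.0 Å (community clustering convention; the source convention is
unstated) and falls back to the global minimum with a warning when no
pose qualifies. Docking execution itself is out of scope; scores are
consumed from CSV.

## Synthetic generators

One root seed fans out to fixed per-generator child streams
(`seed·1000003 + stream·7919 + 12345 mod 2^31`), so adding a generator
never perturbs existing draws; identical configuration and seed give
byte-identical outputs.

Defaults encode the emulated study design: nine 2-fold dilutions from
100 µg/mL, triplicates, true IC50 18.09 µg/mL with top 100/bottom 0;
Hill slope 1.5 and replicate noise SD 3 percentage points are choices —
typical of crude-extract MTT curves — where the design leaves them
unstated. PPI stand-ins are Barabási–Albert preferential-attachment
graphs (n = 300, m = 5 by default) with uniform [0.15, 1] edge
confidences; planted hubs are wired to 40% of the network, far above the
organic hub degrees. Docking grids default to the −6.9…−4.0 kcal/mol span.

Flow-event clusters are bivariate normal on the log10 scale, one per
quadrant, **clipped a small margin inside their quadrant**: realized
quadrant membership then equals the multinomial ground truth exactly, so
recovery tests measure counting arithmetic and sampling error rather than
gate placement. Cell-cycle draws are likewise clipped inside their phase
gates.

What passing tests on these generators shows — and does not. Recovery of
planted hubs, planted terms, true IC50s and quadrant weights demonstrates
that the screens and estimators are implemented correctly and are
well-calibrated under clean, well-separated signals. Real data differ:
interactome confidence correlates with degree and study bias, annotation
terms overlap hierarchically, cytometry clouds have spillover, debris and
doublets, and composition tables carry co-elution ambiguity. Results on
real inputs therefore inherit those caveats; the generators make the
arithmetic testable, not the biology.

Problem sizes in the test suite and acceptance script (300-node networks,
50 000 events, 100–200 fit replicates, 1000 null-enrichment replicates)
were chosen to give stable statistics at interactive runtimes.

## Known limitations

- No mass-spectral library matching; identification support is RI-based
  only.
- No live database clients (target prediction, disease genes, STRING,
  annotation portals); all such inputs are files.
- The published absolute centrality values and network sizes of the
  original screen depend on a specific interactome snapshot and are not
  reproducible from this package; what is checked is the internal
  consistency of the published table with its own recorded thresholds.
- Gates for quadrants and cell-cycle phases are user inputs; automatic
  gate estimation (and model-based cell-cycle deconvolution) is out of
  scope.
- Docking, receptor preparation and pocket prediction are external.
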