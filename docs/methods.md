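# Methods

`lipimark` re-implements, as a tested library, the computational chain used
to discriminate meat samples from different origins by widely targeted
lipidomics: QC-driven feature filtering, lipid nomenclature and class
accounting, fatty-acid profile arithmetic, Duncan-protected group
comparison, random-forest recursive feature elimination (RF-RFE) for marker
selection, and lipid–quality correlation networks. This note records the
models, the parameter choices that matter, and the places where the design
was genuinely open.

## Lipid catalogue

Shorthand names (`PC (16:0_16:1)`, `Carnitine C3:0`) are parsed into a
subclass token plus `(carbons, double bonds)` acyl chains. The `_` and `/`
chain separators are treated identically because the assay does not resolve
sn-position. Ether (`-O`) and plasmalogen (`-P`) suffixes stay on the
subclass. The subclass → class ontology (six LIPID MAPS-style categories:
FA, GL, GP, PR, SP, ST) ships as an editable two-column CSV; unknown codes
fail loudly rather than being silently classified. Molecular formulas are
parsed over C, H, N, O, P, S and masses are **monoisotopic** neutral masses
(C 12 exactly, H 1.0078250319, N 14.0030740052, O 15.9949146221,
P 30.97376151) — verified numerically to reproduce every vendor-reported
molecular weight in the shipped marker table at two decimals. Adduct m/z
([M+H]⁺, [M−H]⁻, [M+COOH]⁻) is provided as a convenience and is not used
downstream. GC fatty-acid shorthand (`C18:1n9c`) is classified by
double-bond count: 0 → SFA, 1 → MUFA, ≥2 → PUFA.

## Synthetic study generator

No raw lipidome is publicly deposited for the study this package mirrors,
so every downstream stage is exercised on synthetic data with the study's
design: 3 origin groups × 6 animals, ~1000 lipid features, 5 pooled-QC
injections, and 10 planted origin markers.

Peak areas are log-normal: they are positive, right-skewed, and CV-based QC
filtering presupposes multiplicative noise. Defaults, chosen once on
realism grounds:

| parameter | default | meaning |
|---|---|---|
| `base_log_mean` | 13.0 | log peak area location (~4×10⁵ cps) |
| `base_log_spread` | 1.5 | feature-to-feature log-abundance spread (dynamic range) |
| `biological_sigma` | 0.5 | within-group log sd (~53% inter-animal CV) |
| `effect_size` | 4.0 | fold elevation of a marker in its up-group |
| `technical_cv` | 0.1 | QC replicate CV |
| `dropout_rate` | 0.05 | QC cells blanked at random |

Each marker is elevated in exactly one group (assigned round-robin), the
pattern origin-marker lipids show in practice. QC columns are the
per-feature arithmetic mean of all biological samples times unbiased
multiplicative log-normal noise at `technical_cv`; detection dropout is
missing-at-random on QC cells only (the detection-rate filter targets QC
columns). Features planted to fail QC do so deterministically: detection
failures keep strictly fewer than half the QC cells; CV failures get an
alternating 3× inflation (CV ≈ 0.6).

Quality traits (pH, L*, a*, b*, shear force, centrifugal loss, cooking
loss, moisture, fat, protein) are drawn around realistic baselines; a wired
trait is `mean + scale·(r·z + √(1−r²)·ε)` with `z` the standardized
log-intensity of its marker, so the population trait–marker correlation is
`r` by construction. The fatty-acid generator draws Gaussian samples around
the published per-group means ± sd of the 17 detected acids.

What the generator does **not** emulate: chromatographic drift, batch
effects, biological detection dropout, correlated lipid modules, or
non-log-normal heavy tails. Tests passing on this generator show the
pipeline's logic is correct under its stated assumptions, not that real
data satisfy them.

## QC filtering and reliability

A feature is removed iff its QC detection rate (fraction of QC cells
present and ≥ the 1000 cps floor) is **below** 0.5 or its QC CV (sample sd
over mean, n−1 denominator — the small-n convention for 5 replicates) is
**above** 0.3; both boundaries are kept. The floor enters only the
detection-rate computation, never as value truncation, which would distort
CVs. Filtering is idempotent, order-independent, and monotone in both
thresholds.

Reliability: pairwise Pearson correlation between QC injections on
natural-log intensities over shared-present features (pairs with <2 shared
features are flagged, not silently NaN), and a PCA of all samples on
mean-imputed, feature-centered log intensities. The dispersion statistic —
mean QC distance to the QC centroid over mean sample distance to the grand
centroid in PC1/2 — is ≪1 for a stable platform. The log transform before
correlation/PCA is this package's choice; the mirrored workflow does not
state its transform.

## Profile arithmetic

External standard curves are unweighted OLS of peak area on concentration
(1/x weighting optional); concentration is recovered by inverse prediction,
with negative estimates flagged below-range. Class/subclass accounting
tallies parsed species; unparseable names are listed, never dropped.
Composition shares are computed on raw (not log) intensities, since they
describe content shares. Fatty-acid totals are plain sums over member acids
per saturation class, and the unsaturation index is
UFA/FA = (MUFA+PUFA)/(SFA+MUFA+PUFA), reported at 3 decimals. In the shipped
reference profile two printed totals (NX PUFA, GS SFA) differ from their
component sums by one unit in the last digit — the printed components are
themselves rounded; the package reports component sums and the tests
document the ±0.001 gap instead of hiding it.

## Duncan's multiple range test

After a one-way ANOVA (MSE and error df exposed), a span of p ordered means
is tested against the least significant range
`LSR_p = q((1−α)^(p−1); p, df_e) · √(MSE/n_h)` with `n_h` the harmonic mean
group size (Duncan's convention for unequal n; the mirrored design is
balanced at n = 6). Protection is explicit: spans are tested from widest to
narrowest and an accepted (non-significant) span shields every enclosed
pair. Letters are the maximal accepted intervals over descending means plus
singletons, so two groups share a letter iff they are not significantly
different — verified against brute-force pairwise decisions. Studentized
range quantiles come from `scipy.stats.studentized_range` numerically
(cached), so arbitrary error df are supported without tabulated values.
With two groups the procedure reduces to the t-based LSD decision.

No correction is applied across variables when many features are tested
one at a time; that mirrors common practice and is a known statistical
limitation of this pipeline.

## RF-RFE marker screening

Each round fits random forests (default 1000 trees; scaled runs use fewer)
and estimates error on repeatedly held-out data. "One fifth held out, ten
repeats" is read as a stratified 20% evaluation split per repeat: per-tree
bootstrap OOB would make a 10-repeat average largely redundant, but it
remains available (`oob_mode="bagging"`). Importance defaults to
permutation accuracy on the held-out set (the MetaboAnalyst convention),
computed by a batched predict over per-feature-permuted copies; impurity
importance is an option. Each round removes the bottom 20% by mean
importance — `max(1, floor(0.2·p))` features, ties broken by feature id for
reproducibility — and importances are recomputed from scratch on the
surviving set. The panel is the smallest round achieving the trajectory's
minimal mean error.

Two caveats this implementation surfaces rather than hides:

- **Selection leakage.** Every round re-evaluates features that earlier
  rounds selected on the same 18 samples, so late-round errors are
  optimistic; even pure noise drifts below chance along the trajectory.
  The "no informative minimum" flag therefore uses the only selection-free
  estimate — the full-feature first round — and requires it to beat chance
  (1 − 1/k for balanced groups) by two binomial standard errors.
- **Panel-size collapse.** When markers are individually strong, the few
  markers needed to cover all groups already achieve the minimal error, so
  the smallest-round-at-minimum rule selects panels much smaller than the
  planted marker set. This is a property of the rule under noisy
  re-evaluation at small n, not a bug; the trajectory object retains every
  round so users can prefer a larger plateau round.

## Correlation networks

Marker log-intensities and quality traits enter one Pearson matrix
(pairwise deletion of missing cells; two-sided p from the exact t
transform; zero-variance or <3-observation pairs are undefined, never
silently zero). Edges are exactly the pairs with |r| ≥ 0.7 and p ≤ 0.05 by
default — the mirrored workflow acknowledges a plotting threshold without
printing it, so both cutoffs are configurable; no multiplicity correction
is applied to edge p-values by default (optional BH flag would be a
one-liner via statsmodels but is deliberately not the default to mirror
practice). Heatmap ordering uses average-linkage clustering of 1−r
distance. Networks export to GraphML and edge-list CSV, round-tripping
losslessly and byte-stably.

## Problem sizes used by the test suite

Simulation-based checks are scaled to keep the default run quick while
preserving the statistical question: marker recovery runs 8 studies of 200
features with 200-tree forests; QC behaviour uses 50 studies of 300
features; ANOVA calibration uses 2000 null datasets; the correlation
critical value uses 2000 replicates; Duncan letter consistency uses 1000
random instances. The pipeline's defaults remain the full study shape
(1000 features, 1000 trees).
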