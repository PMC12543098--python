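# Methods

This note documents the models, defaults, and numerical choices behind
`diacidseq`, and what its synthetic-data validation does and does not
establish.

## Pooled-fitness estimation

**Strain fitness.** Reads for each barcoded strain are compared between a
condition sample and its time-zero control. Sample counts are first scaled
by the library-size ratio (total t0 reads / total sample reads); strain
fitness is the log2 ratio of scaled sample reads to t0 reads with a
pseudocount ε added to both (default ε = 0.5). The pseudocount keeps strains
that drop to zero reads finite and shrinks extreme ratios at low counts.

**Gene fitness.** Only insertions with position fraction in [0.10, 0.90]
contribute: insertions near either gene end often leave a functional
protein. The gene score is the weighted mean of its passing strains with
weights

    w_i = 1 / (1/(n_{0,i} + ε) + 1/(n_i·s + ε)),

the inverse of the delta-method variance of a log-ratio of two counts. This
down-weights low-count strains. Genes with no passing strain are reported as
masked, never as zero — absence of evidence is not neutrality.

**Normalization.** Per experiment, the median gene fitness is subtracted,
encoding the assumption that the typical gene is neutral in any one
condition. The normalization absorbs any constant offset in the raw
log-ratios (e.g. overall depth changes), which also makes the t-scores
invariant to such offsets.

**t-score.** t = fitness / sqrt(max(s², σ²_floor)/n), where s² is the
weighted within-gene variance across mutants (with the n/(n−1) small-sample
correction) and σ²_floor = 0.25 (fitness² units). The floor prevents genes
whose few mutants agree by chance from reaching arbitrarily large |t|; a
single-mutant gene uses the floor alone. This estimator is deliberately
simple — it uses the named ingredient (between-mutant variance) without a
hierarchical prior; the floor plays the regularizing role a prior would.

**Replicates.** Biological duplicates are combined by unweighted means of
both fitness and t. Averaging t (rather than recomputing it from pooled
strains) is a convention; it is conservative in that a condition passed by
only one replicate keeps that replicate's values unmasked.

## Phenotype classification

Significance: |fitness| > 1 and |t| > 4, both strict. Specificity: at least
one significant experimental condition *and* |fitness| < 1 on the control
carbon source (D-glucose, or DL-lactate where glucose is not utilizable).
A masked control cell fails the screen conservatively. An alternative rule
(`control_rule="no_significant"`), under which the control merely must not
itself be significant, is exposed because the two phrasings circulate
interchangeably; the |fitness| < 1 form is the default as the stricter,
operational one.

Protocatechuate counts as an experimental (non-control) condition — its
catabolism passes through a diacid intermediate — but contributes no DA/FA
class label; likewise acetate is experimental but classless. Chain-length
parity and range are computed over significant DA/FA conditions only.

## Profile comparison

Pearson correlations between gene fitness vectors use only conditions
observed in both genes, require ≥ 3 shared conditions (configurable), and
return null for constant restrictions. Imputation for embedding input is
k = 2 nearest neighbours under the nan-Euclidean distance (squared
differences averaged over co-observed columns, rescaled by total column
count), with the missing cell replaced by the unweighted mean of the
donors' values; it delegates to scikit-learn's `KNNImputer`, which
implements exactly these semantics. The embedding itself (t-SNE, perplexity
25, 50,000 iterations, early exaggeration 100) is treated as visualization
plumbing: the package guarantees its input (a complete matrix) and records
its parameters, but does not test the stochastic projection.

## Synthetic data: the stated world

The generator emulates one organism's experiment set: DA and FA carbon
sources at chain lengths C4–C10 and C12, acetate, protocatechuate, and a
glucose control, in biological duplicate (19 conditions, 40 sequenced
samples). Defaults: 200 genes, Poisson(15) insertions per gene conditioned
≥ 1, 20% intergenic strains, log-normal (σ = 1) time-zero abundances,
multinomial sampling at depth 10⁶ per sample. Depths, strain densities and
generation counts are field-typical conventions — the assays themselves
report none — and true fitness is expressed directly in per-experiment
log2 units (generation scaling folded in).

Ground truth is pathway-structured: 30 DA-only and 20 FA-only genes with
defects of −4 on contiguous chain-length windows (width 2–4), 10 genes hit
in both classes, one repressor with +13.55 on glutarate and +4.7 on
protocatechuate, and 5 control-driven decoys (−2 on glucose only) that must
never be called specific. Intergenic strains are retained with true fitness
0 so the central-gene filter is exercised.

What a green parameter-recovery test establishes: the estimator recovers
median-centered truth with RMSE < 0.3 at this depth and strain density, the
classifier detects |f| ≥ 3 defects with > 95% sensitivity, and the control
screen rejects control-driven genes. What it does not establish: robustness
to sequencing error, barcode collisions, chimeric reads, insertion-site
bias, condition-dependent bottlenecks, or over-dispersion beyond
multinomial (a Dirichlet perturbation hook exists but is off by default).

## Stoichiometric model and MTY

The core template is a deliberately small, element-balanced network: TCA
cycle, glyoxylate shunt (serving as the anaplerotic route), malic enzyme +
pyruvate dehydrogenase (the cataplerotic link that lets C4 intermediates
feed acetyl-CoA), glutamate dehydrogenase + glutamine synthetase for
nitrogen assimilation, and lumped respiration: NADH and FADH2 oxidases pump
4·(P/O) periplasmic protons each (defaults P/O 2.5 and 1.5), an ATP
synthase imports 4 H⁺ per ATP, and an irreversible proton leak dissipates
excess proton-motive force (it can consume PMF, never create it). The PMF
lives entirely in the periplasmic proton, which has no free exchange — so
proton-symport import carries a real energetic cost. CO2 exchange is
secretion-only; at an MTY optimum all substrate carbon leaves as
indigoidine or CO2, which the tests assert as an equality.

Pathway additions per Cn diacid: symport with 2 H⁺ (n ≤ 6) or ABC import
hydrolyzing 2 ATP (n ≥ 7); AMP-forming CoA ligase (ATP → AMP + PPi, with
pyrophosphatase, i.e. 2 ATP-equivalents — the ligase type is a modeling
choice); β-oxidation rounds releasing acetyl-CoA down to succinyl-CoA
(even n, (n−4)/2 rounds) or glutaryl-CoA (odd n, (n−5)/2 rounds); and for
odd chains the decarboxylative route (glutaryl-CoA → crotonyl-CoA + CO2,
then hydration/oxidation/thiolysis to two acetyl-CoA). Succinate (C4)
enters the TCA cycle directly after transport; malonate (C3) and acetate
are outside the pathway builder's scope. The CoA-independent glutarate
route is deliberately not modeled.

Indigoidine synthesis is 2 gln + 2 O2 + 2a ATP → indigoidine + (6−2a) H2O +
2a ADP + 2a Pi + 2a H⁺ with a = ATP per glutamine (default 1, the
adenylation cost; configurable). The fixed formula C10H8N4O4 drives the
10-carbon yield factor: carbon_yield = 10·v_ind/(n·uptake).

Metabolite formulas follow the ionized (BiGG-style) convention inside the
model so reactions balance against standard cofactor formulas; the
yield-accounting module uses neutral acids (CnH(2n−2)O4) for molar masses.
The same modification code applies to any SBML Level 3 FBC model loaded via
`load_sbml`, which is the intended route for genome-scale reproductions;
the shipped core template exists so every test runs offline. Core-template
MTYs are upper-bound estimates of a different network than a genome-scale
model's and are not expected to match genome-scale values exactly.

## Yield accounting

Molar masses use CODATA atomic weights to two decimals. The colorimetric
calibration is read as concentration (g/L) = 0.268·OD612 − 0.0109 — the
"correlate OD to g/L" orientation — with negative predictions clamped to
zero. Carbon incorporation divides product carbon (titer / 248.20 g·mol⁻¹ ×
10 C × 1000) by the medium's total carbon in mmol/L; percent-of-MTY divides
that fraction by the carbon-mole-weighted model ceiling.

## Numerical choices and degenerate inputs

- LPs are solved with GLPK via cobra; toy networks are cross-checked
  against exhaustive basic-point enumeration in the tests.
- Imputation neighbour ties break by row order (scikit-learn's stable
  ordering); a row with no observed cells is an error, not silently filled.
- Empty call sets summarize to zero counts with an explicit `empty` flag
  rather than undefined percentages.
- Expectation-mode simulation rounds expected counts to integers; exactness
  tests therefore carry a small tolerance, and conditions dominated by a
  2^13.55-fold-enriched mutant push other strains to the rounding floor —
  a property of sequencing depth, not of the estimator.
- Masked (NaN) cells are excluded from every statistic; a masked control
  fails the specificity screen.

## Limitations

- The t estimator is not the hierarchical-prior version used by the public
  fitness-browser pipeline; deposited t-values will differ in detail.
- Chromosomal-position bias correction, cofitness networks, and
  library-quality ("passed metric") flags are out of scope; quality flags
  are consumed as metadata if present.
- The core template omits biomass (a biomass sink can be enabled but is off
  by default), so MTYs are pure product ceilings with no growth coupling.
- Sequence identity tables are inputs from an external aligner; the package
  does not re-implement protein alignment.
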