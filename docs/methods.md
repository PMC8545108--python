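# Methods

## Scope and model

`domthermo` scores the thermodynamic quality of soil dissolved organic
matter (DOM) from ultrahigh-resolution (FT-ICR) mass-spectral peak lists and
links that quality to soil properties and the bacterial community. The
chain is: peak-list reduction → molecular-formula assignment → per-compound
thermodynamics → sample summaries → regression / multivariate linkage →
phylotype classification. A synthetic-data generator emulates a six-site,
three-treatment, three-replicate survey (54 samples) so that every stage is
testable against planted ground truth without any external data.

### Thermodynamic scoring

For a neutral molecule C_cH_hN_nO_oS_sP_p with net charge Z, the nominal
oxidation state of carbon is

    NOSC = 4 − (−Z + 4c + h − 3n − 2o + 5p − 2s) / c

and the standard-state Gibbs energy of the carbon-oxidation half reaction,
per mole of carbon, follows the empirical linear relation

    ΔG°Cox = 60.3 − 28.5 · NOSC   [kJ (mol C)⁻¹].

Z is taken as 0 for every assigned compound (formulas are reported for the
neutral molecule after deprotonation is undone). Positive ΔG°Cox means the
half reaction is endergonic at standard state and must be coupled to a
terminal electron acceptor; higher values therefore mean poorer substrate.
A sample's substrate quality is the **median** ΔG°Cox over its assigned
compounds (even counts average the central pair).

### Peak-list funnel

1. **S/N filter** — peaks with signal-to-noise strictly below 6 are
   discarded; S/N exactly 6 is kept.
2. **Blank subtraction** — peaks within 1 ppm of any procedural-blank peak
   are removed.
3. **Alignment** — all samples' peaks are pooled, sorted by mass, and
   single-linkage-clustered with a 1 ppm gap threshold; the consensus mass
   is the intensity-weighted member mean. This is deterministic and
   invariant to sample order. If one sample contributes two peaks to a
   cluster, the more intense peak represents it (logged).
4. **Occurrence filter** — consensus peaks present in fewer than 6 samples
   are dropped, removing the long singleton tail. The threshold is a
   config knob (`min_occurrence`); 6 is the default because the emulated
   design has six sites.

Peak counts are monotone non-increasing through the funnel; the pipeline
manifest records each stage's count.

### Formula assignment

Observed m/z values are deprotonated-ion masses ([M−H]⁻); the neutral mass
adds one proton mass (1.007276467 Da). Candidate formulas are every
composition within the element limits C 0–100, H 0–200, O 0–30, N 0–4,
S 0–2, P 0–1 whose mass lies strictly within 1 ppm of the neutral mass.
The search enumerates heavy-atom compositions from a cached grid and
inverts the hydrogen count (only h = round(residual/m_H) ± 1 can land in a
sub-mDa window), pruning compositions whose residual is unreachable; an
independent no-pruning Cartesian enumerator exists purely as a test oracle.
Exact masses are pinned: ¹²C = 12, ¹H = 1.007825032, ¹⁴N = 14.003074005,
¹⁶O = 15.994914620, ³²S = 31.972071174, ³¹P = 30.973761998.

Selection among candidates: (1) reject P-bearing candidates with fewer
than four oxygens (phosphate/phosphonate chemistry) and carbon-free
compositions; (2) fewest heteroatoms (N+S+P); (3) smallest |mass error|;
(4) lexicographic (c,h,n,o,s,p). Heteroatom parsimony is ranked above
error because it is the conventionally dominant rule in CHNOSP assignment
and yields a total order; the alternative ordering is a one-line change.
No nitrogen-rule or ring-double-bond filters are applied by default — they
are not part of the assignment contract here.

### Compound classes

Elemental classes are CHO / CHNO / CHOS / CHNOS with any P-bearing formula
in its own "P-containing" class. Van Krevelen biochemical classes use a
priority-ordered rectangle table on molar O/C (x) and H/C (y): lipid
(O/C [0,0.3), H/C [1.5,2.5)), protein (O/C [0.3,0.67), H/C [1.5,2.3),
requires N), carbohydrate (O/C [0.67,1.2], H/C [1.5,2.5)), lignin
(O/C [0.1,0.67), H/C [0.7,1.5)), tannin (O/C [0.67,1.2], H/C [0.5,1.5)),
condensed aromatic (O/C [0,0.67), H/C [0.2,0.7)). Published schemes vary;
the table is an argument, not a constant, so any alternative can be
substituted. Points outside all rectangles are "unassigned".

### Community statistics

Rarefaction subsamples each sample to exactly 7,000 reads without
replacement (multivariate hypergeometric draw); shallower samples are
dropped, not scaled. Richness is the nonzero-taxon count. Faith's
phylogenetic diversity sums the branch lengths of every edge whose subtree
contains an observed taxon — the minimal rooted spanning subtree including
the root connection; the test oracle recomputes it as the union of
root-to-tip paths. Bray–Curtis dissimilarity d = Σ|x−y| / Σ(x+y) serves
both the community (counts) and DOM occurrence matrices
(presence/absence by default, intensities by flag).

### Linkage statistics

Mantel correlation is the Pearson correlation of strictly-lower-triangle
distance vectors, tested one-sidedly by simultaneous row/column permutation
with the add-one estimator p = (1+hits)/(1+n_perm), default 999
permutations. Procrustes uses the symmetric convention (both
configurations centered, unit sum of squares) so the residual
m12² = 1 − (Σσ)² lies in [0,1]; PROTEST permutes sample rows. Ordination
is classical principal-coordinates analysis (double-centered −D²/2,
eigendecomposition); metric PCoA replaces stress-based NMDS because it is
closed-form and deterministic, and the vector-fitting inference downstream
is agnostic to the ordination method — an externally computed ordination
can be supplied instead. Vector fitting regresses a centered variable on
the ordination scores; r² is the explained variance fraction and p comes
from permuting the variable. All permutation procedures accept
`exhaustive=True` (all n! relabelings, identity included), used by tests at
n = 5–6.

The multinutrient cycling (MNC) index is the mean of seven nutrient
Z-scores (SOM, total N, alkaline hydrolytic N, total P, available P,
total K, available K), using the n−1 standard deviation. SOM participates
both in MNC and as a standalone response. Simple regressions use
closed-form OLS with the slope t-test; no multiple-testing correction is
applied across the handful of headline regressions (a Benjamini–Hochberg
step would be trivial to add but is deliberately not the default). The
site-combination scan refits a regression on every k-subset of sites and
reports the significant fraction.

### Phylotype classification

Ubiquitous phylotypes are those detected in ≥ 5 of 6 sites (the ">4/6"
reading; ≥ 4 "more than half" and per-treatment-sample modes are available
via `min_sites`/custom site maps). Each ubiquitous taxon's relative
abundance (after rarefaction) is correlated with sample median ΔG°Cox and
with SOM, by both Spearman (mid-ranks, t approximation, exact permutation
for n ≤ 8) and Pearson. Classification defaults to Pearson at α = 0.05:
taxa significant with ≥ 1 variable enter the significant set; cluster I
requires every significant correlation to follow (−ΔG, +SOM), cluster II
the mirror; other sign patterns are unclassified with a conflict flag;
"core" taxa are significant with both. Negating ΔG swaps labels exactly
for taxa whose significance involves ΔG alone; core taxa become sign
conflicts (their SOM association is untouched), and negating both
variables is the exact mirror — the tests check precisely these scoped
symmetries.

## Synthetic data: what it emulates and what it does not

The generator plants every association the pipeline is meant to detect:

* **Formula library** (default 800 formulas, 150–800 Da) drawn to a
  ~45/37/12/4/2% CHO/CHNO/CHOS/P-containing/CHNOS mix via per-class
  quotas. Each formula is pairwise mass-unique within 1 ppm **and** must
  win the assignment ranking against every rival composition within a
  2.5 ppm guard band (no rival with as few heteroatoms); without this
  well-posedness constraint a sizable fraction of random heteroatom-bearing
  formulas would be legitimately outranked by CHO near-isobars and planted
  recovery would be ill-defined rather than a test of the code.
* **Peak lists**: presence probabilities combine a skewed per-formula
  baseline with a logistic tilt of each formula's ΔG°Cox rank by the
  sample's target median ΔG°Cox, so realized sample medians track their
  targets (r ≈ 0.97). Mass error is multiplicative Gaussian
  (σ = 0.2 ppm default), intensities log-normal, 10% of real peaks fall
  below S/N 6, per-sample unassignable random-mass decoy singletons
  exercise the "no formula" path and are removed by the occurrence filter,
  and 15 contaminant masses recur in all samples and in two blank lists.
* **Soils**: site-mean SOM spans ~12–49 g/kg, pH ~4.9–8.1; target median
  ΔG°Cox = −√R²·z(SOM) + √(1−R²)·ε mapped to a 66 ± 1.5 kJ (mol C)⁻¹
  band, with the population R² set to 0.15 by default. The *realized* R²
  at n = 54 has wide sampling spread (roughly 0.03–0.33 across seeds);
  calibration is therefore asserted on the 20-seed mean.
* **Community**: 400 taxa (tests use 200: 40 + 40 planted, 120 null) on a
  random bifurcating tree with exponential branch lengths. Planted taxa
  get latent Gaussian scores correlated with the standardized composite
  driver z(−ΔG) + z(SOM) at latent ρ = 2·sin(π·ρ_s/6) for a target
  Spearman ρ_s = 0.6 (Gaussian copula), shifting log-abundance before a
  multinomial draw at depths 8,000–16,000.

Not emulated: instrument transients and resolution-dependent peak shapes,
isotopologs and adducts, chimeric reads, compositional coupling between
taxa beyond the multinomial constraint, spatial autocorrelation among
sites, and measurement error in soil chemistry. Passing the planted-truth
tests therefore demonstrates the pipeline's correctness and sensitivity at
realistic effect sizes — not that real soils satisfy the generator's
independence assumptions.

## Numerical choices

* ppm comparisons are strict (`< 1 ppm`) for assignment, inclusive
  (`≤ tol`) for blank matching and alignment gaps.
* Permutation p-values: add-one estimator (Monte Carlo) or exact fraction
  (exhaustive); comparisons use a 1e-12 slack so ties count as hits.
* Eigendecomposition uses the symmetrized Gram matrix; negative PCoA
  eigenvalues (semimetric input) are kept in metadata, excluded from scores.
* Matrix TSVs are written with `%.17g` so doubles round-trip exactly.
* Degenerate inputs error loudly by policy: carbon-free NOSC, zero-variance
  nutrients or regressors, all-zero sample pairs in Bray–Curtis, samples
  with no assigned compounds.

## Problem sizes used in the tests

Unit tests run on 54-sample bundles with 80–120 formulas and 60–200 taxa;
the recovery tests use 500 formulas (one seed) and 200 taxa (20 seeds);
oracle-equivalence checks use 50 random masses against the full Cartesian
enumerator and exhaustive permutations at n = 5–6. The full suite runs in
about a minute on one CPU.

## Known limitations

* Assignment considers only [M−H]⁻ (and [M+H]⁺ for generality); no
  multiply charged ions, adducts, or isotope-pattern scoring.
* The heteroatom-before-error precedence is a documented convention; tools
  differ, and borderline peaks can legitimately differ between packages.
* Spearman p-values at 8 < n < ~25 rely on the t approximation.
* The van Krevelen table is one published-style scheme among several; class
  proportions are sensitive to boundary choices.
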