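# Methods

## The experimental setting being modelled

The package targets trials in bedded semi-field facilities: two beds,
each split into two independent half-bed units of 150 sown rows at 0.25 m
spacing, one inbred line per row, with a sub-surface water gradient that
makes half of every row a "wet" and the other half a "dry" observation
(up to 1200 half-row records for ~70 lines).  Minirhizotron tubes under
one unit per bed photograph roots every 5 cm of soil depth (0.4–2.7 m) at
three time points during the season; visible root length per image is
summed into total (TRL), shallow (100–120 cm, SRL) and deep (120–180 cm,
DRL) root length per tube and time point.  The shared 120 cm boundary is
counted once, in the deep window (windows `[100,120)` and `[120,180]`),
so TRL = SRL + DRL + length outside both windows holds exactly.

## Spatial covariance structures

Environmental trend along the row axis is modelled with row-level random
effects whose correlation comes from overlapping neighbour windows.  For
target rows i and loading matrix X (rows of X indexed by target rows,
columns by real-plus-virtual rows of the layout):

* `S_knn`: X holds indicator loadings on the target row and its k = 5
  nearest rows per side; `S = XX' / (tr(XX')/n)`.  Interior entries are
  exactly `(11-d)/11` at row separation d (0 beyond 10).
* `S_euc`: the same window, but loadings decay linearly with physical
  distance, `w = 1 - d/d_max` with `d_max = 2.75 m` (the span of 11
  rows).  Relative to `S_knn` this weights close neighbours more and
  distant neighbours less: the euc/knn correlation ratio decreases with
  distance from lag 2 on (from lag 0 to 1 it necessarily rises, both
  diagonals being 1).  An alternative reading — every row within
  `d_max` per side contributes — is available via `restrict_to_k=None`;
  it makes the euc correlations larger than knn at every lag, which does
  not match the reported behaviour of the two structures, and is
  therefore not the default.

Virtual rows pad each unit edge by `max(k, ceil(d_max/spacing))` so every
real row has a complete window; they occupy loading columns only.  Units
never share neighbours.  Trace normalisation uses n = number of real
target rows, making every interior diagonal exactly 1.

## Genomic relationships

Dosages (0/1/2, NaN missing) pass a fixed QC chain: SNPs with > 10 %
missing data, then lines with > 10 % missing data, then SNPs with
MAF < 3 % on the retained set.  Residual missingness is mean-imputed
(2p̂ per SNP).  The relationship matrix is VanRaden's first method,
`G = MM'/(2Σp_j(1-p_j))` with M centred by twice the counted-allele
frequency computed from the analysed sample.  For inbred material the
average diagonal d(G) approaches 1 + F; the synthetic generator's default
population gives d(G) ≈ 1.86.

## Mixed models

Above-ground model (per trait): combined unit-bed-treatment fixed cell
means plus random additive genomic (kernel G), line (identity), neighbour
genomic and neighbour line (each observation loads the lines of its left
and right flanking rows with coefficient 1 — the factor 2 in the
phenotypic-variance formula below reflects exactly two neighbours), row
(identity), genotype-by-treatment (kernel `diag(G, G)` over line ×
treatment levels), line-by-treatment (identity), one spatial term per
water treatment (kernel `S_knn` or `S_euc` over rows), and residual.
Root model: bed-camera-time fixed cells (bed-time if no camera column);
random genomic, line and row(tube) terms plus one spatial term per time
point; tube records at different time points are repeated measures
sharing the row effect.  No neighbour terms in the root model.

### AI-REML

`MixedLMM.fit()` maximises the restricted likelihood over the variance
components.  Implementation choices, all of which matter in practice on
these heavily structured designs:

* The restricted log-likelihood convention includes `- log|X'X|`, making
  values exactly equal to the density of any orthonormal error-contrast
  projection.
* Updates: two monotone EM burn-in iterations, then average-information
  steps taken on the log-variance scale (`theta * exp(delta)`), clipped
  at a factor e^3 and step-halved until the likelihood does not decrease.
  Two escapes handle likelihood-ridge crawls, where monotone steps make
  steady but uselessly small progress: if no step fraction is monotone
  and the EM gain is below 1e-3, a quarter AI step with a bounded dip
  (0.5 log-likelihood units) is accepted; and if the gain over the last
  ten iterations sits between 1e-3 and 1, the full AI step is accepted
  with a dip of up to 50 units.  The best visited point is restored at
  the end if an excursion never pays off.  Pure multiplicative updates
  can never drive a variance negative.
* Active set: a component below 1e-4 of the phenotypic variance whose
  gradient points downhill is pinned at the floor (1e-8 of the
  phenotypic variance) for the rest of the fit — near-boundary curvature
  otherwise poisons the AI system and EM takes hundreds of iterations to
  shuffle the last 1e-4 of variance.  Terms no observation loads are
  floored immediately.  Floored components are reported, never dropped.
* Convergence: maximum relative component change < 1e-8 or restricted
  log-likelihood change < 1e-9 (defaults; the simulation studies shipped
  with the package call `fit(ltol=1e-6)`, which was verified to leave
  every estimate and standard error unchanged to four decimals while
  cutting iterations several-fold).  Non-convergence is flagged on the
  results object, and standard errors are reported only at convergence.
* Standard errors are square roots of the diagonal of the inverse AI
  matrix at the solution.  Fixed-effect rank deficiency is resolved by
  dropping dependent columns in first-occurrence order.
* Dense linear algebra throughout (V is n × n, inverted via Cholesky +
  `dpotri`); at the intended sizes (n ≤ ~1500, ≤ ~700 effect levels)
  sparse methods buy nothing.

On likelihood ridges — in particular between the genomic term (kernel G
with average diagonal ≈ 1.86) and the identity line term, which only the
off-diagonal family structure of G separates — REML point estimates can
legitimately sit on the zero boundary for one of the two components while
the other absorbs the shared variance; the reported AI standard errors
are large in exactly these directions.

### Genetic parameters

Phenotypic variance per context i (treatment for above-ground, time
point for roots) sums the components:
`σ²_P,i = d(G)σ²_g + σ²_l + 2d(G)σ²_gn + 2σ²_ln + σ²_r + d(G)σ²_tg +
σ²_tl + σ²_s,i + σ²_e` (above-ground) and
`σ²_P,k = d(G)σ²_g + σ²_l + σ²_r + σ²_s,k + σ²_e` (roots).
Heritabilities: `h² = d(G)σ²_g / σ²_P`, `H² = (σ²_l + d(G)σ²_g)/σ²_P`.
Both a d(G)-scaled and an unscaled variant are produced: the published
variance-component tables this package's worked examples reproduce are
internally consistent only when the d(G) factors are omitted from both
numerator and σ²_P (e.g. grain yield: 0.23/1.09 ≈ 0.21 matching the
printed average 0.22, against 0.43/1.30 ≈ 0.33 with the factors), so the
unscaled variant is the table reconciliation and both are reported side
by side.  `GCV = 100·σ_g/x̄` with x̄ the overall trait mean.

## Cross-validation and prediction quality

Variance components and fixed effects are estimated once from the full
data.  Corrected phenotypes are `y_c = y - Xb̂`.  For each line, all its
records are deleted, the mixed-model solution is recomputed at the fixed
variance components, and the line's GEBV is predicted through G (the
BLUP of an unobserved level, `σ²_g G Z' P y`).  Predictive ability is the
correlation between `y_c` and the paired line GEBVs at observation level
(line-mean pairing available as an option); the ceiling is
`maxPA = sqrt(n h²/(1+(n-1)h²))` with n the mean records per line, and
ACC = PA/maxPA.  Dispersion is `b_wp = cov(ĝ_whole, ĝ_partial) /
var(ĝ_partial)`; 1 means no inflation.  Standard errors come from an
ordinary non-parametric bootstrap (resampling observation pairs for PA
and line pairs for b_wp; 10,000 replicates by default).  Two models
sharing the corrected phenotypes are compared with the Hotelling-Williams
t-test on dependent correlations (df = n - 3, two-sided).

Note that LOO predictive ability is bounded by between-line relatedness,
not only by h²: PA approaches maxPA only as the left-out line's relatives
approach genetic copies.  In both the published study and the package's
synthetic experiments ACC sits around 0.45–0.65.

## The synthetic-data generator

`simulate_experiment` draws a complete experiment from one seed (named
substreams per component, so adding draws to one component never shifts
another's):

* Genotypes: per-SNP allele frequencies uniform on (0.05, 0.5); 12 fully
  inbred founders; each line inherits either parent's allele per SNP from
  a random founder pair (a doubled-haploid-like derivative, no linkage),
  with residual heterozygosity 0.05.  This produces the full/half-sib
  family structure genomic prediction relies on and d(G) ≈ 1.86.
  Optional per-entry missingness exercises the QC chain.
* Above-ground records: one record per real row and treatment, drawn
  exactly from the above-ground model equation.  Default variance
  components are the study-scale magnitudes for each trait (e.g. grain
  yield 0.23/0.11/0.13/0.12/0.06/0.48 for g/l/r/s1/s2/e with zero
  neighbour and interaction variances, matching the finding that no
  relevant interaction effects exist); treatment means default to the
  published fixed-effect estimates (wet 7.20, dry 6.91 t/ha for yield),
  plus small unit-bed offsets (SD 2 % of the trait mean).  Kernel draws
  use Cholesky factors of G and S (jitter 1e-8).
* Root images: latent tube × time TRL from the root-model equation
  (defaults at the study's TRL magnitudes; mean TRL 20/34/46 cm across
  time points), truncated at zero, then allocated over the 5 cm depth
  grid (40–270 cm) by a Gaussian depth profile whose mean deepens over
  time (80/110/140 cm, SD 30/35/40 cm) — so image sums reproduce the
  latent total exactly and the deep-window share grows with time.  The
  profile is a modelling convenience: only the summarisation contract
  matters, and no claim is made that real depth profiles are Gaussian.

What the generator does not emulate: linkage disequilibrium decay along
chromosomes, selection structure between breeding cycles, heteroscedastic
or non-Gaussian measurement error, image segmentation noise, and 2-D
(across-bed) spatial trend.  Passing recovery tests therefore show the
estimation machinery is correct under the stated model, not that the
model is adequate for any particular real facility.

## Data editing

Records of lines without genomic information are removed; per trait,
values outside ±3 SD of the unedited column mean are removed in a single
pass (sample SD; a zero-SD column is a no-op).  Editing is global by
default with an optional grouping column; re-applying the edit re-derives
the statistics and may remove more — the single pass is the contract.
Border-row exclusion is treated as a property of the input data.

## Problem sizes and runtimes shipped with the package

The recovery study runs 20 replicates at the full design (70 lines,
~1200 records, 10 variance components; a fit converges in typically
11–20 AI iterations); the cross-validation studies use 30–70 lines.  The
acceptance script fits one above-ground and one root model and
cross-validates the former with 1000 bootstrap replicates.

## Known limitations

* Single-trait models only; the multi-trait genetic-correlation analysis
  is out of scope.
* Heterogeneous residual variances (per treatment or time point) are not
  supported; heterogeneity enters through the spatial terms only.
* AI standard errors are asymptotic and understate uncertainty for
  components at or near the zero boundary.
* The LOO solver re-factorises the training covariance per fold (no
  low-rank downdating); at ~70 lines this costs seconds, not minutes.
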