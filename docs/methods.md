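# Methods

`beegradient` implements a quantitative synthesis of multi-study wild-bee
survey data along two agricultural stressor gradients — pesticide hazard in
the focal field and the loss of semi-natural habitat (SNH) in the
surrounding landscape — together with a synthetic multi-study generator that
makes the whole pipeline testable without any external data.  This note
documents the models, the defaults and the numerical choices, and what the
synthetic tests do and do not show about real data.

## Pesticide hazard quotients

Per site, the hazard quotient sums the log ratio of application rate to
honey-bee LD50 over the site's N pesticide applications:

    HQ = Σ_{n=1}^{N} log( application_rate_n [g a.i./ha] / LD50_n [µg/bee] )

The log captures the nonlinearity of dose–response curves; contributions can
be negative (rate below LD50) and are never floored.  Resolution cascade per
active ingredient:

* **Unbounded LD50s** ("> x", limit-test minima) enter at their bound value
  x — the most conservative number available.
* **Missing oral LD50** falls back to the contact LD50 as a proxy (and
  symmetrically for the contact pathway).  The **both** pathway takes the
  per-ingredient minimum of oral and contact, the most conservative choice;
  no standard definition exists, so this is declared here.
* **Missing application rate** falls back to the label-default rate carried
  in the product/toxicity table (mirroring rates "recommended by the
  national product label").
* **Type-only records** (no ingredient at all) and ingredients with no LD50
  on either pathway receive the mean per-application contribution of the
  same pesticide type and production system within the same study; if that
  stratum is empty, the cross-study mean of the same type and system; if no
  stratum exists anywhere, 0 with a warning.  Filling a stratum with its own
  mean leaves the stratum mean unchanged (a tested invariant).

The log base (natural by default, base-10 optional) rescales every HQ by a
positive constant; because all models standardize HQ within datasets, every
downstream standardized estimate is invariant to the base (tested to ten
significant digits).  Exposure-pathway selection follows the synthesis
recipe: per pathway, the mean absolute Pearson correlation between
within-dataset-standardized HQ and the standardized abundance, richness,
functional and phylogenetic diversity; the argmax wins, ties resolved in
favour of oral.

Pesticide-use intensity is the binary alternative where no spray records
exist: conventional → high, organic → low; it is modelled 0/1, never
together with HQ in one model.

## Community descriptors

Computed per site after three preprocessing steps: the managed honey bee
(*Apis mellifera*) is excluded from every metric; abundance is divided by
sampling effort (individuals per sample unit); metrics are computed per
(year, method) panel, then averaged over years within a method and then over
methods, so unbalanced designs do not bias site values.  Sites averaging ten
or fewer bees per panel are flagged and excluded from the models.

* **Richness**: observed species count; **rarefied richness** uses the exact
  hypergeometric formula for m ≤ N and Chao1-based extrapolation above N
  (bias-corrected form when no doubletons exist).  The reference m is the
  smallest positive site total of the dataset, so within a dataset
  rarefaction interpolates; this reference is configurable because the
  synthesis did not fix one.
* **Functional space**: per dataset, a Gower dissimilarity over six traits
  (continuous body size; categorical lecty, sociality, nest location,
  nesting strategy; binary kleptoparasitism).  Missing trait values are
  handled by pairwise deletion with weight renormalization — no imputation.
  Per-trait weights are balanced by constrained optimization so every
  trait's partial dissimilarity correlates equally with the total
  (gawdis-style); constant traits are excluded with weight 0.  The space is
  a classical-scaling (PCoA) embedding of the square-root-transformed
  dissimilarities (the square root renders Gower input effectively
  Euclidean; the transform is a switch, and without it Euclidean input is
  reproduced exactly).  Four axes are retained by default, capped at S − 1.
* **Functional diversity (FD)**: total branch length of the UPGMA dendrogram
  of the Gower dissimilarities, over the minimal root-inclusive subtree of
  the species present.  **Phylogenetic diversity (PD)**: the same quantity
  on the taxonomy tree (root → family → genus → species) with Grafen branch
  lengths — node height ((#descendant tips − 1)/(#tips − 1))^ρ, ρ = 1, root
  height 1 — which makes the tree ultrametric.  Including the root path
  (Faith convention) gives single-species sites a defined positive value.
* **Functional / phylogenetic MPD**: abundance-weighted mean pairwise
  distance, Σ p_i p_j d_ij / Σ p_i p_j over i ≠ j, in the PCoA space or
  along the tree.
* **FEve** (functional evenness): Villéger's index along the minimum
  spanning tree of the assemblage in functional space; requires S ≥ 3.
* **FSpe** (functional specialization): abundance-weighted mean distance to
  the unweighted centroid of the dataset-wide species pool, normalized by
  the pool maximum.

Both FEve and FSpe are invariant to rigid motions of the functional space
(tested to 1e−8).  Every metric matches an independent brute-force
implementation on small instances (exhaustive enumeration for rarefaction,
Prüfer-sequence enumeration of all spanning trees for the MST, naive loops
for WNODF and MPD).

## Stressor models

Continuous responses and predictors are z-transformed within datasets
(square root first for abundance and richness), which removes protocol
differences between studies and puts all slopes on a comparable standardized
scale.  Models are linear mixed models with a per-dataset random intercept
and independent (diagonal) random slopes for the continuous predictors —
the diagonal structure is robust at 20–36 groups — fitted by maximum
likelihood so likelihood-ratio tests between nested fits are valid.
P-values per fixed term come from LRTs refitting without the term under the
same random structure.  The HQ × SNH interaction is screened first and the
additive model reported as final when the interaction's LRT p exceeds 0.05.
Collinearity is monitored with variance inflation factors (VIF_j =
1/(1 − R²_j)).

Numerical details: the optimizer (L-BFGS with tight tolerances) is polished
by warm-restarting until the log-likelihood stabilizes, which makes
estimates reproducible to ~10 significant digits even on flat variance
surfaces; when every random variance sits at the zero boundary and the
Hessian is singular, the fit falls back to OLS (with which ML coincides at
the boundary) and is flagged `singular` — common here because z-scored
responses force dataset means to zero, so the intercept variance is often
exactly 0.  Fixed-effect CIs use normal quantiles on the ML covariance.

## Beta diversity: nestedness and directional turnover

Site × species abundance matrices (years averaged; fractional year-averaged
cells are rounded to integers so the one-individual swap moves of the null
model stay well defined) are ordered by increasing HQ or decreasing SNH,
ties broken by site id (recorded, since many sites share HQ = 0).  **WNODF** is computed on the matrix as ordered, never
re-sorted internally: a row pair (upper i, lower j) scores
100·|{k : 0 < x_jk < x_ik}| / |{k : x_jk > 0}| when row i occupies strictly
more cells than the nonempty row j, else 0; column pairs analogous; the
combined statistic divides the summed pair scores by the total number of
pairs.  This matches the reference implementation in vegan's `nestednodf`
exactly (cross-checked), including its use of binary fill — not abundance
totals — in the decreasing-fill condition.

The null model is a **quantitative swap**: repeatedly move one unit from the
diagonal to the anti-diagonal of a random 2 × 2 submatrix, rejecting moves
that would change the number of zero cells; row sums, column sums and fill
are preserved exactly (an asserted contract on every draw).  The chain burns
in for 10 × #cells accepted moves and is sampled every 5 × #cells proposals;
thinning counts proposals rather than accepted moves because accept-counted
thinning freezes the chain's state parity on tiny matrices (on a 2 × 2 the
ensemble would collapse onto one of the two admissible tables).  A matrix
admitting no valid move yields an ensemble of copies flagged degenerate.
999 nulls by default (199 in the fast acceptance settings); z = (observed −
null mean)/null sd.  Dataset z-scores are averaged within studies before a
two-sided one-sample t-test against 0, and the two gradients are compared
per study with a paired Wilcoxon signed-rank test (exact for ≤ 25 nonzero
differences, continuity-corrected normal above).

**Directional decomposition**: on occurrence data (years pooled), site pairs
shifted by three gradient positions (pair r with r + 3, skipping nearly-tied
neighbours) are decomposed with the Jaccard denominator: with a shared,
b lost (earlier-only) and c gained (later-only) species, D = (b+c)/(a+b+c),
turnover T = 2·min(b,c)/(a+b+c), nestedness component Nc = |b−c|/(a+b+c),
so T + Nc = D.  Each pair's T and Nc are attributed wholly to its net
direction (losing if b > c, gaining if c > b; balanced pairs to neither) —
the cited directional-response method publishes no formula, so this
attribution is declared here.  Per matrix, the paired losing-vs-gaining
values across site pairs give a small-sample-corrected Hedges' g
(J = 1 − 3/(4(n−1)−1), variance 1/n + g²/2n), and matrices are pooled by a
**DerSimonian–Laird random-effects meta-analysis**: τ² = max(0,(Q−df)/C),
weights 1/(v_i + τ²), I² = max(0,(Q−df)/Q)·100, H² = max(1, Q/df), pooled
test on a t reference with k − 1 df.  Crop attractiveness enters as a
moderator whose omnibus QM test runs first; the moderator is dropped at
p > 0.05, leaving the random-effects model.  Leave-one-out Cook's distances
(Δpooled² / var(pooled)) flag influential matrices.

## The synthetic generator

The generator emulates the synthesis' structure: 26 studies, 36 datasets
(ten studies contribute two), 18 sites per dataset, SNH uniform on [0, 0.8],
~30% organic sites, 2–10 applications per conventional site from a pool of
40 ingredients with type-specific lognormal LD50s and label rates (organic
sites get rare, low-rate applications), a 120-species pool in six families
with geometric clade sizes, and lognormal abundance propensities giving few
common and many rare species.

Planted effects are defined **on the standardized scale**: `beta_hq = −0.3`
and `beta_snh = +0.3` are the slopes the standardized regression of
z(√relative abundance) on z(HQ) and z(SNH) should recover.  Internally the
expected site total is M·exp(γ_hq·zHQ + γ_snh·zSNH + γ_int·zHQ·zSNH) with γ
calibrated from a delta-method estimate of the sqrt-scale noise of
negative-binomial totals (per-species dispersion 1.0 by default, a free
choice — real assemblages' dispersion is not reported), so that the
standardized slope equals the requested beta in expectation.  Species-level
hazard sensitivity is an ordered sequence (rarer species more negative)
applied through a softmax-style composition reweighting that leaves the
expected total untouched: totals carry the beta effects, composition carries
the nestedness.  This is what makes high-hazard communities statistically
nested subsets of low-hazard ones, giving the WNODF stage a testable
positive signal.  One root seed with per-purpose/per-dataset child streams
(`SeedSequence` spawn keys) makes every output reproducible and insensitive
to adding datasets.

`degrade_collection` overlays the pathologies of real compilations at the
synthesis' reported rates: 64% of LD50s unbounded, 6% oral LD50s missing,
3% of applications type-only, 10% of rates missing, trait missingness 24%
(body size), 28% (lecty) and 4% elsewhere.  A managed honey-bee column with
gradient-independent counts exercises the taxon-exclusion path.

**What passing tests show — and do not.**  Parameter recovery, coverage and
type-I behaviour hold under this generator's assumptions: log-linear
effects, negative-binomial noise, independent sites, gradients uncorrelated
by construction (|r| < 0.15, mirroring the synthesis' near-orthogonality).
They do not speak to spatial autocorrelation, detection differences between
sampling methods, phenological turnover within seasons, or confounding
between SNH and management intensity — none of which the generator
simulates.

## Problem sizes in tests and the acceptance script

Simulation-based checks use deliberately chosen sizes: parameter recovery at
30 datasets × 20 sites × 100 replicates; the planted-nestedness signal at 20
studies with default matrix dimensions and 199 nulls; null calibration of
the study-level t-test at 100 replicates of 20 smaller matrices (10 × ~20,
199 nulls).  `scripts/acceptance.py` runs the full pipeline at the default
study conditions with 199 nulls per ordered matrix; `--n-nulls 999` restores
the synthesis default.

## Known limitations

* The `both` exposure pathway and the directional attribution rule are
  declared definitions, not reproductions of an external reference.
* The gawdis-style trait balancing minimizes the spread of trait–total
  correlations numerically; it can settle in local optima for pathological
  trait tables (it then falls back to equal weights with a warning).
* Mixed models assume independent Gaussian residuals after standardization;
  heavy-tailed site effects will widen the planted-effect recovery bands.
* The swap chain's mixing is assessed only through the exchange contract and
  small-matrix enumeration; extremely sparse matrices mix slowly and may be
  flagged degenerate rather than sampled.
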