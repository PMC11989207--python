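# Methods

## Setting and scope

The package analyses a single-arm neoadjuvant rectal-cancer cohort in
which each patient carries baseline clinical MRI stages (cT, cN),
post-treatment pathologic stages (ypT, ypN) and MRI stages, regression
grades (mrTRG 1–5 radiologic, pTRG 0–3 pathologic), CD3+/CD8+ T-cell
densities in two tumor regions, tumor differentiation grade, and
disease-free/overall survival follow-up clocked from initial diagnosis.
It computes the response scores, derives the response endpoints, and
runs the contingency and survival statistics connecting them.  Stage
assignment itself (imaging, pathology, digital cell counting) is out of
scope: stages, grades and densities are inputs.

## Scores and endpoints

**Stage encoding.** Stage labels are AJCC/UICC 8th-edition text codes.
Substage letters (T3a–d, N1a–c, …) are collapsed to the integer stage
for all score arithmetic, because the NAR formula is defined on integer
stages; `Tis` maps to 0.  Encoders are total over the label grammar
`T{0–4}[a–d] | Tis`, `N{0–2}[a–c]` and reject everything else with an
error naming the offending value — an invalid label is never silently
coerced.

**Immunoscore.** Per marker-region (CD3-CT, CD3-IM, CD8-CT, CD8-IM) the
density percentile is computed against the analysis cohort itself with
the Hazen plotting position `100·(rank − ½)/n`, mid-ranks at ties.  The
convention is symmetric (cohort mean exactly 50), bounded away from
0/100, and standard for small cohorts.  The IS is the arithmetic mean of
the four percentiles; class *high* iff mean ≥ 62.  The boundary value 62
is classed high: the cutoff "distinguishes" the groups and ≥ is the
conventional closed side.  An external reference population would change
individual IS values but nothing about the module contract; none is
published for this cohort, so cohort-internal ranking is the default and
the only implemented reference.

**NAR score.** `NAR = (5·pN − 3·(cT − pT) + 12)²/9.61` (pathologic), with
post-treatment MRI stages substituted for the radiologic variant.  Over
the encoded domain (cT, pT ∈ 0–4; pN ∈ 0–2) the inner term ranges over
the integers 0–34, so attainable values form the finite set {k²/9.61}
and never equal the category boundaries 8 and 16 exactly; the boundaries
are nevertheless fixed as inclusive-intermediate ("8 to 16") for the
contract.  A pCR patient (ypT0, ypN0) with baseline cT ≥ 2 has
NAR ≤ 36/9.61 ≈ 3.75, always *low* — which is why a printed table
showing one intermediate-NAR pCR patient cannot be formula-consistent
(see below).

**Endpoints.** pCR = pTRG 0 **and** ypN0 (the conventional ypT0N0
reading; the source tables are compatible with either reading and never
state it); near-pCR = pTRG ≤ 1; radiologic complete response =
mrTRG 1; combined stratum = IS-high and mrTRG 1.  Missing inputs
propagate as missing — each analysis later applies its own complete-case
denominator, since the published denominators differ between analyses.

## Statistical machinery

* **Exact tests.** For a 2×2 or 2×3 table, every table with the observed
  margins is enumerated; each has multivariate hypergeometric
  probability (∏rᵢ!·∏cⱼ!)/(N!·∏nᵢⱼ!), and the two-sided p sums
  probabilities ≤ the observed one (relative tie tolerance 1e-9 for
  float safety).  For 2×2 this is the classic two-sided Fisher test
  (checked exhaustively against a hypergeometric-pmf oracle and scipy);
  for 2×3 the Freeman–Halton generalization.  An all-zero column needs
  no special handling — enumeration forces it to zero, so the result
  equals the reduced table's — while a zero row margin is degenerate and
  returns p = 1 with a warning.  The published analysis text says 2×2
  but its table is 2×3; both are supported and the pipeline uses the
  2×3 form matching the printed table.
* **Welch t test** (unequal variances, Welch–Satterthwaite df): the safer
  default where only "independent-sample t test" is specified.  Two
  zero-variance samples with unequal means raise instead of returning a
  fake infinity.
* **Kaplan–Meier / log-rank.** Product-limit estimator with events
  before censorings at tied times (standard convention); the log-rank
  statistic is (O−E)ᵀV⁻¹(O−E) over K−1 groups with the hypergeometric
  covariance at each event time, df = K−1.  Both are cross-checked
  against lifelines in the tests.  End-of-follow-up event-free
  proportions are the KM estimate at the maximum observed time.

## Fixtures: reconstructing the cohort from printed counts

The printed marginals — 35 patients, 15 pCR, 23 IS-high, 14 mrTRG=1, and
9 patients IS-high∧mrTRG=1 of whom 6 pCR — determine the joint
(IS, mrTRG=1, pCR) cell counts uniquely: (high, TRG1) 9/6 pCR,
(high, other) 14/5, (low, TRG1) 5/1, (low, other) 7/3.  The fixture
materializes these 35 records with endpoint-consistent stages (pCR ⇒
ypT0, ypN0, pTRG 0; non-TRG1 patients carry grade 2).

Densities deserve a note: under cohort-internal ranking the mean of the
four percentiles averages 50 over the cohort, so 23/35 patients above a
62 cutoff is impossible when the four marker ranks coincide.  It is
attainable when core and margin ranks anti-correlate; the fixture pairs
ascending core ranks with descending margin ranks within the high group
(global ranks 13–35, every patient's mean percentile 67.1) and the low
group (ranks 1–12, mean 17.1).  This reproduces the printed 23/12 split
exactly while using only the public scoring path.

Two discrepancies in the printed record are **preserved, not repaired**:
(i) the headline count is 15 pCR but the printed NAR and grade tables
imply 13; (ii) one pCR patient is printed with an intermediate
pathologic NAR, unattainable under the formula for a cT ≥ 2 enrollee.
The joint fixture (internally consistent, 15 pCR) and the as-printed
tables (13 pCR) are therefore kept separate, and the pipeline logs the
13-vs-15 inconsistency whenever it analyses the printed tables.  No
single patient-level dataset can reproduce every printed number
simultaneously.

## Synthetic-cohort simulator

The generative model draws, per patient: baseline cT from
(0.05, 0.90, 0.05) over T2/T3/T4 (the trial's MRIs contained one T2 and
no T4) with node-positivity forced for cT2 (inclusion criterion);
log-normal densities `log d = μ_m + 0.8·u + 0.6·ε` with a shared
standard-normal immune factor u (so the four markers correlate) and
region means around 500/800/200/400 cells/mm²; a latent response
`z = 1.5·(mean IS percentile)/100 + N(0,1)`; mrTRG by thresholding z at
(−0.78, −0.17, 0.33, 1.03) (scaled by `mrtrg_link`), placing ≈40% of
patients at grade 1; pCR ~ Bernoulli(logistic(b + z)) with
b = −1.0851 frozen from the package's own moment-matching calibration
(`calibrate_pcr_base_logit`, 20,000 latent draws, default seed) to the
0.43 trial prevalence; endpoint-consistent post-treatment stages (pCR ⇒
ypT0/ypN0/pTRG 0; otherwise pTRG ∈ {1,2,3} by z, ypT between 1 and cT,
ypN ≤ cN; mrTRG 1 ⇒ radiologic T0/N0).  Progression times are
exponential with the hazard of the patient's pathologic NAR category —
defaults (0.0008, 0.0026, 0.0147) events/month back-solved from the
published 40-month DFS proportions 100/90/55.6% — death follows
progression at 0.02/month, and both clocks are administratively censored
at 40 months, so an observed death always has DFS time ≤ OS time.  All
draws come from one `numpy` Generator seeded from the config
(default 20180329, an arbitrary documented constant), making cohorts
byte-reproducible.

What the simulator does **not** emulate: the trial's 0.66 IS-high
fraction (cohort-internal ranking with positively correlated markers
bounds it near 0.38 — only the fixture's anti-correlated construction
reaches 0.66); inter-rater MRI variability; non-exponential hazards;
dependence of survival on anything but the NAR category.  Passing
simulator tests therefore demonstrate internal consistency and
statistical correctness of the machinery, not fidelity of any particular
real-world effect size.

## Numerical and reporting choices

Percentages are emitted both as raw ratios and rounded to one decimal,
and every report self-checks |pct − 100·count/n| ≤ 0.05 on emission.
(15/35 = 42.857% is emitted as 42.9; the source's "42.8%" appears to be
a truncation and would fail this self-check.)  The grade tabulation is
additionally quoted at two decimals (92.31%) where the source does so.
CSV interchange is comma-delimited UTF-8 with a header, "." decimal
separator, empty cell = missing, events as 0/1, times in months; score
columns are written with 3 decimals, and simulated times/densities are
generated at 3-decimal resolution so cohorts round-trip exactly.

Problem sizes: fixture analyses are exact and instantaneous; simulator
recovery checks use n = 10,000 (binomial SE ≈ 0.5% on the pCR rate,
3-SE acceptance band), which this package treats as its standard
large-cohort verification size.

## Known limitations

No Cox regression, KM confidence bands, or multiplicity adjustment
(none used in the source analyses); no AJCC stage-group derivation; no
external immunoscore reference population; the published per-patient
survival times are not recoverable from the printed record, so the
published survival percentages and log-rank p-values are verified only
at the level of the machinery (against lifelines and against simulated
cohorts with known hazards), not as numbers.
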