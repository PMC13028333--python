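# Methods

This note documents the models implemented in `kinanthro`, the conventions
chosen where the field offers several, and what the synthetic-data tests do
and do not demonstrate.

## Anthropometric profile

A profile is the ISAK-style restricted set: body mass (kg), stretch stature,
sitting height, arm span, six breadths, eight girths (cm) and eight
skinfolds (mm), plus age and playing position. Validation is strict and
non-imputing: every downstream formula needs all 26 measurements, so a
record with a missing or physiologically impossible value (non-positive
measurement, sitting height ≥ stature, flexed arm girth more than 2 cm below
the relaxed girth, humerus breadth ≥ femur breadth + 5 cm, age outside
[15, 60] unless relaxed) is rejected (strict mode) or dropped with a warning.
CSV I/O uses a canonical snake_case header set with an alias map for common
spellings; units are fixed (kg/cm/mm) — silent unit guessing would corrupt
the skinfold-vs-girth corrections. Full precision is kept internally;
one-decimal rounding only happens where printed reference values are
compared.

## Phantom five-way fractionation

Measurements are geometrically scaled to the unisex phantom (stature
170.18 cm) and expressed as Z-scores, `Z = (x·(170.18/h)^d − p)/s` with
dimension exponent d = 1 for linear measures and 3 for masses. Tissue masses
are back-transformed as `m = (Z·s_m + p_m)/(170.18/h)^3`. Indicator sets:

| tissue   | indicator Z (mean of)                                           | (p_m, s_m) kg |
|----------|-----------------------------------------------------------------|---------------|
| adipose  | sum of six skinfolds (triceps, subscapular, supraspinale, abdominal, front thigh, medial calf) | (25.60, 5.85) |
| muscle   | five skinfold-corrected girths, corrected girth = girth − π·skinfold/10 | (24.50, 5.40) |
| skeletal | biacromial, biiliocristal, humerus, femur breadths + head girth | (7.90, 1.52)  |
| residual | transverse chest, A-P chest depth, waist girth, scaled by sitting height against the phantom sitting height 89.92 cm (ratio and cubic back-transform both use sitting height; the convention is isolated in one function) | (6.10, 1.24) |
| skin     | body-surface area: SA(cm²) = 68.308·h^0.725·m^0.425, thickness 2.07 mm at phantom stature scaled linearly with stature, density 1.05 g/cm³ | — |

All constants live in `data/phantom_constants.csv`; the loader refuses an
incomplete table. Conventions worth noting:

- **Head girth is phantom-scaled like every other indicator.** Some published
  variants leave the head unscaled on the argument that head size scales
  weakly with stature; the uniform treatment keeps the method exactly
  geometrically similar (all masses scale as k³ when all linear measures
  scale as k), which is tested as an identity.
- **Error sign**: `error = scale − estimated`, so negative error means the
  anthropometric estimate exceeds the scale — on heavy muscular athletes the
  method characteristically over-estimates by a few kg.
- **Agreement statistics**: Spearman rho CI via Fisher z with the
  Bonett–Wright standard error; R² and its CI from the Pearson r Fisher-z
  interval (endpoints squared); RSE from the OLS fit of estimated on scale
  mass; ICC is the two-way random-effects, absolute-agreement,
  single-measure form ICC(A,1) (the usual report leaves the form
  unspecified; this is the conservative choice for method agreement).
- **TEM** = sqrt(Σd²/2n) over duplicate pairs, %TEM normalized by the grand
  mean.

Mass closure (Σ tissues ≡ estimated total) and percentage closure
(Σ tissue% + error% ≡ 100% of scale mass) are exact identities, not
tolerances.

## Heath–Carter somatotype

- endomorphy: X = (triceps + subscapular + supraspinale)·(170.18/h);
  endo = −0.7182 + 0.1451X − 0.00068X² + 0.0000014X³
- mesomorphy = 0.858·humerus + 0.601·femur + 0.188·(arm flexed − triceps/10)
  + 0.161·(calf girth − calf skinfold/10) − 0.131·h + 4.5
- ectomorphy from HWR = h/m^(1/3): 0.732·HWR − 28.58 for HWR ≥ 40.75;
  0.463·HWR − 17.63 for 38.25 < HWR < 40.75; floor otherwise. Exactly 40.75
  takes the upper formula; exactly 38.25 floors (strict/weak inequalities of
  the standard method).

All components are floored at 0.1. Mesomorphy is linear in its inputs, so
its value at group means equals the group mean of values — this drives the
deterministic acceptance checks. Magnitude bands: low 0–2.9, moderate 3–5,
high 5.5–7, very high >7; the unassigned gap (5.0, 5.5) is labelled
"moderate" (conservative reading). Dominance naming uses the 0.5-unit
negligibility rule: all three within 0.5 → "central"; a two-way tie for the
top → compound ("endo-mesomorph"); otherwise adjective-noun
("endomorphic mesomorph"), with "balanced" when the two non-dominant
components are within 0.5. Note that under this strict rule the profile
3.8–7.0–0.8 is an *endomorphic mesomorph* (endomorphy leads ectomorphy by
3.0), even though such profiles are sometimes loosely called "balanced".
SAM uses the grand-sample mean somatotype as the reference; its 95% CI is a
t-interval on the individual SADs, clipped at zero.

## Indices

Ratios printed per-100: ape, cormic, relative breadths, shoulder–hip,
Manouvrier. Two deliberate conventions:

- **Manouvrier** uses the stature denominator, (h − sitting height)/h·100
  (≈47 for adults), not the classical sitting-height denominator (≈90).
  With this convention Manouvrier + cormic = 100 exactly — tested as an
  identity.
- **Shoulder–hip** is biacromial/biiliocristal per its textual definition
  (≈144); published tables in this domain are sometimes only consistent
  with the inverted ratio (≈70), so `inverted=True` provides that
  compatibility variant.

Σ8SF is implemented from its definition (sum of all eight sites); reference
tables occasionally mis-print this row.

## Positional comparison battery

Per variable: Shapiro–Wilk per group for n < 50 (all positional groups
here), otherwise a standardized KS test; any non-normal group → Kruskal–
Wallis. Otherwise Levene (median-centered); heteroscedastic → Welch's
ANOVA, else classical ANOVA. Effect sizes: η² = SS_between/SS_total (equal
to the Cohen-f conversion f²/(1+f²) exactly, verified to 1e−12);
ε² = H·(n+1)/(n²−1) with tie-corrected H. Labels at 0.01/0.06/0.14. Note
that ε² cannot reach 1 for multi-member groups — perfect rank separation
maximizes it short of 1 (verified by brute force over assignments at n = 6).
Post hoc: Games–Howell (studentized range with Welch–Satterthwaite df per
pair — implemented directly on `scipy.stats.studentized_range` and
cross-checked against pingouin) after ANOVA/Welch; Dunn's rank test with tie
correction after Kruskal–Wallis, Holm-adjusted by default (bonferroni/none
configurable) — implemented in-package as no installed library provides it.
Ordering strings sort groups by mean and cluster greedily: a group joins the
current block iff it is non-significant against every block member; a
trailing block of ≥3 groups renders as "Rest".

Under the null (all groups one distribution) the adaptive battery's
rejection rate is calibrated: [0.03, 0.07] at α = 0.05 over 2000 simulated
7-group datasets (n = 20 per group), checked in the acceptance suite.

## Stepwise canonical discriminant analysis

Scatter matrices W (pooled within) and B (between); Λ(S) = det(W_S)/det(T_S).
Stepwise entry maximizes F = ((n−g−q)/(g−1))·(1−Λ_partial)/Λ_partial with
defaults F-to-enter 3.84 / F-to-remove 2.71 (classical defaults; the source
analyses rarely state theirs). Canonical functions from the symmetric
generalized eigenproblem `B a = λ W a`, normalized to unit pooled
within-group score variance, sign fixed so the largest coefficient is
positive. Identities maintained and tested: canonical r_k = sqrt(λ_k/(1+λ_k));
Λ = Π 1/(1+λ_k) equals the determinant ratio to 1e−10; χ² =
−(n−1−(p+g)/2)·lnΛ with df = p(g−1) (conventions differ across software;
printed χ² values from other packages are not chased). min(g−1, p) functions
are retained; the territorial map uses the first two.

Classification uses Fisher linear classification functions with equal priors
by default — the positional group sizes are design artifacts, not population
frequencies; proportional priors are a flag. Exact score ties (measure zero)
go to the lowest-index group. The territorial map assigns each DF1–DF2 grid
cell by maximizing −½‖z − centroid‖² + ln(prior), valid because scores are
within-group whitened; per-group RMS score radii are exported for plotting.

Box's M uses the standard χ² approximation with scaling
c = (Σ1/(n_i−1) − 1/(n−g))·(2p²+3p−1)/(6(p+1)(g−1)); VIF via statsmodels.
Flags are advisory: the analysis is exploratory.

Independent verification: canonical correlations are compared (to 1e−8)
against a QR/SVD canonical-correlation oracle between the features and the
one-hot group coding — an entirely different computational route — and
classifications against scikit-learn's LDA.

## Synthetic cohort generator

The generator emulates a 188-athlete, seven-position professional cohort
(DB 30, DL 33, LB 33, OL 27, QB 18, RB 16, WR 31) whose per-position
marginal means and SDs are the shipped parameter table. Only marginals are
published, so the joint structure is a design choice, made explicit:

- a factor model with a global **size** factor (variance share 0.65 for body
  mass, 0.45 girths, 0.35 lengths/breadths, 0.05 skinfolds), an
  **adiposity** factor (0.55 skinfolds, 0.25 mass, 0.10 girths) and one
  residual block factor per family, calibrated so within-family correlations
  hit the configured targets (girths 0.70, skinfolds 0.60, lengths 0.70,
  breadths 0.70). Implied cross-correlations are realistic for adult
  athletes: mass–girth ≈ 0.70, mass–skinfold ≈ 0.55, girth–skinfold ≈ 0.39.
- truncation to a **symmetric** band, mean ± min(4·SD, mean): symmetry keeps
  redraws from biasing the mean while guaranteeing positivity.
- the flexed ≥ relaxed − 2 cm arm-girth consistency rule is enforced by
  redrawing only the pair's idiosyncratic noise, leaving all other marginals
  untouched; the pair's own moments are conditioned slightly (mean shifts
  ≲ 0.3%, SD shrinks ≲ 10% under the independent model, far less under the
  block model where violations are rare).
- an optional moment-matched lognormal marginal for skinfolds exercises the
  Kruskal–Wallis path (real skinfold distributions are right-skewed).

Sampling is deterministic given the seed. Agreement pairs for exercising the
reliability statistics are scale ~ N(97.1, 19.3²) kg with estimated =
bias·scale + N(0, σ²), defaults bias 1.05 and σ = 3.2 kg.

**What passing tests show — and don't.** The generator reproduces marginal
moments, plausible inter-measurement correlation, and the qualitative
positional structure (linemen largest and most dispersed, skill positions
overlapping), and the full pipeline run on it reproduces the characteristic
pattern of results (large mass effects with OL on top, null proportionality
indices, DF1 separating linemen from skill positions with ~85% of the
explained variance). It does not reproduce any real cohort's joint
distribution, measurement error, or non-normality beyond the lognormal
option — so pipeline correctness, not field validity, is what the synthetic
tests establish.

## Problem sizes and numerical choices

Simulation-based tests use: the 188-athlete default cohort at fixed seeds;
n = 10⁴ single-position draws for moment recovery (mean deviations judged
per-variable against a simultaneous 3.5-SEM bound with RMS < 2 SEM, since a
literal per-variable 2-SEM gate over 25 simultaneous comparisons false-alarms
with probability ≈ 0.7); 2000 replicates for null calibration; 40–100
replicates for stepwise-selection stability and null classification. Matrix
work uses `slogdet` for Λ (no overflow), symmetric generalized `eigh` for
the canonical problem, and eigenvalues clipped at zero. CSVs are written at
%.17g and parsed with correctly-rounded conversion so cohort round-trips are
bit-exact.

## Known limitations

- Fractionation constants are transcribed reference values; the skin-mass
  surface-area coefficient and thickness vary slightly across published
  variants (phantom skin mass here: 3.617 kg).
- The discriminant model is descriptive: no cross-validation is performed
  (matching the exploratory framing of the analyses it supports), so
  reported accuracies are resubstitution accuracies.
- Statistical power is not computed.
- The Kruskal–Wallis ε² upper bound < 1 for grouped data means its Cohen-style
  labels are conservative near the top of the range.
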