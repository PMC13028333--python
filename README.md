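# kinanthro

Kinanthropometric profiling of athletes from restricted ISAK anthropometric
profiles. Built around positional morphology in American football, the
toolkit takes 26 surface-anthropometry measurements per athlete — body mass,
stretch stature, sitting height, arm span, six bone breadths, eight girths,
eight skinfolds — and derives:

- **Five-way tissue fractionation** (adipose, muscle, skeletal, residual,
  skin masses) via the phantom stratagem: each indicator is geometrically
  scaled to the 170.18 cm phantom reference and expressed as a Z-score,
  `Z = (value * (170.18/h)^d - p) / s`, then back-transformed through the
  phantom tissue mass, `mass = (Z*s_m + p_m) / (170.18/h)^3`. Scale-vs-
  estimated mass agreement is quantified with Spearman's rho, R², residual
  standard error and a two-way random-effects absolute-agreement ICC.
- **Heath–Carter somatotype**: endomorphy from three height-corrected
  skinfolds, mesomorphy from bone breadths and skinfold-corrected girths
  relative to stature, ectomorphy from the height–weight ratio
  `HWR = h / m^(1/3)`; category labels, somatochart coordinates
  `(x, y) = (ecto − endo, 2·meso − endo − ecto)` and attitudinal dispersion
  (SAD = Euclidean distance between somatotypes; SAM = mean SAD of a group
  to the grand-mean somatotype).
- **Proportionality indices**: BMI, Σ6/Σ8 skinfolds, ape (arm-span/stature),
  cormic (sitting-height/stature), relative breadths, shoulder–hip,
  Manouvrier `(h − sitting height)/h`, muscle-to-bone and locomotive
  `(adipose + residual)/(muscle + bone)` ratios.
- **Positional comparison battery**: per-variable normality
  (Shapiro–Wilk/KS) and homoscedasticity (Levene) checks route each variable
  to one-way ANOVA, Welch's ANOVA or Kruskal–Wallis; effect sizes η²
  (= SS_between/SS_total) or ε² (= H·(n+1)/(n²−1)) with Cohen magnitude
  labels; Games–Howell or Holm-adjusted Dunn post hocs; compact ordering
  strings such as `OL>DL>LB>Rest`.
- **Stepwise canonical discriminant analysis**, written from scratch:
  greedy minimization of partial Wilks' Λ with F-to-enter/remove gates,
  canonical functions from the generalized eigenproblem `B a = λ W a`,
  Bartlett's χ² on `−(n − 1 − (p+g)/2)·ln Λ`, Fisher classification
  functions with configurable priors, confusion matrices and a rasterized
  territorial map of the DF1–DF2 plane. Box's M and VIF assumption checks
  included.
- A **synthetic cohort generator** that reproduces a seven-position
  professional cohort (DB/DL/LB/OL/QB/RB/WR) from published per-position
  means and SDs, with a factor model inducing realistic positive
  correlations among girths, skinfolds, lengths, breadths and body mass —
  so the entire pipeline is exercisable without access to raw data.

## Worked example

```bash
$ kinanthro synth --seed 7 --out lfa.csv
wrote lfa.csv (188 athletes)

$ kinanthro somatotype lfa.csv --sam | tail -7
DB: SAM = 1.61 (95% CI 1.36-1.86, n = 30)
DL: SAM = 2.05 (95% CI 1.69-2.41, n = 33)
LB: SAM = 1.25 (95% CI 1.03-1.48, n = 33)
OL: SAM = 3.55 (95% CI 3.14-3.97, n = 27)
QB: SAM = 1.99 (95% CI 1.49-2.48, n = 18)
RB: SAM = 1.69 (95% CI 1.22-2.16, n = 16)
WR: SAM = 2.21 (95% CI 1.76-2.66, n = 31)
```

Offensive linemen (OL) are the most heterogeneous physiques — their mean
attitudinal distance from the grand-mean somatotype (3.55 somatotype units)
is roughly twice that of the tightly clustered linebackers (1.25).

```bash
$ kinanthro discriminate lfa.csv
entry order: thigh_girth -> triceps_sf -> stretch_stature
Wilks' Lambda = 0.220 (chi2 = 275.9, df = 18, p = 4.2e-48)
DF1: eigenvalue = 2.259, canonical r = 0.833, 86.0% of explained variance
DF2: eigenvalue = 0.231, canonical r = 0.433, 8.8% of explained variance
DF3: eigenvalue = 0.136, canonical r = 0.346, 5.2% of explained variance
classification accuracy = 54.3%

$ kinanthro fractionate lfa.csv --agreement --out masses.csv | tail -1
spearman rho = 0.940 (95% CI 0.916-0.957); R^2 = 0.911; RSE = 6.5 kg; ICC = 0.943
```

The first discriminant function carries ~86% of the between-position
separation and splits linemen (positive DF1 centroids) from skill positions
(negative); just over half the athletes are classified into their true
position from three girth/length measurements, and the anthropometric mass
estimate agrees closely with scale mass across the cohort.

Other subcommands: `summarize`, `indices`, `compare` — see
`kinanthro <cmd> --help`. Everything is also available as a library
(`import kinanthro`).

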