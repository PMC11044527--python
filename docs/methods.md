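# Methods

This note documents the models, numerical choices and known limitations
behind `cd26flow`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The measurement model

A peripheral-blood acquisition is an events × channels intensity matrix
over the panel FSC, SSC, CD45, CD34, CD38, CD26, CD3. Intensities are
taken as already compensated; they may be negative. Fluorescence channels
are mapped to the display/gating scale by `asinh(x / cofactor)` with a
single cofactor (default 150, the conventional choice for
conventional-cytometer fluorescence); scatter stays linear. Every gate
decision in the package is a threshold on this scale. Because the
transform is strictly increasing, gate logic and all rank-based
statistics downstream depend only on event order — the exact cofactor
value is immaterial as long as the scale is monotone, which is also why a
logicle/biexponential scale was deliberately not implemented: it adds
parameters without changing any trough-threshold decision.

## 2. Trough thresholds

`density_trough` fits a Gaussian-kernel density estimate with Silverman's
bandwidth, `0.9 · min(sd, IQR/1.34) · n^(−1/5)`, evaluated on a 512-point
grid spanning the 0.1–99.9 percentile range of the data; the grid step
defines the threshold resolution. For n ≤ 10,000 the density is the
exact Gaussian sum over events; above that a linear-binned convolution
(histogram on the grid, Gaussian filter of width `bw/step`) is used —
the two agree to well under a grid step at the trough (tested), and the
binned route makes a full 100,000-event pipeline run in well under a
second.

Mode detection does not take raw local maxima at face value: on a KDE of
10⁵ events, sampling wiggles near the main mode top would masquerade as
modes. A local maximum counts as a mode only if its prominence is at
least 5% of the peak density and it is separated from a larger peak by
at least 5% of the grid range. The threshold is the minimum-density grid
point strictly between the two highest surviving modes; ties are broken
toward the lowest intensity (a consistent, conservative choice — the
marginal event is called negative).

### Fallbacks for degenerate shapes

A unimodal density has no trough, so each gate declares a fallback and
sets a warning flag:

| gate | fallback | rationale |
|---|---|---|
| debris (FSC) | 1st percentile | a debris-less sample is retained |
| CD45 | 1st percentile | an all-CD45+ parent is retained |
| CD34 | mode + 5 × robust SD | see below |
| CD38 split | median | split an unresolvable compartment evenly |
| CD26 cutoff | 99.9th percentile of lymphocyte CD26 | the lymphocytes then bound negativity from above; cutoff flagged low-confidence |

The CD34 gate is special because CD34+ events are typically a ~1–3%
minority whose KDE mode sits below the prominence floor: the rare-positive
fallback places the threshold at the upper bound of the negative
mode, `mode + 5·(1.4826·MAD)`. A percentile fallback was rejected here:
the 99.9th percentile calls the top 0.1% of the parent positive even when
no CD34+ population exists, and truncates a genuinely present rare
population to 0.1%. The robust-sigma bound yields a zero count for an
absent population (the normal tail beyond 5 SDs is empty at these event
counts) while a real CD34+ population several SDs above the bulk is
retained in full; both behaviours are under test.

## 3. The gate hierarchy and the CD26 cutoff

```
all events → debris_free (FSC) → CD45pos → CD34pos → {CD38pos, LSC}
                                                        LSC → {LSC_CD26pos, LSC_CD26neg}
```

Gates are 1-D thresholds rather than the hand-drawn 2-D polygons of
interactive analysis: polygon geometry is operator-dependent and not
numerically specifiable, whereas thresholds make the pipeline
deterministic and testable. The second axis of each conventional plot
(SSC) is retained for display but does not alter membership.

The CD26 positivity cutoff is never derived from the LSC events
themselves (there are too few, and their CD26 split is the quantity
under measurement). Instead CD3+ lymphocytes serve as an internal
control: T cells are abundant and their CD26 expression is reliably
bimodal. The lymphocyte pre-gate is CD45+, SSC below the
lymphocyte/granulocyte trough, CD3 above its trough — the conventional
reading of "CD3-positive lymphocytes", adopted and flagged as an
interpretation since no numeric definition exists. The CD26 trough of
those cells is the sample's single cutoff. Fewer than 50 CD3+
lymphocytes is a calibration failure: the report marks CD26 quantities
unavailable rather than emitting a silent zero.

Low LSC counts (< 20 events) annotate the report but never suppress it —
reported percentages go down to 0.001%, which at 10⁵ events means
single-digit event counts were accepted as results.

## 4. Quantification conventions

The headline percentage uses CD45+ events as denominator (not all
acquired events), matching how such results are reported; the absolute
count is `WBC/µL × %CD26(CD45)/100` exactly, an identity asserted on
every emitted record. Empty denominators (failed gates) yield NaN plus a
flag — a failed gate must not fabricate a negative finding. Percentages
are carried at full precision and rendered to 3 significant figures.

## 5. Rank statistics

The four procedures report what clinical software prints: midranks,
tie-corrected asymptotic Z (no continuity correction), chi-square H with
df, per-group mean ranks, two-sided p. Formulas:

* Mann–Whitney: `U₁ = R₁ − n₁(n₁+1)/2`, reported U is min(U₁, U₂);
  `Var = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]`.
* Kruskal–Wallis: `H = [12/(N(N+1)) · Σ R_j²/n_j − 3(N+1)] / (1 − Σ(t³−t)/(N³−N))`.
* Wilcoxon signed-rank: zero differences dropped, `Var = n(n+1)(2n+1)/24 − Σ(t³−t)/48`;
  differences are after − before, so a uniform decrease gives Z < 0.
* Spearman: product-moment correlation of midranks; p via the t
  approximation with n−2 df.

For two untied groups H equals the Mann–Whitney Z² (verified to 1e-9).
Exact-distribution p-values are out of scope; the asymptotics are
validated against full-enumeration permutation oracles at small n in the
test suite. Quartiles use linear interpolation between order statistics —
one declared convention makes the IQR testable.

## 6. The synthetic-data generator

The generator emulates the study conditions so that every stage has a
ground-truth oracle: 100,000-event acquisitions with debris (5%),
lymphocytes (23%, of which ~two-thirds CD3+, of those 55% CD26+ — the
bimodality the cutoff calibration requires), monocytes (5%),
granulocytes (remainder), CD34+CD38+ progenitors (2%) and a CD34+CD38−
compartment sized from two targets: %CD26 of CD45+ events and %CD26 of
the compartment. Controls carry a small (0.2%) CD26-negative HSC
compartment and force the CD26+ target to zero.

Intensities are per-population normals on the gating scale (correlated
FSC/SSC pair, ρ = 0.3), mapped to raw units through the inverse
transform. Locations and spreads are free template parameters chosen so
the gate topology holds by construction: every trough-flanked mode pair
is ≥ 3 pooled SDs apart, and the CD26− mode sits ~9 SDs below the CD26+
mode so that thin-tailed false positives cannot occur in controls — the
empirical counterpart of an assay whose controls are reliably
CD26-negative. They are not estimates of any particular instrument.

Cohort draws follow the printed study ranges: diagnosis WBC log-uniform
over 42.6–828.3 ×10³/µL, %CD26(CD45) log-uniform over 0.001–1.77 at
diagnosis and 0.001–0.2 at follow-up (log-uniform because reported
medians sit far below range midpoints, indicating strong right skew);
follow-up WBC over the normal range 4–11 ×10³/µL (complete hematological
response). Follow-up partners reuse the patient identity and, for a
configurable share of pairs (default all), draw their target at or below
the diagnosis value. Sokal risk (8:31:4 high:intermediate:low) and phase
(39:4 chronic:blast-crisis) follow the study composition via
largest-remainder apportionment; only chronic-phase patients get
follow-up samples. The %CD26-of-compartment target is drawn log-uniformly
over [max(0.05, 4·t), 55.94] where t is the %CD26(CD45) target — the
lower bound keeps the implied compartment below ~24% of events
(unconstrained joint draws over both printed ranges can demand a stem
compartment larger than the acquisition).

Rare-event floor: when a target implies fewer than 5 expected CD26+ LSC
events, the count is pinned deterministically (rounded expectation,
optionally floored — cohort diagnosis samples floor at 5) instead of
drawn multinomially, making detection tests deterministic in the 0.001%
regime. All randomness flows from one seed through per-sample spawned
streams, so cohorts are bit-reproducible.

### What the simulator does not model

Doublets, time drift, spillover/compensation error, heavy-tailed or
skewed fluorescence noise, autofluorescence structure, accelerated-phase
biology, and any correlation between %CD26 and WBC. Passing tests
therefore demonstrate that the pipeline recovers truth under clean,
well-separated populations — the regime the assay itself assumes — not
robustness to stain quality or instrument drift.

## 7. Problem sizes used in validation

Single-sample checks run at the study's acquisition size (100,000
events). The acceptance script simulates the full 81-sample cohort at
that size, plus 300 seeded acquisitions (100 per target at 0.01 / 0.1 /
1.0 %CD26 of CD45+) for the parameter-recovery rate; unit and cohort
tests use 4,000–25,000-event samples where only structural behaviour is
under test. The trough oracle runs at n = 10,000, inside the exact-KDE
regime, so the brute-force grid-minimization comparison is exact.

## 8. Known limitations

* The CD45 and CD34 stages usually take their flagged fallback routes on
  realistic samples (few CD45− non-debris events; rare CD34+): correct
  here by construction, but on real data the 1st-percentile CD45
  fallback discards 1% of CD45+ events by definition, a small systematic
  undercount of the denominator.
* The CD26 cutoff inherits the lymphocyte CD26+ fraction; a sample with
  genuinely unimodal lymphocyte CD26 yields only a flagged,
  low-confidence percentile cutoff.
* Asymptotic p-values are used at every n, including n as small as the
  28 follow-up pairs; exact tests are not implemented.
* FCS support is deliberately narrow: 3.0/3.1 list mode, float or
  linear-integer data, no spillover parsing, no FCS 2.0.
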