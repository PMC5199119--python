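# Methods

This note documents the statistical model behind `plasmaprofiler`, the
design choices made where the design was genuinely open, and what the
synthetic cohort does and does not emulate.

## Observation model

All analysis operates on label-free quantification (LFQ) intensities, an
arbitrary-unit linear-scale measure of protein abundance per MS run. A
stored zero conventionally means "not quantified" and is mapped to an
explicit missing state at read time; downstream statistics treat
missingness explicitly rather than imputing.

The synthetic generator draws log2 intensities as

    x[p,i,t,r] = mu_p + b[p,i] + delta_p * g_a(t) * m_i + e[p,i,t] + eps[p,i,t,r]

with

* `mu_p` — per-protein baseline abundance, uniform on (18, 28.5) log2
  for unnamed proteins; named roster proteins sit at (26, 29), with the
  genuinely most abundant plasma proteins (ALB, APOA1, APOB, A2M,
  fibrinogens, hemoglobins) pinned at 28–31 log2;
* `b[p,i] ~ N(0, sigma_b^2)` — individual-specific offsets,
  `sigma_b ~ U(0.15, 1.05)` log2 per protein. This makes most proteins
  differ >2-fold from the cohort mean in at least one of 43 individuals
  and a minority >5-fold, the regime longitudinal plasma studies report;
* `delta_p * g_a(t)` — the weight-loss response: `delta_p` is the log2
  fold change at the end of weight loss (week 0) and `g_a(t) ∈ [0,1]` one
  of seven archetype shapes (rapid change with full recovery, with hold,
  with partial decline, slow monotone adaptation in either direction, and
  an acute transient), all zero at the week −8 baseline. Signs are tied
  to archetypes so each archetype is one direction of regulation. Named
  proteins carry published percent changes (SHBG +117%, APOF +37%,
  SERPINF1 −16%, SAA1 −43%, CRP −35%, LPA +95%, ALB +8%, …); unnamed
  responders draw 12–45% decreases or 12–90% increases;
* `m_i` — a per-individual response modifier: the 3 planted
  "non-improver" completers follow a weight-regain profile in which the
  week-0 response decays back to baseline, mirroring their BMI curve;
* `e ~ N(0, sigma_w^2)` — within-individual biological drift over time,
  default `sigma_w = 0.12` log2 (~8% CV), small against between-individual
  spread, as observed for most plasma proteins;
* `eps ~ N(0, sigma_t(p)^2)` — technical replicate noise. `sigma_t`
  interpolates from 0.15 log2 at the top of the abundance range to 0.60
  at the bottom (counting-type noise). A single homoscedastic sigma
  cannot simultaneously reproduce quadruplicate correlations of ~0.97
  across a >10-log2 dynamic range and the very small paired
  per-individual standard deviations implied by P < 1e-13 for a −16%
  change; abundance-dependent noise reconciles both and is the standard
  LFQ behaviour.

Missingness is missing-not-at-random: each replicate measurement is
dropped with probability `logistic(11.6 − 0.675 · x)`, ≈ 35% at the
bottom of the abundance range and negligible above ~24 log2 (≈ 6–9%
overall), matching the left-censoring character of LFQ plasma data.

The design constants are those of the study: 52 enrolled individuals
sampled at weeks −8 and 0, of whom 43 complete weeks 4–52; four
technical replicates per sample; an 18-run matching library counted in
the run bookkeeping (52·2 + 43·5 = 319 samples; 319·4 + 18 = 1,294
proteomes).

### QC failures

One planted erythrocyte-lysis run adds +4 log2 to HBA1/HBB/HBD/CA1; five
planted coagulation runs add −3 log2 to FGA/FGB/FGG (the study's
reported event counts). Scoring measures each run's mean log2 deviation
of the markers from the cohort-wide per-protein median — robust to the
perturbed runs themselves — with flags at +3 / −2 log2. Flags annotate;
exclusion is a configuration switch, because such events are reported,
not silently removed.

### Clinical covariates

BMI follows the designed 12%-drop-and-hold curve per individual (baseline
U(30, 40) kg/m², regain profile for non-improvers); weight is BMI ×
height². Laboratory variables (HDL, LDL, cholesterol, triglycerides,
glucose, leptin, HOMA-IR) exist at weeks −8, 0 and 52 only and are built
as weighted sums of the standardized *measured* protein levels plus
Gaussian noise. Because linked proteins are mutually correlated (shared
archetypes, burden-group offsets), the weights solve `w = C⁻¹ r` against
the empirical correlation matrix `C`, so each protein correlates with
the variable at its own target r; jointly infeasible targets (rᵀC⁻¹r ≥
0.9) are shrunk with a warning. Working from measured rather than
noise-free levels keeps the targets from being attenuated by technical
noise. BMI is the one exception: its marginal shape is pinned by the
design, so BMI links are realized in the reverse direction — a
standardized-BMI component is injected into the linked protein with a
coefficient solved from the protein's empirical covariance with BMI.
Either direction yields the same joint law; the reverse route also
absorbs chance between-individual associations that would otherwise bias
individual links by ±0.2 at n = 43.

A planted high-metabolic-burden subgroup (14 of 43 completers) carries
+1.5·sigma_b offsets on the inflammation and pro-IR roster proteins and
−1.5·sigma_b on the anti-IR proteins, which simultaneously produces the
inflammation/IR clustering structure and realistic HOMA-IR correlations
for inflammation factors.

### Pseudo-randomness

Every logical entity (protein, individual, clinical block, QC block)
draws from its own `numpy` generator keyed by `(seed, kind, index)`:
growing `n_proteins` never reshuffles earlier proteins, and identical
configurations are bit-reproducible.

## Analysis choices

* **Replicate aggregation** — median of observed log2 replicate values
  (mean available); a cell is missing only if all replicates are.
* **Unit of replication** — the individual. Plasma protein levels are
  individual-specific, so the screen forms per-individual paired log2
  fold changes and applies a one-sample t-test (two-sided) across
  individuals, BH-adjusted across proteins at FDR 0.05. Degenerate
  cases: all-zero deltas → (t = 0, p = 1); zero variance with non-zero
  mean → p = 0 sentinel with a warning; n < 3 → not evaluable. Percent
  changes are reported as the median over individuals of `2^Δ − 1`.
* **CV scale** — longitudinal CVs use linear-scale intensities with the
  sample (n−1) standard deviation, the conventional reading of
  "coefficient of variation" for LFQ data; weeks −8 and 0 are excluded so
  the intervention does not inflate apparent variability. The fold
  difference keeps the individual inside the cohort average.
  "Tightly controlled" is a protein-level call (max |fold| < 1.3-fold and
  max CV < 20% over individuals, ≥3 individuals evaluable).
* **Time-profile Z-scores** — population-sd convention (divide by n),
  the usual heat-map normalization for a fixed 7-point profile; pinned by
  test ({0,0,0,0,0,0,7} → z₇ = √6 ≈ 2.4495).
* **Clustering** — agglomerative, Euclidean distance, average linkage,
  cut at k = 7 (a configuration default, not a constant). Rows are
  sorted by identifier before linkage so the partition is independent of
  input order. The burden stratification instead uses Ward linkage cut
  at k = 2, the standard choice for a balanced two-group heat-map split,
  restricted to individuals with ≥3 observed weeks so weight-loss-only
  dropouts do not enter; the "high" cluster is the one with the greater
  oriented mean panel score, and identical individuals yield a flagged
  degenerate split with everyone labeled low.
* **Correlations** — Pearson r over pooled (individual, week)
  observations with the two-sided t-transform p, minimum 10 pairs,
  BH-adjusted within each clinical variable. Repeated measures of one
  person are deliberately not de-correlated; this matches how such
  longitudinal screens are conventionally run and is recorded as a known
  simplification.
* **Panels** — the C1QA/B/C complex collapses to one entry whose value
  is the mean z of its chains. Panel slopes regress on actual week
  numbers (4…52), not rank order. IR panel ties in p break by |r|, then
  symbol; immunoglobulin-flagged genes are excluded. Benefit = negative
  OLS slope of the individual's mean panel z over the seven weeks.
* **APOB/APOA1 ratio** — per-individual linear ratio per week, percent
  change against week −8. The cohort summary reports both mean ± SEM and
  the median percent change; the median is the robust location because
  ratios of log-normal intensities are right-skewed (the mean is inflated
  by Jensen's inequality at exactly the technical noise level the
  replicate design implies).

## What the simulations show — and what they do not

Passing recovery tests demonstrates that the pipeline's statistics are
correct and well calibrated *under the generator's assumptions*:
Gaussian log-scale noise, archetype-shaped mean trajectories shared
across individuals, logistic MNAR missingness, and linearly linked
clinical covariates. Real plasma data add features the generator does
not emulate: correlated protein modules beyond the planted panels,
batch and storage effects, heavy-tailed outliers (e.g. infection spikes
in acute-phase proteins), assay drift, and non-linear clinical
relationships. Conclusions about real cohorts therefore rest on the
correctness of the machinery, not on the synthetic effect sizes.

Problem sizes used by the test suite and the acceptance script — a full
319-sample default cohort, 800 (suite) or 200 (script) null cohorts of
200 proteins × 40 individuals for the FDR calibration, 12 cohorts × 10
planted proteins for specificity recovery, and 140 noisy profiles for
archetype recovery — were chosen so every recovery estimate has its
estimator noise well inside the decision margin.

## Known limitations

* The differential screen treats aggregated replicate medians as one
  observation per individual; replicate-level uncertainty is not
  propagated into the t-test (consistent with the paired design).
* Keyword and GO matching is string-level on the provided annotation
  table; no ontology traversal or enrichment statistics.
* The pro-IR roster of the generator is a synthetic stand-in (the
  positively correlating panel is not publicly itemized); anti-IR mixes
  the known members ADIPOQ, NRP1 and APOF with stand-ins SHBG and GC.
* The BMI-correlation reference table used by the panel-selection worked
  example carries the published panel membership with synthetic r/p
  magnitudes in the reported range.
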