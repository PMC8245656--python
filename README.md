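# algalmeta

Elements-of-metacommunity-structure (EMS) analysis for site-by-genus
community tables, built for long-term freshwater algal monitoring data of
the kind collected in river-connected lakes: monthly cell-density counts
per genus, paired water-quality measurements, and lake/region/season
groupings.  The package answers two questions: *what idealized
metacommunity pattern does the community follow along its dominant
gradient?* and *which environmental variables drive that gradient?*

## The method

Given a binary site-by-taxon incidence matrix, the community is ordinated
by **reciprocal averaging** (correspondence analysis): sites and taxa are
ordered by their first non-trivial CA axis scores, and three statistics are
read off the ordered matrix:

- **Coherence** — the number of *embedded absences* `Abs` (gaps strictly
  inside a taxon's, or a site's, occupied range), referred to a
  **fixed–fixed (R1) null model**: uniform random matrices with the
  observed row and column totals, drawn by a margin-preserving swap chain
  and re-ordinated individually.
- **Turnover** — the number of pairwise replacements on the range-filled
  ordered matrix, `Rep = Σ_{i<j} (#sites with i only) · (#sites with j
  only)`, referred to a range-shift null (range sizes kept, positions
  randomized along the axis).
- **Boundary clumping** — Morisita's index `I = n·Σx(x−1)/(X(X−1))` of the
  per-site counts of range starts and ends, with its chi-square test
  against an equiprobable boundary distribution.

Null deviations are reported as `z = (sim mean − observed) / sim SD`, so
coherent communities have positive coherence z and gradient-like
communities have negative turnover z.  A decision tree maps the three
components onto the idealized structures — checkerboard, random, nested
(clumped / stochastic / hyperdispersed), evenly spaced, Gleasonian,
Clementsian — with *quasi-* variants when turnover is non-significant.

Environmental attribution uses **canonical correspondence analysis**: the
chi-square-standardized community matrix is projected onto the standardized
water-quality variables and each variable's axis-1 loading (its weighted
correlation with the community-derived site scores) is flagged as important
when `|loading| > 0.5`.  Diversity statistics (richness contrasts with a
Shapiro–Wilk-gated ANOVA/Kruskal–Wallis test and compact letter display,
beta-diversity clustering of pooled presence/absence profiles, and a
131-tree random-forest indicator-genus ranking by mean decrease in Gini)
round out the pipeline.

Because monitoring data of this kind are rarely public, the
`algalmeta.synthetic` module generates incidence matrices with known
planted structure (all six idealized patterns), linked environment tables,
log-normal abundance overlays, and a full six-lake study-shape scenario
(432 samples × 55 genera × 9 variables), so that every stage of the
pipeline is testable against ground truth.

## Worked example

Generate a three-compartment (Clementsian) community of 40 sites × 25
genera and classify it:

```bash
ems synth --structure clementsian --seed 1 --out demo/
ems classify --community demo/community.csv --seed 2 --n-sims 1000
```

prints (abridged):

```json
{
 "abs": 275.0,
 "coherence_z": 31.4,
 "coherence_sim_mean": 931.7,
 "coherence_sim_sd": 20.9,
 "rep": 39695.0,
 "turnover_z": -5.9,
 "morisita_index": 5.81,
 "boundary_p": 3.2e-37,
 "df": 39,
 "structure": "Clementsian"
}
```

The observed 275 embedded absences sit far below the null expectation of
931.7 ± 20.9 (z = +31.4: strongly coherent); replacements exceed the
range-shift null (z = −5.9: a true gradient, not nestedness); and range
boundaries are heavily clumped (Morisita I = 5.8, p ≪ 0.001) — together:
Clementsian, discrete groups of genera replacing each other along the
gradient, which is exactly the planted structure.

The numbered scripts under `analysis/` run the full study-shaped analysis
(simulate → EMS per lake and pooled → CCA attribution → diversity and
indicators) and write their tables under `results/`:

```bash
python analysis/01_simulate_study_data.py
python analysis/02_ems_classification.py
python analysis/03_gradient_attribution.py
python analysis/04_diversity_and_indicators.py
```

A YAML-driven run over your own tables: `ems run --config cfg.yaml` (see
`algalmeta.pipeline.RunConfig` for the schema).

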