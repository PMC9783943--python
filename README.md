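# elevdiv

Elevational diversity and Rapoport's rule analysis for montane insect
communities, built around the kind of survey where moths are light-trapped
at replicate sites along a mountain transect grid, identified by a mix of
morphology and COI DNA barcodes, and analysed for (a) how diversity changes
with altitude and (b) whether species' elevational range sizes grow with
elevation.

It is a library plus a thin `elevdiv` command line, aimed at ecologists who
want the whole chain — occurrence tables → species ranges → Hill-number
diversity with rarefaction/extrapolation → four Rapoport's-rule tests →
barcode-based species delimitation — reproducible from one seed, with a
synthetic community generator so every stage can be exercised (and its
statistical behaviour calibrated) without any field data.

## What it computes

**Alpha diversity** per pooled altitude area, as Hill numbers

$$ {}^{q}D = \Big(\sum_i p_i^{\,q}\Big)^{1/(1-q)} $$

for q = 0 (species richness), q = 1 (exponential Shannon entropy) and q = 2
(inverse Simpson concentration), each both empirically and asymptotically
(bias-corrected Chao1 for q = 0, the Chao–Jost coverage-based entropy
estimator for q = 1, the minimum-variance unbiased inverse Simpson for
q = 2), with sample-size rarefaction/extrapolation curves, the sample
coverage estimator

$$ \hat C = 1 - \frac{f_1}{n}\cdot\frac{(n-1)f_1}{(n-1)f_1 + 2f_2}, $$

and 1000-replicate bootstrap 95% confidence intervals.

**Rapoport's rule** on per-species elevational ranges (singletons — species
represented by one specimen — excluded), via four classical tests over
200-m elevation bands:

| method | species-to-band rule | fit |
|---|---|---|
| Stevens | every band the range overlaps | linear |
| Pagel | band containing the upper range limit | linear |
| Rohde (mid-point) | band containing the range midpoint | linear + parabolic |
| cross-species | no banding; one point per species | linear |

Each fit reports slope, Pearson r, R², and a two-sided t-test p-value; the
mid-point method additionally flags a unimodal (interior-maximum) profile,
the signature of the mid-domain effect on a bounded gradient.

**Barcode delimitation**: Kimura 2-parameter distances
(d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)), a neighbor-joining tree, bootstrap
supports from column resampling, and a per-species monophyly report.

**Synthetic communities**: species ranges on a bounded 880–2280 m domain
with a tunable range-width/midpoint slope (the Rapoport handle), lognormal
abundances, and Poisson detection at 15 × 2 jittered transect sites — with
ground truth retained for parameter-recovery experiments.

## Worked example

Run the full pipeline on the built-in study-like synthetic preset:

```bash
elevdiv run --seed 1 --out demo_out
```

which prints (abbreviated):

```
TOTALS
- n_individuals: 451
- n_species: 74
- n_singleton_species: 15
- dominant_share_pct: 12.86

SPECIES RANGES
- n_representative_species: 59
- mean_range_m: 418.01

ALPHA DIVERSITY (PER ALTITUDE AREA)
- low  q=0: empirical 48.0, asymptotic 56.3 [44.6, 73.5], n=262
- mid  q=0: empirical 41.0, asymptotic 61.1 [38.1, 87.0], n=119
- high q=0: empirical 23.0, asymptotic 35.5 [20.1, 72.0], n=70

RAPOPORT TESTS
- stevens:        slope 0.2262, R2 0.8123, p 0.0056  -> positive
- pagel:          slope 0.3359, R2 0.6552, p 0.0274  -> positive
- rohde_midpoint: slope 0.2247, R2 0.4073, p 0.17    -> inconclusive
                  parabolic R2 0.7663, unimodal True
- cross_species:  slope 0.2622, R2 0.1397, p 0.0035  -> positive
```

Reading this: 74 species were observed (15 as single specimens, which are
excluded from range analyses, leaving 59 representative species); observed
richness falls from 48 species in the low area to 23 in the high area;
three of the four range-size tests find a significantly positive
range-size/elevation relationship, while the mid-point test instead shows
the unimodal profile expected from the mid-domain effect — the qualitative
fingerprint such montane moth surveys report.

Note the command runs the simulator with its *defaults* (`elevdiv run`
without a config uses the null community); the output above used the study
preset, e.g. via a YAML config:

```yaml
# cfg.yaml
seed: 1
community:
  rapoport_beta: 0.6
  abundance_lognormal_mu: -0.8
  abundance_elevation_decay: 0.0012
  midpoint_tilt: 2.0
```

```bash
elevdiv run --config cfg.yaml --out demo_out
```

Other subcommands (`simulate`, `ingest`, `ranges`, `diversity`, `rapoport`,
`barcode`, `report`) expose the individual stages; `elevdiv --help` lists
them. Real data enter as two CSVs (a site table with
site/transect/replicate/elevation columns, an occurrence table with
species/site/count columns) plus optionally an aligned FASTA whose headers
are `sequence_id|species`.

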