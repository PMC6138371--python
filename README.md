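# isomatch

Dual-method geographic assignment for migratory birds: probability-of-origin
surfaces from feather stable isotopes, kernel-density non-breeding ranges
from light-level geolocator fixes, and the concordance statistics that
compare the two.

The package is aimed at movement ecologists who want to test how well
isotope-based assignment of moult origin agrees with direct tracking. It was
built around a study system of Palaearctic barn swallows (*Hirundo rustica*)
moulting at sub-Saharan non-breeding sites, but consumes any isoscapes,
samples and fixes that conform to its interfaces.

## What it computes

**Assignment.** A feather's isotope vector **x** = (δ²H, δ¹³C, δ¹⁵N) (or the
two-isotope subset δ¹³C, δ¹⁵N) is compared with feather-equivalent isoscapes
on a 0.33° grid. Source isoscapes are first transformed: precipitation δ²H
through a linear transfer function δ²H_f = a·δ²H_p + b (residual SD added in
quadrature), and plant δ¹³C / δ¹⁵N by discrimination offsets of +2 ‰ and
+5 ‰. The likelihood that cell *i* is the origin is the multivariate normal
density

  f(**x** | μ_i, Σ_i),  Σ_i = diag(σ²_isoscape,i + σ²_residual + σ²_analytical),

with analytical SDs defaulting to 2 ‰ (δ²H), 0.1 ‰ (δ¹³C) and 0.2 ‰ (δ¹⁵N).
Normalizing over land cells (no spatial prior) gives a posterior
origin surface; the "1:1 odds" and "3:1 odds" binary maps are the smallest
sets of highest-posterior cells holding 50 % and 75 % of the posterior mass
(spatial credible regions). Individual maps are summed into population
count maps.

**Cluster assignment.** Samples are also assigned to discrete isotopic
clusters (4 for the three-isotope set, 5 for the two-isotope set) by linear
discriminant posteriors — Bayes' rule under per-cluster Gaussians with a
pooled covariance — and grid cells are classified to their
maximum-posterior cluster.

**Tracking.** Non-breeding ranges are quartic (biweight) kernel densities of
October–March geolocator fixes with a 300 km search radius, computed on a
10 km azimuthal-equidistant working grid; the 50 % / 75 % volume contours
are the core and extended ranges, rasterized back onto the 0.33° grid.

**Concordance.** Per individual, the 50 % KDE is intersected with the 1:1
odds map and the 75 % KDE with the 3:1 map; overlap is reported in cells and
as a percentage of the KDE's cells, with population means and match counts.

A synthetic-data module generates complete, statistically realistic input
bundles (smooth gradient-plus-random-field isoscapes, calibrated feather
values with Gaussian noise, fix clouds with larger latitudinal than
longitudinal error) with known truth, so the full pipeline is testable
without any external data. The study's published per-individual tables ship
as checksummed fixtures.

## Worked example

Recompute the population concordance summary from the packaged
per-individual table:

```python
from isomatch import fixtures_table1, summarize
from isomatch.concordance import records_from_table

records = records_from_table(fixtures_table1())
s = summarize(records)
print(f"{s.n} individuals")
for iso, lvl, odds in [("HCN", 0.50, "1:1"), ("HCN", 0.75, "3:1"),
                       ("CN", 0.50, "1:1"), ("CN", 0.75, "3:1")]:
    key = f"ov_{iso.lower()}_pct_{int(lvl*100)}"
    print(f"{iso} {odds} odds vs {int(lvl*100)}% KDE: "
          f"mean overlap {s.means[key]}%, "
          f"{s.match_counts[(iso, lvl)]} birds with any overlap")
```

prints

```
32 individuals
HCN 1:1 odds vs 50% KDE: mean overlap 0.3%, 2 birds with any overlap
HCN 3:1 odds vs 75% KDE: mean overlap 1.4%, 13 birds with any overlap
CN 1:1 odds vs 50% KDE: mean overlap 3.6%, 12 birds with any overlap
CN 3:1 odds vs 75% KDE: mean overlap 8.5%, 18 birds with any overlap
```

i.e. the three-isotope assignment recovers almost none of the tracked
non-breeding ranges, and dropping δ²H (the noisiest isoscape) improves the
agreement but still leaves it low — the central negative result this
pipeline quantifies.

The same analysis runs end-to-end on synthetic data from the command line:

```sh
isomatch simulate --out bundle --n 32 --seed 7
isomatch run --config bundle/config.json --out results
```

which writes `results/table1.csv` (one row per bird, same columns as the
fixture above plus a mean row), `summary.csv`, per-isotope-set cluster
posterior tables, population count rasters and a run manifest.

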