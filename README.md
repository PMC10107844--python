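# monotrace

Quantification pipeline for monosynaptic rabies-tracing experiments in mouse
auditory cortex: detecting labelled cells in two-channel slice images,
classifying starter versus presynaptic input cells, mapping cells into a
flattened cortical coordinate system, and computing the connectivity
statistics used to compare input landscapes across interneuron subtypes
(PV, SST and VIP).

## Who this is for

In a rabies tracing experiment, starter cells co-express a helper construct
(mCherry) and the rabies reporter (GFP), while presynaptic input cells
express GFP alone. Quantifying the experiment means counting both populations
across hundreds of coronal slices, locating each cell in a common coordinate
frame, and summarising connectivity per animal and brain region. This package
implements that analysis chain as a tested library plus a thin CLI, together
with a synthetic-data generator so that every stage can be validated against
known ground truth without any imaging data.

## The quantities at the core

* **Convergence index (CI).** For an animal (or a region within an animal),
  CI = *n*(input cells) / *n*(starter cells) — inputs per starter,
  dimensionless. Starter counts vary several-fold between animals, so CI, not
  the raw count, is the comparable measure.
* **Proportion tables.** Per animal, the fraction of long-range input cells
  per region (local auditory regions A1/AuD/AuV excluded); rows sum to 1.
  Because CI_r and proportion_r are two normalisations of the same count,
  the ratio CI_r / proportion_r estimates one number per animal — its total
  long-range inputs per starter — which the packaged table reproduces to
  within a few percent for every animal (a strong internal-consistency
  check on printed, rounded values).
* **Flattened coordinates.** Each cell is mapped to (x, y) where y is its
  distance to the nearest point on the pia and x the signed arc length along
  the pia from the rhinal fissure to that point (dorsal positive). Layers are
  depth bins; regions are simplified per-slice polygons.
* **Starter classification rule.** After thresholding and morphological
  opening, a connected component of the green∧red overlap mask strictly
  larger than 5 px marks a starter; unclaimed green components are inputs.
* **Distance distributions.** Pairwise |input − starter| distances along the
  dorso-ventral or anterior-posterior axis (or each input's distance to the
  starter-population centre), compared between groups with the two-sample
  Kolmogorov–Smirnov test. Group effects on scalar measures use a
  Kruskal–Wallis omnibus gating Tukey HSD pairwise comparisons.

## Worked example

```python
import numpy as np
import monotrace as mt

# packaged long-range table: 14 animals (PV 4 / SST 6 / VIP 4), 50 regions
table = mt.load_table()
res = mt.implied_total_ci(table, "PV", "13")
print(f"PV-13 implied total long-range CI: {res.median:.2f} "
      f"(spread {100 * res.dispersion:.1f}%)")

# synthetic experiment at the study's default rates
cfg = mt.GeneratorConfig(n_animals_per_group={"PV": 2, "SST": 2, "VIP": 2})
truth = mt.simulate_experiment(cfg, seed=7)
cm = mt.build_count_matrix(truth.cells, truth.longrange_counts)
print(mt.ci_table(cm)[["group", "n_starters", "ci_total"]])

st = truth.cells[truth.cells.channel_class == "starter"]
inp = truth.cells[truth.cells.channel_class == "input"]
d_sst = mt.distance_sample(inp[inp.group == "SST"], st[st.group == "SST"],
                           axis="dv", mode="pairwise")
d_pv = mt.distance_sample(inp[inp.group == "PV"], st[st.group == "PV"],
                          axis="dv", mode="pairwise")
stat, p = mt.ks_compare(d_sst, d_pv)
print(f"KS SST vs PV: D={stat:.3f}, p={p:.3g}")
```

prints

```
PV-13 implied total long-range CI: 6.29 (spread 1.8%)
          group  n_starters   ci_total
animal_id
PV1          PV         252  31.801587
PV2          PV         383  31.872063
SST1        SST         291  36.415808
SST2        SST         358  36.418994
VIP1        VIP         117  39.555556
VIP2        VIP         176  39.130682
KS SST vs PV: D=0.144, p=0
```

The per-animal CIs scatter tightly around the configured per-starter input
rates (31.5 / 36.4 / 39.1 for PV / SST / VIP) regardless of how many starter
cells an animal happens to have, and the wider configured lateral spread of
SST local inputs (300 µm vs 150 µm) is detected decisively by the KS test.

## Command line

```bash
monotrace simulate --config cfg.yaml --out sim/ --seed 3 --render
monotrace detect   --images sim/images_PV1.tif --out cells.csv
monotrace register --cells sim/cells.csv --geometry sim/geometry.json --out flat.csv
monotrace stats    --cells flat.csv --counts sim/longrange_counts.csv --out results/
monotrace table    --check
```

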