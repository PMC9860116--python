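# retfid — retinal cell-identity mapping and organoid-fidelity benchmarking

`retfid` scores how faithfully human retinal organoids recapitulate the
cell types of the human eye. It is built for groups generating retinal
organoid scRNA-seq data who want a quantitative, reference-based answer to
"how good is my differentiation protocol?", and for anyone constructing
cell-identity references from multi-batch single-cell atlases.

The package covers the full pipeline: per-batch **differential-stability
scoring** of genes per cell type, robustness diagnostics (batch
subsampling, principal variance component analysis, clustering
concordance), **marker discovery and validation** (kNN classification,
random-forest importance), **maturation-gene discovery** by correlating
identity scores with developmental age, and a **six-metric benchmark** of
organoid datasets against mature and fetal tissue references. A synthetic
data generator with planted ground truth makes every stage testable
offline.

## The core statistic

For one (dataset, batch), each gene *g* gets two stability summaries per
cell type *k* over log-normalized values: the nonzero fraction
*nz(g, k)* and the coefficient of variation *cv(g, k)* (sd/mean; +∞ for
silent genes). Within each cell type, genes are rank-normalized
(ascending fractional ranks, ties averaged, divided by the gene count *G*,
so ranks lie in (0, 1]); stable identity genes have high rank on *nz* and
on −*cv*. With *m = (r_nz + r_−cv) / 2*, the identity score is the mean
pairwise contrast

```
score(g, k) = 1/(K−1) · Σ_{k′≠k} [ m(g, k) − m(g, k′) ]
```

For every gene the scores sum to zero across the *K* cell types and lie
strictly inside (−1, 1). Scores are computed per batch and averaged
across batches into reference atlases; being rank-based, they are robust
to batch effect, which the `robustness` module quantifies.

The six benchmark metrics per organoid unit (protocol × dataset × batch):
cell identity vs the mature and vs the fetal reference (mean per-cell-type
Pearson *r* of score profiles), a signed maturation trajectory correlation
(positive = adult-like, negative = fetal-like), coverage of the seven
major retinal types (RGC, amacrine, bipolar, horizontal, Müller glia,
rod, cone), cell-type proportion similarity (1 − total-variation
distance), and the off-target fraction from a nearest-centroid classifier
with rejection (unassigned + intermediate cells).

## Worked example

```python
import numpy as np
import retfid as rf

# 1. simulate a mature tissue atlas and an age-resolved fetal series
cfg = rf.SimConfig.default_fixture(seed=1)
tissue, ann, truth = rf.simulate_tissue(cfg)
fetal_cfg = rf.SimConfig.default_fixture(
    seed=1, n_batches=12, ages_dpc=list(np.linspace(50, 200, 12)))
fetal, fetal_ann, fetal_truth = rf.simulate_tissue(fetal_cfg)

# 2. per-batch identity scores and marker discovery
avg = rf.average_scores(rf.score_batches(tissue, ann))
markers = rf.select_markers(avg, top_n=5)
print("top rod markers:", markers.markers["rod"]["gene"].tolist())

# 3. benchmark two simulated organoid protocols against the references
mature_ref = rf.build_reference([(tissue, ann)], group="mature")
fetal_ref = rf.build_reference([(fetal, fetal_ann)], group="fetal")
lognorm = rf.log_normalize(tissue)
labels = ann.set_index("cell_id").loc[
    lognorm.cells.to_numpy(), "cell_type"].to_numpy()
units = []
for name, kw in [("late_organoid", {"age_position": 1.0}),
                 ("early_degraded", {"age_position": 0.1,
                                     "identity_noise_sd": 0.5,
                                     "dropped_types": {"RGC"},
                                     "offtarget_fraction": 0.2})]:
    om, oann, _ = rf.simulate_organoid(
        fetal_truth, rf.OrganoidSimConfig(seed=5, protocol=name, **kw))
    units.append((name, om, oann))
report = rf.benchmark(units, {"mature": mature_ref, "fetal": fetal_ref},
                      ref_train=(lognorm, labels))
print(report.raw[["ci_mature", "maturation", "coverage",
                  "proportion", "offtarget"]].round(3))
```

Output:

```
top rod markers: ['G01188', 'G00706', 'G01409', 'G00933', 'G00600']
                       ci_mature  maturation  coverage  proportion  offtarget
late_organoid|org|b0       0.922       0.966     1.000       1.000        0.0
early_degraded|org|b0      0.664      -0.832     0.857       0.857        0.2
```

The five rod markers are all planted rod markers of the simulation. The
faithful late-stage organoid correlates at *r* = 0.92 with the mature
reference, tracks the old end of the fetal trajectory (maturation +0.97),
contains all 7 expected cell types, matches the tissue composition and
produces no off-target cells, so it ranks first (combined score 0.997 vs
0.147). The degraded unit loses identity fidelity (0.66), looks
fetal-like (−0.83), misses RGCs (coverage 6/7) and carries exactly its
planted 20 % off-target admixture.

A thin CLI mirrors the pipeline stages
(`retfid simulate | ingest | score | build-ref | maturation | benchmark`);
run `retfid --help`.

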