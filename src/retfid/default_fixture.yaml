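# Shared simulation fixture: 7 retinal cell types in equal proportion,
# 2000 genes, 50 planted markers per type at a 2 natural-log fold effect,
# 4 batches of 1400 cells (200 cells per type per batch).
n_genes: 2000
cell_types:
  RGC: 0.14285714285714285
  amacrine: 0.14285714285714285
  bipolar: 0.14285714285714285
  horizontal: 0.14285714285714285
  muller_glia: 0.14285714285714285
  rod: 0.14285714285714285
  cone: 0.14285714285714288
n_markers: 50
marker_effect: 2.0
type_signal_sd: 0.5
n_batches: 4
batch_sd: 0.15
cells_per_batch: 1400
libsize_sdlog: 0.3
nb_dispersion: 0.3
n_ramp_genes: 20
ramp_slope: 4.0
seed: 0
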