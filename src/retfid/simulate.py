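"""Synthetic multi-batch retinal scRNA-seq with known ground truth.

The generator follows standard single-cell count phenomenology: per-gene
relative abundances are log-normal, counts are negative-binomial
(gamma-Poisson) around cell means given by library size x relative
abundance, and structure is planted on top:

* marker genes are up-shifted by a natural-log fold change in their own
  cell type;
* per-batch multiplicative gene factors (log-normal) emulate batch effect;
* age-ramp genes scale linearly with the batch's scaled developmental age,
  in their own cell type only, in either direction;
* organoid data re-draws cells from the tissue model with per-(gene, type)
  identity jitter, dropped types, Dirichlet-skewed proportions and an
  admixture of off-target cells from an unrelated expression program.

Every draw flows from a single integer seed, so outputs are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from ._exceptions import ConfigError
from .io import CANONICAL_TYPES, ExpressionMatrix

DEFAULT_PROPORTIONS = {ct: 1.0 / len(CANONICAL_TYPES)
                       for ct in CANONICAL_TYPES}


@dataclass
class SimConfig:
    """Parameters of the tissue simulator (defaults = standard fixture)."""

    n_genes: int = 2000
    cell_types: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    n_markers: int = 50
    marker_effect: float = 2.0  # natural-log fold change in own type
    type_signal_sd: float = 0.5  # global per-(gene, type) signature, ln scale
    n_batches: int = 4
    batch_sd: float = 0.15
    cells_per_batch: int = 1400
    libsize_meanlog: float = float(np.log(2500.0))
    libsize_sdlog: float = 0.3
    nb_dispersion: float = 0.3
    ages_dpc: Sequence[float] | None = None  # one age per batch
    n_ramp_genes: int = 20  # per type and direction
    ramp_slope: float = 4.0
    dataset: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        props = np.asarray(list(self.cell_types.values()), float)
        if abs(props.sum() - 1.0) > 1e-6 or (props < 0).any():
            raise ConfigError("cell-type proportions must form a simplex")
        if self.ages_dpc is not None and \
                len(self.ages_dpc) != self.n_batches:
            raise ConfigError("ages_dpc must have one age per batch")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def default_fixture(cls, **overrides) -> "SimConfig":
        """The shared default fixture (shipped as ``default_fixture.yaml``)."""
        text = resources.files("retfid").joinpath(
            "default_fixture.yaml").read_text()
        cfg = yaml.safe_load(text)
        cfg.update(overrides)
        return cls(**cfg)


@dataclass
class OrganoidSimConfig:
    """Degradation knobs for organoid simulation (all neutral by default)."""

    identity_noise_sd: float = 0.0
    dropped_types: frozenset[str] = frozenset()
    proportion_skew: float | None = None  # Dirichlet conc.; None = exact
    offtarget_fraction: float = 0.0
    age_position: float = 1.0  # 0 = youngest, 1 = oldest reference age
    n_cells: int = 1400
    protocol: str = "simproto"
    dataset: str = "org"
    batch: str = "b0"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.offtarget_fraction <= 1:
            raise ConfigError("offtarget_fraction must be in [0, 1]")
        self.dropped_types = frozenset(self.dropped_types)


@dataclass
class TissueTruth:
    """Ground truth of a simulated tissue dataset."""

    genes: pd.Index
    rel_expr: pd.Series  # baseline relative abundance per gene
    type_factors: pd.DataFrame  # gene x type multiplicative signature
    markers: dict[str, list[str]]  # per type
    ramps: dict[str, dict[str, list[str]]]  # per type: positive / negative
    proportions: pd.Series
    config: SimConfig


def _allocate(n: int, props: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n cells to proportions."""
    raw = props * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with var = m + phi m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _type_means(truth: TissueTruth, scaled_age: float | None
                ) -> dict[str, np.ndarray]:
    """Per-type relative expression including marker and ramp effects."""
    cfg = truth.config
    genes = truth.genes
    base = truth.rel_expr.to_numpy(float)
    out = {}
    for ct in truth.proportions.index:
        mu = base * truth.type_factors[ct].to_numpy(float)
        idx = genes.get_indexer(truth.markers[ct])
        mu[idx] *= np.exp(cfg.marker_effect)
        if scaled_age is not None and ct in truth.ramps:
            up = genes.get_indexer(truth.ramps[ct]["positive"])
            dn = genes.get_indexer(truth.ramps[ct]["negative"])
            mu[up] *= 1.0 + cfg.ramp_slope * scaled_age
            mu[dn] *= 1.0 + cfg.ramp_slope * (1.0 - scaled_age)
        out[ct] = mu
    return out


def simulate_tissue(cfg: SimConfig
                    ) -> tuple[ExpressionMatrix, pd.DataFrame, TissueTruth]:
    """Simulate a multi-batch tissue dataset with planted structure."""
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"G{i:05d}" for i in range(cfg.n_genes)], name="gene")
    rel = pd.Series(rng.lognormal(0.0, 1.0, cfg.n_genes), index=genes)
    types = list(cfg.cell_types)
    need = len(types) * (cfg.n_markers + 2 * cfg.n_ramp_genes)
    if need > cfg.n_genes:
        raise ConfigError("not enough genes for the requested markers/ramps")
    # planted markers / ramp genes come from the moderate-abundance band
    # of the transcriptome: dropout-silent genes cannot act as detectable
    # identity genes, and ubiquitous high-abundance genes have saturated
    # detection in every type — neither is a plausible marker
    lo, hi = np.quantile(rel, [0.2, 0.6])
    eligible = np.flatnonzero((rel.to_numpy() >= lo) & (rel.to_numpy() <= hi))
    if need > len(eligible):
        raise ConfigError("not enough expressed genes for markers/ramps")
    special = rng.choice(eligible, size=need, replace=False)
    pos = 0
    markers: dict[str, list[str]] = {}
    ramps: dict[str, dict[str, list[str]]] = {}
    for ct in types:
        markers[ct] = genes[special[pos:pos + cfg.n_markers]].tolist()
        pos += cfg.n_markers
        ramps[ct] = {
            "positive": genes[special[pos:pos + cfg.n_ramp_genes]].tolist(),
            "negative": genes[special[pos + cfg.n_ramp_genes:
                                      pos + 2 * cfg.n_ramp_genes]].tolist(),
        }
        pos += 2 * cfg.n_ramp_genes
    props = pd.Series(cfg.cell_types, dtype=float)
    # every gene carries a mild type-specific signature on top of its
    # baseline abundance: real cell types differ transcriptome-wide, not
    # only in their canonical markers.  The signature is bounded (ln-uniform
    # with matching sd) so that planted markers remain, by construction,
    # the strongest identity genes
    half_width = cfg.type_signal_sd * np.sqrt(3.0)
    type_factors = pd.DataFrame(
        np.exp(rng.uniform(-half_width, half_width,
                           (cfg.n_genes, len(types)))),
        index=genes, columns=types)
    # a planted marker's type signature is exactly its planted effect;
    # overlaying a second random signature would make the truth ill-defined
    for ct in types:
        type_factors.loc[markers[ct]] = 1.0
    truth = TissueTruth(genes=genes, rel_expr=rel, type_factors=type_factors,
                        markers=markers, ramps=ramps, proportions=props,
                        config=cfg)

    ages = cfg.ages_dpc
    if ages is not None:
        ages = np.asarray(ages, float)
        span = np.ptp(ages)
        scaled_ages = (ages - ages.min()) / span if span > 0 \
            else np.zeros_like(ages)
    blocks, ann_rows = [], []
    for b in range(cfg.n_batches):
        batch_factor = rng.lognormal(0.0, cfg.batch_sd, cfg.n_genes)
        sa = None if ages is None else float(scaled_ages[b])
        means = _type_means(truth, sa)
        n_per = _allocate(cfg.cells_per_batch, props.to_numpy())
        for ct, n_ct in zip(types, n_per):
            if n_ct == 0:
                continue
            p = means[ct] * batch_factor
            p = p / p.sum()
            lib = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, n_ct)
            mean = np.outer(p, lib)
            counts = _nb_counts(rng, mean, cfg.nb_dispersion)
            blocks.append(sp.csr_matrix(counts))
            for i in range(n_ct):
                ann_rows.append({
                    "cell_id": f"{cfg.dataset}_b{b}_{ct}_{i}",
                    "cell_type": ct, "dataset": cfg.dataset,
                    "batch": f"b{b}",
                    "source": ("tissue_fetal" if ages is not None
                               else "tissue_mature"),
                    "protocol": None,
                    "age_dpc": None if ages is None else float(ages[b]),
                })
    values = sp.hstack(blocks, format="csr")
    ann = pd.DataFrame(ann_rows)
    m = ExpressionMatrix(values, genes, pd.Index(ann["cell_id"]),
                         layer="counts")
    return m, ann, truth


def simulate_organoid(truth: TissueTruth, ocfg: OrganoidSimConfig
                      ) -> tuple[ExpressionMatrix, pd.DataFrame,
                                 pd.DataFrame]:
    """Draw an organoid unit from a degraded copy of the tissue model.

    Returns the count matrix, an annotation table (off-target cells are
    labeled ``"other"``) and a per-cell truth table with an
    ``is_offtarget`` flag.
    """
    cfg = truth.config
    rng = np.random.default_rng(ocfg.seed)
    kept = [ct for ct in truth.proportions.index
            if ct not in ocfg.dropped_types]
    if not kept:
        raise ConfigError("all cell types dropped")
    base = truth.proportions[kept].to_numpy(float)
    base = base / base.sum()
    if ocfg.proportion_skew is None or np.isinf(ocfg.proportion_skew):
        props = base
    else:
        props = rng.dirichlet(ocfg.proportion_skew * base)
    n_off = int(np.floor(ocfg.offtarget_fraction * ocfg.n_cells))
    n_on = ocfg.n_cells - n_off
    n_per = _allocate(n_on, props)

    sa = ocfg.age_position if cfg.ages_dpc is not None else None
    means = _type_means(truth, sa)
    blocks, ann_rows, truth_rows = [], [], []
    for ct, n_ct in zip(kept, n_per):
        if n_ct == 0:
            continue
        jitter = (rng.lognormal(0.0, ocfg.identity_noise_sd, cfg.n_genes)
                  if ocfg.identity_noise_sd > 0 else 1.0)
        p = means[ct] * jitter
        p = p / p.sum()
        lib = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, n_ct)
        counts = _nb_counts(rng, np.outer(p, lib), cfg.nb_dispersion)
        blocks.append(sp.csr_matrix(counts))
        for i in range(n_ct):
            cid = f"{ocfg.dataset}_{ct}_{i}"
            ann_rows.append({"cell_id": cid, "cell_type": ct,
                             "dataset": ocfg.dataset, "batch": ocfg.batch,
                             "source": "organoid",
                             "protocol": ocfg.protocol, "age_dpc": None})
            truth_rows.append({"cell_id": cid, "true_type": ct,
                               "is_offtarget": False})
    if n_off:
        rel_off = rng.lognormal(0.0, 1.0, cfg.n_genes)
        p = rel_off / rel_off.sum()
        lib = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, n_off)
        counts = _nb_counts(rng, np.outer(p, lib), cfg.nb_dispersion)
        blocks.append(sp.csr_matrix(counts))
        for i in range(n_off):
            cid = f"{ocfg.dataset}_offtarget_{i}"
            ann_rows.append({"cell_id": cid, "cell_type": "other",
                             "dataset": ocfg.dataset, "batch": ocfg.batch,
                             "source": "organoid",
                             "protocol": ocfg.protocol, "age_dpc": None})
            truth_rows.append({"cell_id": cid, "true_type": "offtarget",
                               "is_offtarget": True})
    values = sp.hstack(blocks, format="csr")
    ann = pd.DataFrame(ann_rows)
    m = ExpressionMatrix(values, truth.genes, pd.Index(ann["cell_id"]),
                         layer="counts")
    return m, ann, pd.DataFrame(truth_rows)
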