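"""Synthetic single-cell count data with planted ground truth.

The generator emulates the structure of an embryonic MGE single-cell cohort:
two dominant populations (proliferating neural progenitors and immature
neurons) whose mixing proportions shift with embryonic age, nested
sub-populations inside each population, a handful of rare non-neuronal cells
each carrying at least four exclusive marker genes, negative-binomial counts
with lognormal cell-wise library-size variation, a flagged mitochondrial gene
set, and per-cell total-read metadata spanning the 2-million-read QC
boundary (planted low-quality cells fall below it and carry an inflated
mitochondrial load).

Counts are drawn as a gamma-Poisson mixture: count(g,c) ~ Poisson(lambda),
lambda ~ Gamma(1/a, a * mu(g,c)) with shared dispersion a, so that
mean = mu and var = mu + a * mu^2. Gene means are bimodal by design —
"expressed" background genes are detected in nearly every cell and "silent"
genes in almost none — so planted markers are the only genes that can satisfy
the marker rule and the planted truth is exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import CountMatrix, ValidationError
from .qpcr import CtMatrix

__all__ = [
    "SubpopSpec",
    "PopulationSpec",
    "RareTypeSpec",
    "SimConfig",
    "SimTruth",
    "default_config",
    "default_reference_config",
    "simulate_counts",
    "simulate_reference",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class SubpopSpec:
    name: str
    proportion: float
    de_genes: tuple  # ((gene index, log2 effect), ...)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    proportion_per_condition: dict  # condition -> proportion in [0, 1]
    de_genes: tuple
    subpopulations: tuple = ()


@dataclass(frozen=True)
class RareTypeSpec:
    name: str
    n_cells: int
    marker_genes: tuple  # >= 4 exclusive gene indices
    marker_mean: float = 50.0


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults live in default_config()."""

    n_genes: int
    n_cells_per_condition: dict
    populations: tuple
    rare_types: tuple = ()
    dual_signature_cells: tuple = ()  # ((type_x, type_y), ...) one cell each
    nb_dispersion: float = 0.5
    library_size_lognormal: tuple = (0.0, 0.25)
    mito_gene_fraction: float = 0.015
    mito_expression_scale: float = 8.0
    total_reads_range: tuple = (2_200_000, 4_000_000)
    low_quality_reads_range: tuple = (600_000, 1_800_000)
    n_low_quality: int = 8
    expressed_gene_fraction: float = 0.7
    expressed_mean_log: tuple = (np.log(8.0), 0.8)  # lognormal for expressed genes
    silent_mean: float = 0.02
    reference_cells_per_class: int = 20
    reference_dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be > 0")
        conditions = list(self.n_cells_per_condition)
        for cond in conditions:
            total = sum(p.proportion_per_condition.get(cond, 0.0) for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"population proportions for {cond!r} sum to {total}, expected 1"
                )
        for pop in self.populations:
            if pop.subpopulations:
                s = sum(sp.proportion for sp in pop.subpopulations)
                if abs(s - 1.0) > 1e-9:
                    raise ValidationError(
                        f"subpopulation proportions of {pop.name!r} sum to {s}"
                    )
        used_markers: set = set()
        for rt in self.rare_types:
            if len(rt.marker_genes) < 4:
                raise ValidationError(f"rare type {rt.name!r} needs >= 4 exclusive markers")
            if set(rt.marker_genes) & used_markers:
                raise ValidationError(f"markers of {rt.name!r} are not exclusive")
            used_markers |= set(rt.marker_genes)
        for idx in self._all_effect_indices():
            if not (0 <= idx < self.n_genes):
                raise ValidationError(f"gene index {idx} out of range")
        known = {rt.name for rt in self.rare_types}
        for tx, ty in self.dual_signature_cells:
            if tx not in known or ty not in known:
                raise ValidationError(f"dual-signature pair ({tx}, {ty}) names unknown types")

    def _all_effect_indices(self):
        for rt in self.rare_types:
            yield from rt.marker_genes
        for pop in self.populations:
            for idx, _ in pop.de_genes:
                yield idx
            for sp in pop.subpopulations:
                for idx, _ in sp.de_genes:
                    yield idx


@dataclass
class SimTruth:
    """Planted ground truth for a simulated cohort.

    ``cells`` is indexed by cell_id with population, subpopulation, rare_type,
    is_low_quality and is_dual_signature columns; ``markers`` maps rare-type
    name to its planted marker gene ids; ``de_genes`` maps population name to
    {gene_id: signed log2 effect}.
    """

    cells: pd.DataFrame
    markers: dict
    de_genes: dict
    meta: dict = field(default_factory=dict)


def _block(start: int, n: int, effect: float) -> tuple:
    return tuple((i, effect) for i in range(start, start + n))


def default_config(seed: int = 0) -> SimConfig:
    """The default synthetic MGE-like cohort.

    Condition cell counts follow the embryonic cohort sizes of the study
    system (E11.5=96, E13.5=48, E15.5=63, E17.5=18); per-age population
    mixing follows the observed composition, with the immature-neuron share
    rising steeply at the later ages. Three rare non-neuronal types (microglia,
    astrocyte, endothelial) carry five exclusive markers each, one planted
    cell co-expresses two types' markers to exercise the conflict path, and
    eight planted low-quality cells sit below the 2M-read / above the 5%-mito
    QC gates.
    """
    # per-age progenitor shares follow the study's observed two-population
    # composition (61/46/76/93% immature neurons at E11.5/E13.5/E15.5/E17.5)
    prog_prop = {"E11.5": 0.39, "E13.5": 0.54, "E15.5": 0.24, "E17.5": 0.07}
    neu_prop = {c: round(1.0 - p, 10) for c, p in prog_prop.items()}
    rare = (
        RareTypeSpec("microglia", 4, tuple(range(0, 5))),
        RareTypeSpec("astrocyte", 4, tuple(range(5, 10))),
        RareTypeSpec("endothelial", 1, tuple(range(10, 15))),
    )
    populations = (
        PopulationSpec(
            "progenitor",
            prog_prop,
            de_genes=_block(15, 60, 2.5),
            subpopulations=(
                SubpopSpec("VZ-mito-ribo", 0.30, _block(135, 25, 2.5)),
                SubpopSpec("VZ-replication", 0.30, _block(160, 25, 2.5)),
                SubpopSpec("SVZ-Gad2", 0.20, _block(185, 25, 2.5)),
                SubpopSpec("SVZ-Arx", 0.20, _block(210, 25, 2.5)),
            ),
        ),
        PopulationSpec(
            "neuron",
            neu_prop,
            de_genes=_block(75, 60, 2.5),
            subpopulations=(
                SubpopSpec("MGE-neuron", 0.40, _block(235, 25, 2.5)),
                SubpopSpec("LGE-neuron", 0.35, _block(260, 25, 2.5)),
                SubpopSpec("mixed-neuron", 0.25, _block(285, 25, 2.5)),
            ),
        ),
    )
    return SimConfig(
        n_genes=2000,
        n_cells_per_condition={"E11.5": 96, "E13.5": 48, "E15.5": 63, "E17.5": 18},
        populations=populations,
        rare_types=rare,
        dual_signature_cells=(("microglia", "astrocyte"),),
        seed=seed,
    )


def default_reference_config(seed: int = 0) -> SimConfig:
    """Labelled reference default: 3 classes x 20 cells, 5 exclusive markers each."""
    cfg = default_config(seed=seed)
    cfg.reference_cells_per_class = 20
    return cfg


def _largest_remainder(total: int, proportions: list) -> list:
    """Integer allocation of ``total`` by proportions, exact and deterministic."""
    raw = [total * p for p in proportions]
    base = [int(np.floor(r)) for r in raw]
    short = total - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def _gene_table(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Gene annotation plus base means and the set of planted (non-background) genes."""
    n = cfg.n_genes
    gene_ids = [f"g{i:04d}" for i in range(n)]
    lengths = rng.integers(500, 5001, size=n)
    planted = sorted(set(cfg._all_effect_indices()))
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted] = True
    marker_mask = np.zeros(n, dtype=bool)
    for rt in cfg.rare_types:
        marker_mask[list(rt.marker_genes)] = True

    mu_log, sd_log = cfg.expressed_mean_log
    base = rng.lognormal(mu_log, sd_log, size=n)
    background = ~planted_mask
    silent = background & (rng.random(n) > cfg.expressed_gene_fraction)
    base[silent] = cfg.silent_mean
    base[marker_mask] = 0.0  # exclusive markers: zero outside the owning type

    n_mito = int(round(cfg.mito_gene_fraction * n))
    candidates = np.flatnonzero(background & ~silent)
    mito_idx = rng.choice(candidates, size=n_mito, replace=False)
    is_mito = np.zeros(n, dtype=bool)
    is_mito[mito_idx] = True
    symbols = [
        (f"mt-Gene{i}" if is_mito[i] else f"Gene{i}") for i in range(n)
    ]
    genes = pd.DataFrame(
        {"symbol": symbols, "length_bp": lengths, "is_mitochondrial": is_mito},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return genes, base, is_mito


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and var mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    return rng.poisson(lam)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, SimTruth]:
    """Generate the synthetic cohort count matrix with its planted truth."""
    rng = np.random.default_rng(cfg.seed)
    genes, base, is_mito = _gene_table(cfg, rng)
    gene_ids = genes.index

    cell_rows = []  # (cell_id, condition, population, subpopulation, rare_type, dual)
    log2_effect_cols = []
    for cond, n_cells in cfg.n_cells_per_condition.items():
        pops = list(cfg.populations)
        alloc = _largest_remainder(n_cells, [p.proportion_per_condition[cond] for p in pops])
        i_cell = 0
        for pop, n_pop in zip(pops, alloc):
            if pop.subpopulations:
                sub_alloc = _largest_remainder(n_pop, [sp.proportion for sp in pop.subpopulations])
            else:
                sub_alloc = [n_pop]
            subs = list(pop.subpopulations) or [None]
            for sp, n_sub in zip(subs, sub_alloc):
                for _ in range(n_sub):
                    eff = np.zeros(cfg.n_genes)
                    for idx, e in pop.de_genes:
                        eff[idx] += e
                    if sp is not None:
                        for idx, e in sp.de_genes:
                            eff[idx] += e
                    cell_rows.append(
                        (f"{cond}_c{i_cell:03d}", cond, pop.name,
                         sp.name if sp else None, None, False)
                    )
                    log2_effect_cols.append(eff)
                    i_cell += 1

    first_cond = next(iter(cfg.n_cells_per_condition))
    for rt in cfg.rare_types:
        for j in range(rt.n_cells):
            eff = np.zeros(cfg.n_genes)
            cell_rows.append((f"{rt.name}_r{j}", first_cond, None, None, rt.name, False))
            log2_effect_cols.append(eff)
    for j, (tx, ty) in enumerate(cfg.dual_signature_cells):
        cell_rows.append((f"dual_{tx}_{ty}_{j}", first_cond, None, None, None, True))
        log2_effect_cols.append(np.zeros(cfg.n_genes))

    n_cells_total = len(cell_rows)
    cell_ids = [r[0] for r in cell_rows]
    mu = base[:, None] * np.power(2.0, np.array(log2_effect_cols).T)

    # marker expression: owning rare type (and planted dual-signature cells)
    rt_by_name = {rt.name: rt for rt in cfg.rare_types}
    for j, row in enumerate(cell_rows):
        if row[4] is not None:
            rt = rt_by_name[row[4]]
            mu[list(rt.marker_genes), j] = rt.marker_mean
    dual_iter = iter(cfg.dual_signature_cells)
    for j, row in enumerate(cell_rows):
        if row[5]:  # dual-signature cell: both named types' markers fire
            tx, ty = next(dual_iter)
            mu[list(rt_by_name[tx].marker_genes), j] = rt_by_name[tx].marker_mean
            mu[list(rt_by_name[ty].marker_genes), j] = rt_by_name[ty].marker_mean

    # planted low-quality cells: inflate mitochondrial means, low read totals
    pop_cell_idx = [j for j, r in enumerate(cell_rows) if r[2] is not None]
    n_lowq = min(cfg.n_low_quality, len(pop_cell_idx))
    lowq_idx = rng.choice(pop_cell_idx, size=n_lowq, replace=False) if n_lowq else []
    is_lowq = np.zeros(n_cells_total, dtype=bool)
    is_lowq[lowq_idx] = True
    mu[np.ix_(is_mito, is_lowq)] *= cfg.mito_expression_scale

    lib = rng.lognormal(*cfg.library_size_lognormal, size=n_cells_total)
    counts = _nb_counts(rng, mu * lib[None, :], cfg.nb_dispersion)

    reads = rng.integers(*cfg.total_reads_range, size=n_cells_total)
    lo, hi = cfg.low_quality_reads_range
    reads[is_lowq] = rng.integers(lo, hi, size=int(is_lowq.sum()))

    cells = pd.DataFrame(
        {
            "condition": [r[1] for r in cell_rows],
            "total_mapped_reads": reads,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=cells.index), genes, cells, unit="reads"
    )
    truth_cells = pd.DataFrame(
        {
            "condition": [r[1] for r in cell_rows],
            "population": [r[2] for r in cell_rows],
            "subpopulation": [r[3] for r in cell_rows],
            "rare_type": [r[4] for r in cell_rows],
            "is_low_quality": is_lowq,
            "is_dual_signature": [r[5] for r in cell_rows],
        },
        index=cells.index,
    )
    markers = {
        rt.name: [gene_ids[i] for i in rt.marker_genes] for rt in cfg.rare_types
    }
    de_map = {
        pop.name: {gene_ids[i]: e for i, e in pop.de_genes} for pop in cfg.populations
    }
    for pop in cfg.populations:
        for sp in pop.subpopulations:
            de_map[f"{pop.name}/{sp.name}"] = {gene_ids[i]: e for i, e in sp.de_genes}
    return cm, SimTruth(
        truth_cells, markers, de_map,
        meta={
            "seed": cfg.seed,
            "base_means": pd.Series(base, index=gene_ids),
            "library_factors": pd.Series(lib, index=cells.index),
        },
    )


def simulate_reference(cfg: SimConfig) -> tuple[CountMatrix, pd.Series]:
    """Labelled molecule-count reference with the config's rare types as classes.

    Each class expresses its planted markers at a level that clears the
    marker rule (norm >= 1 in >= 75% of its cells) under the defaults;
    classes configured with zero cells are omitted from the labels.
    """
    if not cfg.rare_types:
        raise ValidationError("reference simulation needs rare_types as classes")
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_genes
    gene_ids = pd.Index([f"g{i:04d}" for i in range(n)], name="gene_id")
    marker_mask = np.zeros(n, dtype=bool)
    for rt in cfg.rare_types:
        marker_mask[list(rt.marker_genes)] = True

    mu_log, sd_log = cfg.expressed_mean_log
    base = rng.lognormal(mu_log, sd_log, size=n)
    silent = ~marker_mask & (rng.random(n) > cfg.expressed_gene_fraction)
    base[silent] = cfg.silent_mean
    base[marker_mask] = 0.0

    per_class = cfg.reference_cells_per_class
    cols, labels, mus = [], [], []
    for rt in cfg.rare_types:
        n_class = per_class.get(rt.name, 0) if isinstance(per_class, dict) else per_class
        # a class configured with zero cells is simply omitted from the labels
        for j in range(n_class):
            mu = base.copy()
            mu[list(rt.marker_genes)] = rt.marker_mean
            cols.append(f"{rt.name}_ref{j:02d}")
            labels.append(rt.name)
            mus.append(mu)
    if not cols:
        raise ValidationError("no reference cells generated")
    mu_mat = np.array(mus).T
    lib = rng.lognormal(0.0, 0.15, size=len(cols))
    counts = _nb_counts(rng, mu_mat * lib[None, :], cfg.reference_dispersion)

    lengths = rng.integers(500, 5001, size=n)
    genes = pd.DataFrame(
        {
            "symbol": [f"Gene{i}" for i in range(n)],
            "length_bp": lengths,
            "is_mitochondrial": np.zeros(n, dtype=bool),
        },
        index=gene_ids,
    )
    cells = pd.DataFrame(
        {"condition": "reference", "total_mapped_reads": counts.sum(axis=0)},
        index=pd.Index(cols, name="cell_id"),
    )
    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=cells.index),
        genes, cells, unit="molecules",
    )
    return cm, pd.Series(labels, index=cells.index, name="level1class")


QPCR_GENES = [
    "Actb", "Vim", "H2afv", "Lmo1", "Olig2", "Hes1", "Notch1", "Sox2",
    "Tubb3", "Stmn2", "Gng3", "Gap43", "Lhx6", "Gad1", "Gad2", "Dcx",
]


def simulate_qpcr(
    n_genes: int = 16, n_cells: int = 60, missing_rate: float = 0.1,
    seed: int = 0, gene_names: list | None = None,
) -> tuple[CtMatrix, pd.Series]:
    """Simulate a single-cell qPCR Ct matrix with two planted populations.

    Genes alternate between a progenitor-high and a neuron-high program
    (about 5 cycles apart between populations); Actb is constant up to a
    per-cell assay offset and is never missing. Missing reactions appear at
    ``missing_rate`` as NaN. Returns the Ct matrix and the planted labels.
    """
    if not (0 <= missing_rate < 1):
        raise ValidationError("missing_rate must lie in [0, 1)")
    if gene_names is None:
        gene_names = (QPCR_GENES + [f"Gene{i}" for i in range(len(QPCR_GENES), n_genes)])[:n_genes]
    if "Actb" not in gene_names:
        raise ValidationError("gene list must include the reference gene Actb")
    rng = np.random.default_rng(seed)
    genes = pd.Index(gene_names, name="gene")
    cell_ids = pd.Index([f"q{j:03d}" for j in range(n_cells)], name="cell_id")
    labels = pd.Series(
        ["progenitor" if j < n_cells // 2 else "neuron" for j in range(n_cells)],
        index=cell_ids, name="population",
    )

    base_ct = rng.uniform(18.0, 26.0, size=n_genes)
    cell_offset = rng.normal(0.0, 0.5, size=n_cells)
    ct = np.empty((n_genes, n_cells))
    is_neuron = (labels == "neuron").to_numpy()
    for i, g in enumerate(gene_names):
        if g == "Actb":
            row = 15.0 + cell_offset
        else:
            prog_high = i % 2 == 1  # alternate programs over the non-reference genes
            shift = np.where(is_neuron != prog_high, -5.0, 0.0)
            row = base_ct[i] + shift + cell_offset
        ct[i] = row + rng.normal(0.0, 0.8, size=n_cells)
    ct = np.clip(ct, 10.0, 35.0)

    # failed reactions concentrate in weak (high-Ct) wells, as on a real chip;
    # the overall missing fraction is held at missing_rate exactly
    maskable = np.ones((n_genes, n_cells), dtype=bool)
    maskable[gene_names.index("Actb"), :] = False
    n_mask = int(round(missing_rate * maskable.sum()))
    if n_mask:
        weights = np.exp((ct - ct.max()) / 2.0).ravel()[maskable.ravel()]
        flat = np.flatnonzero(maskable.ravel())
        chosen = rng.choice(flat, size=n_mask, replace=False, p=weights / weights.sum())
        ct.ravel()[chosen] = np.nan
    cm = CtMatrix(pd.DataFrame(ct, index=genes, columns=cell_ids))
    return cm, labels
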