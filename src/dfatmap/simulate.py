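"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* a negative-binomial UMI count simulator with planted cluster marker
  programs, per-cell library-size variation, mitochondrial genes and
  injected low-quality cells — including paired query/reference datasets
  whose clusters share marker programs through a known correspondence;
* a three-condition (CD, HFD, HFD-CD) CpG methylome simulator that plants
  Pattern 1/2/3 diet-reversibility structure around gene TSSs on a
  synthetic chromosome, with binomial read sampling at Poisson coverage.

Both are deterministic given their seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix
from .methylation import MethylationTrack

__all__ = [
    "ScSimConfig",
    "MethSimConfig",
    "TruthLabels",
    "simulate_sc_dataset",
    "simulate_query_reference_pair",
    "simulate_methylomes",
    "write_fixtures",
    "LOW_QUALITY_LABEL",
]

LOW_QUALITY_LABEL = "low_quality"
_CHROM = "chrSim"


@dataclass(frozen=True)
class ScSimConfig:
    """Single-cell simulation parameters.

    Counts are negative binomial with variance mu + mu^2/dispersion; marker
    genes of a cell's own cluster have their mean multiplied by
    ``marker_fold_change``.  ``libsize_cv`` is the coefficient of variation
    of a per-cell lognormal library-size multiplier (mean 1).
    """

    n_genes: int = 1200
    n_cells_per_cluster: tuple[int, ...] = (150, 150, 150)
    n_marker_genes_per_cluster: int = 60
    marker_fold_change: float = 4.0
    baseline_mean: float = 1.0
    gene_mean_cv: float = 0.3
    nb_dispersion: float = 10.0
    libsize_cv: float = 0.1
    frac_mito_genes: float = 0.03
    n_lowquality_cells: int = 0
    seed: int = 0
    n_query_cells_per_cluster: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.n_cells_per_cluster) == 0 or any(
            n <= 0 for n in self.n_cells_per_cluster
        ):
            raise ValueError("n_cells_per_cluster must be positive integers")
        if self.n_marker_genes_per_cluster <= 0:
            raise ValueError("n_marker_genes_per_cluster must be positive")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be positive")
        if self.libsize_cv < 0 or self.gene_mean_cv < 0:
            raise ValueError("libsize_cv and gene_mean_cv must be >= 0")
        if not 0 <= self.frac_mito_genes <= 1:
            raise ValueError("frac_mito_genes must be in [0, 1]")
        if self.n_lowquality_cells < 0:
            raise ValueError("n_lowquality_cells must be >= 0")
        n_mito = int(round(self.frac_mito_genes * self.n_genes))
        needed = len(self.n_cells_per_cluster) * self.n_marker_genes_per_cluster
        if needed > self.n_genes - n_mito:
            raise ValueError("not enough non-mitochondrial genes for marker programs")

    @property
    def n_clusters(self) -> int:
        return len(self.n_cells_per_cluster)

    @property
    def cluster_names(self) -> list[str]:
        return [f"C{i}" for i in range(self.n_clusters)]


@dataclass
class TruthLabels:
    """Ground truth of a simulation.

    ``cell_to_cluster`` maps every simulated cell (reference and, for paired
    simulations, query) to its planted cluster; ``cluster_markers`` maps each
    cluster to its marker gene list; ``correspondence`` maps query clusters
    to reference clusters for paired simulations.
    """

    cell_to_cluster: pd.Series
    cluster_markers: dict[str, list[str]]
    correspondence: dict[str, str] = field(default_factory=dict)


def _gene_universe(config: ScSimConfig):
    n_mito = int(round(config.frac_mito_genes * config.n_genes))
    n_main = config.n_genes - n_mito
    genes = [f"Gene{i:05d}" for i in range(n_main)] + [
        f"mt-Gene{i:05d}" for i in range(n_mito)
    ]
    mito = np.zeros(config.n_genes, dtype=bool)
    mito[n_main:] = True
    flags = pd.DataFrame({"mito": mito, "nuclear": ~mito}, index=pd.Index(genes))
    return pd.Index(genes), flags


def _marker_map(config: ScSimConfig, genes: pd.Index) -> dict[str, list[str]]:
    nm = config.n_marker_genes_per_cluster
    return {
        name: list(genes[i * nm : (i + 1) * nm])
        for i, name in enumerate(config.cluster_names)
    }


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def _lib_factors(rng, n: int, cv: float) -> np.ndarray:
    if cv == 0 or n == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=n)


def _gene_mean_factors(rng, config: ScSimConfig) -> np.ndarray:
    """Per-gene lognormal mean factor (mean 1, CV = gene_mean_cv), giving
    genes a realistic spread of expression levels.

    Marker genes keep factor 1 so the planted fold change acts on a known
    baseline (markers are, by construction, decently expressed genes).
    """
    if config.gene_mean_cv == 0:
        return np.ones(config.n_genes)
    sigma2 = math.log1p(config.gene_mean_cv**2)
    factors = rng.lognormal(-sigma2 / 2, math.sqrt(sigma2), size=config.n_genes)
    n_marker = config.n_clusters * config.n_marker_genes_per_cluster
    factors[:n_marker] = 1.0
    return factors


def _simulate_cells(
    rng,
    config: ScSimConfig,
    genes: pd.Index,
    markers: dict[str, list[str]],
    sizes: dict[str, int],
    marker_program: dict[str, str],
    cell_prefix: str,
    gene_factors: np.ndarray,
) -> tuple[sp.csr_matrix, pd.Index, pd.Series]:
    """Simulate cluster blocks; ``marker_program[cluster]`` names the marker
    set (possibly of another cluster, for query simulations) whose genes are
    elevated."""
    blocks, cell_ids, labels = [], [], []
    counter = 0
    for cname, size in sizes.items():
        if size == 0:
            continue
        mean = config.baseline_mean * gene_factors.copy()
        midx = genes.get_indexer(pd.Index(markers[marker_program[cname]]))
        mean[midx] *= config.marker_fold_change
        lib = _lib_factors(rng, size, config.libsize_cv)
        mu = mean[:, None] * lib[None, :]
        blocks.append(sp.csr_matrix(_nb_draw(rng, mu, config.nb_dispersion)))
        cell_ids.extend(f"{cell_prefix}{counter + j:05d}" for j in range(size))
        labels.extend([cname] * size)
        counter += size
    if blocks:
        counts = sp.hstack(blocks, format="csr")
    else:
        counts = sp.csr_matrix((config.n_genes, 0), dtype=np.int64)
    idx = pd.Index(cell_ids)
    return counts, idx, pd.Series(labels, index=idx)


def _lowquality_block(
    rng, config: ScSimConfig, genes: pd.Index, flags: pd.DataFrame, prefix: str
) -> tuple[sp.csr_matrix, pd.Index]:
    """Cells violating at least one default QC gate.

    Even-indexed cells carry counts on only a handful of genes (fails the
    detected-gene and nuclear-gene minima); odd-indexed cells get a plausible
    transcriptome plus a mitochondrial count boost pushing pct_mito to ~33%.
    """
    n = config.n_lowquality_cells
    cols = []
    mito_idx = np.flatnonzero(flags["mito"].to_numpy())
    nuclear_idx = np.flatnonzero(flags["nuclear"].to_numpy())
    for j in range(n):
        col = np.zeros(config.n_genes, dtype=np.int64)
        if j % 2 == 0 or len(mito_idx) == 0:
            pick = nuclear_idx[: min(5, len(nuclear_idx))]
            col[pick] = 1
        else:
            mu = np.full(config.n_genes, config.baseline_mean)
            col = _nb_draw(rng, mu[:, None], config.nb_dispersion).ravel()
            boost = int(np.ceil(0.5 * max(col.sum(), 1)))
            col[rng.choice(mito_idx)] += boost
        cols.append(sp.csr_matrix(col[:, None]))
    counts = (
        sp.hstack(cols, format="csr")
        if cols
        else sp.csr_matrix((config.n_genes, 0), dtype=np.int64)
    )
    return counts, pd.Index([f"{prefix}lq{j:03d}" for j in range(n)])


def simulate_sc_dataset(config: ScSimConfig) -> tuple[CountMatrix, TruthLabels]:
    """Simulate one clustered dataset; marker sets of distinct clusters are
    disjoint by construction.  Injected low-quality cells carry the label
    ``low_quality``."""
    rng = np.random.default_rng(config.seed)
    genes, flags = _gene_universe(config)
    markers = _marker_map(config, genes)
    sizes = dict(zip(config.cluster_names, config.n_cells_per_cluster))
    program = {c: c for c in config.cluster_names}
    gene_factors = _gene_mean_factors(rng, config)
    counts, cells, labels = _simulate_cells(
        rng, config, genes, markers, sizes, program, "cell", gene_factors
    )
    lq_counts, lq_cells = _lowquality_block(rng, config, genes, flags, "")
    if len(lq_cells):
        counts = sp.hstack([counts, lq_counts], format="csr")
        cells = cells.append(lq_cells)
        labels = pd.concat(
            [labels, pd.Series(LOW_QUALITY_LABEL, index=lq_cells)]
        )
    meta = pd.DataFrame({"true_cluster": labels}, index=cells)
    cm = CountMatrix(
        genes=genes, cells=cells, counts=counts, cell_meta=meta, gene_flags=flags
    )
    return cm, TruthLabels(cell_to_cluster=labels, cluster_markers=markers)


def simulate_query_reference_pair(
    config: ScSimConfig, correspondence: dict[str, str]
) -> tuple[CountMatrix, CountMatrix, TruthLabels]:
    """Paired query/reference simulation with shared marker programs.

    ``correspondence`` maps each query cluster name to a reference cluster;
    corresponding clusters share the same marker program and both matrices
    share the gene universe.  Query cluster sizes come from
    ``config.n_query_cells_per_cluster`` (positionally over the
    correspondence entries; defaults to the reference sizes) and may be 0,
    in which case the cluster is simply absent.
    """
    ref_names = set(config.cluster_names)
    unknown = [r for r in correspondence.values() if r not in ref_names]
    if unknown:
        raise ValueError(f"correspondence references unknown clusters {unknown}")
    rng = np.random.default_rng(config.seed)
    genes, flags = _gene_universe(config)
    markers = _marker_map(config, genes)

    ref_sizes = dict(zip(config.cluster_names, config.n_cells_per_cluster))
    ref_program = {c: c for c in config.cluster_names}
    gene_factors = _gene_mean_factors(rng, config)  # shared gene universe
    ref_counts, ref_cells, ref_labels = _simulate_cells(
        rng, config, genes, markers, ref_sizes, ref_program, "ref", gene_factors
    )

    q_names = list(correspondence)
    if config.n_query_cells_per_cluster is not None:
        if len(config.n_query_cells_per_cluster) != len(q_names):
            raise ValueError(
                "n_query_cells_per_cluster length must match correspondence"
            )
        q_sizes = dict(zip(q_names, config.n_query_cells_per_cluster))
    else:
        sizes_cycle = list(config.n_cells_per_cluster)
        q_sizes = {q: sizes_cycle[i % len(sizes_cycle)] for i, q in enumerate(q_names)}
    q_counts, q_cells, q_labels = _simulate_cells(
        rng, config, genes, markers, q_sizes, dict(correspondence), "qry",
        gene_factors,
    )

    ref = CountMatrix(
        genes=genes,
        cells=ref_cells,
        counts=ref_counts,
        cell_meta=pd.DataFrame({"true_cluster": ref_labels}, index=ref_cells),
        gene_flags=flags,
    )
    query = CountMatrix(
        genes=genes,
        cells=q_cells,
        counts=q_counts,
        cell_meta=pd.DataFrame({"true_cluster": q_labels}, index=q_cells),
        gene_flags=flags,
    )
    truth = TruthLabels(
        cell_to_cluster=pd.concat([ref_labels, q_labels]),
        cluster_markers=markers,
        correspondence={q: r for q, r in correspondence.items() if q_sizes.get(q, 0)},
    )
    return query, ref, truth


# --------------------------------------------------------------------------
# methylome simulation


@dataclass(frozen=True)
class MethSimConfig:
    """Three-condition methylome simulation parameters.

    ``effect_size`` is the methylation offset planted in the patterned
    conditions (fraction units); each patterned gene shifts up or down with
    probability 1/2.  ``pattern_fractions`` defaults follow roughly the
    proportions seen in diet-switch methylome studies (about 20/11/14% of
    genes in Patterns 1-3, the rest unchanged).  ``coverage_mean`` may be
    ``inf`` for the noise-free infinite-coverage limit.
    """

    n_genes: int = 300
    flank: int = 2000
    cpg_spacing: int = 20
    coverage_mean: float = 30.0
    conditions: tuple[str, ...] = ("CD", "HFD", "HFD-CD")
    pattern_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "Pattern1": 0.196,
            "Pattern2": 0.112,
            "Pattern3": 0.136,
            "null": 0.556,
        }
    )
    effect_size: float = 0.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.flank <= 0:
            raise ValueError("flank must be positive")
        if self.cpg_spacing <= 0:
            raise ValueError("cpg_spacing must be positive")
        if len(self.conditions) != 3:
            raise ValueError("exactly 3 conditions required for pattern simulation")
        total = sum(self.pattern_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_fractions must sum to 1 (got {total})")
        if not 0 < self.effect_size <= 1:
            raise ValueError("effect_size must be in (0, 1]")
        if self.effect_size > 0.6:
            raise ValueError(
                "effect_size above 0.6 cannot be planted without clipping levels"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (self.coverage_mean > 0):
            raise ValueError("coverage_mean must be positive")


_PATTERN_OFFSETS = {
    # multiples of the signed effect for (CD, HFD, HFD-CD)
    "Pattern1": (0.0, 1.0, 0.0),
    "Pattern2": (0.0, 1.0, 1.0),
    "Pattern3": (0.0, 0.0, 1.0),
    "null": (0.0, 0.0, 0.0),
}


def _planted_labels(rng, config: MethSimConfig) -> np.ndarray:
    names = ["Pattern1", "Pattern2", "Pattern3", "null"]
    counts = [int(np.floor(config.pattern_fractions.get(p, 0) * config.n_genes))
              for p in names[:3]]
    counts.append(config.n_genes - sum(counts))
    labels = np.repeat(names, counts)
    return labels[rng.permutation(config.n_genes)]


def simulate_methylomes(
    config: MethSimConfig,
) -> tuple[list[MethylationTrack], pd.DataFrame, pd.Series]:
    """Simulate per-CpG methylomes for the three diet conditions.

    Each gene sits on a synthetic chromosome with CpGs every
    ``cpg_spacing`` bp across TSS +/- flank; the baseline profile is a
    plateau with a Gaussian dip at the TSS (the canonical promoter
    methylation valley).  Condition offsets implement the planted pattern;
    observed levels are binomial(coverage, true level) fractions with
    Poisson coverage, or the true levels exactly when coverage is infinite.

    Returns (tracks, TSS annotation, planted pattern labels).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    labels = _planted_labels(rng, config)
    genes = [f"G{i:05d}" for i in range(n)]
    gap = 1000
    spacing_region = 2 * config.flank + gap
    tss = 1 + config.flank + gap + np.arange(n) * spacing_region  # 1-based
    strand = np.where(np.arange(n) % 2 == 0, "+", "-")
    annot = pd.DataFrame(
        {"gene": genes, "chrom": _CHROM, "tss": tss, "strand": strand}
    )

    lo = max(0.4, (config.effect_size + 0.02) / 0.7)
    hi = min(0.8, 0.98 - config.effect_size)
    plateau = rng.uniform(lo, hi, size=n)
    direction = rng.choice([-1.0, 1.0], size=n)
    dip_sigma = config.flank / 8.0

    offsets_rel = np.array([_PATTERN_OFFSETS[p] for p in labels])  # n x 3
    offsets = offsets_rel * (direction * config.effect_size)[:, None]

    rel = np.arange(-config.flank, config.flank, config.cpg_spacing)
    dip = np.exp(-(rel**2) / (2 * dip_sigma**2))
    infinite_cov = math.isinf(config.coverage_mean)

    per_condition: list[list[np.ndarray]] = [[] for _ in config.conditions]
    starts_all: list[np.ndarray] = []
    for g in range(n):
        tss0 = tss[g] - 1
        starts = tss0 + rel
        starts_all.append(starts)
        base = plateau[g] * (1 - 0.3 * dip)
        for ci in range(3):
            true = base + offsets[g, ci]
            if config.noise_sd > 0:
                true = true + rng.normal(0, config.noise_sd, size=true.shape)
            true = np.clip(true, 0.01, 0.99)
            if infinite_cov:
                per_condition[ci].append(np.column_stack([true, np.full_like(true, np.nan)]))
            else:
                cov = np.maximum(rng.poisson(config.coverage_mean, size=true.shape), 1)
                meth = rng.binomial(cov, true)
                per_condition[ci].append(np.column_stack([meth / cov, cov]))

    starts = np.concatenate(starts_all)
    tracks = []
    for ci, cond in enumerate(config.conditions):
        arr = np.vstack(per_condition[ci])
        rec = pd.DataFrame(
            {
                "chrom": _CHROM,
                "start": starts,
                "end": starts + 1,
                "level": arr[:, 0],
            }
        )
        if not infinite_cov:
            rec["coverage"] = arr[:, 1].astype(int)
        tracks.append(MethylationTrack(condition=cond, records=rec))

    truth = pd.Series(labels, index=pd.Index(genes, name="gene"), name="pattern")
    return tracks, annot, truth


def write_fixtures(datasets: dict[str, object], out_dir) -> dict[str, object]:
    """Write a named collection of simulated objects as plain-text fixtures.

    Dispatch by type: CountMatrix -> MTX triple in a subdirectory;
    MethylationTrack -> bedGraph; TSS annotation DataFrame -> BED6;
    Series/DataFrame truth tables -> TSV.  Returns a manifest mapping each
    name to the written path(s); an empty input writes nothing.
    """
    from pathlib import Path

    from .io import write_bedgraph, write_count_matrix, write_tss_bed

    out_dir = Path(out_dir)
    manifest: dict[str, object] = {}
    for name, obj in datasets.items():
        if isinstance(obj, CountMatrix):
            manifest[name] = {
                k: str(v) for k, v in write_count_matrix(obj, out_dir / name).items()
            }
        elif isinstance(obj, MethylationTrack):
            out_dir.mkdir(parents=True, exist_ok=True)
            manifest[name] = str(write_bedgraph(obj, out_dir / f"{name}.bedgraph"))
        elif isinstance(obj, pd.DataFrame) and {"gene", "chrom", "tss", "strand"} <= set(
            obj.columns
        ):
            out_dir.mkdir(parents=True, exist_ok=True)
            manifest[name] = str(write_tss_bed(obj, out_dir / f"{name}.bed"))
        elif isinstance(obj, (pd.Series, pd.DataFrame)):
            out_dir.mkdir(parents=True, exist_ok=True)
            path = out_dir / f"{name}.tsv"
            obj.to_csv(path, sep="\t")
            manifest[name] = str(path)
        else:
            raise TypeError(f"cannot write fixture {name!r} of type {type(obj)!r}")
    return manifest
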