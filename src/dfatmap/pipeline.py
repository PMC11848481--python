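"""Configuration-driven orchestration of the full synthetic workflow.

simulate -> QC -> reference markers -> label transfer -> TSS methylation
profiles -> reversibility patterns -> over-representation, with every output
file, parameter and seed recorded in a JSON manifest sufficient to replay
the run.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .containers import QCThresholds
from .deg import DEGParams, find_markers
from .enrichment import ora, write_gmt
from .label_transfer import (
    assign_labels,
    mapping_table,
    score_cells,
    subsample_per_group,
    top_markers,
)
from .methylation import (
    PatternParams,
    classify_patterns,
    cluster_patterns,
    composite_profile,
    gene_methylation_summary,
    tss_profile_matrix,
)
from .sc_core import compute_qc_metrics, filter_cells, log_normalize
from .simulate import (
    LOW_QUALITY_LABEL,
    MethSimConfig,
    ScSimConfig,
    simulate_methylomes,
    simulate_query_reference_pair,
    write_fixtures,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs; YAML-serializable."""

    out_dir: str = "dfatmap_run"
    seed: int = 0
    sc_sim: ScSimConfig = field(default_factory=ScSimConfig)
    meth_sim: MethSimConfig = field(default_factory=MethSimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    deg: DEGParams = field(default_factory=DEGParams)
    patterns: PatternParams = field(default_factory=PatternParams)
    n_top_markers: int = 50
    subsample_fraction: float = 0.1
    profile_flank: int = 2000
    profile_bin: int = 10
    summary_flank: int = 1000
    run_sc: bool = True
    run_methylation: bool = True
    run_enrichment: bool = True

    def __post_init__(self) -> None:
        # propagate the run seed into sub-configs that keep their default
        if self.sc_sim.seed == 0 and self.seed != 0:
            self.sc_sim = dataclasses.replace(self.sc_sim, seed=self.seed)
        if self.meth_sim.seed == 0 and self.seed != 0:
            self.meth_sim = dataclasses.replace(self.meth_sim, seed=self.seed + 1)
        if self.patterns.seed == 0 and self.seed != 0:
            self.patterns = dataclasses.replace(self.patterns, seed=self.seed + 2)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in [
            ("sc_sim", ScSimConfig),
            ("meth_sim", MethSimConfig),
            ("qc", QCThresholds),
            ("deg", DEGParams),
            ("patterns", PatternParams),
        ]:
            if key in kwargs and isinstance(kwargs[key], dict):
                subkw = kwargs[key]
                for listy in (
                    "n_cells_per_cluster",
                    "n_query_cells_per_cluster",
                    "conditions",
                ):
                    if listy in subkw and subkw[listy] is not None:
                        subkw[listy] = tuple(subkw[listy])
                kwargs[key] = sub(**subkw)
        return cls(**kwargs)


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "params": {
            "sc_sim": _asdict(cfg.sc_sim),
            "meth_sim": _asdict(cfg.meth_sim),
            "qc": _asdict(cfg.qc),
            "deg": _asdict(cfg.deg),
            "patterns": _asdict(cfg.patterns),
            "n_top_markers": cfg.n_top_markers,
            "subsample_fraction": cfg.subsample_fraction,
            "profile_flank": cfg.profile_flank,
            "profile_bin": cfg.profile_bin,
            "summary_flank": cfg.summary_flank,
        },
        "outputs": {},
    }
    outputs = manifest["outputs"]

    pattern_truth = None
    if cfg.run_sc:
        query, ref, truth = simulate_query_reference_pair(
            cfg.sc_sim, {f"Q{i}": c for i, c in enumerate(cfg.sc_sim.cluster_names)}
        )
        outputs["fixtures_sc"] = write_fixtures(
            {"reference": ref, "query": query}, out / "fixtures"
        )

        # QC + normalization on both datasets
        for name, cm in [("reference", ref), ("query", query)]:
            metrics = compute_qc_metrics(cm)
            metrics.to_csv(out / f"qc_{name}.tsv", sep="\t")
            outputs[f"qc_{name}"] = str(out / f"qc_{name}.tsv")
        ref_f = filter_cells(ref, compute_qc_metrics(ref), cfg.qc)
        query_f = filter_cells(query, compute_qc_metrics(query), cfg.qc)
        ref_nm = log_normalize(ref_f)
        query_nm = log_normalize(query_f)

        ref_labels = ref_f.cell_meta["true_cluster"]
        deg_tables = {
            c: find_markers(ref_nm, ref_labels, c, cfg.deg)
            for c in cfg.sc_sim.cluster_names
        }
        deg_all = pd.concat(deg_tables.values(), ignore_index=True)
        deg_all.to_csv(out / "reference_markers.tsv", sep="\t", index=False)
        outputs["reference_markers"] = str(out / "reference_markers.tsv")

        marker_sets = top_markers(deg_tables, n_top=cfg.n_top_markers)
        q_labels = query_f.cell_meta["true_cluster"]
        keep = subsample_per_group(
            query_f.cells, q_labels, cfg.subsample_fraction, seed=cfg.seed
        )
        query_sub = query_f.subset_cells(keep)
        scores = score_cells(log_normalize(query_sub), marker_sets)
        assignment = assign_labels(scores)
        assignment.to_csv(out / "assignments.tsv", sep="\t")
        outputs["assignments"] = str(out / "assignments.tsv")
        flows = mapping_table(assignment, query_sub.cell_meta["true_cluster"])
        flows.to_csv(out / "mapping_table.tsv", sep="\t", index=False)
        outputs["mapping_table"] = str(out / "mapping_table.tsv")

    if cfg.run_methylation:
        tracks, annot, pattern_truth = simulate_methylomes(cfg.meth_sim)
        outputs["fixtures_meth"] = write_fixtures(
            {
                **{f"meth_{t.condition}": t for t in tracks},
                "tss": annot,
                "pattern_truth": pattern_truth,
            },
            out / "fixtures",
        )
        for t in tracks:
            profile = tss_profile_matrix(
                t, annot, flank=cfg.profile_flank, bin_size=cfg.profile_bin
            )
            comp = composite_profile(profile)
            comp.to_csv(out / f"composite_{t.condition}.tsv", sep="\t")
            outputs[f"composite_{t.condition}"] = str(
                out / f"composite_{t.condition}.tsv"
            )
        summary = gene_methylation_summary(tracks, annot, flank=cfg.summary_flank)
        summary.to_csv(out / "tss_methylation_summary.tsv", sep="\t")
        outputs["tss_methylation_summary"] = str(out / "tss_methylation_summary.tsv")
        clusters = cluster_patterns(summary, cfg.patterns)
        patterns = classify_patterns(summary, clusters, cfg.patterns)
        patterns.to_csv(out / "pattern_assignment.tsv", sep="\t")
        outputs["pattern_assignment"] = str(out / "pattern_assignment.tsv")

        if cfg.run_enrichment:
            # ORA of called Pattern-1 genes against the planted-pattern sets
            collection = {
                f"PLANTED_{p.upper()}": (
                    f"genes simulated with {p}",
                    list(pattern_truth.index[pattern_truth == p]),
                )
                for p in ("Pattern1", "Pattern2", "Pattern3")
            }
            gmt_path = out / "planted_patterns.gmt"
            write_gmt(collection, gmt_path)
            outputs["gene_sets"] = str(gmt_path)
            universe = list(summary.index)
            p1 = list(patterns.index[patterns["pattern"] == "Pattern1"])
            if p1:
                enr = ora(p1, universe, collection)
                enr.to_csv(out / "enrichment_pattern1.tsv", sep="\t", index=False)
                outputs["enrichment_pattern1"] = str(out / "enrichment_pattern1.tsv")

    def _relativize(entry):
        if isinstance(entry, dict):
            return {k: _relativize(v) for k, v in entry.items()}
        p = Path(entry)
        return str(p.relative_to(out)) if p.is_absolute() or str(p).startswith(
            str(out)
        ) else str(p)

    # record paths relative to out_dir so manifests of identical runs match
    manifest["outputs"] = _relativize(outputs)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"] = {
        k: (v if isinstance(v, dict) else str(out / v))
        for k, v in manifest["outputs"].items()
    }
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest
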