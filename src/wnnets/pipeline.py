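"""End-to-end orchestration: raw tables in, result bundle + manifest out."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as wio
from .design import ComparisonDesign, comparison_label
from .network import build_master_network, degree_matrix
from .simulate import run_random_null
from .stats import (
    detect_sfcp,
    detect_ssp,
    difference_summary,
    high_degree_sets,
    set_intersections,
    ssp_subnetwork,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths and thresholds for a full run.

    Defaults pin the study's analysis choices: STRING score threshold 400,
    FDR 0.1 for both detectors, |log2 fold change| threshold 1, the 75%
    degree quantile, and 100 random-null trials.
    """

    spc_path: str
    mw_path: str
    edges_path: str
    design_path: str
    out_dir: str = "wnnets_out"
    score_threshold: float = 400.0
    ssp_alpha: float = 0.1
    sfcp_alpha: float = 0.1
    log2fc_threshold: float = 1.0
    quantile: float = 0.75
    equal_var: bool = False
    null_trials: int = 0
    seed: int | None = None
    delimiter: str | None = None
    formats: tuple[str, ...] = ("csv", "graphml", "sif")

    def __post_init__(self) -> None:
        if not 0 < self.ssp_alpha < 1 or not 0 < self.sfcp_alpha < 1:
            raise ValueError("alpha thresholds must be in (0, 1)")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        if self.null_trials < 0:
            raise ValueError("null_trials must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PipelineResult:
    weights: pd.DataFrame
    removed_proteins: list[str]
    master: object
    degrees: pd.DataFrame
    ssp: pd.DataFrame
    sfcp: pd.DataFrame
    high_degree: object
    differences: object
    intersections: object
    null_summary: object | None
    manifest: Mapping = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis: read → normalize → filter → master network →
    degrees → SSP/SFCP/high-degree/differences/intersections → optional null.

    Writes every table (CSV), the master network and per-comparison SSP
    subnetworks (GraphML/SIF), and a manifest recording parameters, seed and
    input checksums.  Any stage failure aborts with a stage-named message and
    removes partial outputs.
    """
    stage = "read inputs"
    out_dir = Path(config.out_dir)
    try:
        spc = wio.read_spc_matrix(config.spc_path, config.delimiter)
        mw = wio.read_molecular_weights(config.mw_path, config.delimiter)
        edges = wio.read_edge_table(config.edges_path, config.delimiter)
        design = ComparisonDesign.from_yaml(config.design_path)

        stage = "normalize and filter"
        raw_weights = wio.normalize_by_mw(spc, mw)
        weights, removed = wio.filter_shared_proteins(raw_weights)

        stage = "master network"
        master = build_master_network(
            edges, set(weights.index), score_threshold=config.score_threshold
        )

        stage = "degree matrix"
        degrees = degree_matrix(master, weights)

        stage = "statistics"
        ssp = detect_ssp(degrees, design, alpha=config.ssp_alpha,
                         equal_var=config.equal_var)
        sfcp = detect_sfcp(
            weights.loc[degrees.index], design,
            log2_threshold=config.log2fc_threshold,
            alpha=config.sfcp_alpha, equal_var=config.equal_var,
        )
        hds = high_degree_sets(degrees, design.groups, q=config.quantile)
        diffs = difference_summary(degrees, design)

        named_sets: dict[str, set] = {
            f"{g}-highdegree": set(s) for g, s in hds.sets.items()
        }
        subnetworks = {}
        for treated, control in design.comparisons:
            label = comparison_label(treated, control)
            ssps = set(ssp.loc[(ssp["comparison"] == label) & ssp["is_ssp"], "protein"])
            sfcps = set(
                sfcp.loc[(sfcp["comparison"] == label) & sfcp["is_sfcp"], "protein"]
            )
            named_sets[f"{label}-SSP"] = ssps
            named_sets[f"{label}-SFCP"] = sfcps
            subnetworks[f"ssp_subnetwork_{label}"] = ssp_subnetwork(
                master, ssps, sfcps
            )
        inter = set_intersections(named_sets)

        null_summary = None
        if config.null_trials > 0:
            stage = "random null"
            null_summary = run_random_null(
                master, design, n_trials=config.null_trials,
                observed=weights.loc[degrees.index],
                alpha=config.ssp_alpha, seed=config.seed,
                equal_var=config.equal_var,
            )

        stage = "write outputs"
        tables = {
            "weights": weights,
            "degree_matrix": degrees,
            "ssp": ssp.set_index(["comparison", "protein"]),
            "sfcp": sfcp.set_index(["comparison", "protein"]),
            "high_degree_group_means": hds.group_means,
            "difference_per_protein": diffs.per_protein,
            "intersections": inter.exclusive.assign(
                members=[";".join(m) for m in inter.exclusive["members"]]
            ).set_index("count"),
        }
        if null_summary is not None:
            tables["null_trials"] = null_summary.trials.set_index("trial")
        graphs = {"master_network": master, **subnetworks}
        extra = {
            "parameters": {
                k: v for k, v in asdict(config).items() if k != "formats"
            },
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in {
                    "spc": config.spc_path,
                    "molecular_weights": config.mw_path,
                    "edges": config.edges_path,
                    "design": config.design_path,
                }.items()
            },
            "removed_proteins": removed,
            "high_degree_thresholds": dict(hds.thresholds),
            "global_mean_differences": dict(diffs.global_mean),
            "difference_ratios": {
                f"{a}/{b}": r for (a, b), r in diffs.ratios.items()
            },
            "component_sizes": master.graph["component_sizes"],
        }
        if null_summary is not None:
            extra["null"] = {
                "n_trials": null_summary.n_trials,
                "n_trials_with_ssp": null_summary.n_trials_with_ssp,
                "weight_range": list(null_summary.weight_range),
            }
        manifest = wio.write_outputs(
            out_dir, tables=tables, graphs=graphs,
            formats=config.formats, extra=extra,
        )
    except Exception as exc:
        for leftover in out_dir.glob("*") if out_dir.exists() else []:
            if leftover.is_file():
                leftover.unlink()
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return PipelineResult(
        weights=weights,
        removed_proteins=removed,
        master=master,
        degrees=degrees,
        ssp=ssp,
        sfcp=sfcp,
        high_degree=hds,
        differences=diffs,
        intersections=inter,
        null_summary=null_summary,
        manifest=manifest,
    )
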