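"""End-to-end analysis pipeline.

Runs, in order: low-total OTU filtering per group, per-sample diversity
profiles plus group means and pairwise t-tests, per-group species
interaction networks with summary panels, motif censuses and dense-module
detection, and — when a metabolite table is supplied — the
diversity–metabolite and metabolite–OTU networks. All outputs are plain
TSV/GraphML plus a JSON manifest recording the parameters, seed and
package version needed to reproduce the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import DEFAULT_Q_GRID, group_mean_profile, pairwise_group_tests, profiles_from_table
from .io_tables import (
    FeatureTable,
    GroupAssignment,
    read_feature_table,
    read_group_assignment,
    write_network,
)
from .modules_motifs import mcode_clusters, motif_census, negative_links_in_cluster
from .netstats import annotate_hubs_and_mao, summarize, summary_frame
from .network import build_dmn, build_mon, build_sin

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    otu_table: str
    groups: str
    out_dir: str
    metabolite_table: str | None = None
    alpha: float = 0.05
    min_total: float = 5
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID
    community_method: str = "greedy"
    mcode: dict = field(default_factory=dict)
    seed: int = 0
    exclude_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if any(float(q) < 0 for q in self.q_grid):
            raise ValueError("q_grid must be non-negative")
        self.q_grid = tuple(float(q) for q in self.q_grid)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate_paths(self) -> None:
        for p in (self.otu_table, self.groups, self.metabolite_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage name added for the user
                raise PipelineError(name, exc) from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns a manifest dict (also written to ``manifest.json``) listing the
    parameters and every output file. Idempotent for fixed inputs and seed.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    @_stage("load")
    def _load():
        otu = read_feature_table(config.otu_table, feature_kind="otu")
        groups = read_group_assignment(config.groups)
        groups.validate_against(otu)
        met = (
            read_feature_table(config.metabolite_table, feature_kind="metabolite")
            if config.metabolite_table
            else None
        )
        return otu, groups, met

    otu, groups, met = _load()

    @_stage("diversity")
    def _diversity():
        profiles = profiles_from_table(otu, config.q_grid)
        profiles_long = profiles.reset_index().melt(
            id_vars="sample_id", var_name="q", value_name="hill_number"
        )
        profiles_long.to_csv(out / "profiles.tsv", sep="\t", index=False)
        means = group_mean_profile(profiles, groups, exclude_samples=config.exclude_samples)
        means.to_csv(out / "group_means.tsv", sep="\t")
        tests = pairwise_group_tests(profiles, groups, exclude_samples=config.exclude_samples)
        tests.to_csv(out / "ttests.tsv", sep="\t", index=False)
        outputs.update(
            profiles="profiles.tsv", group_means="group_means.tsv", ttests="ttests.tsv"
        )
        return profiles

    _diversity()

    @_stage("networks")
    def _networks():
        nets = {}
        for label, members in groups.groups().items():
            sub = otu.subset_samples(members)
            net = build_sin(sub, alpha=config.alpha, min_total=config.min_total)
            annotate_hubs_and_mao(net)
            path = out / f"sin_{label}.graphml"
            write_network(net, path, "graphml")
            outputs[f"sin_{label}"] = path.name
            nets[label] = net
        return nets

    nets = _networks()

    @_stage("network_stats")
    def _stats():
        summaries = {
            label: summarize(net, config.community_method, config.seed)
            for label, net in nets.items()
            if net.number_of_nodes()
        }
        df = summary_frame(summaries)
        df.to_csv(out / "network_summary.tsv", sep="\t")
        outputs["network_summary"] = "network_summary.tsv"

    _stats()

    @_stage("motifs_modules")
    def _motifs_modules():
        motif_rows, cluster_rows, neg_rows = [], [], []
        for label, net in nets.items():
            for k in (3, 4):
                for cls, count in motif_census(net, k).items():
                    motif_rows.append({"network": label, "size": k, "motif": cls, "count": count})
            clusters = mcode_clusters(net, **config.mcode)
            for c in clusters:
                cluster_rows.append(
                    {"network": label, "rank": c.rank, "score": c.score,
                     "n_nodes": c.n_nodes, "n_edges": c.n_edges,
                     "members": ",".join(map(str, c.nodes))}
                )
            if clusters:
                for a, b in negative_links_in_cluster(net, clusters[0]):
                    neg_rows.append({"network": label, "node_a": a, "node_b": b})
        pd.DataFrame(motif_rows).to_csv(out / "motifs.tsv", sep="\t", index=False)
        pd.DataFrame(cluster_rows, columns=["network", "rank", "score", "n_nodes",
                                            "n_edges", "members"]).to_csv(
            out / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame(neg_rows, columns=["network", "node_a", "node_b"]).to_csv(
            out / "cluster_negative_links.tsv", sep="\t", index=False)
        outputs.update(motifs="motifs.tsv", clusters="clusters.tsv",
                       cluster_negative_links="cluster_negative_links.tsv")

    _motifs_modules()

    if met is not None:
        @_stage("dmn_mon")
        def _dmn_mon():
            dmn = build_dmn(otu, met, config.q_grid, alpha=config.alpha)
            write_network(dmn, out / "dmn.graphml", "graphml")
            mon = build_mon(met, otu, alpha=config.alpha, min_total=config.min_total)
            write_network(mon, out / "mon.graphml", "graphml")
            outputs.update(dmn="dmn.graphml", mon="mon.graphml")

        _dmn_mon()

    manifest = {
        "milknet_version": __version__,
        "parameters": dataclasses.asdict(config),
        "outputs": outputs,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    return manifest
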