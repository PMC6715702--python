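"""End-to-end orchestration: preprocess -> correlate -> threshold ->
cluster -> enrich -> risk, with one configuration object and a manifest."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, build_annotations
from .enrichment import ContingencyTable2x2, OddsRatioResult, enrich, odds_ratio
from .errors import ConfigError, StatsError
from .mcl import ClusterPartition, MclParams, mcl_cluster
from .network import (
    CorrelationNetwork,
    pearson_matrix,
    threshold_graph,
    threshold_scan,
)
from .preprocess import MorphometricMatrix, median_center, normalize_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "RunManifest"]

DEFAULT_CATEGORIES = [
    "breed",
    "breed_group",
    "craniofacial",
    "age_category",
    "sex_neuter",
    "septal_integrity",
    "diagnostic_class",
    "clade",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one place (defaults follow the reference
    analysis: r > 0.7, inflation 2.2, minimum cluster size 3, minimum
    observed count 3)."""

    centering: str = "ratio"
    threshold: float = 0.7
    scan_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
    mcl: MclParams = field(default_factory=MclParams)
    adjust_method: str = "bh"
    min_observed: int = 3
    categories: tuple[str, ...] = tuple(DEFAULT_CATEGORIES)
    registry: Optional[dict] = None
    risk_exposure: str = "FN"
    risk_reference: str = "FE"
    risk_outcome: str = "tumour"
    risk_ci_method: str = "woolf"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "mcl" in raw and isinstance(raw["mcl"], dict):
            raw["mcl"] = MclParams(**raw["mcl"])
        for key in ("scan_thresholds", "categories"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["mcl"] = asdict(self.mcl)
        out["scan_thresholds"] = list(self.scan_thresholds)
        out["categories"] = list(self.categories)
        return out


@dataclass
class PipelineResult:
    matrix: MorphometricMatrix
    correlations: np.ndarray
    correlation_scan_ids: list[str]
    network: CorrelationNetwork
    partition: ClusterPartition
    annotations: pd.DataFrame
    enrichment: pd.DataFrame
    class_enrichment: pd.DataFrame
    threshold_table: pd.DataFrame
    risk: Optional[OddsRatioResult]
    risk_table: Optional[ContingencyTable2x2]
    counts: dict

    def summary_text(self) -> str:
        c = self.counts
        lines = [
            f"scans in cohort:           {c['n_scans']}",
            f"scans in numeric matrix:   {c['n_matrix']}",
            f"scans dropped (missing):   {c['n_dropped']}",
            f"correlation threshold:     r > {c['threshold']}",
            f"network nodes:             {c['n_nodes']}",
            f"network edges:             {c['n_edges']}",
            f"scans without any edge:    {c['n_excluded']}",
            f"clusters (size >= {c['min_cluster_size']}):      {c['n_clusters']}",
            f"scans clustered:           {c['n_clustered']}",
            f"scans unclustered:         {c['n_unclustered']}",
        ]
        return "\n".join(lines) + "\n"


def _risk_contingency(
    annotations: pd.DataFrame, config: PipelineConfig
) -> Optional[ContingencyTable2x2]:
    sn = annotations["sex_neuter"]
    dc = annotations["diagnostic_class"]
    exposed = sn == config.risk_exposure
    unexposed = sn == config.risk_reference
    outcome = dc == config.risk_outcome
    a = int((exposed & outcome).sum())
    b = int((exposed & ~outcome).sum())
    c = int((unexposed & outcome).sum())
    d = int((unexposed & ~outcome).sum())
    if a + b == 0 or c + d == 0:
        return None
    return ContingencyTable2x2(a, b, c, d)


def run_pipeline(
    cohort: CohortTable, config: Optional[PipelineConfig] = None
) -> PipelineResult:
    """Execute every stage on an in-memory cohort and return all artifacts."""
    config = config or PipelineConfig()
    normalized = normalize_cohort(cohort, config.registry)
    centered = median_center(normalized, mode=config.centering)
    corr, scan_ids = pearson_matrix(centered)
    net = threshold_graph(corr, scan_ids, config.threshold)
    scan_table = threshold_scan(corr, sorted(config.scan_thresholds))
    partition = mcl_cluster(net, config.mcl)

    annotations = build_annotations(cohort)
    networked = sorted(set(net.nodes) | set(net.excluded_nodes))
    ann_net = annotations.loc[annotations.index.intersection(networked)]

    groups = {
        f"cluster_{k}": set(members)
        for k, members in enumerate(partition.clusters, start=1)
    }
    enrichment = enrich(
        groups,
        ann_net,
        categories=[c for c in config.categories if c in ann_net.columns],
        min_observed=config.min_observed,
        adjust_method=config.adjust_method,
    )
    class_sets = {
        f"class:{label}": set(idx)
        for label, idx in ann_net.groupby("diagnostic_class").groups.items()
    }
    class_enrichment = enrich(
        class_sets,
        ann_net,
        categories=[
            c
            for c in config.categories
            if c in ann_net.columns and c != "diagnostic_class"
        ],
        min_observed=config.min_observed,
        adjust_method=config.adjust_method,
    )

    risk_table = _risk_contingency(annotations, config)
    risk = None
    if risk_table is not None:
        try:
            risk = odds_ratio(risk_table, ci_method=config.risk_ci_method)
        except StatsError:
            risk = None

    counts = {
        "n_scans": len(cohort),
        "n_matrix": len(centered.scan_ids),
        "n_dropped": len(centered.dropped_scans),
        "threshold": config.threshold,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_excluded": len(net.excluded_nodes),
        "min_cluster_size": config.mcl.min_cluster_size,
        "n_clusters": partition.n_clusters,
        "n_clustered": partition.n_clustered,
        "n_unclustered": len(partition.unclustered),
    }
    return PipelineResult(
        matrix=centered,
        correlations=corr,
        correlation_scan_ids=scan_ids,
        network=net,
        partition=partition,
        annotations=annotations,
        enrichment=enrichment,
        class_enrichment=class_enrichment,
        threshold_table=scan_table,
        risk=risk,
        risk_table=risk_table,
        counts=counts,
    )


@dataclass
class RunManifest:
    """Provenance record for a pipeline run: input digests, the config
    snapshot, software version and per-stage counts."""

    input_digests: dict
    config: dict
    counts: dict
    version: str = __version__
    python: str = platform.python_version()
    timestamp: str = ""

    @staticmethod
    def digest(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        return h.hexdigest()

    @classmethod
    def build(cls, inputs: dict, config: PipelineConfig, counts: dict) -> "RunManifest":
        return cls(
            input_digests={name: cls.digest(p) for name, p in inputs.items()},
            config=config.to_dict(),
            counts=counts,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
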