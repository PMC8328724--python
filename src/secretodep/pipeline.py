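"""End-to-end orchestration: simulate/load -> funnel -> DEP -> partition -> ORA.

Each endpoint (T50, T90) is processed as its own dataset, mirroring a design
where the two cohorts are acquired and filtered independently: the funnel is
applied to the endpoint's four 6-animal cells, paired fold changes and DEP
calls are computed for CT and LPS groups, control-deregulated proteins are
excluded, and the two endpoints' retained identification lists are then
partitioned into common / T50-specific / T90-specific sets. A manifest
records the configuration, a content hash, every filter-funnel stage and the
headline counts; it contains no wall-clock state, so a rerun with the same
inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .dep_calling import call_dep, exclude_control_dep, paired_log2fc, partition_sets, summarize_dep
from .enrichment import enrich
from .errors import ConfigurationError
from .io_tables import (
    AnnotationSet,
    QuantMatrix,
    SampleDesign,
    read_design,
    read_gmt,
    read_quant_matrix,
    write_results,
)
from .preprocess import run_funnel

ENDPOINT_GROUPS = {"T50": ("CT50", "LPS50"), "T90": ("CT90", "LPS90")}


@dataclass
class RunConfig:
    """All stage thresholds plus input/output locations."""

    quant_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "results"
    spike_id: str = "P00924"
    min_peptides: int = 2
    min_score: float = 6.0
    max_na_per_group: int = 2
    min_coverage_pct: float = 15.0
    fc_threshold: float = 1.0
    min_qualifying: int = 4
    min_term_size: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def validate(self, n_animals_per_group: int | None = None) -> None:
        if self.min_peptides < 0 or self.min_score < 0:
            raise ConfigurationError("quantifiability thresholds must be non-negative")
        if self.max_na_per_group < 0:
            raise ConfigurationError("max_na_per_group must be non-negative")
        if not 0 <= self.min_coverage_pct <= 100:
            raise ConfigurationError("min_coverage_pct must lie in [0, 100]")
        if self.fc_threshold <= 0:
            raise ConfigurationError("fc_threshold must be positive")
        if self.min_qualifying < 1:
            raise ConfigurationError("min_qualifying must be >= 1")
        if n_animals_per_group is not None and self.min_qualifying > n_animals_per_group:
            raise ConfigurationError(
                f"min_qualifying={self.min_qualifying} exceeds the "
                f"group size {n_animals_per_group}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    _PATH_FIELDS = ("quant_path", "design_path", "gmt_path", "out_dir")

    def analytic_dict(self) -> dict:
        """Stage parameters only — no filesystem locations.

        This is what the manifest records and hashes, so reruns of the same
        analysis into different directories produce identical manifests.
        """
        return {k: v for k, v in asdict(self).items() if k not in self._PATH_FIELDS}


@dataclass
class EndpointResult:
    endpoint: str
    retained_ids: frozenset
    lps_calls: pd.DataFrame
    control_excluded: frozenset
    filter_reports: list = field(default_factory=list)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.analytic_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def process_endpoint(
    q: QuantMatrix, d: SampleDesign, endpoint: str, config: RunConfig
) -> EndpointResult:
    """Funnel + fold changes + DEP calls + control exclusion for one endpoint."""
    groups = [g for g in ENDPOINT_GROUPS[endpoint] if g in set(d.groups)]
    d_ep = d.subset_groups(groups)
    q_ep = q.subset(samples=d_ep.sample_ids)
    q_f, d_f, reports = run_funnel(
        q_ep,
        d_ep,
        spike_id=config.spike_id,
        min_peptides=config.min_peptides,
        min_score=config.min_score,
        max_na_per_group=config.max_na_per_group,
        min_coverage_pct=config.min_coverage_pct,
    )
    fc = paired_log2fc(q_f, d_f)
    calls = call_dep(fc, threshold=config.fc_threshold, min_qualifying=config.min_qualifying)
    lps_calls = calls[calls["group"].str.startswith("LPS")].reset_index(drop=True)
    ct_calls = calls[calls["group"].str.startswith("CT")].reset_index(drop=True)
    if len(ct_calls):
        lps_calls, excluded = exclude_control_dep(lps_calls, ct_calls)
    else:
        excluded = frozenset()
    retained = frozenset(q_f.protein_ids) - {config.spike_id} - excluded
    lps_calls = lps_calls[lps_calls["protein_id"].isin(retained)].reset_index(drop=True)
    return EndpointResult(endpoint, retained, lps_calls, excluded, reports)


def run_all(
    config: RunConfig,
    q: QuantMatrix | None = None,
    d: SampleDesign | None = None,
    annotations: AnnotationSet | None = None,
) -> dict:
    """Run the full pipeline and write result tables plus a manifest.

    Inputs may be passed in memory or read from the paths in ``config``.
    Returns the manifest (also written to ``<out_dir>/manifest.json``).
    """
    if d is None:
        if config.design_path is None:
            raise ConfigurationError("no design provided")
        d = read_design(config.design_path)
    if q is None:
        if config.quant_path is None:
            raise ConfigurationError("no quantification matrix provided")
        q = read_quant_matrix(config.quant_path, design=d)
    if annotations is None and config.gmt_path is not None:
        annotations = read_gmt(config.gmt_path)

    n_per_group = int(d.table.groupby("group")["animal_id"].nunique().min())
    config.validate(n_animals_per_group=n_per_group)

    endpoints = sorted({d.endpoint_of_group(g) for g in d.groups})
    results = {ep: process_endpoint(q, d, ep, config) for ep in endpoints}

    t50 = results.get("T50")
    t90 = results.get("T90")
    all_calls = pd.concat(
        [r.lps_calls for r in results.values()], ignore_index=True
    ) if results else pd.DataFrame()
    excluded = frozenset().union(*(r.control_excluded for r in results.values()))
    partition = partition_sets(
        t50.retained_ids if t50 else frozenset(),
        t90.retained_ids if t90 else frozenset(),
        control_excluded_ids=excluded,
    )
    tables = summarize_dep(all_calls, partition, metadata=q.metadata)
    tables["dep_calls"] = all_calls

    enrichments = {}
    if annotations is not None:
        for ep, res in results.items():
            universe = res.retained_ids
            for direction in ("up", "down"):
                dep_ids = set(
                    res.lps_calls.loc[res.lps_calls["direction"] == direction, "protein_id"]
                ) & universe
                enr = enrich(dep_ids, universe, annotations, config.min_term_size)
                key = f"enrichment_{ep.lower()}_{direction}"
                enrichments[key] = enr
        tables.update(enrichments)

    out_dir = Path(config.out_dir)
    written = write_results(tables, out_dir)

    manifest = {
        "tool": "secretodep",
        "version": __version__,
        "seed": config.seed,
        "config": config.analytic_dict(),
        "config_hash": _config_hash(config),
        "endpoints": {
            ep: {
                "filter_funnel": [r.as_row() for r in res.filter_reports],
                "n_retained": len(res.retained_ids),
                "n_control_excluded": len(res.control_excluded),
                "n_dep": int((res.lps_calls["direction"] != "none").sum()),
                "n_dep_up": int((res.lps_calls["direction"] == "up").sum()),
                "n_dep_down": int((res.lps_calls["direction"] == "down").sum()),
            }
            for ep, res in results.items()
        },
        "partition": {
            "n_common": len(partition.common_ids),
            "n_t50_specific": len(partition.t50_specific_ids),
            "n_t90_specific": len(partition.t90_specific_ids),
            "n_control_excluded": len(partition.control_excluded_ids),
        },
        "outputs": sorted(p.name for p in written),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
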