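"""Normalization, replicate collapsing and the inclusion/exclusion funnel.

Stages, in pipeline order:

1. ``normalize_to_spike`` — divide each sample column by that sample's
   internal-standard signal relative to the geometric mean of the spike across
   samples. Using the geometric mean as the reference keeps the output
   invariant under permutation of sample order and leaves intensities on their
   original scale.
2. ``collapse_tech_reps`` — average technical replicates (arithmetic mean of
   observed values; missing only when all replicates are missing).
3. ``filter_quantifiable`` — keep proteins quantified from at least 2 unique
   peptides with identification quality score >= 6.
4. ``filter_missingness`` — drop proteins with 3 or more missing values in any
   (group, time point) cell of animal-level columns.
5. ``filter_coverage`` — drop proteins with sequence coverage below 15%.

Filters are pure row selections: retained intensities are never altered. Each
filter returns a :class:`FilterReport` so a funnel can be audited stage by
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError, FormatError, NormalizationError
from .io_tables import QuantMatrix, SampleDesign, DESIGN_COLUMNS


@dataclass
class FilterReport:
    """Audit record of one exclusion stage."""

    stage: str
    n_before: int
    n_after: int
    removed_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_after != self.n_before - len(self.removed_ids):
            raise ValueError(
                f"inconsistent report for {self.stage}: "
                f"{self.n_before} - {len(self.removed_ids)} != {self.n_after}"
            )

    def as_row(self) -> dict:
        return {
            "stage": self.stage,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_removed": len(self.removed_ids),
        }


def check_chain(reports: list[FilterReport]) -> None:
    """Assert a funnel is gap-free: each stage starts where the last ended."""
    for prev, nxt in zip(reports, reports[1:]):
        if nxt.n_before != prev.n_after:
            raise ValueError(
                f"funnel gap between {prev.stage} (n_after={prev.n_after}) "
                f"and {nxt.stage} (n_before={nxt.n_before})"
            )


def normalize_to_spike(q: QuantMatrix, spike_id: str) -> QuantMatrix:
    """Scale each sample by its internal-standard signal.

    Sample j is divided by ``spike[j] / geomean(spike)``; a column whose raw
    signal (spike included) was globally scaled by any constant comes out
    identical to the unscaled case. Idempotent: the spike row itself becomes
    flat at the geometric mean, so a second application is a no-op.
    """
    if spike_id not in q.intensities.index:
        raise NormalizationError(f"spike protein {spike_id!r} not in matrix")
    spike = q.intensities.loc[spike_id].to_numpy(dtype=float)
    if np.isnan(spike).any():
        bad = [s for s, v in zip(q.sample_ids, spike) if np.isnan(v)]
        raise NormalizationError(f"spike {spike_id!r} missing in samples {bad[:5]}")
    if (spike <= 0).any():
        raise NormalizationError(f"spike {spike_id!r} has non-positive intensity")
    geo_mean = np.exp(np.mean(np.log(spike)))
    factors = spike / geo_mean
    out = q.intensities / factors
    return QuantMatrix(out, q.metadata.copy())


def collapse_tech_reps(q: QuantMatrix, d: SampleDesign) -> tuple[QuantMatrix, SampleDesign]:
    """Average technical replicates into one column per (animal, time point).

    The mean runs over observed replicates only; the collapsed value is
    missing only when every replicate is missing. Collapsed sample ids are
    ``<animal>_<timepoint>``.
    """
    t = d.table
    rows = []
    cols = {}
    for (animal, tp), sub in t.groupby(["animal_id", "timepoint"], sort=False):
        rep_cols = [s for s in sub["sample_id"] if s in set(q.sample_ids)]
        if not rep_cols:
            raise DesignError(f"no quant columns for ({animal}, {tp})")
        new_id = f"{animal}_{tp}"
        cols[new_id] = q.intensities[rep_cols].mean(axis=1, skipna=True)
        first = sub.iloc[0]
        rows.append(
            {
                "sample_id": new_id,
                "animal_id": animal,
                "condition": first["condition"],
                "timepoint": tp,
                "tech_rep": 1,
                "group": first["group"],
            }
        )
    collapsed = pd.DataFrame(cols, index=q.intensities.index)
    design = SampleDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))
    return QuantMatrix(collapsed, q.metadata.copy()), design


def filter_quantifiable(
    q: QuantMatrix, min_peptides: int = 2, min_score: float = 6.0
) -> tuple[QuantMatrix, FilterReport]:
    """Keep proteins with >= ``min_peptides`` unique peptides and score >= ``min_score``."""
    meta = q.metadata
    for col in ("n_unique_peptides", "quality_score"):
        if meta[col].isna().any():
            raise FormatError(f"metadata field {col!r} has missing entries")
    keep = (meta["n_unique_peptides"] >= min_peptides) & (meta["quality_score"] >= min_score)
    removed = list(meta.index[~keep])
    out = q.subset(proteins=list(meta.index[keep]))
    report = FilterReport("quantifiable", len(meta), int(keep.sum()), removed)
    return out, report


def filter_missingness(
    q: QuantMatrix, d: SampleDesign, max_na_per_group: int = 2
) -> tuple[QuantMatrix, FilterReport]:
    """Drop proteins with more than ``max_na_per_group`` NAs in any group cell.

    A cell is the set of animal-level columns of one (group, time point) pair
    — six columns in the reference design. Technical replicates must already
    be collapsed so each animal contributes one column per time point.
    """
    t = d.table
    if (t.groupby(["animal_id", "timepoint"]).size() > 1).any():
        raise DesignError("technical replicates must be collapsed before the NA filter")
    n_before = len(q.intensities)
    bad = pd.Series(False, index=q.intensities.index)
    for (_, _), sub in t.groupby(["group", "timepoint"]):
        cell_cols = [s for s in sub["sample_id"] if s in set(q.sample_ids)]
        if not cell_cols:
            raise DesignError("group cell with 0 samples")
        na_count = q.intensities[cell_cols].isna().sum(axis=1)
        bad |= na_count > max_na_per_group
    removed = list(q.intensities.index[bad])
    out = q.subset(proteins=list(q.intensities.index[~bad]))
    report = FilterReport("missingness", n_before, n_before - len(removed), removed)
    return out, report


def filter_coverage(
    q: QuantMatrix, min_coverage_pct: float = 15.0
) -> tuple[QuantMatrix, FilterReport]:
    """Keep proteins with sequence coverage >= ``min_coverage_pct`` percent."""
    if not 0 <= min_coverage_pct <= 100:
        raise ConfigurationError("min_coverage_pct must lie in [0, 100]")
    cov = q.metadata["coverage_pct"]
    keep = cov >= min_coverage_pct
    removed = list(q.metadata.index[~keep])
    out = q.subset(proteins=list(q.metadata.index[keep]))
    report = FilterReport("coverage", len(cov), int(keep.sum()), removed)
    return out, report


def run_funnel(
    q: QuantMatrix,
    d: SampleDesign,
    spike_id: str = "P00924",
    min_peptides: int = 2,
    min_score: float = 6.0,
    max_na_per_group: int = 2,
    min_coverage_pct: float = 15.0,
) -> tuple[QuantMatrix, SampleDesign, list[FilterReport]]:
    """Normalize, collapse replicates and apply the three filters in order."""
    q = normalize_to_spike(q, spike_id)
    q, d = collapse_tech_reps(q, d)
    reports = []
    q, rep = filter_quantifiable(q, min_peptides, min_score)
    reports.append(rep)
    q, rep = filter_missingness(q, d, max_na_per_group)
    reports.append(rep)
    q, rep = filter_coverage(q, min_coverage_pct)
    reports.append(rep)
    check_chain(reports)
    return q, d, reports
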