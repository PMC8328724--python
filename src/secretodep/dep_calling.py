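"""Paired fold-change computation and count-based deregulation calling.

Each animal is its own control: the statistic per protein, group and animal is
``log2(intensity_endpoint / intensity_T0)`` on normalized, replicate-collapsed
intensities. A protein is called deregulated (DEP) in a group when at least
``min_qualifying`` of the group's animals (default 4 of 6) show
``log2FC >= +threshold`` (up) or ``log2FC <= -threshold`` (down, default
threshold 1, i.e. two-fold). Up and down tallies are counted independently;
with 4-of-6 defaults they can never both reach quorum. Animals with a missing
fold change never count toward the quorum and the denominator stays at the
group size — the rule is an absolute count, not a proportion of observed
animals.

Summary statistics (median, min, max) are computed over the qualifying
animals only; ``min`` is the qualifying value closest to the threshold
(smallest magnitude) and ``max`` the most extreme, matching how ranges are
conventionally reported for such calls.

Proteins called deregulated in the time-matched control group are excluded
from the LPS DEP list (``exclude_control_dep``), and the retained
identification lists of the two endpoints are partitioned into common,
T50-specific and T90-specific sets (``partition_sets``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DesignError
from .io_tables import QuantMatrix, SampleDesign

CALL_COLUMNS = [
    "protein_id",
    "group",
    "direction",
    "n_qualifying",
    "n_animals",
    "log2fc_median",
    "log2fc_min",
    "log2fc_max",
]


@dataclass(frozen=True)
class DepCall:
    """Verdict for one protein in one group."""

    protein_id: str
    group: str
    direction: str  # up | down | none
    n_qualifying: int
    n_animals: int
    log2fc_median: float = float("nan")
    log2fc_min: float = float("nan")
    log2fc_max: float = float("nan")


@dataclass
class DepPartition:
    """Three-level split of the identification lists of the two endpoints."""

    common_ids: frozenset
    t50_specific_ids: frozenset
    t90_specific_ids: frozenset
    control_excluded_ids: frozenset = frozenset()
    dep_by_set: dict = field(default_factory=dict)

    def set_of(self, protein_id: str) -> str:
        if protein_id in self.common_ids:
            return "common"
        if protein_id in self.t50_specific_ids:
            return "t50_specific"
        if protein_id in self.t90_specific_ids:
            return "t90_specific"
        return "absent"


def paired_log2fc(q: QuantMatrix, d: SampleDesign) -> pd.DataFrame:
    """Per-animal paired log2 fold change, endpoint vs T0.

    Returns a long table (protein_id, group, animal_id, log2fc); log2fc is NaN
    when either time point is missing. Observed zero intensities are rejected:
    a zero in a pair has no defined log-ratio and is treated as a data error
    rather than silently dropped.
    """
    t = d.table
    if (t.groupby(["animal_id", "timepoint"]).size() > 1).any():
        raise DesignError("collapse technical replicates before computing fold changes")
    frames = []
    for group, sub in t.groupby("group", sort=True):
        endpoint = sorted(set(sub["timepoint"]) - {"T0"})
        if len(endpoint) != 1:
            raise DesignError(f"group {group!r} lacks a unique endpoint")
        endpoint = endpoint[0]
        animals = sorted(sub["animal_id"].unique())
        for animal in animals:
            asub = sub[sub["animal_id"] == animal].set_index("timepoint")["sample_id"]
            if "T0" not in asub.index or endpoint not in asub.index:
                raise DesignError(f"animal {animal!r} lacks a time point")
            t0 = q.intensities[asub["T0"]]
            tend = q.intensities[asub[endpoint]]
            observed_zero = ((t0 == 0) & tend.notna()) | ((tend == 0) & t0.notna())
            if observed_zero.any():
                bad = list(q.intensities.index[observed_zero])[:5]
                raise DesignError(
                    f"zero intensity in a paired sample of animal {animal!r} "
                    f"(proteins {bad}); cannot take log ratio"
                )
            lfc = np.log2(tend / t0)
            frames.append(
                pd.DataFrame(
                    {
                        "protein_id": q.intensities.index,
                        "group": group,
                        "animal_id": animal,
                        "log2fc": lfc.to_numpy(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def classify_vector(
    values, threshold: float = 1.0, min_qualifying: int = 4, n_animals: int | None = None
) -> DepCall:
    """Apply the k-of-n rule to one group's fold-change vector.

    ``values`` may contain NaN (animals with a missing pair); those count
    toward neither tally. ``n_animals`` defaults to ``len(values)``.
    """
    arr = np.asarray(values, dtype=float)
    n = n_animals if n_animals is not None else len(arr)
    if min_qualifying > n:
        raise ConfigurationError(f"min_qualifying={min_qualifying} exceeds group size {n}")
    up_mask = arr >= threshold
    down_mask = arr <= -threshold
    n_up, n_down = int(up_mask.sum()), int(down_mask.sum())
    if n_up >= min_qualifying:
        direction, qualifying = "up", arr[up_mask]
    elif n_down >= min_qualifying:
        direction, qualifying = "down", arr[down_mask]
    else:
        return DepCall("", "", "none", 0, n)
    order = np.abs(qualifying)
    return DepCall(
        "",
        "",
        direction,
        len(qualifying),
        n,
        float(np.median(qualifying)),
        float(qualifying[order.argmin()]),
        float(qualifying[order.argmax()]),
    )


def call_dep(
    fc: pd.DataFrame, threshold: float = 1.0, min_qualifying: int = 4
) -> pd.DataFrame:
    """Call DEP per (protein, group) from a long fold-change table.

    Returns one row per protein x group with direction, qualifying count,
    group size and the qualifying-animal summary statistics (NaN when the
    direction is none).
    """
    group_sizes = fc.groupby("group")["animal_id"].nunique()
    for g, n in group_sizes.items():
        if min_qualifying > n:
            raise ConfigurationError(
                f"min_qualifying={min_qualifying} exceeds group size {n} in {g!r}"
            )
    rows = []
    for (protein, group), sub in fc.groupby(["protein_id", "group"], sort=True):
        call = classify_vector(
            sub["log2fc"].to_numpy(), threshold, min_qualifying, int(group_sizes[group])
        )
        rows.append(
            {
                "protein_id": protein,
                "group": group,
                "direction": call.direction,
                "n_qualifying": call.n_qualifying,
                "n_animals": call.n_animals,
                "log2fc_median": call.log2fc_median,
                "log2fc_min": call.log2fc_min,
                "log2fc_max": call.log2fc_max,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def _endpoint_of(group: str) -> str:
    for ep in ("50", "90"):
        if group.endswith(ep):
            return "T" + ep
    raise DesignError(f"cannot infer endpoint from group label {group!r}")


def exclude_control_dep(
    lps_calls: pd.DataFrame, ct_calls: pd.DataFrame
) -> tuple[pd.DataFrame, frozenset]:
    """Drop from the LPS calls any protein deregulated in the matched control.

    Both call tables must concern the same endpoint. A protein deregulated in
    the control group in either direction is removed (its LPS rows dropped)
    and recorded in the returned excluded set.
    """
    lps_eps = {_endpoint_of(g) for g in lps_calls["group"].unique()}
    ct_eps = {_endpoint_of(g) for g in ct_calls["group"].unique()}
    if lps_eps and ct_eps and lps_eps != ct_eps:
        raise DesignError(f"endpoint mismatch between call tables: {lps_eps} vs {ct_eps}")
    control_dep = frozenset(ct_calls.loc[ct_calls["direction"] != "none", "protein_id"])
    retained = lps_calls[~lps_calls["protein_id"].isin(control_dep)].reset_index(drop=True)
    excluded = frozenset(p for p in lps_calls["protein_id"].unique() if p in control_dep)
    return retained, excluded


def partition_sets(
    retained_t50_ids, retained_t90_ids, control_excluded_ids=(), dep_by_set=None
) -> DepPartition:
    """Split the two endpoints' identification lists into common/specific sets."""
    t50 = frozenset(retained_t50_ids)
    t90 = frozenset(retained_t90_ids)
    return DepPartition(
        common_ids=t50 & t90,
        t50_specific_ids=t50 - t90,
        t90_specific_ids=t90 - t50,
        control_excluded_ids=frozenset(control_excluded_ids),
        dep_by_set=dep_by_set or {},
    )


def summarize_dep(
    calls: pd.DataFrame,
    partition: DepPartition,
    metadata: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Result tables per identification set, styled like published DEP tables.

    One table per (set, endpoint): common split by endpoint, plus the two
    specific sets. Columns: accession, protein/gene names when metadata is
    supplied, direction, Log2FC median (min; max) over qualifying animals, and
    n of group size. Sorted up-calls first, then descending qualifying count,
    then descending |median|. Only rows with a direction are listed, and
    control-excluded proteins never appear.
    """
    dep = calls[calls["direction"] != "none"].copy()
    dep = dep[~dep["protein_id"].isin(partition.control_excluded_ids)]
    tables: dict[str, pd.DataFrame] = {}
    sets = {
        "common_t50": (partition.common_ids, "T50"),
        "common_t90": (partition.common_ids, "T90"),
        "t50_specific": (partition.t50_specific_ids, "T50"),
        "t90_specific": (partition.t90_specific_ids, "T90"),
    }
    for name, (ids, endpoint) in sets.items():
        sub = dep[
            dep["protein_id"].isin(ids)
            & (dep["group"].map(_endpoint_of) == endpoint)
        ].copy()
        sub["_dir_rank"] = (sub["direction"] == "down").astype(int)
        sub["_abs_median"] = sub["log2fc_median"].abs()
        sub = sub.sort_values(
            ["_dir_rank", "n_qualifying", "_abs_median", "protein_id"],
            ascending=[True, False, False, True],
        ).drop(columns=["_dir_rank", "_abs_median"])
        if metadata is not None:
            sub.insert(1, "gene_name", sub["protein_id"].map(metadata["gene_name"]))
        sub["n_of_n"] = sub["n_qualifying"].astype(str) + "/" + sub["n_animals"].astype(str)
        tables[name] = sub.reset_index(drop=True)
    return tables
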