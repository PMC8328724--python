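"""Reference DEP summaries and reconstructed fold-change vectors.

The package ships the per-protein deregulation summaries reported for a rat
LPS endotoxemic-shock plasma secretome experiment: for each called protein,
its identification set (common to both endpoints, T50-specific or
T90-specific), endpoint, direction, the qualifying-animal count ``n`` (of 6),
and the Log2FC median with its (min; max) range over qualifying animals.
Summary rows sharing an ``n/6`` cell in the source tables carry that count
down to the rows below them, matching the per-section prose counts.

Because only summaries are published, six-animal fold-change vectors are
reconstructed deterministically so the DEP caller can be exercised end to
end: the qualifying entries are ``[min] + [median]*(n-2) + [max]`` (the
median of that multiset equals the printed median whenever min <= median <=
max) and the ``6-n`` non-qualifying entries are 0. Three source rows are
internally inconsistent and are flagged: two have a median whose sign
contradicts its range (direction is taken from table placement and the
vector is built from absolute magnitudes with that sign), and one has a
median outside its own (min; max) range (the median fill is clamped into the
range, so its reconstructed median is the range boundary). Flagged rows keep
their direction and count and are excluded from value-exactness checks only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import write_results

N_ANIMALS = 6


@dataclass(frozen=True)
class ReferenceRow:
    accession: str
    protein_name: str
    gene_name: str
    set_label: str  # common | t50_specific | t90_specific
    endpoint: str  # T50 | T90
    direction: str  # up | down
    median: float
    fc_min: float
    fc_max: float
    n_qualifying: int
    sign_consistent: bool = True
    stats_consistent: bool = True


# fmt: off
REFERENCE_ROWS: tuple[ReferenceRow, ...] = (
    # common set, T50 endpoint
    ReferenceRow("P06765", "Platelet factor 4", "Pf4", "common", "T50", "up", 3.31, 1.02, 5.20, 5),
    ReferenceRow("D3ZFH5", "Inter-alpha-trypsin inhibitor heavy chain 2", "Itih2", "common", "T50", "up", 1.25, 1.08, 2.34, 4),
    ReferenceRow("P26644", "Beta-2-glycoprotein 1", "Apoh", "common", "T50", "up", 1.45, 1.03, 1.55, 4),
    ReferenceRow("O55004", "Ribonuclease 4", "Rnase4", "common", "T50", "up", 1.78, 1.70, 2.90, 4),
    ReferenceRow("P00697", "Lysozyme C-1", "Lyz1", "common", "T50", "up", 1.77, 1.70, 2.63, 4),
    ReferenceRow("P23764", "Glutathione peroxidase 3", "Gpx3", "common", "T50", "down", -2.58, -1.45, -4.75, 4),
    # common set, T90 endpoint
    ReferenceRow("P17475", "Alpha-1-antiproteinase", "Serpina1", "common", "T90", "up", 3.73, 2.97, 5.65, 5),
    ReferenceRow("Q99PS8", "Histidine-rich glycoprotein", "Hrg", "common", "T90", "up", 2.39, 1.37, 3.89, 5),
    ReferenceRow("D3ZFH5", "Inter-alpha-trypsin inhibitor heavy chain 2", "Itih2", "common", "T90", "up", 1.92, 1.58, 3.82, 4),
    ReferenceRow("Q9QUH3", "Apolipoprotein A-V", "Apoa5", "common", "T90", "up", 1.44, 1.00, 2.24, 4),
    ReferenceRow("P24594", "Insulin-like growth factor-binding protein 5", "Igfbp5", "common", "T90", "up", 2.14, 1.02, 3.79, 4),
    ReferenceRow("P08650", "Complement C5", "C5", "common", "T90", "up", 5.27, 3.28, 6.21, 4),
    ReferenceRow("O55004", "Ribonuclease 4", "Rnase4", "common", "T90", "up", 1.68, 1.28, 2.32, 4),
    ReferenceRow("D3ZTE0", "Coagulation factor XII", "F12", "common", "T90", "up", 1.42, 1.32, 1.73, 4),
    ReferenceRow("P00697", "Lysozyme C-1", "Lyz1", "common", "T90", "up", 2.86, 1.25, 3.81, 4),
    ReferenceRow("Q6IRK9", "Carboxypeptidase Q", "Cpq", "common", "T90", "up", 1.94, 1.05, 3.34, 4),
    ReferenceRow("P04638", "Apolipoprotein A-II", "Apoa2", "common", "T90", "down", -1.96, -1.19, -5.20, 5),
    ReferenceRow("P55797", "Apolipoprotein C-IV", "Apoc4", "common", "T90", "down", -1.88, -1.37, -2.91, 5),
    # median printed +2.39 against a negative (min; max): sign-inconsistent
    ReferenceRow("P20767", "Ig lambda-2 chain C region", "N/A", "common", "T90", "down", 2.39, -1.50, -3.30, 5, sign_consistent=False),
    ReferenceRow("Q8R2H5", "Phosphatidylinositol-glycan-specific phospholipase D", "Gpld1", "common", "T90", "down", -1.48, -1.02, -2.72, 5),
    ReferenceRow("P14630", "Apolipoprotein M", "Apom", "common", "T90", "down", -2.94, -1.46, -4.82, 5),
    ReferenceRow("P23764", "Glutathione peroxidase 3", "Gpx3", "common", "T90", "down", -2.05, -1.48, -3.44, 5),
    ReferenceRow("Q68FP1", "Gelsolin", "Gsn", "common", "T90", "down", -2.05, -1.67, -4.47, 4),
    ReferenceRow("P06759", "Apolipoprotein C-III", "Apoc3", "common", "T90", "down", -2.60, -1.08, -3.66, 4),
    ReferenceRow("P55159", "Serum paraoxonase/arylesterase 1", "Pon1", "common", "T90", "down", -2.15, -1.17, -2.49, 4),
    ReferenceRow("P02651", "Apolipoprotein A-IV", "Apoa4", "common", "T90", "down", -1.54, -1.04, -2.61, 4),
    ReferenceRow("P35859", "IGFBP complex acid labile subunit", "Igfals", "common", "T90", "down", -2.49, -2.20, -2.90, 4),
    ReferenceRow("P10960", "Prosaposin", "Psap", "common", "T90", "down", -2.57, -1.53, -3.90, 4),
    # T50-specific set
    ReferenceRow("Q5FVN3", "Ccl9-like protein", "Ccl9", "t50_specific", "T50", "up", 3.69, 1.38, 4.98, 4),
    ReferenceRow("Q05820", "Putative lysozyme C-2", "Lyz2", "t50_specific", "T50", "up", 1.67, 1.30, 2.64, 4),
    # median 1.10 below its own min 1.30: stats-inconsistent
    ReferenceRow("Q63556", "Serine protease inhibitor A3M", "Serpina3m", "t50_specific", "T50", "up", 1.10, 1.30, 2.63, 4, stats_consistent=False),
    ReferenceRow("Q5BK77", "Chemerin", "Rarres2", "t50_specific", "T50", "down", -2.24, -1.36, -2.98, 5),
    # T90-specific set
    ReferenceRow("Q5GAM5", "Angiogenin ribonuclease 2", "Ang2", "t90_specific", "T90", "up", 1.79, 1.32, 3.47, 4),
    ReferenceRow("Q6MG90", "C4a anaphylatoxin", "C4a", "t90_specific", "T90", "down", -3.22, -1.42, -6.85, 6),
    # median printed -2.37 against a positive (min; max): sign-inconsistent
    ReferenceRow("D3ZQ25", "Fibulin-1", "Fbln1", "t90_specific", "T90", "down", -2.37, 1.24, 5.70, 6, sign_consistent=False),
    ReferenceRow("Q5M890", "Apolipoprotein N", "Apon", "t90_specific", "T90", "down", -4.55, -1.46, -5.61, 6),
    ReferenceRow("Q5M8C3", "Serine proteinase inhibitor clade A member 4", "Serpina4", "t90_specific", "T90", "down", -1.59, -1.11, -2.75, 6),
    ReferenceRow("Q64240", "Protein AMBP", "Ambp", "t90_specific", "T90", "down", -3.25, -1.09, -5.11, 6),
    ReferenceRow("B1H260", "Coagulation factor XIII B chain", "F13b", "t90_specific", "T90", "down", -3.86, -1.07, -5.12, 5),
    ReferenceRow("F1LZ11", "Ig-like domain-containing protein", "N/A", "t90_specific", "T90", "down", -1.72, -1.00, -3.56, 5),
    ReferenceRow("A0A0G2JXI1", "Coagulation factor V", "F5", "t90_specific", "T90", "down", -2.23, -1.76, -4.25, 4),
    ReferenceRow("P08649", "Complement C4", "C4", "t90_specific", "T90", "down", -3.14, -1.16, -4.59, 4),
    ReferenceRow("P07151", "Beta-2-microglobulin", "B2m", "t90_specific", "T90", "down", -1.51, -1.32, -2.36, 4),
)
# fmt: on


def build_vector(row: ReferenceRow, n_animals: int = N_ANIMALS) -> np.ndarray:
    """Reconstruct a deterministic fold-change vector consistent with a row.

    Qualifying entries are ``[min] + [median]*(n-2) + [max]`` built from
    absolute magnitudes and signed by the row's direction; the median fill is
    clamped into [|min|, |max|] so inconsistent rows still qualify. The
    ``n_animals - n`` remaining entries are 0 (non-qualifying).
    """
    sign = 1.0 if row.direction == "up" else -1.0
    mn, mx = sorted([abs(row.fc_min), abs(row.fc_max)])
    med = float(np.clip(abs(row.median), mn, mx))
    n = row.n_qualifying
    qualifying = [mn] + [med] * (n - 2) + [mx]
    values = np.array(qualifying + [0.0] * (n_animals - n), dtype=float)
    return sign * values


def reference_table() -> pd.DataFrame:
    """All reference rows as a flat DataFrame."""
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "protein_name": r.protein_name,
                "gene_name": r.gene_name,
                "set_label": r.set_label,
                "endpoint": r.endpoint,
                "direction": r.direction,
                "log2fc_median": r.median,
                "log2fc_min": r.fc_min,
                "log2fc_max": r.fc_max,
                "n_qualifying": r.n_qualifying,
                "n_animals": N_ANIMALS,
                "sign_consistent": r.sign_consistent,
                "stats_consistent": r.stats_consistent,
            }
            for r in REFERENCE_ROWS
        ]
    )


def fixture_fold_changes() -> pd.DataFrame:
    """Long fold-change table over all reference rows, ready for the caller.

    Rows are keyed by (set_label, endpoint) via the group label
    ``<set_label>:LPS<endpoint digits>``, and animals ``a1..a6``, so the same
    accession can recur in different sets/endpoints without collision.
    """
    frames = []
    for r in REFERENCE_ROWS:
        vec = build_vector(r)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": r.accession,
                    "group": f"{r.set_label}:LPS{r.endpoint[1:]}",
                    "animal_id": [f"a{i}" for i in range(1, N_ANIMALS + 1)],
                    "log2fc": vec,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def make_fixtures(out_dir) -> list[Path]:
    """Write the reference summary table and reconstructed vectors as TSVs."""
    out_dir = Path(out_dir)
    vectors = fixture_fold_changes()
    wide = vectors.pivot_table(
        index=["group", "protein_id"], columns="animal_id", values="log2fc", sort=True
    ).reset_index()
    wide.columns.name = None
    return write_results(
        {"reference_summaries": reference_table(), "reference_fold_changes": wide},
        out_dir,
    )
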