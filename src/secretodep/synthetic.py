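"""Synthetic paired label-free quantification data with known ground truth.

The generator emulates the study design the pipeline targets: four groups
(CT50, LPS50, CT90, LPS90) of six animals, each animal sampled at baseline T0
and at its endpoint (T50 or T90), every sample measured in technical
duplicate, and a yeast-enolase internal standard spiked into every sample at a
fixed amount. Deregulations are planted multiplicatively between an animal's
T0 and endpoint values in the LPS groups; "control drift" proteins receive the
same perturbation in the control groups as well, so the control-exclusion
stage has known targets. Per-sample global scale factors (run-to-run signal
drift) are applied to every protein including the spike, making spike
normalization necessary, and missing values are injected with an
intensity-dependent (MNAR) bias.

Intensity model: per-protein log-normal baselines with log10 means uniform on
a configurable range, animal-level biological variation, endpoint biological
noise on the log2 fold change, and multiplicative technical-replicate noise.
All stochastic knobs are configurable so that noise-free data (exact planted
ratios) can be generated for invariant checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_tables import AnnotationSet, QuantMatrix, SampleDesign, DESIGN_COLUMNS

DEFAULT_GROUPS = (("CT", "T50"), ("LPS", "T50"), ("CT", "T90"), ("LPS", "T90"))

PLANTED_CLASSES = ("up", "down", "control_drift", "null")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Counts of planted proteins are ``floor(n_proteins * fraction)`` so they are
    deterministic. The spike protein is an extra row on top of ``n_proteins``,
    never planted and never missing.
    """

    n_animals_per_group: int = 6
    groups: tuple = DEFAULT_GROUPS
    n_proteins: int = 300
    n_technical_replicates: int = 2
    spike_protein_id: str = "P00924"
    spike_amount: float = 1.0e6
    effect_log2fc: float = 2.0
    frac_deregulated_up: float = 0.05
    frac_deregulated_down: float = 0.05
    frac_control_drift: float = 0.02
    missing_rate: float = 0.10
    mnar_strength: float = 1.0
    coverage_range: tuple = (5.0, 95.0)
    seed: int = 0
    # Noise/scale knobs; zeros give exact planted ratios after normalization.
    baseline_log10_range: tuple = (4.0, 8.0)
    animal_sd_log10: float = 0.20
    fc_noise_sd: float = 0.30
    tech_rep_sd_log10: float = 0.05
    scale_factor_range: tuple = (0.5, 2.0)
    frac_unquantifiable: float = 0.05

    def validate(self) -> None:
        if self.n_animals_per_group < 1:
            raise ConfigurationError("n_animals_per_group must be >= 1")
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if self.n_technical_replicates < 1:
            raise ConfigurationError("n_technical_replicates must be >= 1")
        if self.spike_amount <= 0:
            raise ConfigurationError("spike_amount must be positive")
        fracs = {
            "frac_deregulated_up": self.frac_deregulated_up,
            "frac_deregulated_down": self.frac_deregulated_down,
            "frac_control_drift": self.frac_control_drift,
            "missing_rate": self.missing_rate,
            "frac_unquantifiable": self.frac_unquantifiable,
        }
        for name, val in fracs.items():
            if not 0 <= val <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {val}")
        total = self.frac_deregulated_up + self.frac_deregulated_down + self.frac_control_drift
        if total > 1:
            raise ConfigurationError(
                f"planted fractions sum to {total}, must be <= 1"
            )
        if self.mnar_strength < 0:
            raise ConfigurationError("mnar_strength must be >= 0")
        lo, hi = self.coverage_range
        if not (0 <= lo <= hi <= 100):
            raise ConfigurationError("coverage_range must satisfy 0 <= low <= high <= 100")
        for cond, endpoint in self.groups:
            if cond not in ("CT", "LPS") or endpoint not in ("T50", "T90"):
                raise ConfigurationError(f"invalid group ({cond}, {endpoint})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = [list(g) for g in self.groups]
        return d


def _planted_classes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_proteins
    n_up = int(np.floor(n * cfg.frac_deregulated_up))
    n_down = int(np.floor(n * cfg.frac_deregulated_down))
    n_drift = int(np.floor(n * cfg.frac_control_drift))
    classes = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_up]] = "up"
    classes[order[n_up : n_up + n_down]] = "down"
    classes[order[n_up + n_down : n_up + n_down + n_drift]] = "control_drift"
    return classes


def _build_design(cfg: SimulationConfig) -> SampleDesign:
    rows = []
    for cond, endpoint in cfg.groups:
        group = f"{cond}{endpoint[1:]}"  # CT + 50 -> CT50
        for a in range(1, cfg.n_animals_per_group + 1):
            animal = f"{group}-{a}"
            for tp in ("T0", endpoint):
                for rep in range(1, cfg.n_technical_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{animal}_{tp}_r{rep}",
                            "animal_id": animal,
                            "condition": cond,
                            "timepoint": tp,
                            "tech_rep": rep,
                            "group": group,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def generate_dataset(cfg: SimulationConfig) -> tuple[QuantMatrix, SampleDesign, pd.DataFrame]:
    """Generate (QuantMatrix, SampleDesign, TruthTable) for one synthetic study.

    The truth table has one row per protein (including the spike) with its
    planted class and the true log2 fold change per group
    (``true_log2fc_<group>`` columns). Deterministic for a fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    design = _build_design(cfg)
    dt = design.table
    group_labels = sorted(dt["group"].unique())
    group_cond = {g: dt.loc[dt["group"] == g, "condition"].iloc[0] for g in group_labels}

    width = max(4, len(str(cfg.n_proteins)))
    protein_ids = [f"SYN{i:0{width}d}" for i in range(1, cfg.n_proteins + 1)]
    classes = _planted_classes(cfg, rng)

    # true log2fc per (protein, group): LPS groups carry up/down effects,
    # control-drift proteins shift in every group.
    true_lfc = pd.DataFrame(0.0, index=protein_ids, columns=group_labels)
    for g in group_labels:
        is_lps = group_cond[g] == "LPS"
        col = np.zeros(cfg.n_proteins)
        if is_lps:
            col[classes == "up"] = cfg.effect_log2fc
            col[classes == "down"] = -cfg.effect_log2fc
        col[classes == "control_drift"] = cfg.effect_log2fc
        true_lfc[g] = col

    lo10, hi10 = cfg.baseline_log10_range
    base_log10 = rng.uniform(lo10, hi10, size=cfg.n_proteins)

    animals = dt[["animal_id", "group"]].drop_duplicates().reset_index(drop=True)
    n_animals = len(animals)
    # animal-level T0 abundance and endpoint biological noise, per protein
    animal_dev = rng.normal(0.0, cfg.animal_sd_log10, size=(cfg.n_proteins, n_animals))
    fc_noise = rng.normal(0.0, cfg.fc_noise_sd, size=(cfg.n_proteins, n_animals))

    t0_log10 = base_log10[:, None] + animal_dev
    lfc_by_animal = np.column_stack(
        [true_lfc[animals.loc[j, "group"]].to_numpy() for j in range(n_animals)]
    )
    tend_log10 = t0_log10 + (lfc_by_animal + fc_noise) * np.log10(2.0)

    animal_pos = {a: j for j, a in enumerate(animals["animal_id"])}
    sample_ids = list(dt["sample_id"])
    log_half, log_two = np.log(cfg.scale_factor_range[0]), np.log(cfg.scale_factor_range[1])
    scale = np.exp(rng.uniform(log_half, log_two, size=len(sample_ids)))

    intens = np.empty((cfg.n_proteins + 1, len(sample_ids)))
    spike_row = cfg.n_proteins  # spike appended last
    for s, (sid, animal, tp) in enumerate(zip(dt["sample_id"], dt["animal_id"], dt["timepoint"])):
        j = animal_pos[animal]
        col_log10 = t0_log10[:, j] if tp == "T0" else tend_log10[:, j]
        tech = rng.normal(0.0, cfg.tech_rep_sd_log10, size=cfg.n_proteins + 1)
        intens[:spike_row, s] = 10 ** (col_log10 + tech[:spike_row]) * scale[s]
        intens[spike_row, s] = cfg.spike_amount * 10 ** tech[spike_row] * scale[s]

    # MNAR missingness on non-spike rows only
    if cfg.missing_rate > 0:
        body = np.log10(intens[:spike_row, :])
        sd = body.std() or 1.0
        z = (body - body.mean()) / sd
        w = 1.0 / (1.0 + np.exp(cfg.mnar_strength * z))
        p = np.clip(cfg.missing_rate * w / w.mean(), 0.0, 0.95)
        drop = rng.uniform(size=p.shape) < p
        intens[:spike_row, :][drop] = np.nan

    all_ids = protein_ids + [cfg.spike_protein_id]
    intensities = pd.DataFrame(intens, index=all_ids, columns=sample_ids)

    # metadata: most proteins pass the quantifiability gate, a small fraction
    # is emitted with 1 peptide or a score below 6 to exercise the filter
    n_unq = int(np.floor(cfg.n_proteins * cfg.frac_unquantifiable))
    unq_idx = rng.choice(cfg.n_proteins, size=n_unq, replace=False) if n_unq else np.array([], dtype=int)
    peptides = 2 + rng.poisson(5, size=cfg.n_proteins)
    score = rng.uniform(6.0, 20.0, size=cfg.n_proteins)
    half = n_unq // 2
    peptides[unq_idx[:half]] = 1
    score[unq_idx[half:]] = rng.uniform(0.0, 5.99, size=n_unq - half)
    coverage = rng.uniform(cfg.coverage_range[0], cfg.coverage_range[1], size=cfg.n_proteins)
    metadata = pd.DataFrame(
        {
            "gene_name": [f"gene{i:0{width}d}" for i in range(1, cfg.n_proteins + 1)] + ["ENO1"],
            "n_unique_peptides": np.append(peptides, 10),
            "quality_score": np.append(score, 20.0),
            "coverage_pct": np.append(coverage, 80.0),
        },
        index=all_ids,
    )

    truth = pd.DataFrame({"protein_id": all_ids, "planted_class": list(classes) + ["null"]})
    for g in group_labels:
        truth[f"true_log2fc_{g}"] = list(true_lfc[g]) + [0.0]

    return QuantMatrix(intensities, metadata), design, truth


def generate_annotation(
    truth: pd.DataFrame,
    n_terms: int = 20,
    seed: int = 0,
    term_size_range: tuple = (5, 25),
) -> AnnotationSet:
    """Random flat annotation plus a ``planted_up`` term for enrichment tests.

    The ``planted_up`` term contains exactly the proteins planted as
    upregulated, giving the enrichment stage a known positive control. Random
    term members are drawn without replacement from all protein accessions.
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    all_ids = list(truth["protein_id"])
    up_ids = sorted(truth.loc[truth["planted_class"] == "up", "protein_id"])
    terms: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    if up_ids:
        terms["planted_up"] = frozenset(up_ids)
        names["planted_up"] = "proteins planted as upregulated"
    lo, hi = term_size_range
    hi = min(hi, len(all_ids))
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(all_ids, size=size, replace=False)
        term = f"RND{i:04d}"
        terms[term] = frozenset(members.tolist())
        names[term] = f"random term {i}"
    return AnnotationSet(terms, names)


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
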