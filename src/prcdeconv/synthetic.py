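"""Synthetic bait-prey MS experiments with known ground truth.

The generator emulates a comparative interactome screen: two cell lines, one
engineered to overexpress the hub bait and one to knock it down, each
carrying an empty-backbone control; pull-downs for the hub bait, a partner
bait discriminating complex variants, a catalytic histone-mark bait, and a
no-antibody mock; two independent cultures x two technical replicates per
condition.  Planted protein complexes are recovered by their detecting
baits, contaminants stick to beads in every run (mocks included) with a
per-run probability, and complexes coupled to the hub scale their abundance
with the modulated hub expression.

Intensities are drawn log-normally around a per-protein baseline (MS2
intensity distributions are right-skewed and downstream statistics average
raw intensities); values below the dropout threshold are recorded as not
detected.  All randomness flows through a single seeded generator, so a
fixed seed reproduces the fixture byte-for-byte.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .filtering import ContaminantRepository, IntensityMatrix

MEMBERSHIP_CATEGORIES = (
    "canonical_only",
    "shared_core",
    "noncanonical_only",
    "chromatome_catalytic",
    "chromatome_independent",
    "bait_independent_unassigned",
)


@dataclass(frozen=True)
class ComplexModel:
    """One planted protein complex.

    ``baits_detecting`` lists the pull-downs that recover the complex;
    ``coupled_to_hub`` marks complexes whose member abundance scales with
    the modulated hub bait (stoichiometric partners).
    """

    complex_id: str
    members: tuple
    baits_detecting: frozenset
    coupled_to_hub: bool = False

    def __post_init__(self):
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "baits_detecting", frozenset(self.baits_detecting))
        if not self.members:
            raise ConfigurationError(f"complex {self.complex_id!r}: members empty")
        if not self.baits_detecting:
            raise ConfigurationError(
                f"complex {self.complex_id!r}: baits_detecting empty"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated screen.

    The first cell line is the overexpression-modulated line, the second the
    knockdown-modulated line; in their ``modulated`` condition, coupled
    complex members are multiplied by ``modulation_multiplier_up`` and
    ``modulation_multiplier_down`` respectively.
    """

    n_proteins: int = 500
    complexes: tuple = ()
    n_contaminants: int = 50
    contaminant_detection_prob: float = 0.6
    baseline_log_intensity_mean: float = math.log(1e6)
    log_noise_sd: float = 0.4
    dropout_threshold: float = 1000.0
    modulation_multiplier_up: float = 4.0
    modulation_multiplier_down: float = 0.25
    cell_lines: tuple = ("U87MG", "LN428")
    baits: tuple = ("BMI1", "RYBP", "H2AK119ub", "mock")
    mock_label: str = "mock"
    hub_bait: str = "BMI1"
    partner_bait: str = "RYBP"
    mark_bait: str = "H2AK119ub"
    conditions: tuple = ("control", "modulated")
    n_cultures: int = 2
    n_tech_reps: int = 2
    seed: int = 0
    # spread of per-protein baseline log-intensities around the global mean
    baseline_protein_sd: float = 0.5
    # sporadic one-off detection rate for unassigned background proteins
    background_detection_prob: float = 0.02
    # probability that a true complex member leaks into a mock run
    mock_carryover_prob: float = 0.0

    def validate(self) -> None:
        if self.n_cultures < 1:
            raise ConfigurationError("n_cultures must be >= 1")
        if self.n_tech_reps < 1:
            raise ConfigurationError("n_tech_reps must be >= 1")
        if not (self.modulation_multiplier_up > 1):
            raise ConfigurationError("modulation_multiplier_up must be > 1")
        if not (0 < self.modulation_multiplier_down < 1):
            raise ConfigurationError(
                "modulation_multiplier_down must be in (0, 1)"
            )
        if self.dropout_threshold < 0:
            raise ConfigurationError("dropout_threshold must be >= 0")
        if self.n_contaminants < 0:
            raise ConfigurationError("n_contaminants must be >= 0")
        for name in (
            "contaminant_detection_prob",
            "background_detection_prob",
            "mock_carryover_prob",
        ):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.log_noise_sd < 0:
            raise ConfigurationError("log_noise_sd must be >= 0")
        if len(self.cell_lines) != 2:
            raise ConfigurationError(
                "cell_lines must hold exactly two lines "
                "(overexpression line first, knockdown line second)"
            )
        if self.mock_label not in self.baits:
            raise ConfigurationError("baits must include mock_label")
        non_mock = set(self.baits) - {self.mock_label}
        ids = [c.complex_id for c in self.complexes]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("complexes: complex_ids must be unique")
        seen = set()
        for c in self.complexes:
            if not c.baits_detecting <= non_mock:
                raise ConfigurationError(
                    f"complexes: baits_detecting of {c.complex_id!r} not among baits"
                )
            overlap = seen & set(c.members)
            if overlap:
                raise ConfigurationError(
                    f"complexes: protein {sorted(overlap)[0]!r} in multiple complexes"
                )
            seen |= set(c.members)
        if self.n_proteins < len(seen) + self.n_contaminants:
            raise ConfigurationError(
                "n_proteins smaller than complex members + n_contaminants"
            )

    @property
    def member_ids(self) -> list:
        out = []
        for c in self.complexes:
            out.extend(c.members)
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Per-protein truth table for scoring downstream stages.

    Columns: ``true_complex`` (empty string for non-members),
    ``is_contaminant``, ``is_modulation_coupled``, plus the derived
    ``expected_category`` a perfect deconvolution would assign.
    """

    table: pd.DataFrame

    def __post_init__(self):
        if self.table.index.duplicated().any():
            raise ConfigurationError("ground truth: duplicated protein IDs")

    @property
    def contaminants(self) -> frozenset:
        return frozenset(self.table.index[self.table["is_contaminant"]])

    @property
    def coupled(self) -> frozenset:
        return frozenset(self.table.index[self.table["is_modulation_coupled"]])

    def members_of(self, complex_id: str) -> frozenset:
        return frozenset(self.table.index[self.table["true_complex"] == complex_id])

    @property
    def expected_categories(self) -> pd.Series:
        return self.table["expected_category"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["is_contaminant"] = out["is_contaminant"].astype(int)
        out["is_modulation_coupled"] = out["is_modulation_coupled"].astype(int)
        out.to_csv(path, sep="\t", index_label="protein_id")

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", index_col="protein_id", keep_default_na=False)
        df.index = df.index.astype(str)
        df["true_complex"] = df["true_complex"].astype(str)
        df["is_contaminant"] = df["is_contaminant"].astype(int).astype(bool)
        df["is_modulation_coupled"] = (
            df["is_modulation_coupled"].astype(int).astype(bool)
        )
        return cls(table=df)


def _expected_category(config: SimulationConfig, cm: ComplexModel | None) -> str:
    """Category a perfect multi-bait deconvolution assigns to a complex."""
    if cm is None:
        return "bait_independent_unassigned"
    d = cm.baits_detecting
    hub, partner, mark = config.hub_bait, config.partner_bait, config.mark_bait
    if hub in d and partner in d:
        return "shared_core"
    if partner in d:
        return "noncanonical_only"
    if hub in d and mark in d:
        return "chromatome_catalytic"
    if hub in d:
        return "canonical_only"
    return "bait_independent_unassigned"


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for line, cond, bait, culture, rep in itertools.product(
        config.cell_lines,
        config.conditions,
        config.baits,
        range(1, config.n_cultures + 1),
        range(1, config.n_tech_reps + 1),
    ):
        sid = f"{line}.{cond}.{bait}.c{culture}.r{rep}"
        rows.append(
            {
                "sample_id": sid,
                "cell_line": line,
                "bait": bait,
                "condition": cond,
                "culture": culture,
                "tech_rep": rep,
                "is_mock": int(bait == config.mock_label),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_interactome(config: SimulationConfig):
    """Simulate one full screen.

    Returns
    -------
    (IntensityMatrix, GroundTruth)
        One sample column per (cell line x condition x bait x culture x
        technical replicate), mocks included.  Identical seed, identical
        output.
    """
    config.validate()
    samples = _sample_table(config)
    n_samp = len(samples)

    members = config.member_ids
    n_members = len(members)
    contaminants = [f"CONT{i:04d}" for i in range(1, config.n_contaminants + 1)]
    n_bg = config.n_proteins - n_members - config.n_contaminants
    background = [f"BG{i:04d}" for i in range(1, n_bg + 1)]
    proteins = list(members) + contaminants + background
    if len(set(proteins)) != len(proteins):
        raise ConfigurationError(
            "complexes: member IDs collide with generated CONT/BG IDs"
        )

    rng = np.random.default_rng(config.seed)
    baseline = config.baseline_log_intensity_mean + rng.normal(
        0.0, config.baseline_protein_sd, len(proteins)
    )
    cont_mask = rng.random((config.n_contaminants, n_samp)) < (
        config.contaminant_detection_prob
    )
    bg_mask = rng.random((n_bg, n_samp)) < config.background_detection_prob
    carry_mask = rng.random((n_members, n_samp)) < config.mock_carryover_prob
    noise = rng.normal(0.0, config.log_noise_sd, (len(proteins), n_samp))

    is_mock_col = samples["is_mock"].to_numpy(dtype=bool)
    bait_col = samples["bait"].to_numpy()
    line_col = samples["cell_line"].to_numpy()
    cond_col = samples["condition"].to_numpy()

    detect = np.zeros((len(proteins), n_samp), dtype=bool)
    mult = np.ones((len(proteins), n_samp))
    modulated = cond_col == config.conditions[1]
    up_cols = modulated & (line_col == config.cell_lines[0])
    down_cols = modulated & (line_col == config.cell_lines[1])

    row = 0
    for cm in config.complexes:
        bait_hit = np.isin(bait_col, sorted(cm.baits_detecting)) & ~is_mock_col
        for _ in cm.members:
            detect[row] = bait_hit | (carry_mask[row] & is_mock_col)
            if cm.coupled_to_hub:
                mult[row, up_cols] = config.modulation_multiplier_up
                mult[row, down_cols] = config.modulation_multiplier_down
            row += 1
    detect[row : row + config.n_contaminants] = cont_mask
    row += config.n_contaminants
    detect[row : row + n_bg] = bg_mask

    values = np.exp(baseline[:, None] + noise) * mult
    values[~detect] = np.nan
    values[values < config.dropout_threshold] = np.nan

    matrix = IntensityMatrix(
        values=pd.DataFrame(values, index=pd.Index(proteins, name="protein_id"),
                            columns=samples.index),
        samples=samples,
    )

    truth_rows = []
    for cm in config.complexes:
        cat = _expected_category(config, cm)
        for pid in cm.members:
            truth_rows.append(
                (pid, cm.complex_id, False, cm.coupled_to_hub, cat)
            )
    for pid in contaminants:
        truth_rows.append((pid, "", True, False, "bait_independent_unassigned"))
    for pid in background:
        truth_rows.append((pid, "", False, False, "bait_independent_unassigned"))
    truth = GroundTruth(
        table=pd.DataFrame(
            truth_rows,
            columns=[
                "protein_id",
                "true_complex",
                "is_contaminant",
                "is_modulation_coupled",
                "expected_category",
            ],
        ).set_index("protein_id")
    )
    return matrix, truth


def repository_from_truth(
    truth: GroundTruth, frequency: float = 0.6, n_control_runs: int = 400
) -> ContaminantRepository:
    """Contaminant-repository table listing the simulation's true contaminants.

    Every true contaminant is recorded at the given control-run detection
    frequency; genuine interactors are absent from the repository, matching
    how a frequency repository built from unrelated negative controls would
    look for this screen.
    """
    cont = sorted(truth.contaminants)
    return ContaminantRepository(
        frequencies=pd.Series(frequency, index=pd.Index(cont, name="protein_id")),
        n_control_runs=n_control_runs,
    )


def write_fixture(matrix: IntensityMatrix, truth: GroundTruth, path) -> dict:
    """Write the TSV intensity table, metadata sheet and ground-truth table.

    Returns the mapping of logical name to file path; all three files
    round-trip through :func:`prcdeconv.filtering.read_intensity_table` and
    :meth:`GroundTruth.from_tsv`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": path / "intensities.tsv",
        "samples": path / "samples.tsv",
        "ground_truth": path / "ground_truth.tsv",
    }
    matrix.write(paths["intensities"], paths["samples"])
    truth.to_tsv(paths["ground_truth"])
    return paths


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default synthetic experiment.

    500 proteins: three planted complexes mirroring a canonical-variant
    complex (hub bait only, coupled), a shared core (hub + partner + mark
    baits, coupled) and a non-canonical variant (partner bait only,
    uncoupled), plus 50 bead contaminants and sporadic background proteins.
    """
    complexes = (
        ComplexModel(
            "cPRC1",
            tuple(f"CPRC1_{i:03d}" for i in range(1, 61)),
            frozenset({"BMI1"}),
            coupled_to_hub=True,
        ),
        ComplexModel(
            "core",
            tuple(f"CORE_{i:03d}" for i in range(1, 26)),
            frozenset({"BMI1", "RYBP", "H2AK119ub"}),
            coupled_to_hub=True,
        ),
        ComplexModel(
            "ncPRC1",
            tuple(f"NCPRC1_{i:03d}" for i in range(1, 41)),
            frozenset({"RYBP"}),
            coupled_to_hub=False,
        ),
    )
    return SimulationConfig(complexes=complexes, seed=seed, **overrides)


def concordance_benchmark_config(
    seed: int = 0, n_interactors: int = 218, n_coupled: int = 105
) -> SimulationConfig:
    """Noise-free benchmark for concordance classification.

    All interactors are recovered by the hub bait; exactly ``n_coupled`` of
    them carry the planted concordant modulation effect (intensity up in the
    overexpression line, down in the knockdown line) and the remainder carry
    none.
    """
    if not 0 <= n_coupled <= n_interactors:
        raise ConfigurationError("n_coupled must be in [0, n_interactors]")
    complexes = (
        ComplexModel(
            "coupled",
            tuple(f"COUP_{i:03d}" for i in range(1, n_coupled + 1)),
            frozenset({"BMI1"}),
            coupled_to_hub=True,
        ),
        ComplexModel(
            "uncoupled",
            tuple(f"UNCO_{i:03d}" for i in range(1, n_interactors - n_coupled + 1)),
            frozenset({"BMI1"}),
            coupled_to_hub=False,
        ),
    )
    return SimulationConfig(
        n_proteins=n_interactors,
        complexes=complexes,
        n_contaminants=0,
        log_noise_sd=0.0,
        dropout_threshold=0.0,
        background_detection_prob=0.0,
        seed=seed,
    )
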