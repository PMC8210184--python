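"""Intensity-table I/O and presence/absence interactor filtering.

An AP-MS or ChIP-MS screen yields, per pull-down run, MS2 spectral
intensities for the proteins identified in that run.  This module holds the
protein x sample intensity container, reads/writes its TSV representation,
and applies the two binary filters that turn raw detections into an
interactor list for one (bait, cell line) experiment:

* **mock subtraction** — proteins detected in no-antibody (mock) pull-downs
  are bead-binding background and are removed outright;
* **contaminant-repository filtering** — proteins detected in a large
  fraction of negative-control runs collected in an external repository
  (CRAPome-style frequency table) are removed above a frequency cutoff.

Both filters are presence/absence based: "detected" means a non-missing
intensity in at least ``min_runs`` replicate runs of the experiment.
Missing values are encoded as empty cells (NaN), never zero, so absence is
distinguishable from low intensity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyDesignError, SchemaError

META_COLUMNS = ("cell_line", "bait", "condition", "culture", "tech_rep", "is_mock")


@dataclass
class IntensityMatrix:
    """Protein x sample MS2-intensity grid with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein ID with one column per sample ID.
        Entries are non-negative intensities; NaN means *not detected*.
    samples
        DataFrame indexed by sample ID with columns
        ``cell_line, bait, condition, culture, tech_rep, is_mock``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise SchemaError(f"duplicated protein ID {dup!r} in intensity table")
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise SchemaError(f"duplicated sample ID {dup!r} in metadata")
        missing_cols = [c for c in META_COLUMNS if c not in self.samples.columns]
        if missing_cols:
            raise SchemaError(f"metadata missing columns {missing_cols}")
        unmet = set(self.values.columns) - set(self.samples.index)
        if unmet:
            raise SchemaError(
                f"sample {sorted(unmet)[0]!r} has no metadata row"
            )
        extra = set(self.samples.index) - set(self.values.columns)
        if extra:
            raise SchemaError(
                f"metadata sample {sorted(extra)[0]!r} absent from intensity table"
            )
        if self.samples[list(META_COLUMNS)].isna().any().any():
            bad = self.samples.index[
                self.samples[list(META_COLUMNS)].isna().any(axis=1)
            ][0]
            raise SchemaError(f"incomplete metadata for sample {bad!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            rows = self.values.index[(self.values < 0).any(axis=1)]
            raise SchemaError(f"negative intensity in row {rows[0]!r}")
        if not set(self.samples["is_mock"].astype(int)) <= {0, 1}:
            raise SchemaError("is_mock must be 0 or 1")
        # keep sample order aligned with columns
        self.samples = self.samples.loc[self.values.columns]

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    def run_ids(
        self,
        *,
        bait: str | None = None,
        cell_line: str | None = None,
        condition: str | None = None,
        is_mock: bool | None = None,
    ) -> list[str]:
        """Sample IDs matching the given design coordinates."""
        mask = pd.Series(True, index=self.samples.index)
        if bait is not None:
            mask &= self.samples["bait"] == bait
        if cell_line is not None:
            mask &= self.samples["cell_line"] == cell_line
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if is_mock is not None:
            mask &= self.samples["is_mock"].astype(int) == int(is_mock)
        return list(self.samples.index[mask])

    def write(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="protein_id")
        self.samples.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, values_path, meta_path) -> "IntensityMatrix":
        return read_intensity_table(values_path, meta_path)


def read_intensity_table(path, meta_path) -> IntensityMatrix:
    """Read the TSV intensity table and metadata sheet, validating both."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"is_mock": int})
    for frame, name in ((values, path), (meta, meta_path)):
        if frame.index.isna().any():
            raise SchemaError(f"empty ID field in {name}")
    values.index = values.index.astype(str)
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    return IntensityMatrix(values=values.astype(float), samples=meta)


@dataclass(frozen=True)
class InteractorSet:
    """Post-filter prey set for one (bait, cell line, condition) experiment.

    ``provenance`` is the ordered list of applied filters with the number of
    proteins each removed; counts always sum to the total shrinkage from the
    initial detection set.
    """

    bait: str
    cell_line: str
    condition: str
    proteins: frozenset
    provenance: tuple = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.proteins)

    def with_filter(self, name: str, kept: frozenset) -> "InteractorSet":
        removed = len(self.proteins) - len(kept)
        return replace(
            self, proteins=kept, provenance=self.provenance + ((name, removed),)
        )

    def to_tsv(self, path, sidecar: bool = True) -> None:
        pd.Series(sorted(self.proteins), name="protein_id").to_csv(
            path, sep="\t", index=False
        )
        if sidecar:
            side = Path(str(path) + ".provenance.json")
            side.write_text(
                json.dumps(
                    {
                        "bait": self.bait,
                        "cell_line": self.cell_line,
                        "condition": self.condition,
                        "n_proteins": len(self.proteins),
                        "filters": [
                            {"name": n, "removed": r} for n, r in self.provenance
                        ],
                    },
                    indent=2,
                    sort_keys=True,
                )
            )

    @classmethod
    def read_proteins(cls, path) -> frozenset:
        col = pd.read_csv(path, sep="\t")["protein_id"].astype(str)
        return frozenset(col)


@dataclass(frozen=True)
class ContaminantRepository:
    """Contaminant detection frequencies across negative-control runs.

    Maps protein ID to the fraction of ``n_control_runs`` control pull-downs
    in which it was detected.  Proteins absent from the repository are
    treated as never observed in controls and are kept by the filter.
    """

    frequencies: pd.Series
    n_control_runs: int = 0

    def __post_init__(self):
        freq = self.frequencies.astype(float)
        if ((freq < 0) | (freq > 1)).any():
            bad = freq.index[(freq < 0) | (freq > 1)][0]
            raise SchemaError(f"repository frequency outside [0,1] for {bad!r}")
        object.__setattr__(self, "frequencies", freq)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "protein_id": self.frequencies.index,
                "frequency": self.frequencies.to_numpy(),
                "n_runs": self.n_control_runs,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ContaminantRepository":
        df = pd.read_csv(path, sep="\t")
        for col in ("protein_id", "frequency"):
            if col not in df.columns:
                raise SchemaError(f"repository table missing column {col!r}")
        n_runs = int(df["n_runs"].iloc[0]) if "n_runs" in df.columns and len(df) else 0
        return cls(
            frequencies=pd.Series(
                df["frequency"].to_numpy(), index=df["protein_id"].astype(str)
            ),
            n_control_runs=n_runs,
        )


def detect_present(
    matrix: IntensityMatrix,
    bait: str,
    cell_line: str,
    condition: str,
    min_runs: int = 2,
) -> frozenset:
    """Proteins detected in >= ``min_runs`` replicate runs of the experiment.

    Replicate runs are the non-mock samples matching (bait, cell line,
    condition); with two cultures and two technical replicates that is four
    runs, and the default ``min_runs=2`` requires reproducible detection.
    """
    cols = matrix.run_ids(
        bait=bait, cell_line=cell_line, condition=condition, is_mock=False
    )
    if not cols:
        raise EmptyDesignError(
            f"no runs for bait={bait!r}, cell_line={cell_line!r}, "
            f"condition={condition!r}"
        )
    if not 1 <= min_runs <= len(cols):
        raise ValueError(f"min_runs must be in [1, {len(cols)}], got {min_runs}")
    counts = matrix.values[cols].notna().sum(axis=1)
    return frozenset(matrix.values.index[counts >= min_runs])


def detect_in_mocks(
    matrix: IntensityMatrix,
    cell_line: str,
    condition: str | None = None,
    min_runs: int = 1,
) -> frozenset:
    """Proteins detected in >= ``min_runs`` mock (no-antibody) runs.

    The default ``min_runs=1`` implements strict mock subtraction: a single
    detection in any mock run marks the protein as bead background.
    """
    cols = matrix.run_ids(cell_line=cell_line, condition=condition, is_mock=True)
    if not cols:
        raise EmptyDesignError(
            f"no mock runs for cell_line={cell_line!r}, condition={condition!r}"
        )
    counts = matrix.values[cols].notna().sum(axis=1)
    return frozenset(matrix.values.index[counts >= min_runs])


def build_interactor_set(
    matrix: IntensityMatrix,
    bait: str,
    cell_line: str,
    condition: str,
    min_runs: int = 2,
) -> InteractorSet:
    """Initial (unfiltered) interactor set from the detection rule."""
    proteins = detect_present(matrix, bait, cell_line, condition, min_runs)
    return InteractorSet(
        bait=bait,
        cell_line=cell_line,
        condition=condition,
        proteins=proteins,
        provenance=((f"detect_present(min_runs={min_runs})", 0),),
    )


def subtract_mock(ip_set, mock_set) -> InteractorSet:
    """Remove every protein detected in mock pull-downs.

    ``ip_set`` may be an :class:`InteractorSet` (provenance is extended) or a
    plain set (a fresh unlabelled InteractorSet is created).
    """
    mock = frozenset(mock_set)
    if isinstance(ip_set, InteractorSet):
        base = ip_set
    else:
        base = InteractorSet(
            bait="", cell_line="", condition="", proteins=frozenset(ip_set)
        )
    kept = frozenset(base.proteins - mock)
    return base.with_filter("mock_subtraction", kept)


def filter_contaminants(
    s: InteractorSet,
    repo: ContaminantRepository,
    max_freq: float = 0.10,
) -> InteractorSet:
    """Remove proteins whose control-run detection frequency exceeds ``max_freq``.

    Proteins not listed in the repository are kept.
    """
    if not 0 <= max_freq <= 1:
        raise ValueError(f"max_freq must be in [0, 1], got {max_freq}")
    freq = repo.frequencies
    removed = {p for p in s.proteins if p in freq.index and freq[p] > max_freq}
    kept = frozenset(s.proteins - removed)
    return s.with_filter(f"contaminant_filter(max_freq={max_freq})", kept)
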