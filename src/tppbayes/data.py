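"""Domain types and I/O for protein-level thermal proteome profiling tables.

A TPP experiment measures the relative solubility of each protein at a
ladder of temperatures (typically ten, 37-67 °C in 3 °C steps) under two
conditions (vehicle/control vs. treatment), each with a small number of
replicates.  The canonical on-disk format here is a long-format delimited
table with columns ``protein_id, condition, replicate, temperature_C,
rel_solubility``; a wide-format importer covers TPP-package-style exports.

Missing cells are represented explicitly as NaN and counted; they are never
imputed.  Proteins with any missing cell are excluded from model fitting
(the exclusion is visible through :meth:`ProteinMeltingData.is_complete`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

LONG_COLUMNS = ["protein_id", "condition", "replicate", "temperature_C", "rel_solubility"]


class TPPDataError(ValueError):
    """Raised for malformed TPP input tables."""


@dataclass
class ProteinMeltingData:
    """Melting measurements for one protein.

    Parameters
    ----------
    protein_id : str
    temperatures : array of shape (D,)
        Strictly increasing temperatures in °C, D >= 4.
    conditions : (str, str)
        Ordered (control, treatment) labels.
    observations : mapping (condition, replicate) -> array of shape (D,)
        Relative solubility per temperature; NaN marks a missing cell.
    """

    protein_id: str
    temperatures: np.ndarray
    conditions: tuple[str, str]
    observations: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.temperatures.ndim != 1 or self.temperatures.size < 4:
            raise TPPDataError(f"{self.protein_id}: need >= 4 temperatures")
        if not np.all(np.isfinite(self.temperatures)):
            raise TPPDataError(f"{self.protein_id}: non-finite temperature")
        if not np.all(np.diff(self.temperatures) > 0):
            raise TPPDataError(f"{self.protein_id}: temperatures must be strictly increasing")
        if len(self.conditions) != 2:
            raise TPPDataError(f"{self.protein_id}: exactly two conditions required")
        for key, y in self.observations.items():
            y = np.asarray(y, dtype=float)
            if y.shape != self.temperatures.shape:
                raise TPPDataError(f"{self.protein_id}: observation {key} has wrong length")
            if np.any(y[np.isfinite(y)] < 0):
                raise TPPDataError(f"{self.protein_id}: negative solubility in {key}")
            self.observations[key] = y

    @property
    def n_temperatures(self) -> int:
        return int(self.temperatures.size)

    def replicates(self, condition: str) -> list[int]:
        return sorted(k for (c, k) in self.observations if c == condition)

    @property
    def n_replicates(self) -> dict[str, int]:
        return {c: len(self.replicates(c)) for c in self.conditions}

    @property
    def n_missing(self) -> int:
        return int(sum(np.sum(~np.isfinite(y)) for y in self.observations.values()))

    def is_complete(self) -> bool:
        return self.n_missing == 0 and all(v >= 1 for v in self.n_replicates.values())

    def condition_block(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (temperatures, observations) across replicates of one condition."""
        reps = self.replicates(condition)
        if not reps:
            raise TPPDataError(f"{self.protein_id}: no replicates for condition {condition!r}")
        T = np.concatenate([self.temperatures for _ in reps])
        y = np.concatenate([self.observations[(condition, k)] for k in reps])
        return T, y

    def pooled_block(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (temperatures, observations) across both conditions."""
        parts = [self.condition_block(c) for c in self.conditions]
        return (np.concatenate([p[0] for p in parts]), np.concatenate([p[1] for p in parts]))


@dataclass
class TPPDataset:
    """A collection of :class:`ProteinMeltingData` sharing one temperature grid."""

    proteins: dict[str, ProteinMeltingData]
    metadata: dict = field(default_factory=dict)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.proteins)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def conditions(self) -> tuple[str, str]:
        first = next(iter(self.proteins.values()))
        return first.conditions

    @property
    def temperatures(self) -> np.ndarray:
        first = next(iter(self.proteins.values()))
        return first.temperatures

    def complete_proteins(self) -> list[str]:
        return [pid for pid, p in self.proteins.items() if p.is_complete()]


@dataclass
class DatasetSummary:
    n_proteins: int
    n_complete_proteins: int
    temperatures: np.ndarray
    replicate_design: dict[str, int]
    n_missing_cells: int


def _read_delimited(path) -> pd.DataFrame:
    # sep=None lets pandas sniff TSV vs CSV
    return pd.read_csv(path, sep=None, engine="python")


def read_long_table(path, conditions: tuple[str, str] | None = None) -> TPPDataset:
    """Read a long-format TPP table.

    Requires columns ``protein_id, condition, replicate, temperature_C,
    rel_solubility`` and exactly two condition labels.  Rows with non-finite
    solubility are recorded as missing cells, never dropped silently.
    Duplicate (protein, condition, replicate, temperature) cells are an error.
    """
    df = _read_delimited(path)
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TPPDataError(f"missing required columns: {missing_cols}")
    labels = sorted(df["condition"].astype(str).unique())
    if len(labels) > 2:
        raise TPPDataError(f"more than two conditions: {labels}")
    if len(labels) < 2:
        raise TPPDataError(f"need two conditions, found {labels}")
    if conditions is None:
        conditions = (labels[0], labels[1])
    temps = np.asarray(df["temperature_C"], dtype=float)
    if not np.all(np.isfinite(temps)):
        raise TPPDataError("non-numeric or non-finite temperature_C values")
    dup = df.duplicated(subset=["protein_id", "condition", "replicate", "temperature_C"])
    if dup.any():
        rows = df.loc[dup, ["protein_id", "condition", "replicate", "temperature_C"]].head(3)
        raise TPPDataError(f"duplicate measurement cells, e.g.\n{rows}")

    grid = np.array(sorted(df["temperature_C"].unique()), dtype=float)
    t_index = {t: j for j, t in enumerate(grid)}
    proteins: dict[str, ProteinMeltingData] = {}
    for pid, sub in df.groupby("protein_id", sort=True):
        obs: dict[tuple[str, int], np.ndarray] = {}
        for (cond, rep), cell in sub.groupby(["condition", "replicate"]):
            y = np.full(grid.size, np.nan)
            idx = [t_index[t] for t in cell["temperature_C"]]
            y[idx] = np.asarray(cell["rel_solubility"], dtype=float)
            obs[(str(cond), int(rep))] = y
        proteins[str(pid)] = ProteinMeltingData(str(pid), grid, conditions, obs)
    return TPPDataset(proteins=proteins)


def read_wide_table(path, temperature_map: Mapping[str, float],
                    conditions: tuple[str, str] | None = None) -> TPPDataset:
    """Read a wide-format table (one row per protein x condition x replicate).

    ``temperature_map`` assigns each abundance column a temperature in °C.
    Any column that is neither an id column nor mapped is an error.  If the
    map lists temperatures out of order, the dataset reports the sorted grid
    with observations permuted accordingly.
    """
    df = _read_delimited(path)
    id_cols = {"protein_id", "condition", "replicate"}
    missing_cols = id_cols - set(df.columns)
    if missing_cols:
        raise TPPDataError(f"missing required columns: {sorted(missing_cols)}")
    abundance_cols = [c for c in df.columns if c not in id_cols]
    unmapped = [c for c in abundance_cols if c not in temperature_map]
    if unmapped:
        raise TPPDataError(f"abundance columns not in temperature_map: {unmapped}")
    long = df.melt(id_vars=sorted(id_cols), value_vars=abundance_cols,
                   var_name="_col", value_name="rel_solubility")
    long["temperature_C"] = long["_col"].map(dict(temperature_map))
    long = long.drop(columns="_col")[LONG_COLUMNS]
    buf = io.StringIO()
    long.to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return read_long_table(buf, conditions=conditions)


def to_long_frame(ds: TPPDataset) -> pd.DataFrame:
    """Long-format DataFrame of a dataset (inverse of :func:`read_long_table`)."""
    rows = []
    for pid, prot in ds.proteins.items():
        for (cond, rep), y in sorted(prot.observations.items()):
            for T, v in zip(prot.temperatures, y):
                rows.append((pid, cond, rep, T, v))
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def write_long_table(ds: TPPDataset, path, sep: str = "\t") -> None:
    to_long_frame(ds).to_csv(path, sep=sep, index=False)


def summarize_dataset(ds: TPPDataset) -> DatasetSummary:
    if ds.n_proteins == 0:
        return DatasetSummary(0, 0, np.array([]), {}, 0)
    design: dict[str, int] = {}
    for prot in ds.proteins.values():
        for c, n in prot.n_replicates.items():
            design[c] = max(design.get(c, 0), n)
    return DatasetSummary(
        n_proteins=ds.n_proteins,
        n_complete_proteins=len(ds.complete_proteins()),
        temperatures=ds.temperatures,
        replicate_design=design,
        n_missing_cells=sum(p.n_missing for p in ds.proteins.values()),
    )


RESULT_COLUMNS = [
    "protein_id",
    "nparc_F", "nparc_p", "nparc_p_adj",
    "logml_M0_sigmoid", "logml_M1_sigmoid", "log_bf10_sigmoid", "posterior_prob_M1_sigmoid",
    "logml_M0_semiparametric", "logml_M1_semiparametric", "log_bf10_semiparametric",
    "posterior_prob_M1_semiparametric",
    "hit_sigmoid", "hit_semiparametric",
    "r2_sigmoid", "r2_semiparametric", "delta_r2", "non_sigmoid_flag",
    "elpd_loo_sigmoid", "elpd_loo_se_sigmoid", "loo_n_high_k_sigmoid",
    "elpd_loo_semiparametric", "elpd_loo_se_semiparametric",
    "loo_n_high_k_semiparametric", "ppc_coverage_50", "ppc_coverage_95",
    "sampler_flagged", "sampler_notes",
]


def write_results(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a results table with floats at 6 significant digits."""
    df.to_csv(path, sep=sep, index=False, float_format="%.6g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")
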