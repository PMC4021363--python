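"""Typed participant tables and delimited-text I/O.

Two table kinds flow through the pipeline: food-group intakes in grams/day
(optionally with a total-energy column in kJ/day) and risk-factor response
panels. Both are complete-case by contract: any missing cell is rejected at
read time with its location, mirroring the exclusion of participants with
incomplete data rather than imputing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Column name reserved for total energy intake (kJ/day) in intake tables.
ENERGY_COLUMN = "energy_kj"


class TableError(ValueError):
    """Raised when a participant table violates its contract."""


@dataclass
class IntakeTable:
    """Participants x food groups, in g/day, for one measurement wave.

    ``foods`` is indexed by participant id; ``energy`` (kJ/day), if present,
    is aligned on the same index.
    """

    foods: pd.DataFrame
    wave: str = "wave"
    energy: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        _check_complete(self.foods, "intake")
        if self.foods.shape[1] < 2:
            raise TableError("an intake table needs at least 2 food columns")
        if (self.foods.to_numpy() < 0).any():
            bad = self.foods.columns[(self.foods < 0).any()].tolist()
            raise TableError(f"negative intakes in columns {bad}")
        if self.energy is not None:
            self.energy = self.energy.reindex(self.foods.index)
            if self.energy.isna().any():
                raise TableError("energy column does not cover all participants")
            if (self.energy <= 0).any():
                raise TableError("energy must be strictly positive (kJ/day)")

    @property
    def participants(self) -> pd.Index:
        return self.foods.index

    @property
    def food_names(self) -> list[str]:
        return list(self.foods.columns)

    def to_frame(self) -> pd.DataFrame:
        df = self.foods.copy()
        if self.energy is not None:
            df[ENERGY_COLUMN] = self.energy
        return df


@dataclass
class ResponsePanel:
    """Participants x risk-factor responses for one wave.

    The canonical response set is BMI (kg/m^2), systolic/diastolic blood
    pressure (mmHg), total and HDL cholesterol (mmol/l) and uric acid
    (mmol/l), but arbitrary numeric response sets are accepted.
    """

    values: pd.DataFrame
    wave: str = "wave"

    def __post_init__(self) -> None:
        _check_complete(self.values, "response")

    @property
    def participants(self) -> pd.Index:
        return self.values.index

    @property
    def response_names(self) -> list[str]:
        return list(self.values.columns)


def _check_complete(df: pd.DataFrame, kind: str) -> None:
    """Reject duplicate ids, missing cells and non-numeric columns."""
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise TableError(f"duplicate participant ids in {kind} table: {dups}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()].tolist()
            raise TableError(
                f"non-numeric cells in {kind} column {col!r} at rows {bad[:5]}"
            )
    if df.isna().any().any():
        cells = [
            (str(idx), str(col))
            for col in df.columns
            for idx in df.index[df[col].isna()]
        ]
        raise TableError(
            f"{len(cells)} missing cell(s) in {kind} table "
            f"(complete-case required); first offenders: {cells[:5]}"
        )


def read_table(
    path: str | Path, kind: str, wave: str | None = None
) -> IntakeTable | ResponsePanel:
    """Read a delimited participant table.

    Parameters
    ----------
    path:
        CSV file with a header row; first column is the participant id.
    kind:
        ``"intake"`` or ``"response"``.
    wave:
        Wave label; defaults to the file stem.
    """
    if kind not in ("intake", "response"):
        raise ValueError(f"kind must be 'intake' or 'response', got {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    label = wave if wave is not None else path.stem
    if kind == "intake":
        energy = None
        if ENERGY_COLUMN in df.columns:
            energy = df[ENERGY_COLUMN]
            df = df.drop(columns=[ENERGY_COLUMN])
        return IntakeTable(foods=df, wave=label, energy=energy)
    return ResponsePanel(values=df, wave=label)


def write_table(table: IntakeTable | ResponsePanel, path: str | Path) -> Path:
    """Write a table back to CSV (RFC 4180, '.' decimal separator)."""
    path = Path(path)
    df = table.to_frame() if isinstance(table, IntakeTable) else table.values
    df.to_csv(path, index_label="participant_id")
    return path


def align_waves(
    intake: IntakeTable, responses: ResponsePanel
) -> tuple[IntakeTable, ResponsePanel]:
    """Check 1:1 participant alignment between an intake table and a panel."""
    if not intake.participants.equals(responses.participants):
        if set(intake.participants) == set(responses.participants):
            responses = ResponsePanel(
                values=responses.values.reindex(intake.participants),
                wave=responses.wave,
            )
        else:
            only_i = set(intake.participants) - set(responses.participants)
            only_r = set(responses.participants) - set(intake.participants)
            raise TableError(
                f"participant mismatch between intake and response tables "
                f"(intake-only: {sorted(only_i)[:5]}, response-only: {sorted(only_r)[:5]})"
            )
    return intake, responses
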