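"""Data model and I/O for multi-wave disaster-recovery panels.

Panels are wide, one row per subject, with per-wave measures in columns
named ``<var>_t<k>`` (e.g. ``distress_t1``) and time-invariant covariates in
plain columns (``gender``, ``time_since``). Missing cells are empty fields
in CSV and NaN in memory. Scale variables carry declared ranges and
validation rejects (rather than coerces) out-of-range values.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_RANGES",
    "PanelDataset",
    "VariableRoles",
    "PanelSummary",
    "read_panel",
    "write_panel",
    "summarize_panel",
    "PanelSchemaError",
    "PanelIntegrityError",
    "PanelRangeError",
]

#: declared ranges for the standard study variables (item-mean scales,
#: counts and demographics); time_since is unbounded above.
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "distress": (0.0, 4.0),
    "cse": (1.0, 7.0),
    "loss": (0.0, 4.0),
    "pd": (0.0, 5.0),
    "exposure": (0.0, 11.0),
    "gender": (0.0, 1.0),
    "time_since": (0.0, math.inf),
}

_WAVE_RE = re.compile(r"^(?P<var>.+)_(?P<wave>t\d+)$")


class PanelSchemaError(ValueError):
    """A required column or role variable is absent."""


class PanelIntegrityError(ValueError):
    """Duplicate subject identifiers or malformed wave structure."""


class PanelRangeError(ValueError):
    """A cell value lies outside its declared scale range."""


@dataclass(frozen=True)
class VariableRoles:
    """Assignment of panel variables to cusp roles for one contrast.

    ``state`` is the repeatedly measured outcome, ``bifurcation`` the column
    multiplied into the z term, ``asymmetry`` the ordered covariate columns,
    and ``wave_pair`` the (earlier, later) wave labels of the contrast.
    """

    state: str
    bifurcation: str
    asymmetry: Tuple[str, ...]
    wave_pair: Tuple[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "asymmetry", tuple(self.asymmetry))
        object.__setattr__(self, "wave_pair", tuple(self.wave_pair))
        if self.state == self.bifurcation:
            raise PanelSchemaError("state and bifurcation roles must differ")
        if self.state in self.asymmetry:
            raise PanelSchemaError("state cannot also be an asymmetry variable")
        if len(self.wave_pair) != 2 or self.wave_pair[0] == self.wave_pair[1]:
            raise PanelSchemaError("wave_pair must name two distinct waves")


def _wave_suffix(wave_label: str) -> str:
    return wave_label.lower()


@dataclass
class PanelDataset:
    """Wide multi-wave panel with per-cell missingness (NaN).

    ``data`` is indexed by unique ``subject_id``; ``wave_labels`` is the
    ordered wave sequence (e.g. ``("T1", "T2", "T3")``); ``ranges`` maps base
    variable names to inclusive bounds used for validation.
    """

    data: pd.DataFrame
    wave_labels: Tuple[str, ...]
    ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        self.wave_labels = tuple(self.wave_labels)
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def column(self, var: str, wave: str | None = None) -> str:
        """Column name for ``var`` at ``wave`` (or a time-invariant column)."""
        name = f"{var}_{_wave_suffix(wave)}" if wave is not None else var
        if name not in self.data.columns:
            raise PanelSchemaError(f"panel has no column {name!r}")
        return name

    def base_variable(self, column: str) -> str:
        m = _WAVE_RE.match(column)
        return m.group("var") if m else column

    def copy(self) -> "PanelDataset":
        return PanelDataset(self.data.copy(), self.wave_labels, dict(self.ranges))

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise PanelIntegrityError(f"duplicate subject_id values: {dupes}")
        if len(self.wave_labels) != len(set(self.wave_labels)):
            raise PanelIntegrityError("wave labels must be unique and ordered")
        for col in self.data.columns:
            base = self.base_variable(col)
            if base not in self.ranges:
                continue
            lo, hi = self.ranges[base]
            vals = pd.to_numeric(self.data[col], errors="coerce")
            bad = self.data[col].notna() & ((vals < lo) | (vals > hi) | vals.isna())
            if bad.any():
                offender = self.data.loc[bad, col].iloc[0]
                raise PanelRangeError(
                    f"column {col!r}: value {offender!r} outside declared "
                    f"range [{lo}, {hi}]"
                )

    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing) aligned with ``data``."""
        return self.data.isna()


def read_panel(
    path: str | Path | io.TextIOBase,
    ranges: Mapping[str, Tuple[float, float]] | None = None,
    required: Sequence[str] = (),
) -> PanelDataset:
    """Read a wide panel CSV (header row, empty string = missing).

    The file must carry a ``subject_id`` column; wave structure is inferred
    from the ``<var>_t<k>`` column pattern. ``required`` lists columns that
    must be present (schema error otherwise); out-of-range cells raise.
    """
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise PanelSchemaError("panel CSV must have a subject_id column")
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise PanelSchemaError(f"missing mandatory columns: {missing_cols}")
    df = df.set_index("subject_id")
    waves = sorted(
        {m.group("wave") for c in df.columns if (m := _WAVE_RE.match(c))},
        key=lambda w: int(w[1:]),
    )
    wave_labels = tuple(w.upper() for w in waves)
    return PanelDataset(df, wave_labels, dict(ranges or DEFAULT_RANGES))


def write_panel(panel: PanelDataset, path: str | Path | io.TextIOBase) -> None:
    """Write a panel to CSV (UTF-8, comma, empty cells for missing values)."""
    panel.data.to_csv(path, na_rep="", index_label="subject_id")


@dataclass
class PanelSummary:
    """Descriptive summary: per-variable mean/SD and pairwise Pearson r."""

    mean: pd.Series
    sd: pd.Series
    corr: pd.DataFrame
    n_pairs: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Correlation matrix with Mean and SD appended as trailing rows."""
        out = self.corr.copy()
        out.loc["Mean"] = self.mean
        out.loc["SD"] = self.sd
        return out


def summarize_panel(
    panel: PanelDataset, columns: Sequence[str] | None = None
) -> PanelSummary:
    """Means, sample SDs (n-1) and pairwise-complete Pearson correlations.

    Constant columns yield undefined (NaN) correlations; correlation cells
    with fewer than two complete pairs are NaN as well.
    """
    df = panel.data[list(columns)] if columns is not None else panel.data
    num = df.apply(pd.to_numeric, errors="coerce")
    mean = num.mean()
    sd = num.std(ddof=1)
    corr = num.corr(method="pearson", min_periods=2)
    notna = num.notna().astype(int)
    n_pairs = notna.T @ notna
    return PanelSummary(mean=mean, sd=sd, corr=corr, n_pairs=n_pairs)
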