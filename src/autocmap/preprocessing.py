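"""Complement-coded min-max preprocessing of marker panels.

A raw subject x marker table of flow-cytometry percentages is turned into
the dataset the Auto Contractive Map consumes: every marker is min-max
scaled to [0, 1] over the cohort and paired with its complement (1 - x),
so each variable occupies two map positions — one attracted by its *high*
values, one by its *low* values.  The clinical phenotype label is appended
as a set of binary indicator variables, one per group, so that phenotypes
enter the network as nodes alongside the markers.

With the default 11-marker panel and five phenotype groups this yields
27 variables: 22 complement-coded marker variables plus 5 indicators.

Printed two-decimal values are reproduced by *truncation* (floor), not
rounding: the full-precision scaled value of 25 on [0.1, 60] is 0.41569…,
which truncates to the conventional display 0.41.  Internal computation
always keeps full precision; :func:`display_value` exists only to render
numbers at display precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The 11-marker immunophenotype panel (percent of gated cells): Th17-axis
#: transcription factors and cytokines on CD4 T cells, IL-6 on monocytes
#: (CD14) and B cells (CD19), and TGF-beta on B cells.
MARKERS: tuple[str, ...] = (
    "CD4+RORC/γτ+",
    "CD4+IL17A+",
    "CD4+IL22+",
    "CD4+TBET+",
    "CD4+IL9+",
    "CD4+GATA+",
    "CD4+IL13+",
    "CD4+IL25+",
    "CD14+IL6+",
    "CD19+IL-6+",
    "CD19+TGFβ",
)

#: Clinical groups: relapsing-remitting, benign, secondary progressive and
#: primary progressive multiple sclerosis, plus healthy controls.
PHENOTYPES: tuple[str, ...] = ("RR", "BB", "SP", "PP", "HC")

ID_COLUMN = "subject_id"
PHENOTYPE_COLUMN = "phenotype"


class RangeError(ValueError):
    """A value fell outside the range its transformation requires."""


class DegenerateVariableError(ValueError):
    """A variable is constant over the cohort, so min-max scaling is undefined."""


def scale_minmax(x: float, lo: float, hi: float, name: str | None = None) -> float:
    """Min-max scale ``x`` from the observed range ``[lo, hi]`` to [0, 1].

    ``hi`` maps to 1, ``lo`` maps to 0, everything in between linearly.
    Full precision is kept; use :func:`display_value` for two-decimal output.
    """
    label = name or "value"
    if not (hi > lo):
        raise DegenerateVariableError(
            f"cannot scale {label!r}: observed min {lo} is not below observed max {hi}"
        )
    if not (lo <= x <= hi):
        raise RangeError(f"{label!r}: value {x} outside observed range [{lo}, {hi}]")
    return (x - lo) / (hi - lo)


def unscale_minmax(x: float, lo: float, hi: float) -> float:
    """Inverse of :func:`scale_minmax`: map a scaled value back to raw units."""
    return lo + x * (hi - lo)


def complement(x: float) -> float:
    """Return ``1 - x`` for a scaled value, exactly.

    The complement is the "low" pole of a complement-coded variable: where
    the scaled variable is attracted by high raw values, the complement is
    attracted by low ones.
    """
    if not (0.0 <= x <= 1.0):
        raise RangeError(f"complement requires a value in [0, 1], got {x}")
    return 1.0 - x


def display_value(x: float) -> str:
    """Render a scaled value at two decimals by truncation (floor).

    Truncation, not rounding: 0.41569… displays as ``"0.41"``.  Decimal
    arithmetic on the shortest float repr avoids binary-representation
    artifacts (e.g. 0.29 never displaying as "0.28").
    """
    if not (0.0 <= x <= 1.0):
        raise RangeError(f"display_value requires a value in [0, 1], got {x}")
    quantized = Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_DOWN)
    return f"{quantized:.2f}"


def encode_phenotype(
    label: str, groups: Sequence[str] = PHENOTYPES
) -> np.ndarray:
    """One-hot encode a phenotype label over the ordered group set."""
    if label not in groups:
        raise ValueError(
            f"unknown phenotype {label!r}; accepted labels: {', '.join(groups)}"
        )
    vec = np.zeros(len(groups))
    vec[list(groups).index(label)] = 1.0
    return vec


@dataclass(frozen=True)
class VariableSpec:
    """One column of the scaled dataset: its name, scaling bounds and polarity.

    ``polarity`` is ``"high"`` for a scaled marker, ``"low"`` for its
    complement, ``"indicator"`` for a phenotype dummy.  ``observed_min`` and
    ``observed_max`` are the bounds used for scaling (for indicators, 0/1).
    """

    name: str
    observed_min: float
    observed_max: float
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in ("high", "low", "indicator"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        if self.polarity == "indicator":
            if (self.observed_min, self.observed_max) != (0.0, 1.0):
                raise ValueError("indicator variables must have bounds [0, 1]")
        elif not (self.observed_min < self.observed_max):
            raise DegenerateVariableError(
                f"variable {self.name!r}: observed_min must be < observed_max"
            )


@dataclass
class ScaledDataset:
    """Records x variables matrix in [0, 1], ready for AutoCM training.

    ``records`` has one row per subject and one column per
    :class:`VariableSpec` in ``variables`` (high/low marker pairs first,
    phenotype indicators last).  ``provenance`` maps each derived variable
    to its source column and transformation.
    """

    records: np.ndarray
    variables: list[VariableSpec]
    subject_ids: list[str]
    phenotypes: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def n_records(self) -> int:
        return self.records.shape[0]

    @property
    def polarities(self) -> dict[str, str]:
        return {v.name: v.polarity for v in self.variables}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.records, columns=self.variable_names)
        frame.insert(0, PHENOTYPE_COLUMN, self.phenotypes)
        frame.insert(0, ID_COLUMN, self.subject_ids)
        return frame


def _validate_marker_table(
    table: pd.DataFrame,
    markers: Sequence[str],
    groups: Sequence[str],
) -> None:
    for column in (ID_COLUMN, PHENOTYPE_COLUMN):
        if column not in table.columns:
            raise ValueError(f"input table is missing required column {column!r}")
    missing = [m for m in markers if m not in table.columns]
    if missing:
        raise ValueError(
            "input table is missing marker column(s): " + ", ".join(repr(m) for m in missing)
        )
    if len(table) < 2:
        raise ValueError("need at least 2 subjects to establish observed ranges")
    bad_labels = sorted(set(table[PHENOTYPE_COLUMN]) - set(groups))
    if bad_labels:
        raise ValueError(
            f"unknown phenotype label(s) {bad_labels}; accepted labels: {', '.join(groups)}"
        )
    marker_block = table[list(markers)]
    if marker_block.isna().any().any():
        na_cols = [c for c in markers if marker_block[c].isna().any()]
        raise ValueError(
            "missing marker values are not accepted (no imputation); "
            "affected column(s): " + ", ".join(repr(c) for c in na_cols)
        )
    negative = [c for c in markers if (marker_block[c] < 0).any()]
    if negative:
        raise ValueError(
            "marker percentages must be non-negative; offending column(s): "
            + ", ".join(repr(c) for c in negative)
        )


def assemble_dataset(
    table: pd.DataFrame,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    markers: Sequence[str] = MARKERS,
    groups: Sequence[str] = PHENOTYPES,
) -> ScaledDataset:
    """Build the complement-coded scaled dataset from a raw marker table.

    For each marker column, the observed cohort min/max (or an explicit
    override from ``bounds``) defines the scaling range; the column is
    emitted twice, as ``high <name>`` (scaled) and ``low <name>``
    (complement).  Phenotype indicators are appended last.  Per record,
    every high/low pair sums to 1 by construction.

    Parameters
    ----------
    table
        Columns ``subject_id``, ``phenotype``, then the marker columns.
    bounds
        Optional per-marker ``(lo, hi)`` scaling overrides, for reusing a
        trained preprocessing on a new cohort.
    """
    _validate_marker_table(table, markers, groups)
    bounds = dict(bounds or {})

    columns: list[np.ndarray] = []
    variables: list[VariableSpec] = []
    provenance: dict[str, dict] = {}

    for marker in markers:
        raw = table[marker].to_numpy(dtype=float)
        lo, hi = bounds.get(marker, (float(raw.min()), float(raw.max())))
        if not (lo < hi):
            raise DegenerateVariableError(
                f"marker column {marker!r} is degenerate (min == max == {lo}); "
                "cannot min-max scale a constant variable"
            )
        scaled = np.array([scale_minmax(x, lo, hi, name=marker) for x in raw])
        high_name, low_name = f"high {marker}", f"low {marker}"
        columns.append(scaled)
        columns.append(1.0 - scaled)
        variables.append(VariableSpec(high_name, lo, hi, "high"))
        variables.append(VariableSpec(low_name, lo, hi, "low"))
        provenance[high_name] = {
            "source": marker,
            "transform": "minmax",
            "observed_min": lo,
            "observed_max": hi,
        }
        provenance[low_name] = {
            "source": marker,
            "transform": "complement-of-minmax",
            "observed_min": lo,
            "observed_max": hi,
        }

    labels = list(table[PHENOTYPE_COLUMN])
    indicator_block = np.stack([encode_phenotype(lbl, groups) for lbl in labels])
    for k, group in enumerate(groups):
        columns.append(indicator_block[:, k])
        variables.append(VariableSpec(group, 0.0, 1.0, "indicator"))
        provenance[group] = {"source": PHENOTYPE_COLUMN, "transform": "indicator"}

    records = np.column_stack(columns)
    return ScaledDataset(
        records=records,
        variables=variables,
        subject_ids=[str(s) for s in table[ID_COLUMN]],
        phenotypes=labels,
        provenance=provenance,
    )


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a raw marker CSV (UTF-8, header row, decimal point)."""
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")


def write_scaled_dataset(
    dataset: ScaledDataset, csv_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write the scaled CSV (full precision) and the provenance JSON sidecar."""
    dataset.to_frame().to_csv(csv_path, index=False, encoding="utf-8")
    sidecar = {
        "variables": [
            {
                "name": v.name,
                "observed_min": v.observed_min,
                "observed_max": v.observed_max,
                "polarity": v.polarity,
            }
            for v in dataset.variables
        ],
        "provenance": dataset.provenance,
    }
    Path(sidecar_path).write_text(
        json.dumps(sidecar, indent=2, ensure_ascii=False), encoding="utf-8"
    )


def read_scaled_dataset(
    csv_path: str | Path, sidecar_path: str | Path
) -> ScaledDataset:
    """Load a scaled dataset written by :func:`write_scaled_dataset`.

    Values round-trip exactly: the CSV stores shortest-repr floats.
    """
    frame = pd.read_csv(csv_path, encoding="utf-8", float_precision="round_trip")
    sidecar = json.loads(Path(sidecar_path).read_text(encoding="utf-8"))
    variables = [
        VariableSpec(
            v["name"], v["observed_min"], v["observed_max"], v["polarity"]
        )
        for v in sidecar["variables"]
    ]
    names = [v.name for v in variables]
    return ScaledDataset(
        records=frame[names].to_numpy(dtype=float),
        variables=variables,
        subject_ids=[str(s) for s in frame[ID_COLUMN]],
        phenotypes=list(frame[PHENOTYPE_COLUMN]),
        provenance=sidecar["provenance"],
    )
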