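"""Synthetic MS cohort generator.

Emulates a five-group flow-cytometry study — four multiple-sclerosis
phenotypes (RR relapsing-remitting, BB benign, SP secondary progressive,
PP primary progressive) plus healthy controls (HC) — with planted
phenotype–marker effects and latent-factor correlation blocks, so that
the whole preprocessing → AutoCM → connectivity-map pipeline can be
exercised and its recovery of known structure measured.

Each marker value is a clipped Gaussian:

    x = mu(group, marker) + sd * (sign(lam) * sqrt(|lam|) * f + sqrt(1 - |lam|) * e)

where f is the subject's latent draw for the marker's correlation block
and e is independent noise (f, e ~ N(0, 1)).  ``lam`` is the block
loading, defined as the *shared-variance fraction*: the within-group
Pearson correlation between two block members equals lam, and the
marginal variance stays sd^2 regardless of block membership.  Markers
outside any block take x = mu + sd * e.  Values are clipped to
[value_floor, value_cap], mimicking the bounded, non-negative nature of
gated-percentage readouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocessing import ID_COLUMN, MARKERS, PHENOTYPE_COLUMN, PHENOTYPES


@dataclass
class CohortDesign:
    """Cohort layout and planted effect structure.

    group_sizes
        Subjects per phenotype group.
    baseline_mean, noise_sd
        Per-marker baseline mean and within-group standard deviation
        (units: percent of gated cells).
    effects
        ``{phenotype: {marker: shift}}`` additive mean shifts, in percent.
    correlation_blocks
        ``[(marker tuple, loading)]``; one latent factor per block per
        subject, loading = shared-variance fraction in [-1, 1].
    value_floor, value_cap
        Clipping bounds for generated percentages.
    """

    group_sizes: dict[str, int]
    baseline_mean: dict[str, float]
    noise_sd: dict[str, float]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    correlation_blocks: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    value_floor: float = 0.1
    value_cap: float = 60.0

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.baseline_mean)

    @property
    def total_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def group_mean(self, group: str, marker: str) -> float:
        return self.baseline_mean[marker] + self.effects.get(group, {}).get(marker, 0.0)

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("design has no groups")
        for group, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {group!r} has non-positive count {n}")
        if not (0 <= self.value_floor < self.value_cap):
            raise ValueError("need 0 <= value_floor < value_cap")
        markers = set(self.markers)
        if set(self.noise_sd) != markers:
            raise ValueError("noise_sd must cover exactly the baseline_mean markers")
        for marker, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd for {marker!r} must be >= 0")
        seen: set[str] = set()
        for block, loading in self.correlation_blocks:
            if not (-1.0 <= loading <= 1.0):
                raise ValueError(f"block loading {loading} outside [-1, 1]")
            for marker in block:
                if marker not in markers:
                    raise ValueError(f"block marker {marker!r} not in design")
                if marker in seen:
                    raise ValueError(f"marker {marker!r} appears in two blocks")
                seen.add(marker)
        for group, shifts in self.effects.items():
            if group not in self.group_sizes:
                raise ValueError(f"effect references unknown group {group!r}")
            for marker, shift in shifts.items():
                if marker not in markers:
                    raise ValueError(f"effect references unknown marker {marker!r}")
                mean = self.baseline_mean[marker] + shift
                if not (self.value_floor <= mean <= self.value_cap):
                    raise ValueError(
                        f"mean for ({group!r}, {marker!r}) = {mean} outside "
                        f"[{self.value_floor}, {self.value_cap}]"
                    )


# Default magnitudes: baselines around 10% with sd 4% sit in the low tens,
# the order of magnitude of cytokine-positive gated fractions, and planted
# shifts are 1.5 within-group sd — recoverable but not trivial.
_BASELINE = 10.0
_SD = 4.0
_SHIFT = 1.5 * _SD


def default_ms_design() -> CohortDesign:
    """The study-sized default design: 30/26/33/14/42 subjects (RR/BB/SP/PP/HC).

    Planted structure:

    * CD4+IL25+ lowered in SP, PP and HC; raised in RR.
    * CD4+RORC/γτ+ raised in SP only (HC shares the low-IL25 signature but
      lacks the inflammatory-subset association; so does PP).
    * CD4+IL13+ and CD14+IL6+ raised in BB.
    * Latent factor coupling CD4+IL25+ and CD4+IL13+ (loading 0.8) — the
      IL-25 → IL-13 induction axis.
    * Latent factor coupling CD4+IL9+ with CD4+GATA+, CD4+TBET+ and
      CD4+IL22+ (loading 0.8) with no phenotype effect anywhere in the
      block: a Th9 cluster tied to the main CD4 lineages but detached
      from the disease-course part of the map.
    """
    effects = {
        "RR": {"CD4+IL25+": +_SHIFT},
        "BB": {"CD4+IL13+": +_SHIFT, "CD14+IL6+": +_SHIFT},
        "SP": {"CD4+IL25+": -_SHIFT, "CD4+RORC/γτ+": +_SHIFT},
        "PP": {"CD4+IL25+": -_SHIFT},
        "HC": {"CD4+IL25+": -_SHIFT},
    }
    design = CohortDesign(
        group_sizes={"RR": 30, "BB": 26, "SP": 33, "PP": 14, "HC": 42},
        baseline_mean={m: _BASELINE for m in MARKERS},
        noise_sd={m: _SD for m in MARKERS},
        effects=effects,
        correlation_blocks=[
            (("CD4+IL25+", "CD4+IL13+"), 0.8),
            (("CD4+IL9+", "CD4+GATA+", "CD4+TBET+", "CD4+IL22+"), 0.8),
        ],
        value_floor=0.1,
        value_cap=60.0,
    )
    design.validate()
    return design


def generate_cohort(design: CohortDesign, seed: int) -> pd.DataFrame:
    """Draw a subject x marker table from the design; fully seed-determined.

    Returns a DataFrame with columns ``subject_id``, ``phenotype`` and the
    design's markers, in the raw-CSV dialect the preprocessing expects.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    markers = design.markers
    block_of: dict[str, tuple[int, float]] = {}
    for b, (block, loading) in enumerate(design.correlation_blocks):
        for marker in block:
            block_of[marker] = (b, loading)

    rows = []
    group_order = [g for g in PHENOTYPES if g in design.group_sizes] + [
        g for g in design.group_sizes if g not in PHENOTYPES
    ]
    for group in group_order:
        for k in range(design.group_sizes[group]):
            factors = rng.standard_normal(len(design.correlation_blocks))
            row: dict[str, object] = {
                ID_COLUMN: f"{group}-{k + 1:03d}",
                PHENOTYPE_COLUMN: group,
            }
            for marker in markers:
                mu = design.group_mean(group, marker)
                sd = design.noise_sd[marker]
                e = rng.standard_normal()
                if marker in block_of:
                    b, lam = block_of[marker]
                    shared = math.copysign(math.sqrt(abs(lam)), lam) * factors[b]
                    z = shared + math.sqrt(1.0 - abs(lam)) * e
                else:
                    z = e
                value = mu + sd * z
                row[marker] = float(
                    min(max(value, design.value_floor), design.value_cap)
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=[ID_COLUMN, PHENOTYPE_COLUMN, *markers])


def design_to_yaml(design: CohortDesign, path: str | Path) -> None:
    """Write a design as YAML (inverse of :func:`design_from_yaml`)."""
    payload = {
        "group_sizes": dict(design.group_sizes),
        "baseline_mean": dict(design.baseline_mean),
        "noise_sd": dict(design.noise_sd),
        "effects": {g: dict(s) for g, s in design.effects.items()},
        "correlation_blocks": [
            {"markers": list(block), "loading": loading}
            for block, loading in design.correlation_blocks
        ],
        "value_floor": design.value_floor,
        "value_cap": design.value_cap,
    }
    Path(path).write_text(
        yaml.safe_dump(payload, allow_unicode=True, sort_keys=False), encoding="utf-8"
    )


def design_from_yaml(path: str | Path) -> CohortDesign:
    """Load a cohort design from YAML and validate it."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    design = CohortDesign(
        group_sizes={str(g): int(n) for g, n in payload["group_sizes"].items()},
        baseline_mean={str(m): float(v) for m, v in payload["baseline_mean"].items()},
        noise_sd={str(m): float(v) for m, v in payload["noise_sd"].items()},
        effects={
            str(g): {str(m): float(v) for m, v in shifts.items()}
            for g, shifts in payload.get("effects", {}).items()
        },
        correlation_blocks=[
            (tuple(str(m) for m in blk["markers"]), float(blk["loading"]))
            for blk in payload.get("correlation_blocks", [])
        ],
        value_floor=float(payload.get("value_floor", 0.1)),
        value_cap=float(payload.get("value_cap", 60.0)),
    )
    design.validate()
    return design
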