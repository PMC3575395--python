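"""Auto Contractive Map: association learning on [0, 1] data.

The Auto Contractive Map (AutoCM) is an unsupervised three-layer network
whose trained hidden→output weight matrix admits a direct reading as a
matrix of many-to-many association strengths among the input variables.
All weights live in [0, C], where C is the *contraction constant*; signal
is progressively "contracted" by the factors (1 - v/C) and (1 - Net/C)
as weights grow toward C.

For a record ``m_s`` in [0, 1]^N:

    hidden   m_h[i] = m_s[i] * (1 - v[i] / C)
    net      Net[i] = sum_j w[i, j] * m_h[j] / C
    output   m_t[i] = m_h[i] * (1 - Net[i] / C)

    dv[i]    = (m_s[i] - m_h[i]) * (1 - v[i] / C)
    dw[i, j] = (m_h[i] - m_t[i]) * (1 - w[i, j] / C) * m_h[j]

Both delta rules are non-negative on [0, 1] inputs, so v and w grow
monotonically and the one-step maps provably keep them below C.  Training
halts when the mean absolute weight change over an epoch drops under the
tolerance.  There is no randomness anywhere: identical data and config
give bit-identical models.

After training, weights convert to distances (d = C - w_sym, strong
association = short distance) and to link strengths (ls = w_sym / C,
in [0, 1], 1 = strongest), the edge currency of the connectivity map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .preprocessing import ScaledDataset

logger = logging.getLogger(__name__)

_UPDATE_MODES = ("online", "batch")
_RECORD_ORDERS = ("as-given", "sorted-by-id")
_SYMMETRIZATIONS = ("mean", "max")
_LS_NORMALIZATIONS = ("contraction", "max-weight")


@dataclass
class AutoCMConfig:
    """Training configuration.

    C
        Contraction constant; ``None`` resolves to the number of variables
        N at training time.  C must dominate Net, which sums N terms each
        at most C * 1/C, so C = N is the natural default.
    epsilon
        Initial value for every weight.  Must be strictly positive: zero
        is a fixed point of the v update rule.
    tolerance
        Convergence threshold on the mean absolute weight change per epoch.
    update_mode
        ``"online"`` applies deltas after each record; ``"batch"`` applies
        the mean of the per-record deltas once per epoch (the mean, being a
        convex combination of one-step maps, keeps weights within [0, C]).
    record_order
        ``"as-given"`` or ``"sorted-by-id"`` (stable sort on subject id).
    symmetrization
        How the (generally asymmetric) trained w is symmetrized before the
        distance/link-strength reading: arithmetic ``"mean"`` or ``"max"``.
    ls_normalization
        ``"contraction"`` divides the symmetrized weights by C (so
        ls = 1 - d/C); ``"max-weight"`` divides by the largest off-diagonal
        symmetrized weight instead.
    """

    C: float | None = None
    epsilon: float = 0.01
    max_epochs: int = 10_000
    tolerance: float = 1e-6
    update_mode: str = "online"
    record_order: str = "as-given"
    symmetrization: str = "mean"
    ls_normalization: str = "contraction"

    def resolve(self, n_variables: int) -> "AutoCMConfig":
        """Validate and return a copy with C pinned for an N-variable dataset."""
        C = float(n_variables) if self.C is None else float(self.C)
        if C < 1:
            raise ValueError(f"contraction constant C must be >= 1, got {C}")
        if not (0 < self.epsilon < C):
            raise ValueError(f"epsilon must lie in (0, C={C}), got {self.epsilon}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.update_mode not in _UPDATE_MODES:
            raise ValueError(f"update_mode must be one of {_UPDATE_MODES}")
        if self.record_order not in _RECORD_ORDERS:
            raise ValueError(f"record_order must be one of {_RECORD_ORDERS}")
        if self.symmetrization not in _SYMMETRIZATIONS:
            raise ValueError(f"symmetrization must be one of {_SYMMETRIZATIONS}")
        if self.ls_normalization not in _LS_NORMALIZATIONS:
            raise ValueError(f"ls_normalization must be one of {_LS_NORMALIZATIONS}")
        return replace(self, C=C)


@dataclass
class AutoCMModel:
    """A trained map: input→hidden weights v, hidden→output weights w.

    ``trace`` records the mean absolute weight change per epoch, the
    quantity the convergence test watches.
    """

    v: np.ndarray
    w: np.ndarray
    C: float
    epochs_run: int
    converged: bool
    trace: list[float]
    variable_names: list[str]
    config: AutoCMConfig

    @property
    def n_variables(self) -> int:
        return self.v.shape[0]


@dataclass
class DistanceMatrix:
    """Symmetric variable x variable distances in [0, C], zero diagonal."""

    values: np.ndarray
    names: list[str]


@dataclass
class LinkStrengthMatrix:
    """Symmetric variable x variable link strengths in [0, 1]."""

    values: np.ndarray
    names: list[str]


def _check_record(record: np.ndarray, n: int) -> np.ndarray:
    record = np.asarray(record, dtype=float)
    if record.shape != (n,):
        raise ValueError(f"record has shape {record.shape}, expected ({n},)")
    return record


def forward_pass(
    record: np.ndarray, model: AutoCMModel
) -> tuple[np.ndarray, np.ndarray]:
    """Propagate one record; return the (hidden, output) activations."""
    m_s = _check_record(record, model.n_variables)
    C = model.C
    m_h = m_s * (1.0 - model.v / C)
    net = model.w @ m_h / C
    m_t = m_h * (1.0 - net / C)
    return m_h, m_t


def update_step(
    record: np.ndarray, model: AutoCMModel
) -> tuple[np.ndarray, np.ndarray]:
    """Compute (dv, dw) for one record without applying them."""
    m_s = _check_record(record, model.n_variables)
    C = model.C
    m_h, m_t = forward_pass(m_s, model)
    dv = (m_s - m_h) * (1.0 - model.v / C)
    dw = ((m_h - m_t)[:, None] * m_h[None, :]) * (1.0 - model.w / C)
    return dv, dw


def _extract(data) -> tuple[np.ndarray, list[str], list[str] | None]:
    if isinstance(data, ScaledDataset):
        return data.records, data.variable_names, data.subject_ids
    records = np.asarray(data, dtype=float)
    if records.ndim != 2:
        raise ValueError("training data must be a 2-D records x variables array")
    names = [f"var{i}" for i in range(records.shape[1])]
    return records, names, None


def train(
    data: ScaledDataset | np.ndarray,
    config: AutoCMConfig | None = None,
    epoch_callback: Callable[[int, np.ndarray, np.ndarray], None] | None = None,
) -> AutoCMModel:
    """Train an Auto Contractive Map until the weights stop moving.

    Fully deterministic: initialization is the constant ``epsilon``,
    record order is fixed by config, and there is no random component.

    Parameters
    ----------
    data
        A :class:`~autocmap.preprocessing.ScaledDataset` or a 2-D array of
        records in [0, 1].
    epoch_callback
        Optional hook called as ``callback(epoch, v, w)`` with copies of
        the weights after each epoch (used e.g. to audit the contraction
        invariant during training).
    """
    records, names, subject_ids = _extract(data)
    n_records, n_vars = records.shape
    if n_records == 0:
        raise ValueError("training data is empty")
    if np.any(records < 0) or np.any(records > 1):
        raise ValueError("training records must lie in [0, 1]")

    cfg = (config or AutoCMConfig()).resolve(n_vars)
    C = float(cfg.C)

    if cfg.record_order == "sorted-by-id" and subject_ids is not None:
        order = sorted(range(n_records), key=lambda i: subject_ids[i])
        records = records[order]

    v = np.full(n_vars, cfg.epsilon, dtype=float)
    w = np.full((n_vars, n_vars), cfg.epsilon, dtype=float)
    model = AutoCMModel(
        v=v, w=w, C=C, epochs_run=0, converged=False, trace=[],
        variable_names=names, config=cfg,
    )

    cell_count = n_records * n_vars * n_vars
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.update_mode == "online":
            abs_dw_sum = 0.0
            for r in range(n_records):
                dv, dw = update_step(records[r], model)
                v += dv
                w += dw
                abs_dw_sum += float(np.abs(dw).sum())
            epoch_change = abs_dw_sum / cell_count
        else:  # batch: mean of per-record deltas, applied once
            dv_acc = np.zeros_like(v)
            dw_acc = np.zeros_like(w)
            for r in range(n_records):
                dv, dw = update_step(records[r], model)
                dv_acc += dv
                dw_acc += dw
            v += dv_acc / n_records
            w += dw_acc / n_records
            epoch_change = float(np.abs(dw_acc).sum()) / cell_count

        model.epochs_run = epoch
        model.trace.append(epoch_change)
        if epoch_callback is not None:
            epoch_callback(epoch, v.copy(), w.copy())
        if epoch_change < cfg.tolerance:
            model.converged = True
            break

    if not model.converged:
        logger.warning(
            "AutoCM did not converge within %d epochs "
            "(last mean |dw| = %.3g, tolerance = %.3g)",
            cfg.max_epochs, model.trace[-1], cfg.tolerance,
        )
    return model


def symmetrize(w: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Symmetrize a square matrix by the arithmetic mean (or elementwise max)."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"symmetrize requires a square matrix, got shape {w.shape}")
    if mode == "mean":
        return (w + w.T) / 2.0
    if mode == "max":
        return np.maximum(w, w.T)
    raise ValueError(f"symmetrization mode must be one of {_SYMMETRIZATIONS}")


def _checked_symmetric_weights(model: AutoCMModel) -> np.ndarray:
    if np.any(model.w > model.C) or np.any(model.w < 0):
        raise RuntimeError(
            "internal consistency violated: trained weights outside [0, C]"
        )
    return symmetrize(model.w, model.config.symmetrization)


def weights_to_distances(model: AutoCMModel) -> DistanceMatrix:
    """Convert trained weights to distances: d = C - w_sym, zero diagonal.

    Strongly associated variable pairs (high weight) come out close;
    weakly associated ones far — the monotone 'translation' that lets the
    minimum spanning tree read association strength as proximity.
    """
    d = model.C - _checked_symmetric_weights(model)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, names=list(model.variable_names))


def link_strengths(model: AutoCMModel) -> LinkStrengthMatrix:
    """Link strengths ls in [0, 1]: w_sym / C (default), diagonal 1.

    Under the default normalization ls = 1 - d/C holds identically.  The
    ``"max-weight"`` alternative rescales by the largest off-diagonal
    symmetrized weight so the strongest observed link reads exactly 1.
    """
    w_sym = _checked_symmetric_weights(model)
    if model.config.ls_normalization == "max-weight":
        off = w_sym[~np.eye(model.n_variables, dtype=bool)]
        denom = float(off.max()) if off.size and off.max() > 0 else model.C
    else:
        denom = model.C
    ls = w_sym / denom
    np.fill_diagonal(ls, 1.0)
    ls = np.clip(ls, 0.0, 1.0)
    return LinkStrengthMatrix(values=ls, names=list(model.variable_names))


def save_model(model: AutoCMModel, path: str | Path) -> None:
    """Serialize a model to JSON.  Floats round-trip exactly (shortest repr)."""
    payload = {
        "config": asdict(model.config),
        "C": model.C,
        "v": model.v.tolist(),
        "w": model.w.tolist(),
        "epochs_run": model.epochs_run,
        "converged": model.converged,
        "trace": model.trace,
        "variable_names": model.variable_names,
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False), encoding="utf-8"
    )


def load_model(path: str | Path) -> AutoCMModel:
    """Load a model written by :func:`save_model`; exact round-trip."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return AutoCMModel(
        v=np.array(payload["v"], dtype=float),
        w=np.array(payload["w"], dtype=float),
        C=float(payload["C"]),
        epochs_run=int(payload["epochs_run"]),
        converged=bool(payload["converged"]),
        trace=[float(t) for t in payload["trace"]],
        variable_names=list(payload["variable_names"]),
        config=AutoCMConfig(**payload["config"]),
    )
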