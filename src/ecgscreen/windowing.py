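"""Past/future time-window feature assembly and window-size grid search.

A classifier deciding whether minute ``t`` contains apnea may look at the
feature vectors of minutes ``t-past .. t+future`` concatenated in temporal
order.  ``(0, 0)`` is the windowless baseline.  The grid search scores every
``(past, future)`` pair by grouped cross-validated per-segment accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

__all__ = [
    "WindowSpec",
    "WindowedMatrix",
    "assemble_windowed_features",
    "grid_search_windows",
    "full_grid",
]


@dataclass(frozen=True, order=True)
class WindowSpec:
    """Minutes of past and future context; (0, 0) is the non-time window."""

    past: int = 0
    future: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.past <= 15 and 0 <= self.future <= 15):
            raise ValueError(f"window sizes must lie in [0, 15], got {self!r}")

    @property
    def width(self) -> int:
        return self.past + self.future + 1


@dataclass
class WindowedMatrix:
    """Design matrix with one row per target minute.

    Row layout: base feature vectors for minutes ``t-past .. t+future``
    concatenated left-to-right, so every row has
    ``len(FEATURE_NAMES) * (past + future + 1)`` values.  ``groups`` carries
    the record id of every row so grouped CV can keep recordings intact.
    """

    spec: WindowSpec
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    minute_index: np.ndarray = field(repr=False)
    feature_names: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        expected = len(FEATURE_NAMES) * self.spec.width
        if self.X.shape[1] != expected:
            raise ValueError(
                f"row length {self.X.shape[1]} != {expected} for window {self.spec}"
            )

    def subset(self, record_ids: Iterable[str]) -> "WindowedMatrix":
        wanted = set(record_ids)
        mask = np.array([g in wanted for g in self.groups])
        return WindowedMatrix(
            self.spec,
            self.X[mask],
            self.y[mask],
            self.groups[mask],
            self.minute_index[mask],
            self.feature_names,
        )


def _window_feature_names(spec: WindowSpec) -> list[str]:
    names = []
    for off in range(-spec.past, spec.future + 1):
        tag = f"t{off:+d}" if off else "t"
        names.extend(f"{n}@{tag}" for n in FEATURE_NAMES)
    return names


def assemble_windowed_features(
    per_record_features: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    spec: WindowSpec = WindowSpec(0, 0),
    edge_policy: str = "replicate",
) -> WindowedMatrix:
    """Concatenate each minute's context block into one design-matrix row.

    ``per_record_features`` maps record ids to per-segment feature tables (as
    produced by :func:`ecgscreen.features.extract_recording_features`, already
    normalized).  Rows never mix features across recordings; out-of-range
    context minutes are filled per ``edge_policy``:

    - ``"replicate"`` (default): repeat the nearest existing minute's vector,
      keeping every annotated minute classifiable (the AHI denominator needs
      all of them);
    - ``"zero"``: fill with zeros (the post-normalization mean);
    - ``"drop"``: discard target minutes whose window leaves the recording.
    """
    if edge_policy not in ("replicate", "zero", "drop"):
        raise ValueError(f"unknown edge policy {edge_policy!r}")
    if not isinstance(per_record_features, Mapping):
        per_record_features = {
            str(df["record_id"].iloc[0]): df for df in per_record_features
        }
    xs, ys, gs, ms = [], [], [], []
    for record_id, df in per_record_features.items():
        minutes = df["minute_index"].to_numpy()
        if not np.all(np.diff(minutes) > 0):
            raise ValueError(f"record {record_id}: minutes must be strictly increasing")
        base = df[FEATURE_NAMES].to_numpy(dtype=float)
        n = base.shape[0]
        offsets = np.arange(-spec.past, spec.future + 1)
        idx = np.arange(n)[:, None] + offsets[None, :]
        if edge_policy == "drop":
            keep = (idx[:, 0] >= 0) & (idx[:, -1] < n)
            idx = idx[keep]
            targets = np.arange(n)[keep]
        else:
            targets = np.arange(n)
            if edge_policy == "replicate":
                idx = np.clip(idx, 0, n - 1)
        if edge_policy == "zero":
            padded = np.vstack([base, np.zeros((1, base.shape[1]))])
            idx = np.where((idx < 0) | (idx >= n), n, idx)
            rows = padded[idx].reshape(len(targets), -1)
        else:
            rows = base[idx].reshape(len(targets), -1)
        xs.append(rows)
        ys.append(df["label"].to_numpy(dtype=bool)[targets])
        gs.append(np.full(len(targets), record_id, dtype=object))
        ms.append(minutes[targets])
    if not xs:
        raise ValueError("no recordings supplied")
    return WindowedMatrix(
        spec=spec,
        X=np.vstack(xs),
        y=np.concatenate(ys),
        groups=np.concatenate(gs),
        minute_index=np.concatenate(ms),
        feature_names=_window_feature_names(spec),
    )


def full_grid(max_past: int = 15, max_future: int = 15) -> list[WindowSpec]:
    """The default (past, future) search grid, 0..max inclusive on both axes."""
    return [
        WindowSpec(p, f)
        for p in range(max_past + 1)
        for f in range(max_future + 1)
    ]


def _tie_break_key(item: tuple[WindowSpec, float]) -> tuple[float, int, int]:
    spec, acc = item
    # maximize accuracy; ties prefer the smallest total context, then the
    # smallest future extent (the cheapest window to realize online)
    return (-acc, spec.past + spec.future, spec.future)


def grid_search_windows(
    per_record_features: Mapping[str, pd.DataFrame],
    classifier_config,
    grid: Iterable[WindowSpec],
    cv_spec,
    evaluator: Callable[[WindowSpec], float] | None = None,
) -> tuple[pd.DataFrame, WindowSpec]:
    """Mean grouped-CV accuracy for every window in ``grid`` plus the argmax.

    ``evaluator`` overrides the scoring function (used for testing the
    selection logic in isolation); the default runs the full cross-validated
    pipeline via :func:`ecgscreen.evaluation.cross_validate_window`.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty window grid")
    if evaluator is None:
        from .evaluation import cross_validate_window

        def evaluator(spec: WindowSpec) -> float:
            return cross_validate_window(
                per_record_features, classifier_config, spec, cv_spec
            )

    surface = {spec: float(evaluator(spec)) for spec in grid}
    best = min(surface.items(), key=_tie_break_key)[0]
    table = pd.DataFrame(
        [(s.past, s.future, a) for s, a in surface.items()],
        columns=["past", "future", "mean_accuracy"],
    ).sort_values(["past", "future"], ignore_index=True)
    return table, best
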