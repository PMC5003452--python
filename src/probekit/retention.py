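"""Retention curves: how many probe pairs and probe-sets survive a cut-off.

A probe pair is retained at threshold ``x`` when its PM intensity is
strictly greater than ``x``; a probe-set is retained while at least one of
its pairs is.  Sweeping ``x`` over a grid traces a vector-valued curve
``x -> (retained_pairs, retained_sets)`` whose knee marks the transition
from conserved, well-hybridising probes to cross-species background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from probekit.affyio import ChipLayout, ProbeMatrix
from probekit.errors import FormatError, ProbekitError

__all__ = [
    "RetentionCurve",
    "default_thresholds",
    "pseudo_min_array",
    "compute_retention",
    "retention_to_flags",
]


def default_thresholds() -> np.ndarray:
    """Cut-off grid 0..1000 with an increment of 1."""
    return np.arange(0, 1001, dtype=float)


@dataclass
class RetentionCurve:
    thresholds: np.ndarray
    retained_pairs: np.ndarray
    retained_sets: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.retained_pairs = np.asarray(self.retained_pairs, dtype=int)
        self.retained_sets = np.asarray(self.retained_sets, dtype=int)
        n = self.thresholds.size
        if self.retained_pairs.size != n or self.retained_sets.size != n:
            raise ProbekitError("curve component lengths differ")
        if n > 1 and np.any(np.diff(self.thresholds) <= 0):
            raise ProbekitError("thresholds must be strictly ascending")
        if np.any(np.diff(self.retained_pairs) > 0) or np.any(
            np.diff(self.retained_sets) > 0
        ):
            raise ProbekitError("retention counts must be non-increasing")
        if np.any(self.retained_pairs < self.retained_sets):
            raise ProbekitError("pairs retained cannot be fewer than sets")

    def __len__(self) -> int:
        return self.thresholds.size

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold\tretained_pairs\tretained_sets\n")
            for x, y1, y2 in zip(
                self.thresholds, self.retained_pairs, self.retained_sets
            ):
                fh.write(f"{float(x)!r}\t{int(y1)}\t{int(y2)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RetentionCurve":
        xs, y1s, y2s = [], [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["threshold", "retained_pairs", "retained_sets"]:
                raise FormatError(f"{path}: unexpected curve header {header}")
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: short row")
                xs.append(float(parts[0]))
                y1s.append(int(parts[1]))
                y2s.append(int(parts[2]))
        return cls(np.asarray(xs), np.asarray(y1s), np.asarray(y2s))


def pseudo_min_array(matrix: ProbeMatrix) -> np.ndarray:
    """Elementwise minimum across chips (the multi-chip mask signal)."""
    if matrix.n_chips < 1:
        raise ProbekitError("pseudo_min_array needs at least one chip")
    return matrix.values.min(axis=1)


def _check_alignment(signal: np.ndarray, layout: ChipLayout) -> np.ndarray:
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (layout.n_pairs,):
        raise ProbekitError(
            f"signal has {signal.shape} values; layout has {layout.n_pairs} "
            "PM probes (canonical order required)"
        )
    return signal


def compute_retention(
    signal: np.ndarray,
    layout: ChipLayout,
    thresholds: np.ndarray | None = None,
) -> RetentionCurve:
    """Count probe pairs and probe-sets surviving each threshold.

    ``signal`` must follow the layout's canonical PM order.  A set survives
    while its maximum PM intensity exceeds the threshold, which is exactly
    the ">= 1 retained pair" rule.
    """
    signal = _check_alignment(signal, layout)
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)

    sorted_signal = np.sort(signal)
    retained_pairs = signal.size - np.searchsorted(
        sorted_signal, thresholds, side="right"
    )

    set_sizes = np.array([len(ps) for ps in layout.probe_sets])
    ends = np.cumsum(set_sizes)
    starts = ends - set_sizes
    set_max = np.maximum.reduceat(signal, starts)
    sorted_max = np.sort(set_max)
    retained_sets = set_max.size - np.searchsorted(
        sorted_max, thresholds, side="right"
    )
    return RetentionCurve(thresholds, retained_pairs, retained_sets)


def retention_to_flags(
    signal: np.ndarray, layout: ChipLayout, x: float
) -> np.ndarray:
    """Per-pair retention flags at cut-off ``x`` (PM intensity > x)."""
    signal = _check_alignment(signal, layout)
    return signal > x
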