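"""Synthetic chip layouts, four-chip gDNA designs and fixture files.

The intensity model is a two-component lognormal mixture: a fraction of
probes hybridise well (conserved targets) while the rest only see
cross-species background, which produces the plateau-then-drop retention
curve the threshold mapper expects.  Planted SFP probes multiply one
parental chip's intensity by a fold factor and propagate the same direction
to the paired bulk chip (B1->B3, B2->B4).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from probekit.affyio import (
    ChipLayout,
    IntensityArray,
    ProbePair,
    ProbeSet,
    write_cdf_text,
    write_cel_text,
)
from probekit.errors import ProbekitError
from probekit.retention import RetentionCurve

__all__ = [
    "SimParams",
    "make_layout",
    "simulate_quad",
    "write_fixture_bundle",
    "planted_knee_curve",
]

CHIP_IDS = ("B1", "B2", "B3", "B4")


def make_layout(
    n_sets: int,
    pairs_per_set: int,
    grid_cols: int,
    grid_rows: int,
    seed: int = 0,
    chip_name: str = "SynthChip",
) -> ChipLayout:
    """Random but seed-deterministic layout with PM/MM on adjacent rows.

    Each probe pair occupies a PM cell at (x, y) and its MM partner at
    (x, y+1).  The grid must hold 2 * n_sets * pairs_per_set cells.
    """
    n_pairs = n_sets * pairs_per_set
    slot_rows = grid_rows // 2
    if n_pairs > grid_cols * slot_rows:
        raise ProbekitError(
            f"grid {grid_cols}x{grid_rows} cannot hold {n_pairs} PM/MM pairs"
        )
    rng = np.random.default_rng(seed)
    slots = rng.permutation(grid_cols * slot_rows)[:n_pairs]
    probe_sets = []
    for s in range(n_sets):
        pairs = []
        for j in range(pairs_per_set):
            slot = int(slots[s * pairs_per_set + j])
            x = slot % grid_cols
            y = 2 * (slot // grid_cols)
            pairs.append(ProbePair((x, y), (x, y + 1)))
        probe_sets.append(ProbeSet(f"set{s:05d}_at", pairs))
    return ChipLayout(chip_name, grid_rows, grid_cols, probe_sets)


@dataclass
class SimParams:
    """Knobs for the four-chip gDNA simulation (log-scale lognormals)."""

    frac_hyb: float = 0.35
    mu_bg: float = 3.5
    mu_hyb: float = 6.5
    sigma: float = 0.35  # probe-to-probe spread of the shared affinity
    sigma_chip: float = 0.10  # per-chip measurement noise
    n_sfp: int = 0
    sfp_fold: float = 4.0
    bulk_consistency: float = 1.0
    #: plant SFPs only on hybridising probes above this affinity quantile
    #: (screens require all four chips above the masking floor, so SFPs on
    #: marginal probes would be invisible by construction)
    sfp_min_quantile: float = 0.85
    seed: int = 0


def simulate_quad(
    layout: ChipLayout, params: SimParams | None = None
) -> tuple[list[IntensityArray], pd.DataFrame]:
    """Simulate the four chips B1 (P1), B2 (P2), B3 (low bulk), B4 (high bulk).

    Every PM probe has a shared affinity drawn from the background or the
    hybridising lognormal; chips add independent lognormal noise.  Planted
    SFPs raise one parent chip ``sfp_fold``-fold and, with probability
    ``bulk_consistency``, the paired bulk chip.  Returns the arrays plus a
    truth table (probe_id, chip_affected, fold, direction).
    """
    p = params or SimParams()
    rng = np.random.default_rng(p.seed)
    probe_ids = layout.pm_probe_ids()
    n = len(probe_ids)

    hyb = rng.random(n) < p.frac_hyb
    n_hyb = int(hyb.sum())
    if p.n_sfp > n_hyb:
        raise ProbekitError(
            f"cannot plant {p.n_sfp} SFPs among {n_hyb} hybridising probes"
        )
    mu = np.where(hyb, p.mu_hyb, p.mu_bg)
    base = np.exp(mu + p.sigma * rng.standard_normal(n))

    fold = np.ones((n, 4))
    truth_rows = []
    if p.n_sfp > 0:
        eligible = np.where(
            hyb & (base >= np.quantile(base[hyb], p.sfp_min_quantile))
        )[0]
        if p.n_sfp > eligible.size:
            raise ProbekitError(
                f"cannot plant {p.n_sfp} SFPs among {eligible.size} eligible "
                "strongly hybridising probes"
            )
        sfp_idx = rng.choice(eligible, size=p.n_sfp, replace=False)
        for i in sfp_idx:
            parent_up = int(rng.integers(2))  # 0 -> B1 up, 1 -> B2 up
            bulk_hit = bool(rng.random() < p.bulk_consistency)
            chips = [parent_up] if not bulk_hit else [parent_up, parent_up + 2]
            for chip in chips:
                fold[i, chip] = p.sfp_fold
            truth_rows.append(
                {
                    "probe_id": probe_ids[int(i)],
                    "chip_affected": CHIP_IDS[parent_up]
                    + ("+" + CHIP_IDS[parent_up + 2] if bulk_hit else ""),
                    "fold": p.sfp_fold,
                    "direction": "P1" if parent_up == 0 else "P2",
                }
            )
    truth = pd.DataFrame(
        truth_rows, columns=["probe_id", "chip_affected", "fold", "direction"]
    )

    # fill grids: background everywhere, then PM/MM cells
    arrays = []
    pm_xy = [pair.pm_xy for _, pair in layout.iter_pairs()]
    mm_xy = [pair.mm_xy for _, pair in layout.iter_pairs()]
    mm_base = np.exp(p.mu_bg + p.sigma * rng.standard_normal(n))
    for m, chip_id in enumerate(CHIP_IDS):
        grid = np.exp(
            p.mu_bg
            + p.sigma * rng.standard_normal((layout.n_rows, layout.n_cols))
        )
        noise = np.exp(p.sigma_chip * rng.standard_normal(n))
        pm_vals = base * fold[:, m] * noise
        mm_noise = np.exp(p.sigma_chip * rng.standard_normal(n))
        for i, (x, y) in enumerate(pm_xy):
            grid[y, x] = pm_vals[i]
        for i, xy in enumerate(mm_xy):
            if xy is not None:
                grid[xy[1], xy[0]] = mm_base[i] * mm_noise[i]
        arrays.append(
            IntensityArray(chip_id, layout.n_rows, layout.n_cols,
                           np.round(grid, 3))
        )
    return arrays, truth


def write_fixture_bundle(
    out_dir: str | Path,
    layout: ChipLayout,
    arrays: list[IntensityArray],
    truth: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write CDF + CEL v3 text files + truth TSV readable by affyio."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cdf_path = out_dir / f"{layout.chip_name}.cdf"
    write_cdf_text(layout, cdf_path)
    paths["cdf"] = cdf_path
    for arr in arrays:
        cel_path = out_dir / f"{arr.chip_id}.cel"
        write_cel_text(arr, cel_path)
        paths[arr.chip_id] = cel_path
    truth_path = out_dir / "truth.tsv"
    if truth is None:
        truth = pd.DataFrame(
            columns=["probe_id", "chip_affected", "fold", "direction"]
        )
    truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def planted_knee_curve(
    seed: int = 0,
    n_sets: int = 20000,
    pairs_per_set: int = 11,
    knee: float | None = None,
    drop_end: float | None = None,
    noise: float = 0.005,
    thresholds: np.ndarray | None = None,
) -> tuple[RetentionCurve, float]:
    """Synthetic plateau-knee-drop retention curve with a known knee.

    The retained-set count holds a plateau until ``knee`` then decays
    linearly to a small floor at ``drop_end``; small multiplicative noise is
    added and monotonicity restored.  Returns ``(curve, knee)``.
    """
    rng = np.random.default_rng(seed)
    if thresholds is None:
        thresholds = np.arange(0, 1001, dtype=float)
    x = np.asarray(thresholds, dtype=float)
    span = x[-1] - x[0]
    if knee is None:
        knee = float(x[0] + rng.uniform(0.2, 0.6) * span)
    if drop_end is None:
        drop_end = float(min(x[-1], knee + rng.uniform(0.3, 0.4) * span))
    floor = 0.02 * n_sets
    sets = np.where(
        x <= knee,
        float(n_sets),
        n_sets - (n_sets - floor) * np.clip((x - knee) / (drop_end - knee), 0, 1),
    )
    sets = sets * np.exp(noise * rng.standard_normal(x.size))
    sets = np.minimum.accumulate(np.minimum(sets, n_sets))
    sets = np.round(sets).astype(int)
    # pairs fall faster than sets: decay even across the plateau
    pairs = n_sets * pairs_per_set * np.exp(-1.5 * (x - x[0]) / span)
    pairs = np.maximum(np.round(pairs).astype(int), sets)
    pairs = np.minimum.accumulate(pairs)
    sets = np.minimum(sets, pairs)
    return RetentionCurve(x, pairs, sets), float(knee)
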