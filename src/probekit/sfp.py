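"""Probe-level single-feature polymorphism (SFP) screening.

A four-chip gDNA design: two parental genotypes (chips B1, B2) and two
phenotypically contrasted F2 bulks (chips B3, B4), paired B1~B3 and B2~B4.
Three screens are provided:

* dual fold-change (DFC): an intensity floor plus direction-consistent
  parental and bulk fold-changes;
* a between-group probe-wise one-sample t-test on the MA-value (mean log2
  within-group ratio), leave-one-out within each probe-set;
* within-group robust one-sample tests on intensity differences (D-values)
  using the gamma-trimmed mean studentized by the Winsorized standard
  deviation, with an optional small-sample scale factor.

Results feed volcano / twin-volcano filters, a four-set Euler partition and
a candidate-selection strategy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from probekit.affyio import ProbeMatrix
from probekit.errors import ProbekitError

__all__ = [
    "QuadDesign",
    "ScreenConfig",
    "symmetric_fc",
    "ma_value",
    "d_value",
    "fcd",
    "dfc_screen",
    "post_between",
    "post_within",
    "trimmed_mean",
    "winsorized_variance",
    "small_sample_scale",
    "bh_adjust",
    "volcano_filter",
    "twin_volcano_filter",
    "euler_partition",
    "candidate_strategy",
    "screen",
]

_TINY_P = 5e-324  # smallest subnormal double; flags degenerate zero-spread


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class QuadDesign:
    """Four-chip single-trait design in the order B1, B2, B3, B4."""

    pm: ProbeMatrix

    def __post_init__(self) -> None:
        if self.pm.n_chips != 4:
            raise ProbekitError(
                f"quad design needs exactly 4 chips, got {self.pm.n_chips}"
            )
        if np.any(self.pm.values <= 0):
            raise ProbekitError(
                "all intensities must be > 0 (preprocess first; ratios must "
                "be defined)"
            )

    @property
    def b(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        v = self.pm.values
        return v[:, 0], v[:, 1], v[:, 2], v[:, 3]

    def set_ids(self) -> np.ndarray:
        return np.asarray(self.pm.set_ids())


@dataclass
class ScreenConfig:
    """Cut-offs and tuning for the DFC / VP / TVP screens."""

    gamma: float = 0.1
    alpha: float = 0.05
    ma_cut: float = 0.75
    fcd_cut: float = 8.0
    fcf2_cut: float | None = 1.5
    fcp_cut: float | None = 2.0
    th: float | None = None  # gDNA intensity floor (e.g. the ATM cut-off)
    eps1: float = 2.0  # parental fold-change cut for DFC
    eps2: float = 1.5  # bulk fold-change cut for DFC
    small_sample_scale: bool = True
    # candidate-strategy tolerances
    fcp_near: float = 0.1
    th_near: float | None = None  # default: 25% of th
    fcd_near: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 0.5):
            raise ProbekitError("gamma must be in (0, 0.5)")
        for name in ("ma_cut", "fcd_cut", "eps1", "eps2"):
            if getattr(self, name) <= 0:
                raise ProbekitError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------

def symmetric_fc(q):
    """Signed fold-change: q for q >= 1, -1/q for q < 1 (symmetric about 1)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ProbekitError("intensity ratio must be positive")
    out = np.where(q >= 1.0, q, -1.0 / q)
    return float(out) if out.ndim == 0 else out


def ma_value(b1, b2, b3, b4):
    """Mean within-group log2 ratio: (log2(b1/b2) + log2(b3/b4)) / 2."""
    arrs = [np.asarray(b, dtype=float) for b in (b1, b2, b3, b4)]
    if any(np.any(a <= 0) for a in arrs):
        raise ProbekitError("MA-value requires positive intensities")
    out = 0.5 * (np.log2(arrs[0] / arrs[1]) + np.log2(arrs[2] / arrs[3]))
    return float(out) if out.ndim == 0 else out


def d_value(b1, b2, b3, b4):
    """Mean within-group intensity difference: ((b1-b2) + (b3-b4)) / 2."""
    arrs = [np.asarray(b, dtype=float) for b in (b1, b2, b3, b4)]
    out = 0.5 * ((arrs[0] - arrs[1]) + (arrs[2] - arrs[3]))
    return float(out) if out.ndim == 0 else out


def fcd(delta):
    """Signed square root of a D-value (fold-change difference)."""
    delta = np.asarray(delta, dtype=float)
    out = np.sign(delta) * np.sqrt(np.abs(delta))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# DFC
# ---------------------------------------------------------------------------

def dfc_screen(
    design: QuadDesign,
    th: float,
    eps1: float = 2.0,
    eps2: float = 1.5,
) -> np.ndarray:
    """Dual fold-change flags.

    A probe passes when all four intensities exceed ``th``, the parental
    fold-change |FC1| >= eps1, the bulk fold-change |FC2| >= eps2, and the
    two fold-changes agree in direction (the bulk acts as a cross-check on
    the parental difference).
    """
    b1, b2, b3, b4 = design.b
    fc1 = symmetric_fc(b1 / b2)
    fc2 = symmetric_fc(b3 / b4)
    above = (b1 > th) & (b2 > th) & (b3 > th) & (b4 > th)
    return (
        above
        & (np.abs(fc1) >= eps1)
        & (np.abs(fc2) >= eps2)
        & (np.sign(fc1) == np.sign(fc2))
    )


# ---------------------------------------------------------------------------
# robust primitives
# ---------------------------------------------------------------------------

def trimmed_mean(values, gamma: float) -> float:
    """Mean after dropping h = floor(gamma*n) order statistics per side."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    h = int(math.floor(gamma * n))
    if 2 * h >= n:
        raise ProbekitError(f"trim count h={h} leaves no data (n={n})")
    return float(v[h:n - h].mean())


def winsorized_variance(values, gamma: float) -> float:
    """Sample variance (n-1 denominator) after clamping h extremes per side."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    h = int(math.floor(gamma * n))
    if 2 * h >= n:
        raise ProbekitError(f"trim count h={h} leaves no data (n={n})")
    w = v.copy()
    w[:h] = v[h]
    w[n - h:] = v[n - h - 1]
    return float(w.var(ddof=1))


def small_sample_scale(n: int, h: int) -> float:
    """Scale factor a(n, h) = 1 + 16*sqrt(h)*exp(2h - n) for n < 18."""
    return 1.0 + 16.0 * math.sqrt(h) * math.exp(2 * h - n)


# ---------------------------------------------------------------------------
# POST
# ---------------------------------------------------------------------------

def _loo_t_between(ma: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out t statistics for one probe-set's MA-values."""
    n_total = ma.size
    n = n_total - 1  # sample size excluding the interrogated probe
    s_all = ma.sum()
    ss_all = (ma ** 2).sum()
    mean_rest = (s_all - ma) / n
    ss_rest = ss_all - ma ** 2
    var_rest = (ss_rest - n * mean_rest ** 2) / (n - 1)
    var_rest = np.maximum(var_rest, 0.0)
    sd_rest = np.sqrt(var_rest)
    scale = sd_rest * math.sqrt(1.0 + 1.0 / n)
    diff = ma - mean_rest
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / scale
    df = np.full(n_total, n - 1, dtype=float)
    p = np.where(
        scale > 0,
        2.0 * t_dist.sf(np.abs(np.where(scale > 0, t, 0.0)), n - 1),
        np.where(diff == 0.0, 1.0, _TINY_P),
    )
    with np.errstate(invalid="ignore"):
        t = np.where(
            scale > 0, t, np.where(diff == 0.0, 0.0, np.inf * np.sign(diff))
        )
    return t, df, p


def post_between(design: QuadDesign) -> pd.DataFrame:
    """Between-group probe-wise test on MA-values.

    For probe k of set i the remaining probes form a sample of size
    n = #set - 1; the statistic is
    ``T = (ma_k - mean_rest) / (sd_rest * sqrt(1 + 1/n))`` with n - 1
    degrees of freedom (prediction-style standardization since probe k is
    excluded from the sample).  Sets with fewer than 3 probes are skipped.
    """
    b1, b2, b3, b4 = design.b
    ma = ma_value(b1, b2, b3, b4)
    set_ids = design.set_ids()
    n_probes = ma.size
    t = np.full(n_probes, np.nan)
    df = np.full(n_probes, np.nan)
    p = np.full(n_probes, np.nan)
    reason = np.full(n_probes, "", dtype=object)
    for idx in _set_slices(set_ids):
        if idx.stop - idx.start < 3:
            reason[idx] = "set too small (need >= 3 probes)"
            continue
        t[idx], df[idx], p[idx] = _loo_t_between(ma[idx])
    return pd.DataFrame(
        {"t": t, "df": df, "p": p, "reason": reason},
        index=design.pm.probe_ids,
    )


def _loo_t_within(
    delta: np.ndarray, gamma: float, use_scale: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_total = delta.size
    n = n_total - 1
    h = int(math.floor(gamma * n))
    df_val = n - 2 * h - 1
    t = np.empty(n_total)
    p = np.empty(n_total)
    for k in range(n_total):
        rest = np.delete(delta, k)
        tm = trimmed_mean(rest, gamma)
        sd = math.sqrt(winsorized_variance(rest, gamma))
        # effective trim proportion h/n, so h = 0 gives the ordinary t
        scale = sd / ((1.0 - 2.0 * h / n) * math.sqrt(n))
        diff = delta[k] - tm
        if scale == 0.0:
            t[k] = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            p[k] = 1.0 if diff == 0.0 else _TINY_P
            continue
        stat = diff / scale
        if use_scale and n < 18:
            stat *= small_sample_scale(n, h)
        t[k] = stat
        p[k] = 2.0 * t_dist.sf(abs(stat), df_val)
    return t, np.full(n_total, float(df_val)), p


def post_within(
    design: QuadDesign,
    group: str,
    gamma: float = 0.1,
    use_small_sample_scale: bool = True,
) -> pd.DataFrame:
    """Within-group robust probe-wise test on D-values.

    For group G1 the per-probe D-value is ``b1 - b2``; for G2 it is
    ``b3 - b4``.  Probe k is compared with the gamma-trimmed mean of the
    other probes, studentized by the Winsorized standard deviation:
    ``t = (d_k - trimmed_mean) / (winsorized_sd / ((1-2h/n)*sqrt(n)))``
    with ``n - 2h - 1`` degrees of freedom and h = floor(gamma*n).  For n < 18 the statistic is
    multiplied by a(n, h) when the small-sample scale is enabled.  Probes
    whose degrees of freedom would be <= 0 are skipped.
    """
    b1, b2, b3, b4 = design.b
    if group == "G1":
        delta = b1 - b2
    elif group == "G2":
        delta = b3 - b4
    else:
        raise ProbekitError("group must be 'G1' or 'G2'")
    set_ids = design.set_ids()
    n_probes = delta.size
    t = np.full(n_probes, np.nan)
    df = np.full(n_probes, np.nan)
    p = np.full(n_probes, np.nan)
    reason = np.full(n_probes, "", dtype=object)
    for idx in _set_slices(set_ids):
        n = (idx.stop - idx.start) - 1
        h = int(math.floor(gamma * n))
        if n - 2 * h - 1 <= 0:
            reason[idx] = "degrees of freedom <= 0"
            continue
        t[idx], df[idx], p[idx] = _loo_t_within(
            delta[idx], gamma, use_small_sample_scale
        )
    return pd.DataFrame(
        {"t": t, "df": df, "p": p, "reason": reason},
        index=design.pm.probe_ids,
    )


def _set_slices(set_ids: np.ndarray):
    """Contiguous slices of equal set id (canonical probe order)."""
    boundaries = np.flatnonzero(set_ids[1:] != set_ids[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [set_ids.size]))
    for s, e in zip(starts, ends):
        yield slice(int(s), int(e))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    restored = np.empty(m)
    restored[order] = adjusted
    out[mask] = restored
    return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def volcano_filter(records: pd.DataFrame, config: ScreenConfig) -> np.ndarray:
    """Between-group volcano flags (adjusted p, |MA|, optional FCF2 and TH)."""
    flag = (records["p_between_adj"].to_numpy() < config.alpha) & (
        np.abs(records["ma"].to_numpy()) >= config.ma_cut
    )
    if config.fcf2_cut is not None:
        flag &= np.abs(records["fc2"].to_numpy()) >= config.fcf2_cut
    if config.th is not None:
        flag &= records["min_intensity"].to_numpy() > config.th
    return flag


def twin_volcano_filter(
    records: pd.DataFrame, config: ScreenConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Within-group twin-volcano flags and the group colour of each flag.

    A probe passes when either group's adjusted p-value is below alpha with
    that group's |FCD| above the cut (plus any optional FCF2 / FCP cuts).
    Returns ``(flags, groups)`` with groups in {"", "G1", "G2", "both"}.
    """
    g1 = (records["p_within_g1_adj"].to_numpy() < config.alpha) & (
        np.abs(records["fcd_g1"].to_numpy()) >= config.fcd_cut
    )
    g2 = (records["p_within_g2_adj"].to_numpy() < config.alpha) & (
        np.abs(records["fcd_g2"].to_numpy()) >= config.fcd_cut
    )
    flag = g1 | g2
    if config.fcf2_cut is not None:
        flag &= np.abs(records["fc2"].to_numpy()) >= config.fcf2_cut
    if config.fcp_cut is not None:
        flag &= np.abs(records["fc1"].to_numpy()) > config.fcp_cut
    groups = np.where(
        flag & g1 & g2, "both", np.where(flag & g1, "G1",
                                         np.where(flag & g2, "G2", ""))
    )
    return flag, groups


# ---------------------------------------------------------------------------
# Euler partition and candidate strategy
# ---------------------------------------------------------------------------

def euler_partition(
    vp4: np.ndarray, dfc2: np.ndarray, tvp2: np.ndarray, tvp4: np.ndarray
) -> np.ndarray:
    """Label each probe by its four-set Euler region.

    Region composition: VP4 = {a,b,d,e}, DFC2 = {d,e}, TVP2 = {b,c,e,f},
    TVP4 = {e,f}.  TVP4 must be a subset of TVP2 (it adds a cut to the same
    screen); combinations the diagram geometry cannot draw collapse onto
    the nearest region (DFC2 & TVP2 -> e, membership in VP4/TVP4
    notwithstanding).
    """
    vp4, dfc2, tvp2, tvp4 = (
        np.asarray(a, dtype=bool) for a in (vp4, dfc2, tvp2, tvp4)
    )
    if np.any(tvp4 & ~tvp2):
        raise ProbekitError("TVP4 must be a subset of TVP2")
    labels = np.full(vp4.shape, "none", dtype=object)
    labels[vp4 & ~dfc2 & ~tvp2] = "a"
    labels[vp4 & ~dfc2 & tvp2 & ~tvp4] = "b"
    labels[~vp4 & ~dfc2 & tvp2 & ~tvp4] = "c"
    labels[dfc2 & ~tvp2] = "d"
    labels[dfc2 & tvp2] = "e"
    labels[tvp2 & tvp4 & ~vp4 & ~dfc2] = "f"
    labels[vp4 & ~dfc2 & tvp4] = "e"  # VP4 ∩ TVP4 is only drawable inside e
    return labels


def candidate_strategy(
    records: pd.DataFrame, config: ScreenConfig
) -> np.ndarray:
    """Final candidate flags from Euler labels.

    * ``e``: keep unless |FCD| only barely exceeds its cut.
    * ``b``: keep when the parental fold-change approaches the cut and
      hybridisation is strong (all four intensities above the floor).
    * ``f``: keep when the weakest intensity is only slightly below the
      floor (poor hybridisation is discarded).
    * ``a``: keep when hybridisation is strong and the parental
      fold-change is near or above the cut.
    * ``c`` and ``d``: never kept.
    """
    labels = records["euler_label"].to_numpy()
    fc1 = np.abs(records["fc1"].to_numpy())
    fcd_abs = np.abs(records["fcd"].to_numpy())
    min_b = records["min_intensity"].to_numpy()
    th = config.th if config.th is not None else 0.0
    th_near = (
        config.th_near if config.th_near is not None else 0.25 * th
    )
    fcp_cut = config.fcp_cut if config.fcp_cut is not None else 2.0

    out = np.zeros(labels.shape, dtype=bool)
    is_e = labels == "e"
    out[is_e] = fcd_abs[is_e] - config.fcd_cut > config.fcd_near
    is_b = labels == "b"
    out[is_b] = (fc1[is_b] >= fcp_cut - config.fcp_near) & (min_b[is_b] > th)
    is_f = labels == "f"
    out[is_f] = min_b[is_f] >= th - th_near
    is_a = labels == "a"
    out[is_a] = (min_b[is_a] > th) & (fc1[is_a] >= fcp_cut - config.fcp_near)
    return out


# ---------------------------------------------------------------------------
# one-stop screen
# ---------------------------------------------------------------------------

def screen(design: QuadDesign, config: ScreenConfig | None = None) -> pd.DataFrame:
    """Run DFC + POST + filters + Euler labelling on a quad design.

    Returns one row per PM probe with ratios, fold-changes, MA/D/FCD
    values, test statistics, raw and BH-adjusted p-values (adjusted
    separately per test family), screen flags, Euler label and candidate
    flag.
    """
    cfg = config or ScreenConfig()
    b1, b2, b3, b4 = design.b
    q1 = b1 / b2
    q2 = b3 / b4
    fc1 = symmetric_fc(q1)
    fc2 = symmetric_fc(q2)
    ma = ma_value(b1, b2, b3, b4)
    d = d_value(b1, b2, b3, b4)
    d_g1 = b1 - b2
    d_g2 = b3 - b4

    between = post_between(design)
    g1 = post_within(design, "G1", cfg.gamma, cfg.small_sample_scale)
    g2 = post_within(design, "G2", cfg.gamma, cfg.small_sample_scale)

    records = pd.DataFrame(
        {
            "set_id": design.set_ids(),
            "q1": q1,
            "q2": q2,
            "fc1": fc1,
            "fc2": fc2,
            "ma": ma,
            "d": d,
            "fcd": fcd(d),
            "fcd_g1": fcd(d_g1),
            "fcd_g2": fcd(d_g2),
            "min_intensity": design.pm.values.min(axis=1),
            "t_between": between["t"].to_numpy(),
            "p_between": between["p"].to_numpy(),
            "t_within_g1": g1["t"].to_numpy(),
            "p_within_g1": g1["p"].to_numpy(),
            "t_within_g2": g2["t"].to_numpy(),
            "p_within_g2": g2["p"].to_numpy(),
        },
        index=design.pm.probe_ids,
    )
    records["p_between_adj"] = bh_adjust(records["p_between"])
    records["p_within_g1_adj"] = bh_adjust(records["p_within_g1"])
    records["p_within_g2_adj"] = bh_adjust(records["p_within_g2"])

    th = cfg.th if cfg.th is not None else 0.0
    records["dfc"] = dfc_screen(design, th, cfg.eps1, cfg.eps2)
    records["vp"] = volcano_filter(records, cfg)
    tvp_flag, tvp_group = twin_volcano_filter(records, cfg)
    records["tvp"] = tvp_flag
    records["tvp_group"] = tvp_group

    # reference sets for the Euler diagram: VP4/DFC2 use the intensity
    # floor; TVP2 omits the FCP cut that TVP4 adds.
    no_fcp = ScreenConfig(**{**cfg.__dict__, "fcp_cut": None})
    tvp2_flag, _ = twin_volcano_filter(records, no_fcp)
    records["euler_label"] = euler_partition(
        records["vp"].to_numpy(),
        records["dfc"].to_numpy(),
        tvp2_flag,
        records["tvp"].to_numpy(),
    )
    records["candidate"] = candidate_strategy(records, cfg)
    return records
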