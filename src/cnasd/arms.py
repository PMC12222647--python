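"""Per-arm CNA quantification from segment profiles.

An arm's alteration load is measured on a fixed grid: points are laid every
30 kb from the arm start, each point is classified lost / gained / neutral
from the mean log-intensity of the covering segment (uncovered points are
neutral), and the loss and gain fractions are the classified shares of all
grid points. Disjoint (nonconsecutive) altered runs all contribute. Binary
CNA calls then threshold the percent-altered value, and per-sample burden
is the number of calls.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ArmTable, IntensityCutoffs, SegmentProfile, ValidationError

logger = logging.getLogger("cnasd")

GRID_STEP = 30_000
DIRECTIONS = ("loss", "gain")


def feature_name(arm: str, direction: str) -> str:
    return f"{arm}_{direction}"


def feature_names(arms: ArmTable) -> list[str]:
    return [feature_name(a, d) for a in arms.included_arms for d in DIRECTIONS]


def percent_arm_altered(
    profile: SegmentProfile,
    arm: pd.Series,
    cutoffs: IntensityCutoffs = IntensityCutoffs(),
    grid_step: int = GRID_STEP,
) -> tuple[float, float]:
    """Loss and gain fractions of one arm for one sample.

    Grid points sit at ``arm start + k * grid_step`` for all k with
    ``point < arm end``; a point inherits the classification of the segment
    whose half-open interval contains it.
    """
    arm_start, arm_end = int(arm["start"]), int(arm["end"])
    if arm_end - arm_start < grid_step:
        raise ValidationError(
            f"arm shorter than one grid step ({arm_end - arm_start} < {grid_step})"
        )
    points = np.arange(arm_start, arm_end, grid_step, dtype=np.int64)
    segs = profile.included
    segs = segs[(segs["chrom"] == arm["chrom"])]
    if segs.empty:
        return 0.0, 0.0
    starts = segs["start"].to_numpy(np.int64)
    ends = segs["end"].to_numpy(np.int64)
    means = segs["mean"].to_numpy(float)
    order = np.argsort(starts)
    starts, ends, means = starts[order], ends[order], means[order]
    # covering segment: last start <= point, provided point < its end
    idx = np.searchsorted(starts, points, side="right") - 1
    valid = idx >= 0
    idx = np.clip(idx, 0, None)
    covered = valid & (points < ends[idx])
    vals = np.where(covered, means[idx], 0.0)
    n = len(points)
    loss = float(np.count_nonzero(covered & (vals < cutoffs.loss)) / n)
    gain = float(np.count_nonzero(covered & (vals > cutoffs.gain)) / n)
    return loss, gain


def fraction_matrix(
    profiles: Iterable[SegmentProfile],
    arms: ArmTable,
    cutoffs: IntensityCutoffs = IntensityCutoffs(),
    grid_step: int = GRID_STEP,
) -> pd.DataFrame:
    """Dense samples x (arm, direction) table of percent-altered fractions.

    Rows are ordered by sample ID, columns ``1p_loss, 1p_gain, ...`` over
    included arms; deterministic regardless of input order.
    """
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    cols = feature_names(arms)
    out = np.zeros((len(profiles), len(cols)))
    arm_frame = arms.included
    arm_points = {
        arm_name: np.arange(int(arm["start"]), int(arm["end"]), grid_step,
                            dtype=np.int64)
        for arm_name, arm in arm_frame.iterrows()
    }
    for i, prof in enumerate(profiles):
        segs = prof.included
        if len(segs) == 0:
            logger.warning("sample %s has zero segments", prof.sample_id)
            continue
        by_chrom = {
            str(chrom): (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["mean"].to_numpy(float),
            )
            for chrom, grp in segs.sort_values(["chrom", "start"]).groupby(
                "chrom"
            )
        }
        j = 0
        for arm_name, arm in arm_frame.iterrows():
            entry = by_chrom.get(str(arm["chrom"]))
            if entry is not None:
                starts, ends, means = entry
                points = arm_points[arm_name]
                idx = np.searchsorted(starts, points, side="right") - 1
                valid = idx >= 0
                idx = np.clip(idx, 0, None)
                covered = valid & (points < ends[idx])
                vals = means[idx]
                n = len(points)
                out[i, j] = np.count_nonzero(
                    covered & (vals < cutoffs.loss)
                ) / n
                out[i, j + 1] = np.count_nonzero(
                    covered & (vals > cutoffs.gain)
                ) / n
            j += 2
    return pd.DataFrame(
        out, index=pd.Index([p.sample_id for p in profiles], name="sample"),
        columns=cols,
    )


def call_matrix(
    fractions: pd.DataFrame, thresholds: int | dict[str, int] | pd.Series
) -> pd.DataFrame:
    """Binary CNA calls: present iff ``fraction * 100 >= threshold``.

    ``thresholds`` is a single integer percent applied uniformly or a
    per-feature mapping; all thresholds must lie in [1, 99].
    """
    if np.isscalar(thresholds):
        thr = pd.Series(float(thresholds), index=fractions.columns)
    else:
        thr = pd.Series(thresholds, dtype=float)
        unknown = set(thr.index) - set(fractions.columns)
        if unknown:
            raise KeyError(f"unknown feature names in thresholds: {sorted(unknown)}")
        thr = thr.reindex(fractions.columns)
        if thr.isna().any():
            raise KeyError(
                f"missing thresholds for features: "
                f"{list(thr.index[thr.isna()])}"
            )
    if ((thr < 1) | (thr > 99)).any():
        raise ValidationError("thresholds must lie in [1, 99]")
    calls = (fractions.to_numpy() * 100.0 >= thr.to_numpy()[None, :]).astype(np.int8)
    out = pd.DataFrame(calls, index=fractions.index, columns=fractions.columns)
    out.attrs["thresholds"] = thr
    return out


def cna_burden(calls: pd.DataFrame) -> pd.Series:
    """Per-sample CNA burden: the number of features called present."""
    return calls.sum(axis=1).rename("burden")


def intensity_sensitivity(
    profiles: Iterable[SegmentProfile],
    arms: ArmTable,
    time: np.ndarray,
    event: np.ndarray,
    loss_grid: Iterable[float],
    gain_grid: Iterable[float],
    horizon: float = 5.0,
    step: int = 1,
    margin: float = 0.02,
) -> pd.DataFrame:
    """Sensitivity of each feature's maximum sweep AUC to the intensity
    cutoffs.

    Recomputes fractions and the full threshold sweep for every
    (loss, gain) cutoff pair on 0.05-spaced grids bracketing the defaults
    and reports each feature's maximum AUC, flagging cutoff pairs that
    improve on the default-pair maximum by more than ``margin``.
    """
    from .sweep import sweep_all  # local import to avoid a cycle

    loss_grid = sorted(set(float(x) for x in loss_grid))
    gain_grid = sorted(set(float(x) for x in gain_grid))
    if len(loss_grid) == 1 and len(gain_grid) == 1:
        import warnings

        warnings.warn("degenerate intensity grid: a single cutoff pair",
                      stacklevel=2)
    profiles = list(profiles)
    rows = []
    baseline: dict[str, float] = {}
    defaults = IntensityCutoffs()
    pairs = [(lo, hi) for lo in loss_grid for hi in gain_grid]
    if (defaults.loss, defaults.gain) in pairs:
        pairs.remove((defaults.loss, defaults.gain))
        pairs.insert(0, (defaults.loss, defaults.gain))
    for lo, hi in pairs:
        cutoffs = IntensityCutoffs(lo, hi)
        fractions = fraction_matrix(profiles, arms, cutoffs)
        results = sweep_all(fractions, time, event, horizon=horizon, step=step)
        for res in results:
            max_auc = res.max_auc
            if (lo, hi) == (defaults.loss, defaults.gain):
                baseline[res.feature] = max_auc
            base = baseline.get(res.feature, np.nan)
            rows.append(
                {
                    "loss_cutoff": lo,
                    "gain_cutoff": hi,
                    "feature": res.feature,
                    "max_auc": max_auc,
                    "improves": bool(
                        np.isfinite(max_auc)
                        and np.isfinite(base)
                        and max_auc > base + margin
                    ),
                }
            )
    return pd.DataFrame(rows)
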