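"""Sliding-window binned CNA analysis.

Chromosome arms are tiled with 200 kb bins (the last bin of an arm may be
shorter). Each bin's intensity for one sample is the weighted mean of the
mean log-intensities of overlapping segments, each segment weighted by its
estimated probe count inside the overlap (overlap length x segment probe
density); bins with no overlapping segment are missing. Bin calls apply the
same loss/gain intensity cutoffs as arm-level calling, per-bin prognostic
value is the td-ROC AUC of the binary bin call, and focal prognostic
regions are maximal runs of contiguous defined bins whose AUC is at least
0.04 above the median of the arm's defined bin AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ArmTable, IntensityCutoffs, SegmentProfile, ValidationError
from .survival import binary_td_auc_matrix

BIN_SIZE = 200_000
FOCAL_MARGIN = 0.04


def make_bin_grid(arms: ArmTable, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Tile every included arm with ``bin_size`` windows.

    Returns a frame with columns ``chrom``, ``arm``, ``start``, ``end``
    indexed by bin name ``"<arm>:<k>"``; bins are disjoint, contiguous and
    clipped to the arm end.
    """
    rows = []
    for arm_name, arm in arms.included.iterrows():
        start, end = int(arm["start"]), int(arm["end"])
        edges = np.arange(start, end, bin_size, dtype=np.int64)
        for k, lo in enumerate(edges):
            rows.append(
                {
                    "chrom": arm["chrom"],
                    "arm": arm_name,
                    "start": int(lo),
                    "end": int(min(lo + bin_size, end)),
                    "bin": f"{arm_name}:{k}",
                }
            )
    return pd.DataFrame(rows).set_index("bin")


def bin_intensity(profile: SegmentProfile, bin_row: pd.Series) -> float:
    """Weighted mean intensity of one bin for one sample (NaN if no
    segment overlaps)."""
    segs = profile.included
    segs = segs[segs["chrom"] == bin_row["chrom"]]
    lo, hi = int(bin_row["start"]), int(bin_row["end"])
    num = 0.0
    den = 0.0
    for _, seg in segs.iterrows():
        ov = min(hi, int(seg["end"])) - max(lo, int(seg["start"]))
        if ov <= 0:
            continue
        density = seg["nprobes"] / (seg["end"] - seg["start"])
        w = ov * density
        num += w * seg["mean"]
        den += w
    return num / den if den > 0 else np.nan


def bin_intensity_matrix(
    profiles: list[SegmentProfile], grid: pd.DataFrame
) -> pd.DataFrame:
    """Samples x bins weighted mean intensities (NaN where no overlap)."""
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    bin_chrom = grid["chrom"].to_numpy()
    bin_lo = grid["start"].to_numpy(np.int64)
    bin_hi = grid["end"].to_numpy(np.int64)
    n_bins = len(grid)
    num = np.zeros((len(profiles), n_bins))
    den = np.zeros((len(profiles), n_bins))
    chrom_bins = {
        chrom: np.flatnonzero(bin_chrom == chrom) for chrom in np.unique(bin_chrom)
    }
    for i, prof in enumerate(profiles):
        segs = prof.included
        for chrom, grp in segs.groupby("chrom"):
            idx = chrom_bins.get(str(chrom))
            if idx is None:
                continue
            lo_c, hi_c = bin_lo[idx], bin_hi[idx]
            for start, end, nprobes, mean in zip(
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["nprobes"].to_numpy(float),
                grp["mean"].to_numpy(float),
            ):
                ov = np.minimum(hi_c, end) - np.maximum(lo_c, start)
                hit = ov > 0
                if not hit.any():
                    continue
                w = ov[hit] * (nprobes / (end - start))
                num[i, idx[hit]] += w * mean
                den[i, idx[hit]] += w
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(
        vals,
        index=pd.Index([p.sample_id for p in profiles], name="sample"),
        columns=grid.index,
    )


def bin_calls(
    intensities: pd.DataFrame,
    cutoffs: IntensityCutoffs = IntensityCutoffs(),
    direction: str = "loss",
) -> pd.DataFrame:
    """Binary per-bin calls from weighted intensities (missing -> no call)."""
    vals = intensities.to_numpy()
    if direction == "loss":
        calls = vals < cutoffs.loss
    elif direction == "gain":
        calls = vals > cutoffs.gain
    else:
        raise ValueError(f"unknown direction {direction!r}")
    calls = np.where(np.isnan(vals), False, calls)
    return pd.DataFrame(
        calls.astype(np.int8), index=intensities.index, columns=intensities.columns
    )


def bin_auc_profile(
    calls: pd.DataFrame, time, event, horizon: float = 5.0
) -> pd.Series:
    """Per-bin td-ROC AUC of the binary bin calls (NaN where a marker
    class is empty)."""
    aucs = binary_td_auc_matrix(
        calls.to_numpy(dtype=bool).T, time, event, horizon
    )
    return pd.Series(aucs, index=calls.columns, name="auc")


@dataclass
class FocalRegion:
    arm: str
    start_bin: str
    end_bin: str
    start: int
    end: int
    peak_auc: float
    n_bins: int


def focal_regions(
    auc_profile: pd.Series,
    grid: pd.DataFrame,
    margin: float = FOCAL_MARGIN,
) -> list[FocalRegion]:
    """Maximal runs of contiguous defined bins with AUC >= arm median +
    margin.

    The reference level is the median of each arm's defined per-bin AUCs,
    so the criterion is invariant to adding a constant to the whole
    profile. Arms with fewer than 3 defined bins are skipped.
    """
    regions: list[FocalRegion] = []
    for arm_name, arm_bins in grid.groupby("arm", sort=False):
        vals = auc_profile.reindex(arm_bins.index).to_numpy()
        defined = np.isfinite(vals)
        if defined.sum() < 3:
            continue
        med = float(np.median(vals[defined]))
        hot = defined & (vals >= med + margin)
        # maximal runs of consecutive hot bins (an undefined bin breaks a run)
        k = 0
        while k < len(hot):
            if not hot[k]:
                k += 1
                continue
            j = k
            while j + 1 < len(hot) and hot[j + 1]:
                j += 1
            block = arm_bins.iloc[k : j + 1]
            regions.append(
                FocalRegion(
                    arm=str(arm_name),
                    start_bin=block.index[0],
                    end_bin=block.index[-1],
                    start=int(block["start"].iloc[0]),
                    end=int(block["end"].iloc[-1]),
                    peak_auc=float(np.nanmax(vals[k : j + 1])),
                    n_bins=j - k + 1,
                )
            )
            k = j + 1
    return regions


def pileup(
    profiles: list[SegmentProfile],
    grid: pd.DataFrame,
    cutoffs: IntensityCutoffs = IntensityCutoffs(),
) -> pd.DataFrame:
    """Per-bin loss and gain sample proportions (missing bins count as
    unaltered)."""
    if not profiles:
        raise ValidationError("pileup requires a non-empty cohort")
    intensities = bin_intensity_matrix(profiles, grid)
    out = pd.DataFrame(index=grid.index)
    for direction in ("loss", "gain"):
        calls = bin_calls(intensities, cutoffs, direction)
        out[direction] = calls.to_numpy().mean(axis=0)
    return out


def write_bedgraph(
    track: pd.Series, grid: pd.DataFrame, path, name: str = "track"
) -> None:
    """Write a per-bin track as bedGraph (0-based half-open; NaN bins
    skipped)."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for bin_name, row in grid.iterrows():
            val = track.get(bin_name, np.nan)
            if not np.isfinite(val):
                continue
            fh.write(
                f"chr{row['chrom']}\t{row['start']}\t{row['end']}\t{val:.6g}\n"
            )


def write_bed(regions: list[FocalRegion], grid: pd.DataFrame, path) -> None:
    """Write focal regions as BED (0-based half-open)."""
    arm_chrom = grid.drop_duplicates("arm").set_index("arm")["chrom"]
    with open(path, "w") as fh:
        for reg in regions:
            chrom = arm_chrom.get(reg.arm, reg.arm)
            fh.write(
                f"chr{chrom}\t{reg.start}\t{reg.end}\t{reg.arm}"
                f"\t{reg.peak_auc:.4f}\n"
            )
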