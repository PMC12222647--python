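"""Readers and validators for segment, chromosome-arm and clinical tables.

Internal coordinates are 0-based half-open. SEG input follows the TCGA
convention (1-based, inclusive end) and is converted on read; the writer
converts back, so a read/write round trip preserves the original file's
coordinates.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cnasd")

#: p-arms of the acrocentric chromosomes, excluded from all analyses.
ACROCENTRIC_P_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})
SEX_CHROMOSOMES = frozenset({"X", "Y"})

_TCGA_COLUMNS = {
    "sample": ["ID", "Sample", "sample", "sampleID"],
    "chrom": ["chrom", "Chromosome", "chromosome", "chr"],
    "start": ["loc.start", "Start", "start"],
    "end": ["loc.end", "End", "end"],
    "nprobes": ["num.mark", "Num_Probes", "num_probes", "nprobes"],
    "mean": ["seg.mean", "Segment_Mean", "seg_mean", "mean"],
}


class FormatError(ValueError):
    """A file does not conform to the declared format."""


class ValidationError(ValueError):
    """Parsed data violate a model invariant."""


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and canonicalize sex-chromosome case."""
    s = str(label).strip()
    s = re.sub(r"^chr", "", s, flags=re.IGNORECASE)
    if s.lower() in {"x", "y"}:
        return s.upper()
    return s


@dataclass(frozen=True)
class IntensityCutoffs:
    """Segment-mean log-ratio cutoffs defining loss and gain calls.

    Defaults follow the manual-inspection values used for both
    methylation-derived and SNP-array segmentations: segments with mean
    intensity below -0.1 are lost, above 0.15 gained.
    """

    loss: float = -0.1
    gain: float = 0.15

    def __post_init__(self) -> None:
        if not (self.loss < 0.0 < self.gain):
            raise ValidationError(
                f"loss cutoff must be negative and gain cutoff positive, "
                f"got loss={self.loss}, gain={self.gain}"
            )


class ArmTable:
    """Per-arm genomic coordinates with inclusion flags.

    The underlying frame has one row per arm with columns ``chrom``, ``arm``
    (``p``/``q``), ``start``, ``end`` (0-based half-open) and ``included``;
    the index is the arm name (``"1p"``, ``"22q"`` ...). Sex chromosomes and
    acrocentric p-arms carry ``included=False``, leaving 39 usable autosomal
    arms for a standard human build.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "arm", "start", "end", "included"}
        missing = required - set(frame.columns)
        if missing:
            raise FormatError(f"arm table missing columns: {sorted(missing)}")
        bad = frame[frame["start"] >= frame["end"]]
        if len(bad):
            raise ValidationError(
                f"arm start must be < arm end; offending arms: {list(bad.index)}"
            )
        for chrom, grp in frame.groupby("chrom"):
            if {"p", "q"} <= set(grp["arm"]):
                p_end = int(grp.loc[grp["arm"] == "p", "end"].iloc[0])
                q_start = int(grp.loc[grp["arm"] == "q", "start"].iloc[0])
                if p_end > q_start:
                    raise ValidationError(
                        f"chromosome {chrom}: p-arm end {p_end} exceeds "
                        f"q-arm start {q_start}"
                    )
        self.frame = frame.copy()

    @property
    def included(self) -> pd.DataFrame:
        return self.frame[self.frame["included"]]

    @property
    def included_arms(self) -> list[str]:
        return list(self.included.index)

    def __len__(self) -> int:
        return len(self.frame)

    def arm(self, name: str) -> pd.Series:
        return self.frame.loc[name]

    @staticmethod
    def _excluded(chrom: str, arm: str) -> bool:
        return chrom in SEX_CHROMOSOMES or f"{chrom}{arm}" in ACROCENTRIC_P_ARMS

    @classmethod
    def from_records(cls, records: list[tuple[str, str, int, int]]) -> "ArmTable":
        """Build from ``(chrom, arm, start, end)`` tuples, applying the
        standard sex-chromosome and acrocentric exclusions."""
        rows = []
        for chrom, arm, start, end in records:
            chrom = normalize_chrom(chrom)
            rows.append(
                {
                    "chrom": chrom,
                    "arm": arm,
                    "start": int(start),
                    "end": int(end),
                    "included": not cls._excluded(chrom, arm),
                }
            )
        frame = pd.DataFrame(rows, index=[f"{r['chrom']}{r['arm']}" for r in rows])
        return cls(frame)


@dataclass
class SegmentProfile:
    """One sample's segmentation, sorted by (chromosome, start).

    ``segments`` has columns ``chrom``, ``start``, ``end``, ``nprobes``,
    ``mean`` and an ``excluded`` flag for rows on sex chromosomes (kept in
    the raw record but ignored by all arm-level computation).
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        self.segments = self.segments.sort_values(["chrom", "start"]).reset_index(
            drop=True
        )

    @property
    def included(self) -> pd.DataFrame:
        return self.segments[~self.segments["excluded"]]

    def __len__(self) -> int:
        return len(self.segments)

    def validated(self, arms: ArmTable) -> "SegmentProfile":
        """Return a repaired copy restricted to included arms.

        Overlapping segments within a chromosome are resolved by truncating
        the earlier segment at the later segment's start (with a warning),
        and segments straddling arm boundaries are split at them, so every
        emitted segment lies entirely within one included arm.
        """
        inc = self.included
        out_rows: list[dict] = []
        arm_frame = arms.included
        for chrom, grp in inc.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype=np.int64).copy()
            ends = grp["end"].to_numpy(dtype=np.int64).copy()
            for i in range(len(grp) - 1):
                if ends[i] > starts[i + 1]:
                    warnings.warn(
                        f"sample {self.sample_id}: overlapping segments on "
                        f"chromosome {chrom} at {starts[i + 1]}; truncating "
                        f"earlier segment",
                        stacklevel=2,
                    )
                    ends[i] = starts[i + 1]
            chrom_arms = arm_frame[arm_frame["chrom"] == str(chrom)]
            for (start, end), (_, row) in zip(
                zip(starts, ends), grp.iterrows(), strict=True
            ):
                if start >= end:
                    continue
                seg_len = end - start
                for arm_name, arm in chrom_arms.iterrows():
                    lo = max(start, int(arm["start"]))
                    hi = min(end, int(arm["end"]))
                    if lo >= hi:
                        continue
                    frac = (hi - lo) / seg_len
                    out_rows.append(
                        {
                            "chrom": str(chrom),
                            "start": lo,
                            "end": hi,
                            "nprobes": int(round(row["nprobes"] * frac)),
                            "mean": float(row["mean"]),
                            "excluded": False,
                        }
                    )
        frame = pd.DataFrame(
            out_rows,
            columns=["chrom", "start", "end", "nprobes", "mean", "excluded"],
        )
        return SegmentProfile(self.sample_id, frame)


@dataclass
class SurvivalData:
    """Per-sample time-to-event data for the two study endpoints.

    ``frame`` is indexed by sample ID with columns ``time_recurrence``,
    ``event_recurrence``, ``time_os``, ``event_os`` (times in years; NaN
    where an endpoint is unavailable) plus any extra covariate columns.
    """

    frame: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    ENDPOINTS = ("recurrence", "os")

    def endpoint(self, name: str) -> tuple[np.ndarray, np.ndarray, pd.Index]:
        """Return (time, event, sample index) for one endpoint, dropping
        samples where it is missing."""
        if name not in self.ENDPOINTS:
            raise KeyError(f"unknown endpoint {name!r}; expected {self.ENDPOINTS}")
        sub = self.frame[[f"time_{name}", f"event_{name}"]].dropna()
        return (
            sub[f"time_{name}"].to_numpy(dtype=float),
            sub[f"event_{name}"].to_numpy(dtype=int),
            sub.index,
        )

    def __len__(self) -> int:
        return len(self.frame)


def _resolve_columns(header: list[str], dialect: str) -> dict[str, str]:
    mapping = {}
    for key, candidates in _TCGA_COLUMNS.items():
        found = next((c for c in candidates if c in header), None)
        if found is None and dialect == "generic" and len(header) >= 6:
            # generic dialect: fall back on positional order
            found = header[list(_TCGA_COLUMNS).index(key)]
        if found is None:
            raise FormatError(f"SEG file is missing a column for {key!r} "
                              f"(accepted names: {candidates})")
        mapping[key] = found
    return mapping


def read_seg(path: str | Path, dialect: str = "tcga") -> list[SegmentProfile]:
    """Read a tab-delimited SEG file into one profile per sample.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Chromosome labels are accepted with or without a ``chr`` prefix. Rows on
    sex chromosomes are retained but flagged ``excluded``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = _resolve_columns(list(raw.columns), dialect)
    if raw.empty:
        logger.warning("SEG file %s contains a header only", path)
        return []
    frame = raw.rename(columns={v: k for k, v in cols.items()})[list(_TCGA_COLUMNS)]
    for col in ("start", "end"):
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise FormatError(
                f"non-numeric {col} coordinate {frame[col][bad].iloc[0]!r} "
                f"on line {line} of {path}"
            )
        frame[col] = coerced.astype(np.int64)
    frame["nprobes"] = (
        pd.to_numeric(frame["nprobes"], errors="coerce").fillna(0).astype(np.int64)
    )
    frame["mean"] = pd.to_numeric(frame["mean"], errors="coerce")
    if (frame["nprobes"] < 0).any():
        raise ValidationError("negative probe counts in SEG file")
    frame["chrom"] = frame["chrom"].map(normalize_chrom)
    # 1-based inclusive -> 0-based half-open
    frame["start"] = frame["start"] - 1
    if (frame["start"] >= frame["end"]).any():
        bad = frame[frame["start"] >= frame["end"]]
        raise ValidationError(
            f"segments with start >= end after conversion: lines "
            f"{[int(i) + 2 for i in bad.index[:5]]}"
        )
    frame["excluded"] = frame["chrom"].isin(SEX_CHROMOSOMES)
    profiles = []
    for sample_id, grp in frame.groupby("sample", sort=True):
        profiles.append(
            SegmentProfile(str(sample_id), grp.drop(columns="sample"))
        )
    return profiles


def write_seg(profiles: list[SegmentProfile], path: str | Path) -> None:
    """Write profiles as a TCGA-dialect SEG file (1-based inclusive)."""
    rows = []
    for prof in profiles:
        for _, seg in prof.segments.iterrows():
            rows.append(
                {
                    "ID": prof.sample_id,
                    "chrom": seg["chrom"],
                    "loc.start": int(seg["start"]) + 1,
                    "loc.end": int(seg["end"]),
                    "num.mark": int(seg["nprobes"]),
                    "seg.mean": f"{seg['mean']:.6f}",
                }
            )
    pd.DataFrame(
        rows, columns=["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]
    ).to_csv(path, sep="\t", index=False)


def read_arm_table(path: str | Path) -> ArmTable:
    """Derive arm coordinates from a UCSC cytoBand file (or load a
    precomputed 4-column arm table).

    For cytoBand input the p-arm spans from the chromosome start to the
    first ``acen`` band, the q-arm from the end of the last ``acen`` band to
    the chromosome end.
    """
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if frame.empty:
        raise FormatError(f"empty arm/cytoBand file: {path}")
    if frame.shape[1] >= 5:
        frame = frame.iloc[:, :5]
        frame.columns = ["chrom", "start", "end", "band", "stain"]
        frame["start"] = frame["start"].astype(np.int64)
        frame["end"] = frame["end"].astype(np.int64)
        records = []
        for chrom, grp in frame.groupby("chrom", sort=False):
            label = normalize_chrom(chrom)
            if not re.fullmatch(r"(\d+|X|Y)", label):
                continue  # skip alt/random contigs
            acen = grp[grp["stain"] == "acen"]
            if acen.empty:
                raise FormatError(
                    f"chromosome {chrom} has no acen (centromere) bands"
                )
            chrom_start = int(grp["start"].min())
            chrom_end = int(grp["end"].max())
            records.append((label, "p", chrom_start, int(acen["start"].min())))
            records.append((label, "q", int(acen["end"].max()), chrom_end))
        return ArmTable.from_records(records)
    if frame.shape[1] == 4:
        records = [
            (row[0], row[1], int(row[2]), int(row[3]))
            for row in frame.itertuples(index=False)
        ]
        return ArmTable.from_records(records)
    raise FormatError(
        f"expected a 5-column cytoBand or 4-column arm table, "
        f"got {frame.shape[1]} columns"
    )


_TRUTHY = {"1", "1.0", "true", "yes", "t"}
_FALSY = {"0", "0.0", "false", "no", "f"}


def _coerce_event(values: pd.Series, col: str) -> pd.Series:
    out = []
    for v in values:
        if pd.isna(v):
            out.append(np.nan)
            continue
        s = str(v).strip().lower()
        if s in _TRUTHY:
            out.append(1.0)
        elif s in _FALSY:
            out.append(0.0)
        else:
            raise ValidationError(
                f"event column {col!r} contains value {v!r} outside {{0,1}}"
            )
    return pd.Series(out, index=values.index)


def read_clinical(
    path: str | Path,
    column_map: dict | None = None,
    time_scale: float = 1.0,
) -> SurvivalData:
    """Read a delimited clinical table into :class:`SurvivalData`.

    ``column_map`` maps the standard keys (``sample``, ``time_recurrence``,
    ``event_recurrence``, ``time_os``, ``event_os``, optional
    ``covariates`` list, optional ``time_scale``) to the file's column
    names, e.g. ``{"time_recurrence": "PFS.time", "time_scale": 365.25}``
    for TCGA-CDR naming with times recorded in days. ``time_scale`` divides
    the raw times to yield years.
    """
    column_map = dict(column_map or {})
    time_scale = float(column_map.pop("time_scale", time_scale))
    covariates = list(column_map.pop("covariates", []))
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)

    def col(key: str, default: str) -> str | None:
        name = column_map.get(key, default)
        return name if name in raw.columns else None

    sample_col = col("sample", "sample")
    if sample_col is None:
        raise FormatError("clinical table has no sample ID column")
    frame = pd.DataFrame(index=pd.Index(raw[sample_col].astype(str), name="sample"))
    if not frame.index.is_unique:
        raise ValidationError("duplicate sample IDs in clinical table")
    for endpoint in SurvivalData.ENDPOINTS:
        tcol = col(f"time_{endpoint}", f"time_{endpoint}")
        ecol = col(f"event_{endpoint}", f"event_{endpoint}")
        if tcol is None or ecol is None:
            frame[f"time_{endpoint}"] = np.nan
            frame[f"event_{endpoint}"] = np.nan
            continue
        times = pd.to_numeric(raw[tcol], errors="coerce") / time_scale
        nonpos = times <= 0
        if nonpos.any():
            ids = list(raw.loc[nonpos.fillna(False), sample_col])
            raise ValidationError(
                f"non-positive {endpoint} times for samples {ids}"
            )
        frame[f"time_{endpoint}"] = times.to_numpy()
        frame[f"event_{endpoint}"] = _coerce_event(raw[ecol], ecol).to_numpy()
    has_any = frame[["time_recurrence", "time_os"]].notna().any(axis=1) & (
        frame[["event_recurrence", "event_os"]].notna().any(axis=1)
    )
    if (~has_any).any():
        logger.warning(
            "dropping %d samples missing both endpoints", int((~has_any).sum())
        )
        frame = frame[has_any]
    for cov in covariates:
        if cov not in raw.columns:
            raise FormatError(f"covariate column {cov!r} not in clinical table")
        frame[cov] = pd.to_numeric(
            raw.set_index(raw[sample_col].astype(str))[cov], errors="coerce"
        ).reindex(frame.index).to_numpy()
    return SurvivalData(frame, covariates)
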