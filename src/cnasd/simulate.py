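"""Synthetic cohort generator with planted prognostic CNA effects.

Emits per-sample segment lists (SEG), a two-endpoint clinical table and a
ground-truth ledger, so every pipeline stage can be exercised without
external data. Each sample's genome is built arm by arm: with a
per-(arm, direction) probability an alteration is drawn from a size
mixture — broad events covering a Beta-distributed fraction of the arm
anchored at the telomeric end, or focal events 0.2-5 Mb wide at a uniform
position — and unaltered spans are filled with neutral segments. Segment
intensities are Gaussian around the loss / gain / neutral levels; probe
counts follow a fixed density. Survival times for both endpoints come from
a Weibull proportional-hazards model whose linear predictor sums the
planted arm-level size-dependent effects (active iff the true altered
fraction reaches the activation fraction), focal-locus effects, pair
interaction effects and burden terms, with independent uniform censoring.

Default effect sizes and noise levels are chosen for testability
(detectable at a few hundred samples), not to mimic any particular cohort;
the configuration object is the single source of truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ArmTable, SegmentProfile, SurvivalData, ValidationError, write_seg

# Approximate hg38 arm boundaries (Mb, rounded); adequate for simulation
# and for exercising genome-scale coordinates, not for annotation.
_HG38_ARMS_MB = {
    "1": (0, 121.7, 125.1, 249.0), "2": (0, 91.8, 96.0, 242.2),
    "3": (0, 87.8, 94.0, 198.3), "4": (0, 48.2, 51.8, 190.2),
    "5": (0, 46.1, 50.1, 181.5), "6": (0, 58.5, 59.9, 170.8),
    "7": (0, 58.1, 60.9, 159.3), "8": (0, 43.2, 45.9, 145.1),
    "9": (0, 42.2, 45.5, 138.4), "10": (0, 38.0, 41.6, 133.8),
    "11": (0, 51.0, 54.4, 135.1), "12": (0, 34.8, 37.2, 133.3),
    "13": (0, 16.0, 18.0, 114.4), "14": (0, 16.0, 18.2, 107.0),
    "15": (0, 17.0, 19.7, 102.0), "16": (0, 36.3, 38.3, 90.3),
    "17": (0, 22.7, 27.4, 83.3), "18": (0, 15.4, 21.1, 80.4),
    "19": (0, 24.5, 27.2, 58.6), "20": (0, 26.4, 30.0, 64.4),
    "21": (0, 10.9, 13.0, 46.7), "22": (0, 13.7, 17.4, 50.8),
    "X": (0, 58.6, 62.4, 156.0), "Y": (0, 10.3, 10.6, 57.2),
}
_MB = 1_000_000


def hg38_arm_table() -> ArmTable:
    """Approximate hg38-like arm table (39 included autosomal arms)."""
    records = []
    for chrom, (start, cen_lo, cen_hi, end) in _HG38_ARMS_MB.items():
        records.append((chrom, "p", int(start * _MB), int(cen_lo * _MB)))
        records.append((chrom, "q", int(cen_hi * _MB), int(end * _MB)))
    return ArmTable.from_records(records)


def toy_arm_table(n_chrom: int = 4, p_len: int = 30 * _MB,
                  q_len: int = 60 * _MB, gap: int = 3 * _MB) -> ArmTable:
    """Small arm table for fast tests: ``n_chrom`` chromosomes, fixed arm
    lengths, 3 Mb centromere gap."""
    records = []
    for c in range(1, n_chrom + 1):
        records.append((str(c), "p", 0, p_len))
        records.append((str(c), "q", p_len + gap, p_len + gap + q_len))
    return ArmTable.from_records(records)


@dataclass
class ArmEffect:
    """Arm-level size-dependent effect: active iff the true altered
    fraction of the arm reaches ``activation``."""

    feature: str  # e.g. "1p_loss"
    log_hr: float
    activation: float = 0.25
    endpoints: tuple[str, ...] = ("recurrence", "os")


@dataclass
class FocalEffect:
    """Focal prognostic deletion planted at a fixed locus with the given
    prevalence."""

    arm: str
    position: int
    width: int
    log_hr: float
    prevalence: float
    direction: str = "loss"
    endpoints: tuple[str, ...] = ("recurrence", "os")


@dataclass
class PairEffect:
    """Extra hazard when both member arm effects are simultaneously
    active."""

    feature_a: str
    feature_b: str
    log_hr: float
    endpoints: tuple[str, ...] = ("recurrence", "os")


@dataclass
class BurdenEffect:
    """Burden terms: a linear coefficient per altered feature and/or a
    hazard step once burden reaches ``threshold``."""

    coef: float = 0.0
    threshold: int | None = None
    step_log_hr: float = 0.0
    endpoints: tuple[str, ...] = ("recurrence", "os")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort. ``seed`` is mandatory."""

    seed: int
    n_samples: int = 400
    arm_table: str = "hg38"  # "hg38", "toy", or an ArmTable instance
    alteration_prob: float | dict = 0.10
    p_broad: float = 0.5
    broad_beta: tuple[float, float] = (1.0, 2.0)
    focal_size_range: tuple[int, int] = (200_000, 5_000_000)
    loss_mean: float = -0.45
    gain_mean: float = 0.30
    alt_sd: float = 0.10
    neutral_mean: float = 0.0
    neutral_sd: float = 0.05
    probes_per_10kb: float = 3.0
    arm_effects: list[ArmEffect] = field(default_factory=list)
    focal_effects: list[FocalEffect] = field(default_factory=list)
    pair_effects: list[PairEffect] = field(default_factory=list)
    burden: BurdenEffect = field(default_factory=BurdenEffect)
    default_activation: float = 0.25
    weibull_shape: dict = field(
        default_factory=lambda: {"recurrence": 1.2, "os": 1.2}
    )
    weibull_scale: dict = field(
        default_factory=lambda: {"recurrence": 12.0, "os": 18.0}
    )
    censor_max: float = 12.0

    def arms(self) -> ArmTable:
        if isinstance(self.arm_table, ArmTable):
            return self.arm_table
        if self.arm_table == "hg38":
            return hg38_arm_table()
        if self.arm_table == "toy":
            return toy_arm_table()
        raise ValidationError(f"unknown arm table {self.arm_table!r}")

    def prob(self, feature: str) -> float:
        if isinstance(self.alteration_prob, dict):
            return float(self.alteration_prob.get(
                feature, self.alteration_prob.get("default", 0.0)
            ))
        return float(self.alteration_prob)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, typ in (
            ("arm_effects", ArmEffect),
            ("focal_effects", FocalEffect),
            ("pair_effects", PairEffect),
        ):
            d[key] = [
                typ(**{**e, "endpoints": tuple(e.get("endpoints",
                                                     ("recurrence", "os")))})
                for e in d.get(key, [])
            ]
        if "burden" in d and isinstance(d["burden"], dict):
            b = dict(d["burden"])
            b["endpoints"] = tuple(b.get("endpoints", ("recurrence", "os")))
            d["burden"] = BurdenEffect(**b)
        for key in ("broad_beta", "focal_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _validate_config(config: SimConfig, arms: ArmTable) -> None:
    if config.n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    probs = (
        list(config.alteration_prob.values())
        if isinstance(config.alteration_prob, dict)
        else [config.alteration_prob]
    )
    probs += [config.p_broad] + [f.prevalence for f in config.focal_effects]
    if any(not (0 <= p <= 1) for p in probs):
        raise ValidationError("all probabilities must lie in [0, 1]")
    included = set(arms.included_arms)
    for eff in config.focal_effects:
        if eff.arm not in included:
            raise ValidationError(f"focal effect on excluded/unknown arm "
                                  f"{eff.arm!r}")
        arm = arms.arm(eff.arm)
        if eff.width >= arm["end"] - arm["start"]:
            raise ValidationError(
                f"focal width {eff.width} not smaller than arm {eff.arm}"
            )
        if not (arm["start"] <= eff.position
                and eff.position + eff.width <= arm["end"]):
            raise ValidationError(
                f"focal locus outside arm {eff.arm}: "
                f"[{eff.position}, {eff.position + eff.width})"
            )
        if eff.prevalence * config.n_samples < 1:
            raise ValidationError(
                f"planted prevalence {eff.prevalence} unachievable at "
                f"n={config.n_samples}"
            )
    features = {
        f"{a}_{d}" for a in included for d in ("loss", "gain")
    }
    for eff in config.arm_effects:
        if eff.feature not in features:
            raise ValidationError(f"unknown planted feature {eff.feature!r}")
    for eff in config.pair_effects:
        for f in (eff.feature_a, eff.feature_b):
            if f not in features:
                raise ValidationError(f"unknown pair member {f!r}")


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _subtract(intervals, blockers) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        pieces = [(s, e)]
        for bs, be in blockers:
            nxt = []
            for ps, pe in pieces:
                if be <= ps or bs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < bs:
                    nxt.append((ps, bs))
                if be < pe:
                    nxt.append((be, pe))
            pieces = nxt
        out.extend(pieces)
    return [p for p in out if p[1] > p[0]]


@dataclass
class SimulatedCohort:
    profiles: list[SegmentProfile]
    clinical: SurvivalData
    truth: dict
    arms: ArmTable
    config: SimConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seg = out / "cohort.seg"
        clin = out / "clinical.csv"
        truth = out / "truth.json"
        write_seg(self.profiles, seg)
        self.clinical.frame.to_csv(clin, index_label="sample")
        with open(truth, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=_json_default)
        return {"seg": seg, "clinical": clin, "truth": truth}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def simulate_cohort(config: SimConfig,
                    out_dir: str | Path | None = None) -> SimulatedCohort:
    """Draw one cohort; fully reproducible from ``config.seed``."""
    arms = config.arms()
    _validate_config(config, arms)
    rng = np.random.default_rng(config.seed)
    arm_frame = arms.included
    activation = {e.feature: e.activation for e in config.arm_effects}

    profiles = []
    clinical_rows = []
    truth_samples = []
    density = config.probes_per_10kb / 10_000.0
    for i in range(config.n_samples):
        sid = f"S{i:04d}"
        intervals: dict[str, dict[str, list]] = {"loss": {}, "gain": {}}
        for arm_name, arm in arm_frame.iterrows():
            a_start, a_end = int(arm["start"]), int(arm["end"])
            a_len = a_end - a_start
            for direction in ("loss", "gain"):
                if rng.random() >= config.prob(f"{arm_name}_{direction}"):
                    continue
                if rng.random() < config.p_broad:
                    frac = float(np.clip(rng.beta(*config.broad_beta),
                                         0.01, 1.0))
                    length = max(int(frac * a_len), 1)
                    if arm["arm"] == "p":  # telomere at the arm start
                        iv = (a_start, a_start + length)
                    else:
                        iv = (a_end - length, a_end)
                else:
                    lo, hi = config.focal_size_range
                    width = int(rng.uniform(lo, min(hi, a_len)))
                    pos = int(rng.uniform(a_start, a_end - width))
                    iv = (pos, pos + width)
                intervals[direction].setdefault(arm_name, []).append(iv)
        focal_flags = []
        for eff in config.focal_effects:
            hit = bool(rng.random() < eff.prevalence)
            focal_flags.append(hit)
            if hit:
                intervals[eff.direction].setdefault(eff.arm, []).append(
                    (eff.position, eff.position + eff.width)
                )
        # merge within direction; losses take precedence over gains
        for arm_name in list(intervals["loss"]):
            intervals["loss"][arm_name] = _merge(intervals["loss"][arm_name])
        for arm_name in list(intervals["gain"]):
            merged = _merge(intervals["gain"][arm_name])
            blockers = intervals["loss"].get(arm_name, [])
            intervals["gain"][arm_name] = _subtract(merged, blockers)

        seg_rows = []
        fractions = {}
        for arm_name, arm in arm_frame.iterrows():
            a_start, a_end = int(arm["start"]), int(arm["end"])
            a_len = a_end - a_start
            marks = []
            for direction, level in (("loss", config.loss_mean),
                                     ("gain", config.gain_mean)):
                ivs = intervals[direction].get(arm_name, [])
                fractions[f"{arm_name}_{direction}"] = (
                    sum(e - s for s, e in ivs) / a_len
                )
                marks.extend((s, e, level) for s, e in ivs)
            marks.sort()
            cursor = a_start
            pieces = []
            for s, e, level in marks:
                if s > cursor:
                    pieces.append((cursor, s, None))
                pieces.append((s, e, level))
                cursor = e
            if cursor < a_end:
                pieces.append((cursor, a_end, None))
            for s, e, level in pieces:
                if level is None:
                    mean = rng.normal(config.neutral_mean, config.neutral_sd)
                else:
                    mean = rng.normal(level, config.alt_sd)
                seg_rows.append(
                    {
                        "chrom": arm["chrom"],
                        "start": s,
                        "end": e,
                        "nprobes": max(1, int(round((e - s) * density))),
                        "mean": float(mean),
                        "excluded": False,
                    }
                )
        profiles.append(SegmentProfile(sid, pd.DataFrame(seg_rows)))

        active = {
            e.feature: fractions[e.feature] >= e.activation
            for e in config.arm_effects
        }
        # burden counts CNA events at the activation scale, mirroring how
        # the pipeline counts calls at size thresholds
        burden_true = sum(
            1 for v in fractions.values() if v >= config.default_activation
        )
        lp = {"recurrence": 0.0, "os": 0.0}
        for e in config.arm_effects:
            if active[e.feature]:
                for ep in e.endpoints:
                    lp[ep] += e.log_hr
        for e, hit in zip(config.focal_effects, focal_flags):
            if hit:
                for ep in e.endpoints:
                    lp[ep] += e.log_hr
        pair_active = []
        for e in config.pair_effects:
            on = all(
                fractions[f] >= activation.get(f, config.default_activation)
                for f in (e.feature_a, e.feature_b)
            )
            pair_active.append(on)
            if on:
                for ep in e.endpoints:
                    lp[ep] += e.log_hr
        for ep in config.burden.endpoints:
            lp[ep] += config.burden.coef * burden_true
            if (config.burden.threshold is not None
                    and burden_true >= config.burden.threshold):
                lp[ep] += config.burden.step_log_hr
        row = {"sample": sid}
        for ep in ("recurrence", "os"):
            shape = config.weibull_shape[ep]
            scale = config.weibull_scale[ep]
            u = rng.random()
            t_event = scale * (-np.log(u) / np.exp(lp[ep])) ** (1.0 / shape)
            c = rng.uniform(0.0, config.censor_max)
            row[f"time_{ep}"] = max(min(t_event, c), 1e-6)
            row[f"event_{ep}"] = int(t_event <= c)
        clinical_rows.append(row)
        truth_samples.append(
            {
                "sample": sid,
                "fractions": fractions,
                "active": active,
                "focal_hits": focal_flags,
                "pair_active": pair_active,
                "burden": burden_true,
                "lp": lp,
            }
        )

    clinical = SurvivalData(
        pd.DataFrame(clinical_rows).set_index("sample")
    )
    truth = {
        "config": {
            "seed": config.seed,
            "n_samples": config.n_samples,
            "arm_effects": [asdict(e) for e in config.arm_effects],
            "focal_effects": [asdict(e) for e in config.focal_effects],
            "pair_effects": [asdict(e) for e in config.pair_effects],
            "burden": asdict(config.burden),
        },
        "samples": truth_samples,
    }
    cohort = SimulatedCohort(profiles, clinical, truth, arms, config)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def expected_censoring_fraction(config: SimConfig, truth: dict,
                                endpoint: str = "recurrence") -> float:
    """Analytic expected censoring fraction under the Weibull/uniform
    model, averaged over the cohort's true linear predictors."""
    from scipy.integrate import quad

    shape = config.weibull_shape[endpoint]
    scale = config.weibull_scale[endpoint]
    cmax = config.censor_max
    lps = np.array([s["lp"][endpoint] for s in truth["samples"]])
    out = []
    for lp in np.unique(lps):
        # P(censored | lp) = (1/cmax) * int_0^cmax S(t | lp) dt
        val, _ = quad(
            lambda t: np.exp(-((t / scale) ** shape) * np.exp(lp)), 0, cmax
        )
        out.append((np.mean(lps == lp), val / cmax))
    return float(sum(w * v for w, v in out))


def truth_recovery_report(
    truth: dict,
    sweep_summary: pd.DataFrame | None = None,
    focal_auc: pd.Series | None = None,
    focal_grid: pd.DataFrame | None = None,
    selected_features: list[str] | None = None,
    endpoint: str = "recurrence",
) -> dict:
    """Score pipeline outputs against the planted ground truth.

    Reports threshold-recovery error and size-dependence sensitivity /
    false-flag rate (from the sweep summary), focal localization error
    (from the bin AUC profile) and pair-selection sensitivity (from the
    selected tuple features). Raises when every output is missing.
    """
    if sweep_summary is None and focal_auc is None and selected_features is None:
        raise ValidationError("no pipeline outputs supplied")
    report: dict = {}
    cfg = truth["config"]
    if sweep_summary is not None:
        planted = {e["feature"]: e for e in cfg["arm_effects"]}
        missing = set(planted) - set(sweep_summary.index)
        if missing:
            raise ValidationError(f"sweep summary lacks features {missing}")
        errors = {}
        for feat, eff in planted.items():
            opt = sweep_summary.loc[feat, f"opt_{endpoint}"]
            errors[feat] = (
                None if opt is None or (isinstance(opt, float) and np.isnan(opt))
                else float(opt) - 100.0 * eff["activation"]
            )
        flags = sweep_summary["size_dependent"]
        non_planted = [f for f in sweep_summary.index if f not in planted]
        report["threshold_error"] = errors
        report["size_dependence_sensitivity"] = (
            float(np.mean([bool(flags.get(f)) for f in planted]))
            if planted else None
        )
        report["false_flag_rate"] = (
            float(np.mean([bool(flags.get(f)) for f in non_planted]))
            if non_planted else None
        )
    if focal_auc is not None:
        if focal_grid is None:
            raise ValidationError("focal_grid required with focal_auc")
        errs = []
        for eff in cfg["focal_effects"]:
            arm_bins = focal_grid[focal_grid["arm"] == eff["arm"]]
            vals = focal_auc.reindex(arm_bins.index)
            if vals.notna().sum() == 0:
                errs.append(None)
                continue
            peak = vals.idxmax()
            mid = (arm_bins.loc[peak, "start"] + arm_bins.loc[peak, "end"]) / 2
            locus_mid = eff["position"] + eff["width"] / 2
            errs.append(float(abs(mid - locus_mid)))
        report["focal_localization_bp"] = errs
    if selected_features is not None:
        pairs = [
            frozenset((e["feature_a"], e["feature_b"]))
            for e in cfg["pair_effects"]
        ]
        selected = [frozenset(f.split("&")) for f in selected_features]
        if pairs:
            report["pair_selection_sensitivity"] = float(
                np.mean([p in selected for p in pairs])
            )
    return report
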