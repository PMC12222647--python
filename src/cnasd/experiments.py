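"""Planted-truth validation experiments.

Each function builds a synthetic cohort with a known planted effect, runs
the relevant pipeline stage from scratch and scores recovery. They back
both the acceptance test suite and the reproduction script, and are useful
for power analyses when adapting the pipeline to new cohorts.

Problem sizes follow the package's validation protocol: cohorts of 400-500
samples, 10-20 replicates per experiment, and a reduced 100-replicate
permutation null for the SD criterion (the full null uses 500).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arms import call_matrix, cna_burden, fraction_matrix, percent_arm_altered
from .cooccur import burden_partition, regularized_cox_cv, stratified_km, \
    tuple_features
from .focal import bin_auc_profile, bin_calls, bin_intensity_matrix, \
    focal_regions, make_bin_grid
from .io import ArmTable, IntensityCutoffs
from .simulate import ArmEffect, BurdenEffect, FocalEffect, PairEffect, \
    SimConfig, simulate_cohort
from .survival import km_survival_at, td_auc
from .sweep import SizeThresholdOptimizer, fdr_at_cutoff, \
    null_sd_distribution, sweep_feature

GRID_STEP = 30_000


def _surv(rng, lp, shape=1.2, scale=8.0, censor_max=10.0):
    lp = np.asarray(lp, dtype=float)
    t = scale * (-np.log(rng.random(len(lp))) / np.exp(lp)) ** (1.0 / shape)
    c = rng.uniform(0, censor_max, len(lp))
    return np.minimum(t, c), (t <= c).astype(int)


def arm_fraction_oracle_errors(n_profiles: int = 200, seed: int = 0) -> np.ndarray:
    """Absolute errors of the grid fraction against the exact per-base
    altered share.

    Profiles carry one randomly placed altered interval per direction on a
    3 Mb arm, so the grid error is bounded by one grid step over the arm
    length.
    """
    rng = np.random.default_rng(seed)
    arm_len = 3_000_000
    arms = ArmTable.from_records(
        [("1", "p", 0, arm_len), ("1", "q", arm_len + 500_000,
                                  3 * arm_len + 500_000)]
    )
    arm = arms.arm("1p")
    errors = []
    for _ in range(n_profiles):
        rows = []
        exact = {"loss": 0.0, "gain": 0.0}
        placed: list[tuple[int, int]] = []
        for direction, level in (("loss", -0.5), ("gain", 0.4)):
            width = int(rng.integers(40_000, 1_200_000))
            start = int(rng.integers(0, arm_len - width))
            if any(start < e and start + width > s for s, e in placed):
                continue
            placed.append((start, start + width))
            rows.append({"chrom": "1", "start": start, "end": start + width,
                         "nprobes": max(1, width // 5000), "mean": level,
                         "excluded": False})
            exact[direction] = width / arm_len
        from .io import SegmentProfile

        prof = SegmentProfile(f"p{seed}", pd.DataFrame(
            rows, columns=["chrom", "start", "end", "nprobes", "mean",
                           "excluded"]
        ))
        loss, gain = percent_arm_altered(prof, arm)
        errors.append(abs(loss - exact["loss"]))
        errors.append(abs(gain - exact["gain"]))
    return np.asarray(errors)


def td_auc_concordance_errors(n_datasets: int = 100, seed: int = 0) -> np.ndarray:
    """Per-dataset |td-AUC - empirical concordance| in the no-censoring
    limit (marker ties included)."""
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_datasets):
        n = int(rng.integers(8, 51))
        t = rng.exponential(5, n)
        t = np.where(np.abs(t - 5.0) < 1e-6, t + 0.01, t)
        e = np.ones(n, int)
        if (t <= 5).sum() == 0 or (t > 5).sum() == 0:
            continue
        m = np.round(rng.normal(size=n), 1)
        r = td_auc(m, t, e, 5.0)
        cases, ctrls = m[t <= 5], m[t > 5]
        wins = (cases[:, None] > ctrls[None, :]).sum()
        ties = (cases[:, None] == ctrls[None, :]).sum()
        conc = (wins + 0.5 * ties) / (len(cases) * len(ctrls))
        diffs.append(abs(r.auc - conc))
    return np.asarray(diffs)


def threshold_recovery_config(seed: int, n: int = 400) -> SimConfig:
    """Planted size-dependent loss: activation 25% of the arm, log HR 1.1,
    ~20% active prevalence, against a background with appreciable
    sub-activation alteration mass (without it, thresholds below the
    activation are indistinguishable and recovery is unidentifiable)."""
    return SimConfig(
        seed=seed, n_samples=n, p_broad=0.8, broad_beta=(1.0, 2.0),
        alteration_prob={"default": 0.10, "1p_loss": 0.45},
        arm_effects=[ArmEffect("1p_loss", log_hr=1.1, activation=0.25)],
    )


def threshold_recovery_experiment(reps: int = 20, seed: int = 0,
                                  n: int = 400) -> dict:
    """Optimal-threshold and size-dependence-flag recovery for the planted
    feature across replicates."""
    optima, flags = [], []
    for r in range(reps):
        cohort = simulate_cohort(threshold_recovery_config(seed + 1000 + r, n))
        frac = fraction_matrix(cohort.profiles, cohort.arms)
        t, e, _ = cohort.clinical.endpoint("recurrence")
        res = sweep_feature(frac["1p_loss"].to_numpy(), t, e,
                            feature="1p_loss")
        optima.append(res.optimal_threshold)
        flags.append(
            res.max_auc >= 0.60 and res.sd >= 0.01 and res.prevalence >= 0.025
        )
    optima = np.asarray(optima, dtype=float)
    return {
        "optima": optima,
        "recovery_rate": float(np.mean(np.abs(optima - 25) <= 10)),
        "flag_rate": float(np.mean(flags)),
        "reps": reps,
        "n": n,
    }


def fdr_calibration_experiment(seed: int = 0, n: int = 400,
                               null_reps: int = 100) -> dict:
    """Under a global null (survival independent of CNAs), the share of
    features whose AUC-curve SD reaches the 0.01 cutoff should match the
    permutation-null tail estimate."""
    cohort = simulate_cohort(SimConfig(seed=seed + 2000, n_samples=n,
                                       alteration_prob=0.15))
    frac = fraction_matrix(cohort.profiles, cohort.arms)
    rng = np.random.default_rng(seed + 2001)
    t, e = _surv(rng, np.zeros(n))
    opt = SizeThresholdOptimizer().fit(frac, {"recurrence": (t, e)})
    sds = opt.summary_["sd_recurrence"].to_numpy(dtype=float)
    sds = sds[np.isfinite(sds)]
    observed = float(np.mean(sds >= 0.01))
    nulls = null_sd_distribution(frac, t, e, mode="permute", reps=null_reps,
                                 seed=seed + 2002)
    fdr = fdr_at_cutoff(nulls, 0.01)
    mc_se = float(np.sqrt(max(fdr * (1 - fdr), 1e-6) / len(sds)))
    return {
        "observed_rate": observed,
        "fdr_estimate": float(fdr),
        "mc_se": mc_se,
        "n_features": int(len(sds)),
        "null_reps": null_reps,
        "n": n,
    }


def focal_localization_experiment(reps: int = 10, seed: int = 0,
                                  n: int = 400) -> dict:
    """Planted 400 kb prognostic deletion (HR 2.5, prevalence 15%): peak
    bin proximity and the median+0.04 focal criterion."""
    locus_start, width = 50_000_000, 400_000
    locus_mid = locus_start + width / 2
    within, criterion = [], []
    for r in range(reps):
        cfg = SimConfig(
            seed=seed + 3000 + r, n_samples=n, arm_table="toy",
            alteration_prob=0.08,
            focal_effects=[FocalEffect(arm="2q", position=locus_start,
                                       width=width, log_hr=np.log(2.5),
                                       prevalence=0.15)],
        )
        cohort = simulate_cohort(cfg)
        grid = make_bin_grid(cohort.arms)
        intens = bin_intensity_matrix(cohort.profiles, grid)
        t, e, _ = cohort.clinical.endpoint("recurrence")
        calls = bin_calls(intens, IntensityCutoffs(), "loss")
        profile = bin_auc_profile(calls, t, e)
        arm_bins = grid[grid["arm"] == "2q"]
        vals = profile.reindex(arm_bins.index)
        peak = vals.idxmax()
        mid = (arm_bins.loc[peak, "start"] + arm_bins.loc[peak, "end"]) / 2
        within.append(abs(mid - locus_mid) <= 600_000)
        regions = focal_regions(profile, grid)
        criterion.append(any(
            r2.arm == "2q" and r2.start < locus_start + width
            and r2.end > locus_start
            for r2 in regions
        ))
    return {
        "within_600kb_rate": float(np.mean(within)),
        "criterion_rate": float(np.mean(criterion)),
        "reps": reps,
        "n": n,
    }


def pair_recovery_experiment(reps: int = 20, seed: int = 0,
                             n: int = 400) -> dict:
    """Planted pair interaction (extra log HR 1.0) among noise pairs:
    selection by cross-validated lasso Cox under the 1-SE rule, and the
    'both' stratum having the worst 5-year survival."""
    selected, both_worst, n_noise = [], [], []
    for r in range(reps):
        cfg = SimConfig(
            seed=seed + 4000 + r, n_samples=n, p_broad=0.8,
            alteration_prob={"default": 0.30, "1p_loss": 0.5,
                             "22q_loss": 0.5},
            arm_effects=[ArmEffect("1p_loss", log_hr=0.3),
                         ArmEffect("22q_loss", log_hr=0.3)],
            pair_effects=[PairEffect("1p_loss", "22q_loss", log_hr=1.0)],
        )
        cohort = simulate_cohort(cfg)
        frac = fraction_matrix(cohort.profiles, cohort.arms)
        calls = call_matrix(frac, 25)
        t, e, _ = cohort.clinical.endpoint("recurrence")
        tuples = tuple_features(calls, ["1p_loss", "22q_loss"], order=2)
        n_noise.append(tuples.shape[1] - 1)
        if "1p_loss&22q_loss" not in tuples.columns:
            selected.append(False)
            both_worst.append(False)
            continue
        model = regularized_cox_cv(tuples, t, e, alphas=[1.0], folds=10,
                                   seed=seed + r)
        selected.append("1p_loss&22q_loss" in model.selected_features_)
        km = stratified_km(calls["1p_loss"].to_numpy(),
                           calls["22q_loss"].to_numpy(), t, e)
        labels = km.labels.to_numpy()
        fives = {
            lab: km_survival_at(t[labels == lab], e[labels == lab], 5.0)
            for lab in np.unique(labels)
        }
        both_worst.append(fives["both"] == min(fives.values()))
    return {
        "selection_rate": float(np.mean(selected)),
        "both_worst_rate": float(np.mean(both_worst)),
        "median_noise_pairs": float(np.median(n_noise)),
        "reps": reps,
        "n": n,
    }


def burden_partition_experiment(reps: int = 20, seed: int = 0,
                                n: int = 500) -> dict:
    """Planted burden change-point (hazard x4 at burden >= 5): root-split
    recovery; and ordered KM strata under a monotone burden-hazard model."""
    first_ok, ordered_ok, logrank_ps = [], [], []
    for r in range(reps):
        cfg = SimConfig(
            seed=seed + 5000 + r, n_samples=n, alteration_prob=0.16,
            p_broad=0.9,
            burden=BurdenEffect(threshold=5, step_log_hr=np.log(4)),
        )
        cohort = simulate_cohort(cfg)
        frac = fraction_matrix(cohort.profiles, cohort.arms)
        burden = cna_burden(call_matrix(frac, 25)).to_numpy()
        t, e, _ = cohort.clinical.endpoint("recurrence")
        part = burden_partition(burden, t, e)
        first_ok.append(part.first_split_ is not None
                        and abs(part.first_split_ - 5) <= 1)

        # monotone burden-hazard model: strata must be hazard-ordered
        cfg2 = SimConfig(
            seed=seed + 5500 + r, n_samples=n, alteration_prob=0.16,
            p_broad=0.9, burden=BurdenEffect(coef=0.25),
        )
        cohort2 = simulate_cohort(cfg2)
        frac2 = fraction_matrix(cohort2.profiles, cohort2.arms)
        burden2 = cna_burden(call_matrix(frac2, 25)).to_numpy()
        t2, e2, _ = cohort2.clinical.endpoint("recurrence")
        part2 = burden_partition(burden2, t2, e2)
        if part2.n_strata_ < 2:
            ordered_ok.append(False)
            continue
        strata = part2.predict(burden2)
        fives = [
            km_survival_at(t2[strata == s], e2[strata == s], 5.0)
            for s in range(part2.n_strata_)
        ]
        ordered_ok.append(all(a >= b for a, b in zip(fives, fives[1:])))
        logrank_ps.append(part2.km_.p_value)
    return {
        "first_split_rate": float(np.mean(first_ok)),
        "ordered_km_rate": float(np.mean(ordered_ok)),
        "max_logrank_p": float(np.max(logrank_ps)) if logrank_ps else np.nan,
        "reps": reps,
        "n": n,
    }


def end_to_end_experiment(seed: int, out_dir, n: int = 300) -> dict:
    """Full pipeline on a simulated cohort, run twice to verify
    bit-reproducibility of the manifest and stage outputs."""
    from pathlib import Path

    from .pipeline import run_all

    cfg = {
        "seed": seed,
        "simulate": {
            "seed": seed, "n_samples": n, "p_broad": 0.8,
            "alteration_prob": {"default": 0.30, "1p_loss": 0.5,
                                "22q_loss": 0.5},
            "arm_effects": [
                {"feature": "1p_loss", "log_hr": 0.8, "activation": 0.25},
                {"feature": "22q_loss", "log_hr": 0.5, "activation": 0.25},
            ],
            "pair_effects": [
                {"feature_a": "1p_loss", "feature_b": "22q_loss",
                 "log_hr": 0.7},
            ],
        },
        "sweep": {"null_reps": 20},
        "cooccur": {"alphas": [1.0], "folds": 5},
    }
    out_dir = Path(out_dir)
    m1 = run_all(cfg, out_dir / "run1")
    m2 = run_all(cfg, out_dir / "run2")
    a = (out_dir / "run1" / "manifest.json").read_text().replace(
        str(out_dir / "run1"), "OUT"
    )
    b = (out_dir / "run2" / "manifest.json").read_text().replace(
        str(out_dir / "run2"), "OUT"
    )
    same_outputs = all(
        (out_dir / "run1" / rel).read_bytes()
        == (out_dir / "run2" / rel).read_bytes()
        for rel in ("fractions/fractions.tsv", "sweep/summary.tsv",
                    "risk/scores.tsv")
    )
    return {
        "stages_completed": len(m1["stages"]),
        "reproducible": bool(a == b and same_outputs),
        "n": n,
    }
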