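"""End-to-end orchestration: validate -> fractions -> sweep -> focal ->
cooccur -> risk, driven by one YAML config, with a machine-readable run
manifest and config-hash stage caching."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arms import cna_burden, fraction_matrix
from .cooccur import burden_partition, regularized_cox_cv, tuple_features
from .focal import (
    bin_auc_profile,
    bin_calls,
    bin_intensity_matrix,
    focal_regions,
    make_bin_grid,
    pileup,
    write_bed,
    write_bedgraph,
)
from .io import (
    ArmTable,
    IntensityCutoffs,
    ValidationError,
    read_arm_table,
    read_clinical,
    read_seg,
)
from .riskscore import BoostedCoxRiskScore
from .simulate import SimConfig, hg38_arm_table, simulate_cohort, toy_arm_table
from .sweep import (
    SizeThresholdOptimizer,
    fdr_at_cutoff,
    null_sd_distribution,
)

logger = logging.getLogger("cnasd")

STAGES = ("validate", "fractions", "sweep", "focal", "cooccur", "risk")

#: Methodological decisions recorded with every run so that outputs are
#: self-describing.
DECISIONS_METADATA = {
    "td_roc_estimator": "km-cumulative-dynamic (non-nearest-neighbor), "
                        "marker ties contribute 1/2",
    "cox_ties": "efron (breslow inside coordinate-descent penalized fits)",
    "focal_reference": "median of the arm's defined per-bin AUCs",
    "fdr_construction": "null-tail proportion of permuted/bootstrapped "
                        "AUC-curve SDs (per-test false-positive rate used "
                        "as an FDR proxy)",
    "argmax_ties": "smallest threshold",
    "auc_sd": "sample SD (ddof=1) over defined thresholds, per endpoint",
    "booster": "linear steepest-ascent boosting of the Cox partial "
               "likelihood; depth not applicable",
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _log(stage: str, **fields) -> None:
    logger.info(json.dumps({"stage": stage, **fields}, default=str))


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


class _StageCache:
    def __init__(self, out_dir: Path, config_hash: str):
        self.out_dir = out_dir
        self.hash = config_hash

    def fresh(self, stage: str) -> bool:
        marker = self.out_dir / stage / ".stage.json"
        if not marker.exists():
            return False
        try:
            return json.loads(marker.read_text()).get("config_hash") == self.hash
        except (json.JSONDecodeError, OSError):
            return False

    def mark(self, stage: str, outputs: dict) -> None:
        stage_dir = self.out_dir / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        (stage_dir / ".stage.json").write_text(
            json.dumps({"config_hash": self.hash, "outputs": outputs},
                       indent=1, sort_keys=True)
        )


def _resolve_arms(source) -> ArmTable:
    if isinstance(source, ArmTable):
        return source
    if source in (None, "hg38"):
        return hg38_arm_table()
    if source == "toy":
        return toy_arm_table()
    return read_arm_table(source)


def _aligned_endpoint(clinical, samples: pd.Index, name: str):
    time, event, idx = clinical.endpoint(name)
    keep = idx.isin(samples)
    common = idx[keep]
    pos = {s: i for i, s in enumerate(idx)}
    sel = [pos[s] for s in common]
    return time[sel], event[sel].astype(int), common


def run_all(config, out_dir: str | Path) -> dict:
    """Execute every pipeline stage; returns the run manifest.

    Stages whose ``.stage.json`` marker matches the current config hash are
    skipped; outputs are deterministic given the config (all randomness is
    seeded from it), so a rerun with an identical config reproduces the
    manifest bit for bit.
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    cache = _StageCache(out_dir, chash)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "config_hash": chash,
        "seed": seed,
        "version": __version__,
        "decisions": DECISIONS_METADATA,
        "stages": {},
    }

    def record(stage: str, outputs: dict, cached: bool = False) -> None:
        # the manifest itself carries no volatile fields, so reruns with an
        # identical config reproduce it byte for byte
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
        }
        if not cached:
            cache.mark(stage, {k: str(v) for k, v in outputs.items()})
        _log(stage, status="cached" if cached else "complete")

    def fail(stage: str, err: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {err}") from err

    # ---- validate ---------------------------------------------------------
    stage_dir = out_dir / "validate"
    stage_dir.mkdir(exist_ok=True)
    try:
        if "simulate" in cfg:
            sim_cfg = dict(cfg["simulate"])
            sim_cfg.setdefault("seed", seed)
            sim = simulate_cohort(SimConfig.from_dict(sim_cfg), stage_dir)
            profiles, arms, clinical = sim.profiles, sim.arms, sim.clinical
            outputs = {
                "seg": stage_dir / "cohort.seg",
                "clinical": stage_dir / "clinical.csv",
                "truth": stage_dir / "truth.json",
            }
        else:
            inputs = cfg["inputs"]
            for key in ("seg", "clinical"):
                if not Path(inputs[key]).exists():
                    raise ValidationError(f"missing input file: {inputs[key]}")
            arms = _resolve_arms(inputs.get("arms"))
            profiles = read_seg(inputs["seg"], inputs.get("dialect", "tcga"))
            clinical = read_clinical(inputs["clinical"],
                                     inputs.get("column_map"))
            outputs = {"seg": inputs["seg"], "clinical": inputs["clinical"]}
        profiles = [p.validated(arms) for p in profiles]
    except Exception as err:  # noqa: BLE001 - stage boundary
        fail("validate", err)
    record("validate", outputs)

    cutoffs = IntensityCutoffs(
        float(cfg.get("loss_cutoff", -0.1)), float(cfg.get("gain_cutoff", 0.15))
    )

    # ---- fractions --------------------------------------------------------
    stage_dir = out_dir / "fractions"
    stage_dir.mkdir(exist_ok=True)
    frac_path = stage_dir / "fractions.tsv"
    try:
        if cache.fresh("fractions") and frac_path.exists():
            fractions = pd.read_csv(frac_path, sep="\t", index_col=0)
            record("fractions", {"fractions": frac_path}, cached=True)
        else:
            fractions = fraction_matrix(profiles, arms, cutoffs)
            fractions.to_csv(frac_path, sep="\t", float_format="%.10g")
            record("fractions", {"fractions": frac_path})
    except Exception as err:  # noqa: BLE001
        fail("fractions", err)

    sweep_cfg = cfg.get("sweep", {})
    endpoints = list(sweep_cfg.get("endpoints", ["recurrence", "os"]))
    horizon = float(sweep_cfg.get("horizon", 5.0))
    step = int(sweep_cfg.get("step", 1))

    y = {}
    sample_sets = {}
    for ep in endpoints:
        t, e, idx = _aligned_endpoint(clinical, fractions.index, ep)
        if len(idx) and e.sum() > 0:
            y[ep] = (t, e)
            sample_sets[ep] = idx
    if not y:
        fail("sweep", ValidationError("no endpoint with events"))

    # ---- sweep ------------------------------------------------------------
    stage_dir = out_dir / "sweep"
    stage_dir.mkdir(exist_ok=True)
    try:
        optimizer = SizeThresholdOptimizer(horizon=horizon, step=step)
        optimizer.fit(
            fractions.loc[sample_sets[next(iter(y))]],
            {ep: y[ep] for ep in y},
        )
        outputs = {}
        for ep in y:
            path = stage_dir / f"auc_curves_{ep}.tsv"
            optimizer.auc_curves_[ep].to_csv(path, sep="\t",
                                             float_format="%.10g")
            outputs[f"auc_{ep}"] = path
        summary_path = stage_dir / "summary.tsv"
        optimizer.summary_.to_csv(summary_path, sep="\t",
                                  float_format="%.10g")
        outputs["summary"] = summary_path
        null_reps = int(sweep_cfg.get("null_reps", 100))
        fdr_report = {}
        if null_reps > 0:
            ep0 = next(iter(y))
            nulls = null_sd_distribution(
                fractions.loc[sample_sets[ep0]], *y[ep0],
                mode=sweep_cfg.get("null_mode", "permute"),
                reps=null_reps, seed=seed, horizon=horizon, step=step,
            )
            fdr_report = {
                "endpoint": ep0,
                "reps": null_reps,
                "mode": sweep_cfg.get("null_mode", "permute"),
                "fdr_at_sd_0.01": fdr_at_cutoff(nulls, 0.01),
                "null_sd_quantiles": {
                    q: float(np.quantile(nulls, q))
                    for q in (0.5, 0.9, 0.95, 0.99)
                },
            }
        report_path = stage_dir / "criteria.json"
        report_path.write_text(json.dumps(
            {
                "criteria": {"min_auc": 0.60, "min_sd": 0.01,
                             "min_prevalence": 0.025},
                "size_dependent": list(
                    optimizer.summary_.index[optimizer.size_dependent_]
                ),
                "fdr": fdr_report,
            },
            indent=1, sort_keys=True,
        ))
        outputs["criteria"] = report_path
    except Exception as err:  # noqa: BLE001
        fail("sweep", err)
    record("sweep", outputs)

    # ---- focal ------------------------------------------------------------
    focal_cfg = cfg.get("focal", {})
    focal_ep = focal_cfg.get("endpoint", next(iter(y)))
    stage_dir = out_dir / "focal"
    stage_dir.mkdir(exist_ok=True)
    try:
        grid = make_bin_grid(arms, int(focal_cfg.get("bin_size", 200_000)))
        intensities = bin_intensity_matrix(profiles, grid)
        intensities = intensities.loc[sample_sets[focal_ep]]
        outputs = {}
        pile = pileup(profiles, grid, cutoffs)
        for direction in ("loss", "gain"):
            calls = bin_calls(intensities, cutoffs, direction)
            profile = bin_auc_profile(calls, *y[focal_ep], horizon=horizon)
            regions = focal_regions(
                profile, grid, float(focal_cfg.get("margin", 0.04))
            )
            auc_path = stage_dir / f"auc_{direction}.bedgraph"
            write_bedgraph(profile, grid, auc_path, f"auc_{direction}")
            bed_path = stage_dir / f"focal_{direction}.bed"
            write_bed(regions, grid, bed_path)
            pileup_path = stage_dir / f"pileup_{direction}.bedgraph"
            write_bedgraph(pile[direction], grid, pileup_path,
                           f"pileup_{direction}")
            outputs[f"auc_{direction}"] = auc_path
            outputs[f"regions_{direction}"] = bed_path
            outputs[f"pileup_{direction}"] = pileup_path
    except Exception as err:  # noqa: BLE001
        fail("focal", err)
    record("focal", outputs)

    # ---- cooccur ----------------------------------------------------------
    co_cfg = cfg.get("cooccur", {})
    co_ep = co_cfg.get("endpoint", next(iter(y)))
    stage_dir = out_dir / "cooccur"
    stage_dir.mkdir(exist_ok=True)
    try:
        calls = optimizer.transform(
            fractions.loc[sample_sets[co_ep]], endpoint=co_ep
        )
        sd_features = list(optimizer.summary_.index[optimizer.size_dependent_])
        tuples = tuple_features(
            calls, sd_features, order=int(co_cfg.get("order", 2)),
            min_prevalence=float(co_cfg.get("min_prevalence", 0.025)),
        )
        tuples_path = stage_dir / "tuples.tsv"
        tuples.to_csv(tuples_path, sep="\t")
        outputs = {"tuples": tuples_path}
        selection = {"selected": [], "note": "no eligible tuples"}
        if tuples.shape[1] >= 2:
            model = regularized_cox_cv(
                tuples, *y[co_ep],
                alphas=co_cfg.get("alphas"),
                folds=int(co_cfg.get("folds", 10)),
                seed=seed,
            )
            selection = {
                "selected": model.selected_features_,
                "alpha": model.alpha_,
                "lambda": model.lambda_,
                "best_cindex": model.best_cindex_,
            }
        burden = cna_burden(calls)
        part_result = {"cutpoints": [], "note": "burden constant"}
        if burden.nunique() > 1:
            part = burden_partition(
                burden.to_numpy(), *y[co_ep],
                min_leaf=int(co_cfg.get("min_leaf", 20)),
            )
            part_result = {"cutpoints": part.cutpoints_,
                           "n_strata": part.n_strata_}
        sel_path = stage_dir / "selection.json"
        sel_path.write_text(json.dumps(
            {"pairs": selection, "burden_partition": part_result},
            indent=1, sort_keys=True, default=float,
        ))
        outputs["selection"] = sel_path
    except Exception as err:  # noqa: BLE001
        fail("cooccur", err)
    record("cooccur", outputs)

    # ---- risk -------------------------------------------------------------
    risk_cfg = cfg.get("risk", {})
    risk_ep = risk_cfg.get("endpoint", next(iter(y)))
    stage_dir = out_dir / "risk"
    stage_dir.mkdir(exist_ok=True)
    try:
        calls = optimizer.transform(
            fractions.loc[sample_sets[risk_ep]], endpoint=risk_ep
        )
        features = calls
        sd_features = [
            f for f in optimizer.summary_.index[optimizer.size_dependent_]
            if f in calls.columns
        ]
        if sd_features:
            features = calls[sd_features]
        model = BoostedCoxRiskScore(
            rate=float(risk_cfg.get("rate", 0.009)),
            rounds=int(risk_cfg.get("rounds", 2)),
        ).fit(features, y[risk_ep])
        scores = model.predict(features)
        groups = model.predict_group(features)
        score_path = stage_dir / "scores.tsv"
        pd.DataFrame(
            {"score": scores, "group": groups}, index=features.index
        ).to_csv(score_path, sep="\t", float_format="%.10g")
        card_path = stage_dir / "model.json"
        card_path.write_text(json.dumps(
            {
                "coefficients": model.coef_.to_dict(),
                "cutpoints": list(model.cutpoints_),
                "rate": model.rate,
                "rounds": model.rounds,
            },
            indent=1, sort_keys=True, default=float,
        ))
        outputs = {"scores": score_path, "model": card_path}
    except Exception as err:  # noqa: BLE001
        fail("risk", err)
    record("risk", outputs)

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    manifest["manifest_path"] = str(manifest_path)
    return manifest
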