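"""End-to-end orchestration of the stratification analyses.

The analysis grid comprises seven clustering runs: four on MMN features
(controls + baseline patients, controls + follow-up patients, baseline +
follow-up patients, and patients' 6-month MMN change) and three on
delta-band AverageDifference features (the three cohort runs).  For each
configured run the pipeline preprocesses the epoch sets, extracts the
24-channel features, MAD-screens AverageDifference observations,
builds the elbow curve, fits k-means, and characterizes the clusters
against the clinical table.  A failed run is logged and skipped; the
other runs continue.

All randomness derives from the config seed; every result bundle embeds
a hash of the fully serialized config for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import erp, profiling, stratify, timefreq
from .montage import EOG_CHANNELS, FRONTOCENTRAL_24, SCALP_64
from .preprocess import (EpochSet, RejectionRules, baseline_correct,
                         correct_ocular, crop_epochs, reject_artifacts)

logger = logging.getLogger("mmnstrat")

#: (feature source, run design) pairs of the full analysis grid
ANALYSIS_GRID: tuple[tuple[str, str], ...] = (
    ("mmn", "HC+baselineFEP"),
    ("mmn", "HC+followupFEP"),
    ("mmn", "baselineFEP+followupFEP"),
    ("mmn_change", "FEP_change"),
    ("avgdiff_delta", "HC+baselineFEP"),
    ("avgdiff_delta", "HC+followupFEP"),
    ("avgdiff_delta", "baselineFEP+followupFEP"),
)


@dataclass
class PipelineConfig:
    """Validated end-to-end analysis settings."""

    runs: tuple[tuple[str, str], ...] = ANALYSIS_GRID
    mmn_window_ms: tuple[float, float] = (120.0, 250.0)
    freq_window_ms: tuple[float, float] = (-100.0, 280.0)
    avgdiff_window_ms: tuple[float, float] = (0.0, 280.0)
    baseline_ms: tuple[float, float] = (-100.0, 0.0)
    rejection: RejectionRules = field(default_factory=RejectionRules)
    eog_channels: tuple[str, str] = EOG_CHANNELS
    morlet_cycles: float = 7.0
    k: int = 2
    k_max: int = 10
    n_restarts: int = 50
    mad_threshold: float = 3.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for source, design in self.runs:
            if source not in ("mmn", "mmn_change", "avgdiff_delta"):
                raise ValueError(f"unknown feature source {source!r}")
            if design not in stratify.RUN_DESIGNS:
                raise ValueError(f"unknown run design {design!r}")
            if source == "mmn_change" and design != "FEP_change":
                raise ValueError("mmn_change features imply the FEP_change design")
        if self.k < 2 or self.k_max < 3 or self.n_restarts < 1:
            raise ValueError("invalid clustering settings")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def preprocess_epochs(es: EpochSet, cfg: PipelineConfig) -> EpochSet:
    """Baseline-correct, ocular-correct, and artifact-screen one epoch set.

    Screening covers scalp channels only: EOG keeps its recorded signal
    after regression correction and would otherwise trip the amplitude
    rule on every blink.
    """
    es = baseline_correct(es, cfg.baseline_ms)
    if all(c in es.channel_names for c in cfg.eog_channels):
        es = correct_ocular(es, cfg.eog_channels)
    scalp = [c for c in es.channel_names if c in SCALP_64]
    es = reject_artifacts(es, cfg.rejection, channels=scalp)
    logger.info("%s@%s: %d/%d epochs survive screening", es.subject_id,
                es.timepoint, int((~es.rejected).sum()), es.n_trials)
    return es


def _design_observations(design: str, table: pd.DataFrame) -> list[tuple[str, str]]:
    """(subject, timepoint) observations entering a run design."""
    hc = table[table["group"] == "HC"]
    fep = table[table["group"] == "FEP"]
    hc_base = [(s, "baseline") for s in hc.loc[hc["timepoint"] == "baseline",
                                               "subject"]]
    fep_base = [(s, "baseline") for s in fep.loc[fep["timepoint"] == "baseline",
                                                 "subject"]]
    fep_fu = [(s, "followup") for s in fep.loc[fep["timepoint"] == "followup",
                                               "subject"]]
    if design == "HC+baselineFEP":
        return hc_base + fep_base
    if design == "HC+followupFEP":
        return hc_base + fep_fu
    if design == "baselineFEP+followupFEP":
        return fep_base + fep_fu
    if design == "FEP_change":
        both = set(s for s, _ in fep_base) & set(s for s, _ in fep_fu)
        return [(s, "change") for s in sorted(both)]
    raise ValueError(design)


def _mmn_feature_matrix(source, design, mmn_feats, cfg) -> stratify.FeatureMatrix:
    rows, index = [], []
    if source == "mmn_change":
        subjects = [s for s, _ in _mmn_change_pairs(mmn_feats)]
        for sid in subjects:
            ch = erp.change_features(mmn_feats[(sid, "baseline")],
                                     mmn_feats[(sid, "followup")])
            rows.append(ch.delta_amplitudes)
            index.append(f"{sid}@change")
    else:
        raise ValueError(source)
    return stratify.FeatureMatrix(
        data=pd.DataFrame(rows, index=pd.Index(index, name="obs"),
                          columns=list(FRONTOCENTRAL_24)),
        source=source, run_design=design,
    )


def _mmn_change_pairs(mmn_feats: dict) -> list[tuple[str, None]]:
    subs = sorted({s for (s, tp) in mmn_feats if tp == "baseline"}
                  & {s for (s, tp) in mmn_feats if tp == "followup"})
    return [(s, None) for s in subs]


def run_full_pipeline(
    epoch_sets: dict[tuple[str, str], EpochSet],
    table: pd.DataFrame,
    cfg: PipelineConfig,
) -> dict:
    """Execute every configured run design; returns the result bundle.

    ``epoch_sets`` maps (subject, timepoint) to raw epoch-level data;
    ``table`` is the cohort clinical table.  The bundle maps
    ``"<source>:<design>"`` to elbow curve, cluster result, per-channel
    t-tests, and clinical profile; failures are recorded under "errors".
    """
    profiling.validate_cohort_table(table)
    clean = {key: preprocess_epochs(es, cfg) for key, es in epoch_sets.items()}

    mmn_feats: dict[tuple[str, str], erp.MMNFeatures] = {}
    for key, es in clean.items():
        try:
            mmn_feats[key] = erp.mmn_amplitudes(es, cfg.mmn_window_ms)
        except ValueError as exc:  # e.g. no surviving epochs
            logger.warning("MMN features failed for %s: %s", key, exc)

    needs_avgdiff = any(s == "avgdiff_delta" for s, _ in cfg.runs)
    avgdiff_feats: dict[tuple[str, str], timefreq.AvgDiffFeatures] = {}
    if needs_avgdiff:
        for key, es in clean.items():
            try:
                cropped = crop_epochs(es, cfg.freq_window_ms)
                bp = timefreq.morlet_band_power(
                    cropped, timefreq.DELTA, n_cycles=cfg.morlet_cycles,
                    channels=FRONTOCENTRAL_24)
                avgdiff_feats[key] = timefreq.average_difference(
                    bp, cfg.avgdiff_window_ms)
            except ValueError as exc:
                logger.warning("AverageDifference failed for %s: %s", key, exc)

    bundle: dict = {"config_hash": cfg.config_hash(), "runs": {},
                    "errors": {}, "counts": {}}
    bundle["counts"] = {
        f"{k[0]}@{k[1]}": {
            "presented": es.n_trials,
            "rejected": int(es.rejected.sum()),
            "S1_surviving": int(es.surviving("S1").sum()),
            "S2_surviving": int(es.surviving("S2").sum()),
        } for k, es in clean.items()
    }

    for source, design in cfg.runs:
        name = f"{source}:{design}"
        try:
            bundle["runs"][name] = _run_one(
                source, design, mmn_feats, avgdiff_feats, table, cfg)
        except Exception as exc:  # noqa: BLE001 - isolate run failures
            logger.warning("run %s failed: %s", name, exc)
            bundle["errors"][name] = str(exc)
    if cfg.output_dir:
        _write_bundle(bundle, cfg)
    return bundle


def _run_one(source, design, mmn_feats, avgdiff_feats, table, cfg) -> dict:
    if source == "mmn_change":
        X = _mmn_feature_matrix(source, design, mmn_feats, cfg)
    else:
        obs = _design_observations(design, table)
        feats = mmn_feats if source == "mmn" else avgdiff_feats
        missing = [o for o in obs if o not in feats]
        if missing:
            raise ValueError(f"no features for observation(s): {missing}")
        rows = {f"{s}@{tp}": (feats[(s, tp)].amplitudes if source == "mmn"
                              else feats[(s, tp)].values) for s, tp in obs}
        X = stratify.FeatureMatrix(
            data=pd.DataFrame.from_dict(rows, orient="index",
                                        columns=list(FRONTOCENTRAL_24)),
            source=source, run_design=design,
        )
        X.data.index.name = "obs"

    # MAD screening applies to AverageDifference runs only
    if source == "avgdiff_delta":
        res = stratify.screen_and_cluster(
            X, k=cfg.k, seed=cfg.seed, n_restarts=cfg.n_restarts,
            mad_threshold=cfg.mad_threshold)
        kept = X.data.index.difference(pd.Index(res.outliers))
        X_used = stratify.FeatureMatrix(data=X.data.loc[kept], source=X.source,
                                        run_design=X.run_design)
    else:
        res = stratify.kmeans_cluster(X, k=cfg.k, seed=cfg.seed,
                                      n_restarts=cfg.n_restarts)
        X_used = X
    elbow = stratify.elbow_select_k(X_used, k_max=cfg.k_max, seed=cfg.seed,
                                    n_restarts=cfg.n_restarts)
    ttests = profiling.per_channel_cluster_ttests(X_used, res)

    profile = None
    if design != "FEP_change":
        profile = profiling.characterize_clusters(_design_table(design, table), res)
    else:
        fu = table[(table["group"] == "FEP") & (table["timepoint"] == "followup")]
        fu = fu.assign(timepoint="change")  # follow-up measures profile changes
        profile = profiling.characterize_clusters(fu, res)
    return {"features": X, "elbow": elbow, "clusters": res,
            "channel_ttests": ttests, "profile": profile}


def _design_table(design: str, table: pd.DataFrame) -> pd.DataFrame:
    obs = _design_observations(design, table)
    key = pd.MultiIndex.from_frame(table[["subject", "timepoint"]])
    mask = key.isin(obs)
    return table[mask]


def _write_bundle(bundle: dict, cfg: PipelineConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": bundle["config_hash"], "counts": bundle["counts"],
            "errors": bundle["errors"]}
    (out / "pipeline_meta.json").write_text(json.dumps(meta, indent=1))
    for name, run in bundle["runs"].items():
        stem = name.replace(":", "_").replace("+", "-")
        run["features"].data.to_csv(out / f"{stem}_features.csv")
        elbow = run["elbow"]
        (out / f"{stem}_elbow.json").write_text(json.dumps({
            "config_hash": bundle["config_hash"],
            "k": elbow.k_values.tolist(), "J": elbow.J.tolist(),
            "chosen_k": elbow.chosen_k}, indent=1))
        res = run["clusters"]
        res.assignments.to_csv(out / f"{stem}_assignments.csv")
        run["channel_ttests"].to_csv(out / f"{stem}_channel_ttests.csv",
                                     index=False)
        if run["profile"] is not None:
            run["profile"].variables.to_csv(out / f"{stem}_profile.csv",
                                            index=False)
            (out / f"{stem}_profile.md").write_text(run["profile"].to_markdown())
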