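"""Cohort-level synthesis: epoch sets plus clinical tables.

Two generation tiers are provided.  The full tier synthesizes EEG
epochs per subject and samples a clinical table from per-cluster models
(for end-to-end pipeline tests).  The feature tier draws 24-channel
feature matrices or clinical tables directly from the same per-cluster
models — orders of magnitude faster, for clustering- and profiling-stage
tests that do not need raw EEG.

Hidden ground-truth cluster labels travel in a ``true_cluster`` column /
series for test assertions only; no analysis operation reads them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..montage import FRONTOCENTRAL_24
from ..preprocess import EpochSet
from ..stratify import FeatureMatrix
from . import profiles
from .epochs import generate_subject_epochs
from .specs import CohortSpec, ParadigmSpec, SubjectSpec

PATIENT_ONLY_VARS = ("PANSS_positive", "PANSS_negative", "PANSS_general",
                     "PANSS_total", "chlorpromazine_eq")


def generate_cohort(
    cohort: CohortSpec,
    window_ms: tuple[float, float] = (-100.0, 400.0),
) -> tuple[dict[tuple[str, str], EpochSet], pd.DataFrame]:
    """One EpochSet per subject/timepoint plus a sampled clinical table."""
    ss = np.random.SeedSequence(cohort.seed)
    epoch_seeds = ss.spawn(len(cohort.subjects))
    out: dict[tuple[str, str], EpochSet] = {}
    for spec, child in zip(cohort.subjects, epoch_seeds):
        es = generate_subject_epochs(
            spec, cohort.paradigm,
            seed=int(child.generate_state(1)[0] % (2**31)),
            window_ms=window_ms,
        )
        out[(spec.subject_id, spec.timepoint)] = es
    table = sample_clinical_table(
        cohort.subjects, cohort.clinical_model, cohort.categorical_model,
        seed=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
    )
    return out, table


def sample_clinical_table(
    subjects: list[SubjectSpec],
    clinical_model: dict[str, dict[int, tuple[float, float]]],
    categorical_model: dict[str, dict[int, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical table drawn per hidden cluster from the sampling models.

    Patient-only measures (PANSS, chlorpromazine) are set missing for
    healthy controls regardless of the model.
    """
    categorical_model = categorical_model or {}
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        row: dict = {
            "subject": s.subject_id, "group": s.group, "timepoint": s.timepoint,
            "patient": s.group == "FEP", "true_cluster": s.true_cluster,
        }
        for var, per_cluster in clinical_model.items():
            mean, sd = per_cluster[s.true_cluster]
            val = rng.normal(mean, sd) if sd > 0 else float(mean)
            if var in PATIENT_ONLY_VARS and s.group == "HC":
                val = np.nan
            if var == "UPSA":
                val = float(np.clip(val, 0.0, 100.0))
            row[var] = val
        for var, per_cluster in categorical_model.items():
            if var == "patient":
                continue  # determined by the subject's group
            p = per_cluster[s.true_cluster]
            val: object = bool(rng.random() < p)
            if var == "schizophrenia" and s.group == "HC":
                val = np.nan
            row[var] = val
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convenience builders
# ---------------------------------------------------------------------------

def two_cluster_subject_specs(
    design: str = "HC+baselineFEP",
    n1: int | None = None,
    n2: int | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
    artifact_rate: float = 0.0,
    blink_rate: float = 0.0,
    band_power_profile: dict[str, tuple[float, float]] | None = None,
    patient_fraction: tuple[float, float] = (0.31, 0.41),
) -> list[SubjectSpec]:
    """Subject specs with per-site MMN profiles drawn from the default
    two-cluster effect model for ``design`` (subject profile ~ N(cluster
    mean, SD) per site)."""
    c1, c2, sd = profiles.mmn_profile(design)
    if n1 is None or n2 is None:
        n1, n2 = profiles.CLUSTER_SIZES_MMN[design]
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n1 + n2):
        cluster = 1 if i < n1 else 2
        mean = c1 if cluster == 1 else c2
        profile = rng.normal(mean, sd)
        p_pat = patient_fraction[cluster - 1]
        specs.append(SubjectSpec(
            subject_id=f"S{i + 1:03d}",
            group="FEP" if rng.random() < p_pat else "HC",
            timepoint="baseline",
            true_cluster=cluster,
            mmn_profile=dict(zip(FRONTOCENTRAL_24, profile)),
            band_power_profile=dict(band_power_profile or {}),
            noise_sd=noise_sd,
            artifact_rate=artifact_rate,
            blink_rate=blink_rate,
        ))
    return specs


def feature_matrix_cohort(
    source: str = "mmn",
    design: str = "HC+baselineFEP",
    n1: int | None = None,
    n2: int | None = None,
    seed: int = 0,
) -> tuple[FeatureMatrix, pd.Series]:
    """Feature matrix drawn directly from the two-cluster effect model.

    ``source``: "mmn" (per-design amplitude profiles), "mmn_change"
    (6-month change profiles), or "avgdiff_delta" (delta-band
    AverageDifference profiles, raw units).  Returns the matrix and the
    hidden true labels.
    """
    if source == "mmn":
        c1, c2, sd = profiles.mmn_profile(design)
        default_n = profiles.CLUSTER_SIZES_MMN[design]
    elif source == "mmn_change":
        c1, c2, sd = profiles.change_profile()
        default_n = profiles.CLUSTER_SIZES_CHANGE
    elif source == "avgdiff_delta":
        c1, c2, sd = profiles.avgdiff_profile(design)
        default_n = profiles.CLUSTER_SIZES_AVGDIFF[design]
    else:
        raise ValueError(f"unknown source {source!r}")
    if n1 is None or n2 is None:
        n1, n2 = default_n
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(c1, sd, size=(n1, 24)),
                   rng.normal(c2, sd, size=(n2, 24))])
    idx = pd.Index([f"S{i + 1:03d}@baseline" for i in range(n1 + n2)], name="obs")
    truth = pd.Series([1] * n1 + [2] * n2, index=idx, name="true_cluster")
    fm = FeatureMatrix(
        data=pd.DataFrame(X, index=idx, columns=list(FRONTOCENTRAL_24)),
        source=source, run_design=design,
    )
    return fm, truth


def clinical_table_cohort(
    n1: int,
    n2: int,
    clinical_model: dict | None = None,
    categorical_model: dict | None = None,
    seed: int = 0,
    groups: tuple[str, str] = ("HC", "HC"),
) -> pd.DataFrame:
    """Clinical-only cohort for profiling tests (no EEG synthesis)."""
    if clinical_model is None:
        clinical_model = profiles.CLINICAL_MODEL_MIXED
        categorical_model = profiles.CATEGORICAL_MODEL_MIXED
    specs = [
        SubjectSpec(subject_id=f"S{i + 1:03d}",
                    group=groups[0] if i < n1 else groups[1],
                    true_cluster=1 if i < n1 else 2)
        for i in range(n1 + n2)
    ]
    return sample_clinical_table(specs, clinical_model,
                                 categorical_model or {}, seed=seed)


def three_group_cohort_table(seed: int = 0) -> pd.DataFrame:
    """Controls / baseline patients / follow-up patients table sampled
    from the default three-group cohort model (33 / 20 / 18; follow-up
    subjects are a subset of the baseline patients)."""
    rng = np.random.default_rng(seed)
    rows = []

    def sample_group(group_key: str, group: str, timepoint: str,
                     subject_ids: list[str]) -> None:
        p_fem = profiles.COHORT_FEMALE[group_key]
        for sid in subject_ids:
            row: dict = {"subject": sid, "group": group, "timepoint": timepoint,
                         "patient": group == "FEP",
                         "female": bool(rng.random() < p_fem)}
            for var, per_group in profiles.COHORT_MODEL.items():
                if group_key in per_group:
                    mean, sd = per_group[group_key]
                    val = float(rng.normal(mean, sd))
                    if var == "UPSA":
                        val = float(np.clip(val, 0, 100))
                    if var == "chlorpromazine_eq":
                        val = max(val, 0.0)
                    row[var] = val
                elif var in PATIENT_ONLY_VARS:
                    row[var] = np.nan
            rows.append(row)

    n_hc = profiles.COHORT_SIZES["HC"]
    n_b = profiles.COHORT_SIZES["baseline"]
    n_f = profiles.COHORT_SIZES["followup"]
    sample_group("HC", "HC", "baseline", [f"C{i + 1:03d}" for i in range(n_hc)])
    patient_ids = [f"P{i + 1:03d}" for i in range(n_b)]
    sample_group("baseline", "FEP", "baseline", patient_ids)
    sample_group("followup", "FEP", "followup", patient_ids[:n_f])
    return pd.DataFrame(rows)
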