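"""Clinical, cognitive, and functioning characterization of clusters.

Given cluster assignments from the stratification stage and a subject
cohort table, this module reproduces the study's table machinery:
per-channel two-sample t-tests between clusters, per-variable cluster
profiles (mean, SD, pooled-variance t or chi-square, significance at
p < 0.05 with no multiplicity correction), and three-group cohort
comparisons (controls vs baseline patients vs follow-up patients:
one-way ANOVA / chi-square / two-group t for patient-only measures).

Pooled-variance (Student) t-tests are used rather than Welch: cluster
profile tables conventionally report a single pooled SD per variable
pair.  Tests are two-sided by default; a one-sided switch exists for the
directional-hypothesis reading of symptom comparisons.  An optional
Benjamini-Hochberg correction is provided but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: cohort-table column dictionary
CONTINUOUS_VARIABLES = (
    "age", "education_years", "UPSA", "MCAS", "MCAS_independent",
    "MCAS_social", "MATRICS_social", "MATRICS_composite", "TASIT",
    "PANSS_positive", "PANSS_negative", "PANSS_general", "PANSS_total",
    "chlorpromazine_eq",
)
CATEGORICAL_VARIABLES = ("patient", "schizophrenia", "female")
ID_COLUMNS = ("subject", "group", "timepoint")

#: instrument score ranges used for validation
SCORE_RANGES = {"UPSA": (0.0, 100.0)}


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table against the column dictionary.

    PANSS and chlorpromazine must be missing for healthy controls; UPSA
    must lie in its 0-100 instrument range.  Returns the table unchanged.
    """
    missing_cols = [c for c in ID_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing column(s): {missing_cols}")
    hc = table["group"] == "HC"
    for var in ("PANSS_positive", "PANSS_negative", "PANSS_general",
                "PANSS_total", "chlorpromazine_eq"):
        if var in table.columns and table.loc[hc, var].notna().any():
            raise ValueError(f"{var} must be missing for healthy controls")
    for var, (lo, hi) in SCORE_RANGES.items():
        if var in table.columns:
            vals = table[var].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"{var} outside instrument range [{lo}, {hi}]")
    dup = table.duplicated(subset=["subject", "timepoint"])
    if dup.any():
        raise ValueError(
            f"duplicate subject/timepoint rows: "
            f"{table.loc[dup, ['subject', 'timepoint']].values.tolist()}"
        )
    return table


@dataclass
class ProfileReport:
    """Per-variable cluster comparison plus the per-channel block."""

    variables: pd.DataFrame  # variable, cluster stats, test, p, significant
    channels: pd.DataFrame | None = None
    cluster_sizes: dict[int, int] | None = None
    labels: dict[int, str] | None = None

    def to_markdown(self) -> str:
        """Markdown table; significant rows are rendered in bold."""
        lines = ["| Variable | Cluster 1 | Cluster 2 | Test | p |",
                 "|---|---|---|---|---|"]
        for _, r in self.variables.iterrows():
            def cell(mean, sd):
                if pd.isna(mean):
                    return "N/A"
                return f"{mean:.2f} ({sd:.2f})" if pd.notna(sd) else f"{mean:.2f}"
            c1 = cell(r.get("mean_1"), r.get("sd_1"))
            c2 = cell(r.get("mean_2"), r.get("sd_2"))
            test = (f"{r['test']} = {r['statistic']:.2f}"
                    if pd.notna(r["statistic"]) else "N/A")
            p = f"{r['p']:.3g}" if pd.notna(r["p"]) else "N/A"
            row = [str(r["variable"]), c1, c2, test, p]
            if bool(r.get("significant")):
                row = [f"**{v}**" for v in row]
            lines.append("| " + " | ".join(row) + " |")
        return "\n".join(lines)


def _pooled_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance t; returns (t, two-sided p)."""
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def per_channel_cluster_ttests(X, res) -> pd.DataFrame:
    """Two-sample pooled-variance t-test between clusters on each channel.

    ``X`` is a FeatureMatrix (or a DataFrame with site columns), ``res`` a
    two-cluster ClusterResult.  No multiplicity correction is applied;
    the significance flag is the raw p < 0.05.
    """
    data = X.data if hasattr(X, "data") else X
    assign = res.assignments
    clusters = sorted(assign.unique())
    if len(clusters) != 2:
        raise ValueError("per-channel t-tests require exactly two clusters")
    m1 = assign.index[assign == clusters[0]]
    m2 = assign.index[assign == clusters[1]]
    testable = len(m1) >= 2 and len(m2) >= 2
    rows = []
    for site in data.columns:
        a = data.loc[m1, site].to_numpy(dtype=float)
        b = data.loc[m2, site].to_numpy(dtype=float)
        if not testable:  # singleton cluster: means reported, no test
            rows.append({
                "site": site, "mean_1": a.mean(), "mean_2": b.mean(),
                "pooled_sd": np.nan, "t": np.nan,
                "df": len(a) + len(b) - 2, "p": np.nan, "significant": False,
            })
            continue
        t, p = _pooled_ttest(a, b)
        sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                     / (len(a) + len(b) - 2))
        rows.append({
            "site": site,
            "mean_1": a.mean(), "mean_2": b.mean(), "pooled_sd": sp,
            "t": t, "df": len(a) + len(b) - 2, "p": p,
            "significant": p < 0.05,
        })
    return pd.DataFrame(rows)


def characterize_clusters(
    table: pd.DataFrame,
    res,
    variables: tuple[str, ...] | None = None,
    one_sided: bool = False,
    fdr: bool = False,
) -> ProfileReport:
    """Cluster profile table: per-variable means/SDs and tests.

    Continuous variables get a pooled-variance t-test, categorical ones a
    Pearson chi-square (no continuity correction).  A variable missing
    for every member of some cluster (e.g. PANSS in a mixed HC/patient
    cluster) is reported N/A and untestable, as is any variable where a
    cluster has fewer than two non-missing values.
    """
    if "subject" in table.columns and "timepoint" in table.columns:
        table = table.set_index(_obs_index(table))
    assign = res.assignments
    unmatched = [i for i in assign.index if i not in table.index]
    if unmatched:
        raise ValueError(f"observations not in cohort table: {unmatched}")
    clusters = sorted(assign.unique())
    if len(clusters) != 2:
        raise ValueError("profiling expects two clusters")

    cont = [v for v in CONTINUOUS_VARIABLES if v in table.columns]
    cat = [v for v in CATEGORICAL_VARIABLES if v in table.columns]
    if variables is not None:
        cont = [v for v in cont if v in variables]
        cat = [v for v in cat if v in variables]

    groups = {c: table.loc[assign.index[assign == c]] for c in clusters}
    rows = []
    for var in cont:
        vals = {c: g[var].dropna().to_numpy(dtype=float)
                for c, g in groups.items()}
        r = {"variable": var, "kind": "continuous"}
        for j, c in enumerate(clusters, start=1):
            v = vals[c]
            r[f"n_{j}"] = len(v)
            r[f"mean_{j}"] = v.mean() if len(v) else np.nan
            r[f"sd_{j}"] = v.std(ddof=1) if len(v) > 1 else np.nan
        if all(len(v) >= 2 for v in vals.values()):
            t, p = _pooled_ttest(vals[clusters[0]], vals[clusters[1]])
            if one_sided:
                p = p / 2.0
            r.update(test="t", statistic=t, p=p, significant=p < 0.05)
        else:
            r.update(test="t", statistic=np.nan, p=np.nan, significant=False)
        rows.append(r)
    for var in cat:
        counts = np.array([
            [groups[c][var].fillna(False).astype(bool).sum(),
             (~groups[c][var].fillna(False).astype(bool)).sum()]
            for c in clusters
        ])
        r = {"variable": var, "kind": "categorical"}
        for j, c in enumerate(clusters, start=1):
            n = counts[j - 1].sum()
            r[f"n_{j}"] = n
            r[f"mean_{j}"] = counts[j - 1, 0] / n if n else np.nan  # proportion
            r[f"sd_{j}"] = np.nan
        if groups[clusters[0]][var].isna().all() or groups[clusters[1]][var].isna().all():
            r.update(test="chi2", statistic=np.nan, p=np.nan, significant=False)
        elif counts.sum(axis=0).min() == 0:  # a column of all-zeros: no test
            r.update(test="chi2", statistic=np.nan, p=np.nan, significant=False)
        else:
            chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
            r.update(test="chi2", statistic=float(chi2), p=float(p),
                     significant=p < 0.05)
        rows.append(r)

    out = pd.DataFrame(rows)
    if fdr and out["p"].notna().any():
        from statsmodels.stats.multitest import multipletests
        mask = out["p"].notna()
        rej, p_adj, *_ = multipletests(out.loc[mask, "p"], alpha=0.05,
                                       method="fdr_bh")
        out.loc[mask, "p_fdr"] = p_adj
        out.loc[mask, "significant"] = rej
    sizes = {int(c): int((assign == c).sum()) for c in clusters}
    return ProfileReport(variables=out, cluster_sizes=sizes, labels=res.labels)


def cohort_group_comparison(
    table: pd.DataFrame, one_sided: bool = False
) -> pd.DataFrame:
    """Three-group cohort description: HC vs baseline vs follow-up patients.

    Continuous variables measured in all three groups are compared with
    one-way ANOVA; sex with a Pearson chi-square; patient-only measures
    (PANSS subscales, chlorpromazine equivalents) with a two-group t-test
    between baseline and follow-up patients.
    """
    hc = table[(table["group"] == "HC")]
    fep_b = table[(table["group"] == "FEP") & (table["timepoint"] == "baseline")]
    fep_f = table[(table["group"] == "FEP") & (table["timepoint"] == "followup")]
    for name, g in (("HC", hc), ("baseline FEP", fep_b), ("follow-up FEP", fep_f)):
        if len(g) == 0:
            raise ValueError(f"empty design group: {name}")
    groups = (hc, fep_b, fep_f)
    group_names = ("HC", "baseline_FEP", "followup_FEP")

    rows = []
    patient_only = ("PANSS_positive", "PANSS_negative", "PANSS_general",
                    "PANSS_total", "chlorpromazine_eq")
    for var in [v for v in CONTINUOUS_VARIABLES if v in table.columns]:
        r = {"variable": var}
        samples = []
        for name, g in zip(group_names, groups):
            v = g[var].dropna().to_numpy(dtype=float)
            r[f"mean_{name}"] = v.mean() if len(v) else np.nan
            r[f"sd_{name}"] = v.std(ddof=1) if len(v) > 1 else np.nan
            samples.append(v)
        if var in patient_only:
            a, b = samples[1], samples[2]
            if len(a) >= 2 and len(b) >= 2:
                t, p = _pooled_ttest(a, b)
                if one_sided:
                    p = p / 2.0
                r.update(test="t", statistic=t, p=p)
            else:
                r.update(test="t", statistic=np.nan, p=np.nan)
        else:
            if all(len(s) >= 2 for s in samples):
                pooled = np.concatenate(samples)
                if np.var(pooled) == 0:  # identical constant groups
                    f, p = 0.0, 1.0
                else:
                    f, p = stats.f_oneway(*samples)
                r.update(test="F", statistic=float(f), p=float(p))
            else:
                r.update(test="F", statistic=np.nan, p=np.nan)
        rows.append(r)
    if "female" in table.columns:
        counts = np.array([
            [g["female"].astype(bool).sum(), (~g["female"].astype(bool)).sum()]
            for g in groups
        ])
        r = {"variable": "female"}
        for name, g, c in zip(group_names, groups, counts):
            r[f"mean_{name}"] = c[0] / c.sum()
            r[f"sd_{name}"] = np.nan
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
        r.update(test="chi2", statistic=float(chi2), p=float(p))
        rows.append(r)
    out = pd.DataFrame(rows)
    out["significant"] = out["p"] < 0.05
    return out


def _obs_index(table: pd.DataFrame) -> pd.Index:
    """Observation id 'subject@timepoint' used to join with clustering."""
    return pd.Index(table["subject"].astype(str) + "@" + table["timepoint"],
                    name="obs")
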