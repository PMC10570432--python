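"""Group-comparison statistics and report tables.

The battery mirrors a standard case-control IGT analysis: Mann-Whitney U
tests (with normal-approximation Z and the effect size r = |Z| / sqrt(N))
on the fitted model parameters, Spearman rank correlations between
parameters and symptom severity, a two-way mixed-design ANOVA (group x
block) on net scores with Bonferroni post-hocs and simple main effects, and
Student/Welch t tests for scalar group contrasts.

Conventions: the reported U value is min(U1, U2); Z uses midranks, the tie
correction and a continuity correction; when the pooled sample is small
(N <= 20) and tie-free, the exact permutation distribution supplies the
p-value instead of the normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .pvl_model import PARAM_NAMES

EXACT_MAX_N = 20


@dataclass(frozen=True)
class GroupComparisonResult:
    """Mann-Whitney outcome: U (smaller convention), Z, p, effect size r."""

    name: str
    u: float
    u1: float
    u2: float
    z: float
    p: float
    r: float
    n1: int
    n2: int
    method: str  # "exact" or "asymptotic"
    degenerate: bool = False
    group_stats: pd.DataFrame | None = None


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p: float
    degenerate: bool = False


@dataclass
class AnovaTable:
    """Mixed-design ANOVA output plus post-hoc and simple-effect tables."""

    anova: pd.DataFrame
    posthoc_blocks: pd.DataFrame
    simple_group_by_block: pd.DataFrame
    simple_block_by_group: pd.DataFrame


def effect_size_r(z: float, n_total: int) -> float:
    """r = |Z| / sqrt(N), the rank-biserial-style effect size."""
    return abs(z) / np.sqrt(n_total)


def mann_whitney(
    x, y, alternative: str = "two-sided", method: str = "auto", name: str = ""
) -> GroupComparisonResult:
    """Mann-Whitney U test with tie-corrected continuity-corrected Z.

    ``alternative`` follows the scipy convention on x vs y.  ``method``:
    "exact" (full permutation distribution, tie-free data only), "asymptotic"
    (normal approximation), or "auto" (exact when N <= 20 and no ties).
    A sample where every value is identical across both groups yields a
    degenerate result (Z and p are NaN) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2, n = x.size, y.size, x.size + y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = float(n1 * n2 - u1)
    u = min(u1, u2)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    group_stats = pd.DataFrame(
        {"n": [n1, n2], "mean": [x.mean(), y.mean()], "sd": [x.std(ddof=1), y.std(ddof=1)]},
        index=["x", "y"],
    )
    if sigma2 <= 0:
        return GroupComparisonResult(
            name=name, u=u, u1=u1, u2=u2, z=np.nan, p=np.nan, r=np.nan,
            n1=n1, n2=n2, method="degenerate", degenerate=True, group_stats=group_stats,
        )
    sigma = np.sqrt(sigma2)
    # continuity-corrected Z; sign follows U1 - mu (positive when x ranks higher)
    if u1 > mu:
        z = (u1 - mu - 0.5) / sigma
    elif u1 < mu:
        z = (u1 - mu + 0.5) / sigma
    else:
        z = 0.0

    if method == "auto":
        method = "exact" if (n <= EXACT_MAX_N and not has_ties) else "asymptotic"
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        p = float(stats.mannwhitneyu(x, y, alternative=alternative, method="exact").pvalue)
    else:
        if alternative == "two-sided":
            p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        elif alternative == "greater":
            p = float(stats.norm.sf((u1 - mu - 0.5) / sigma))
        elif alternative == "less":
            p = float(stats.norm.cdf((u1 - mu + 0.5) / sigma))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return GroupComparisonResult(
        name=name, u=u, u1=u1, u2=u2, z=float(z), p=float(p),
        r=effect_size_r(z, n), n1=n1, n2=n2, method=method, group_stats=group_stats,
    )


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return CorrelationResult(rho=np.nan, n=x.size, p=np.nan, degenerate=True)
    res = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(res.statistic), n=int(x.size), p=float(res.pvalue))


def group_t_tests(x, y, welch: bool = False) -> tuple[float, float, float]:
    """Student's pooled or Welch's unpooled t test; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def net_scores_long(block_scores: np.ndarray, groups, subjects=None) -> pd.DataFrame:
    """Shape an (n_subjects, n_blocks) score array into a long frame."""
    scores = np.asarray(block_scores, dtype=float)
    n, b = scores.shape
    subjects = [f"s{i}" for i in range(n)] if subjects is None else list(subjects)
    rows = [
        {"subject": subjects[i], "group": groups[i], "block": j + 1, "score": scores[i, j]}
        for i in range(n)
        for j in range(b)
    ]
    return pd.DataFrame(rows)


def net_score_anova(data: pd.DataFrame) -> AnovaTable:
    """Two-way mixed ANOVA on net scores: group (between) x block (within).

    ``data`` is long-format with columns subject, group, block, score and a
    balanced block design (every subject observed in every block).  Returns
    the omnibus table (F, df, p, partial eta-squared), Bonferroni-adjusted
    pairwise block comparisons, per-block group simple main effects, and
    per-group block simple main effects (one-way repeated measures within
    each group; the df convention is the univariate one).
    """
    required = {"subject", "group", "block", "score"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    counts = data.groupby("subject")["block"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: all subjects need the same block count")
    aov = pg.mixed_anova(
        data=data, dv="score", within="block", subject="subject", between="group"
    )
    posthoc = pg.pairwise_tests(
        data=data, dv="score", within="block", subject="subject", padjust="bonf"
    )
    simple_group = []
    for block, sub in data.groupby("block"):
        res = pg.anova(data=sub, dv="score", between="group", detailed=False)
        simple_group.append(
            {
                "block": block,
                "F": float(res["F"].iloc[0]),
                "df1": float(res["ddof1"].iloc[0]),
                "df2": float(res["ddof2"].iloc[0]),
                "p": float(res["p_unc"].iloc[0]),
                "partial_eta_sq": float(res["np2"].iloc[0]),
            }
        )
    simple_block = []
    for group, sub in data.groupby("group"):
        res = pg.rm_anova(data=sub, dv="score", within="block", subject="subject")
        f = float(res["F"].iloc[0])
        df1 = float(res["ddof1"].iloc[0])
        df2 = float(res["ddof2"].iloc[0])
        simple_block.append(
            {
                "group": group,
                "F": f,
                "df1": df1,
                "df2": df2,
                "p": float(res["p_unc"].iloc[0]),
                # partial eta^2 from the F identity: F*df1 / (F*df1 + df2)
                "partial_eta_sq": f * df1 / (f * df1 + df2),
            }
        )
    return AnovaTable(
        anova=aov,
        posthoc_blocks=posthoc,
        simple_group_by_block=pd.DataFrame(simple_group),
        simple_block_by_group=pd.DataFrame(simple_block),
    )


# -- report rendering -----------------------------------------------------


def _fmt_mean_sd(values: np.ndarray, decimals: int = 3) -> str:
    mean = np.mean(values)
    sd = np.std(values, ddof=1) if len(values) > 1 else np.nan
    sd_txt = "NA" if np.isnan(sd) else f"{sd:.{decimals}f}"
    return f"{mean:.{decimals}f} ({sd_txt})"


def parameter_comparison_table(
    estimates: pd.DataFrame, labels: pd.Series, groups: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Per-parameter group contrast: mean (SD) per group, U, Z, p, r."""
    df = estimates.copy()
    df["group"] = df["subject_id"].map(labels)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "subject_id"].tolist()
        raise KeyError(f"subjects without labels: {missing[:5]}")
    present = list(pd.unique(df["group"]))
    if groups is None:
        if len(present) != 2:
            raise ValueError(f"need exactly two groups, found {present}")
        groups = tuple(present)
    rows = []
    for name in PARAM_NAMES:
        a = df.loc[df["group"] == groups[0], name].to_numpy()
        b = df.loc[df["group"] == groups[1], name].to_numpy()
        res = mann_whitney(a, b, name=name)
        rows.append(
            {
                "parameter": name,
                groups[0]: _fmt_mean_sd(a),
                groups[1]: _fmt_mean_sd(b),
                "U": res.u,
                "Z": np.round(res.z, 3),
                "p": res.p,
                "r": np.round(res.r, 2),
            }
        )
    return pd.DataFrame(rows)


def severity_correlation_table(
    estimates: pd.DataFrame, severity: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of each parameter with a severity score."""
    df = estimates.set_index("subject_id")
    sev = severity.reindex(df.index)
    if sev.isna().any():
        raise KeyError("severity scores missing for some fitted subjects")
    rows = []
    for name in PARAM_NAMES:
        res = spearman(df[name].to_numpy(), sev.to_numpy())
        rows.append({"parameter": name, "rho": np.round(res.rho, 3), "n": res.n, "p": res.p})
    return pd.DataFrame(rows)


def block_net_score_table(data: pd.DataFrame) -> pd.DataFrame:
    """Per-block (and total) net-score mean (SD) by group, long-format input."""
    rows = []
    groups = list(pd.unique(data["group"]))
    for block, sub in data.groupby("block"):
        row = {"block": str(block)}
        for g in groups:
            row[g] = _fmt_mean_sd(sub.loc[sub["group"] == g, "score"].to_numpy(), 2)
        rows.append(row)
    totals = data.groupby(["subject", "group"])["score"].sum().reset_index()
    row = {"block": "total"}
    for g in groups:
        row[g] = _fmt_mean_sd(totals.loc[totals["group"] == g, "score"].to_numpy(), 2)
    rows.append(row)
    return pd.DataFrame(rows)


def render_report(
    estimates: pd.DataFrame,
    metadata: pd.DataFrame,
    net_scores: pd.DataFrame | None = None,
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Assemble the study's report tables from fits and cohort metadata.

    ``metadata`` needs columns subject_id and group, optionally severity
    (severity correlations are computed within the first group, the
    patient-like one).  ``net_scores`` is the long-format block table; when
    given, the block summary and mixed ANOVA are included.  Tables are
    returned as DataFrames and, if ``out_dir`` is set, written as CSV plus a
    plain-text report.
    """
    if estimates.empty:
        raise ValueError("no fitted subjects to report on")
    if not {"subject_id", "group"}.issubset(metadata.columns):
        raise ValueError("metadata must have subject_id and group columns")
    labels = metadata.set_index("subject_id")["group"]
    tables: dict[str, pd.DataFrame] = {}
    tables["parameters"] = parameter_comparison_table(estimates, labels)
    if "severity" in metadata.columns:
        first_group = metadata["group"].iloc[0]
        ids = metadata.loc[metadata["group"] == first_group, "subject_id"]
        sev = metadata.set_index("subject_id")["severity"]
        sub = estimates[estimates["subject_id"].isin(ids)]
        if len(sub) >= 3:  # a rank correlation needs at least 3 pairs
            tables["severity_correlations"] = severity_correlation_table(sub, sev)
    if net_scores is not None:
        tables["net_scores"] = block_net_score_table(net_scores)
        anova = net_score_anova(net_scores)
        tables["anova"] = anova.anova
        tables["anova_posthoc"] = anova.posthoc_blocks
        tables["anova_simple_group"] = anova.simple_group_by_block
        tables["anova_simple_block"] = anova.simple_block_by_group
    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = []
        for key, tab in tables.items():
            tab.to_csv(out / f"{key}.csv", index=False)
            lines += [key, tab.to_string(index=False), ""]
        (out / "report.txt").write_text("\n".join(lines))
    return tables
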