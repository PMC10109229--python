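"""Split-plot mixed ANOVA, Bonferroni post hoc tests, and the subgroup ANOVA.

Two analyses are implemented from first principles:

1. For each wellbeing indicator, a mixed (split-plot) ANOVA::

       indicator ~ period + exposure_group + period * exposure_group

   with the four study periods as the within-subjects factor and the
   three-tier exposure group as the between-subjects factor.  The classical
   split-plot decomposition puts the between-subjects sum of squares into
   group and subject-within-group strata, and the within-subjects sum of
   squares into period, period x group, and residual strata; the group effect
   is tested against subject(group), the two within effects against the
   within residual.  The decomposition uses the sample-size (weighted) metric
   throughout, which keeps the five components exactly additive for any group
   imbalance (the within-subject design is complete by construction) and
   coincides with the usual Type III analysis on balanced data.  No
   sphericity correction is applied by default; a Greenhouse-Geisser epsilon
   is available behind a flag.

2. The subgroup ANOVA on war-minus-baseline deltas::

       delta ~ exposure_group + age_group + gender + income_level + baseline_level

   an additive between-subjects model with Type III sums of squares
   (sum-to-zero coding) to handle the unbalanced demographic cells.

Paired post hoc comparisons use paired t tests with Bonferroni correction
(family size m = 6, all period pairs, configurable) and paired Cohen's d
(mean of differences over their SD).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .studycal import PERIODS

log = logging.getLogger(__name__)

#: the three period pairs reported (all contain the baseline)
BASELINE_PAIRS = (("B", "W"), ("B", "R1"), ("B", "R2"))
ALL_PAIRS = tuple((PERIODS[i], PERIODS[j])
                  for i in range(4) for j in range(i + 1, 4))
DEFAULT_FAMILY_SIZE = 6


# ------------------------------------------------------------------ mixed ANOVA

@dataclass
class MixedAnovaResult:
    """SS/df/MS/F/p per effect of the split-plot decomposition."""

    table: pd.DataFrame            # index: effect; columns: SS, df, MS, F, p
    n_per_group: dict[str, int]
    grand_mean: float
    period_means: dict[str, float]
    cell_means: pd.DataFrame       # group x period means
    gg_epsilon: float | None = None
    diagnostics: list[str] = field(default_factory=list)

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def _gg_epsilon(Y: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    p = Y.shape[1]
    resid = Y.astype(float).copy()
    for g in np.unique(groups):
        sel = groups == g
        resid[sel] -= resid[sel].mean(axis=0, keepdims=True)
    S = resid.T @ resid / max(1, len(Y) - len(np.unique(groups)))
    # orthonormal contrasts via QR of centered identity
    C = np.linalg.qr(np.eye(p) - 1.0 / p)[0][:, :p - 1].T
    M = C @ S @ C.T
    tr = np.trace(M)
    denom = (p - 1) * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / (p - 1), tr ** 2 / denom)))


def mixed_anova(data: pd.DataFrame, periods=PERIODS,
                greenhouse_geisser: bool = False) -> MixedAnovaResult:
    """Split-plot ANOVA on complete-case wide data.

    ``data`` has one row per participant: a ``group`` column plus one column
    per period level.  Requires at least two represented groups and at least
    two complete cases in each; anything less aborts with a diagnostic
    rather than silently dropping the test.
    """
    periods = list(periods)
    missing = [c for c in ("group", *periods) if c not in data.columns]
    if missing:
        raise AnalysisError(f"mixed_anova input missing columns {missing}")
    complete = data.dropna(subset=list(periods))
    groups = complete["group"].to_numpy()
    Y = complete[periods].to_numpy(dtype=float)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise AnalysisError(
            f"mixed_anova needs >=2 exposure groups, got {list(uniq)}")
    small = {g: int(c) for g, c in zip(uniq, counts) if c < 2}
    if small:
        raise AnalysisError(
            f"mixed_anova: groups with <2 complete cases: {small}")

    N, p = Y.shape
    g = len(uniq)
    grand = Y.mean()
    subj_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    group_means = np.array([subj_means[groups == gr].mean() for gr in uniq])
    cell = np.array([Y[groups == gr].mean(axis=0) for gr in uniq])
    n_g = counts.astype(float)

    ss_between = p * float(((subj_means - grand) ** 2).sum())
    ss_group = p * float((n_g * (group_means - grand) ** 2).sum())
    ss_subject = ss_between - ss_group
    ss_period = N * float(((col_means - grand) ** 2).sum())
    inter_resid = cell - group_means[:, None] - col_means[None, :] + grand
    ss_inter = float((n_g[:, None] * inter_resid ** 2).sum())
    ss_within_total = float(((Y - subj_means[:, None]) ** 2).sum())
    ss_resid = ss_within_total - ss_period - ss_inter

    df = {"group": g - 1, "subject(group)": N - g, "period": p - 1,
          "period:group": (g - 1) * (p - 1), "residual": (N - g) * (p - 1)}
    ss = {"group": ss_group, "subject(group)": ss_subject,
          "period": ss_period, "period:group": ss_inter, "residual": ss_resid}
    ms = {k: (ss[k] / df[k] if df[k] > 0 else np.nan) for k in ss}

    diagnostics: list[str] = []

    def f_test(effect: str, error: str) -> tuple[float, float]:
        if not np.isfinite(ms[error]) or ms[error] <= 0:
            diagnostics.append(
                f"{effect}: zero-variance error stratum ({error}); "
                "F undefined")
            return np.nan, np.nan
        F = ms[effect] / ms[error]
        return F, float(stats.f.sf(F, df[effect], df[error]))

    eps = _gg_epsilon(Y, groups) if greenhouse_geisser else None
    rows = {}
    for effect, error in [("group", "subject(group)"),
                          ("period", "residual"),
                          ("period:group", "residual")]:
        F, pval = f_test(effect, error)
        if eps is not None and effect in ("period", "period:group") and np.isfinite(F):
            pval = float(stats.f.sf(F, df[effect] * eps, df["residual"] * eps))
        rows[effect] = (ss[effect], df[effect], ms[effect], F, pval)
    for stratum in ("subject(group)", "residual"):
        rows[stratum] = (ss[stratum], df[stratum], ms[stratum], np.nan, np.nan)

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["SS", "df", "MS", "F", "p"]).loc[
        ["group", "subject(group)", "period", "period:group", "residual"]]
    return MixedAnovaResult(
        table=table,
        n_per_group={gr: int(c) for gr, c in zip(uniq, counts)},
        grand_mean=float(grand),
        period_means={per: float(m) for per, m in zip(periods, col_means)},
        cell_means=pd.DataFrame(cell, index=uniq, columns=periods),
        gg_epsilon=eps,
        diagnostics=diagnostics,
    )


# ----------------------------------------------------------- paired comparisons

def cohens_d_paired(values_p1, values_p2) -> float:
    """Paired Cohen's d: mean(p2 - p1) / SD(p2 - p1), n-1 denominator.

    The sign carries direction.  Zero-variance differences are undefined and
    raise :class:`AnalysisError`.
    """
    x1 = np.asarray(values_p1, dtype=float)
    x2 = np.asarray(values_p2, dtype=float)
    if len(x1) != len(x2) or len(x1) < 2:
        raise AnalysisError("cohens_d_paired needs >=2 paired values")
    diff = x2 - x1
    sd = diff.std(ddof=1)
    if sd == 0.0:
        raise AnalysisError("cohens_d_paired: zero SD of differences")
    return float(diff.mean() / sd)


def bonferroni_posthoc(data: pd.DataFrame, pairs=BASELINE_PAIRS,
                       family_size: int = DEFAULT_FAMILY_SIZE) -> pd.DataFrame:
    """Paired t comparisons of period means with Bonferroni correction.

    The family size defaults to 6 (all pairs of four periods) even though
    only the three baseline-containing pairs are reported, matching common
    statistical-package behavior.  Corrected p values clamp at 1.
    """
    rows = []
    for p1, p2 in pairs:
        sub = data.dropna(subset=[p1, p2])
        diff = (sub[p2] - sub[p1]).to_numpy(dtype=float)
        n = len(diff)
        if n < 2 or diff.std(ddof=1) == 0.0:
            log.warning("bonferroni_posthoc %s-%s: zero variance or n<2; "
                        "p reported missing", p1, p2)
            rows.append({"pair": f"{p1} & {p2}", "n": n,
                         "mean_diff": diff.mean() if n else np.nan,
                         "t": np.nan, "p_uncorrected": np.nan,
                         "p_bonferroni": np.nan, "cohens_d": np.nan,
                         "direction": "none"})
            continue
        se = diff.std(ddof=1) / np.sqrt(n)
        t = diff.mean() / se
        p_unc = float(2.0 * stats.t.sf(abs(t), n - 1))
        d = float(diff.mean() / diff.std(ddof=1))
        rows.append({
            "pair": f"{p1} & {p2}", "n": n, "mean_diff": float(diff.mean()),
            "t": float(t), "p_uncorrected": p_unc,
            "p_bonferroni": min(1.0, family_size * p_unc),
            "cohens_d": d,
            "direction": "increase" if diff.mean() > 0 else
                         ("decrease" if diff.mean() < 0 else "none"),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------- subgroup ANOVA

SUBGROUP_FACTORS = ("exposure", "age_group", "gender", "income_level",
                    "baseline_level")


def derive_subgroup_factors(profiles: pd.DataFrame, aggregates: pd.DataFrame,
                            indicator: str,
                            exposure: pd.DataFrame) -> pd.DataFrame:
    """Factor table for the subgroup delta-ANOVA of one indicator.

    Age splits younger (<=59) / older (>=60); the baseline level splits at
    the population median of the indicator's baseline-period weighted mean
    (ties count as at-or-above).  Unspecified income becomes missing (those
    participants drop out of the subgroup fit only).  Exposure is restricted
    to the affected groups (medium and high).
    """
    base = aggregates[(aggregates["indicator"] == indicator)
                      & (aggregates["period"] == "B")]
    base = base.dropna(subset=["weighted_mean"])
    med = base["weighted_mean"].median()
    baseline_level = pd.Series(
        np.where(base["weighted_mean"] >= med, "at_or_above_median",
                 "below_median"),
        index=base["participant_id"])

    df = profiles[["participant_id", "age", "gender", "income_level"]].copy()
    df["age_group"] = np.where(df["age"] <= 59, "younger", "older")
    df["income_level"] = df["income_level"].where(
        df["income_level"] != "unspecified")
    df = df.merge(exposure[["participant_id", "group"]], on="participant_id",
                  how="left").rename(columns={"group": "exposure"})
    df = df[df["exposure"].isin(["medium", "high"])]
    df["baseline_level"] = df["participant_id"].map(baseline_level)
    return df[["participant_id", "exposure", "age_group", "gender",
               "income_level", "baseline_level"]].reset_index(drop=True)


def _sum_coded(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (effect) coding; returns matrix and level order."""
    levels = sorted(pd.unique(values))
    L = len(levels)
    X = np.zeros((len(values), L - 1))
    idx = {lev: i for i, lev in enumerate(levels)}
    for r, v in enumerate(values):
        i = idx[v]
        if i < L - 1:
            X[r, i] = 1.0
        else:
            X[r, :] = -1.0
    return X, levels


@dataclass
class SubgroupAnovaResult:
    table: pd.DataFrame                    # per-factor SS, df, F, p
    adjusted_means: dict[str, dict[str, float]]
    n: int
    dropped_factors: list[str]


def subgroup_anova(deltas: pd.DataFrame,
                   factors: pd.DataFrame) -> SubgroupAnovaResult:
    """Additive Type-III between-subjects ANOVA of deltas on the five factors.

    Rows with any missing factor (e.g. unspecified income) are excluded.
    A factor left with fewer than two observed levels is dropped with a
    diagnostic instead of aborting the whole test.
    """
    df = deltas.merge(factors, on="participant_id", how="inner")
    df = df.dropna(subset=["delta", *SUBGROUP_FACTORS])
    n = len(df)
    if n < len(SUBGROUP_FACTORS) + 2:
        raise AnalysisError(f"subgroup_anova: only {n} complete cases")

    dropped = []
    used = []
    blocks: dict[str, tuple[np.ndarray, list[str]]] = {}
    for f in SUBGROUP_FACTORS:
        X, levels = _sum_coded(df[f])
        if len(levels) < 2:
            dropped.append(f)
            log.warning("subgroup_anova: factor %s has a single observed "
                        "level (%s); dropped", f, levels)
            continue
        used.append(f)
        blocks[f] = (X, levels)

    y = df["delta"].to_numpy(dtype=float)
    ones = np.ones((n, 1))

    def rss(mat: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(mat, y, rcond=None)
        r = y - mat @ beta
        return float(r @ r)

    X_full = np.hstack([ones] + [blocks[f][0] for f in used])
    rss_full = rss(X_full)
    rank_full = np.linalg.matrix_rank(X_full)
    df_err = n - rank_full
    mse = rss_full / df_err if df_err > 0 else np.nan

    rows = {}
    for f in used:
        X_red = np.hstack([ones] + [blocks[g][0] for g in used if g != f])
        ss = max(0.0, rss(X_red) - rss_full)
        dfree = blocks[f][0].shape[1]
        if np.isfinite(mse) and mse > 0:
            F = (ss / dfree) / mse
            pval = float(stats.f.sf(F, dfree, df_err))
        else:
            F, pval = np.nan, np.nan
        rows[f] = (ss, dfree, F, pval)
    rows["residual"] = (rss_full, df_err, np.nan, np.nan)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["SS", "df", "F", "p"])

    # adjusted (marginal) means per level from the sum-coded fit
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    offset = 1
    adjusted: dict[str, dict[str, float]] = {}
    for f in used:
        X, levels = blocks[f]
        k = X.shape[1]
        coefs = beta[offset:offset + k]
        effects = list(coefs) + [-float(np.sum(coefs))]
        adjusted[f] = {lev: float(beta[0] + e)
                       for lev, e in zip(levels, effects)}
        offset += k
    return SubgroupAnovaResult(table=table, adjusted_means=adjusted,
                               n=n, dropped_factors=dropped)


# -------------------------------------------------------------- results table

def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def direction_arrow(mean_diff: float) -> str:
    if not np.isfinite(mean_diff) or mean_diff == 0:
        return ""
    return "↑" if mean_diff > 0 else "↓"


def build_results_table(mixed: dict[str, MixedAnovaResult],
                        posthoc: dict[str, pd.DataFrame],
                        group_posthoc: dict[str, dict[str, pd.DataFrame]] | None = None
                        ) -> pd.DataFrame:
    """One row per indicator: main/interaction p values, per-pair corrected p,
    stars and direction arrows — the report structure of the headline table.

    ``group_posthoc`` optionally carries per-exposure-group post hoc tables
    keyed as [indicator][group].
    """
    rows = []
    for ind, res in mixed.items():
        row: dict[str, object] = {"indicator": ind}
        p_period = res.p_value("period")
        p_inter = res.p_value("period:group")
        row["period_p"] = p_period
        row["period_stars"] = significance_stars(p_period)
        row["interaction_p"] = p_inter
        row["interaction_stars"] = significance_stars(p_inter)
        ph = posthoc.get(ind)
        if ph is not None:
            for r in ph.itertuples(index=False):
                tag = r.pair.replace(" & ", "_")
                row[f"{tag}_p"] = r.p_bonferroni
                row[f"{tag}_stars"] = significance_stars(r.p_bonferroni)
                row[f"{tag}_arrow"] = (direction_arrow(r.mean_diff)
                                       if significance_stars(r.p_bonferroni)
                                       else "")
                row[f"{tag}_d"] = r.cohens_d
        if group_posthoc and ind in group_posthoc:
            for grp, ph_g in group_posthoc[ind].items():
                for r in ph_g.itertuples(index=False):
                    tag = f"{grp}_{r.pair.replace(' & ', '_')}"
                    row[f"{tag}_p"] = r.p_bonferroni
                    row[f"{tag}_stars"] = significance_stars(r.p_bonferroni)
                    row[f"{tag}_arrow"] = (direction_arrow(r.mean_diff)
                                           if significance_stars(r.p_bonferroni)
                                           else "")
        rows.append(row)
    return pd.DataFrame(rows)


def format_results_text(table: pd.DataFrame) -> str:
    """Plain-text rendering of the results table."""

    def mark(x) -> str:   # CSV round-trips empty marks as NaN
        return x if isinstance(x, str) else ""

    lines = []
    for r in table.itertuples(index=False):
        d = r._asdict()
        parts = [f"{d['indicator']:<16}",
                 f"period p={d['period_p']:.4g}{mark(d['period_stars'])}",
                 f"interaction p={d['interaction_p']:.4g}"
                 f"{mark(d['interaction_stars'])}"]
        for pair in ("B_W", "B_R1", "B_R2"):
            if f"{pair}_p" in d and np.isfinite(d[f"{pair}_p"]):
                parts.append(f"{pair}: p={d[f'{pair}_p']:.4g}"
                             f"{mark(d[f'{pair}_stars'])}"
                             f"{mark(d[f'{pair}_arrow'])}")
        lines.append("  ".join(parts))
    return "\n".join(lines)
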