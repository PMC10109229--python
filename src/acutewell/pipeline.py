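"""End-to-end orchestration: cohort tables in, result tables out.

The full analysis chain is: label and clean the raw tables, infer exposure
groups from GPS (hometown fallback), aggregate daily indicators to weighted
period means, apply per-indicator inclusion filters, run the split-plot
mixed ANOVA with Bonferroni post hoc per indicator, run the subgroup
delta-ANOVA on the affected exposure groups, and compute the siren
heart-rate response statistic.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import anova, exposure, siren
from .errors import AnalysisError
from .io import CohortBundle, build_indicator_table
from .studycal import PERIODS

log = logging.getLogger(__name__)


def build_mixed_input(aggregates: pd.DataFrame, exposure_df: pd.DataFrame,
                      indicator: str,
                      eligible: dict[str, set] | None = None,
                      periods=PERIODS) -> pd.DataFrame:
    """Wide complete-case table (group + one column per period) for one indicator."""
    sub = aggregates[aggregates["indicator"] == indicator]
    if eligible is not None:
        sub = sub[sub["participant_id"].isin(eligible.get(indicator, set()))]
    wide = (sub.pivot_table(index="participant_id", columns="period",
                            values="weighted_mean", aggfunc="first",
                            observed=True)
            .reindex(columns=list(periods)))
    wide = wide.merge(
        exposure_df.set_index("participant_id")[["group"]],
        left_index=True, right_index=True, how="inner")
    return wide.dropna().reset_index()


def analyze_indicator(aggregates: pd.DataFrame, exposure_df: pd.DataFrame,
                      indicator: str,
                      eligible: dict[str, set] | None = None,
                      family_size: int = anova.DEFAULT_FAMILY_SIZE,
                      greenhouse_geisser: bool = False) -> dict:
    """Mixed ANOVA + overall and per-group post hoc for one indicator."""
    data = build_mixed_input(aggregates, exposure_df, indicator, eligible)
    result = anova.mixed_anova(data, greenhouse_geisser=greenhouse_geisser)
    ph = anova.bonferroni_posthoc(data, family_size=family_size)
    per_group = {
        g: anova.bonferroni_posthoc(data[data["group"] == g],
                                    family_size=family_size)
        for g in data["group"].unique()
    }
    return {"input": data, "mixed": result, "posthoc": ph,
            "group_posthoc": per_group}


def run_study(bundle: CohortBundle,
              reference=exposure.DEFAULT_REFERENCE,
              indicators: list[str] | None = None,
              family_size: int = anova.DEFAULT_FAMILY_SIZE,
              subgroup_indicators: list[str] | None = None,
              run_sirens: bool = True) -> dict:
    """Run the full pipeline on a cohort bundle.

    Returns a dict with the exposure table, period aggregates, eligibility
    sets, per-indicator mixed-ANOVA results, the formatted results table,
    subgroup ANOVA results, and (when heart-rate data are present) the siren
    response summary.
    """
    records = build_indicator_table(bundle)
    exposure_df = exposure.assign_exposure(bundle.profiles, bundle.gps,
                                           bundle.calendar, reference)
    aggregates = agg.period_aggregates(records)
    eligible4 = agg.apply_inclusion_filter(aggregates, PERIODS)
    eligible2 = agg.apply_inclusion_filter(aggregates, ("B", "W"))

    if indicators is None:
        indicators = sorted(aggregates["indicator"].unique())
    mixed, posthoc, group_posthoc, failures = {}, {}, {}, {}
    for ind in indicators:
        try:
            out = analyze_indicator(aggregates, exposure_df, ind, eligible4,
                                    family_size)
        except AnalysisError as exc:
            failures[ind] = str(exc)
            log.warning("indicator %s: %s", ind, exc)
            continue
        mixed[ind] = out["mixed"]
        posthoc[ind] = out["posthoc"]
        group_posthoc[ind] = out["group_posthoc"]

    results_table = anova.build_results_table(mixed, posthoc, group_posthoc)

    deltas_bw = agg.period_delta(aggregates, "B", "W", eligible2)
    subgroup = {}
    for ind in (subgroup_indicators if subgroup_indicators is not None
                else indicators):
        sub_deltas = deltas_bw[deltas_bw["indicator"] == ind]
        factors = anova.derive_subgroup_factors(
            bundle.profiles, aggregates, ind, exposure_df)
        try:
            subgroup[ind] = anova.subgroup_anova(sub_deltas, factors)
        except AnalysisError as exc:
            failures[f"subgroup:{ind}"] = str(exc)

    out = {
        "records": records,
        "exposure": exposure_df,
        "aggregates": aggregates,
        "eligible": eligible4,
        "mixed": mixed,
        "posthoc": posthoc,
        "group_posthoc": group_posthoc,
        "results_table": results_table,
        "deltas_bw": deltas_bw,
        "subgroup": subgroup,
        "failures": failures,
    }
    if run_sirens and len(bundle.heart_rate) and len(bundle.sirens):
        try:
            out["siren"] = siren.siren_response_analysis(
                bundle.heart_rate, bundle.sirens, exposure_df)
        except AnalysisError as exc:
            failures["siren"] = str(exc)
    return out


def recovered_paired_d(aggregates: pd.DataFrame, exposure_df: pd.DataFrame,
                       indicator: str, groups=("medium", "high"),
                       p1: str = "B", p2: str = "W") -> float:
    """Paired Cohen's d of p1->p2 weighted-mean changes in the given groups.

    This is the pipeline's effect-size recovery metric: participants must
    pass the two-period inclusion filter for the indicator.
    """
    eligible = agg.apply_inclusion_filter(aggregates, (p1, p2))
    deltas = agg.period_delta(aggregates, p1, p2, eligible)
    deltas = deltas[deltas["indicator"] == indicator]
    keep = exposure_df.loc[exposure_df["group"].isin(groups), "participant_id"]
    d = deltas[deltas["participant_id"].isin(set(keep))]["delta"].to_numpy()
    if len(d) < 2 or d.std(ddof=1) == 0:
        raise AnalysisError("recovered_paired_d: degenerate delta sample")
    return float(d.mean() / d.std(ddof=1))
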