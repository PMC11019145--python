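"""Score transfer, composite endpoints, and outcome association models.

Covers applying training-cohort metabolite weights to a second cohort,
building the time-to-first-event composite ("healthy ager" flag),
proportional-hazards association of scores with endpoints (HR per SD,
serial adjustment tiers, Efron ties), Kaplan-Meier curves by score
tertile, and the score x phenotype linear association grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from metabaxes.integrate import AgingAxes, MetabolicScores, compute_scores
from metabaxes.mwas import mwas_scan

COMPOSITE_COMPONENTS = ("CVD", "cancer", "dementia", "disability", "death")
MINIMAL_TIER = ("age", "sex", "race")
FULL_TIER = MINIMAL_TIER + (
    "education",
    "smoker",
    "bmi",
    "hypertension",
    "diabetes",
    "cystatin_c",
)


class OutcomeError(ValueError):
    pass


@dataclass
class CoxSpec:
    adjustment_tier: str = "minimal"  # "minimal" | "full" | "none"
    covariates: tuple[str, ...] | None = None
    per_sd: bool = True

    def tier_covariates(self) -> tuple[str, ...]:
        if self.covariates is not None:
            return self.covariates
        if self.adjustment_tier == "minimal":
            return MINIMAL_TIER
        if self.adjustment_tier == "full":
            return FULL_TIER
        if self.adjustment_tier == "none":
            return ()
        raise OutcomeError(f"unknown adjustment tier {self.adjustment_tier!r}")


def transfer_scores(
    axes: AgingAxes, Z_target: pd.DataFrame, cohort: str = "target",
    zero_fill: bool = False,
) -> MetabolicScores:
    """Apply training-cohort metabolite weights to a second cohort.

    ``Z_target`` must be preprocessed cohort-locally (imputation, log,
    standardization within the target cohort).  Alignment is by
    metabolite id; missing metabolites raise unless ``zero_fill``.
    Scores are re-standardized within the target cohort and inherit the
    training axes' signs and labels.
    """
    available = axes.weights.index.isin(Z_target.columns).mean()
    if zero_fill and available < 0.90:
        warnings.warn(
            f"only {available:.1%} of weighted metabolites available in "
            f"cohort {cohort!r}",
            stacklevel=2,
        )
    scores = compute_scores(axes.weights, Z_target, cohort=cohort, zero_fill=zero_fill)
    scores.labels = dict(axes.labels) if axes.labels else None
    return scores


@dataclass
class CompositeResult:
    table: pd.DataFrame       # participant_id, time_years, event, healthy_ager
    excluded: list[str]       # baseline-prevalent participants
    flagged_missing: list[str]


def build_composite(
    outcomes: pd.DataFrame,
    horizon_years: float = 10.0,
    components: tuple[str, ...] = COMPOSITE_COMPONENTS,
) -> CompositeResult:
    """Time-to-first-event composite with administrative censoring.

    ``outcomes`` is long format (participant_id, endpoint, time_years,
    event, prevalent).  Participants prevalent for any component at
    baseline are excluded.  Composite time is the minimum component
    time; the composite event fires iff the first occurrence is an
    event.  A participant missing some component endpoint is censored at
    their last contact across available components and flagged.  The
    healthy-ager flag is true when the participant is event-free and
    under observation through the horizon.
    """
    if (outcomes["time_years"] <= 0).any():
        bad = outcomes.loc[outcomes["time_years"] <= 0, "participant_id"].tolist()
        raise OutcomeError(f"non-positive follow-up time for: {bad[:5]}")
    comp = outcomes[outcomes["endpoint"].isin(components)]
    prevalent = comp.loc[comp["prevalent"] == 1, "participant_id"].unique()
    comp = comp[~comp["participant_id"].isin(prevalent)]

    rows = []
    flagged = []
    for pid, grp in comp.groupby("participant_id", sort=True):
        have = set(grp["endpoint"])
        missing_components = set(components) - have
        t_first = grp["time_years"].min()
        first_rows = grp[grp["time_years"] == t_first]
        event = int(first_rows["event"].max())
        if missing_components and not event:
            flagged.append(str(pid))
        time = min(t_first, horizon_years)
        if t_first > horizon_years:
            event = 0
        healthy = (not event) and t_first >= horizon_years and not missing_components
        rows.append(
            {
                "participant_id": pid,
                "time_years": float(time),
                "event": event,
                "healthy_ager": bool(healthy),
            }
        )
    table = pd.DataFrame(rows)
    return CompositeResult(
        table=table,
        excluded=[str(p) for p in prevalent],
        flagged_missing=flagged,
    )


@dataclass
class CoxResult:
    endpoint: str
    tier: str
    hr_per_sd: float
    ci_low: float
    ci_high: float
    log_hr: float
    se: float
    p: float
    n: int
    n_events: int
    reciprocal_hr: float = field(init=False)

    def __post_init__(self) -> None:
        # convenience for "protective" presentation: >1 means protective
        # when the modeled event is composite failure
        self.reciprocal_hr = 1.0 / self.hr_per_sd


def fit_cox(
    score: pd.Series,
    endpoint_table: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    spec: CoxSpec | None = None,
    endpoint: str = "composite",
) -> CoxResult:
    """HR per +1 SD of the score from an Efron-ties Cox model.

    ``endpoint_table`` is indexed by participant id with columns
    ``time_years`` and ``event``.  Adjustment covariates are taken from
    ``covariates`` per the CoxSpec tier.  For a composite-failure endpoint
    the protective "healthy aging" presentation is the reciprocal HR,
    exposed as ``reciprocal_hr``.
    """
    spec = spec or CoxSpec()
    tier_cols = spec.tier_covariates()
    frame = endpoint_table[["time_years", "event"]].copy()
    s = score.reindex(frame.index)
    if spec.per_sd:
        sd = s.std(ddof=1)
        if not sd > 0:
            raise OutcomeError("score has zero variance")
        s = (s - s.mean()) / sd
    frame["score"] = s
    if tier_cols:
        if covariates is None:
            raise OutcomeError("covariates required for adjusted tiers")
        missing = [c for c in tier_cols if c not in covariates.columns]
        if missing:
            raise OutcomeError(f"covariates missing from table: {missing}")
        frame = frame.join(covariates[list(tier_cols)])
    frame = frame.dropna()
    n_events = int(frame["event"].sum())
    if n_events == 0:
        raise OutcomeError(f"no events for endpoint {endpoint!r}")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time_years", event_col="event")
    except Exception as exc:  # convergence and design failures
        raise OutcomeError(f"Cox model failed for {endpoint!r}: {exc}") from exc
    row = cph.summary.loc["score"]
    return CoxResult(
        endpoint=endpoint,
        tier=spec.adjustment_tier,
        hr_per_sd=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        log_hr=float(row["coef"]),
        se=float(row["se(coef)"]),
        p=float(row["p"]),
        n=len(frame),
        n_events=n_events,
    )


def km_by_tertile(
    score: pd.Series,
    endpoint_table: pd.DataFrame,
    n_groups: int = 3,
) -> pd.DataFrame:
    """Kaplan-Meier product-limit curves per score tertile.

    Cuts at the empirical 1/3 and 2/3 quantiles (or ``n_groups``
    quantile groups generally; 1 disables stratification).  Returns a
    long table (stratum, time, survival, at_risk, events, censored).
    Raises if tied quantile boundaries collapse a stratum.
    """
    if score.nunique() < 3:
        raise OutcomeError("need at least 3 distinct score values")
    frame = endpoint_table[["time_years", "event"]].join(score.rename("score")).dropna()
    if n_groups == 1:
        frame["stratum"] = "all"
    else:
        try:
            frame["stratum"] = pd.qcut(
                frame["score"], n_groups,
                labels=[f"T{i + 1}" for i in range(n_groups)],
            )
        except ValueError as exc:
            raise OutcomeError(
                "tied score boundaries collapse a stratum; consider jittering "
                f"quantiles: {exc}"
            ) from exc
    out = []
    kmf = KaplanMeierFitter()
    for stratum, grp in frame.groupby("stratum", observed=True):
        kmf.fit(grp["time_years"], grp["event"], label=str(stratum))
        ev = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        for t in ev.index:
            out.append(
                {
                    "stratum": str(stratum),
                    "time_years": float(t),
                    "survival": float(surv.loc[t]),
                    "at_risk": int(ev.loc[t, "at_risk"]),
                    "events": int(ev.loc[t, "observed"]),
                    "censored": int(ev.loc[t, "censored"]),
                }
            )
    return pd.DataFrame(out)


def association_grid(
    scores: pd.DataFrame,
    phenotypes: pd.DataFrame,
    covariates: pd.DataFrame,
    tiers: dict[str, tuple[str, ...]] | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-SD score effects on each phenotype with BH flags per tier.

    Reuses the MWAS machinery with scores in the metabolite slot: each
    cell is the OLS coefficient of the (standardized) score in a model
    for the harmonized phenotype with tier covariates.  BH adjustment is
    applied across the grid within each tier.
    """
    tiers = tiers or {"minimal": MINIMAL_TIER}
    results = []
    for tier, cols in tiers.items():
        missing = [c for c in cols if c not in covariates.columns]
        if missing:
            raise OutcomeError(f"tier {tier!r} covariates missing: {missing}")
        res = mwas_scan(
            phenotypes=phenotypes,
            metabolites=scores,
            covariates=covariates[list(cols)],
            fdr_level=fdr_level,
            scope="global",
        )
        res = res.rename(columns={"metabolite_id": "score_id"})
        res["tier"] = tier
        res = res.drop(columns=["domain"])
        results.append(res)
    return pd.concat(results, ignore_index=True)
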