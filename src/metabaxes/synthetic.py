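"""Synthetic two-cohort generator with planted latent aging axes.

A small number of latent axes drive (a) log metabolite intensities,
(b) a correlated multi-domain phenotype panel, and (c) exponential
proportional-hazards event times per endpoint — so every downstream
stage of the pipeline can be checked against ground truth.  A paired
"younger" cohort reuses the same loading matrices with attenuated axis
variance and a lower event rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from metabaxes.preprocess import MetaboliteMatrix

DOMAINS = (
    "physical_function",
    "neurocognitive",
    "adiposity_sarcopenia",
    "vascular",
    "dietary_pattern",
    "physical_activity",
    "psychosocial_stress",
)

ENDPOINTS = ("CVD", "cancer", "dementia", "disability", "death")


class ConfigError(ValueError):
    """A GeneratorConfig field violates its invariant."""


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 2000
    n_metabolites: int = 300
    n_phenotypes: int = 20
    n_axes: int = 4
    domain_map: tuple[str, ...] | None = None
    metabolite_loading_sparsity: float = 0.22
    snr_phenotype: float = 4.0
    snr_metabolite: float = 3.0
    # per-axis multipliers on snr_phenotype; staggered so the planted axes
    # have distinct variance shares (separated PCA eigenvalues).  None
    # derives a geometric ladder 2.0 * 0.62**axis.
    axis_snr_multipliers: tuple[float, ...] | None = None
    lod_quantile: float = 0.05
    extra_missing_rate: float = 0.01
    qc_replicates: int = 20
    cv_target: float = 0.05
    log_hr_per_sd: tuple[float, ...] = (-0.30, -0.20, -0.15, -0.10)
    baseline_hazard: float = 0.05
    followup_years: float = 10.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.05, "sex": 0.10, "race": 0.05}
    )
    axis_scale: float = 1.0
    age_mean: float = 74.0
    age_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_axes > min(self.n_metabolites, self.n_phenotypes):
            raise ConfigError("n_axes must be <= min(n_metabolites, n_phenotypes)")
        for name in ("metabolite_loading_sparsity", "lod_quantile", "extra_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_participants", "n_metabolites", "n_phenotypes", "n_axes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.followup_years <= 0:
            raise ConfigError("followup_years must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.snr_phenotype <= 0 or self.snr_metabolite <= 0:
            raise ConfigError("snr_phenotype and snr_metabolite must be > 0")
        if len(self.log_hr_per_sd) != self.n_axes:
            raise ConfigError(
                f"log_hr_per_sd must have length n_axes={self.n_axes}, "
                f"got {len(self.log_hr_per_sd)}"
            )
        if self.domain_map is not None and len(self.domain_map) != self.n_phenotypes:
            raise ConfigError("domain_map must assign a domain to every phenotype")
        if self.axis_scale <= 0:
            raise ConfigError("axis_scale must be > 0")
        if self.axis_snr_multipliers is not None:
            if len(self.axis_snr_multipliers) != self.n_axes:
                raise ConfigError("axis_snr_multipliers must have length n_axes")
            if any(m <= 0 for m in self.axis_snr_multipliers):
                raise ConfigError("axis_snr_multipliers must be > 0")
        if self.qc_replicates < 0:
            raise ConfigError("qc_replicates must be >= 0")


@dataclass
class CohortTruth:
    """Ground truth planted by the generator."""

    axes: pd.DataFrame                 # participants x k latent axis values
    metabolite_loadings: pd.DataFrame  # metabolites x k log-intensity loadings
    phenotype_axis: pd.Series          # phenotype -> driving axis index
    log_hr_per_sd: np.ndarray
    linear_predictor: pd.Series        # per-participant log relative hazard


@dataclass
class SyntheticCohort:
    metabolites: MetaboliteMatrix
    phenotypes: pd.DataFrame
    phenotype_meta: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame  # long: participant_id, endpoint, time_years, event, prevalent
    truth: CohortTruth
    config: GeneratorConfig


def default_domain_map(n_phenotypes: int, n_axes: int) -> tuple[str, ...]:
    """Block-structured domain assignment.

    Phenotypes are arranged in ``n_axes`` contiguous blocks (one per
    axis).  Most phenotypes in a block share one of the first ``n_axes``
    domains; leftover domains are sprinkled on block tails so all seven
    appear.
    """
    block = math.ceil(n_phenotypes / n_axes)
    domains = []
    spare = list(DOMAINS[n_axes:])
    for j in range(n_phenotypes):
        axis = min(j // block, n_axes - 1)
        pos = j % block
        if pos == block - 1 and spare:
            domains.append(spare.pop(0))
        else:
            domains.append(DOMAINS[axis % len(DOMAINS)])
    return tuple(domains)


def _phenotype_axis_blocks(p: int, k: int) -> np.ndarray:
    """Contiguous axis blocks with staggered sizes.

    Block sizes start from an even split and shift phenotypes from the
    trailing axes to the first (e.g. 7/5/4/4 for p=20, k=4), so planted
    axes have distinct phenotype counts — separated PCA eigenvalues
    downstream, avoiding component rotation between adjacent axes.
    """
    base, rem = divmod(p, k)
    sizes = [base + (1 if a < rem else 0) for a in range(k)]
    if k >= 3 and sizes[-1] > 1 and sizes[-2] > 1:
        sizes[0] += 2
        sizes[-1] -= 1
        sizes[-2] -= 1
    elif k == 2 and sizes[-1] > 1:
        sizes[0] += 1
        sizes[-1] -= 1
    return np.repeat(np.arange(k), sizes)


@dataclass
class _CohortModel:
    """Loading matrices and noise scales shared between paired cohorts."""

    loadings: np.ndarray        # m x k
    met_noise_sd: np.ndarray    # m
    met_baseline: np.ndarray    # m, baseline log intensity
    phen_axis: np.ndarray       # p, axis index per phenotype
    phen_noise_sd: np.ndarray   # p
    phen_meta: pd.DataFrame
    domains: tuple[str, ...]


def _build_model(config: GeneratorConfig, rng: np.random.Generator) -> _CohortModel:
    m, p, k = config.n_metabolites, config.n_phenotypes, config.n_axes
    loadings = np.zeros((m, k))
    n_load = max(1, round(config.metabolite_loading_sparsity * m))
    # axis supports are disjoint while the pool lasts (keeps cross-axis
    # leakage out of the planted scores); overlap only when k*sparsity > 1
    pool = list(rng.permutation(m))
    for a in range(k):
        if len(pool) < n_load:
            used = set(pool)
            refill = [i for i in rng.permutation(m) if i not in used]
            pool += refill
        idx = [pool.pop() for _ in range(n_load)]
        loadings[idx, a] = rng.standard_normal(n_load)

    signal_var = (loadings**2).sum(axis=1)
    # snr may be inf (noise-free limit); metabolites loading on no axis get
    # unit-free noise so they are not constant columns
    with np.errstate(divide="ignore"):
        scaled = np.sqrt(signal_var / config.snr_metabolite)
    met_noise_sd = np.where(signal_var > 0, scaled, 0.5)
    met_baseline = rng.normal(10.0, 1.0, size=m)

    phen_axis = _phenotype_axis_blocks(p, k)
    mult = config.axis_snr_multipliers or tuple(2.0 * 0.62**a for a in range(k))
    snr = config.snr_phenotype * np.asarray(mult)[phen_axis]
    with np.errstate(divide="ignore"):
        phen_noise_sd = np.where(np.isfinite(snr), 1.0 / np.sqrt(snr), 0.0)

    domains = config.domain_map or default_domain_map(p, k)
    phen_ids = [f"phen_{j:02d}" for j in range(p)]
    meta = pd.DataFrame(
        {
            "domain": list(domains),
            "adverse": [(j % 4 == 3) for j in range(p)],
            "transform": ["log" if j % 5 == 2 else "none" for j in range(p)],
            "index_to_height": [j % 5 == 4 for j in range(p)],
        },
        index=pd.Index(phen_ids, name="phenotype_id"),
    )
    return _CohortModel(
        loadings=loadings,
        met_noise_sd=met_noise_sd,
        met_baseline=met_baseline,
        phen_axis=phen_axis,
        phen_noise_sd=phen_noise_sd,
        phen_meta=meta,
        domains=tuple(domains),
    )


def _sample_cohort(
    config: GeneratorConfig,
    model: _CohortModel,
    rng: np.random.Generator,
    cohort_tag: str,
) -> SyntheticCohort:
    n, m, p, k = (
        config.n_participants,
        config.n_metabolites,
        config.n_phenotypes,
        config.n_axes,
    )
    pid = [f"{cohort_tag}_{i:05d}" for i in range(n)]
    met_ids = [f"met_{j:04d}" for j in range(m)]
    phen_ids = list(model.phen_meta.index)

    # latent axes: exactly mean-0 / unit-sample-variance before scaling
    axes = rng.standard_normal((n, k))
    axes = (axes - axes.mean(axis=0)) / axes.std(axis=0, ddof=1)
    axes = axes * config.axis_scale

    # covariates
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = rng.integers(0, 2, size=n)
    race = (rng.random(n) < 0.4).astype(int)
    height = rng.normal(1.68, 0.09, size=n)
    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": race,
            "height_m": height,
            "education": (rng.random(n) < 0.75).astype(int),
            "smoker": (rng.random(n) < 0.10).astype(int),
            "bmi": rng.normal(27.0, 4.8, size=n),
            "hypertension": (rng.random(n) < 0.50).astype(int),
            "diabetes": (rng.random(n) < 0.14).astype(int),
            "cystatin_c": rng.normal(1.0, 0.2, size=n),
        },
        index=pd.Index(pid, name="participant_id"),
    )

    # metabolites: log intensity = baseline + axes @ L' + noise, exp to raw
    log_x = (
        model.met_baseline[None, :]
        + axes @ model.loadings.T
        + rng.standard_normal((n, m)) * model.met_noise_sd[None, :]
    )
    raw = np.exp(log_x)
    pooled_mean = raw.mean(axis=0)  # before censoring; basis for QC rows

    # LOD left-censoring: lowest lod_quantile of each column goes missing
    values = pd.DataFrame(raw.copy(), index=pid, columns=met_ids)
    if config.lod_quantile > 0:
        n_censor = int(np.floor(config.lod_quantile * n))
        if n_censor > 0:
            order = np.argsort(raw, axis=0)
            row_idx = order[:n_censor, :].ravel()
            col_idx = np.repeat(np.arange(m)[None, :], n_censor, axis=0).ravel()
            arr = values.to_numpy()
            arr[row_idx, col_idx] = np.nan
            values = pd.DataFrame(arr, index=pid, columns=met_ids)
    if config.extra_missing_rate > 0:
        mask = rng.random((n, m)) < config.extra_missing_rate
        values = values.mask(mask)
    values.index.name = "participant_id"

    # pooled-QC replicates: lognormal around the pooled mean with raw CV == cv_target
    qc = None
    if config.qc_replicates > 0:
        sigma = math.sqrt(math.log1p(config.cv_target**2))
        qc_log = (
            np.log(pooled_mean)[None, :]
            - 0.5 * sigma**2
            + sigma * rng.standard_normal((config.qc_replicates, m))
        )
        qc = pd.DataFrame(
            np.exp(qc_log),
            index=[f"QC_{i:03d}" for i in range(config.qc_replicates)],
            columns=met_ids,
        )

    # phenotypes: oriented linear image of one axis + covariate effects + noise
    eff = config.covariate_effects
    cov_term = (
        eff.get("age", 0.0) * (age - config.age_mean) / max(config.age_sd, 1e-12)
        + eff.get("sex", 0.0) * sex
        + eff.get("race", 0.0) * race
    )
    signal = axes[:, model.phen_axis]
    z = (
        signal
        + cov_term[:, None]
        + rng.standard_normal((n, p)) * model.phen_noise_sd[None, :]
    )
    meta = model.phen_meta
    raw_phen = np.empty_like(z)
    h_pow = height**1.7
    for j, phen in enumerate(phen_ids):
        col = -z[:, j] if meta.loc[phen, "adverse"] else z[:, j]
        if meta.loc[phen, "transform"] == "log":
            raw_phen[:, j] = np.exp(col)
        elif meta.loc[phen, "index_to_height"]:
            raw_phen[:, j] = col * h_pow
        else:
            raw_phen[:, j] = col
    phenotypes = pd.DataFrame(raw_phen, index=pid, columns=phen_ids)
    phenotypes.index.name = "participant_id"

    # outcomes: exponential PH per endpoint, administratively censored
    beta = np.asarray(config.log_hr_per_sd, dtype=float)
    lp = axes @ beta
    rate = config.baseline_hazard * np.exp(lp)
    records = []
    for endpoint in ENDPOINTS:
        t_event = rng.exponential(1.0 / rate)
        event = (t_event <= config.followup_years).astype(int)
        time = np.minimum(t_event, config.followup_years)
        for i in range(n):
            records.append((pid[i], endpoint, float(time[i]), int(event[i]), 0))
    outcomes = pd.DataFrame(
        records,
        columns=["participant_id", "endpoint", "time_years", "event", "prevalent"],
    )

    axes_df = pd.DataFrame(
        axes, index=pid, columns=[f"axis_{a}" for a in range(k)]
    )
    axes_df.index.name = "participant_id"
    truth = CohortTruth(
        axes=axes_df,
        metabolite_loadings=pd.DataFrame(
            model.loadings, index=met_ids, columns=[f"axis_{a}" for a in range(k)]
        ),
        phenotype_axis=pd.Series(model.phen_axis, index=phen_ids),
        log_hr_per_sd=beta,
        linear_predictor=pd.Series(lp, index=pid),
    )
    return SyntheticCohort(
        metabolites=MetaboliteMatrix(values=values, qc=qc),
        phenotypes=phenotypes,
        phenotype_meta=meta.copy(),
        covariates=covariates,
        outcomes=outcomes,
        truth=truth,
        config=config,
    )


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate one cohort; identical config + seed gives identical tables."""
    ss = np.random.SeedSequence(config.seed)
    model_seed, cohort_seed, _ = ss.spawn(3)
    model = _build_model(config, np.random.default_rng(model_seed))
    return _sample_cohort(config, model, np.random.default_rng(cohort_seed), "P")


def generate_cohort_pair(
    config: GeneratorConfig,
    young_axis_scale: float = 0.6,
    young_baseline_hazard: float | None = None,
    young_n_participants: int | None = None,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Generate an older cohort plus a younger one sharing its loading matrices.

    The younger cohort draws fresh participants with attenuated axis
    variance (``young_axis_scale``) and a lower event rate, mirroring a
    transfer-validation design.
    """
    ss = np.random.SeedSequence(config.seed)
    model_seed, older_seed, younger_seed = ss.spawn(3)
    model = _build_model(config, np.random.default_rng(model_seed))
    older = _sample_cohort(config, model, np.random.default_rng(older_seed), "P")
    young_cfg = replace(
        config,
        axis_scale=config.axis_scale * young_axis_scale,
        baseline_hazard=young_baseline_hazard or config.baseline_hazard / 3.0,
        n_participants=young_n_participants or config.n_participants,
        age_mean=32.0,
        age_sd=3.6,
    )
    younger = _sample_cohort(
        young_cfg, model, np.random.default_rng(younger_seed), "Y"
    )
    return older, younger


@dataclass
class AlignmentResult:
    pairs: list[tuple[str, str]]      # (truth axis, estimated axis)
    correlations: list[float]         # matched |Pearson r|, same order
    unmatched_truth: list[str]

    def min_abs_r(self) -> float:
        return min(self.correlations) if self.correlations else 0.0


def truth_alignment(
    truth_axes: pd.DataFrame, estimated_scores: pd.DataFrame
) -> AlignmentResult:
    """Match estimated axes to truth axes maximizing total |Pearson r|.

    One-to-one assignment via the Hungarian algorithm on the absolute
    correlation matrix.  If fewer estimated axes than truth axes are
    supplied, a partial matching is returned with the unmatched truth
    axes listed.
    """
    if len(truth_axes) != len(estimated_scores):
        raise ValueError(
            "truth and estimated tables must have equal participant counts"
        )
    est = estimated_scores.reindex(truth_axes.index)
    if est.isna().any().any():
        raise ValueError("participant ids of estimated scores do not match truth")
    t = truth_axes.to_numpy(dtype=float)
    e = est.to_numpy(dtype=float)
    t_c = t - t.mean(axis=0)
    e_c = e - e.mean(axis=0)
    denom = np.outer(
        np.linalg.norm(t_c, axis=0), np.linalg.norm(e_c, axis=0)
    )
    corr = np.abs(t_c.T @ e_c) / np.where(denom == 0, np.nan, denom)
    corr = np.nan_to_num(corr, nan=0.0)
    row, col = linear_sum_assignment(-corr)
    pairs = [
        (str(truth_axes.columns[r]), str(est.columns[c])) for r, c in zip(row, col)
    ]
    matched_truth = {p[0] for p in pairs}
    unmatched = [str(c) for c in truth_axes.columns if str(c) not in matched_truth]
    return AlignmentResult(
        pairs=pairs,
        correlations=[float(corr[r, c]) for r, c in zip(row, col)],
        unmatched_truth=unmatched,
    )


def expected_event_count(
    linear_predictor: np.ndarray | pd.Series,
    baseline_hazard: float,
    followup_years: float,
) -> tuple[float, float]:
    """Closed-form expected events and binomial SD under exponential hazard.

    Conditional on the realized linear predictors, each participant's
    event probability before administrative censoring at ``followup_years``
    is ``1 - exp(-h0 * exp(lp) * T)``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    prob = 1.0 - np.exp(-baseline_hazard * np.exp(lp) * followup_years)
    return float(prob.sum()), float(np.sqrt((prob * (1.0 - prob)).sum()))
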