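"""LASSO-coefficient-matrix PCA: axes, weights, and metabolic scores.

The core integration method: prune highly correlated metabolites, fit a
cross-validated LASSO of each harmonized phenotype on the pruned
standardized metabolite panel, stack the coefficient vectors into a
metabolites x phenotypes matrix B, and take the PCA of B.  Right
singular vectors are phenotype-space loadings, metabolite projections
are per-metabolite weights, and standardized linear combinations of the
weights with standardized metabolite levels give per-participant
metabolic scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold


class IntegrationError(ValueError):
    pass


PRUNE_THRESHOLD_DEFAULT = 0.8
MIN_PROP_DEFAULT = 0.10


@dataclass
class PruneLog:
    """Removal trace: order, triggering pair, and mean |r| at removal."""

    removed: list[str]
    trigger_pairs: list[tuple[str, str]]
    mean_abs_corr: list[float]


def prune_correlated(
    X: pd.DataFrame, threshold: float = PRUNE_THRESHOLD_DEFAULT
) -> tuple[list[str], PruneLog]:
    """Iteratively drop metabolites until all pairwise |r| <= threshold.

    While any pair exceeds the threshold, the metabolite with the largest
    mean absolute correlation against all currently retained metabolites
    (among those participating in a violating pair) is removed, and the
    means are recomputed.  Ties break toward the lower column index.
    """
    if X.shape[1] < 2:
        return list(X.columns), PruneLog([], [], [])
    sd = X.std(axis=0, ddof=1)
    if (sd <= 0).any() or sd.isna().any():
        bad = X.columns[(sd <= 0) | sd.isna()].tolist()
        raise IntegrationError(f"constant metabolite columns: {bad}")
    corr = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    cols = list(X.columns)
    active = list(range(len(cols)))
    log = PruneLog([], [], [])
    while True:
        sub = corr[np.ix_(active, active)]
        viol = sub > threshold
        if not viol.any():
            break
        in_pair = viol.any(axis=0)
        mean_abs = sub.mean(axis=1) * len(active) / max(len(active) - 1, 1)
        candidates = np.where(in_pair)[0]
        worst_local = candidates[np.argmax(mean_abs[candidates])]
        partner_local = int(np.argmax(sub[worst_local]))
        log.removed.append(cols[active[worst_local]])
        log.trigger_pairs.append(
            (cols[active[worst_local]], cols[active[partner_local]])
        )
        log.mean_abs_corr.append(float(mean_abs[worst_local]))
        del active[worst_local]
    kept = [cols[i] for i in active]
    return kept, log


@dataclass
class LassoFit:
    coefficients: pd.Series
    alpha: float
    cv_rule: str


def fit_lasso_phenotype(
    y: pd.Series,
    X: pd.DataFrame,
    folds: int = 10,
    cv_seed: int = 0,
    rule: str = "min",
    n_alphas: int = 50,
    eps: float = 5e-3,
    max_iter: int = 20000,
) -> LassoFit:
    """Cross-validated LASSO of one phenotype on the metabolite panel.

    X must already be standardized; no internal re-standardization is
    applied.  The penalty is chosen at minimum mean CV error (``rule`` =
    ``"min"``) or by the one-standard-error rule (``"1se"``).  Unselected
    metabolites are exact zeros; the intercept is not returned.
    """
    if rule not in ("min", "1se"):
        raise IntegrationError(f"unknown CV rule {rule!r}")
    frame = pd.concat([y.rename("__y"), X], axis=1).dropna()
    if len(frame) <= folds:
        raise IntegrationError(
            f"{len(frame)} complete rows is not enough for {folds}-fold CV"
        )
    yv = frame["__y"].to_numpy(dtype=float)
    if np.ptp(yv) == 0:
        raise IntegrationError("phenotype is constant")
    Xv = frame[X.columns].to_numpy(dtype=float)
    cv = KFold(n_splits=folds, shuffle=True, random_state=cv_seed)
    model = LassoCV(alphas=n_alphas, eps=eps, cv=cv, max_iter=max_iter).fit(Xv, yv)
    alpha = float(model.alpha_)
    coef = model.coef_
    if rule == "1se":
        mse = model.mse_path_.mean(axis=1)
        se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(model.mse_path_.shape[1])
        best = int(np.argmin(mse))
        ceiling = mse[best] + se[best]
        # alphas_ is decreasing; the largest admissible penalty is the
        # earliest index with mean MSE under the ceiling
        idx = int(np.nonzero(mse <= ceiling)[0][0])
        alpha = float(model.alphas_[idx])
        from sklearn.linear_model import Lasso

        refit = Lasso(alpha=alpha, max_iter=max_iter).fit(Xv, yv)
        coef = refit.coef_
    return LassoFit(
        coefficients=pd.Series(coef, index=X.columns, name=y.name),
        alpha=alpha,
        cv_rule=rule,
    )


@dataclass
class CoefficientMatrix:
    B: pd.DataFrame  # metabolites x phenotypes
    lambda_per_phenotype: pd.Series
    cv_seed: int

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.B.index)

    @property
    def phenotype_ids(self) -> list[str]:
        return list(self.B.columns)


def assemble_coefficients(
    fits: dict[str, LassoFit], cv_seed: int = 0
) -> CoefficientMatrix:
    """Stack per-phenotype coefficient vectors into B (metabolites x phenotypes).

    All vectors must be indexed on the same metabolite list.  All-zero
    rows are retained; all-zero columns are retained with a warning.
    """
    ids = None
    for phen, fit in fits.items():
        if ids is None:
            ids = list(fit.coefficients.index)
        elif list(fit.coefficients.index) != ids:
            raise IntegrationError(
                f"metabolite list for {phen!r} does not match the others"
            )
    B = pd.DataFrame({phen: fit.coefficients for phen, fit in fits.items()})
    empty = B.columns[(B == 0).all(axis=0)].tolist()
    if empty:
        warnings.warn(f"LASSO selected no metabolites for: {empty}", stacklevel=2)
    lambdas = pd.Series({phen: fit.alpha for phen, fit in fits.items()})
    return CoefficientMatrix(B=B, lambda_per_phenotype=lambdas, cv_seed=cv_seed)


@dataclass
class AgingAxes:
    """Phenotype loadings, metabolite weights, and variance proportions."""

    loadings: pd.DataFrame            # phenotypes x k
    weights: pd.DataFrame             # metabolites x k
    variance_proportion: pd.Series    # length k
    center: pd.Series                 # per-phenotype column means removed
    labels: dict[str, str] | None = None
    signs: pd.Series | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def pca_on_coefficients(
    coeffs: CoefficientMatrix, center: bool = True, scale: bool = False
) -> AgingAxes:
    """SVD of the (column-centered) coefficient matrix.

    Metabolites are observations, phenotypes variables.  Loadings are
    the right singular vectors, weights the metabolite projections
    (U * S), and variance proportions the normalized squared singular
    values.  Components beyond the matrix rank are dropped.  A
    deterministic sign convention (largest-|loading| entry positive) is
    applied; final orientation happens in :func:`orient_and_label`.
    """
    B = coeffs.B.to_numpy(dtype=float)
    if not np.all(np.isfinite(B)):
        raise IntegrationError("coefficient matrix contains non-finite entries")
    col_mean = B.mean(axis=0) if center else np.zeros(B.shape[1])
    Bc = B - col_mean
    if scale:
        col_sd = Bc.std(axis=0, ddof=1)
        col_sd[col_sd == 0] = 1.0
        Bc = Bc / col_sd
    U, s, Vt = np.linalg.svd(Bc, full_matrices=False)
    tol = s.max() * max(Bc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if rank == 0:
        raise IntegrationError("coefficient matrix has rank 0")
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    # canonical signs: make each component's largest-|loading| entry positive
    flip = np.sign(Vt[np.arange(rank), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp = [f"axis_{i}" for i in range(rank)]
    return AgingAxes(
        loadings=pd.DataFrame(Vt.T, index=coeffs.B.columns, columns=comp),
        weights=pd.DataFrame(U * s, index=coeffs.B.index, columns=comp),
        variance_proportion=pd.Series(s**2 / (s**2).sum(), index=comp),
        center=pd.Series(col_mean, index=coeffs.B.columns),
    )


def select_components(
    variance_proportion: pd.Series, min_prop: float = MIN_PROP_DEFAULT
) -> int:
    """Number of leading components individually explaining >= min_prop.

    At least one component is always returned (with a warning if none
    pass the rule).  The scree values themselves live in
    ``variance_proportion`` for plotting/export.
    """
    if len(variance_proportion) == 0:
        raise IntegrationError("empty variance proportions")
    vp = variance_proportion.to_numpy(dtype=float)
    if np.any(np.diff(vp) > 1e-12):
        raise IntegrationError("variance proportions must be non-increasing")
    k = int((vp >= min_prop).cumprod().sum())
    if k == 0:
        warnings.warn(
            f"no component reaches {min_prop:.0%} variance; keeping the first",
            stacklevel=2,
        )
        k = 1
    return k


def truncate_axes(axes: AgingAxes, k: int) -> AgingAxes:
    comp = list(axes.loadings.columns[:k])
    return AgingAxes(
        loadings=axes.loadings[comp],
        weights=axes.weights[comp],
        variance_proportion=axes.variance_proportion[comp],
        center=axes.center,
        labels={c: axes.labels[c] for c in comp} if axes.labels else None,
        signs=axes.signs[comp] if axes.signs is not None else None,
    )


@dataclass
class MetabolicScores:
    scores: pd.DataFrame  # participants x k, standardized within cohort
    cohort: str
    labels: dict[str, str] | None = None


def compute_scores(
    weights: pd.DataFrame,
    Z: pd.DataFrame,
    cohort: str = "train",
    zero_fill: bool = False,
) -> MetabolicScores:
    """Scores = Z @ weights per axis, then standardized within cohort.

    Z must be the cohort-locally standardized log metabolite matrix with
    columns aligned by metabolite id.  Metabolites missing from Z raise
    unless ``zero_fill`` is set (which warns and contributes zero).
    """
    missing = [m for m in weights.index if m not in Z.columns]
    if missing:
        if not zero_fill:
            raise IntegrationError(
                f"{len(missing)} weighted metabolites absent from matrix: "
                f"{missing[:10]}"
            )
        coverage = 1.0 - len(missing) / len(weights)
        warnings.warn(
            f"zero-filling {len(missing)} absent metabolites "
            f"(coverage {coverage:.1%})",
            stacklevel=2,
        )
    present = [m for m in weights.index if m in Z.columns]
    raw = Z[present].to_numpy(dtype=float) @ weights.loc[present].to_numpy(dtype=float)
    raw = pd.DataFrame(raw, index=Z.index, columns=weights.columns)
    sd = raw.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = raw.columns[sd <= 0].tolist()
        raise IntegrationError(f"degenerate (constant) scores for axes: {bad}")
    std = (raw - raw.mean(axis=0)) / sd
    return MetabolicScores(scores=std, cohort=cohort)


def orient_and_label(
    axes: AgingAxes,
    scores: MetabolicScores,
    harmonized_phenotypes: pd.DataFrame,
    domain_map: dict[str, str] | None = None,
) -> tuple[AgingAxes, MetabolicScores]:
    """Sign axes so scores correlate positively with their top phenotype.

    For each axis the phenotype with the highest |loading| (ties to the
    lower column index) anchors the orientation: if the training-cohort
    score correlates negatively with it, the axis's weights, loadings,
    and scores are all negated.  The label is the anchor phenotype's
    domain plus its name.
    """
    loadings = axes.loadings.copy()
    weights = axes.weights.copy()
    sc = scores.scores.copy()
    phen = harmonized_phenotypes.reindex(sc.index)
    labels: dict[str, str] = {}
    signs = {}
    for comp in loadings.columns:
        abs_load = loadings[comp].abs()
        top = abs_load.index[int(np.argmax(abs_load.to_numpy()))]
        r = float(np.corrcoef(sc[comp], phen[top])[0, 1])
        sign = 1.0
        if abs(r) < 1e-10:
            warnings.warn(
                f"{comp}: score uncorrelated with top phenotype {top!r}; "
                "orientation unchanged",
                stacklevel=2,
            )
        elif r < 0:
            sign = -1.0
        loadings[comp] *= sign
        weights[comp] *= sign
        sc[comp] *= sign
        signs[comp] = sign
        domain = (domain_map or {}).get(top, "")
        labels[comp] = f"{domain}:{top}" if domain else str(top)
    oriented = AgingAxes(
        loadings=loadings,
        weights=weights,
        variance_proportion=axes.variance_proportion,
        center=axes.center,
        labels=labels,
        signs=pd.Series(signs),
    )
    return oriented, MetabolicScores(scores=sc, cohort=scores.cohort, labels=labels)


def integrate(
    harmonized_phenotypes: pd.DataFrame,
    Z: pd.DataFrame,
    domain_map: dict[str, str] | None = None,
    prune_threshold: float = PRUNE_THRESHOLD_DEFAULT,
    min_prop: float = MIN_PROP_DEFAULT,
    folds: int = 10,
    cv_seed: int = 0,
    cv_rule: str = "1se",
    n_components: int | None = None,
) -> tuple[AgingAxes, MetabolicScores, CoefficientMatrix, PruneLog]:
    """End-to-end integration on one training cohort.

    prune -> LASSO per phenotype -> PCA on B -> component selection
    (manual override via ``n_components``) -> scores -> orientation.
    """
    kept, prune_log = prune_correlated(Z, prune_threshold)
    Zp = Z[kept]
    common = harmonized_phenotypes.index.intersection(Zp.index)
    fits = {
        phen: fit_lasso_phenotype(
            harmonized_phenotypes.loc[common, phen],
            Zp.loc[common],
            folds=folds,
            cv_seed=cv_seed,
            rule=cv_rule,
        )
        for phen in harmonized_phenotypes.columns
    }
    coeffs = assemble_coefficients(fits, cv_seed=cv_seed)
    axes = pca_on_coefficients(coeffs)
    k = n_components if n_components is not None else select_components(
        axes.variance_proportion, min_prop
    )
    axes = truncate_axes(axes, min(k, axes.k))
    scores = compute_scores(axes.weights, Zp, cohort="train")
    axes, scores = orient_and_label(
        axes, scores, harmonized_phenotypes.loc[common], domain_map
    )
    return axes, scores, coeffs, prune_log
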