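"""Trait preparation and phylogenetic regression of threat levels.

Threat level (log-transformed RT%) is regressed on species traits with
generalized least squares whose residual covariance comes from the
phylogeny under Pagel's lambda transform:

    V(lambda) = lambda * (C - diag C) + diag C,

where C is the shared-branch-length matrix of the tree (C_ij = branch
length from the root to the most recent common ancestor of tips i and
j).  lambda = 0 removes all phylogenetic signal from the residuals;
lambda = 1 is the Brownian-motion expectation.  lambda is estimated by
profile maximum likelihood on [0, 1]; coefficients, t statistics and p
values follow from the GLS fit at the optimum.

Variable importance follows the permutation approach: each covariate's
values are shuffled, predictions are recomputed with the *fitted*
coefficients, and importance is 1 minus Pearson's r between original
and shuffled-data predictions, averaged over iterations (and, when
several tree replicates are supplied, summarised across replicates).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .synthetic_world import _shared_branch_matrix, pagel_covariance

logger = logging.getLogger(__name__)

LOTIC_KEYWORDS = ("river", "stream", "creek", "canal", "channel", "delta", "estuaries")
LENTIC_KEYWORDS = ("lake", "pool", "bog", "swamp", "pond")

#: Default covariates entering the regression design.
DEFAULT_COVARIATES = (
    "log10_range_km2",
    "log10_body_length_cm",
    "climate_zone",
    "trophic_group",
    "habitat_type",
    "iucn_category",
    "commercial_importance",
)


# ---------------------------------------------------------------------------
# Trait classification
# ---------------------------------------------------------------------------

def classify_trophic(trophic_level: float) -> str:
    """Trophic group from Fishbase-style trophic level.

    Carnivore above 2.79; Omnivore in (2.19, 2.79]; Herbivore at or
    below 2.19.
    """
    if trophic_level <= 0:
        raise ValueError(f"trophic level must be positive, got {trophic_level}")
    if trophic_level > 2.79:
        return "Carnivore"
    if trophic_level > 2.19:
        return "Omnivore"
    return "Herbivore"


def classify_habitat(
    habitat_keywords: Sequence[str], *, freshwater: bool = True, marine: bool = False
) -> str:
    """Habitat type from habitat descriptor strings.

    Species in both freshwater and marine environments are
    lotic-marine (takes precedence).  Otherwise keyword hits decide:
    lotic words (river, stream, ...) and lentic words (lake, pool, ...)
    yield lotic / lentic / lotic-lentic; no hit yields "unknown",
    which downstream filtering excludes from the regression.
    """
    if not habitat_keywords:
        raise ValueError("empty habitat descriptor set")
    if freshwater and marine:
        return "lotic-marine"
    text = " ".join(k.lower() for k in habitat_keywords)
    lotic = any(word in text for word in LOTIC_KEYWORDS)
    lentic = any(word in text for word in LENTIC_KEYWORDS)
    if lotic and lentic:
        return "lotic-lentic"
    if lotic:
        return "lotic"
    if lentic:
        return "lentic"
    logger.warning("no habitat keyword matched %r; classified unknown", habitat_keywords)
    return "unknown"


def assign_climate_zone(
    range_cells: Sequence[int],
    zone_labels: Mapping[int, str] | pd.Series,
    cell_areas: Mapping[int, float] | pd.Series,
    *,
    precedence: Sequence[str] = ("A", "B", "C", "D", "E"),
) -> str:
    """Majority climate zone of a range, by summed cell area.

    Exact area ties go to the earlier zone in ``precedence`` with a
    logged warning.
    """
    totals: dict[str, float] = {}
    for c in range_cells:
        z = zone_labels[c]
        totals[z] = totals.get(z, 0.0) + float(cell_areas[c])
    best = max(totals.values())
    winners = sorted(
        (z for z, a in totals.items() if a == best),
        key=lambda z: precedence.index(z) if z in precedence else len(precedence),
    )
    if len(winners) > 1:
        logger.warning("climate-zone tie among %s; taking %s", winners, winners[0])
    return winners[0]


def log_response(rt_percent: np.ndarray | pd.Series, offset: float = 0.01) -> np.ndarray:
    """log10(RT% + offset); the offset admits wholly unthreatened species."""
    return np.log10(np.asarray(rt_percent, dtype=float) + offset)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design(
    traits: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    reference_levels: Mapping[str, str] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Treatment-contrast design matrix with an intercept.

    Continuous covariates enter as-is; categorical covariates are dummy
    coded against a reference level (the most frequent one unless fixed
    via ``reference_levels``).  Returns (X, column names, reference
    levels used) so that the identical encoding can be rebuilt for
    permuted data.
    """
    covariates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    refs: dict[str, str] = dict(reference_levels or {})
    cols: list[np.ndarray] = [np.ones(len(traits))]
    names: list[str] = ["intercept"]
    for cov in covariates:
        series = traits[cov]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(float))
            names.append(cov)
        else:
            if cov not in refs:
                refs[cov] = series.value_counts().idxmax()
            ref = refs[cov]
            for level in sorted(series.unique()):
                if level == ref:
                    continue
                cols.append((series == level).to_numpy(float))
                names.append(f"{cov}[{level}]")
    X = np.column_stack(cols)
    return X, names, refs


# ---------------------------------------------------------------------------
# PGLS fit
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    coefficients: pd.Series
    std_errors: pd.Series
    t_statistics: pd.Series
    p_values: pd.Series
    lambda_: float
    sigma2: float
    log_likelihood: float
    pearson_r_pred_obs: float
    n_obs: int
    covariates: tuple[str, ...]
    reference_levels: dict[str, str] = field(default_factory=dict)
    _C: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients.to_numpy()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "std_error": self.std_errors,
                "abs_t": self.t_statistics.abs(),
                "p_value": self.p_values,
            }
        )


def _gls_profile(
    lam: float, C: np.ndarray, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """Profile ML log-likelihood at lambda; returns (logL, beta, XtVinvX_inv, sigma2_ml)."""
    n = y.size
    V = pagel_covariance(C, lam)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.full(X.shape[1], np.nan), np.eye(X.shape[1]), np.nan
    Xs = solve_triangular(L, X, lower=True)
    ys = solve_triangular(L, y, lower=True)
    XtX = Xs.T @ Xs
    beta = np.linalg.solve(XtX, Xs.T @ ys)
    resid = ys - Xs @ beta
    sigma2 = float(resid @ resid) / n
    logdetV = 2.0 * float(np.log(np.diag(L)).sum())
    logL = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV + n)
    return logL, beta, np.linalg.inv(XtX), sigma2


def fit_pgls(
    traits: pd.DataFrame,
    tree: dendropy.Tree,
    response: str = "response",
    covariates: Sequence[str] | None = None,
    *,
    lambda_fixed: float | None = None,
    reference_levels: Mapping[str, str] | None = None,
    collinearity_screen: bool = True,
) -> PglsFit:
    """Phylogenetic GLS with Pagel's lambda estimated by ML on [0, 1].

    ``traits`` must carry a ``species_id`` column matching the tree's
    tip labels (the tree may contain extra tips) and the response and
    covariate columns with no missing values.  A non-ultrametric tree
    is accepted with a warning.  Rank-deficient designs are rejected
    naming the aliased columns.
    """
    species = traits["species_id"].astype(str).tolist()
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [s for s in species if s not in tip_labels]
    if missing:
        raise ValueError(f"species absent from tree: {missing[:5]}...")

    C = _shared_branch_matrix(tree, species)
    depths = np.diag(C)
    if not np.allclose(depths, depths[0], rtol=1e-6):
        warnings.warn("tree is not ultrametric; proceeding with raw depths", stacklevel=2)
    if np.any(depths <= 0):
        raise ValueError("tree must have positive root-to-tip depths")

    X, names, refs = build_design(traits, covariates, reference_levels)
    y = traits[response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} species for {p} design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(p) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    if collinearity_screen:
        _collinearity_warnings(traits, covariates or DEFAULT_COVARIATES)

    if lambda_fixed is not None:
        lam_hat = float(lambda_fixed)
    else:
        res = optimize.minimize_scalar(
            lambda lam: -_gls_profile(lam, C, X, y)[0],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        lam_hat = float(res.x)
        # the bounded optimiser never evaluates the exact endpoints; take
        # them when they beat the interior optimum
        for endpoint in (0.0, 1.0):
            if _gls_profile(endpoint, C, X, y)[0] > _gls_profile(lam_hat, C, X, y)[0]:
                lam_hat = endpoint

    logL, beta, XtVinvX_inv, sigma2_ml = _gls_profile(lam_hat, C, X, y)
    df_resid = n - p
    sigma2_unbiased = sigma2_ml * n / df_resid
    se = np.sqrt(np.diag(XtVinvX_inv) * sigma2_unbiased)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)
    pred = X @ beta
    r = float(stats.pearsonr(pred, y)[0]) if np.std(pred) > 0 else np.nan

    idx = pd.Index(names, name="term")
    return PglsFit(
        coefficients=pd.Series(beta, index=idx),
        std_errors=pd.Series(se, index=idx),
        t_statistics=pd.Series(tvals, index=idx),
        p_values=pd.Series(pvals, index=idx),
        lambda_=lam_hat,
        sigma2=sigma2_unbiased,
        log_likelihood=logL,
        pearson_r_pred_obs=r,
        n_obs=n,
        covariates=tuple(covariates or DEFAULT_COVARIATES),
        reference_levels=refs,
        _C=C,
    )


def _collinearity_warnings(traits: pd.DataFrame, covariates: Sequence[str]) -> None:
    """Spearman (continuous pairs) and VIF screens, warnings only."""
    numeric = [c for c in covariates if pd.api.types.is_numeric_dtype(traits[c])]
    for i, a in enumerate(numeric):
        for b in numeric[i + 1:]:
            rho = stats.spearmanr(traits[a], traits[b]).statistic
            if abs(rho) >= 0.4:
                warnings.warn(
                    f"|Spearman rho|={abs(rho):.2f} between {a} and {b} (>= 0.4)",
                    stacklevel=3,
                )
    if len(numeric) >= 2:
        Xn = traits[numeric].to_numpy(float)
        Xn = np.column_stack([np.ones(len(Xn)), Xn])
        for j, name in enumerate(numeric, start=1):
            others = [k for k in range(Xn.shape[1]) if k != j]
            beta, *_ = np.linalg.lstsq(Xn[:, others], Xn[:, j], rcond=None)
            resid = Xn[:, j] - Xn[:, others] @ beta
            tss = float(((Xn[:, j] - Xn[:, j].mean()) ** 2).sum())
            r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
            vif = 1.0 / max(1.0 - r2, 1e-12)
            if vif >= 1.5:
                warnings.warn(f"VIF {vif:.2f} for {name} (>= 1.5)", stacklevel=3)


# ---------------------------------------------------------------------------
# Permutation variable importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceScores:
    mean: pd.Series          # per covariate, across replicates
    sd: pd.Series
    n_iterations: int
    n_replicates: int


def _importance_one_fit(
    fit: PglsFit,
    traits: pd.DataFrame,
    n_iterations: int,
    rng: np.random.Generator,
) -> pd.Series:
    X0, names, refs = build_design(traits, list(fit.covariates), fit.reference_levels)
    pred0 = X0 @ fit.coefficients.to_numpy()
    out: dict[str, float] = {}
    for cov in fit.covariates:
        scores = np.empty(n_iterations)
        for it in range(n_iterations):
            perm = traits.copy()
            perm[cov] = rng.permutation(perm[cov].to_numpy())
            Xp, _, _ = build_design(perm, list(fit.covariates), refs)
            predp = Xp @ fit.coefficients.to_numpy()
            if np.std(predp) == 0 or np.std(pred0) == 0:
                warnings.warn(
                    f"constant predictions while permuting {cov}; importance set to 0",
                    stacklevel=3,
                )
                scores[it] = 0.0
            else:
                scores[it] = 1.0 - float(np.corrcoef(pred0, predp)[0, 1])
        out[cov] = float(scores.mean())
    return pd.Series(out, name="importance")


def variable_importance(
    fits: PglsFit | Sequence[PglsFit],
    traits: pd.DataFrame | Sequence[pd.DataFrame],
    n_iterations: int = 100,
    seed: int = 0,
) -> ImportanceScores:
    """Permutation importance: 1 - Pearson r(original, permuted predictions).

    Predictions for permuted data reuse the fitted coefficients (no
    refit).  Pass several fits (one per phylogenetic-tree replicate,
    each with its matching trait table) to obtain the mean and SD of
    the scores across replicates; a single fit reports SD 0.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    fit_list = [fits] if isinstance(fits, PglsFit) else list(fits)
    trait_list = [traits] if isinstance(traits, pd.DataFrame) else list(traits)
    if len(trait_list) == 1 and len(fit_list) > 1:
        trait_list = trait_list * len(fit_list)
    if len(fit_list) != len(trait_list):
        raise ValueError("need one trait table per fit")
    rng = np.random.default_rng(seed)
    per_rep = pd.DataFrame(
        [_importance_one_fit(f, t, n_iterations, rng) for f, t in zip(fit_list, trait_list)]
    )
    return ImportanceScores(
        mean=per_rep.mean(axis=0),
        sd=per_rep.std(axis=0, ddof=0) if len(fit_list) > 1 else per_rep.iloc[0] * 0.0,
        n_iterations=n_iterations,
        n_replicates=len(fit_list),
    )
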