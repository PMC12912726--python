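"""Multivariate-normal multiple imputation: EM start + data-augmentation chains.

The missing-trait problem (fossil rows with unobserved descent
proportions and partially observed morphology) is modeled as one
multivariate normal over taxa x variables. Estimation proceeds in two
stages:

1. **EM** maximizes the observed-data likelihood over (mu, Sigma),
   sweeping missingness patterns: the E-step fills each row's missing
   block with its conditional mean (adding the conditional covariance to
   the expected cross-products), the M-step re-estimates mu and Sigma by
   maximum likelihood. The observed-data log-likelihood is
   non-decreasing across iterations.
2. **Data augmentation** runs short Markov chains from the EM solution:
   the I-step draws the missing cells from their conditional normal
   given the observed cells and current parameters; the P-step draws
   (mu, Sigma) from the normal-inverse-Wishart posterior under the
   Jeffreys noninformative prior (Sigma ~ IW(n - 1, S), mu | Sigma ~
   N(xbar, Sigma/n)).

Many independent chains (default 5000 runs of 50 steps) yield one
completed draw each; the point prediction of a missing cell is the mean
over runs, with between-run SD and 2.5/97.5 percentile intervals.
Predicted proportions are clamped to [0, 100] after averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "EMResult",
    "em_mvnorm",
    "da_chain",
    "ImputationProblem",
    "MIResult",
    "mi_predict",
    "HEAD_FIRST_PREDICTORS",
    "assemble_imputation_matrix",
]

# the six morphological variables retained for the head-first model;
# body mass enters on the log10 scale
HEAD_FIRST_PREDICTORS = [
    "log10_body_mass", "eq", "pct_forelimb_body", "pct_hindlimb_body",
    "intermembral_index", "pct_tail_body",
]


@dataclass(frozen=True)
class EMResult:
    mean: np.ndarray
    cov: np.ndarray
    loglik_path: np.ndarray
    n_iter: int
    converged: bool


def _patterns(mask: np.ndarray):
    """Group row indices by missingness pattern (mask True = missing)."""
    groups: dict[tuple, list[int]] = {}
    for i, row in enumerate(mask):
        groups.setdefault(tuple(row), []).append(i)
    return [(np.array(key, dtype=bool), np.array(idx)) for key, idx in groups.items()]


def _observed_loglik(X, mask, mean, cov, patterns):
    total = 0.0
    for pat, idx in patterns:
        obs = ~pat
        if not obs.any():
            continue
        sub = X[np.ix_(idx, np.where(obs)[0])]
        total += stats.multivariate_normal.logpdf(
            sub, mean=mean[obs], cov=cov[np.ix_(obs, obs)], allow_singular=True
        ).sum()
    return float(total)


def em_mvnorm(
    X: np.ndarray | pd.DataFrame,
    mask: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    ridge: float = 1e-8,
) -> EMResult:
    """EM estimate of the mean and covariance of an incomplete MVN sample.

    ``X`` is taxa x variables with NaN (or ``mask`` True) marking missing
    cells. Singular covariance updates are ridge-stabilized with a
    warning. Convergence is declared when the observed-data
    log-likelihood improves by less than ``tol``.
    """
    X = np.asarray(X, dtype=float)
    if mask is None:
        mask = np.isnan(X)
    mask = np.asarray(mask, dtype=bool)
    n, p = X.shape
    if mask.all(axis=0).any():
        raise ValueError("a variable is fully missing; the model is not identifiable")
    work = X.copy()
    col_means = np.nanmean(np.where(mask, np.nan, X), axis=0)
    work[mask] = np.take(col_means, np.where(mask)[1])
    mean = work.mean(axis=0)
    cov = np.cov(work, rowvar=False, bias=True) + ridge * np.eye(p)
    patterns = _patterns(mask)
    logliks = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        filled = X.copy()
        extra = np.zeros((p, p))
        for pat, idx in patterns:
            if not pat.any():
                continue
            o = np.where(~pat)[0]
            m = np.where(pat)[0]
            if o.size:
                B = np.linalg.solve(cov[np.ix_(o, o)], cov[np.ix_(o, m)])
                cond_mean = mean[m] + (X[np.ix_(idx, o)] - mean[o]) @ B
                cond_cov = cov[np.ix_(m, m)] - cov[np.ix_(m, o)] @ B
            else:
                cond_mean = np.tile(mean[m], (idx.size, 1))
                cond_cov = cov[np.ix_(m, m)]
            filled[np.ix_(idx, m)] = cond_mean
            extra[np.ix_(m, m)] += idx.size * cond_cov
        # M-step (maximum likelihood, denominator n)
        mean = filled.mean(axis=0)
        centered = filled - mean
        cov = (centered.T @ centered + extra) / n
        try:
            linalg.cholesky(cov, lower=True)
        except linalg.LinAlgError:
            warnings.warn("singular covariance update; ridge-stabilizing", RuntimeWarning)
            cov = cov + ridge * np.trace(cov) * np.eye(p)
        logliks.append(_observed_loglik(X, mask, mean, cov, patterns))
        if len(logliks) > 1 and abs(logliks[-1] - logliks[-2]) < tol:
            converged = True
            break
    return EMResult(mean, cov, np.array(logliks), it, converged)


def _draw_parameters(filled: np.ndarray, rng: np.random.Generator, max_retries: int = 5):
    """P-step: (mu, Sigma) from the Jeffreys-prior posterior given complete data."""
    n, p = filled.shape
    xbar = filled.mean(axis=0)
    S = (filled - xbar).T @ (filled - xbar)
    for attempt in range(max_retries):
        try:
            sigma = stats.invwishart.rvs(df=n - 1, scale=S, random_state=rng)
            mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")
            return mu, sigma
        except linalg.LinAlgError:
            S = S + 10.0 ** (attempt - 8) * np.trace(S) / p * np.eye(p)
    raise linalg.LinAlgError("P-step draw failed after jittered retries")


def da_chain(
    X: np.ndarray,
    mean0: np.ndarray,
    cov0: np.ndarray,
    steps: int,
    rng: np.random.Generator | int | None,
) -> np.ndarray:
    """One data-augmentation chain; returns the final completed matrix."""
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    mask = np.isnan(X)
    if not mask.any():
        return X.copy()
    patterns = _patterns(mask)
    mean, cov = np.asarray(mean0, float), np.asarray(cov0, float)
    filled = X.copy()
    for _ in range(steps):
        # I-step
        for pat, idx in patterns:
            if not pat.any():
                continue
            o = np.where(~pat)[0]
            m = np.where(pat)[0]
            if o.size:
                B = np.linalg.solve(cov[np.ix_(o, o)], cov[np.ix_(o, m)])
                cond_mean = mean[m] + (X[np.ix_(idx, o)] - mean[o]) @ B
                cond_cov = cov[np.ix_(m, m)] - cov[np.ix_(m, o)] @ B
            else:
                cond_mean = np.tile(mean[m], (idx.size, 1))
                cond_cov = cov[np.ix_(m, m)]
            cond_cov = 0.5 * (cond_cov + cond_cov.T)
            try:
                Lc = linalg.cholesky(cond_cov + 1e-12 * np.eye(m.size), lower=True)
            except linalg.LinAlgError:
                w, V = np.linalg.eigh(cond_cov)
                Lc = V * np.sqrt(np.clip(w, 0, None))
            noise = rng.standard_normal((idx.size, m.size)) @ Lc.T
            filled[np.ix_(idx, m)] = cond_mean + noise
        # P-step
        mean, cov = _draw_parameters(filled, rng)
    return filled


@dataclass
class ImputationProblem:
    """A taxa x variables matrix with missing cells and MI settings.

    ``response`` names the column to predict (descent proportion, %);
    predictor columns are everything else. Fossil rows have the
    response (and possibly predictors) missing.
    """

    data: pd.DataFrame
    response: str
    runs: int = 5000
    steps: int = 50
    seed: int | None = None
    clamp: tuple[float, float] | None = (0.0, 100.0)

    def __post_init__(self) -> None:
        if self.response not in self.data.columns:
            raise ValueError(f"response column {self.response!r} not in data")
        if self.runs < 1 or self.steps < 1:
            raise ValueError("runs and steps must be >= 1")
        if self.data.isna().all(axis=0).any():
            raise ValueError("a variable is fully missing; the model is not identifiable")
        if not self.data.notna().all(axis=0).any():
            warnings.warn(
                "no fully observed variable: rows with no observed cell are "
                "imputed from weakly identified marginals", RuntimeWarning,
            )


@dataclass
class MIResult:
    """Pooled multiple-imputation predictions for the missing response cells."""

    predictions: pd.DataFrame  # index: taxa with missing response
    em: EMResult
    runs: int
    steps: int
    seed: int | None
    draws: np.ndarray | None = None

    def provenance(self) -> dict:
        return {"runs": self.runs, "steps": self.steps, "seed": self.seed,
                "em_iterations": self.em.n_iter, "em_converged": self.em.converged}


def mi_predict(problem: ImputationProblem, keep_draws: bool = False) -> MIResult:
    """Multiple-imputation prediction of the missing response cells.

    Runs ``problem.runs`` independent data-augmentation chains of
    ``problem.steps`` steps from the EM solution and pools the final
    draws of each missing response cell: mean (clamped to the response
    scale), between-run SD, and 2.5/97.5 percentile interval. Rows with
    no observed predictor at all are still predicted (from the
    marginals) but flagged low-confidence.
    """
    data = problem.data
    X = data.to_numpy(dtype=float)
    resp_j = data.columns.get_loc(problem.response)
    missing_rows = np.where(np.isnan(X[:, resp_j]))[0]
    if missing_rows.size == 0:
        raise ValueError("no missing response cells to predict")
    em = em_mvnorm(X)
    seeds = np.random.SeedSequence(problem.seed).spawn(problem.runs)
    draws = np.empty((problem.runs, missing_rows.size))
    for r, ss in enumerate(seeds):
        completed = da_chain(X, em.mean, em.cov, problem.steps, np.random.default_rng(ss))
        draws[r] = completed[missing_rows, resp_j]
    mean = draws.mean(axis=0)
    lo_q, hi_q = np.percentile(draws, [2.5, 97.5], axis=0)
    if problem.clamp is not None:
        lo, hi = problem.clamp
        mean = np.clip(mean, lo, hi)
        lo_q, hi_q = np.clip(lo_q, lo, hi), np.clip(hi_q, lo, hi)
    pred_cols = [c for c in data.columns if c != problem.response]
    no_predictors = data.iloc[missing_rows][pred_cols].isna().all(axis=1).to_numpy()
    predictions = pd.DataFrame(
        {
            "prediction": mean,
            "between_run_sd": draws.std(axis=0, ddof=1) if problem.runs > 1 else np.nan,
            "q2.5": lo_q,
            "q97.5": hi_q,
            "low_confidence": no_predictors,
        },
        index=data.index[missing_rows],
    )
    return MIResult(predictions, em, problem.runs, problem.steps, problem.seed,
                    draws if keep_draws else None)


def assemble_imputation_matrix(
    morphology: pd.DataFrame,
    response: pd.Series,
    predictors: list[str] = HEAD_FIRST_PREDICTORS,
    response_name: str = "head_first_pct",
) -> pd.DataFrame:
    """Join morphology predictors with a descent-proportion response.

    ``morphology`` is the per-taxon profile table (see
    :mod:`vertdescent.morphometrics`); ``body_mass_g`` is converted to
    ``log10_body_mass`` on the fly. Taxa absent from ``response``
    (fossils) get NaN response cells.
    """
    morph = morphology.copy()
    if "log10_body_mass" in predictors and "log10_body_mass" not in morph.columns:
        morph["log10_body_mass"] = np.log10(morph["body_mass_g"])
    missing = [c for c in predictors if c not in morph.columns]
    if missing:
        raise ValueError(f"morphology table lacks predictor columns {missing}")
    out = morph[predictors].copy()
    out[response_name] = response.reindex(morph.index)
    return out
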