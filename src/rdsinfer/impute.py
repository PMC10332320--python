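"""Multiple imputation of missing self-reported network sizes.

Network size (degree) drives the successive-sampling inclusion-probability
model, so respondents with missing degrees cannot simply be dropped.  Missing
degrees are imputed on the log scale by predictive mean matching (PMM) within
a chained-equations loop: observed log-degrees are regressed on the catalogue
covariates (plus the recruiter's degree, which is itself updated across
cycles when it was imputed), regression parameters are drawn from their
approximate posterior, and each missing entry receives the observed degree of
one of its ``k`` nearest neighbours in predicted-mean space.  Matching on
observed donors keeps imputed values on the observed support: integers >= 1
with the right skew of real network-size reports.

``m`` completed datasets are produced; downstream estimates are combined with
the standard multiple-imputation pooling rule (:func:`pool_estimates`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import VariableCatalogue
from .io import RespondentRecord, records_to_frame


@dataclass
class ImputationSet:
    """``m`` completed degree vectors; observed entries identical across all."""

    m: int
    completed: list[np.ndarray]
    method: str
    random_seed: int | None

    def __post_init__(self) -> None:
        if self.m != len(self.completed):
            raise ValueError("m must equal the number of completed vectors")
        for vec in self.completed:
            if np.any(~np.isfinite(vec)) or np.any(vec < 1):
                raise ValueError("completed degrees must be finite and >= 1")

    def to_frame(self) -> pd.DataFrame:
        """m-column sidecar (one column per completed dataset)."""
        return pd.DataFrame(
            {f"imputation_{i + 1}": v for i, v in enumerate(self.completed)})


def _design_matrix(frame: pd.DataFrame, predictors: list[str],
                   catalogue: VariableCatalogue) -> np.ndarray:
    """Numeric predictor matrix with simple mean-fill + missing indicators.

    Covariate missingness is rare relative to degree missingness here; a
    fill-plus-indicator treatment keeps every row usable without a full
    multivariate imputation of the covariates (out of scope).
    """
    cols = [np.ones(len(frame))]
    for name in predictors:
        var = catalogue[name]
        if var.kind == "binary":
            x = frame[name].to_numpy(dtype=float)
            miss = np.isnan(x)
            if miss.any():
                filled = np.where(miss, np.nanmean(x) if not np.all(miss)
                                  else 0.0, x)
                cols.append(filled)
                cols.append(miss.astype(float))
            else:
                cols.append(x)
        else:
            vals = frame[name]
            for level in var.contrast_levels:
                cols.append((vals == level).to_numpy(dtype=float))
            if vals.isna().any():
                cols.append(vals.isna().to_numpy(dtype=float))
    return np.column_stack(cols)


def _drop_collinear(x: np.ndarray) -> np.ndarray:
    """Greedily drop columns that are numerically collinear (logged)."""
    keep: list[int] = []
    for j in range(x.shape[1]):
        trial = x[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    if len(keep) < x.shape[1]:
        warnings.warn(
            f"dropped {x.shape[1] - len(keep)} collinear predictor columns "
            "from the degree-imputation model")
    return x[:, keep]


def _pmm_draw(rng: np.random.Generator, x_obs: np.ndarray, y_obs: np.ndarray,
              x_mis: np.ndarray, k: int) -> np.ndarray:
    """One PMM draw: Bayesian linear regression + k-nearest-donor matching."""
    n, p = x_obs.shape
    beta_hat, _, _, _ = np.linalg.lstsq(x_obs, y_obs, rcond=None)
    resid = y_obs - x_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    xtx_inv = np.linalg.pinv(x_obs.T @ x_obs)
    beta_star = rng.multivariate_normal(beta_hat, sigma2 * xtx_inv,
                                        method="svd")
    # donors and targets are placed on the same drawn-coefficient scale, so
    # a donor sharing the target's predictor profile is always its nearest
    # neighbour (distance zero) whatever the draw
    pred_obs = x_obs @ beta_star
    pred_mis = x_mis @ beta_star
    out = np.empty(len(x_mis))
    for i, pm in enumerate(pred_mis):
        dist = np.abs(pred_obs - pm)
        kk = min(k, n)
        donors = np.argpartition(dist, kk - 1)[:kk]
        out[i] = y_obs[donors[rng.integers(kk)]]
    return out


def impute_degrees(records: list[RespondentRecord],
                   catalogue: VariableCatalogue,
                   m: int = 10,
                   predictors: list[str] | None = None,
                   k: int = 5,
                   random_seed: int | None = None,
                   include_recruiter_degree: bool = True,
                   n_cycles: int = 5) -> ImputationSet:
    """Multiply impute missing degrees by chained predictive mean matching.

    Parameters
    ----------
    predictors
        Catalogue variable names entering the imputation model; defaults to
        every catalogue covariate (the survey does not name the predictors it
        used, so the list is configuration).
    include_recruiter_degree
        Add the recruiter's (log) degree as a predictor; seeds get the sample
        mean plus a seed indicator.  Because recruiters' degrees may
        themselves be imputed, the model is re-fit for ``n_cycles`` cycles
        with updated values, chained-equations style.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    frame = records_to_frame(records, catalogue)
    degrees = frame["degree"].to_numpy(dtype=float)
    observed = ~np.isnan(degrees)
    if not observed.any():
        raise ValueError("cannot impute: all degrees are missing")
    if predictors is None:
        predictors = [n for n in catalogue.covariate_names()
                      if n in frame.columns]
    for name in predictors:
        if name not in catalogue:
            raise KeyError(f"unknown predictor {name!r}")

    base_x = _drop_collinear(_design_matrix(frame, predictors, catalogue))
    log_deg = np.where(observed, np.log(degrees), np.nan)

    id_to_row = {rid: i for i, rid in enumerate(frame["respondent_id"])}
    recruiter_row = np.array([
        id_to_row.get(rec) if rec is not None else -1
        for rec in frame["recruiter_id"]
    ], dtype=object)

    ss = np.random.SeedSequence(random_seed)
    chains = [np.random.default_rng(s) for s in ss.spawn(m)]

    completed: list[np.ndarray] = []
    missing_idx = np.flatnonzero(~observed)
    obs_idx = np.flatnonzero(observed)
    for rng in chains:
        if missing_idx.size == 0:
            completed.append(degrees.astype(np.int64))
            continue
        work = log_deg.copy()
        # initialise missing entries from random observed donors
        work[missing_idx] = rng.choice(work[obs_idx], size=missing_idx.size)
        cycles = n_cycles if include_recruiter_degree else 1
        for _ in range(cycles):
            if include_recruiter_degree:
                rec_log = np.empty(len(frame))
                is_seed = np.zeros(len(frame))
                for i, rr in enumerate(recruiter_row):
                    if rr == -1:
                        rec_log[i] = np.nan
                        is_seed[i] = 1.0
                    else:
                        rec_log[i] = work[rr]
                rec_log = np.where(np.isnan(rec_log),
                                   np.nanmean(work), rec_log)
                x = np.column_stack([base_x, rec_log, is_seed])
            else:
                x = base_x
            work[missing_idx] = _pmm_draw(
                rng, x[obs_idx], log_deg[obs_idx], x[missing_idx], k)
        out = degrees.copy()
        out[missing_idx] = np.exp(work[missing_idx])
        completed.append(np.round(out).astype(np.int64))
    return ImputationSet(m=m, completed=completed,
                         method=f"pmm(log degree, k={k}, cycles={n_cycles})",
                         random_seed=random_seed)


def pool_estimates(per_dataset: list[tuple[float, float]]
                   ) -> tuple[float, float]:
    """Combine per-imputation (estimate, variance) pairs.

    Pooled estimate is the mean of the estimates; pooled variance is the
    within-imputation mean plus ``(1 + 1/m)`` times the between-imputation
    variance (the standard multiple-imputation combining rule).
    """
    m = len(per_dataset)
    if m == 0:
        raise ValueError("need at least one (estimate, variance) pair")
    est = np.array([e for e, _ in per_dataset], dtype=float)
    var = np.array([v for _, v in per_dataset], dtype=float)
    pooled = float(est.mean())
    if m == 1:
        return pooled, float(var[0])
    between = float(est.var(ddof=1))
    total = float(var.mean()) + (1.0 + 1.0 / m) * between
    return pooled, total
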