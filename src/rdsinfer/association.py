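"""Correlate-outcome association analysis for RDS samples.

Three layers:

* classical 2x2 machinery — :func:`crosstab` and :func:`odds_ratio_wald`
  (cross-product OR, Wald 95% CI and p-value, 0.5 continuity correction on
  zero cells);
* logistic regression — :func:`logistic_fit` (maximum likelihood via IRLS,
  through statsmodels GLM/Binomial) with catalogue-driven reference-level
  contrasts, plus :func:`select_multivariable` implementing the
  include-if-bivariably-associated rule;
* the recruitment-tree dependent permutation test —
  :func:`dependent_permutation_test` — which replaces the iid permutation
  null with one that preserves the chain dependence RDS induces: the
  correlate is regenerated along the recruitment forest from a first-order
  Markov transition matrix estimated from observed recruiter-recruit pairs,
  severing any link to the (fixed) outcome while keeping the sampling and
  dependence structure of the observed data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .catalogue import VariableCatalogue
from .io import RecruitmentForest, recruiter_recruit_pairs, records_to_frame

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (exposed & outcome, exposed & no outcome,
    unexposed & outcome, unexposed & no outcome)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def swapped_exposure(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass
class OddsRatioResult:
    or_: float | None
    ci: tuple[float, float] | None
    p: float | None
    log_or: float | None
    se_log_or: float | None
    continuity_corrected: bool = False
    undefined: bool = False


@dataclass
class AssociationResult:
    """One correlate-contrast vs outcome comparison."""

    correlate: str
    level: str
    reference: str
    table: ContingencyTable2x2
    or_: float | None
    ci: tuple[float, float] | None
    wald_p: float | None
    perm_p: float | None
    n_used: int


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference per coefficient."""

    params: pd.Series
    cov: pd.DataFrame
    aor: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    n_used: int
    converged: bool
    separation_flags: list[str] = field(default_factory=list)


@dataclass
class PermutationResult:
    p: float
    t_obs: float
    r_used: int
    n_redrawn: int
    statistic: str
    regenerated: str


def _binary_series(frame: pd.DataFrame, variable: str,
                   catalogue: VariableCatalogue | None,
                   contrast: str | None) -> pd.Series:
    """0/1/NaN series for a variable, binarized by level-vs-reference when a
    contrast level is given (other levels become missing)."""
    col = frame[variable]
    if col.dtype != object and contrast in (None, "1", 1):
        return col.astype(float)
    if catalogue is None or variable not in catalogue:
        raise ValueError(
            f"{variable!r} needs a catalogue entry to binarize by contrast")
    var = catalogue[variable]
    if contrast is None:
        raise ValueError(f"{variable!r} is categorical: a contrast level is "
                         "required")
    ref = var.reference
    out = pd.Series(np.nan, index=frame.index)
    out[col == str(contrast)] = 1.0
    out[col == ref] = 0.0
    return out


def crosstab(records, correlate: str, outcome: str,
             catalogue: VariableCatalogue | None = None,
             level_contrast: str | None = None) -> ContingencyTable2x2:
    """2x2 table of a (possibly binarized) correlate against a binary outcome.

    Complete-case on the pair: respondents missing either value are excluded
    (their number is recoverable as ``len(records) - table.n``).
    """
    frame = records if isinstance(records, pd.DataFrame) else \
        records_to_frame(records, catalogue)
    if len(frame) == 0:
        raise ValueError("no records")
    x = _binary_series(frame, correlate, catalogue, level_contrast)
    y = _binary_series(frame, outcome, catalogue, None)
    mask = x.notna() & y.notna()
    xv = x[mask].to_numpy()
    yv = y[mask].to_numpy()
    a = int(np.sum((xv == 1) & (yv == 1)))
    b = int(np.sum((xv == 1) & (yv == 0)))
    c = int(np.sum((xv == 0) & (yv == 1)))
    d = int(np.sum((xv == 0) & (yv == 0)))
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio_wald(table: ContingencyTable2x2) -> OddsRatioResult:
    """Cross-product OR with Wald 95% CI and two-sided p.

    ``OR = ad/bc``; ``CI = exp(ln OR +- 1.96 * sqrt(1/a+1/b+1/c+1/d))``.
    Any zero cell triggers a 0.5 continuity correction applied to all four
    cells (flagged).  Two zero cells on a diagonal leave the OR undefined.
    """
    a, b, c, d = table.as_tuple()
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return OddsRatioResult(None, None, None, None, None, undefined=True)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    log_or = float(np.log(a * d / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    lo, hi = np.exp(log_or - Z95 * se), np.exp(log_or + Z95 * se)
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return OddsRatioResult(float(np.exp(log_or)), (float(lo), float(hi)), p,
                           log_or, se, continuity_corrected=corrected)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def build_design(frame: pd.DataFrame, predictors: list[str],
                 catalogue: VariableCatalogue, outcome: str
                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Complete-case outcome vector and design matrix with catalogue
    reference-level contrasts.  Binary predictors enter as single 0/1
    columns; categorical predictors expand to indicator columns named
    ``var[level]`` against the declared reference."""
    cols: dict[str, pd.Series] = {}
    for name in predictors:
        var = catalogue[name]
        if var.kind == "binary":
            cols[name] = frame[name].astype(float)
        else:
            base = frame[name]
            missing = base.isna()
            for level in var.contrast_levels:
                ind = (base == level).astype(float)
                ind[missing] = np.nan
                cols[f"{name}[{level}]"] = ind
    x = pd.DataFrame(cols, index=frame.index)
    y = _binary_series(frame, outcome, catalogue, None)
    mask = y.notna() & x.notna().all(axis=1)
    x = sm.add_constant(x[mask], prepend=True)
    return y[mask], x


def logistic_fit(records, outcome: str, predictors: list[str],
                 catalogue: VariableCatalogue,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS) with Wald inference.

    Raises on non-convergence; flags quasi-complete separation when any
    coefficient magnitude exceeds 15.
    """
    frame = records if isinstance(records, pd.DataFrame) else \
        records_to_frame(records, catalogue)
    y, x = build_design(frame, predictors, catalogue, outcome)
    if len(y) < x.shape[1]:
        raise ValueError(
            f"only {len(y)} complete cases for {x.shape[1]} parameters")
    if y.nunique() < 2:
        raise ValueError(f"outcome {outcome!r} is constant in the sample")
    model = sm.GLM(y, x, family=sm.families.Binomial())
    res = model.fit(maxiter=max_iter, tol=tol)
    converged = bool(res.converged)
    if not converged:
        raise RuntimeError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(deviance {res.deviance:.4g})")
    params = res.params
    flags = [name for name, val in params.items()
             if name != "const" and abs(val) > 15]
    if flags:
        warnings.warn(f"possible quasi-complete separation: {flags}")
    ci = np.exp(res.conf_int())
    ci.columns = ["low", "high"]
    return LogisticFit(
        params=params,
        cov=res.cov_params(),
        aor=np.exp(params),
        conf_int=ci,
        pvalues=res.pvalues,
        n_used=int(len(y)),
        converged=converged,
        separation_flags=flags,
    )


def select_multivariable(bivariable_results, threshold: float = 0.05,
                         comparator: str = "le") -> list[str]:
    """Predictors whose bivariable model p meets the threshold.

    A categorical predictor enters whole if any non-reference level
    qualifies.  ``bivariable_results`` is an iterable of
    :class:`AssociationResult` (or ``(correlate, level, p)`` tuples).
    ``comparator`` is ``"le"`` (p <= threshold) or ``"lt"``.
    """
    if comparator not in ("le", "lt"):
        raise ValueError("comparator must be 'le' or 'lt'")
    selected: list[str] = []
    for item in bivariable_results:
        if isinstance(item, tuple):
            name, _, p = item
        else:
            name, p = item.correlate, item.wald_p
        if p is None:
            continue
        ok = p <= threshold if comparator == "le" else p < threshold
        if ok and name not in selected:
            selected.append(name)
    return selected


# ---------------------------------------------------------------------------
# dependent permutation test
# ---------------------------------------------------------------------------

def _chain_transition(forest: RecruitmentForest,
                      x_by_id: dict[str, float]) -> tuple[np.ndarray, float]:
    """First-order Markov transition of the binarized correlate along
    recruiter-recruit edges, with 0.5 pseudocounts; plus the root marginal
    (observed overall proportion)."""
    counts = np.full((2, 2), 0.5)
    for node, par in forest.parent.items():
        if par is None:
            continue
        pv, cv = x_by_id.get(par), x_by_id.get(node)
        if pv is None or cv is None or np.isnan(pv) or np.isnan(cv):
            continue
        counts[int(pv), int(cv)] += 1.0
    trans = counts / counts.sum(axis=1, keepdims=True)
    obs = np.array([v for v in x_by_id.values()
                    if v is not None and not np.isnan(v)])
    marginal = float(obs.mean())
    return trans, marginal


def _log_or_stat(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ln OR for replicate correlate matrix ``x`` (R, n) against a
    fixed outcome ``y`` (n,).  Zero-cell tables get a 0.5 correction.
    Returns (statistics, defined mask); undefined = correlate constant."""
    x = x.astype(np.int64, copy=False)
    y = y.astype(np.int64, copy=False)
    n = y.size
    y1 = int(y.sum())
    n1 = x.sum(axis=1)
    a = x @ y
    b = n1 - a
    c = y1 - a
    d = n - n1 - c
    cells = np.stack([a, b, c, d], axis=1).astype(float)
    defined = (n1 > 0) & (n1 < n)
    zero = (cells == 0).any(axis=1)
    cells[zero] += 0.5
    t = np.log(cells[:, 0] * cells[:, 3] / (cells[:, 1] * cells[:, 2]))
    return t, defined


def _regenerate(rng: np.random.Generator, r: int, wave_order: list[np.ndarray],
                parent_pos: np.ndarray, trans: np.ndarray,
                marginal: float, n: int) -> np.ndarray:
    """Draw ``r`` null correlate vectors over the forest (wave by wave)."""
    x = np.zeros((r, n), dtype=np.int8)
    p1 = trans[:, 1]  # P(child = 1 | parent level)
    for depth, nodes in enumerate(wave_order):
        if depth == 0:
            x[:, nodes] = rng.random((r, nodes.size)) < marginal
        else:
            pv = x[:, parent_pos[nodes]]
            x[:, nodes] = rng.random((r, nodes.size)) < p1[pv]
    return x


def dependent_permutation_test(records, forest: RecruitmentForest,
                               correlate: str, outcome: str,
                               catalogue: VariableCatalogue | None = None,
                               r_replicates: int = 9_999,
                               random_seed: int | None = None,
                               rng: np.random.Generator | None = None,
                               level_contrast: str | None = None,
                               statistic: str = "log_or",
                               regenerate: str = "correlate",
                               transition: np.ndarray | None = None
                               ) -> PermutationResult:
    """Dependence-preserving permutation p-value for correlate vs outcome.

    Null replicates regenerate the correlate over the recruitment forest:
    roots are drawn from the observed marginal and every recruit from the
    estimated recruiter->recruit transition row of its parent's regenerated
    level.  This preserves a sampling and dependence structure like the
    observed one while breaking any correlate-outcome association.  The test
    statistic is ln OR (continuity-corrected on zero cells); the two-sided
    p-value is ``(1 + #{|T_r| >= |T_obs|}) / (R + 1)``.

    ``regenerate="outcome"`` and ``statistic="correlation"`` (the phi
    coefficient) are admissible alternative readings of the construction and
    are provided as options.

    Replicates with an undefined statistic (regenerated variable constant)
    are redrawn, capped at ``10 * R`` total draws.  ``transition`` overrides
    the estimated transition matrix (e.g. equal rows for an iid null).
    """
    if r_replicates < 99:
        raise ValueError("need R >= 99 permutation replicates")
    if statistic not in ("log_or", "correlation"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if regenerate not in ("correlate", "outcome"):
        raise ValueError(f"unknown regenerate target {regenerate!r}")
    frame = records if isinstance(records, pd.DataFrame) else \
        records_to_frame(records, catalogue)
    if rng is None:
        rng = np.random.default_rng(random_seed)

    x = _binary_series(frame, correlate, catalogue, level_contrast)
    y = _binary_series(frame, outcome, catalogue, None)
    if regenerate == "outcome":
        x, y = y, x
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    mask = ~np.isnan(xv) & ~np.isnan(yv)
    if xv[mask].std() == 0:
        raise ValueError("correlate is constant among analysed respondents")
    if yv[mask].std() == 0:
        raise ValueError("outcome is constant among analysed respondents")

    ids = list(frame["respondent_id"])
    pos = {rid: i for i, rid in enumerate(ids)}
    x_by_id = {rid: xv[pos[rid]] for rid in ids}
    trans, marginal = _chain_transition(forest, x_by_id)
    if transition is not None:  # override (e.g. a known/null transition)
        trans = np.asarray(transition, dtype=float)

    depths = forest.depths()
    max_depth = max(depths.values())
    wave_order = [
        np.array(sorted(pos[nid] for nid, dep in depths.items()
                        if dep == depth), dtype=np.int64)
        for depth in range(max_depth + 1)
    ]
    parent_pos = np.full(len(ids), -1, dtype=np.int64)
    for nid, par in forest.parent.items():
        if par is not None:
            parent_pos[pos[nid]] = pos[par]

    y_used = yv[mask].astype(np.int8)
    mask_idx = np.flatnonzero(mask)

    def stat_for(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # sub: (replicates, n_used) binary correlate values on analysed rows
        if statistic == "log_or":
            return _log_or_stat(sub, y_used)
        xc = sub - sub.mean(axis=1, keepdims=True)
        yc = y_used - y_used.mean()
        sx = sub.std(axis=1)
        defined = sx > 0
        sx = np.where(defined, sx, 1.0)
        t = (xc @ yc) / (len(y_used) * sx * y_used.std())
        return t, defined

    t_obs_arr, _ = stat_for(xv[mask][None, :].astype(np.int8))
    t_obs = float(t_obs_arr[0])

    r = r_replicates
    t_null = np.empty(r)
    filled = 0
    drawn = 0
    n_redrawn = 0
    while filled < r:
        batch = min(r - filled, r)
        if drawn + batch > 10 * r:
            raise RuntimeError(
                "permutation statistic undefined in too many replicates")
        x_rep = _regenerate(rng, batch, wave_order, parent_pos, trans,
                            marginal, len(ids))
        t, defined = stat_for(x_rep[:, mask_idx])
        n_bad = int((~defined).sum())
        n_redrawn += n_bad
        keep = t[defined][: r - filled]
        t_null[filled:filled + keep.size] = keep
        filled += keep.size
        drawn += batch
    p = float((1 + np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12)) / (r + 1))
    return PermutationResult(p=p, t_obs=t_obs, r_used=r, n_redrawn=n_redrawn,
                             statistic=statistic, regenerated=regenerate)


# ---------------------------------------------------------------------------
# bivariable -> selection -> multivariable pathway
# ---------------------------------------------------------------------------

def bivariable_associations(records, forest: RecruitmentForest | None,
                            outcome: str, correlates: list[str],
                            catalogue: VariableCatalogue, *,
                            r_replicates: int = 999,
                            rng: np.random.Generator | None = None,
                            include_permutation: bool = True
                            ) -> list[AssociationResult]:
    """Per-contrast bivariable OR, Wald p (from the one-predictor logistic
    model) and, optionally, the dependent permutation p."""
    frame = records if isinstance(records, pd.DataFrame) else \
        records_to_frame(records, catalogue)
    results: list[AssociationResult] = []
    for name in correlates:
        var = catalogue[name]
        try:
            fit = logistic_fit(frame, outcome, [name], catalogue)
        except ValueError:
            fit = None
        for level in var.contrast_levels:
            coef_name = name if var.kind == "binary" else f"{name}[{level}]"
            contrast = level if var.kind == "categorical" else None
            table = crosstab(frame, name, outcome, catalogue,
                             level_contrast=contrast)
            orr = odds_ratio_wald(table)
            wald_p = (float(fit.pvalues[coef_name])
                      if fit is not None and coef_name in fit.pvalues
                      else orr.p)
            perm_p = None
            if include_permutation and forest is not None:
                try:
                    perm = dependent_permutation_test(
                        frame, forest, name, outcome, catalogue,
                        r_replicates=r_replicates, rng=rng,
                        level_contrast=contrast)
                    perm_p = perm.p
                except ValueError:
                    perm_p = None
            results.append(AssociationResult(
                correlate=name, level=level, reference=var.reference,
                table=table, or_=orr.or_, ci=orr.ci, wald_p=wald_p,
                perm_p=perm_p, n_used=table.n))
    return results


def association_pathway(records, forest: RecruitmentForest | None,
                        outcome: str, correlates: list[str],
                        catalogue: VariableCatalogue, *,
                        threshold: float = 0.05, comparator: str = "le",
                        r_replicates: int = 999,
                        rng: np.random.Generator | None = None,
                        include_permutation: bool = True) -> dict:
    """Bivariable associations, p-threshold selection, multivariable fit."""
    bivariable = bivariable_associations(
        records, forest, outcome, correlates, catalogue,
        r_replicates=r_replicates, rng=rng,
        include_permutation=include_permutation)
    selected = select_multivariable(bivariable, threshold, comparator)
    multivariable = None
    if selected:
        multivariable = logistic_fit(records, outcome, selected, catalogue)
    return {"bivariable": bivariable, "selected": selected,
            "multivariable": multivariable}


def multiple_overdose_model(records, outcome_recoded: str,
                            catalogue: VariableCatalogue,
                            correlates: list[str] | None = None, *,
                            threshold: float = 0.05, comparator: str = "le",
                            rng: np.random.Generator | None = None) -> dict:
    """Repeat-event model: the same bivariable -> selection -> multivariable
    pathway applied to a recoded outcome (>= 2 events vs one) on the
    subsample with any event (respondents missing the recode are excluded).

    Permutation p-values are not computed here: restricting to the event
    subsample fragments the recruitment chains the dependent null relies on.
    """
    frame = records if isinstance(records, pd.DataFrame) else \
        records_to_frame(records, catalogue)
    sub = frame[frame[outcome_recoded].notna()].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no respondents with the recoded outcome observed")
    if sub[outcome_recoded].nunique() < 2:
        raise ValueError(f"recoded outcome {outcome_recoded!r} is constant")
    if len(sub) < 30:
        warnings.warn(f"repeat-event subsample has only {len(sub)} members")
    if correlates is None:
        correlates = [n for n in catalogue.covariate_names()
                      if n != outcome_recoded and sub[n].nunique() > 1]
    result = association_pathway(
        sub, None, outcome_recoded, correlates, catalogue,
        threshold=threshold, comparator=comparator, rng=rng,
        include_permutation=False)
    result["n_subsample"] = int(len(sub))
    return result
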