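"""Successive-sampling (SS) population proportion estimation.

The SS model treats an RDS sample as ``n`` sequential draws without
replacement from a working population of ``N`` units, each drawn with
probability proportional to its network size (degree).  Respondents'
inclusion probabilities under that model are therefore unequal, and
population proportions are estimated by inverse-inclusion-probability
weighting.

Inclusion probabilities have no convenient closed form at interior ``n/N``;
they are estimated here by Monte-Carlo simulation of the successive-sampling
process itself, using the equivalence between PPS sequential sampling and an
"exponential race": unit ``i`` with size ``d_i`` draws ``T_i = E_i / d_i``
with ``E_i`` standard exponential, and the sample consists of the ``n``
smallest ``T_i``.  The estimator iterates between (a) re-estimating the
population degree composition from the current weights and (b) re-estimating
per-degree-class inclusion probabilities by simulation, starting from the
with-replacement ``1/degree`` approximation.

Degrees are pooled into classes holding at least ``min_class_size`` sample
members, and the Monte-Carlo inclusion probabilities are smoothed by
isotonic regression (inclusion probability is non-decreasing in degree),
which keeps the weight-degree relationship monotone in the presence of
simulation noise.

Standard errors come from a seed-level tree bootstrap that resamples whole
recruitment trees, respecting the dependence recruitment chains induce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogue import VariableCatalogue
from .io import RecruitmentForest, RespondentRecord, records_to_frame


@dataclass(frozen=True)
class SSConfig:
    """Tuning for the SS estimator.

    ``N`` is the assumed working population size; ``n_inner_simulations``
    the number of simulated successive-sampling draws per iteration;
    ``B`` the number of tree-bootstrap replicates.
    """

    N: int = 15_000
    n_inner_simulations: int = 1_000
    max_iterations: int = 20
    tolerance: float = 1e-3
    B: int = 500
    min_class_size: int = 5
    isotonic: bool = True
    random_seed: int | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.n_inner_simulations < 1:
            raise ValueError("n_inner_simulations must be >= 1")


@dataclass
class SSWeights:
    """Normalized SS weights plus convergence diagnostics."""

    weights: np.ndarray
    iterations: int
    converged: bool
    near_census: bool
    pi_by_class: np.ndarray
    class_of: np.ndarray
    class_degrees: np.ndarray

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.weights, dtype=dtype)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class SSEstimate:
    """Population proportion estimate for one variable level."""

    variable: str
    level: str
    estimate: float
    se: float | None
    n_used: int
    N: int
    weights: np.ndarray | None = field(default=None, repr=False)
    iterations: int = 0
    converged: bool = True
    near_census: bool = False


def _pava_increasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators: non-decreasing fit to y."""
    y = y.astype(float).copy()
    w = w.astype(float).copy()
    blocks = [[i] for i in range(len(y))]
    vals = list(y)
    wts = list(w)
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1] + 1e-15:
            tot = wts[i] + wts[i + 1]
            vals[i] = (vals[i] * wts[i] + vals[i + 1] * wts[i + 1]) / tot
            wts[i] = tot
            blocks[i].extend(blocks[i + 1])
            del vals[i + 1], wts[i + 1], blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty_like(y)
    for val, idxs in zip(vals, blocks):
        out[list(idxs)] = val
    return out


def _largest_remainder_round(x: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing to ``total``; entries
    with positive input keep at least one unit."""
    base = np.floor(x).astype(np.int64)
    frac = x - base
    short = total - int(base.sum())
    if short > 0:
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(frac, kind="stable")
        take = order[base[order] > 0][: -short]
        base[take] -= 1
    # every observed degree value must appear at least once
    zero = (base == 0) & (x > 0)
    while zero.any() and base.sum() >= zero.sum():
        base[zero] = 1
        excess = int(base.sum()) - total
        if excess > 0:
            big = np.argsort(-base, kind="stable")
            for j in big:
                if excess == 0:
                    break
                room = base[j] - 1
                take = min(room, excess)
                base[j] -= take
                excess -= take
        zero = (base == 0) & (x > 0)
    return base


def _degree_classes(counts: np.ndarray, min_size: int) -> np.ndarray:
    """Pool ascending unique degrees into classes of >= min_size members."""
    class_of = np.zeros(len(counts), dtype=np.int64)
    cls = 0
    acc = 0
    for i, c in enumerate(counts):
        class_of[i] = cls
        acc += c
        if acc >= min_size and i < len(counts) - 1:
            cls += 1
            acc = 0
    # merge an undersized trailing class into its neighbour
    if cls > 0 and acc and acc < min_size:
        class_of[class_of == cls] = cls - 1
    # renumber densely
    _, dense = np.unique(class_of, return_inverse=True)
    return dense


def ss_weights(degrees, config: SSConfig | None = None, *,
               rng: np.random.Generator | None = None,
               init: np.ndarray | None = None) -> SSWeights:
    """Iterative Monte-Carlo successive-sampling weights.

    Parameters
    ----------
    degrees
        Complete (post-imputation) vector of positive integer degrees.
    init
        Optional warm-start weight vector (e.g. the full-sample solution
        when re-weighting bootstrap replicates).

    Returns normalized weights (summing to 1).  If the weight iteration does
    not reach ``config.tolerance`` within ``config.max_iterations`` the last
    iterate is returned with ``converged=False`` and a warning.
    """
    if config is None:
        config = SSConfig()
    d = np.asarray(degrees, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("degrees must be a non-empty 1-d vector")
    if np.any(~np.isfinite(d)) or np.any(d < 1):
        raise ValueError("degrees must be present (imputed) and >= 1")
    n = d.size
    N = config.N
    if N < n:
        raise ValueError(f"working population size N={N} is smaller than n={n}")
    near_census = n / N >= 0.8
    if rng is None:
        rng = np.random.default_rng(config.random_seed)

    uniq, inv = np.unique(d, return_inverse=True)
    counts = np.bincount(inv)
    class_of_uniq = _degree_classes(counts, config.min_class_size)
    cls = class_of_uniq[inv]
    n_classes = int(class_of_uniq.max()) + 1
    class_degrees = np.array([
        np.average(uniq[class_of_uniq == c], weights=counts[class_of_uniq == c])
        for c in range(n_classes)
    ])

    w = init.copy().astype(float) if init is not None else 1.0 / d
    w = w / w.sum()
    sims = config.n_inner_simulations
    converged = False
    iteration = 0
    floor = 1.0 / (2.0 * sims)
    for iteration in range(1, config.max_iterations + 1):
        # population composition implied by the current weights
        target = N * np.bincount(inv, weights=w, minlength=len(uniq))
        M = _largest_remainder_round(target, N)
        pop_deg = np.repeat(uniq, M)
        pop_cls = np.repeat(class_of_uniq, M)  # sorted (uniq ascending)
        starts = np.searchsorted(pop_cls, np.arange(n_classes))
        n_pop_cls = np.bincount(pop_cls, minlength=n_classes).astype(float)

        incl = np.zeros(n_classes)
        chunk = max(1, int(3e7 // max(N, 1)))
        done = 0
        pop_deg32 = pop_deg.astype(np.float32)
        while done < sims:
            c = min(chunk, sims - done)
            t = rng.standard_exponential((c, N), dtype=np.float32) / pop_deg32
            kth = np.partition(t, n - 1, axis=1)[:, n - 1]
            inc = t <= kth[:, None]
            incl += np.add.reduceat(inc, starts, axis=1).sum(axis=0)
            done += c
        pi = incl / (sims * np.maximum(n_pop_cls, 1.0))
        if np.any(pi <= 0):
            warnings.warn("zero simulated inclusion probability; flooring")
            pi = np.maximum(pi, floor)
        if config.isotonic and n_classes > 1:
            pi = _pava_increasing(pi, n_pop_cls)
        w_new = 1.0 / pi[cls]
        w_new = w_new / w_new.sum()
        rel = float(np.max(np.abs(w_new / w - 1.0)))
        w = w_new
        if rel < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SS weight iteration stopped after {iteration} iterations "
            "without meeting tolerance; returning last iterate")
    return SSWeights(weights=w, iterations=iteration, converged=converged,
                     near_census=near_census, pi_by_class=pi, class_of=cls,
                     class_degrees=class_degrees)


def _frame(records, catalogue):
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records, catalogue)


def _level_indicator(frame: pd.DataFrame, variable: str, level) -> tuple[
        np.ndarray, np.ndarray]:
    """(observed mask, indicator of `level`) for one variable column."""
    col = frame[variable]
    if col.dtype == object:
        obs = col.notna().to_numpy()
        ind = (col == str(level)).to_numpy()
    else:
        vals = col.to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        ind = vals == float(level)
    return obs, ind


def ss_proportion(records, variable: str, level, weights,
                  catalogue: VariableCatalogue | None = None) -> float:
    """Weighted population proportion of ``level`` among observed cases.

    Respondents missing on the variable are excluded and the weights
    renormalized over observed cases, matching the per-variable reduced-n
    convention of descriptive survey tables.
    """
    frame = _frame(records, catalogue)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(frame):
        raise ValueError("weights length must match the number of records")
    obs, ind = _level_indicator(frame, variable, level)
    if not obs.any():
        raise ValueError(f"all values of {variable!r} are missing")
    denom = w[obs].sum()
    return float(w[obs & ind].sum() / denom)


def ss_bootstrap_se(records, forest: RecruitmentForest, variable: str, level,
                    config: SSConfig,
                    catalogue: VariableCatalogue | None = None, *,
                    degrees: np.ndarray | None = None,
                    rng: np.random.Generator | None = None,
                    warm_start: bool = True) -> float:
    """Tree-bootstrap standard error of the SS proportion.

    Recruitment trees (seeds) are resampled with replacement until the
    resampled size reaches ``n``; the last tree is truncated breadth-first.
    SS weights and the weighted proportion are recomputed per replicate and
    the SE is the standard deviation over ``config.B`` replicates.
    """
    if config.B < 2:
        raise ValueError("need B >= 2 bootstrap replicates")
    if len(forest.roots) == 1:
        warnings.warn("single-tree forest: bootstrap SE is unreliable")
    frame = _frame(records, catalogue)
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    n = len(frame)
    if degrees is None:
        degrees = frame["degree"].to_numpy(dtype=float)
    degrees = np.asarray(degrees, dtype=float)
    row_of = {rid: i for i, rid in enumerate(frame["respondent_id"])}
    tree_rows = [
        np.array([row_of[x] for x in forest.bfs_order(root)], dtype=np.int64)
        for root in forest.roots
    ]
    base = ss_weights(degrees, config, rng=rng) if warm_start else None
    obs, ind = _level_indicator(frame, variable, level)

    estimates = np.empty(config.B)
    n_trees = len(tree_rows)
    for b in range(config.B):
        rows: list[np.ndarray] = []
        size = 0
        while size < n:
            tree = tree_rows[int(rng.integers(n_trees))]
            take = min(len(tree), n - size)
            rows.append(tree[:take])  # bfs prefix when truncating
            size += take
        idx = np.concatenate(rows)
        init = base.weights[idx] if base is not None else None
        wts = ss_weights(degrees[idx], config, rng=rng, init=init).weights
        o, i_ = obs[idx], ind[idx]
        estimates[b] = wts[o & i_].sum() / wts[o].sum()
    return float(np.std(estimates, ddof=1))


def sensitivity_to_N(records, variable: str, level, n_grid,
                     config: SSConfig,
                     catalogue: VariableCatalogue | None = None, *,
                     degrees: np.ndarray | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Point estimate across a grid of working population sizes.

    Returns a frame with columns ``N``, ``estimate`` and ``near_census``;
    the maximum absolute spread is stored in ``frame.attrs["max_spread"]``.
    """
    frame = _frame(records, catalogue)
    if degrees is None:
        degrees = frame["degree"].to_numpy(dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.random_seed)
    rows = []
    for N in n_grid:
        cfg = SSConfig(N=int(N), n_inner_simulations=config.n_inner_simulations,
                       max_iterations=config.max_iterations,
                       tolerance=config.tolerance, B=config.B,
                       min_class_size=config.min_class_size,
                       isotonic=config.isotonic,
                       random_seed=config.random_seed)
        ws = ss_weights(degrees, cfg, rng=rng)
        est = ss_proportion(frame, variable, level, ws.weights)
        rows.append({"N": int(N), "estimate": est,
                     "near_census": ws.near_census})
    out = pd.DataFrame(rows)
    out.attrs["max_spread"] = float(out["estimate"].max()
                                    - out["estimate"].min())
    return out
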