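"""Synthetic hidden populations and coupon-limited RDS recruitment.

The generator produces a ground-truth population — an undirected simple
contact graph with controllable degree distribution, trait homophily and an
outcome drawn from a logistic model over traits — and then simulates
respondent-driven sampling on it: seeds root recruitment trees, each
respondent offers up to ``coupon_limit`` coupons to uniformly chosen
unsampled neighbours, and each offered coupon is redeemed with a fixed
probability.  Because the ground truth (graph, trait values, inclusion
order) is retained, every downstream stage — degree imputation,
successive-sampling estimation, dependence-aware testing — can be checked
against known population quantities.

Graph construction is a configuration model (stub matching with rejection of
self-loops and multi-edges) followed by targeted double-edge swaps that raise
each trait's edge concordance to a target that is a monotone function of its
homophily weight ``h``:

    C(h) = C0 + (1 - C0) * h / (1 + h),   C0 = sum_l p_l^2

where ``C0`` is the concordance expected under independent assignment.
Rewiring preserves the degree sequence exactly.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .catalogue import VariableCatalogue, default_study_catalogue
from .io import RecruitmentForest, RespondentRecord, build_forest


class RewiringError(RuntimeError):
    """Homophily rewiring failed to reach its concordance targets."""


@dataclass(frozen=True)
class TraitSpec:
    """One population trait: prevalence (binary) or level probabilities
    (categorical), homophily weight ``h >= 0`` and an optional log-degree
    coefficient that tilts binary trait assignment toward high-degree nodes
    (used to induce the degree-trait correlation that biases raw RDS sample
    proportions)."""

    name: str
    prevalence: float | None = None
    levels: tuple[str, ...] | None = None
    probs: tuple[float, ...] | None = None
    homophily: float = 0.0
    degree_coef: float = 0.0

    def __post_init__(self) -> None:
        if (self.prevalence is None) == (self.levels is None):
            raise ValueError(f"{self.name}: give prevalence xor levels/probs")
        if self.prevalence is not None and not 0 < self.prevalence < 1:
            raise ValueError(f"{self.name}: prevalence must be in (0, 1)")
        if self.levels is not None:
            if self.probs is None or len(self.probs) != len(self.levels):
                raise ValueError(f"{self.name}: probs must match levels")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ValueError(f"{self.name}: probs must sum to 1")
        if self.homophily < 0:
            raise ValueError(f"{self.name}: homophily must be >= 0")

    @property
    def kind(self) -> str:
        return "binary" if self.prevalence is not None else "categorical"

    def level_probs(self) -> np.ndarray:
        if self.kind == "binary":
            return np.array([1 - self.prevalence, self.prevalence])
        return np.asarray(self.probs, dtype=float)

    def independence_concordance(self) -> float:
        p = self.level_probs()
        return float(np.sum(p * p))

    def target_concordance(self) -> float:
        c0 = self.independence_concordance()
        return c0 + (1.0 - c0) * self.homophily / (1.0 + self.homophily)


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic outcome generator: logit P(Y=1) = intercept + sum(coef).

    Coefficient keys are trait names for binary traits or ``"name:level"``
    for categorical indicator contrasts.  If ``target_prevalence`` is given,
    the intercept is solved on the realized population so the expected
    outcome prevalence hits the target.
    """

    intercept: float | None = None
    coef: dict[str, float] = field(default_factory=dict)
    target_prevalence: float | None = None

    def __post_init__(self) -> None:
        if (self.intercept is None) == (self.target_prevalence is None):
            raise ValueError("give intercept xor target_prevalence")
        for key, val in self.coef.items():
            if not math.isfinite(val):
                raise ValueError(f"non-finite coefficient for {key!r}")


@dataclass(frozen=True)
class PopulationSpec:
    population_size: int = 15_000
    degree_distribution: tuple[str, dict] = (
        "nbinom", {"mean": 9.0, "shape": 1.5},
    )
    traits: tuple[TraitSpec, ...] = ()
    outcome_model: OutcomeModel | None = None
    missing_degree_rate: float = 0.0
    #: optional departure from MCAR for imputation stress tests: respondents
    #: with this binary trait = 1 have `missing_degree_odds`-fold odds of a
    #: missing degree (overall rate kept at missing_degree_rate)
    missing_degree_covariate: str | None = None
    missing_degree_odds: float = 2.0
    degree_noise_sd: float = 0.0  # sd of multiplicative log-normal reporting noise
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.missing_degree_rate < 1:
            raise ValueError("missing_degree_rate must be in [0, 1)")


@dataclass(frozen=True)
class RDSSampleSpec:
    n_target: int = 539
    n_seeds: int = 20
    coupon_limit: int = 3
    referral_acceptance: float = 0.5
    seed_selection: str = "degree_weighted"  # "uniform" | "degree_weighted"
    reseed_on_exhaustion: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds > self.n_target:
            raise ValueError("n_seeds must be <= n_target")
        if not 0 <= self.referral_acceptance <= 1:
            raise ValueError("referral_acceptance must be in [0, 1]")
        if self.seed_selection not in ("uniform", "degree_weighted"):
            raise ValueError(f"unknown seed_selection {self.seed_selection!r}")


@dataclass
class SyntheticWorld:
    """Ground-truth population: simple graph, trait values, outcome draws."""

    spec: PopulationSpec
    edges: np.ndarray                  # (m, 2) int node pairs, u < v
    degrees: np.ndarray                # realized degree per node
    traits: dict[str, np.ndarray]      # binary: 0/1; categorical: level codes
    trait_levels: dict[str, tuple[str, ...]]
    outcome: np.ndarray | None
    realized_prevalence: dict[str, object]
    aux: dict[str, np.ndarray] = field(default_factory=dict)  # float, NaN ok
    _adjacency: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False)

    @property
    def population_size(self) -> int:
        return self.spec.population_size

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR-style (indptr, indices) adjacency for fast neighbour lookup."""
        if self._adjacency is None:
            n = self.population_size
            heads = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
            tails = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
            order = np.argsort(heads, kind="stable")
            indices = tails[order]
            counts = np.bincount(heads, minlength=n)
            indptr = np.concatenate([[0], np.cumsum(counts)])
            self._adjacency = (indptr, indices)
        return self._adjacency

    @property
    def graph(self):
        """The population contact network as a ``networkx.Graph``."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.population_size))
        g.add_edges_from(map(tuple, self.edges))
        return g


@dataclass
class SimulatedSample:
    """One RDS draw: respondent records, recruitment forest, ground truth."""

    records: list[RespondentRecord]
    forest: RecruitmentForest
    truth: dict


# ---------------------------------------------------------------------------
# population construction
# ---------------------------------------------------------------------------

def _draw_degrees(rng: np.random.Generator, family: str, params: dict,
                  n: int) -> np.ndarray:
    if family == "nbinom":
        mean, shape = params["mean"], params["shape"]
        p = shape / (shape + mean)
        deg = rng.negative_binomial(shape, p, size=n) + 1
    elif family == "poisson":
        deg = rng.poisson(params["mean"], size=n) + 1
    elif family == "uniform":
        deg = rng.integers(params["low"], params["high"] + 1, size=n)
    elif family == "constant":
        deg = np.full(n, int(params["value"]))
    else:
        raise ValueError(f"unknown degree family {family!r}")
    deg = np.asarray(deg, dtype=np.int64)
    # parity fix: resample one entry until the stub count is even
    while deg.sum() % 2 == 1:
        idx = int(rng.integers(n))
        deg[idx] = _draw_degrees(rng, family, params, 1)[0]
    return deg


def _configuration_edges(rng: np.random.Generator,
                         degrees: np.ndarray) -> np.ndarray:
    """Stub-matching configuration model; self-loops and multi-edges are
    rejected (dropped), and any node left isolated is reattached to a random
    partner so every realized degree is >= 1."""
    n = degrees.size
    stubs = np.repeat(np.arange(n), degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    keep = pairs[:, 0] != pairs[:, 1]
    pairs = pairs[keep]
    pairs = np.sort(pairs, axis=1)
    pairs = np.unique(pairs, axis=0)
    realized = np.bincount(pairs.ravel(), minlength=n)
    isolated = np.flatnonzero(realized == 0)
    if isolated.size:
        extra = []
        for node in isolated:
            partner = int(rng.integers(n - 1))
            if partner >= node:
                partner += 1
            extra.append((min(node, partner), max(node, partner)))
        pairs = np.unique(np.vstack([pairs, np.array(extra)]), axis=0)
    return pairs


def _assign_binary_trait(rng: np.random.Generator, spec: TraitSpec,
                         degrees: np.ndarray) -> np.ndarray:
    if spec.degree_coef == 0.0:
        return (rng.random(degrees.size) < spec.prevalence).astype(np.int8)
    z = spec.degree_coef * (np.log(degrees) - np.log(degrees).mean())
    a = brentq(lambda c: expit(c + z).mean() - spec.prevalence, -25, 25)
    return (rng.random(degrees.size) < expit(a + z)).astype(np.int8)


def edge_concordance(edges: np.ndarray, values: np.ndarray) -> float:
    """Fraction of edges whose two endpoints share the same trait level."""
    return float(np.mean(values[edges[:, 0]] == values[edges[:, 1]]))


def _rewire_for_homophily(edges: np.ndarray, values: list[np.ndarray],
                          targets: list[float], rng: np.random.Generator,
                          tol: float = 0.01, max_passes: int = 300,
                          fail_slack: float = 0.015) -> np.ndarray:
    """Batched double-edge swaps pushing each trait's edge concordance to its
    target (from either side).  Degree-preserving; self-loops and duplicate
    edges are rejected per proposal.  Raises :class:`RewiringError`, reporting
    the achieved concordances, if targets are not met within ``fail_slack``.
    """
    edges = edges.copy()
    m = len(edges)
    n_nodes = int(edges.max()) + 1
    n_traits = len(values)
    conc = np.array([edge_concordance(edges, v) for v in values])
    targets = np.asarray(targets, dtype=float)

    def key(a, b):  # unordered pair -> unique int64
        lo = np.minimum(a, b).astype(np.int64)
        hi = np.maximum(a, b).astype(np.int64)
        return lo * n_nodes + hi

    edge_set = set(key(edges[:, 0], edges[:, 1]).tolist())

    for _ in range(max_passes):
        deficit = targets - conc
        signs = np.where(deficit > tol, 1.0, np.where(deficit < -tol, -1.0, 0.0))
        if not signs.any():
            break
        perm = rng.permutation(m)
        k = m // 2
        i1, i2 = perm[:k], perm[k:2 * k]
        e1, e2 = edges[i1], edges[i2]
        flip = rng.random(k) < 0.5  # try both pairings of the second edge
        u2 = np.where(flip, e2[:, 1], e2[:, 0])
        v2 = np.where(flip, e2[:, 0], e2[:, 1])
        u1, v1 = e1[:, 0], e1[:, 1]
        ok = (u1 != v2) & (u2 != v1)
        delta = np.zeros((n_traits, k))
        for t, vals in enumerate(values):
            delta[t] = (
                (vals[u1] == vals[v2]).astype(np.int8)
                + (vals[u2] == vals[v1]).astype(np.int8)
                - (vals[u1] == vals[v1]).astype(np.int8)
                - (vals[u2] == vals[v2]).astype(np.int8)
            )
        gain = (signs[:, None] * delta).sum(axis=0)
        cand = np.flatnonzero(ok & (gain > 0))
        new1 = key(u1, v2)
        new2 = key(u2, v1)
        old1 = key(e1[:, 0], e1[:, 1])
        old2 = key(e2[:, 0], e2[:, 1])
        check_every = 512
        for step, c in enumerate(cand):
            if new1[c] == new2[c] or new1[c] in edge_set or new2[c] in edge_set:
                continue
            edge_set.discard(int(old1[c]))
            edge_set.discard(int(old2[c]))
            edge_set.add(int(new1[c]))
            edge_set.add(int(new2[c]))
            edges[i1[c]] = (u1[c], v2[c]) if u1[c] < v2[c] else (v2[c], u1[c])
            edges[i2[c]] = (u2[c], v1[c]) if u2[c] < v1[c] else (v1[c], u2[c])
            conc += delta[:, c] / m
            if step % check_every == 0:
                d = targets - conc
                if not ((d > tol) | (d < -tol)).any():
                    break
    deficit = targets - conc
    if np.any(deficit > tol + fail_slack):
        raise RewiringError(
            f"rewiring did not converge: achieved concordance {conc.tolist()} "
            f"for targets {list(targets)}"
        )
    return edges


def generate_population(spec: PopulationSpec,
                        rng: np.random.Generator | None = None) -> SyntheticWorld:
    """Realize a ground-truth population from a :class:`PopulationSpec`."""
    if rng is None:
        rng = np.random.default_rng(spec.random_seed)
    n = spec.population_size
    family, params = spec.degree_distribution
    target_degrees = _draw_degrees(rng, family, params, n)
    edges = _configuration_edges(rng, target_degrees)
    degrees = np.bincount(edges.ravel(), minlength=n)

    traits: dict[str, np.ndarray] = {}
    trait_levels: dict[str, tuple[str, ...]] = {}
    for tspec in spec.traits:
        if tspec.kind == "binary":
            traits[tspec.name] = _assign_binary_trait(rng, tspec, degrees)
            trait_levels[tspec.name] = ("0", "1")
        else:
            traits[tspec.name] = rng.choice(
                len(tspec.levels), size=n, p=tspec.probs).astype(np.int8)
            trait_levels[tspec.name] = tuple(tspec.levels)

    homophilous = [t for t in spec.traits if t.homophily > 0]
    if homophilous:
        edges = _rewire_for_homophily(
            edges,
            [traits[t.name] for t in homophilous],
            [t.target_concordance() for t in homophilous],
            rng,
        )

    outcome = None
    if spec.outcome_model is not None:
        om = spec.outcome_model
        lin = np.zeros(n)
        for key, beta in om.coef.items():
            if ":" in key:
                name, level = key.split(":", 1)
                ind = traits[name] == trait_levels[name].index(level)
            else:
                ind = traits[key] == 1
            lin += beta * ind
        u = rng.random(n)
        if om.intercept is not None:
            intercept = om.intercept
            outcome = (u < expit(intercept + lin)).astype(np.int8)
        else:
            # quantile-coupled draw: node i gets the outcome iff
            # logit(u_i) - lin_i falls below the k-th order statistic, so the
            # realized prevalence equals the target exactly (up to 1/n)
            score = np.log(u / (1.0 - u)) - lin
            k = int(round(om.target_prevalence * n))
            intercept = float(np.partition(score, k - 1)[k - 1])
            outcome = (score <= intercept).astype(np.int8)

    realized: dict[str, object] = {}
    for tspec in spec.traits:
        vals = traits[tspec.name]
        if tspec.kind == "binary":
            realized[tspec.name] = float(vals.mean())
        else:
            realized[tspec.name] = {
                lvl: float(np.mean(vals == i))
                for i, lvl in enumerate(tspec.levels)
            }
    if outcome is not None:
        realized["__outcome__"] = float(outcome.mean())

    return SyntheticWorld(spec, edges, degrees, traits, trait_levels,
                          outcome, realized)


# ---------------------------------------------------------------------------
# RDS recruitment simulation
# ---------------------------------------------------------------------------

def simulate_rds(world: SyntheticWorld, spec: RDSSampleSpec,
                 rng: np.random.Generator | None = None,
                 outcome_name: str | None = None) -> SimulatedSample:
    """Simulate one coupon-limited, without-replacement RDS sample.

    Recruitment proceeds in waves: each sampled respondent offers up to
    ``coupon_limit`` coupons to uniformly chosen unsampled neighbours; each
    offer is redeemed independently with probability ``referral_acceptance``.
    If every chain dies before ``n_target`` is reached the sample is returned
    partial with ``truth["exhausted"] = True`` (or, when
    ``reseed_on_exhaustion`` is set, fresh uniform seeds are drawn and counted
    in ``truth["reseeds"]``).

    Reported degree equals the true graph degree (optionally perturbed by
    log-normal reporting noise), masked missing-completely-at-random at the
    population spec's ``missing_degree_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.random_seed)
    if spec.n_target >= world.population_size:
        raise ValueError("n_target must be smaller than the population")
    indptr, indices = world.adjacency()
    degrees = world.degrees

    sampled = np.zeros(world.population_size, dtype=bool)
    order: list[int] = []
    parent_node: dict[int, int | None] = {}
    queue: deque[int] = deque()
    n_reseeds = 0
    exhausted = False

    def draw_seeds(count: int) -> np.ndarray:
        pool = np.flatnonzero(~sampled)
        if spec.seed_selection == "degree_weighted":
            w = degrees[pool].astype(float)
            p = w / w.sum()
        else:
            p = None
        return rng.choice(pool, size=min(count, pool.size), replace=False, p=p)

    seeds = draw_seeds(spec.n_seeds)
    for s in seeds:
        sampled[s] = True
        order.append(int(s))
        parent_node[int(s)] = None
        queue.append(int(s))

    while len(order) < spec.n_target:
        if not queue:
            if spec.reseed_on_exhaustion:
                new = draw_seeds(1)
                if new.size == 0:
                    exhausted = True
                    break
                n_reseeds += 1
                node = int(new[0])
                sampled[node] = True
                order.append(node)
                parent_node[node] = None
                queue.append(node)
                continue
            exhausted = True
            break
        recruiter = queue.popleft()
        nbrs = indices[indptr[recruiter]:indptr[recruiter + 1]]
        avail = nbrs[~sampled[nbrs]]
        if avail.size == 0:
            continue
        k = min(spec.coupon_limit, avail.size)
        offered = rng.choice(avail, size=k, replace=False)
        redeemed = rng.random(k) < spec.referral_acceptance
        for node in offered[redeemed]:
            node = int(node)
            if len(order) >= spec.n_target or sampled[node]:
                continue
            sampled[node] = True
            order.append(node)
            parent_node[node] = recruiter
            queue.append(node)

    # --- respondent records -------------------------------------------------
    node_to_rid = {node: f"r{i:04d}" for i, node in enumerate(order)}
    pspec = world.spec
    if pspec.missing_degree_covariate is None:
        probs = np.full(len(order), pspec.missing_degree_rate)
    else:
        flag = world.traits[pspec.missing_degree_covariate][order] == 1
        share = float(np.mean(flag))
        # odds-tilted rates whose mixture preserves the overall rate
        base = pspec.missing_degree_rate / (
            1.0 + share * (pspec.missing_degree_odds - 1.0))
        probs = np.where(flag,
                         np.minimum(base * pspec.missing_degree_odds, 0.95),
                         base)
    missing_mask = rng.random(len(order)) < probs
    records: list[RespondentRecord] = []
    for i, node in enumerate(order):
        reported: int | None = int(degrees[node])
        if world.spec.degree_noise_sd > 0:
            noisy = reported * math.exp(
                rng.normal(0.0, world.spec.degree_noise_sd))
            reported = max(1, int(round(noisy)))
        if missing_mask[i]:
            reported = None
        covariates: dict[str, object] = {}
        for name, vals in world.traits.items():
            levels = world.trait_levels[name]
            if levels == ("0", "1"):
                covariates[name] = int(vals[node])
            else:
                covariates[name] = levels[int(vals[node])]
        for name, vals in world.aux.items():
            v = vals[node]
            covariates[name] = None if np.isnan(v) else int(v)
        outcome_val: int | None = None
        if outcome_name is not None:
            outcome_val = covariates.get(outcome_name)
        elif world.outcome is not None:
            outcome_val = int(world.outcome[node])
        if world.outcome is not None and outcome_name is None:
            covariates.setdefault("__outcome__", outcome_val)
        par = parent_node[node]
        records.append(RespondentRecord(
            respondent_id=node_to_rid[node],
            recruiter_id=None if par is None else node_to_rid[par],
            degree=reported,
            covariates=covariates,
            outcome=outcome_val,
        ))

    forest = build_forest(records, coupon_limit=spec.coupon_limit)
    truth = {
        "nodes": [int(x) for x in order],
        "inclusion_order": {node_to_rid[n]: i for i, n in enumerate(order)},
        "seed_nodes": [int(s) for s in seeds],
        "exhausted": exhausted,
        "reseeds": n_reseeds,
        "population_prevalence": world.realized_prevalence,
        "true_degrees": {node_to_rid[n]: int(degrees[n]) for n in order},
    }
    return SimulatedSample(records, forest, truth)


# ---------------------------------------------------------------------------
# packaged study-shaped fixture
# ---------------------------------------------------------------------------

#: sample prevalences the fixture emulates (sociodemographics and drug use
#: of the young-adult opioid-user survey; categorical shares from the
#: complete-case analysis table)
STUDY_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("age_24_29", prevalence=0.550),
    TraitSpec("gender", levels=("male", "female", "transgender"),
              probs=(0.677, 0.315, 0.008)),
    TraitSpec("race_ethnicity",
              levels=("hispanic", "white_nonhispanic", "nonwhite_nonhispanic"),
              probs=(0.287, 0.615, 0.098), homophily=1.0),
    TraitSpec("income_growing_up",
              levels=("50_100k", "le_50k", "gt_100k", "dont_know_missing"),
              probs=(0.327, 0.421, 0.189, 0.063)),
    TraitSpec("education", levels=("less_than_hs", "hs_grad_ged", "beyond_hs"),
              probs=(0.199, 0.416, 0.385)),
    TraitSpec("ever_homeless", prevalence=0.574, homophily=0.6),
    TraitSpec("hcv_positive", prevalence=0.196, homophily=0.6),
    TraitSpec("benzo_regular", prevalence=0.546),
    TraitSpec("po_regular", prevalence=0.863),
    TraitSpec("heroin_regular", prevalence=0.803),
    TraitSpec("heroin_injection_regular", prevalence=0.578, homophily=0.5),
    TraitSpec("po_injection_regular", prevalence=0.173),
    TraitSpec("nonsterile_syringe", prevalence=0.250),
    TraitSpec("drug_binging", prevalence=0.687),
)

#: log-odds used to generate the lifetime-overdose outcome; positive weight on
#: the adjusted correlates of the study (values are the log adjusted ORs)
STUDY_OUTCOME = OutcomeModel(
    target_prevalence=0.439,
    coef={
        "race_ethnicity:white_nonhispanic": math.log(1.94),
        "race_ethnicity:nonwhite_nonhispanic": math.log(1.51),
        "income_growing_up:le_50k": math.log(1.21),
        "income_growing_up:gt_100k": math.log(1.88),
        "income_growing_up:dont_know_missing": math.log(1.78),
        "education:hs_grad_ged": math.log(0.54),
        "education:beyond_hs": math.log(0.55),
        "ever_homeless": math.log(1.29),
        "hcv_positive": math.log(2.64),
        "benzo_regular": math.log(2.15),
        "heroin_regular": math.log(1.23),
        "heroin_injection_regular": math.log(1.52),
        "po_injection_regular": math.log(1.96),
        "nonsterile_syringe": math.log(1.70),
        "drug_binging": math.log(1.35),
    },
)


@dataclass
class FixtureBundle:
    world: SyntheticWorld
    sample: SimulatedSample
    catalogue: VariableCatalogue

    @property
    def records(self) -> list[RespondentRecord]:
        return self.sample.records

    @property
    def forest(self) -> RecruitmentForest:
        return self.sample.forest


def study_shaped_fixture(random_seed: int = 2014,
                         population_size: int = 15_000,
                         n_target: int = 539,
                         n_seeds: int = 20,
                         missing_degree_rate: float = 0.10) -> FixtureBundle:
    """Deterministic synthetic dataset shaped like the study sample.

    A hidden population of ``population_size`` (default 15,000) young adult
    opioid users with traits at the survey's sample prevalences, homophily on
    race/ethnicity, homelessness, HCV status and regular heroin injection
    (synthetic choices — the survey reports no homophily measurements), and a
    lifetime-overdose outcome at prevalence 0.439 driven by the study's
    adjusted correlates.  An RDS sample of ``n_target`` (default 539) is drawn
    from ``n_seeds`` (default 20) seeds with a coupon limit of 3.

    A ``multiple_overdose`` recode (>=2 lifetime events, defined only among
    those with any overdose) is generated with regular heroin use and PO
    injection as its drivers, prevalence ~0.588 among the overdosed.
    """
    ss = np.random.SeedSequence(random_seed)
    rng_pop, rng_sample, rng_mult = (
        np.random.default_rng(s) for s in ss.spawn(3))
    pspec = PopulationSpec(
        population_size=population_size,
        degree_distribution=("nbinom", {"mean": 9.0, "shape": 1.5}),
        traits=STUDY_TRAITS,
        outcome_model=STUDY_OUTCOME,
        missing_degree_rate=missing_degree_rate,
        random_seed=random_seed,
    )
    world = generate_population(pspec, rng=rng_pop)

    # repeat-overdose recode among those with any overdose
    lin = (1.4 * (world.traits["heroin_regular"] == 1)
           + 1.4 * (world.traits["po_injection_regular"] == 1))
    overdosed = world.outcome == 1
    a = brentq(lambda c: expit(c + lin[overdosed]).mean() - 0.588, -25, 25)
    mult = np.full(world.population_size, np.nan)
    mult[overdosed] = (
        rng_mult.random(int(overdosed.sum())) < expit(a + lin[overdosed])
    ).astype(float)
    world.aux["multiple_overdose"] = mult
    world.realized_prevalence["multiple_overdose"] = float(
        np.nanmean(mult))

    sspec = RDSSampleSpec(n_target=n_target, n_seeds=n_seeds, coupon_limit=3,
                          referral_acceptance=0.5,
                          seed_selection="degree_weighted",
                          random_seed=random_seed)
    catalogue = default_study_catalogue()
    sample = simulate_rds(world, sspec, rng=rng_sample)
    # rename the generated outcome to the catalogue's outcome variable
    for rec in sample.records:
        rec.covariates["ever_overdose"] = rec.covariates.pop("__outcome__")
        rec.outcome = rec.covariates["ever_overdose"]
    return FixtureBundle(world, sample, catalogue)
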