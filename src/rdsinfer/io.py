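"""Reading, validating and writing RDS-structured tabular data.

The on-disk dialect is a flat UTF-8 CSV with the columns ``respondent_id``,
``recruiter_id`` (empty string = seed; a self-reference is also accepted and
normalised to seed), ``degree`` (empty = missing), followed by one column per
catalogue variable.  Binary variables are written as ``0``/``1``, categorical
variables as their level labels; missing values are empty cells.

This module also builds the :class:`RecruitmentForest` (seeds as roots,
coupon-limited out-degree) that downstream variance estimation and the
dependent permutation test rely on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogue import VariableCatalogue

REQUIRED_COLUMNS = ("respondent_id", "recruiter_id", "degree")


class RDSDataError(ValueError):
    """Raised when a dataset violates structural or coding constraints."""


@dataclass
class RespondentRecord:
    """One sampled individual.

    ``recruiter_id is None`` marks a seed.  ``degree`` is the self-reported
    network size (``None`` when missing, otherwise >= 1).  ``covariates`` maps
    variable names to 0/1 integers (binary) or level labels (categorical),
    with ``None`` for missing.  ``outcome`` mirrors the catalogue's declared
    outcome variable when one exists.
    """

    respondent_id: str
    recruiter_id: str | None
    degree: int | None
    covariates: dict[str, object] = field(default_factory=dict)
    outcome: int | None = None


@dataclass
class RecruitmentForest:
    """Set of recruitment trees over respondent ids.

    Invariants (enforced by :func:`build_forest`): acyclic, every node
    reachable from exactly one root, out-degree bounded by the coupon limit.
    """

    parent: dict[str, str | None]
    children: dict[str, list[str]]
    roots: tuple[str, ...]
    coupon_limit: int = 3

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.parent)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def depths(self) -> dict[str, int]:
        """Recruitment wave of every node (seeds are wave 0)."""
        out: dict[str, int] = {}
        for root in self.roots:
            out[root] = 0
            stack = [root]
            while stack:
                node = stack.pop()
                for ch in self.children[node]:
                    out[ch] = out[node] + 1
                    stack.append(ch)
        return out

    def bfs_order(self, root: str) -> list[str]:
        """Nodes of one tree in breadth-first (wave) order."""
        order = [root]
        i = 0
        while i < len(order):
            order.extend(self.children[order[i]])
            i += 1
        return order

    def tree_sizes(self) -> dict[str, int]:
        return {root: len(self.bfs_order(root)) for root in self.roots}

    def to_edge_list(self, path) -> None:
        """Write a (child_id, parent_id) edge-list CSV for inspection."""
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["child_id", "parent_id"])
            for node, par in self.parent.items():
                if par is not None:
                    writer.writerow([node, par])


def _parse_degree(raw: str, row: int, errors: list[str]) -> int | None:
    if raw == "":
        return None
    try:
        val = int(float(raw))
        if float(raw) != val:
            raise ValueError
    except ValueError:
        errors.append(f"row {row}: degree {raw!r} is not an integer")
        return None
    if val <= 0:
        errors.append(f"row {row}: degree must be >= 1, got {val}")
        return None
    return val


def read_rds_table(path, catalogue: VariableCatalogue) -> list[RespondentRecord]:
    """Read an RDS CSV file into validated :class:`RespondentRecord` objects.

    Hard errors (collected and raised together as :class:`RDSDataError`):
    missing required columns, duplicate respondent ids, recruiter ids that do
    not refer to an existing respondent, non-positive or non-integer degrees,
    and level labels not declared in the catalogue.  Missing values are
    preserved as missing, never silently dropped or filled.
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise RDSDataError(f"missing required columns: {missing_cols}")

    errors: list[str] = []
    ids = table["respondent_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        errors.append(f"duplicate respondent_id values: {dupes}")
    id_set = set(ids)

    records: list[RespondentRecord] = []
    for row_idx, row in enumerate(table.itertuples(index=False), start=2):
        rid = row.respondent_id
        recruiter: str | None = row.recruiter_id
        if recruiter in ("", rid):  # empty or self-reference => seed
            recruiter = None
        elif recruiter not in id_set:
            errors.append(
                f"row {row_idx}: recruiter_id {recruiter!r} does not match any "
                "respondent_id"
            )
        degree = _parse_degree(row.degree, row_idx, errors)
        covariates: dict[str, object] = {}
        for var in catalogue:
            if var.name not in table.columns:
                covariates[var.name] = None
                continue
            raw = getattr(row, var.name)
            if raw == "":
                covariates[var.name] = None
            elif raw not in var.levels:
                errors.append(
                    f"row {row_idx}: {var.name}={raw!r} not among declared "
                    f"levels {var.levels}"
                )
                covariates[var.name] = None
            else:
                covariates[var.name] = int(raw) if var.kind == "binary" else raw
        outcome = None
        if catalogue.outcome is not None:
            outcome = covariates.get(catalogue.outcome)
        records.append(RespondentRecord(rid, recruiter, degree, covariates, outcome))

    if errors:
        raise RDSDataError("; ".join(errors))
    return records


def write_rds_table(records: list[RespondentRecord], path,
                    catalogue: VariableCatalogue) -> None:
    """Write records in the flat CSV dialect (lossless round trip)."""
    header = list(REQUIRED_COLUMNS) + catalogue.names
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            row = [
                rec.respondent_id,
                "" if rec.recruiter_id is None else rec.recruiter_id,
                "" if rec.degree is None else str(rec.degree),
            ]
            for var in catalogue:
                val = rec.covariates.get(var.name)
                row.append("" if val is None else str(val))
            writer.writerow(row)


def build_forest(records: list[RespondentRecord],
                 coupon_limit: int = 3) -> RecruitmentForest:
    """Construct the recruitment forest and enforce its invariants.

    Roots are exactly the records with null recruiter id.  Raises
    :class:`RDSDataError` on duplicate ids, dangling recruiter references,
    cycles, or any recruiter with more than ``coupon_limit`` recruits.
    """
    ids = [r.respondent_id for r in records]
    if len(set(ids)) != len(ids):
        raise RDSDataError("duplicate respondent ids")
    id_set = set(ids)

    parent: dict[str, str | None] = {}
    children: dict[str, list[str]] = {rid: [] for rid in ids}
    roots: list[str] = []
    for rec in records:
        par = rec.recruiter_id
        if par == rec.respondent_id:
            par = None
        if par is not None and par not in id_set:
            raise RDSDataError(
                f"recruiter_id {par!r} of respondent {rec.respondent_id!r} "
                "does not exist"
            )
        parent[rec.respondent_id] = par
        if par is None:
            roots.append(rec.respondent_id)
        else:
            children[par].append(rec.respondent_id)

    for recruiter, kids in children.items():
        if len(kids) > coupon_limit:
            raise RDSDataError(
                f"recruiter {recruiter!r} has out-degree {len(kids)} "
                f"> coupon limit {coupon_limit}"
            )

    # cycle check: walk each node to a root, memoising settled nodes
    state: dict[str, int] = {}  # 1 = on current path, 2 = settled
    for rid in ids:
        path = []
        node: str | None = rid
        while node is not None and state.get(node) != 2:
            if state.get(node) == 1:
                raise RDSDataError(f"recruitment cycle involving {node!r}")
            state[node] = 1
            path.append(node)
            node = parent[node]
        for p in path:
            state[p] = 2
    return RecruitmentForest(parent, children, tuple(roots), coupon_limit)


def recruiter_recruit_pairs(forest: RecruitmentForest,
                            records: list[RespondentRecord],
                            variable: str) -> list[tuple[object, object]]:
    """(recruiter level, recruit level) pairs for one variable.

    One pair per non-root node where both ends are non-missing, ordered as
    (recruiter, recruit).  Used for homophily diagnostics and to fit the
    chain-dependence transition matrix of the permutation null.
    """
    values = {r.respondent_id: r.covariates.get(variable) for r in records}
    if records and variable not in records[0].covariates:
        raise KeyError(f"unknown variable {variable!r}")
    pairs = []
    for node, par in forest.parent.items():
        if par is None:
            continue
        pv, cv = values.get(par), values.get(node)
        if pv is not None and cv is not None:
            pairs.append((pv, cv))
    return pairs


def records_to_frame(records: list[RespondentRecord],
                     catalogue: VariableCatalogue) -> pd.DataFrame:
    """Tabular view of the records: one row per respondent.

    Binary variables become float columns (NaN = missing); categorical
    variables become object columns with ``None`` for missing.
    """
    data: dict[str, list] = {
        "respondent_id": [r.respondent_id for r in records],
        "recruiter_id": [r.recruiter_id for r in records],
        "degree": [np.nan if r.degree is None else float(r.degree)
                   for r in records],
    }
    for var in catalogue:
        col = [r.covariates.get(var.name) for r in records]
        if var.kind == "binary":
            data[var.name] = [np.nan if v is None else float(v) for v in col]
        else:
            data[var.name] = col
    return pd.DataFrame(data)
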