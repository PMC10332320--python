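"""End-to-end orchestration: read/validate -> forest -> impute -> SS
estimates -> bivariable (OR + Wald + permutation) -> selection ->
multivariable -> optional repeat-event model.

All randomness derives from one master seed via ``numpy.random.SeedSequence``
spawning, one child per stochastic stage (imputation, SS weights, bootstrap,
permutation, synthetic data); the spawn keys are logged in the report so any
stage can be re-run in isolation.  Two runs with the same configuration and
master seed produce byte-identical JSON reports.

Permutation p-values are computed on the first completed (imputed) dataset
only: degree does not enter the permutation statistic, so the remaining
imputations cannot change it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_pathway, multiple_overdose_model
from .catalogue import VariableCatalogue, default_study_catalogue
from .impute import impute_degrees, pool_estimates
from .io import build_forest, read_rds_table, records_to_frame
from .ss import SSConfig, ss_proportion, ss_weights
from .synthetic import study_shaped_fixture

logger = logging.getLogger("rdsinfer")


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run (YAML-loadable).

    Defaults mirror the study's stated settings: working population size
    15,000, coupon limit 3, selection threshold 0.05 with the ``<=``
    comparator.  Replicate counts are chosen so a full run on the packaged
    fixture stays desk-scale.
    """

    input_csv: str | None = None
    synthetic: dict = field(default_factory=dict)  # study_shaped_fixture kwargs
    outcome: str = "ever_overdose"
    working_population_size: int = 15_000
    coupon_limit: int = 3
    m_imputations: int = 5
    imputation_predictors: list[str] | None = None
    n_inner_simulations: int = 400
    bootstrap_replicates: int = 200
    permutation_replicates: int = 999
    selection_threshold: float = 0.05
    selection_comparator: str = "le"
    multiple_outcome: str | None = "multiple_overdose"
    descriptive_variables: list[str] | None = None
    correlates: list[str] | None = None
    random_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(config: PipelineConfig, catalogue: VariableCatalogue | None,
                 seed: int):
    if catalogue is None:
        catalogue = default_study_catalogue()
    if config.input_csv is not None:
        records = read_rds_table(config.input_csv, catalogue)
        truth = None
    else:
        kwargs = dict(config.synthetic)
        kwargs.setdefault("random_seed", seed)
        bundle = study_shaped_fixture(**kwargs)
        records, truth = bundle.records, bundle.sample.truth
        catalogue = bundle.catalogue
    return records, catalogue, truth


def _ss_stage(frame, forest, catalogue, variables, completed_degrees,
              config: PipelineConfig, rng_ss, rng_boot) -> list[dict]:
    """Pooled SS estimates per variable level.

    Point estimates are pooled over the ``m`` completed degree vectors with
    the multiple-imputation combining rule; the within-imputation variance
    comes from one shared set of tree-bootstrap replicates computed on the
    first completed dataset (the bootstrap re-weighting does not depend on
    which variable is being estimated, so the replicate weights are reused
    across all variables and levels).
    """
    ss_cfg = SSConfig(N=config.working_population_size,
                      n_inner_simulations=config.n_inner_simulations,
                      B=config.bootstrap_replicates)
    weight_sets = [ss_weights(deg, ss_cfg, rng=rng_ss)
                   for deg in completed_degrees]

    # shared bootstrap replicates (row index + weights per replicate)
    n = len(frame)
    degrees0 = np.asarray(completed_degrees[0], dtype=float)
    row_of = {rid: i for i, rid in enumerate(frame["respondent_id"])}
    tree_rows = [
        np.array([row_of[x] for x in forest.bfs_order(root)], dtype=np.int64)
        for root in forest.roots
    ]
    replicates: list[tuple[np.ndarray, np.ndarray]] = []
    base = weight_sets[0]
    for _ in range(config.bootstrap_replicates):
        rows_idx: list[np.ndarray] = []
        size = 0
        while size < n:
            tree = tree_rows[int(rng_boot.integers(len(tree_rows)))]
            take = min(len(tree), n - size)
            rows_idx.append(tree[:take])
            size += take
        idx = np.concatenate(rows_idx)
        wts = ss_weights(degrees0[idx], ss_cfg, rng=rng_boot,
                         init=base.weights[idx]).weights
        replicates.append((idx, wts))

    rows: list[dict] = []
    for name in variables:
        var = catalogue[name]
        col = frame[name]
        n_obs = int(col.notna().sum())
        for level in var.levels:
            target = float(level) if var.kind == "binary" else level
            sample_count = int((col == target).sum())
            boots = []
            for idx, wts in replicates:
                sub = col.iloc[idx]
                obs = sub.notna().to_numpy()
                ind = (sub == target).to_numpy()
                denom = wts[obs].sum()
                if denom > 0:
                    boots.append(wts[obs & ind].sum() / denom)
            within_var = float(np.var(boots, ddof=1)) if len(boots) > 1 else 0.0
            per_imp = [(ss_proportion(frame, name, level, ws.weights),
                        within_var) for ws in weight_sets]
            pooled, pooled_var = pool_estimates(per_imp)
            rows.append({
                "variable": name, "level": level,
                "sample_count": sample_count,
                "sample_pct": 100.0 * sample_count / max(n_obs, 1),
                "population_pct": 100.0 * pooled,
                "se_pct": 100.0 * float(np.sqrt(pooled_var)),
                "n_observed": n_obs,
            })
    return rows


def run_pipeline(config: PipelineConfig, out_dir=None,
                 catalogue: VariableCatalogue | None = None) -> dict:
    """Execute the full analysis; optionally write the report bundle.

    Returns the machine-readable report (dict).  When ``out_dir`` is given,
    writes ``report.json``, Table-1- and Table-3-shaped CSVs and ``run.log``;
    partial outputs are removed if any stage fails.
    """
    master = np.random.SeedSequence(config.random_seed)
    stage_seeds = master.spawn(5)
    stage_names = ["synthetic", "imputation", "ss_weights", "bootstrap",
                   "permutation"]
    rngs = {name: np.random.default_rng(s)
            for name, s in zip(stage_names, stage_seeds)}

    written: list[Path] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    captured: list[str] = []
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report = _run_stages(config, catalogue, rngs, stage_seeds,
                                 stage_names)
            captured = [str(w.message) for w in caught]
        report["warnings"] = captured
        if out_path is not None:
            report_file = out_path / "report.json"
            report_file.write_text(
                json.dumps(report, sort_keys=True, indent=2, default=str)
                + "\n", encoding="utf-8")
            written.append(report_file)
            t1, t3 = render_tables(report)
            f1 = out_path / "descriptives.csv"
            f3 = out_path / "associations.csv"
            t1.to_csv(f1, index=False)
            t3.to_csv(f3, index=False)
            written.extend([f1, f3])
            log_file = out_path / "run.log"
            log_file.write_text(
                "\n".join([f"rdsinfer {__version__}",
                           f"master_seed={config.random_seed}"]
                          + [f"stage_seed[{n}]={list(s.spawn_key)}"
                             for n, s in zip(stage_names, stage_seeds)]
                          + [f"warning: {w}" for w in captured]) + "\n",
                encoding="utf-8")
            written.append(log_file)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline aborted: {exc}") from exc
    return report


def _run_stages(config, catalogue, rngs, stage_seeds, stage_names) -> dict:
    # stage: load/validate ---------------------------------------------------
    records, catalogue, truth = _load_inputs(
        config, catalogue, config.random_seed)
    forest = build_forest(records, coupon_limit=config.coupon_limit)
    frame = records_to_frame(records, catalogue)
    logger.info("loaded %d records in %d trees", len(records),
                len(forest.roots))

    # stage: degree imputation ----------------------------------------------
    imp = impute_degrees(
        records, catalogue, m=config.m_imputations,
        predictors=config.imputation_predictors,
        random_seed=int(rngs["imputation"].integers(2 ** 31)))
    n_missing = int(frame["degree"].isna().sum())

    # stage: SS population estimates ------------------------------------------
    descriptives = config.descriptive_variables
    if descriptives is None:
        descriptives = [n for n in catalogue.covariate_names()
                        if frame[n].notna().any()]
        if catalogue.outcome is not None:
            descriptives = descriptives + [catalogue.outcome]
    ss_rows = _ss_stage(frame, forest, catalogue, descriptives,
                        imp.completed, config, rngs["ss_weights"],
                        rngs["bootstrap"])

    # stage: associations -----------------------------------------------------
    correlates = config.correlates
    if correlates is None:
        correlates = [
            n for n in catalogue.covariate_names()
            if n != config.multiple_outcome
            and frame[n].notna().any() and frame[n].nunique() > 1
        ]
    frame_imp = frame.copy()
    frame_imp["degree"] = imp.completed[0]
    pathway = association_pathway(
        frame_imp, forest, config.outcome, correlates, catalogue,
        threshold=config.selection_threshold,
        comparator=config.selection_comparator,
        r_replicates=config.permutation_replicates,
        rng=rngs["permutation"])

    repeat_model = None
    if (config.multiple_outcome is not None
            and config.multiple_outcome in catalogue
            and frame[config.multiple_outcome].notna().sum() > 0):
        try:
            repeat_model = multiple_overdose_model(
                frame, config.multiple_outcome, catalogue,
                threshold=config.selection_threshold,
                comparator=config.selection_comparator)
        except ValueError as exc:
            logger.warning("repeat-event model skipped: %s", exc)

    # report ------------------------------------------------------------------
    def _fit_dict(fit):
        if fit is None:
            return None
        return {
            "params": {k: float(v) for k, v in fit.params.items()},
            "aor": {k: float(v) for k, v in fit.aor.items()},
            "ci_low": {k: float(v) for k, v in fit.conf_int["low"].items()},
            "ci_high": {k: float(v) for k, v in fit.conf_int["high"].items()},
            "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
            "n_used": fit.n_used,
            "separation_flags": fit.separation_flags,
        }

    bivariable_rows = [{
        "correlate": r.correlate, "level": r.level, "reference": r.reference,
        "table": list(r.table.as_tuple()), "or": r.or_,
        "ci": list(r.ci) if r.ci else None, "wald_p": r.wald_p,
        "perm_p": r.perm_p, "n_used": r.n_used,
    } for r in pathway["bivariable"]]

    report = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "seeds": {n: list(s.spawn_key)
                  for n, s in zip(stage_names, stage_seeds)},
        "n_records": len(records),
        "n_trees": len(forest.roots),
        "n_missing_degree": n_missing,
        "imputation": {"m": imp.m, "method": imp.method},
        "outcome": config.outcome,
        "outcome_prevalence": float(np.nanmean(
            frame[config.outcome].to_numpy(dtype=float))),
        "ss_estimates": ss_rows,
        "n_bivariable_tests": len(bivariable_rows),  # no multiplicity adjustment
        "bivariable": bivariable_rows,
        "selected": pathway["selected"],
        "multivariable": _fit_dict(pathway["multivariable"]),
        "repeat_event_model": None if repeat_model is None else {
            "n_subsample": repeat_model["n_subsample"],
            "selected": repeat_model["selected"],
            "multivariable": _fit_dict(repeat_model["multivariable"]),
        },
        "truth": truth if truth is None else {
            "exhausted": truth["exhausted"],
            "reseeds": truth["reseeds"],
            "population_prevalence": truth["population_prevalence"],
        },
    }
    return report


def render_tables(report: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Publication-shaped tables from a pipeline report.

    Descriptives table: variable, level, sample ``n (p%)`` and population
    ``estimate % (SE)``.  Associations table: correlate, level, outcome-positive
    ``n (%)``, ``OR (CI)``/p, permutation p and ``AOR (CI)``/p with ``ref``
    rows marked.
    """
    t1_rows = []
    outcome_prev = report.get("outcome_prevalence")
    n_rec = report["n_records"]
    t1_rows.append({
        "variable": "Total", "level": "",
        "sample": f"{n_rec} ({100.0 * outcome_prev:.1f}% with outcome)"
        if outcome_prev is not None else str(n_rec),
        "population_estimate": "",
    })
    for row in report["ss_estimates"]:
        t1_rows.append({
            "variable": row["variable"],
            "level": row["level"],
            "sample": f"{row['sample_count']} ({row['sample_pct']:.1f}%)",
            "population_estimate":
                f"{row['population_pct']:.1f}% (±{row['se_pct']:.1f})",
        })
    table1 = pd.DataFrame(t1_rows)

    multi = report.get("multivariable") or {}
    aor = multi.get("aor", {})
    aor_lo = multi.get("ci_low", {})
    aor_hi = multi.get("ci_high", {})
    aor_p = multi.get("pvalues", {})
    selected = set(report.get("selected", []))

    t3_rows = []
    seen_ref: set[str] = set()
    for row in report["bivariable"]:
        name = row["correlate"]
        if name not in seen_ref:
            seen_ref.add(name)
            t3_rows.append({
                "correlate": name, "level": row["reference"] + " (ref)",
                "outcome_n_pct": "", "or_ci": "ref", "wald_p": "ref",
                "perm_p": "ref",
                "aor_ci": "ref" if name in selected else "NA",
                "aor_p": "ref" if name in selected else "NA",
            })
        a, b, _, _ = row["table"]
        pct = 100.0 * a / max(a + b, 1)
        key = name if f"{name}[{row['level']}]" not in aor else \
            f"{name}[{row['level']}]"
        in_model = name in selected and key in aor
        t3_rows.append({
            "correlate": name,
            "level": row["level"],
            "outcome_n_pct": f"{a} ({pct:.1f})",
            "or_ci": (f"{row['or']:.2f} ({row['ci'][0]:.2f}, "
                      f"{row['ci'][1]:.2f})") if row["or"] else "undefined",
            "wald_p": f"{row['wald_p']:.4g}" if row["wald_p"] is not None
            else "NA",
            "perm_p": f"{row['perm_p']:.4g}" if row["perm_p"] is not None
            else "NA",
            "aor_ci": (f"{aor[key]:.2f} ({aor_lo[key]:.2f}, "
                       f"{aor_hi[key]:.2f})") if in_model else "NA",
            "aor_p": f"{aor_p[key]:.4g}" if in_model else "NA",
        })
    table3 = pd.DataFrame(t3_rows)
    return table1, table3
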