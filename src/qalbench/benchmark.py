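"""End-to-end benchmark: synthetic cohort -> univariate statistics ->
logistic selection -> classical baselines and QNN grid -> fixed-
sensitivity comparison and feature importance.

Every model in a run shares one stratified 70/30 train/test split so the
comparison is paired, and all randomness descends from the single global
seed, making the report reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .baselines import fit_classical_baseline
from .cohort import BINARY_FACTORS, MODEL_FACTORS, CohortSpec, generate_cohort
from .circuits import to_qasm, compose, build_zz_feature_map
from .importance import ImportanceConfig, gradient_importance, permutation_importance
from .logistic import information_criteria, odds_ratios, stepwise_select
from .metrics import (
    MetricsReport,
    ThresholdPolicy,
    aggregate_runs,
    classification_report,
    threshold_at_sensitivity,
)
from .optimizers import OptimizerConfig
from .qnn import QNNClassifier, build_ansatz
from .risk_stats import factor_report, mann_whitney_hl
from .simulator import SimConfig
from .training import TrainConfig, stratified_split, train_qnn

__all__ = ["RunConfiguration", "run_benchmark", "write_report"]

log = logging.getLogger("qalbench.benchmark")

#: factor level regarded as the risk exposure in 2x2 tables
_RISK_CATEGORY = {"DM": 1, "Smoking": 1, "ACSP": 0, "NoCoil": 0, "ICG": 0}


@dataclass(frozen=True)
class RunConfiguration:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    ansatze: tuple[str, ...] = ("real_amplitudes", "efficient_su2")
    optimizers: tuple[str, ...] = ("CMAES", "SPSA", "BFGS", "SLSQP", "COBYLA")
    classical: tuple[str, ...] = ("LR", "LDA", "GNB", "AdaBoostStumps", "MLP")
    n_runs: int = 10
    sim: SimConfig = field(default_factory=lambda: SimConfig(shots=None))
    policy: ThresholdPolicy = field(default_factory=ThresholdPolicy)
    importance_repeats: int = 100
    importance_epsilon: float = 1e-2
    run_importance: bool = True
    optimizer_max_iter: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.ansatze and self.optimizers) and not self.classical:
            raise ValueError("configure at least one model")


def _config_hash(config: RunConfiguration) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stats_tables(cohort: pd.DataFrame) -> dict:
    tables = {}
    for factor in BINARY_FACTORS:
        try:
            est = factor_report(cohort, factor, risk_category=_RISK_CATEGORY[factor])
        except ZeroDivisionError:
            # zero cell in a small cohort: the ratio is undefined
            tables[factor] = {"rr": None, "ci_low": None, "ci_high": None,
                              "p_value": None, "test": "undefined"}
            continue
        tables[factor] = {
            "rr": round(est.rr, 2),
            "ci_low": round(est.ci_low, 2),
            "ci_high": round(est.ci_high, 2),
            "p_value": round(est.p_value, 3),
            "test": est.test_used,
        }
    ranks = {}
    for col in cohort.columns:
        if col in BINARY_FACTORS or col == "LEAK":
            continue
        grp1 = cohort.loc[cohort["LEAK"] == 1, col].to_numpy()
        grp0 = cohort.loc[cohort["LEAK"] == 0, col].to_numpy()
        if grp1.size and grp0.size:
            rc = mann_whitney_hl(grp1, grp0)
            ranks[col] = {
                "u": rc.u,
                "p_value": round(rc.p_value, 3),
                "median_diff": rc.median_diff,
                "ci_low": rc.ci_low,
                "ci_high": rc.ci_high,
            }
    return {"binary": tables, "continuous": ranks}


def _evaluate(y_test, scores, policy: ThresholdPolicy) -> MetricsReport:
    thr = threshold_at_sensitivity(y_test, scores, policy)
    return classification_report(y_test, scores, thr)


def run_benchmark(config: RunConfiguration) -> dict:
    """Execute the full pipeline and return the benchmark report dict."""
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(config.seed)
    s_split, s_class, s_qnn, s_imp = ss.spawn(4)

    cohort_spec = replace(config.cohort, seed=int(ss.generate_state(1)[0] % 2**31))
    cohort = generate_cohort(cohort_spec)
    log.info("cohort generated: n=%d, leaks=%d", len(cohort), int(cohort.LEAK.sum()))

    stats = _stats_tables(cohort)

    X = cohort[list(MODEL_FACTORS)]
    y = cohort["LEAK"].to_numpy(dtype=float)
    selection = stepwise_select(X, y, criterion="AIC")
    sel_fit = selection.fit
    aic, bic = information_criteria(sel_fit)
    selection_block = {
        "criterion": selection.criterion,
        "selected": list(selection.selected),
        "coefficients": {"intercept": sel_fit.model.intercept, **sel_fit.model.slopes},
        "loglik": sel_fit.loglik,
        "aic": aic,
        "bic": bic,
        "odds_ratios": odds_ratios(
            sel_fit.model,
            se={n: float(s) for n, s in zip(sel_fit.names, sel_fit.se[1:])},
        ),
        "coding": "protective-state indicators (reconstructed convention)",
    }

    train_idx, test_idx = stratified_split(
        y, 0.3, np.random.default_rng(s_split)
    )
    Xtr, Xte = X.to_numpy(float)[train_idx], X.to_numpy(float)[test_idx]
    ytr, yte = y[train_idx], y[test_idx]

    models: dict[str, dict] = {}
    for kind in config.classical:
        t = time.perf_counter()
        clf = fit_classical_baseline(kind, Xtr, ytr)
        report = _evaluate(yte, clf.predict_proba(Xte), config.policy)
        models[f"classical/{kind}"] = {
            "threshold": report.threshold,
            "metrics": aggregate_runs([report]),
            "n_runs": 1,
        }
        log.info("baseline %s done in %.2fs", kind, time.perf_counter() - t)

    best_qnn = None  # (final_loss, ansatz, params) for the importance stage
    for ansatz in config.ansatze:
        for opt in config.optimizers:
            t = time.perf_counter()
            tc = TrainConfig(
                ansatz_kind=ansatz,
                optimizer=OptimizerConfig(kind=opt, max_iter=config.optimizer_max_iter),
                n_runs=config.n_runs,
                sim=config.sim,
                seed=int(s_qnn.generate_state(1)[0] % 2**31),
            )
            result = train_qnn(cohort, tc, split=(train_idx, test_idx))
            reports = []
            for run in result.runs:
                clf = QNNClassifier(
                    ansatz_kind=ansatz, n_features=len(MODEL_FACTORS),
                    config=replace(config.sim, shots=None),
                )
                scores = clf.predict_proba(run.final_params, Xte)
                reports.append(_evaluate(yte, scores, config.policy))
            agg = aggregate_runs(reports)
            models[f"qnn/{ansatz}/{opt}"] = {
                "threshold": float(np.mean([r.threshold for r in reports])),
                "metrics": agg,
                "n_runs": config.n_runs,
                "mean_final_loss": result.mean_final_loss,
                "std_final_loss": result.std_final_loss,
            }
            best_run = min(result.runs, key=lambda r: r.final_loss)
            if best_qnn is None or best_run.final_loss < best_qnn[0]:
                best_qnn = (best_run.final_loss, ansatz, best_run.final_params)
            log.info(
                "qnn %s/%s done in %.2fs (mean loss %.4f)",
                ansatz, opt, time.perf_counter() - t, result.mean_final_loss,
            )

    importance = {}
    if config.run_importance and best_qnn is not None:
        _, ansatz, params = best_qnn
        clf = QNNClassifier(
            ansatz_kind=ansatz, n_features=len(MODEL_FACTORS),
            config=replace(config.sim, shots=None),
        )
        predict_fn = lambda M: clf.predict_proba(params, M)  # noqa: E731
        icfg = ImportanceConfig(
            n_repeats=config.importance_repeats,
            epsilon=config.importance_epsilon,
            seed=int(s_imp.generate_state(1)[0] % 2**31),
        )
        perm = permutation_importance(
            predict_fn, Xte, yte, icfg, feature_names=MODEL_FACTORS
        )
        grad = gradient_importance(predict_fn, Xte, icfg, feature_names=MODEL_FACTORS)
        importance = {
            "model": f"qnn/{ansatz}",
            "permutation": perm.as_dict(),
            "gradient": grad.as_dict(),
        }

    report = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_patients": int(len(cohort)),
            "leak_count": int(cohort.LEAK.sum()),
        },
        "statistics": stats,
        "selection": selection_block,
        "models": models,
        "importance": importance,
    }
    report["_cohort"] = cohort
    log.info("benchmark finished in %.2fs", time.perf_counter() - t0)
    return report


def _report_csv(models: dict) -> pd.DataFrame:
    cols = [
        "threshold", "accuracy", "specificity", "ppv", "npv", "f1",
        "brier", "log_loss", "efron_r2", "count_r2",
    ]
    rows = []
    for name, block in models.items():
        row = {"model": name, "threshold": block["threshold"]}
        for c in cols[1:]:
            row[c] = block["metrics"][c]["mean"]
        rows.append(row)
    return pd.DataFrame(rows, columns=["model"] + cols)


def write_report(report: dict, out_dir: str | Path, config: RunConfiguration | None = None) -> None:
    """Persist the report bundle: cohort.csv, stats.json, report.json,
    report.csv, importance.json and OpenQASM circuit exports."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = report.get("_cohort")
    payload = {k: v for k, v in report.items() if not k.startswith("_")}
    if cohort is not None:
        cohort.to_csv(out / "cohort.csv", index=False)
    (out / "stats.json").write_text(
        json.dumps(payload["statistics"], indent=2, sort_keys=True) + "\n"
    )
    (out / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n"
    )
    _report_csv(payload["models"]).to_csv(out / "report.csv", index=False)
    if payload.get("importance"):
        (out / "importance.json").write_text(
            json.dumps(payload["importance"], indent=2, sort_keys=True) + "\n"
        )
    if config is not None:
        zeros = np.zeros(len(MODEL_FACTORS))
        for kind in config.ansatze:
            ansatz = build_ansatz(kind, len(MODEL_FACTORS))
            qnn = compose(build_zz_feature_map(zeros), ansatz)
            bound = qnn.bind(np.zeros(qnn.n_params))
            (out / f"qnn_{kind}.qasm").write_text(to_qasm(bound))
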