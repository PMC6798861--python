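"""ROC curves, per-task AUC, ensemble summaries and report comparison.

The summary statistic follows the fixed averaging order: per model, the mean
AUC across evaluable tasks; then the mean of those means across the ensemble.
Tasks that are single-class on the evaluated split cannot be scored and are
excluded from the means, with the exclusion reported.  Two ensembles are
compared with a Welch two-sample t-test on their per-model mean-AUC vectors.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .featurize import MolGraph


class SingleClassError(ValueError):
    """AUC/ROC is undefined when only one class is present."""


def roc_points(y: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """ROC curve as an array of (fpr, tpr) points.

    Thresholds sweep the distinct scores in descending order with ties
    grouped, which makes the curve unique; it starts at (0,0) and ends at
    (1,1).
    """
    y = np.asarray(y, float).ravel()
    scores = np.asarray(scores, float).ravel()
    if y.shape != scores.shape:
        raise ValueError("y and scores must have the same length")
    n_pos = float(np.sum(y == 1))
    n_neg = float(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("ROC undefined: labels contain a single class")
    order = np.argsort(-scores, kind="stable")
    ys, ss = y[order], scores[order]
    # indices where a threshold group (tied scores) ends
    distinct = np.where(np.diff(ss))[0]
    cut = np.concatenate([distinct, [len(ss) - 1]])
    tp = np.cumsum(ys)[cut]
    fp = np.cumsum(1.0 - ys)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return np.column_stack([fpr, tpr])


def auc_score(y: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under :func:`roc_points`; equals the pairwise
    concordance statistic (#concordant + 0.5 #tied) / (n_pos * n_neg)."""
    pts = roc_points(y, scores)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


@dataclasses.dataclass
class EvalReport:
    task_names: list
    per_model_task_auc: np.ndarray     # (models, tasks); NaN for excluded tasks
    per_model_mean_auc: np.ndarray     # (models,)
    ensemble_mean_auc: float
    roc_curves: dict                   # task name -> (n_points, 2) array
    excluded_tasks: list               # [(task name, reason)]

    def to_json(self) -> str:
        return json.dumps({
            "task_names": self.task_names,
            "per_model_task_auc": self.per_model_task_auc.tolist(),
            "per_model_mean_auc": self.per_model_mean_auc.tolist(),
            "ensemble_mean_auc": self.ensemble_mean_auc,
            "excluded_tasks": self.excluded_tasks,
        })


def evaluate_ensemble(models: Sequence, graphs: Sequence[MolGraph],
                      task_names: Optional[Sequence[str]] = None) -> EvalReport:
    """Score an ensemble on a featurized split.

    ``models`` are ModelParams (or ``(params, history)`` pairs).  All models
    must share a featurization fingerprint, and it must match the graphs'
    widths.  ROC curves are computed from the ensemble-averaged predicted
    probabilities per task.
    """
    from .model import ModelParams, batch_forward, pack_graphs  # cycle guard

    params_list = [m[0] if isinstance(m, tuple) else m for m in models]
    if not params_list:
        raise ValueError("no models to evaluate")
    fp0 = params_list[0].fingerprint
    for p in params_list[1:]:
        if p.fingerprint != fp0:
            raise ValueError("ensemble members have mismatched featurization "
                             f"fingerprints: {p.fingerprint} vs {fp0}")

    if any(g.labels is None for g in graphs):
        raise ValueError("evaluation graphs must carry labels")
    y = np.stack([g.labels for g in graphs])
    mask = np.stack([g.label_mask if g.label_mask is not None
                     else np.ones_like(g.labels) for g in graphs])
    c = y.shape[1]
    if task_names is None:
        task_names = [f"task{j + 1}" for j in range(c)]
    task_names = list(task_names)

    all_probs = []
    for p in params_list:
        batch = pack_graphs(graphs, p.mol_standardization)
        probs, _ = batch_forward(batch, p, mode="eval")
        all_probs.append(probs)
    all_probs = np.stack(all_probs)           # (models, n, c)

    per_model_task = np.full((len(params_list), c), np.nan)
    excluded = []
    evaluable = []
    for j in range(c):
        obs = mask[:, j] == 1
        yj = y[obs, j]
        if obs.sum() == 0 or len(np.unique(yj)) < 2:
            excluded.append((task_names[j],
                             "single-class or empty on this split"))
            continue
        evaluable.append(j)
        for mi in range(len(params_list)):
            per_model_task[mi, j] = auc_score(yj, all_probs[mi][obs, j])

    if not evaluable:
        raise ValueError("no task is evaluable on this split")
    per_model_mean = np.nanmean(per_model_task[:, evaluable], axis=1)
    mean_probs = all_probs.mean(axis=0)
    curves = {}
    for j in evaluable:
        obs = mask[:, j] == 1
        curves[task_names[j]] = roc_points(y[obs, j], mean_probs[obs, j])
    return EvalReport(task_names=task_names,
                      per_model_task_auc=per_model_task,
                      per_model_mean_auc=per_model_mean,
                      ensemble_mean_auc=float(per_model_mean.mean()),
                      roc_curves=curves,
                      excluded_tasks=excluded)


def compare_reports(report_a: EvalReport, report_b: EvalReport):
    """Welch two-sample t-test on the per-model mean-AUC vectors; returns
    ``(t, p)`` with a two-sided p-value."""
    a = np.asarray(report_a.per_model_mean_auc, float)
    b = np.asarray(report_b.per_model_mean_auc, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both reports need at least two models for a t-test")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:  # both samples constant
        if a[0] == b[0]:
            return 0.0, 1.0
        return (np.inf if a[0] > b[0] else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# text serialization: one row per model x task plus a summary block


def write_report(report: EvalReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("# molgcn evaluation report\n")
        fh.write("# tasks:\t" + "\t".join(report.task_names) + "\n")
        fh.write("# excluded:\t" + json.dumps(report.excluded_tasks) + "\n")
        fh.write("# per_model_mean_auc:\t"
                 + "\t".join(f"{v:.10f}" for v in report.per_model_mean_auc) + "\n")
        fh.write(f"# ensemble_mean_auc:\t{report.ensemble_mean_auc:.10f}\n")
        fh.write("model\ttask\tauc\n")
        for mi in range(report.per_model_task_auc.shape[0]):
            for j, name in enumerate(report.task_names):
                v = report.per_model_task_auc[mi, j]
                fh.write(f"{mi}\t{name}\t{'NA' if np.isnan(v) else f'{v:.10f}'}\n")


def read_report(path) -> EvalReport:
    task_names, excluded, per_model_mean = [], [], []
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# tasks:"):
                task_names = line.split("\t")[1:]
            elif line.startswith("# excluded:"):
                excluded = [tuple(e) for e in json.loads(line.split("\t", 1)[1])]
            elif line.startswith("# per_model_mean_auc:"):
                per_model_mean = [float(v) for v in line.split("\t")[1:]]
            elif line.startswith("#") or line.startswith("model\t") or not line:
                continue
            else:
                mi, name, v = line.split("\t")
                rows.append((int(mi), name, np.nan if v == "NA" else float(v)))
    n_models = max(r[0] for r in rows) + 1
    mat = np.full((n_models, len(task_names)), np.nan)
    for mi, name, v in rows:
        mat[mi, task_names.index(name)] = v
    per_model_mean = np.asarray(per_model_mean)
    return EvalReport(task_names=task_names, per_model_task_auc=mat,
                      per_model_mean_auc=per_model_mean,
                      ensemble_mean_auc=float(per_model_mean.mean()),
                      roc_curves={}, excluded_tasks=excluded)


def write_roc_tables(report: EvalReport, out_dir) -> list:
    """Export each task's ROC curve as a two-column (fpr, tpr) TSV; returns
    the written paths."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, pts in report.roc_curves.items():
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in name)
        p = os.path.join(out_dir, f"roc_{safe}.tsv")
        np.savetxt(p, pts, delimiter="\t", header="fpr\ttpr", comments="")
        paths.append(p)
    return paths
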