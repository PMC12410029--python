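"""Group-fairness metric panel and bias-reduction statistics.

For each group the panel reports AUROC plus the threshold metrics TPR,
FNR, TNR, FPR, PPV (precision) and FDR, each with a subject-level
bootstrap CI. "Bias" for a metric Q is the signed difference
``Q(first group) - Q(second group)`` under a configured group order; the
bias-reduction statistic between two models is
``100 * (|bias_pre| - |bias_post|) / |bias_pre|``.

AUROC is the Mann-Whitney rank statistic (ties by midrank), identical to
the trapezoidal ROC area. Bootstrapping resamples *subjects*, not rows,
so repeated measurements of one subject stay together.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["FairnessReport", "evaluate", "bias_reduction", "METRICS"]

METRICS = ("auroc", "tpr", "fnr", "tnr", "fpr", "ppv", "fdr")


class FairnessError(ValueError):
    pass


def _panel(scores: np.ndarray, labels: np.ndarray, threshold: float) -> dict[str, float | None]:
    """One group's metric panel; None where a denominator is empty."""
    out: dict[str, float | None] = {}
    pos = labels == 1
    neg = labels == 0
    if pos.any() and neg.any():
        out["auroc"] = float(roc_auc_score(labels, scores))
    else:
        out["auroc"] = None
    pred = scores >= threshold
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & neg))
    fp = int(np.sum(pred & neg))
    out["tpr"] = tp / (tp + fn) if (tp + fn) else None
    out["fnr"] = fn / (tp + fn) if (tp + fn) else None
    out["tnr"] = tn / (tn + fp) if (tn + fp) else None
    out["fpr"] = fp / (tn + fp) if (tn + fp) else None
    out["ppv"] = tp / (tp + fp) if (tp + fp) else None
    out["fdr"] = fp / (tp + fp) if (tp + fp) else None
    return out


@dataclass
class FairnessReport:
    groups: list[str]
    group_pair: tuple[str, str]
    threshold: float
    n_per_group: dict[str, int]
    metrics: dict[str, dict[str, float | None]]  # group -> metric -> value
    ci95: dict[str, dict[str, tuple[float, float] | None]]
    bias: dict[str, float | None]  # metric -> Q(first) - Q(second)
    bias_boot: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    n_boot: int = 0

    def abs_bias(self, metric: str) -> float | None:
        v = self.bias.get(metric)
        return None if v is None else abs(v)

    def to_dict(self) -> dict:
        return {
            "groups": self.groups,
            "group_pair": list(self.group_pair),
            "threshold": self.threshold,
            "n_per_group": self.n_per_group,
            "metrics": self.metrics,
            "ci95": {
                g: {m: (None if ci is None else [float(ci[0]), float(ci[1])]) for m, ci in d.items()}
                for g, d in self.ci95.items()
            },
            "bias": self.bias,
            "n_boot": self.n_boot,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_wide_rows(self) -> list[dict]:
        rows = []
        for g in self.groups:
            for m in METRICS:
                ci = self.ci95.get(g, {}).get(m)
                rows.append(
                    {
                        "group": g,
                        "metric": m,
                        "value": self.metrics[g][m],
                        "ci_lo": None if ci is None else ci[0],
                        "ci_hi": None if ci is None else ci[1],
                    }
                )
        return rows


def evaluate(
    scores: Sequence[float],
    labels: Sequence[int],
    groups: Sequence[str],
    threshold: float = 0.5,
    n_boot: int = 50,
    seed: int = 0,
    subject_ids: Sequence[str] | None = None,
    group_pair: tuple[str, str] | None = None,
) -> FairnessReport:
    """Evaluate the fairness panel for one set of predictions.

    ``group_pair`` fixes the sign convention of the bias column (defaults
    to the first two group names in sorted order). Bootstrap CIs resample
    subjects with replacement within each group.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    glab = np.asarray([str(g) for g in groups])
    if not (scores.shape == labels.shape == glab.shape):
        raise FairnessError("scores, labels and groups must have equal length")
    if not ((labels == 0) | (labels == 1)).all():
        raise FairnessError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise FairnessError("both classes must be present overall")
    if np.nanmin(scores) < 0 or np.nanmax(scores) > 1:
        raise FairnessError("scores must lie in [0, 1]")
    subj = (
        np.asarray([str(s) for s in subject_ids])
        if subject_ids is not None
        else np.arange(scores.size).astype(str)
    )

    names = sorted(np.unique(glab).tolist())
    pair = group_pair or (names[0], names[1] if len(names) > 1 else names[0])
    for g in pair:
        if g not in names:
            raise FairnessError(f"group_pair names unknown group '{g}'")

    metrics: dict[str, dict] = {}
    ci95: dict[str, dict] = {}
    boot_store: dict[str, dict[str, np.ndarray]] = {}
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xFA1)))
    for g in names:
        mask = glab == g
        panel = _panel(scores[mask], labels[mask], threshold)
        metrics[g] = panel
        g_subj = subj[mask]
        uniq, inverse = np.unique(g_subj, return_inverse=True)
        one_row_per_subject = uniq.size == g_subj.size
        if not one_row_per_subject:
            by_subject = [np.flatnonzero(inverse == i) for i in range(uniq.size)]
        g_scores, g_labels = scores[mask], labels[mask]
        reps: dict[str, list[float]] = {m: [] for m in METRICS}
        for _ in range(n_boot):
            pick = rng.integers(0, uniq.size, size=uniq.size)
            if one_row_per_subject:
                idx = pick
            else:
                idx = np.concatenate([by_subject[i] for i in pick])
            p = _panel(g_scores[idx], g_labels[idx], threshold)
            for m in METRICS:
                if p[m] is not None:
                    reps[m].append(p[m])
        boot_store[g] = {m: np.asarray(v) for m, v in reps.items()}
        ci95[g] = {
            m: (
                (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
                if v.size
                else None
            )
            for m, v in boot_store[g].items()
        }

    bias: dict[str, float | None] = {}
    bias_boot: dict[str, np.ndarray] = {}
    a, b = pair
    for m in METRICS:
        va, vb = metrics[a][m], metrics[b][m]
        bias[m] = None if va is None or vb is None else float(va - vb)
        ba, bb = boot_store[a][m], boot_store[b][m]
        if ba.size and bb.size and ba.size == bb.size:
            bias_boot[m] = ba - bb
    return FairnessReport(
        groups=names,
        group_pair=pair,
        threshold=threshold,
        n_per_group={g: int(np.sum(glab == g)) for g in names},
        metrics=metrics,
        ci95=ci95,
        bias=bias,
        bias_boot=bias_boot,
        n_boot=n_boot,
    )


def bias_reduction(
    pre: FairnessReport, post: FairnessReport, metric: str = "auroc"
) -> dict:
    """Percent reduction in |bias| between two models on one metric.

    ``100 * (|bias_pre| - |bias_post|) / |bias_pre|``; negative when the
    bias increased. A paired-bootstrap CI is attached when both reports
    carry replicate bias values of equal length. Returns a dict with
    ``percent`` (None, with a reason, when |bias_pre| == 0).
    """
    if set(pre.group_pair) != set(post.group_pair):
        raise FairnessError("reports compare different group pairs")
    bp, bq = pre.bias.get(metric), post.bias.get(metric)
    if bp is None or bq is None:
        return {"metric": metric, "percent": None, "reason": "metric undefined in a report"}
    if bp == 0:
        return {"metric": metric, "percent": None, "reason": "pre-intervention bias is zero"}
    pct = 100.0 * (abs(bp) - abs(bq)) / abs(bp)
    out = {"metric": metric, "percent": float(pct), "bias_pre": bp, "bias_post": bq}
    rp, rq = pre.bias_boot.get(metric), post.bias_boot.get(metric)
    if rp is not None and rq is not None and rp.size == rq.size and rp.size > 1:
        ok = np.abs(rp) > 1e-12
        if ok.sum() > 1:
            reps = 100.0 * (np.abs(rp[ok]) - np.abs(rq[ok])) / np.abs(rp[ok])
            out["ci95"] = [float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5))]
    return out
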