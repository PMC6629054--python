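"""Cluster-aware discrimination evaluation: AUC, ROC, and operating points.

The AUC is the Mann–Whitney concordance probability — the chance a random
event row outscores a random non-event row, ties counted half.  Because rows
within a patient are dependent, confidence intervals come from a percentile
bootstrap that resamples *patients* (all of a patient's rows move together);
a row-level bootstrap would understate the interval width.

Operating-point planning follows the usual triage arithmetic: given a chosen
sensitivity/specificity cut-point and a prevalence, the positive predictive
value is ``PPV = sens*prev / (sens*prev + (1-spec)*(1-prev))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import AkiPredictError, ConfigurationError


def auc(scores, labels) -> float:
    """Midrank (Mann–Whitney) AUC; requires both classes present."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise AkiPredictError("AUC undefined: need at least one positive and one negative")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC staircase over all unique score thresholds.

    Thresholds are the unique score values (prediction positive when
    ``score >= threshold``) plus a sentinel above the maximum, so the curve
    runs from (sens=1, spec=0) to (sens=0, spec=1).  The trapezoidal area
    under this staircase equals the midrank AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise AkiPredictError("ROC undefined: need at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tp = np.cumsum(y_sorted == 1)[distinct]
    fp = np.cumsum(y_sorted == 0)[distinct]
    thr = s_sorted[distinct]
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, thr],
            "sensitivity": np.r_[0.0, tp / n_pos],
            "specificity": np.r_[1.0, 1.0 - fp / n_neg],
        }
    )


@dataclass
class EvaluationResult:
    """Discrimination summary for one (model, outcome, stratum) cell."""

    auc: float
    ci_low: float
    ci_high: float
    n_rows: int
    n_patients: int
    n_events: int
    stratum: str = ""
    outcome: str = ""
    model_class: str = ""
    n_degenerate_resamples: int = 0
    roc: pd.DataFrame | None = field(default=None, repr=False)

    def format_auc(self) -> str:
        """Reporting style ``0.74 (0.73-0.74)``."""
        return f"{self.auc:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f})"


def clustered_auc_ci(
    scores,
    labels,
    patient_ids,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
    cluster: bool = True,
) -> EvaluationResult:
    """Percentile-bootstrap AUC confidence interval.

    With ``cluster=True`` (the default) patients are resampled with
    replacement and every row of a sampled patient enters the replicate, so
    within-patient dependence is respected.  ``cluster=False`` gives the
    naive row bootstrap, kept for comparison.  Resamples that contain a
    single label class are redrawn and counted; more than 50% degenerate
    resamples is an error.
    """
    if B < 100:
        raise ConfigurationError(f"bootstrap replicates B must be >= 100, got {B}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pids = np.asarray(patient_ids)
    point = auc(s, y)
    rng = np.random.default_rng(seed)

    if cluster:
        uniq, inv = np.unique(pids, return_inverse=True)
        order = np.argsort(inv, kind="stable")
        s_sorted, y_sorted = s[order], y[order]
        counts = np.bincount(inv)
        starts = np.r_[0, np.cumsum(counts)]
        n_clusters = uniq.size
    stats = np.empty(B)
    n_degenerate = 0
    for b in range(B):
        for _ in range(1000):
            if cluster:
                pick = rng.integers(0, n_clusters, n_clusters)
                idx = np.concatenate([np.arange(starts[g], starts[g + 1]) for g in pick])
                yb, sb = y_sorted[idx], s_sorted[idx]
            else:
                idx = rng.integers(0, s.size, s.size)
                yb, sb = y[idx], s[idx]
            if yb.min() != yb.max():
                break
            n_degenerate += 1
            if n_degenerate > B // 2:
                raise AkiPredictError(
                    "degenerate data: most bootstrap resamples contain a single class"
                )
        stats[b] = auc(sb, yb)
    alpha = 1.0 - level
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return EvaluationResult(
        auc=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_rows=int(s.size),
        n_patients=int(np.unique(pids).size),
        n_events=int(np.sum(y == 1)),
        n_degenerate_resamples=n_degenerate,
        roc=roc_points(s, y),
    )


def ppv_at_operating_point(sensitivity: float, specificity: float, prevalence: float) -> tuple[float, int]:
    """PPV at a cut-point: returns (full precision, nearest whole percent)."""
    for name, v in (
        ("sensitivity", sensitivity),
        ("specificity", specificity),
        ("prevalence", prevalence),
    ):
        if not (0.0 < v <= 1.0):
            raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
    ppv = (sensitivity * prevalence) / (
        sensitivity * prevalence + (1.0 - specificity) * (1.0 - prevalence)
    )
    return ppv, int(round(100.0 * ppv))


def operating_point(roc: pd.DataFrame, target: dict[str, float]) -> tuple[float, float, float]:
    """Pick the threshold meeting a sensitivity or specificity target.

    ``target`` is ``{"sensitivity": x}`` or ``{"specificity": y}``.  Among
    thresholds whose achieved value is on the feasible side (>= target), the
    one closest to the target is returned; ties break toward higher
    specificity.  Returns (threshold, sensitivity, specificity).
    """
    if roc is None or len(roc) == 0:
        raise AkiPredictError("empty ROC")
    if set(target) == {"sensitivity"}:
        key, want = "sensitivity", float(target["sensitivity"])
    elif set(target) == {"specificity"}:
        key, want = "specificity", float(target["specificity"])
    else:
        raise ConfigurationError("target must be exactly one of sensitivity / specificity")
    achieved = roc[key].to_numpy()
    feasible = np.flatnonzero(achieved >= want)
    if feasible.size == 0:  # nothing on the feasible side: take the closest overall
        feasible = np.arange(len(roc))
    gap = achieved[feasible] - want
    spec = roc["specificity"].to_numpy()[feasible]
    best = feasible[np.lexsort((-spec, np.abs(gap)))[0]]
    return (
        float(roc["threshold"].iloc[best]),
        float(roc["sensitivity"].iloc[best]),
        float(roc["specificity"].iloc[best]),
    )


def evaluation_grid(
    fits: dict,
    strata: dict[str, pd.DataFrame],
    B: int = 2000,
    seed: int = 0,
    strict: bool = True,
) -> pd.DataFrame:
    """AUC (CI) per covariate class x outcome x evaluation stratum.

    ``fits`` maps ``(model_class, outcome) -> ModelFit``; ``strata`` maps a
    stratum label (partition or hospital) to its observation rows.  Rows are
    complete-case filtered per class before scoring.  Output is a long table;
    pivot on (outcome, stratum) x class for the grid layout.  With
    ``strict=False``, cells that cannot be evaluated (no rows, or a single
    label class in the stratum) are dropped instead of raising.
    """
    from .covariates import OUTCOME_LABELS
    from .discretize import complete_case_filter
    from .model import predict_risk

    records = []
    rng = np.random.default_rng(seed)
    for (model_class, outcome), fit in sorted(fits.items()):
        label_col = OUTCOME_LABELS.get(outcome, outcome)
        for stratum, rows in sorted(strata.items()):
            cc_rows, _ = complete_case_filter(rows, model_class)
            if len(cc_rows) == 0 or cc_rows[label_col].nunique() < 2:
                if strict:
                    raise AkiPredictError(
                        f"cannot evaluate cell (class={model_class}, outcome={outcome}, "
                        f"stratum={stratum}): no rows or single-class labels"
                    )
                continue
            scores = predict_risk(fit, cc_rows)
            try:
                res = clustered_auc_ci(
                    scores,
                    cc_rows[label_col].to_numpy(),
                    cc_rows["patient_id"].to_numpy(),
                    B=B,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            except AkiPredictError:
                if strict:
                    raise
                continue  # too few events in the stratum to bootstrap
            records.append(
                {
                    "model_class": model_class,
                    "outcome": outcome,
                    "stratum": stratum,
                    "auc": res.auc,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "auc_formatted": res.format_auc(),
                    "n_rows": res.n_rows,
                    "n_patients": res.n_patients,
                    "n_events": res.n_events,
                }
            )
    return pd.DataFrame.from_records(records)


def grid_to_table(grid: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long evaluation grid into the class-by-outcome layout."""
    return grid.pivot_table(
        index=["outcome", "stratum"],
        columns="model_class",
        values="auc_formatted",
        aggfunc="first",
    )


def plot_roc_panels(
    fits: dict,
    rows: pd.DataFrame,
    outcomes: tuple[str, ...] = ("aki24", "death", "rrt", "sustained_aki24"),
    path: str | None = None,
):
    """Four-panel ROC figure: one panel per outcome, one curve per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .covariates import OUTCOME_LABELS
    from .discretize import complete_case_filter
    from .model import predict_risk

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, outcome in zip(axes.ravel(), outcomes):
        label_col = OUTCOME_LABELS[outcome]
        for (model_class, fit_outcome), fit in sorted(fits.items()):
            if fit_outcome != outcome:
                continue
            cc_rows, _ = complete_case_filter(rows, model_class)
            if len(cc_rows) == 0 or cc_rows[label_col].nunique() < 2:
                continue
            scores = predict_risk(fit, cc_rows)
            pts = roc_points(scores, cc_rows[label_col].to_numpy())
            ax.plot(1.0 - pts["specificity"], pts["sensitivity"], label=model_class, lw=1.2)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_title(outcome)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, format="svg")
        plt.close(fig)
    return fig
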