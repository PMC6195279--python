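"""Feature-importance rankings from repeated cross-validation.

Two complementary criteria:

* **Selection frequency (sufficiency)** — how often the LASSO keeps a
  feature: the proportion of repeated-CV fits in which its coefficient is
  nonzero at the penalty chosen by the 1-SE rule. Features that are
  nearly always selected behave as motifs: each stands in for the group
  of features correlated with it, since the LASSO keeps whichever member
  it meets first and shrinks the rest.

* **Exclusion delta (necessity)** — the drop in cross-validated adjusted
  R^2 when the feature is removed and the model refit: for each repeat,
  Delta_j = adjR^2(full) - adjR^2(without j), computed on identical fold
  partitions for both arms (common random numbers), summarised by its
  median and quartiles. A negative median means the model *improved*
  without the feature; correlated survivors can compensate for a removed
  feature, so small deltas do not prove unimportance.

No multiple-testing adjustment is applied; the distributions are
descriptive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import CVResult, repeated_cv_evaluate

logger = logging.getLogger(__name__)

__all__ = [
    "selection_frequency",
    "exclusion_delta",
    "rank_features",
    "ExclusionDelta",
    "plot_rank_chart",
]


def _selection_counts(cv: CVResult, columns: pd.Index) -> pd.DataFrame:
    """Per-feature selected / total accounting over all fold-level fits."""
    counts = pd.Series(0, index=columns, dtype=int)
    total = 0
    for repeat_sets in cv.selected:
        for sel in repeat_sets:
            total += 1
            for name in sel:
                counts[name] += 1
    return pd.DataFrame(
        {"selected": counts, "unselected": total - counts, "total_fits": total}
    )


def selection_frequency(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 4,
    repeats: int = 100,
    master_seed: int = 0,
    consensus: str = "fold",
    cv_result: CVResult | None = None,
    **cv_kwargs,
) -> pd.Series:
    """Proportion of repeated-CV LASSO fits selecting each feature.

    ``consensus`` controls the aggregation level: ``"fold"`` (default)
    counts every fold-level fit separately (k*repeats fits); ``"any"``,
    ``"majority"`` and ``"all"`` first collapse each repeat's k fits into
    a per-repeat verdict. A precomputed LASSO ``cv_result`` may be reused.
    """
    if cv_result is None:
        cv_result = repeated_cv_evaluate(
            X, y, family="lasso", k=k, repeats=repeats,
            master_seed=master_seed, **cv_kwargs,
        )
    if consensus == "fold":
        acc = _selection_counts(cv_result, X.columns)
        props = acc["selected"] / acc["total_fits"]
    elif consensus in ("any", "all", "majority"):
        need = {"any": 1, "majority": (cv_result.k // 2) + 1,
                "all": cv_result.k}[consensus]
        hits = pd.Series(0, index=X.columns, dtype=int)
        for repeat_sets in cv_result.selected:
            per_repeat = pd.Series(0, index=X.columns, dtype=int)
            for sel in repeat_sets:
                for name in sel:
                    per_repeat[name] += 1
            hits[per_repeat >= need] += 1
        props = hits / len(cv_result.selected)
    else:
        raise ValueError(f"unknown consensus mode {consensus!r}")
    props.name = "selection_proportion"
    return props


@dataclass
class ExclusionDelta:
    """Paired repeated-CV comparison of the full model vs. model without j."""

    feature: str
    deltas: np.ndarray          # adjR^2(full) - adjR^2(-j), one per repeat
    median: float
    q1: float
    q3: float
    n_dropped: int = 0

    @classmethod
    def from_arms(
        cls, feature: str, full: np.ndarray, reduced: np.ndarray
    ) -> "ExclusionDelta":
        m = min(len(full), len(reduced))
        deltas = full[:m] - reduced[:m]
        ok = deltas[~np.isnan(deltas)]
        q1, med, q3 = (np.percentile(ok, [25, 50, 75]) if ok.size
                       else (np.nan,) * 3)
        return cls(feature, deltas, float(med), float(q1), float(q3),
                   n_dropped=m - ok.size)


def exclusion_delta(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    feature: str,
    k: int = 4,
    repeats: int = 100,
    master_seed: int = 0,
    full_cv: CVResult | None = None,
    **cv_kwargs,
) -> ExclusionDelta:
    """Distribution of Delta_j = adjR^2(full) - adjR^2(without feature j).

    Both arms use identical fold partitions and inner-CV seeds (they are
    functions of ``master_seed`` and the repeat index only), so the
    difference is paired. Pass ``full_cv`` to reuse the full-model arm.
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in design matrix")
    if full_cv is None:
        full_cv = repeated_cv_evaluate(
            X, y, family="lasso", k=k, repeats=repeats,
            master_seed=master_seed, **cv_kwargs,
        )
    reduced = repeated_cv_evaluate(
        X.drop(columns=[feature]), y, family="lasso", k=k, repeats=repeats,
        master_seed=master_seed, **cv_kwargs,
    )
    return ExclusionDelta.from_arms(feature, full_cv.adj_r2, reduced.adj_r2)


def rank_features(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int = 4,
    repeats: int = 100,
    master_seed: int = 0,
    features: list[str] | None = None,
    **cv_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run both importance criteria for every feature.

    Returns ``(rank_table, delta_long)``: one row per feature with its
    selection proportion (fold-level and per-repeat "any" consensus),
    exclusion-delta median and quartiles, and its pairwise correlation
    with the outcome, sorted by selection proportion (ties broken by
    delta median, then name); and the long-format per-repeat delta
    distributions. ``features`` restricts the (expensive) exclusion arm.
    """
    ya = np.asarray(y, dtype=float)
    full_cv = repeated_cv_evaluate(
        X, y, family="lasso", k=k, repeats=repeats,
        master_seed=master_seed, **cv_kwargs,
    )
    props_fold = selection_frequency(X, y, cv_result=full_cv, consensus="fold")
    props_any = selection_frequency(X, y, cv_result=full_cv, consensus="any")

    todo = list(X.columns) if features is None else list(features)
    rows, long_rows = [], []
    for name in todo:
        ed = exclusion_delta(
            X, y, name, k=k, repeats=repeats, master_seed=master_seed,
            full_cv=full_cv, **cv_kwargs,
        )
        corr = float(np.corrcoef(X[name].to_numpy(dtype=float), ya)[0, 1])
        rows.append({
            "feature": name,
            "selection_proportion": float(props_fold[name]),
            "selection_proportion_any_repeat": float(props_any[name]),
            "delta_median": ed.median,
            "delta_q1": ed.q1,
            "delta_q3": ed.q3,
            "outcome_correlation": corr,
        })
        for r, d in enumerate(ed.deltas):
            long_rows.append({"feature": name, "repeat": r, "delta": d})
    table = pd.DataFrame(rows).sort_values(
        by=["selection_proportion", "delta_median", "feature"],
        ascending=[False, False, True],
    ).reset_index(drop=True)
    table["rank_selection"] = (
        table["selection_proportion"].rank(ascending=False, method="min").astype(int)
    )
    table["rank_delta"] = (
        table["delta_median"].rank(ascending=False, method="min").astype(int)
    )
    table.attrs["full_model_adj_r2_median"] = float(np.nanmedian(full_cv.adj_r2))
    return table, pd.DataFrame(long_rows)


def plot_rank_chart(
    rank_table: pd.DataFrame,
    delta_long: pd.DataFrame,
    full_model_median: float | None = None,
    top: int = 10,
    path: str | None = None,
):
    """Stability-ranking chart: selection-proportion diamonds on the top
    axis, per-repeat exclusion adjusted-R^2 dots with quartile boxes on
    the bottom axis, and the full model's median as a reference line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tbl = rank_table.head(top)
    if full_model_median is None:
        full_model_median = rank_table.attrs.get("full_model_adj_r2_median", 0.0)
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(tbl) + 2))
    ypos = np.arange(len(tbl))[::-1]
    for yp, (_, row) in zip(ypos, tbl.iterrows()):
        d = delta_long.loc[delta_long["feature"] == row["feature"], "delta"]
        excl_r2 = full_model_median - d.to_numpy()
        ax.plot(excl_r2, np.full(len(excl_r2), yp), ".", color="tab:blue",
                alpha=0.25, ms=4)
        ax.plot(
            [full_model_median - row["delta_q3"], full_model_median - row["delta_q1"]],
            [yp, yp], "-", color="tab:blue", lw=5, alpha=0.6,
        )
    ax.axvline(full_model_median, color="tab:blue", lw=1.5)
    ax.set_yticks(ypos)
    ax.set_yticklabels(
        [f"{r.feature}  (r={r.outcome_correlation:+.2f})" for r in tbl.itertuples()]
    )
    ax.set_xlabel("out-of-fold adjusted $R^2$ with feature excluded")
    top_ax = ax.twiny()
    top_ax.plot(tbl["selection_proportion"].to_numpy(), ypos, "D",
                color="tab:red", ms=7)
    top_ax.set_xlim(-0.02, 1.02)
    top_ax.set_xlabel("selection proportion", color="tab:red")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
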