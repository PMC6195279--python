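"""Subject-level design matrices.

Collapses per-trial movement metrics into per-subject summaries (mean,
maximum, variance of each of the 12 metrics over that subject's
non-missing trials), joins them with the q = 15 demographic/clinical
covariates into the first-order design (3p + q = 51 columns), optionally
expands to the full second-order design (squares plus all pairwise
interactions), and standardizes columns using statistics from a stated
training subset only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import METRIC_NAMES
from .simulate import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)

SUMMARY_STATS = ("mean", "max", "var")

#: The 36 movement-summary column names, in canonical order.
SUMMARY_COLUMNS = tuple(
    f"{stat}_{metric}" for metric in METRIC_NAMES for stat in SUMMARY_STATS
)

#: The full 51-column first-order schema.
FIRST_ORDER_COLUMNS = SUMMARY_COLUMNS + COVARIATE_COLUMNS


def summarize_subjects(trial_metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean, max, and sample variance of each movement metric.

    Parameters
    ----------
    trial_metrics : DataFrame with ``subject_id``, ``trial_index`` and one
        column per metric; NaN entries mark missing trials and are skipped.

    Returns
    -------
    DataFrame indexed by ``subject_id`` with the 36 ``SUMMARY_COLUMNS``.
    A summary computed from fewer than 2 non-missing trials is NaN and the
    subject/metric pair is logged.
    """
    if "subject_id" not in trial_metrics.columns:
        raise KeyError("trial_metrics must have a subject_id column")
    rows = {}
    for sid, grp in trial_metrics.groupby("subject_id", sort=True):
        row = {}
        for metric in METRIC_NAMES:
            vals = grp[metric].dropna().to_numpy(dtype=float)
            if vals.size < 2:
                logger.warning(
                    "subject %s: metric %s has %d non-missing trials; "
                    "summaries flagged missing", sid, metric, vals.size,
                )
                row[f"mean_{metric}"] = np.nan
                row[f"max_{metric}"] = np.nan
                row[f"var_{metric}"] = np.nan
            else:
                row[f"mean_{metric}"] = vals.mean()
                row[f"max_{metric}"] = vals.max()
                row[f"var_{metric}"] = vals.var(ddof=1)
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out[list(SUMMARY_COLUMNS)]


def assemble_first_order(
    summaries: pd.DataFrame,
    subjects: pd.DataFrame,
    include_treatment: bool = False,
) -> pd.DataFrame:
    """Join movement summaries with subject covariates into the 51-column
    first-order feature table (movement summaries first, covariates after).

    ``include_treatment`` appends the intervention-arm indicator as an
    optional 52nd column; it is off by default because the baseline schema
    contains exactly 3p + q = 51 features.
    """
    subj = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    missing_ids = set(summaries.index) ^ set(subj.index)
    if missing_ids:
        raise KeyError(
            f"subject identifiers do not match between summaries and "
            f"covariates: {sorted(missing_ids)}"
        )
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in subj.columns]
    if missing_cols:
        raise KeyError(f"subject table lacks required columns: {missing_cols}")
    cols = list(COVARIATE_COLUMNS)
    if include_treatment:
        if "treatment" not in subj.columns:
            raise KeyError("subject table lacks required columns: ['treatment']")
        cols.append("treatment")
    table = summaries.join(subj[cols]).astype(float)
    table.attrs["order"] = "first"
    table.attrs["provenance"] = {c: "base" for c in table.columns}
    return table


def expand_second_order(first_order: pd.DataFrame) -> pd.DataFrame:
    """Quadratic expansion: base columns, their squares, and all pairwise
    products; exact-duplicate and constant columns are then dropped.

    Squares of 0/1 indicator columns duplicate their base column and are
    removed by the duplicate pass, so the 51-column schema with 8 binary
    covariates expands to 1377 - 8 = 1369 columns.
    """
    cols = list(first_order.columns)
    X = first_order.to_numpy(dtype=float)
    data: dict[str, np.ndarray] = {c: X[:, i] for i, c in enumerate(cols)}
    provenance = {c: "base" for c in cols}
    for i, c in enumerate(cols):
        name = f"{c}^2"
        data[name] = X[:, i] ** 2
        provenance[name] = "square"
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            name = f"{cols[i]}*{cols[j]}"
            data[name] = X[:, i] * X[:, j]
            provenance[name] = "interaction"
    out = pd.DataFrame(data, index=first_order.index)

    # drop constants, then exact duplicates (keep the earliest occurrence)
    keep: list[str] = []
    seen: dict[bytes, str] = {}
    for c in out.columns:
        col = out[c].to_numpy()
        if np.all(col == col[0]):
            logger.info("dropping constant column %s", c)
            continue
        key = col.tobytes()
        if key in seen:
            logger.info("dropping duplicate column %s (== %s)", c, seen[key])
            continue
        seen[key] = c
        keep.append(c)
    out = out[keep]
    out.attrs["order"] = "second"
    out.attrs["provenance"] = {c: provenance[c] for c in keep}
    return out


@dataclass
class ScalingRecord:
    """Column means/sds used to standardize, for inverse transforms."""

    means: pd.Series
    sds: pd.Series
    dropped: list[str] = field(default_factory=list)

    def inverse_transform_coefficients(
        self, intercept: float, coefs: pd.Series
    ) -> tuple[float, pd.Series]:
        """Map coefficients fit on standardized columns back to the
        original scale so that predictions are unchanged."""
        raw = coefs / self.sds[coefs.index]
        b0 = intercept - float((raw * self.means[coefs.index]).sum())
        return b0, raw

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.means.index
        return (table[cols] - self.means) / self.sds


def standardize(
    table: pd.DataFrame, stats_from: np.ndarray | pd.Index | None = None
) -> tuple[pd.DataFrame, ScalingRecord]:
    """Center/scale every column using mean and sd computed only on the
    ``stats_from`` rows (the training folds); zero-sd columns are dropped.

    Returns the standardized table (all rows transformed with the training
    statistics) and a :class:`ScalingRecord` for inverse transforms.
    """
    ref = table if stats_from is None else table.loc[stats_from]
    if len(ref) == 0:
        raise ValueError("stats_from selects no rows")
    # per-column reductions: statistics must not depend on sibling columns
    # (blocked 2D reductions can differ in the last ulp with table width,
    # breaking paired comparisons between feature subsets)
    means = pd.Series(
        {c: float(np.mean(ref[c].to_numpy(dtype=float))) for c in table.columns}
    )
    sds = pd.Series(
        {c: float(np.std(ref[c].to_numpy(dtype=float))) for c in table.columns}
    )
    dropped = list(sds.index[sds == 0])
    for c in dropped:
        logger.info("dropping zero-variance column %s", c)
    keep = [c for c in table.columns if c not in dropped]
    record = ScalingRecord(means=means[keep], sds=sds[keep], dropped=dropped)
    return record.transform(table), record
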