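"""qRT-PCR relative expression and group comparisons.

Supports the two quantification modes of low-input EV miRNA validation:

* ``2^-ddCt`` against the arithmetic mean of two reference miRNAs
  (miR-20a-5p / miR-28-5p by default), paired EV-vs-cell within biological
  replicates and tested with a two-sided paired t-test;
* ``40 - dCt`` for patient plasma/tissue samples, where an increment of 1
  equals a doubled expression, compared across groups with the
  Mann-Whitney test (exact below n = 21 per group without ties, normal
  approximation with tie correction otherwise).

"Not detected" means a missing Ct or Ct > ``max_ct`` (40 by default);
undetected values are excluded, never imputed, and exclusion counts are
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_REFERENCES = ("miR-20a-5p", "miR-28-5p")
MAX_CT = 40.0

CT_COLUMNS = ("sample_id", "group", "bio_rep", "target", "tech_rep", "ct")


class DegenerateDataError(ValueError):
    """Raised when a statistical test is undefined on the given data."""


def aggregate_ct(table: pd.DataFrame, max_ct: float = MAX_CT) -> pd.DataFrame:
    """Mean Ct over detected technical replicates per (sample, target).

    A replicate is detected when its Ct is present and <= ``max_ct``.
    Pairs whose replicates are all undetected propagate as undetected
    (``ct_mean`` missing, ``detected`` False).
    """
    for col in CT_COLUMNS[:5]:
        if col not in table.columns:
            raise ValueError(f"Ct table lacks required column {col!r}")
    t = table.copy()
    t["ct"] = pd.to_numeric(t["ct"], errors="coerce")  # "undetected" -> NaN
    t.loc[t["ct"] > max_ct, "ct"] = np.nan
    grouped = t.groupby(["sample_id", "group", "bio_rep", "target"], sort=True)["ct"]
    agg = grouped.agg(ct_mean="mean", ct_sd="std", n_detected="count",
                      n_technical="size").reset_index()
    agg["detected"] = agg["n_detected"] > 0
    agg["partial"] = agg["detected"] & (agg["n_detected"] < agg["n_technical"])
    return agg


def delta_ct(agg: pd.DataFrame,
             reference_targets: tuple[str, ...] = DEFAULT_REFERENCES,
             ) -> tuple[pd.DataFrame, list[str]]:
    """dCt = Ct(target) − mean Ct over the reference assays, per sample.

    Samples in which any reference assay is undetected are excluded and
    listed in the second return value.
    """
    refs = agg[agg.target.isin(reference_targets)]
    excluded: list[str] = []
    ref_ct = {}
    for sample_id, sub in refs.groupby("sample_id"):
        if len(sub) < len(reference_targets) or not sub.detected.all():
            excluded.append(str(sample_id))
        else:
            ref_ct[sample_id] = sub.ct_mean.mean()
    targets = agg[~agg.target.isin(reference_targets)].copy()
    targets = targets[~targets.sample_id.isin(excluded)]
    targets["dct"] = targets.ct_mean - targets.sample_id.map(ref_ct)
    return targets, sorted(excluded)


def ddct_fold(dct_sample: float, dct_calibrator: float) -> float:
    """2^-(dCt_sample − dCt_calibrator): fold change under efficiency-2."""
    return float(2.0 ** -(dct_sample - dct_calibrator))


def forty_minus_dct(dct: float | np.ndarray | pd.Series, max_ct: float = MAX_CT):
    """Relative expression on the 40−dCt scale (Δ of 1 = doubled expression)."""
    return max_ct - dct


def group_compare(values: np.ndarray, groups: np.ndarray, paired: bool = False,
                  exact_max_n: int = 20) -> dict:
    """Two-sided group comparison.

    Paired: t-test on within-pair differences (undefined — raises — when the
    differences have zero variance). Unpaired: Mann-Whitney, exact when both
    groups have <= ``exact_max_n`` observations, otherwise the normal
    approximation with tie correction. All-tied input returns p = 1 with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"group_compare needs exactly two groups, got {levels}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison requires complete pairs")
        diffs = a - b
        if np.std(diffs) == 0:
            raise DegenerateDataError(
                "paired t-test undefined: all pair differences are identical")
        t, p = stats.ttest_rel(a, b)
        return {"test": "paired t", "stat": float(t), "p": float(p),
                "n": (len(a), len(b))}
    if np.all(values == values[0]):
        warnings.warn("all values tied; Mann-Whitney p set to 1", stacklevel=2)
        return {"test": "mann-whitney", "stat": len(a) * len(b) / 2.0, "p": 1.0,
                "n": (len(a), len(b))}
    method = "exact" if max(len(a), len(b)) <= exact_max_n else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"test": f"mann-whitney ({method})", "stat": float(u), "p": float(p),
            "n": (len(a), len(b))}


@dataclass
class RelExprResult:
    per_sample: pd.DataFrame
    group_summary: pd.DataFrame
    excluded_samples: list[str]


def paired_relative_expression(table: pd.DataFrame, test_group: str = "EV",
                               ref_group: str = "cell",
                               reference_targets: tuple[str, ...] = DEFAULT_REFERENCES,
                               estimator: str = "mean_of_folds",
                               max_ct: float = MAX_CT) -> RelExprResult:
    """Cell-line mode: per-biological-replicate 2^-ddCt, paired test.

    For each target, fold changes are computed per biological replicate
    (EV dCt vs parental-cell dCt) and summarized either as the mean of the
    per-replicate folds (default) or as 2^-(mean ddCt)
    (``estimator="fold_of_means"``). The paired t-test runs on the dCt pairs.
    """
    if estimator not in ("mean_of_folds", "fold_of_means"):
        raise ValueError(f"unknown estimator {estimator!r}")
    agg = aggregate_ct(table, max_ct)
    dct, excluded = delta_ct(agg, reference_targets)
    per_sample_rows, summary_rows = [], []
    for target, sub in dct.groupby("target", sort=True):
        pivot = sub.pivot_table(index="bio_rep", columns="group", values="dct",
                                aggfunc="mean")
        if test_group not in pivot or ref_group not in pivot:
            continue
        pairs = pivot[[test_group, ref_group]].dropna()
        folds = 2.0 ** -(pairs[test_group] - pairs[ref_group])
        for rep, fold in folds.items():
            per_sample_rows.append({"target": target, "bio_rep": rep, "fold": fold,
                                    "ddct": float(pairs.loc[rep, test_group]
                                                  - pairs.loc[rep, ref_group])})
        if len(pairs) >= 2:
            try:
                test = group_compare(
                    np.concatenate([pairs[test_group], pairs[ref_group]]),
                    np.array([test_group] * len(pairs) + [ref_group] * len(pairs)),
                    paired=True)
            except DegenerateDataError:
                test = {"test": "paired t", "stat": np.nan, "p": np.nan,
                        "n": (len(pairs), len(pairs))}
        else:
            test = {"test": "paired t", "stat": np.nan, "p": np.nan,
                    "n": (len(pairs), len(pairs))}
        if estimator == "mean_of_folds":
            fold_summary = float(folds.mean())
        else:
            fold_summary = float(2.0 ** -(pairs[test_group] - pairs[ref_group]).mean())
        summary_rows.append({"target": target, "fold": fold_summary,
                             "fold_sd": float(folds.std(ddof=1)) if len(folds) > 1
                             else np.nan,
                             "n_pairs": len(pairs), "test": test["test"],
                             "p": test["p"]})
    return RelExprResult(pd.DataFrame(per_sample_rows), pd.DataFrame(summary_rows),
                         excluded)


def plasma_group_comparison(table: pd.DataFrame, groups: tuple[str, str],
                            reference_targets: tuple[str, ...] = DEFAULT_REFERENCES,
                            max_ct: float = MAX_CT) -> RelExprResult:
    """Plasma/tissue mode: per-sample 40−dCt and Mann-Whitney group tests."""
    agg = aggregate_ct(table, max_ct)
    dct, excluded = delta_ct(agg, reference_targets)
    dct = dct.copy()
    dct["rel_expr_40mdct"] = forty_minus_dct(dct["dct"], max_ct)
    summary_rows = []
    for target, sub in dct.groupby("target", sort=True):
        detected = sub[sub.detected & sub.dct.notna()]
        row = {"target": target}
        for g in groups:
            vals = detected.loc[detected.group == g, "rel_expr_40mdct"]
            row[f"mean_{g}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"sd_{g}"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
            row[f"n_{g}"] = int(len(vals))
        row["n_undetected"] = int((~sub.detected).sum())
        try:
            test = group_compare(detected.rel_expr_40mdct.to_numpy(),
                                 detected.group.to_numpy())
            row.update({"test": test["test"], "p": test["p"]})
        except ValueError:
            row.update({"test": "mann-whitney", "p": np.nan})
        summary_rows.append(row)
    return RelExprResult(dct, pd.DataFrame(summary_rows), excluded)
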