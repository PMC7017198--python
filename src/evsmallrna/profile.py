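"""Class-level summaries of mapped counts: per-sample ncRNA class
distributions with condition averages, inter-replicate Pearson correlation,
and the detection-overlap partition between conditions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class ClassProfile:
    #: rows = samples then "<condition> average" rows; one count and one
    #: percentage column per class, plus the mapped total
    per_sample_counts: pd.DataFrame
    per_sample_pct: pd.DataFrame
    table: pd.DataFrame

    def pct(self, sample: str, rna_class: str) -> float:
        return float(self.per_sample_pct.loc[sample, rna_class])


def class_distribution(counts: pd.DataFrame, classmap: Mapping[str, str],
                       condition_of: Mapping[str, str] | None = None) -> ClassProfile:
    """Per-sample (and per-condition average) class totals and percentages.

    Condition averages are arithmetic means of the replicate counts, with
    percentages recomputed from the averaged counts — the construction used
    for published per-class read tables.
    """
    missing = [f for f in counts.index if f not in classmap]
    if missing:
        raise KeyError(f"features missing from class map: {missing[:5]}"
                       + ("..." if len(missing) > 5 else ""))
    classes = pd.Series({f: classmap[f] for f in counts.index}, name="rna_class")
    by_class = counts.groupby(classes).sum().T  # samples x classes
    totals = by_class.sum(axis=1)
    pct = by_class.div(totals.replace(0, np.nan), axis=0) * 100.0

    rows_counts, rows_pct = [by_class], [pct]
    if condition_of:
        for cond in dict.fromkeys(condition_of.values()):
            members = [s for s in by_class.index if condition_of.get(s) == cond]
            avg = by_class.loc[members].mean(axis=0).to_frame(f"{cond} average").T
            avg_tot = avg.sum(axis=1)
            rows_counts.append(avg)
            rows_pct.append(avg.div(avg_tot.replace(0, np.nan), axis=0) * 100.0)
    all_counts = pd.concat(rows_counts)
    all_pct = pd.concat(rows_pct)

    table = pd.concat({"count": all_counts, "pct": all_pct.round(2)}, axis=1)
    table = table.swaplevel(axis=1).sort_index(axis=1, level=0)
    table.index.name = "sample"
    return ClassProfile(all_counts, all_pct, table)


def replicate_correlation(counts: pd.DataFrame, log_transform: bool = True,
                          size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Pairwise Pearson r between samples.

    Default operates on log2(normalized count + 1); pass
    ``log_transform=False`` for raw-scale correlation. Zero-variance samples
    yield missing (NaN) coefficients.
    """
    if counts.shape[1] < 2:
        raise ValueError("replicate correlation requires at least two samples")
    x = counts.astype(float)
    if size_factors is not None:
        x = x.div(size_factors, axis=1)
    if log_transform:
        x = np.log2(x + 1.0)
    r = x.corr(method="pearson")  # pandas leaves NaN for zero-variance columns
    np.fill_diagonal(r.values, np.where(x.std(axis=0) > 0, 1.0, np.nan))
    return r


def detection_overlap(counts: pd.DataFrame, condition_of: Mapping[str, str],
                      threshold: float = 100.0, stat: str = "mean") -> pd.DataFrame:
    """Partition features by whether their per-condition abundance reaches
    the detection threshold (inclusive >=) in both, one, or neither condition.

    ``stat`` is the per-condition summary: "mean" (default) or "min" across
    replicates. Returns a frame with the per-condition statistic and a
    ``category`` in {both, <A>_only, <B>_only, below}.
    """
    conds = list(dict.fromkeys(condition_of.values()))
    if len(conds) != 2:
        raise ValueError(f"detection_overlap needs exactly two conditions, got {conds}")
    agg = {}
    for cond in conds:
        members = [s for s in counts.columns if condition_of.get(s) == cond]
        if not members:
            raise ValueError(f"condition {cond!r} has no samples")
        sub = counts[members]
        agg[cond] = sub.mean(axis=1) if stat == "mean" else sub.min(axis=1)
    a, b = conds
    frame = pd.DataFrame(agg)
    in_a, in_b = frame[a] >= threshold, frame[b] >= threshold
    frame["category"] = np.select(
        [in_a & in_b, in_a & ~in_b, ~in_a & in_b],
        ["both", f"{a}_only", f"{b}_only"], default="below")
    frame.index.name = "feature_id"
    return frame
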