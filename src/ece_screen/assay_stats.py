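"""Closed-form assay computations and statistical contracts.

Implements the quantitative readouts of the enhancer study as pure
functions over tidy tables:

* ChIP-qPCR enrichment as percent input, 100 * 2**(Ct(input) - Ct(IP)).
* Dual-luciferase fold induction: Firefly normalized to Renilla, then
  fold change over the empty-vector control mean.
* Allele-specific expression: the cDNA allelic ratio normalized to the
  genomic-DNA allelic ratio of the same sample (1.0 = balanced, in-cis
  effects shift it away from 1).
* Eccrine gland counts averaged across the left and right forelimb of
  each animal, and the percent difference between genotype groups.
* Group comparisons: ordinary one-way ANOVA with Tukey-adjusted pairwise
  p-values (single pooled variance), or a two-tailed unpaired t test —
  thin contracts over scipy.stats.

Technical replicates are averaged before any biological-replicate
statistic. No outlier removal is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "percent_input",
    "chip_percent_input",
    "fold_induction",
    "allelic_ratio_normalized",
    "allelic_imbalance_table",
    "ifp_gland_mean",
    "group_percent_difference",
    "GroupTestResult",
    "group_tests",
]


def percent_input(ct_input: float, ct_ip: float) -> float:
    """ChIP enrichment over input: 100 * 2**(Ct(input) - Ct(IP)).

    May exceed 100 when the IP amplifies earlier than the input — that is
    a property of the formula, not an error.
    """
    if ct_input <= 0 or ct_ip <= 0:
        raise ValueError("Ct values must be positive")
    return 100.0 * 2.0 ** (ct_input - ct_ip)


def chip_percent_input(records: pd.DataFrame) -> pd.DataFrame:
    """Percent-input enrichment from a tidy Ct table.

    ``records`` columns: target, condition (``input`` plus one or more IP
    conditions, e.g. ``IP_antibody`` / ``IP_IgG``), ct, replicate, and
    optionally ``tech`` for technical replicates, which are averaged
    first. Returns one row per (target, IP condition, replicate).
    """
    required = {"target", "condition", "ct", "replicate"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    ct = (
        records.groupby(["target", "condition", "replicate"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    inputs = ct[ct["condition"] == "input"].set_index(["target", "replicate"])["ct"]
    ips = ct[ct["condition"] != "input"]
    if inputs.empty:
        raise ValueError("no 'input' condition in Ct table")
    rows = []
    for _, r in ips.iterrows():
        key = (r["target"], r["replicate"])
        if key not in inputs.index:
            raise ValueError(f"no input Ct for target/replicate {key}")
        rows.append(
            {
                "target": r["target"],
                "condition": r["condition"],
                "replicate": r["replicate"],
                "percent_input": percent_input(inputs[key], r["ct"]),
            }
        )
    return pd.DataFrame(rows)


def fold_induction(
    records: pd.DataFrame,
    control_label: str,
    per_experiment: bool = True,
) -> pd.DataFrame:
    """Per-replicate luciferase fold change over the empty-vector control.

    ``records`` columns: construct, firefly, renilla, replicate, and
    optionally ``experiment``. Normalized activity is firefly / renilla;
    each replicate's fold is its normalized activity divided by the mean
    normalized activity of ``control_label``. With ``per_experiment``
    (default) and an ``experiment`` column present, the control mean is
    taken within each experiment before pooling.
    """
    required = {"construct", "firefly", "renilla", "replicate"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"luminescence table is missing columns {sorted(missing)}")
    if (records["renilla"] <= 0).any():
        raise ValueError("Renilla luminescence must be positive")
    df = records.copy()
    df["normalized"] = df["firefly"] / df["renilla"]
    group_cols = (
        ["experiment"] if per_experiment and "experiment" in df.columns else []
    )

    def _fold(block: pd.DataFrame) -> pd.DataFrame:
        ctrl = block.loc[block["construct"] == control_label, "normalized"]
        if ctrl.empty:
            raise ValueError(f"control construct {control_label!r} absent")
        ctrl_mean = ctrl.mean()
        if ctrl_mean <= 0:
            raise ValueError("control mean normalized activity must be positive")
        out = block.copy()
        out["fold"] = out["normalized"] / ctrl_mean
        return out

    if group_cols:
        parts = [_fold(b) for _, b in df.groupby(group_cols, sort=False)]
        df = pd.concat(parts, ignore_index=True)
    else:
        df = _fold(df)
    cols = ["construct", "replicate", *group_cols, "normalized", "fold"]
    return df[cols].reset_index(drop=True)


def allelic_ratio_normalized(cdna_ratio: float, gdna_ratio: float) -> float:
    """cDNA allelic ratio divided by the matched genomic-DNA ratio."""
    if gdna_ratio <= 0:
        raise ValueError("genomic DNA allelic ratio must be positive")
    if cdna_ratio <= 0:
        raise ValueError("cDNA allelic ratio must be positive")
    return cdna_ratio / gdna_ratio


def allelic_imbalance_table(records: pd.DataFrame) -> pd.DataFrame:
    """Normalized allelic ratios from a tidy table.

    ``records`` columns: sample, template (``cDNA`` / ``gDNA``),
    ratio_raw. Each sample must have both templates; the output has one
    row per sample with its normalized ratio.
    """
    required = {"sample", "template", "ratio_raw"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"allelic table is missing columns {sorted(missing)}")
    pivot = records.pivot_table(
        index="sample", columns="template", values="ratio_raw", aggfunc="mean"
    )
    for col in ("cDNA", "gDNA"):
        if col not in pivot.columns or pivot[col].isna().any():
            raise ValueError(f"every sample needs a {col} measurement")
    out = pd.DataFrame(
        {
            "sample": pivot.index,
            "ratio_normalized": [
                allelic_ratio_normalized(c, g)
                for c, g in zip(pivot["cDNA"], pivot["gDNA"])
            ],
        }
    )
    return out.reset_index(drop=True)


def ifp_gland_mean(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-animal eccrine gland count averaged across forelimbs.

    ``counts`` columns: animal, left, right (nonnegative integers; one
    side may be NaN, in which case the single available limb is used and
    flagged). Returns animal, mean_glands, single_limb.
    """
    required = {"animal", "left", "right"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"gland table is missing columns {sorted(missing)}")
    rows = []
    for _, r in counts.iterrows():
        limbs = [v for v in (r["left"], r["right"]) if pd.notna(v)]
        if not limbs:
            raise ValueError(f"animal {r['animal']!r} has no limb counts")
        if any(v < 0 or v != int(v) for v in limbs):
            raise ValueError("gland counts must be nonnegative integers")
        rows.append(
            {
                "animal": r["animal"],
                "mean_glands": float(np.mean(limbs)),
                "single_limb": len(limbs) == 1,
            }
        )
    return pd.DataFrame(rows)


def group_percent_difference(group_a: Sequence[float],
                             group_b: Sequence[float]) -> float:
    """100 * (mean(B) - mean(A)) / mean(A): percent change of B over A."""
    mean_a = float(np.mean(group_a))
    if mean_a == 0:
        raise ValueError("reference group mean is zero")
    return 100.0 * (float(np.mean(group_b)) - mean_a) / mean_a


@dataclass
class GroupTestResult:
    method: str
    statistic: float
    pvalue: float
    pairwise: pd.DataFrame | None = None


def group_tests(groups: Mapping[str, Sequence[float]],
                design: str = "anova") -> GroupTestResult:
    """Ordinary one-way ANOVA + Tukey, or a two-tailed unpaired t test.

    ``design="anova"`` requires >= 2 groups of >= 2 values each; the
    Tukey table (scipy.stats.tukey_hsd, single pooled variance) reports
    every pairwise mean difference with its adjusted p-value.
    ``design="ttest"`` requires exactly 2 groups. Zero pooled variance is
    degenerate and raises.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled_within = np.concatenate([a - a.mean() for a in arrays])
    if np.allclose(pooled_within, 0.0):
        raise ValueError("degenerate: zero variance within every group")
    if design == "ttest":
        if len(arrays) != 2:
            raise ValueError("t test requires exactly two groups")
        t = stats.ttest_ind(arrays[0], arrays[1])
        return GroupTestResult("ttest", float(t.statistic), float(t.pvalue))
    if design != "anova":
        raise ValueError(f"unknown design {design!r}")
    if any(a.size < 2 for a in arrays):
        raise ValueError("ANOVA requires >= 2 values per group")
    f = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "pvalue_adj": float(tukey.pvalue[i, j]),
                }
            )
    return GroupTestResult(
        "anova", float(f.statistic), float(f.pvalue), pd.DataFrame(rows)
    )
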