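"""The four cellular immunologic distribution groups.

Crossing the distribution pattern (mixed/unmixed) of a phenotype with its
distance class (close/long from malignant cells) yields four groups:

    group 1 -- mixed pattern, close median distance
    group 2 -- mixed pattern, long median distance
    group 3 -- unmixed pattern, close median distance
    group 4 -- unmixed pattern, long median distance

Subjects are grouped on an anchor phenotype (``CD3+`` T-cells by default, the
predominant immune population); group-wise phenotype-density summaries with a
Kruskal-Wallis test across groups characterise inflamed vs cold
microenvironments.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .spatial import base_pattern

logger = logging.getLogger("spatialtme")

GROUP_MAP = {("mixed", "close"): 1, ("mixed", "long"): 2,
             ("unmixed", "close"): 3, ("unmixed", "long"): 4}


def assign_group(pattern: str, distance_class: str) -> int | None:
    """(pattern, distance class) -> group 1-4; NA inputs yield None."""
    if pattern is None or distance_class is None:
        return None
    if pd.isna(pattern) or pd.isna(distance_class):
        return None
    key = (base_pattern(str(pattern)), str(distance_class))
    if key[0] == "NA" or key[1] == "NA":
        return None
    if key not in GROUP_MAP:
        raise ValueError(f"unknown pattern/distance combination {key!r}")
    return GROUP_MAP[key]


def assign_groups(subject_scores: pd.DataFrame,
                  subject_distances: pd.DataFrame,
                  anchor_phenotype: str = "CD3+",
                  reference: str = "CK+") -> pd.DataFrame:
    """Per-subject group from the anchor phenotype's pattern and its distance
    class relative to malignant cells.

    ``subject_scores`` needs columns subject_id/phenotype/pattern;
    ``subject_distances`` needs subject_id/reference/target/distance_class.
    """
    sc = subject_scores.loc[subject_scores["phenotype"] == anchor_phenotype,
                            ["subject_id", "pattern"]]
    di = subject_distances.loc[
        (subject_distances["reference"] == reference)
        & (subject_distances["target"] == anchor_phenotype),
        ["subject_id", "distance_class"]]
    merged = sc.merge(di, on="subject_id", how="outer")
    merged["phenotype"] = anchor_phenotype
    merged["group"] = [assign_group(p, d) for p, d in
                       zip(merged["pattern"], merged["distance_class"])]
    return merged


def group_prevalence(assignments) -> np.ndarray:
    """Proportion of subjects in each of the four groups (over non-NA)."""
    a = pd.Series(assignments).dropna().astype(int)
    if len(a) == 0:
        raise ValueError("no non-NA group assignments")
    counts = np.array([(a == g).sum() for g in (1, 2, 3, 4)], float)
    return counts / counts.sum()


def densities_by_group(subject_densities: pd.DataFrame,
                       assignments: pd.DataFrame) -> pd.DataFrame:
    """Median phenotype density within each group, with a Kruskal-Wallis test
    across groups.

    ``subject_densities``: columns subject_id/phenotype/density (per-subject
    median densities).  ``assignments``: subject_id/group.  Groups with fewer
    than 2 subjects still report a median but are excluded from the test; a
    test needs >= 2 groups with >= 2 subjects each.
    """
    merged = subject_densities.merge(
        assignments.dropna(subset=["group"])[["subject_id", "group"]],
        on="subject_id")
    rows = []
    for pheno, sub in merged.groupby("phenotype"):
        row = {"phenotype": pheno}
        samples = []
        for g in (1, 2, 3, 4):
            vals = sub.loc[sub["group"] == g, "density"].dropna().to_numpy()
            row[f"median_group{g}"] = float(np.median(vals)) if len(vals) else np.nan
            row[f"n_group{g}"] = len(vals)
            if len(vals) >= 2:
                samples.append(vals)
            elif len(vals) > 0:
                logger.warning("phenotype %s: group %d has <2 subjects; "
                               "excluded from the across-group test", pheno, g)
        if len(samples) >= 2:
            if len(np.unique(np.concatenate(samples))) == 1:
                # every observation tied: the degenerate null case
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.kruskal(*samples)
            row["kruskal_stat"], row["kruskal_p"] = float(stat), float(p)
        else:
            row["kruskal_stat"], row["kruskal_p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows)
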