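"""Per-sample median nearest-neighbor distances and cohort dichotomization.

For each (reference, target) phenotype pair -- malignant cells to each immune
phenotype, plus checkpoint-positive malignant and regulatory-T-cell
references -- the per-core median of the reference-to-nearest-target
distances is computed, aggregated per subject by median, and dichotomized at
the cohort median: values at or below the median are "close", values above
are "long".  No edge correction is applied (the statistic is a median of
nearest-neighbor distances, not a CDF estimate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MALIGNANT
from .spatial import nearest_neighbor_distances

logger = logging.getLogger("spatialtme")

#: Canonical immune phenotypes measured from malignant cells.
CORE_PHENOTYPES = (
    "CD3+", "CD3+CD8+", "CD3+PD-1+", "CD3+PD-L1+", "CD3+CD8+PD-1+",
    "CD3+CD8+PD-L1+", "CD68+", "CD68+PD-L1+", "CD3+CD8+GZB+", "CD3+CD45RO+",
    "CD3+CD8+CD45RO+", "CD3+CD8negFOXP3+", "CD3+CD45RO+FOXP3+", "CD3+B7-H3+",
    "CD3+ICOS+", "CD3+LAG3+", "CD3+OX40+", "CD3+TIM3+", "CD20+", "CD20+ICOS+",
    "CD20+OX40+", "CD20+LAG3+", "CD68+CD11b+", "CD66b+", "CD11b+CD66b+",
    "CD11b+CD66b+CD33+",
)

#: Additional reference phenotypes (checkpoint-positive malignant cells and
#: regulatory T-cells) measured to T/B-cell targets.
EXTRA_REFERENCES = ("CK+PD-L1+", "CK+PD-L1neg", "CK+B7-H3+", "CK+B7-H4+",
                    "CK+IDO-1+", "CD3+CD8negFOXP3+")

_TCELL_TARGETS = (
    "CD3+", "CD3+CD8+", "CD3+PD-1+", "CD3+PD-L1+", "CD3+CD8+PD-1+",
    "CD3+CD8+PD-L1+", "CD3+CD8+GZB+", "CD3+CD45RO+", "CD3+CD8+CD45RO+",
    "CD3+CD8negFOXP3+", "CD3+CD45RO+FOXP3+", "CD3+B7-H3+", "CD3+ICOS+",
    "CD3+LAG3+", "CD3+OX40+", "CD3+TIM3+", "CD20+",
)


def default_pair_list() -> list[tuple[str, str]]:
    """The 128 default (reference, target) distance pairs: malignant cells to
    the 26 canonical phenotypes, plus six special references (checkpoint-
    positive/negative malignant cells and regulatory T-cells) to 17 T/B-cell
    phenotypes each."""
    pairs = [(MALIGNANT, p) for p in CORE_PHENOTYPES]
    for ref in EXTRA_REFERENCES:
        targets = list(_TCELL_TARGETS)
        if ref in targets:  # a reference is never paired with itself
            targets[targets.index(ref)] = "CD68+"
        pairs.extend((ref, t) for t in targets)
    return pairs


@dataclass(frozen=True)
class DistanceSummary:
    subject_id: str
    reference: str
    target: str
    median_nn_distance: float  # um
    distance_class: str = "NA"  # close | long | NA


def median_nn_distance(reference_points: np.ndarray,
                       target_points: np.ndarray) -> float:
    """Median of the per-reference-point nearest-target distances, in um.

    Returns NaN with a warning when the target set is empty (phenotype absent
    in the core)."""
    ref = np.asarray(reference_points, float).reshape(-1, 2)
    tgt = np.asarray(target_points, float).reshape(-1, 2)
    if len(ref) == 0:
        return float("nan")
    if len(tgt) == 0:
        warnings.warn("empty target phenotype: median NN distance is NA",
                      stacklevel=2)
        return float("nan")
    return float(np.median(nearest_neighbor_distances(ref, tgt)))


def distance_panel(cells: pd.DataFrame,
                   phenotype_matrix: pd.DataFrame,
                   pairs=None) -> pd.DataFrame:
    """Per-subject median NN distance for every phenotype pair.

    Per-core medians are aggregated per subject by median; pairs whose
    reference or target phenotype is absent cohort-wide are dropped with a
    warning.  Returns columns ``subject_id``, ``reference``, ``target``,
    ``median_nn_um``.
    """
    if pairs is None:
        pairs = default_pair_list()
    present = {p for p in phenotype_matrix.columns if phenotype_matrix[p].any()}
    kept, dropped = [], []
    for ref, tgt in pairs:
        if ref in present and tgt in present:
            kept.append((ref, tgt))
        else:
            dropped.append((ref, tgt))
    if dropped:
        shown = ", ".join(f"{r}->{t}" for r, t in dropped[:5])
        more = f" (+{len(dropped) - 5} more)" if len(dropped) > 5 else ""
        logger.warning("%d distance pair(s) dropped, phenotype absent "
                       "cohort-wide: %s%s", len(dropped), shown, more)
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    rows = []
    for (subject, core), idx in cells.groupby(["subject_id", "core_id"]).groups.items():
        pm = phenotype_matrix.loc[idx]
        loc = cells.index.get_indexer(idx)
        for ref, tgt in kept:
            ref_pts = xy[loc][pm[ref].to_numpy(bool)]
            tgt_pts = xy[loc][pm[tgt].to_numpy(bool)]
            if len(ref_pts) == 0 or len(tgt_pts) == 0:
                med = float("nan")
            else:
                med = float(np.median(nearest_neighbor_distances(ref_pts, tgt_pts)))
            rows.append({"subject_id": subject, "core_id": core,
                         "reference": ref, "target": tgt, "median_nn_um": med})
    per_core = pd.DataFrame(rows)
    if per_core.empty:
        return pd.DataFrame(columns=["subject_id", "reference", "target",
                                     "median_nn_um"])
    return (per_core.groupby(["subject_id", "reference", "target"], as_index=False)
            ["median_nn_um"].median())


def dichotomize_at_cohort_median(values: pd.Series,
                                 labels: tuple[str, str] = ("close", "long")
                                 ) -> pd.Series:
    """Split per-subject values at the cohort median.

    Values at or below the median get the first label ("close" for distances,
    "low" for densities), values above get the second; NA values stay NA and
    are excluded from the median.  Ties at the median go to the first label,
    so ``count(close) >= count(long)`` always.
    """
    v = pd.Series(values, dtype=float)
    non_na = v.dropna()
    if len(non_na) == 0:
        raise ValueError("cannot dichotomize: all values are NA")
    if len(non_na) < 2:
        raise ValueError("cannot dichotomize fewer than 2 non-NA values")
    med = float(non_na.median())
    out = pd.Series(pd.NA, index=v.index, dtype=object)
    out[v <= med] = labels[0]
    out[v > med] = labels[1]
    return out


def classify_distances(subject_distances: pd.DataFrame,
                       clinical: pd.DataFrame | None = None,
                       by_histology: bool = False) -> pd.DataFrame:
    """Attach a close/long class per (reference, target) pair at the cohort
    median; optionally dichotomize within histology subgroups."""
    df = subject_distances.copy()
    if by_histology and clinical is not None:
        df = df.merge(clinical[["subject_id", "histology"]], on="subject_id",
                      how="left")
        keys = ["reference", "target", "histology"]
    else:
        keys = ["reference", "target"]
    def _dich(group):
        g = group.copy()
        if g["median_nn_um"].notna().sum() >= 2:
            g["distance_class"] = dichotomize_at_cohort_median(g["median_nn_um"])
        else:
            g["distance_class"] = pd.NA
        return g
    out = df.groupby(keys, group_keys=False)[df.columns].apply(_dich)
    return out.drop(columns=["histology"], errors="ignore")
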