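"""Cross-type nearest-neighbor G function and the mixing score.

For a reference phenotype (malignant, ``CK+`` cells by default) and a target
phenotype, the empirical cross-G function

    G_emp(r) = proportion of reference cells whose nearest target cell
               lies within distance r

is compared with the G function of a homogeneous Poisson process of the same
intensity ("complete spatial randomness", CSR),

    G_theo(r) = 1 - exp(-lambda * pi * r**2).

The *mixing score* is the area between the two curves, normalised by the area
under the theoretical curve and expressed in percent:

    score = 100 * integral(G_theo - G_emp) / integral(G_theo).

Under CSR the score is near 0; when targets cluster away from the reference
cells G_emp lags G_theo and the score is positive; when targets are attracted
to reference cells the score is negative.  Scores in [-10, 10] classify the
phenotype's distribution as "mixed" (interspersed with malignant cells) and
scores above 10 as "unmixed" (clustered apart); scores below -10 remain
"mixed" but are flagged as attraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import UM2_PER_MM2, MALIGNANT, PointPattern, Window, build_point_pattern

logger = logging.getLogger("spatialtme")

#: Mixing-score band: |score| <= MIXED_BAND is "mixed", above is "unmixed".
MIXED_BAND = 10.0
#: Default cap on the r grid (um); roughly a core radius, keeps the score
#: from being dominated by the flat tail of the CDFs.
R_MAX_CAP = 200.0
#: G_theo level at which the r grid is truncated by default.
R_MAX_QUANTILE = 0.99
#: Minimum reference/target counts per core for a stable empirical CDF.
MIN_REFERENCE = 5
MIN_TARGET = 5


# ---------------------------------------------------------------------------
# Nearest-neighbor distances
# ---------------------------------------------------------------------------

def nearest_neighbor_distances(reference: np.ndarray,
                               target: np.ndarray) -> np.ndarray:
    """Euclidean distance from each reference point to its nearest target.

    If ``reference`` and ``target`` are the identical array, each point's
    self-distance is excluded.  Raises if the target set is empty (phenotype
    absent in the core).
    """
    ref = np.asarray(reference, dtype=float).reshape(-1, 2)
    tgt = np.asarray(target, dtype=float).reshape(-1, 2)
    if len(tgt) == 0:
        raise ValueError("phenotype absent in core: empty target point set")
    same = ref is target or (ref.shape == tgt.shape and np.array_equal(ref, tgt))
    if same and len(tgt) < 2:
        raise ValueError("self nearest-neighbor distances need >= 2 points")
    tree = cKDTree(tgt)
    if same:
        d, _ = tree.query(ref, k=2)
        return d[:, 1]
    d, _ = tree.query(ref, k=1)
    return d


# ---------------------------------------------------------------------------
# G functions
# ---------------------------------------------------------------------------

def theoretical_poisson_g(intensity_per_mm2: float, r_grid: np.ndarray) -> np.ndarray:
    """CSR nearest-neighbor CDF ``1 - exp(-lambda pi r^2)``; r in um."""
    if intensity_per_mm2 < 0:
        raise ValueError("intensity must be non-negative")
    lam_um2 = intensity_per_mm2 / UM2_PER_MM2
    r = np.asarray(r_grid, dtype=float)
    return 1.0 - np.exp(-lam_um2 * math.pi * r ** 2)


def empirical_cross_g(reference: np.ndarray,
                      target: np.ndarray,
                      r_grid: np.ndarray,
                      edge_correction: str = "none",
                      window: Window | None = None) -> np.ndarray:
    """Empirical cross-G: per-r proportion of reference points with a target
    neighbor within r.

    With ``edge_correction="border"`` (reduced-sample correction), at each r
    only reference points at least r from the window boundary enter the
    numerator and denominator, removing the censoring bias of unobserved
    neighbors outside the window; the resulting curve is made nondecreasing by
    a running maximum.  Radii at which no reference point survives the border
    condition are returned as NaN.
    """
    r = np.asarray(r_grid, dtype=float)
    nn = nearest_neighbor_distances(reference, target)
    if edge_correction == "none":
        return (nn[None, :] <= r[:, None]).mean(axis=1)
    if edge_correction != "border":
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    if window is None:
        raise ValueError("border correction requires the observation window")
    bdist = window.boundary_distance(np.asarray(reference, float).reshape(-1, 2))
    g = np.full(len(r), np.nan)
    for i, ri in enumerate(r):
        keep = bdist >= ri
        k = int(keep.sum())
        if k == 0:
            logger.warning("border correction: no reference points retained at "
                           "r=%.1f um; curve truncated", ri)
            break
        g[i] = np.count_nonzero(nn[keep] <= ri) / k
    # reduced-sample estimates are not automatically monotone; enforce it
    valid = ~np.isnan(g)
    g[valid] = np.maximum.accumulate(g[valid])
    return g


def default_r_grid(intensity_per_mm2: float,
                   r_max: float | None = None,
                   step: float = 1.0) -> np.ndarray:
    """r grid from 0 to the radius where G_theo reaches 0.99, capped at 200 um."""
    if r_max is None:
        lam_um2 = intensity_per_mm2 / UM2_PER_MM2
        if lam_um2 > 0:
            r99 = math.sqrt(-math.log(1.0 - R_MAX_QUANTILE) / (math.pi * lam_um2))
            r_max = min(r99, R_MAX_CAP)
        else:
            r_max = R_MAX_CAP
    if r_max <= 0:
        raise ValueError("r_max must be positive")
    n = int(math.floor(r_max / step))
    return np.linspace(0.0, n * step, n + 1)


# ---------------------------------------------------------------------------
# Mixing score and classification
# ---------------------------------------------------------------------------

def mixing_score(g_emp: np.ndarray, g_theo: np.ndarray,
                 r_grid: np.ndarray) -> float:
    """Normalised area between the theoretical and empirical G curves (%).

    ``100 * trapz(G_theo - G_emp) / trapz(G_theo)`` over the shared r grid.
    NaN tails of the empirical curve (border-corrected radii with no retained
    reference point) truncate the integration range.  Undefined (NaN) when the
    theoretical curve is identically zero.
    """
    r = np.asarray(r_grid, dtype=float)
    ge = np.asarray(g_emp, dtype=float)
    gt = np.asarray(g_theo, dtype=float)
    if not (len(r) == len(ge) == len(gt)):
        raise ValueError("curves must share one r grid")
    valid = ~np.isnan(ge)
    if valid.sum() < 2:
        return float("nan")
    if not valid.all():
        last = np.nonzero(valid)[0].max()
        logger.warning("mixing score: integration truncated at r=%.1f um", r[last])
        r, ge, gt = r[: last + 1], ge[: last + 1], gt[: last + 1]
    denom = np.trapezoid(gt, r)
    if denom <= 0:
        return float("nan")
    # ratio before scaling: keeps the g_emp == 0 extreme at exactly 100
    return float(100.0 * (np.trapezoid(gt - ge, r) / denom))


def classify_pattern(score: float) -> str:
    """Map a mixing score to its distribution pattern.

    Scores in [-10, 10] are "mixed", above 10 "unmixed"; scores below -10 are
    "mixed (attraction)" -- the band only defines mixed/unmixed, and strong
    attraction is still an interspersed arrangement worth flagging.
    """
    if score is None or (isinstance(score, float) and math.isnan(score)):
        return "NA"
    if score > MIXED_BAND:
        return "unmixed"
    if score < -MIXED_BAND:
        return "mixed (attraction)"
    return "mixed"


def base_pattern(pattern: str) -> str:
    """Collapse the attraction flag: 'mixed (attraction)' -> 'mixed'."""
    return "mixed" if pattern.startswith("mixed") else pattern


@dataclass(frozen=True)
class CrossGResult:
    """Cross-G comparison of one (reference, target) phenotype pair in a core."""

    r_grid: np.ndarray
    g_emp: np.ndarray
    g_theo: np.ndarray
    target_intensity: float  # cells/mm2
    n_reference: int
    n_target: int
    score: float
    pattern: str
    edge_correction: str


def cross_g(reference: PointPattern,
            target: PointPattern,
            edge_correction: str = "border",
            r_max: float | None = None,
            min_reference: int = MIN_REFERENCE,
            min_target: int = MIN_TARGET) -> CrossGResult:
    """Full cross-G analysis of one core: curves, mixing score and pattern.

    The theoretical curve uses the target phenotype's realised intensity in
    the shared window.  Cores with fewer than ``min_reference`` reference or
    ``min_target`` target cells yield an NA result.
    """
    n_ref, n_tgt = reference.n, target.n
    lam = target.intensity_per_mm2
    if n_ref < min_reference or n_tgt < min_target:
        empty = np.array([])
        return CrossGResult(empty, empty, empty, lam, n_ref, n_tgt,
                            float("nan"), "NA", edge_correction)
    r = default_r_grid(lam, r_max=r_max)
    g_t = theoretical_poisson_g(lam, r)
    g_e = empirical_cross_g(reference.points, target.points, r,
                            edge_correction=edge_correction,
                            window=reference.window)
    score = mixing_score(g_e, g_t, r)
    return CrossGResult(r, g_e, g_t, lam, n_ref, n_tgt, score,
                        classify_pattern(score), edge_correction)


# ---------------------------------------------------------------------------
# Cohort-level scoring
# ---------------------------------------------------------------------------

def score_all(cells: pd.DataFrame,
              phenotype_matrix: pd.DataFrame,
              included_phenotypes,
              reference_phenotype: str = MALIGNANT,
              window_spec="convex_hull",
              edge_correction: str = "border",
              r_max: float | None = None,
              min_reference: int = MIN_REFERENCE,
              min_target: int = MIN_TARGET) -> pd.DataFrame:
    """Score every (core, phenotype) pair against the reference phenotype.

    Returns one tidy row per core x phenotype with columns ``subject_id``,
    ``core_id``, ``phenotype``, ``n_ref``, ``n_target``, ``lambda``, ``score``,
    ``pattern``, ``edge_correction``, ``r_max``.  Cores failing the minimum
    count preconditions carry an NaN score and "NA" pattern.
    """
    rows = []
    for (subject, core), idx in cells.groupby(["subject_id", "core_id"]).groups.items():
        core_cells = cells.loc[idx]
        pm = phenotype_matrix.loc[idx]
        try:
            ref = build_point_pattern(core_cells, reference_phenotype,
                                      window_spec, phenotype_matrix=pm)
        except ValueError:
            continue
        for pheno in included_phenotypes:
            tgt = PointPattern(points=core_cells[["x_um", "y_um"]]
                               .to_numpy(float)[pm[pheno].to_numpy(bool)],
                               window=ref.window, phenotype=pheno,
                               core_id=str(core))
            res = cross_g(ref, tgt, edge_correction=edge_correction, r_max=r_max,
                          min_reference=min_reference, min_target=min_target)
            rows.append({"subject_id": subject, "core_id": core,
                         "phenotype": pheno, "n_ref": res.n_reference,
                         "n_target": res.n_target, "lambda": res.target_intensity,
                         "score": res.score, "pattern": res.pattern,
                         "edge_correction": edge_correction,
                         "r_max": res.r_grid[-1] if len(res.r_grid) else float("nan")})
    cols = ["subject_id", "core_id", "phenotype", "n_ref", "n_target",
            "lambda", "score", "pattern", "edge_correction", "r_max"]
    return pd.DataFrame(rows, columns=cols)


def aggregate_scores_by_subject(core_scores: pd.DataFrame) -> pd.DataFrame:
    """Median score per subject x phenotype (triplicate cores collapse to one
    value; NA cores are excluded), with the pattern re-classified from the
    median score."""
    valid = core_scores.dropna(subset=["score"])
    agg = (valid.groupby(["subject_id", "phenotype"], as_index=False)
           .agg(score=("score", "median"), n_cores=("score", "size")))
    agg["pattern"] = agg["score"].map(classify_pattern)
    return agg


def summarize_scores_by_phenotype(subject_scores: pd.DataFrame,
                                  clinical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cohort median score per phenotype, optionally split by histology."""
    out = (subject_scores.groupby("phenotype", as_index=False)
           .agg(median_score=("score", "median"), n_subjects=("score", "size")))
    out["pattern"] = out["median_score"].map(classify_pattern)
    if clinical is not None and "histology" in clinical.columns:
        merged = subject_scores.merge(clinical[["subject_id", "histology"]],
                                      on="subject_id", how="left")
        by_hist = (merged.groupby(["phenotype", "histology"])["score"].median()
                   .unstack("histology"))
        by_hist.columns = [f"median_score_{h}" for h in by_hist.columns]
        out = out.merge(by_hist.reset_index(), on="phenotype", how="left")
    return out
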