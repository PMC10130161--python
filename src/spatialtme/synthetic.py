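"""Synthetic multi-type point patterns in tissue-core windows, with survival.

The generator emulates the data a tissue-microarray (TMA) immunofluorescence
study produces: 1-mm-diameter circular cores containing a field of malignant
(``CK+``) cells and immune phenotypes placed at configurable densities in one
of three spatial regimes --

``csr``
    homogeneous Poisson (complete spatial randomness);
``attraction``
    each immune cell is a malignant parent plus an isotropic Gaussian offset,
    modelling immune cells infiltrating between tumor cells;
``segregated_cluster``
    a Thomas cluster process (Poisson parents, Gaussian offspring) whose
    parents keep a minimum exclusion distance from every malignant cell,
    modelling immune aggregates segregated from the tumor.

A cohort generator assigns each subject one of four ground-truth immunologic
distribution groups (mixed/unmixed pattern x close/long distance), simulates
its cores with regime presets that realise the group, and draws exponential
survival times whose hazard depends on the group, enabling end-to-end
recovery tests of the full pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import UM2_PER_MM2, Window

REGIMES = ("csr", "attraction", "segregated_cluster")
#: Retry cap for rejection sampling (per point / per parent).
MAX_TRIES = 10_000


@dataclass(frozen=True)
class PhenotypeSimSpec:
    """Simulation spec for one immune phenotype in a core.

    Exactly the parameters of the named regime are required: ``intensity``
    for ``csr``; ``intensity`` and ``attraction_scale`` for ``attraction``;
    ``cluster_parent_intensity``, ``cluster_offspring_mean``,
    ``cluster_scale`` and ``exclusion_radius`` for ``segregated_cluster``.
    Intensities are cells/mm2, scales um.
    """

    name: str
    regime: str
    intensity: float | None = None
    attraction_scale: float | None = None
    cluster_parent_intensity: float | None = None
    cluster_offspring_mean: float | None = None
    cluster_scale: float | None = None
    exclusion_radius: float | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime in ("csr", "attraction"):
            if self.intensity is None or self.intensity < 0:
                raise ValueError(f"{self.name}: {self.regime} needs intensity >= 0")
        if self.regime == "attraction":
            if not self.attraction_scale or self.attraction_scale <= 0:
                raise ValueError(f"{self.name}: attraction needs attraction_scale > 0")
        if self.regime == "segregated_cluster":
            for fname in ("cluster_parent_intensity", "cluster_offspring_mean",
                          "cluster_scale", "exclusion_radius"):
                v = getattr(self, fname)
                if v is None or v < 0:
                    raise ValueError(f"{self.name}: segregated_cluster needs {fname} >= 0")
            if self.cluster_scale <= 0:
                raise ValueError(f"{self.name}: cluster_scale must be > 0")

    @property
    def nominal_intensity(self) -> float:
        """Expected cells/mm2 implied by the regime parameters."""
        if self.regime == "segregated_cluster":
            return self.cluster_parent_intensity * self.cluster_offspring_mean
        return float(self.intensity)


@dataclass(frozen=True)
class CoreSimConfig:
    """One simulated TMA core: window, malignant field and immune phenotypes."""

    malignant_intensity: float  # cells/mm2
    phenotype_specs: tuple[PhenotypeSimSpec, ...] = ()
    window_shape: str = "circle"  # "circle" | "rectangle"
    window_diameter: float = 1000.0  # um (1-mm TMA core)
    seed: int | None = None

    def __post_init__(self):
        if self.window_diameter <= 0:
            raise ValueError("window_diameter must be positive")
        if self.malignant_intensity < 0:
            raise ValueError("malignant_intensity must be non-negative")
        if self.window_shape not in ("circle", "rectangle"):
            raise ValueError(f"unknown window_shape {self.window_shape!r}")
        object.__setattr__(self, "phenotype_specs", tuple(self.phenotype_specs))

    def window(self) -> Window:
        r = self.window_diameter / 2.0
        if self.window_shape == "circle":
            return Window.circle((r, r), r)
        s = self.window_diameter
        return Window.polygon(np.array([[0, 0], [s, 0], [s, s], [0, s]], float))


# ---------------------------------------------------------------------------
# Point samplers
# ---------------------------------------------------------------------------

def _uniform_in_window(n: int, config: CoreSimConfig,
                       rng: np.random.Generator) -> np.ndarray:
    r = config.window_diameter / 2.0
    if config.window_shape == "circle":
        rad = r * np.sqrt(rng.random(n))
        theta = rng.random(n) * 2 * math.pi
        return np.column_stack([r + rad * np.cos(theta), r + rad * np.sin(theta)])
    return rng.random((n, 2)) * config.window_diameter


def _poisson_count(intensity_per_mm2: float, area_um2: float,
                   rng: np.random.Generator) -> int:
    return int(rng.poisson(intensity_per_mm2 / UM2_PER_MM2 * area_um2))


def _sample_attraction(spec: PhenotypeSimSpec, parents: np.ndarray,
                       config: CoreSimConfig, window: Window,
                       rng: np.random.Generator) -> np.ndarray:
    n = _poisson_count(spec.intensity, window.area_um2, rng)
    if n == 0:
        return np.empty((0, 2))
    if len(parents) == 0:
        raise ValueError(f"phenotype {spec.name!r}: attraction regime needs "
                         "malignant parent cells, but the core has none")
    pts = np.empty((n, 2))
    for i in range(n):
        for _ in range(MAX_TRIES):
            p = parents[rng.integers(len(parents))]
            cand = p + rng.normal(0.0, spec.attraction_scale, 2)
            if window.contains(cand[None, :])[0]:
                pts[i] = cand
                break
        else:
            raise ValueError(f"phenotype {spec.name!r}: could not place an "
                             "attracted point inside the window")
    return pts


def _sample_segregated_cluster(spec: PhenotypeSimSpec, malignant: np.ndarray,
                               config: CoreSimConfig, window: Window,
                               rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial import cKDTree

    n_parents = _poisson_count(spec.cluster_parent_intensity, window.area_um2, rng)
    if n_parents == 0:
        return np.empty((0, 2))
    tree = cKDTree(malignant) if len(malignant) else None
    parents = np.empty((n_parents, 2))
    for i in range(n_parents):
        for _ in range(MAX_TRIES):
            cand = _uniform_in_window(1, config, rng)[0]
            if tree is None or tree.query(cand)[0] >= spec.exclusion_radius:
                parents[i] = cand
                break
        else:
            raise ValueError(
                f"phenotype {spec.name!r}: window too small to place cluster "
                f"parents at exclusion_radius={spec.exclusion_radius} um from "
                "the malignant cells")
    offspring = []
    for p in parents:
        k = int(rng.poisson(spec.cluster_offspring_mean))
        for _ in range(k):
            for _ in range(MAX_TRIES):
                cand = p + rng.normal(0.0, spec.cluster_scale, 2)
                if window.contains(cand[None, :])[0]:
                    offspring.append(cand)
                    break
            else:
                raise ValueError(f"phenotype {spec.name!r}: could not place a "
                                 "cluster offspring inside the window")
    return np.asarray(offspring).reshape(-1, 2)


def simulate_core(config: CoreSimConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one core; returns a table with columns ``x_um``, ``y_um``,
    ``phenotype`` and ``true_regime``.

    Malignant cells (phenotype ``CK+``) are homogeneous Poisson; each immune
    phenotype follows its spec's regime.  Fixed seed implies bit-identical
    output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    window = config.window()
    malignant = _uniform_in_window(
        _poisson_count(config.malignant_intensity, window.area_um2, rng),
        config, rng)
    frames = [pd.DataFrame({"x_um": malignant[:, 0], "y_um": malignant[:, 1],
                            "phenotype": "CK+", "true_regime": "malignant"})]
    for spec in config.phenotype_specs:
        if spec.regime == "csr":
            pts = _uniform_in_window(
                _poisson_count(spec.intensity, window.area_um2, rng), config, rng)
        elif spec.regime == "attraction":
            pts = _sample_attraction(spec, malignant, config, window, rng)
        else:
            pts = _sample_segregated_cluster(spec, malignant, config, window, rng)
        frames.append(pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1],
                                    "phenotype": spec.name,
                                    "true_regime": spec.regime}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohort simulation with ground-truth immunologic groups
# ---------------------------------------------------------------------------

#: Anchor phenotype whose spatial arrangement defines a subject's group.
ANCHOR = "CD3+"
#: Malignant-cell intensity of the cohort presets (cells/mm2); low enough
#: that segregated cluster parents can respect their exclusion radius.
PRESET_MALIGNANT_INTENSITY = 40.0

#: Regime presets realising the four immunologic distribution groups for the
#: anchor phenotype: group 1 = attraction/near (mixed, close), group 2 =
#: attraction/far (mixed, long), group 3 = cluster/near (unmixed, close),
#: group 4 = cluster/far (unmixed, long).
GROUP_PRESETS: dict[int, PhenotypeSimSpec] = {
    1: PhenotypeSimSpec(name=ANCHOR, regime="attraction",
                        intensity=100.0, attraction_scale=12.0),
    2: PhenotypeSimSpec(name=ANCHOR, regime="attraction",
                        intensity=12.0, attraction_scale=150.0),
    3: PhenotypeSimSpec(name=ANCHOR, regime="segregated_cluster",
                        cluster_parent_intensity=120.0, cluster_offspring_mean=2.0,
                        cluster_scale=10.0, exclusion_radius=20.0),
    4: PhenotypeSimSpec(name=ANCHOR, regime="segregated_cluster",
                        cluster_parent_intensity=15.0, cluster_offspring_mean=8.0,
                        cluster_scale=20.0, exclusion_radius=80.0),
}

#: Strong segregation preset used for sensitivity analyses: cluster parents
#: excluded 150 um from a sparser malignant field.
STRONG_SEGREGATION = PhenotypeSimSpec(
    name=ANCHOR, regime="segregated_cluster", cluster_parent_intensity=20.0,
    cluster_offspring_mean=5.0, cluster_scale=20.0, exclusion_radius=150.0)
STRONG_SEGREGATION_MALIGNANT_INTENSITY = 30.0


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort generator: subjects, groups, clinical covariates, survival."""

    n_subjects: int
    cores_per_subject: int = 3
    group_probabilities: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    baseline_hazard: float = 0.02  # events per month
    log_hazard_by_group: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    censoring_rate: float = 0.01  # per month
    covariate_frequencies: dict = field(default_factory=lambda: {
        "smoker": 0.6, "kras_mut": 0.30, "egfr_mut": 0.15, "adc": 0.63})
    malignant_intensity: float = PRESET_MALIGNANT_INTENSITY
    seed: int | None = None

    def __post_init__(self):
        p = np.asarray(self.group_probabilities, float)
        if len(p) != 4 or (p < 0).any() or (p > 1).any() or abs(p.sum() - 1) > 1e-12:
            raise ValueError("group_probabilities must be a 4-vector of "
                             "probabilities summing to 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        if len(self.log_hazard_by_group) != 4:
            raise ValueError("log_hazard_by_group must have 4 entries")


def _markers_for(phenotype: str) -> dict[str, bool]:
    # panel-1 marker flags for the phenotypes the cohort generator emits
    return {"CK": phenotype == "CK+", "CD3": phenotype == ANCHOR,
            "CD8": False, "PD-1": False, "PD-L1": False, "CD68": False}


def simulate_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of subjects with ground-truth groups and outcomes.

    Returns ``(cells, clinical)``.  ``cells`` is a panel-1 cell table
    (subject_id, core_id, panel, x/y um, marker flags) whose anchor-phenotype
    arrangement realises each subject's group; ``clinical`` carries the
    ground-truth ``true_group``, binary covariates, tumor size/stage and
    exponential OS/RFS outcomes with hazard
    ``baseline_hazard * exp(log_hazard_by_group[group])``.
    """
    rng = np.random.default_rng(config.seed)
    groups = rng.choice([1, 2, 3, 4], size=config.n_subjects,
                        p=config.group_probabilities)
    cell_frames, clin_rows = [], []
    for s in range(config.n_subjects):
        sid = f"S{s:04d}"
        g = int(groups[s])
        for c in range(config.cores_per_subject):
            core_cfg = CoreSimConfig(
                malignant_intensity=config.malignant_intensity,
                phenotype_specs=(GROUP_PRESETS[g],))
            core = simulate_core(core_cfg, rng=rng)
            markers = pd.DataFrame([_markers_for(p) for p in core["phenotype"]])
            frame = pd.concat(
                [pd.DataFrame({"subject_id": sid, "core_id": f"{sid}-c{c}",
                               "panel": 1, "x_um": core["x_um"],
                               "y_um": core["y_um"]}),
                 markers], axis=1)
            cell_frames.append(frame)

        hazard = config.baseline_hazard * math.exp(config.log_hazard_by_group[g - 1])
        t_os = rng.exponential(1.0 / hazard)
        t_rfs = rng.exponential(1.0 / (hazard * 1.3))
        if config.censoring_rate > 0:
            cens = rng.exponential(1.0 / config.censoring_rate)
        else:
            cens = math.inf
        cov = {k: int(rng.random() < p)
               for k, p in config.covariate_frequencies.items()}
        if "adc" in cov:
            adc = cov.pop("adc")
        else:
            adc = int(rng.random() < 0.63)
        histology = "ADC" if adc else "SCC"
        clin_rows.append({
            "subject_id": sid, "true_group": g, "histology": histology,
            "smoker": cov.get("smoker", 0),
            "tumor_size_cm": round(float(rng.lognormal(math.log(3.3), 0.45)), 2),
            "stage": rng.choice(["I", "II", "III"], p=[0.5, 0.3, 0.2]),
            "kras": "mut" if cov.get("kras_mut") else "wt",
            "egfr": "mut" if cov.get("egfr_mut") else "wt",
            "os_months": round(min(t_os, cens), 3),
            "os_event": int(t_os <= cens),
            "rfs_months": round(min(t_rfs, cens), 3),
            "rfs_event": int(t_rfs <= cens),
        })
    cells = pd.concat(cell_frames, ignore_index=True)
    clinical = pd.DataFrame(clin_rows)
    return cells, clinical
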