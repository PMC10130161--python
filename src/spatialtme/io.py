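"""Cell-table ingestion, phenotype rules, point patterns and densities.

The package operates on per-cell tables exported from multiplexed
immunofluorescence image analysis: one row per segmented cell carrying a
subject identifier, a tissue-core identifier, the staining panel, x/y
coordinates in micrometres and one boolean column per marker.  Phenotypes
(e.g. ``CD3+CD8+`` cytotoxic T-cells) are assigned by marker co-expression
rules; cell positions of one phenotype within an observation window form a
:class:`PointPattern`, from which densities in cells/mm2 are derived.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import MultiPoint, Point, Polygon

logger = logging.getLogger("spatialtme")

UM2_PER_MM2 = 1e6

#: Marker sets of the five staining panels.
PANEL_MARKERS: dict[int, frozenset[str]] = {
    1: frozenset({"CK", "CD3", "CD8", "PD-1", "PD-L1", "CD68"}),
    2: frozenset({"CK", "CD3", "CD8", "CD45RO", "GZB", "FOXP3"}),
    3: frozenset({"CK", "CD3", "PD-L1", "B7-H3", "B7-H4", "IDO-1", "VISTA"}),
    4: frozenset({"CK", "CD3", "ICOS", "LAG3", "OX40", "TIM3", "CD20"}),
    5: frozenset({"CK", "Arg-1", "CD11b", "CD14", "CD33", "CD66b", "CD68"}),
}

#: Mandatory non-marker columns of a cell table.
CELL_TABLE_COLUMNS = ("subject_id", "core_id", "panel", "x_um", "y_um")

#: Values accepted as "positive" in marker columns.
TRUTHY = {"1", "true", "TRUE", "True", "+", "pos", "yes", 1, True, 1.0}
FALSY = {"0", "false", "FALSE", "False", "-", "neg", "no", 0, False, 0.0, "−"}

#: Label of the malignant (tumor) reference phenotype.
MALIGNANT = "CK+"


# ---------------------------------------------------------------------------
# Observation windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """Observation window: a circle or a simple polygon, coordinates in um."""

    kind: str  # "circle" | "polygon"
    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: np.ndarray | None = None  # (k, 2) for polygons
    _polygon: Polygon | None = field(default=None, repr=False, compare=False)

    @staticmethod
    def circle(center: tuple[float, float], radius: float) -> "Window":
        if radius <= 0:
            raise ValueError("window radius must be positive")
        return Window(kind="circle", center=(float(center[0]), float(center[1])),
                      radius=float(radius))

    @staticmethod
    def polygon(vertices: np.ndarray) -> "Window":
        verts = np.asarray(vertices, dtype=float)
        poly = Polygon(verts)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("polygon window is degenerate")
        win = Window(kind="polygon", vertices=verts)
        object.__setattr__(win, "_polygon", poly)
        return win

    @staticmethod
    def convex_hull(points: np.ndarray) -> "Window":
        pts = np.asarray(points, dtype=float)
        if len(pts) < 3:
            raise ValueError("convex-hull window needs at least 3 cells in the core")
        hull = MultiPoint([tuple(p) for p in pts]).convex_hull
        if hull.geom_type != "Polygon" or hull.area <= 0:
            raise ValueError("convex-hull window is degenerate (collinear cells)")
        win = Window(kind="polygon", vertices=np.asarray(hull.exterior.coords[:-1]))
        object.__setattr__(win, "_polygon", hull)
        return win

    @property
    def shapely(self) -> Polygon:
        if self.kind == "circle":
            return Point(self.center).buffer(self.radius, quad_segs=256)
        if self._polygon is not None:
            return self._polygon
        return Polygon(self.vertices)

    @property
    def area_um2(self) -> float:
        if self.kind == "circle":
            return math.pi * self.radius ** 2
        return self.shapely.area

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / UM2_PER_MM2

    def contains(self, points: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
        """Closed-window membership test (boundary counts as inside)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "circle":
            d2 = (pts[:, 0] - self.center[0]) ** 2 + (pts[:, 1] - self.center[1]) ** 2
            return d2 <= (self.radius + tol) ** 2
        poly = self.shapely
        return np.array([poly.distance(Point(*p)) <= tol or poly.covers(Point(*p))
                         for p in pts])

    def boundary_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from each (interior) point to the window boundary, in um."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "circle":
            d = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
            return np.maximum(self.radius - d, 0.0)
        boundary = self.shapely.exterior
        return np.array([boundary.distance(Point(*p)) for p in pts])


# ---------------------------------------------------------------------------
# Point patterns and densities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointPattern:
    """Locations of one phenotype inside an observation window."""

    points: np.ndarray  # (n, 2) in um
    window: Window
    phenotype: str
    core_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if self.window.area_um2 <= 0:
            raise ValueError("window area must be positive")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def intensity_per_mm2(self) -> float:
        return self.n / self.window.area_mm2


@dataclass(frozen=True)
class DensityRecord:
    phenotype: str
    core_id: str
    density: float  # cells/mm2


def build_point_pattern(core_cells: pd.DataFrame,
                        phenotype: str,
                        window_spec="convex_hull",
                        phenotype_matrix: pd.DataFrame | None = None) -> PointPattern:
    """Construct the point pattern of one phenotype within a core.

    ``window_spec`` is ``"convex_hull"`` (hull of *all* cells in the core, so
    reference and target phenotypes share one window), ``("circle", diameter_um)``
    for a circle fitted to the core centroid, or an explicit :class:`Window`.
    """
    xy_all = core_cells[["x_um", "y_um"]].to_numpy(dtype=float)
    if phenotype_matrix is not None:
        mask = phenotype_matrix[phenotype].to_numpy(dtype=bool)
    elif phenotype in core_cells.columns:
        mask = core_cells[phenotype].to_numpy(dtype=bool)
    else:
        mask = core_cells["phenotype"].to_numpy() == phenotype
    pts = xy_all[mask]

    if isinstance(window_spec, Window):
        window = window_spec
    elif window_spec == "convex_hull":
        window = Window.convex_hull(xy_all)
    elif isinstance(window_spec, (tuple, list)) and window_spec[0] == "circle":
        diameter = float(window_spec[1])
        center = tuple(xy_all.mean(axis=0)) if len(xy_all) else (0.0, 0.0)
        window = Window.circle(center, diameter / 2.0)
    else:
        raise ValueError(f"unknown window_spec: {window_spec!r}")

    core_id = str(core_cells["core_id"].iloc[0]) if len(core_cells) else ""
    return PointPattern(points=pts, window=window, phenotype=phenotype, core_id=core_id)


def compute_density(pattern: PointPattern) -> DensityRecord:
    """Cells per square millimetre within the pattern's window."""
    area = pattern.window.area_mm2
    if area <= 0:
        raise ValueError("window area is zero")
    return DensityRecord(phenotype=pattern.phenotype, core_id=pattern.core_id,
                         density=pattern.n / area)


def filter_phenotypes_by_median_density(densities: pd.DataFrame,
                                        threshold: float = 2.0) -> list[str]:
    """Phenotypes whose median density across samples is >= ``threshold``.

    Low-abundance phenotypes (cohort median below 2 cells/mm2 by default) are
    excluded from spatial scoring to avoid unstable estimates.
    """
    if densities.empty:
        raise ValueError("empty cohort: no densities to filter")
    med = densities.groupby("phenotype")["density"].median()
    return sorted(med.index[med >= threshold].tolist())


# ---------------------------------------------------------------------------
# Phenotype rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeRule:
    """Marker co-expression rule defining one cell phenotype."""

    name: str
    panel: int
    positive: frozenset[str]
    negative: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.positive & self.negative:
            raise ValueError(f"rule {self.name}: a marker cannot be required "
                             "both positive and negative")
        panel_set = PANEL_MARKERS.get(self.panel)
        if panel_set is not None:
            unknown = (self.positive | self.negative) - panel_set
            if unknown:
                raise ValueError(
                    f"rule {self.name}: markers {sorted(unknown)} are not in "
                    f"panel {self.panel}")

    def matches(self, markers: Mapping[str, bool]) -> bool:
        return (all(markers.get(m, False) for m in self.positive)
                and not any(markers.get(m, False) for m in self.negative))


def load_rules(source) -> list[PhenotypeRule]:
    """Load phenotype rules from a YAML/JSON file path or a list of dicts."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if isinstance(raw, dict):
        raw = raw.get("rules", raw)
    rules = []
    seen: set[tuple[int, str]] = set()
    for entry in raw:
        rule = PhenotypeRule(name=entry["name"], panel=int(entry["panel"]),
                             positive=frozenset(entry.get("positive", [])),
                             negative=frozenset(entry.get("negative", [])))
        key = (rule.panel, rule.name)
        if key in seen:
            raise ValueError(f"duplicate rule name {rule.name!r} in panel {rule.panel}")
        seen.add(key)
        rules.append(rule)
    return rules


def default_rules() -> list[PhenotypeRule]:
    """The phenotype rules shipped with the package (all five panels)."""
    return load_rules(Path(__file__).parent / "data" / "default_rules.yaml")


def assign_phenotypes(cells: pd.DataFrame,
                      rules: Sequence[PhenotypeRule]) -> pd.DataFrame:
    """Boolean cell x phenotype matrix of rule matches.

    A cell matches a rule iff every required-positive marker is positive and
    every required-negative marker is negative; rules are nested, so a cell may
    match several (``CD3+`` and ``CD3+CD8+``).  Rules only apply to cells of
    their own panel.
    """
    out = pd.DataFrame(False, index=cells.index,
                       columns=list(dict.fromkeys(r.name for r in rules)))
    panel = cells["panel"].to_numpy()
    for rule in rules:
        in_panel = panel == rule.panel
        if not in_panel.any():
            continue
        match = in_panel.copy()
        for m in rule.positive:
            if m not in cells.columns:
                match &= False
                break
            match &= cells[m].to_numpy(dtype=bool)
        else:
            for m in rule.negative:
                if m in cells.columns:
                    match &= ~cells[m].to_numpy(dtype=bool)
        out.loc[match, rule.name] = True
    return out


# ---------------------------------------------------------------------------
# Cell-table reading and writing
# ---------------------------------------------------------------------------

def _coerce_bool(col: pd.Series, colname: str) -> pd.Series:
    if col.dtype == bool:
        return col
    def conv(v):
        if isinstance(v, str):
            v = v.strip()
        if v in TRUTHY:
            return True
        if v in FALSY or (isinstance(v, float) and np.isnan(v)):
            return False
        raise ValueError(f"column {colname!r}: cannot interpret {v!r} as a "
                         "marker positivity flag")
    return col.map(conv)


def read_cell_table(path, schema: Mapping | None = None) -> pd.DataFrame:
    """Read a delimited per-cell table into the package's cell-table schema.

    ``schema`` may provide ``column_map`` (file column -> canonical name),
    ``markers`` (explicit list of marker columns), ``sep`` and
    ``coordinate_scale`` (multiplier to convert pixel coordinates to um).
    Rows with non-finite coordinates are dropped with a logged warning.
    Unknown marker columns (not in any panel) are ignored with a warning.
    """
    schema = dict(schema or {})
    sep = schema.get("sep")
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if colmap := schema.get("column_map"):
        df = df.rename(columns=colmap)

    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing mandatory column(s): "
                         f"{', '.join(missing)}")

    scale = float(schema.get("coordinate_scale", 1.0))
    df["x_um"] = pd.to_numeric(df["x_um"], errors="coerce") * scale
    df["y_um"] = pd.to_numeric(df["y_um"], errors="coerce") * scale
    df["panel"] = df["panel"].astype(int)

    bad = ~(np.isfinite(df["x_um"]) & np.isfinite(df["y_um"]))
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        logger.warning("%s: dropped %d row(s) with non-finite coordinates "
                       "(file lines %s)", path, int(bad.sum()), lines)
        df = df.loc[~bad].reset_index(drop=True)

    all_known = frozenset().union(*PANEL_MARKERS.values())
    marker_cols = schema.get("markers")
    if marker_cols is None:
        marker_cols = [c for c in df.columns
                       if c not in CELL_TABLE_COLUMNS and c in all_known]
        unknown = [c for c in df.columns
                   if c not in CELL_TABLE_COLUMNS and c not in all_known
                   and c not in ("phenotype", "true_regime", "group")]
        for c in unknown:
            warnings.warn(f"ignoring unknown marker column {c!r}", stacklevel=2)
    for c in marker_cols:
        df[c] = _coerce_bool(df[c], c)

    df["subject_id"] = df["subject_id"].astype(str)
    df["core_id"] = df["core_id"].astype(str)
    return df


def write_cell_table(cells: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a cell table as delimited text with marker flags encoded 0/1."""
    out = cells.copy()
    for c in out.columns:
        if out[c].dtype == bool:
            out[c] = out[c].astype(int)
    out.to_csv(path, sep=sep, index=False)


def read_clinical_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read the per-subject clinical/outcome table."""
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "subject_id" not in df.columns:
        raise ValueError(f"clinical table {path} is missing 'subject_id'")
    df["subject_id"] = df["subject_id"].astype(str)
    return df
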