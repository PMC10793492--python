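"""Cell-cluster subgraphs and the 350-dimensional per-tile feature vector.

Cells of one family (TIL or non-TIL) are linked whenever their Euclidean
distance is at most a threshold ``d_threshold_um`` (inclusive); the
connected components of that proximity graph are the cell clusters.
Cluster geometry (convex hulls, extents, spacing), per-cell neighborhood
structure and cross-family interplay (cluster distances, hull overlap,
kNN mixing) are summarized within the tile into the registry's 350
features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .errors import InvalidConfigError, ValidationError
from .registry import (
    FAMILIES,
    MIXING_KS,
    N_TILE_FEATURES,
    NEIGHBOR_RADII_UM,
    FeatureRegistry,
    default_registry,
)

VALID_FAMILIES = ("TIL", "nonTIL")
VALID_COMPARTMENTS = ("epithelium", "stroma")

#: finite stand-in for ratios with an empty denominator but non-empty numerator
DEFAULT_RATIO_CAP = 100.0


@dataclass
class CellMap:
    """Typed cell centroids of one tile.

    ``cells`` has columns ``x_um``, ``y_um``, ``family`` with family in
    {"TIL", "nonTIL"}; the tile's compartment (epithelium or stroma)
    together with the family encodes the four cell families of the study.
    """

    tile_id: str
    compartment: str
    tile_size_um: float
    cells: pd.DataFrame

    def __post_init__(self):
        if self.compartment not in VALID_COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if not self.tile_size_um > 0:
            raise ValidationError("tile_size_um must be positive")
        required = {"x_um", "y_um", "family"}
        if not required.issubset(self.cells.columns):
            raise ValidationError(f"cells must have columns {sorted(required)}")
        if len(self.cells):
            bad = ~self.cells["family"].isin(VALID_FAMILIES)
            if bad.any():
                raise ValidationError(
                    f"unknown cell families: {sorted(self.cells['family'][bad].unique())}"
                )
            xy = self.cells[["x_um", "y_um"]].to_numpy(float)
            if (xy < 0).any() or (xy >= self.tile_size_um).any():
                raise ValidationError("cell coordinates must lie in [0, tile_size_um)")
        self.cells = self.cells.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, tile_id, compartment, tile_size_um, xy_til, xy_nontil):
        frames = []
        for xy, fam in ((np.asarray(xy_til, float).reshape(-1, 2), "TIL"),
                        (np.asarray(xy_nontil, float).reshape(-1, 2), "nonTIL")):
            frames.append(pd.DataFrame(
                {"x_um": xy[:, 0], "y_um": xy[:, 1], "family": fam}))
        cells = pd.concat(frames, ignore_index=True)
        return cls(tile_id, compartment, tile_size_um, cells)

    def coords(self, family: str | None = None) -> np.ndarray:
        if family is None:
            return self.cells[["x_um", "y_um"]].to_numpy(float)
        if family not in VALID_FAMILIES:
            raise ValidationError(f"unknown family {family!r}")
        sel = self.cells["family"] == family
        return self.cells.loc[sel, ["x_um", "y_um"]].to_numpy(float)

    def family_indices(self, family: str) -> np.ndarray:
        if family not in VALID_FAMILIES:
            raise ValidationError(f"unknown family {family!r}")
        return np.flatnonzero((self.cells["family"] == family).to_numpy())


@dataclass
class ClusterSet:
    """Connected components of one family's proximity graph.

    ``clusters`` holds arrays of indices into the parent CellMap's cell
    table; singletons are clusters of size one.
    """

    family: str
    d_threshold_um: float
    clusters: list[np.ndarray] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.clusters], dtype=int)


def build_cluster_subgraphs(cellmap: CellMap, family: str,
                            d_threshold_um: float) -> ClusterSet:
    """Cluster one family's cells at Euclidean distance <= threshold."""
    if not d_threshold_um > 0:
        raise InvalidConfigError("d_threshold_um must be positive")
    idx = cellmap.family_indices(family)
    if idx.size == 0:
        return ClusterSet(family, d_threshold_um, [])
    coords = cellmap.coords(family)
    n = len(coords)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(d_threshold_um, output_type="ndarray")
    if len(pairs):
        data = np.ones(len(pairs), dtype=bool)
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, labels = connected_components(graph, directed=False)
    else:
        labels = np.arange(n)
    clusters = []
    for lab in np.unique(labels):
        members = idx[labels == lab]
        clusters.append(np.sort(members))
    clusters.sort(key=lambda c: int(c[0]))
    return ClusterSet(family, d_threshold_um, clusters)


def _hull(points: np.ndarray):
    """Convex hull geometry of a point set (Point / LineString / Polygon)."""
    return MultiPoint([tuple(p) for p in points]).convex_hull


def _max_pairwise_dist(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    d = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((d ** 2).sum(-1)).max())


def _mean_nn_dist(points: np.ndarray) -> float:
    if len(points) < 2:
        return math.nan
    tree = cKDTree(points)
    dist, _ = tree.query(points, k=2)
    return float(dist[:, 1].mean())


@dataclass
class ClusterMetrics:
    """Per-cluster table plus tile-level scalars for one family."""

    per_cluster: pd.DataFrame
    hulls: list
    centroids: np.ndarray  # (n_clusters, 2)
    tile: dict


def cluster_metrics(clusters: ClusterSet, cellmap: CellMap) -> ClusterMetrics:
    """Geometry of every cluster plus family-level tile summaries.

    Hull area is 0 for clusters with fewer than 3 non-collinear members;
    hull density is NaN when the hull area is 0.
    """
    tile_area_um2 = cellmap.tile_size_um ** 2
    rows, hulls, cents = [], [], []
    for members in clusters.clusters:
        pts = cellmap.cells.loc[members, ["x_um", "y_um"]].to_numpy(float)
        hull = _hull(pts)
        area = float(hull.area)
        perim = float(hull.length)
        size = len(pts)
        centroid = pts.mean(axis=0)
        extent = _max_pairwise_dist(pts)
        rms = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
        if size >= 2:
            cov = np.cov(pts.T, ddof=0)
            ev = np.sort(np.linalg.eigvalsh(cov))
            # tiny negative eigenvalues from float error clamp to zero
            aspect = math.nan if ev[1] <= 0 else float(np.sqrt(max(ev[0], 0.0) / ev[1]))
        else:
            aspect = math.nan
        rows.append({
            "size": size,
            "hull_area": area,
            "hull_perimeter": perim,
            "hull_density": (size / area) if area > 0 else math.nan,
            "extent": extent,
            "rms_spread": rms,
            "circularity": (4 * math.pi * area / perim ** 2)
                           if (area > 0 and perim > 0) else math.nan,
            "aspect_ratio": aspect,
            "intra_nn_dist": _mean_nn_dist(pts),
        })
        hulls.append(hull)
        cents.append(centroid)
    per_cluster = pd.DataFrame(
        rows, columns=["size", "hull_area", "hull_perimeter", "hull_density",
                       "extent", "rms_spread", "circularity", "aspect_ratio",
                       "intra_nn_dist"])
    centroids = np.array(cents, float).reshape(-1, 2)

    # inter-cluster centroid spacing
    if len(centroids) >= 2:
        tree = cKDTree(centroids)
        dist, _ = tree.query(centroids, k=2)
        per_cluster["centroid_nn_dist"] = dist[:, 1]
    else:
        per_cluster["centroid_nn_dist"] = math.nan

    sizes = per_cluster["size"].to_numpy(float) if len(per_cluster) else np.array([])
    n_cells = int(sizes.sum())
    clustered = float(sizes[sizes >= 2].sum())
    tile = {
        "cell_count": float(n_cells),
        "density": n_cells / tile_area_um2 * 1e6,  # cells per mm^2
        "cluster_count": float(len(per_cluster)),
        "clustered_fraction": clustered / n_cells if n_cells else math.nan,
        "largest_cluster_fraction": (sizes.max() / n_cells) if n_cells else math.nan,
        "hull_area_fraction": float(per_cluster["hull_area"].sum()) / tile_area_um2
                              if len(per_cluster) else math.nan,
    }
    return ClusterMetrics(per_cluster, hulls, centroids, tile)


def _nearest_cross(centroids_a: np.ndarray, centroids_b: np.ndarray):
    """For each centroid in a, distance to and index of nearest b centroid."""
    if len(centroids_a) == 0 or len(centroids_b) == 0:
        return np.array([]), np.array([], dtype=int)
    tree = cKDTree(centroids_b)
    dist, j = tree.query(centroids_a, k=1)
    return np.atleast_1d(dist), np.atleast_1d(j).astype(int)


def hull_iou(hull_a, hull_b) -> float:
    """Intersection-over-union of two hull geometries.

    Degenerate (zero-area) unions score 1.0 when the geometries coincide
    and 0.0 otherwise.
    """
    union = hull_a.union(hull_b)
    if union.area == 0:
        return 1.0 if hull_a.equals(hull_b) else 0.0
    return float(hull_a.intersection(hull_b).area / union.area)


def _ratio(num: float, den: float, cap: float) -> float:
    if den > 0:
        return num / den
    return cap if num > 0 else math.nan


def mixing_indices(cellmap: CellMap, ks=MIXING_KS) -> dict[int, np.ndarray]:
    """Per-cell fraction of k nearest neighbors from the other family.

    Neighbors are searched among all other cells of the tile regardless of
    family; cells with no other cell in the tile are excluded.
    """
    xy = cellmap.coords()
    fam = (cellmap.cells["family"] == "TIL").to_numpy()
    n = len(xy)
    out = {k: np.full(n, math.nan) for k in ks}
    if n < 2:
        return out
    tree = cKDTree(xy)
    kmax = min(max(ks), n - 1)
    dist, nbr = tree.query(xy, k=kmax + 1)
    nbr = np.atleast_2d(nbr)[:, 1:]  # drop self
    for k in ks:
        keff = min(k, n - 1)
        cols = nbr[:, :keff]
        other = fam[cols] != fam[:, None]
        out[k] = other.mean(axis=1)
    return out


def interplay_metrics(til_clusters: ClusterSet, nontil_clusters: ClusterSet,
                      cellmap: CellMap, ratio_cap: float = DEFAULT_RATIO_CAP,
                      ks=MIXING_KS) -> dict:
    """Cross-family interplay: cluster spacing, hull overlap, mixing, ratios."""
    cm_til = cluster_metrics(til_clusters, cellmap)
    cm_non = cluster_metrics(nontil_clusters, cellmap)
    return _interplay_from_metrics(cm_til, cm_non, cellmap, ratio_cap, ks)


def _interplay_from_metrics(cm_til: ClusterMetrics, cm_non: ClusterMetrics,
                            cellmap: CellMap, ratio_cap: float,
                            ks=MIXING_KS) -> dict:
    out: dict = {}
    d_tn, j_tn = _nearest_cross(cm_til.centroids, cm_non.centroids)
    d_nt, j_nt = _nearest_cross(cm_non.centroids, cm_til.centroids)
    out["til_nontil_cluster_dist"] = d_tn
    out["nontil_til_cluster_dist"] = d_nt
    out["til_nontil_hull_iou"] = np.array(
        [hull_iou(cm_til.hulls[i], cm_non.hulls[j]) for i, j in enumerate(j_tn)])
    out["nontil_til_hull_iou"] = np.array(
        [hull_iou(cm_non.hulls[i], cm_til.hulls[j]) for i, j in enumerate(j_nt)])

    mix = mixing_indices(cellmap, ks)
    is_til = (cellmap.cells["family"] == "TIL").to_numpy()
    for k in ks:
        out[f"mixing_k{k}_til"] = mix[k][is_til]
        out[f"mixing_k{k}_nontil"] = mix[k][~is_til]
        out[f"mixing_k{k}_all"] = mix[k]

    t, nn = cm_til.tile, cm_non.tile
    total = t["cell_count"] + nn["cell_count"]
    out["til_fraction"] = t["cell_count"] / total if total else math.nan
    out["til_nontil_count_ratio"] = _ratio(t["cell_count"], nn["cell_count"], ratio_cap)
    out["til_nontil_cluster_count_ratio"] = _ratio(
        t["cluster_count"], nn["cluster_count"], ratio_cap)
    mean_size_t = t["cell_count"] / t["cluster_count"] if t["cluster_count"] else 0.0
    mean_size_n = nn["cell_count"] / nn["cluster_count"] if nn["cluster_count"] else 0.0
    out["til_nontil_mean_cluster_size_ratio"] = _ratio(mean_size_t, mean_size_n, ratio_cap)
    area_t = float(cm_til.per_cluster["hull_area"].sum()) if len(cm_til.per_cluster) else 0.0
    area_n = float(cm_non.per_cluster["hull_area"].sum()) if len(cm_non.per_cluster) else 0.0
    out["til_nontil_hull_area_ratio"] = _ratio(area_t, area_n, ratio_cap)
    cf_t = t["clustered_fraction"]
    cf_n = nn["clustered_fraction"]
    if math.isnan(cf_t) or math.isnan(cf_n):
        out["til_nontil_clustered_fraction_ratio"] = math.nan
    else:
        out["til_nontil_clustered_fraction_ratio"] = _ratio(cf_t, cf_n, ratio_cap)

    out["total_cell_count"] = total
    out["total_density"] = t["density"] + nn["density"]
    out["total_cluster_count"] = t["cluster_count"] + nn["cluster_count"]
    sizes = np.concatenate([
        cm_til.per_cluster["size"].to_numpy(float),
        cm_non.per_cluster["size"].to_numpy(float)]) if total else np.array([])
    out["total_clustered_fraction"] = (
        float(sizes[sizes >= 2].sum()) / total if total else math.nan)

    # cross_edge_fraction needs the distance threshold; callers that have it
    # (extract_tile_features) overwrite this sentinel via cross_edge_fraction()
    out["cross_edge_fraction"] = math.nan

    # infiltration into opposing hulls
    out["til_in_nontil_hull_fraction"] = _in_hull_fraction(
        cellmap.coords("TIL"), cm_non.hulls)
    out["nontil_in_til_hull_fraction"] = _in_hull_fraction(
        cellmap.coords("nonTIL"), cm_til.hulls)
    return out


def _in_hull_fraction(points: np.ndarray, hulls: list) -> float:
    """Fraction of points covered by the union of polygonal hulls."""
    if len(points) == 0:
        return math.nan
    polys = [h for h in hulls if h.area > 0]
    if not polys:
        return 0.0
    from shapely.geometry import Point
    from shapely.ops import unary_union
    union = unary_union(polys)
    inside = sum(union.covers(Point(x, y)) for x, y in points)
    return inside / len(points)


def cross_edge_fraction(cellmap: CellMap, d_threshold_um: float) -> float:
    """Fraction of within-threshold cell pairs that are cross-family."""
    xy = cellmap.coords()
    if len(xy) < 2:
        return math.nan
    tree = cKDTree(xy)
    pairs = tree.query_pairs(d_threshold_um, output_type="ndarray")
    if len(pairs) == 0:
        return math.nan
    fam = (cellmap.cells["family"] == "TIL").to_numpy()
    cross = fam[pairs[:, 0]] != fam[pairs[:, 1]]
    return float(cross.mean())


_STAT_FUNCS = {
    "mean": np.mean,
    "median": np.median,
    "min": np.min,
    "max": np.max,
    "std": lambda a: float(np.std(a)),  # population (ddof=0)
}


def _summarize(values, stat: str, kind: str) -> float:
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        return 0.0 if kind == "count" else math.nan
    return float(_STAT_FUNCS[stat](arr))


@dataclass
class TileFeatureVector:
    """The 350 registry-ordered feature values of one tile."""

    tile_id: str
    compartment: str
    values: np.ndarray

    def to_series(self, registry: FeatureRegistry | None = None) -> pd.Series:
        registry = registry or default_registry()
        return pd.Series(self.values, index=registry.names, name=self.tile_id)


def compute_base_measurements(cellmap: CellMap, d_threshold_um: float,
                              ratio_cap: float = DEFAULT_RATIO_CAP) -> dict:
    """All 70 base measurements of one tile, keyed by registry base name."""
    base: dict = {}
    cms = {}
    csets = {}
    for fam_key, fam in (("til", "TIL"), ("nontil", "nonTIL")):
        cs = build_cluster_subgraphs(cellmap, fam, d_threshold_um)
        cm = cluster_metrics(cs, cellmap)
        csets[fam_key], cms[fam_key] = cs, cm
        pc = cm.per_cluster
        base[f"{fam_key}_cluster_size"] = pc["size"].to_numpy(float)
        for col in ("hull_area", "hull_perimeter", "hull_density", "extent",
                    "rms_spread", "circularity", "aspect_ratio",
                    "intra_nn_dist", "centroid_nn_dist"):
            base[f"{fam_key}_cluster_{col}"] = pc[col].to_numpy(float)
        for scalar in ("cell_count", "density", "cluster_count",
                       "clustered_fraction", "largest_cluster_fraction",
                       "hull_area_fraction"):
            base[f"{fam_key}_{scalar}"] = np.array([cm.tile[scalar]])

        own = cellmap.coords(fam)
        other = cellmap.coords("nonTIL" if fam == "TIL" else "TIL")
        if len(own) >= 2:
            tree = cKDTree(own)
            d, _ = tree.query(own, k=2)
            base[f"{fam_key}_cell_nn_same"] = d[:, 1]
        else:
            base[f"{fam_key}_cell_nn_same"] = np.array([])
        if len(own) and len(other):
            tree = cKDTree(other)
            d, _ = tree.query(own, k=1)
            base[f"{fam_key}_cell_nn_cross"] = np.atleast_1d(d)
        else:
            base[f"{fam_key}_cell_nn_cross"] = np.array([])
        for r in NEIGHBOR_RADII_UM:
            if len(own):
                tree = cKDTree(own)
                counts = np.array(
                    [len(c) - 1 for c in tree.query_ball_point(own, r)], float)
            else:
                counts = np.array([])
            base[f"{fam_key}_neighbors_r{int(r)}"] = counts
            if len(own) and len(other):
                tree = cKDTree(other)
                cross = np.array(
                    [len(c) for c in tree.query_ball_point(own, r)], float)
            else:
                cross = np.array([]) if len(own) == 0 else np.zeros(len(own))
            base[f"{fam_key}_cross_neighbors_r{int(r)}"] = cross

    inter = _interplay_from_metrics(cms["til"], cms["nontil"], cellmap, ratio_cap)
    inter["cross_edge_fraction"] = cross_edge_fraction(cellmap, d_threshold_um)
    for key, val in inter.items():
        base[key] = np.atleast_1d(np.asarray(val, dtype=float))
    return base


def extract_tile_features(cellmap: CellMap,
                          registry: FeatureRegistry | None = None,
                          d_threshold_um: float = 50.0,
                          ratio_cap: float = DEFAULT_RATIO_CAP) -> TileFeatureVector:
    """Compute the full registry feature vector for one tile.

    Degenerate tiles (no cells, one family absent, zero-area hulls) produce
    the documented sentinels — count features 0, geometry features NaN —
    never silently dropped entries.
    """
    registry = registry or default_registry()
    if len(registry) != N_TILE_FEATURES:
        raise InvalidConfigError("registry must define exactly 350 features")
    base = compute_base_measurements(cellmap, d_threshold_um, ratio_cap)
    values = np.empty(len(registry))
    for i, entry in enumerate(registry.entries):
        values[i] = _summarize(base[entry.base], entry.stat, entry.kind)
    return TileFeatureVector(cellmap.tile_id, cellmap.compartment, values)


def extract_features_frame(cellmaps: list[CellMap],
                           registry: FeatureRegistry | None = None,
                           d_threshold_um: float = 50.0) -> pd.DataFrame:
    """Feature table (tiles x 350) with tile_id/compartment columns."""
    registry = registry or default_registry()
    rows = []
    for cm in cellmaps:
        tv = extract_tile_features(cm, registry, d_threshold_um)
        row = {"tile_id": tv.tile_id, "compartment": tv.compartment}
        row.update(dict(zip(registry.names, tv.values)))
        rows.append(row)
    return pd.DataFrame(rows)
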