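"""The named registry of per-tile spatial immune-architecture features.

A tile is described by 70 base measurements of the TIL / non-TIL cell
geometry (per-cluster distributions, per-cell distributions and tile-level
scalars), each summarized within the tile by five statistics
(mean, median, min, max, std), for 350 features per tile.  The registry is
data-driven: the feature set is defined here once, and every downstream
stage (tile extraction, patient aggregation, model fitting) refers to
features by registry name, so the composition can be swapped without code
changes elsewhere.

Measurement kinds drive the sentinel policy for degenerate tiles:

``count``
    empty distribution summarizes to 0 (no cells means zero counts);
``geometry`` / ``fraction`` / ``ratio``
    empty or undefined summarizes to NaN, imputed downstream at
    patient aggregation / model-fit time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidConfigError

#: within-tile summary statistics applied to each base measurement
TILE_STATS: tuple[str, ...] = ("mean", "median", "min", "max", "std")

#: the two cell families distinguished within a tissue compartment
FAMILIES: tuple[str, ...] = ("til", "nontil")

#: neighborhood sizes for the cross-family mixing index
MIXING_KS: tuple[int, ...] = (3, 5, 10)

#: radii (um) for local neighbor-count measurements
NEIGHBOR_RADII_UM: tuple[float, ...] = (25.0, 50.0)

N_BASE_MEASUREMENTS = 70
N_TILE_FEATURES = 350


@dataclass(frozen=True)
class FeatureEntry:
    """One named tile feature: a summary statistic of a base measurement."""

    name: str
    base: str
    stat: str
    kind: str  # count | geometry | fraction | ratio
    group: str
    description: str


def base_measurements() -> list[tuple[str, str, str, str]]:
    """Return the 70 (base-name, kind, group, description) tuples."""
    out: list[tuple[str, str, str, str]] = []
    for fam in FAMILIES:
        label = "TIL" if fam == "til" else "non-TIL"
        grp = f"{fam}_cluster"
        out += [
            (f"{fam}_cluster_size", "count", grp,
             f"member count per {label} cluster"),
            (f"{fam}_cluster_hull_area", "geometry", grp,
             f"convex-hull area (um^2) per {label} cluster"),
            (f"{fam}_cluster_hull_perimeter", "geometry", grp,
             f"convex-hull boundary length (um) per {label} cluster"),
            (f"{fam}_cluster_hull_density", "geometry", grp,
             f"members per hull area (1/um^2) per {label} cluster"),
            (f"{fam}_cluster_extent", "geometry", grp,
             f"major-axis extent: max pairwise member distance (um)"),
            (f"{fam}_cluster_rms_spread", "geometry", grp,
             f"RMS member distance to cluster centroid (um)"),
            (f"{fam}_cluster_circularity", "geometry", grp,
             f"4*pi*area/perimeter^2 of the cluster hull"),
            (f"{fam}_cluster_aspect_ratio", "geometry", grp,
             f"minor/major axis ratio of member coordinate covariance"),
            (f"{fam}_cluster_intra_nn_dist", "geometry", grp,
             f"mean within-cluster nearest-neighbor distance (um)"),
            (f"{fam}_cluster_centroid_nn_dist", "geometry", grp,
             f"distance to nearest other {label} cluster centroid (um)"),
        ]
        grp = f"{fam}_cell"
        out += [
            (f"{fam}_cell_nn_same", "geometry", grp,
             f"per-{label}-cell distance to nearest same-family cell (um)"),
            (f"{fam}_cell_nn_cross", "geometry", grp,
             f"per-{label}-cell distance to nearest other-family cell (um)"),
        ]
        for r in NEIGHBOR_RADII_UM:
            out += [
                (f"{fam}_neighbors_r{int(r)}", "count", grp,
                 f"same-family neighbors within {r} um per {label} cell"),
                (f"{fam}_cross_neighbors_r{int(r)}", "count", grp,
                 f"other-family neighbors within {r} um per {label} cell"),
            ]
        grp = f"{fam}_tile"
        out += [
            (f"{fam}_cell_count", "count", grp, f"{label} cells in tile"),
            (f"{fam}_density", "count", grp, f"{label} cells per mm^2"),
            (f"{fam}_cluster_count", "count", grp, f"{label} clusters in tile"),
            (f"{fam}_clustered_fraction", "fraction", grp,
             f"fraction of {label} cells in clusters of size >= 2"),
            (f"{fam}_largest_cluster_fraction", "fraction", grp,
             f"largest {label} cluster size over {label} cell count"),
            (f"{fam}_hull_area_fraction", "fraction", grp,
             f"total {label} cluster hull area over tile area"),
        ]
    grp = "interplay"
    out += [
        ("til_nontil_cluster_dist", "geometry", grp,
         "per TIL cluster, distance to nearest non-TIL cluster centroid (um)"),
        ("nontil_til_cluster_dist", "geometry", grp,
         "per non-TIL cluster, distance to nearest TIL cluster centroid (um)"),
        ("til_nontil_hull_iou", "fraction", grp,
         "hull IoU of each TIL cluster with its nearest non-TIL cluster"),
        ("nontil_til_hull_iou", "fraction", grp,
         "hull IoU of each non-TIL cluster with its nearest TIL cluster"),
    ]
    for k in MIXING_KS:
        for scope in ("til", "nontil", "all"):
            out.append((f"mixing_k{k}_{scope}", "fraction", grp,
                        f"fraction of each {scope} cell's {k} nearest "
                        f"neighbors from the other family"))
    out += [
        ("til_fraction", "fraction", grp, "TIL cells over all cells"),
        ("til_nontil_count_ratio", "ratio", grp, "TIL/non-TIL cell count ratio"),
        ("til_nontil_cluster_count_ratio", "ratio", grp,
         "TIL/non-TIL cluster count ratio"),
        ("til_nontil_mean_cluster_size_ratio", "ratio", grp,
         "ratio of mean cluster sizes, TIL over non-TIL"),
        ("til_nontil_hull_area_ratio", "ratio", grp,
         "ratio of total cluster hull areas, TIL over non-TIL"),
        ("til_nontil_clustered_fraction_ratio", "ratio", grp,
         "ratio of clustered fractions, TIL over non-TIL"),
        ("total_cell_count", "count", grp, "all cells in tile"),
        ("total_density", "count", grp, "all cells per mm^2"),
        ("total_cluster_count", "count", grp, "all clusters in tile"),
        ("total_clustered_fraction", "fraction", grp,
         "fraction of all cells in clusters of size >= 2"),
        ("cross_edge_fraction", "fraction", grp,
         "cross-family pairs among all cell pairs within the threshold"),
        ("til_in_nontil_hull_fraction", "fraction", grp,
         "fraction of TIL cells inside any non-TIL cluster hull"),
        ("nontil_in_til_hull_fraction", "fraction", grp,
         "fraction of non-TIL cells inside any TIL cluster hull"),
    ]
    assert len(out) == N_BASE_MEASUREMENTS
    return out


class FeatureRegistry:
    """Ordered, validated collection of the 350 tile feature definitions."""

    def __init__(self, entries: list[FeatureEntry]):
        if len(entries) != N_TILE_FEATURES:
            raise InvalidConfigError(
                f"feature registry must contain exactly {N_TILE_FEATURES} "
                f"entries, got {len(entries)}"
            )
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise InvalidConfigError("feature registry names must be unique")
        self.entries = list(entries)
        self.names = names
        self._index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        return self._index[name]


def default_registry() -> FeatureRegistry:
    """Build the default 70 x 5 registry."""
    entries = []
    for base, kind, group, desc in base_measurements():
        for stat in TILE_STATS:
            entries.append(FeatureEntry(
                name=f"{stat}_{base}", base=base, stat=stat, kind=kind,
                group=group, description=f"{stat} over tile of: {desc}",
            ))
    return FeatureRegistry(entries)
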