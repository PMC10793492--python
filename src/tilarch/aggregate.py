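"""Patient-level aggregation of per-tile feature vectors.

Each of the 350 tile features is summarized per compartment over all of a
patient's tiles (pooled across slides) with six statistics — mean, median,
minimum, maximum, range and variance — giving 6 x 2 x 350 = 4,200 named
patient features.  NaN sentinels from degenerate tiles are skipped
per-feature (pairwise deletion); a compartment with no tiles yields an
all-NaN block that downstream model fitting imputes from its training
cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegeneratePatientError
from .features import TileFeatureVector
from .registry import FeatureRegistry, default_registry

PATIENT_STATS: tuple[str, ...] = ("mean", "median", "min", "max", "range", "variance")
COMPARTMENTS: tuple[str, ...] = ("epithelium", "stroma")
N_PATIENT_FEATURES = 4200


def patient_feature_names(registry: FeatureRegistry | None = None) -> list[str]:
    """The 4,200 patient-level feature names, in deterministic order."""
    registry = registry or default_registry()
    names = [f"{stat}_{comp}_{feat}"
             for comp in COMPARTMENTS
             for stat in PATIENT_STATS
             for feat in registry.names]
    assert len(names) == N_PATIENT_FEATURES
    return names


def _stat_block(mat: np.ndarray) -> dict[str, np.ndarray]:
    """Six nan-aware statistics over tiles (rows) for each feature (cols).

    Variance uses the population (n) denominator, so duplicating every
    tile leaves it unchanged.
    """
    with np.errstate(invalid="ignore"):
        any_ = np.sum(np.isfinite(mat), axis=0) > 0
        out = {}
        out["mean"] = _nanstat(np.nanmean, mat, any_)
        out["median"] = _nanstat(np.nanmedian, mat, any_)
        out["min"] = _nanstat(np.nanmin, mat, any_)
        out["max"] = _nanstat(np.nanmax, mat, any_)
        out["range"] = out["max"] - out["min"]
        out["variance"] = _nanstat(lambda m, axis: np.nanvar(m, axis=axis, ddof=0),
                                   mat, any_)
    return out


def _nanstat(func, mat: np.ndarray, any_: np.ndarray) -> np.ndarray:
    res = np.full(mat.shape[1], np.nan)
    if mat.shape[0] == 0:
        return res
    cols = np.flatnonzero(any_)
    if cols.size:
        res[cols] = func(mat[:, cols], axis=0)
    return res


def aggregate_patient(tile_vectors: list[TileFeatureVector], patient_id: str,
                      registry: FeatureRegistry | None = None) -> pd.Series:
    """Aggregate a patient's tile vectors into the 4,200-feature vector."""
    registry = registry or default_registry()
    if not tile_vectors:
        raise DegeneratePatientError(f"patient {patient_id!r} has no tiles")
    values = []
    for comp in COMPARTMENTS:
        mat = np.array([tv.values for tv in tile_vectors
                        if tv.compartment == comp], dtype=float)
        if mat.size == 0:
            mat = mat.reshape(0, len(registry))
        stats = _stat_block(mat)
        for stat in PATIENT_STATS:
            values.append(stats[stat])
    out = pd.Series(np.concatenate(values),
                    index=patient_feature_names(registry), name=patient_id)
    return out


def aggregate_cohort(tile_features: pd.DataFrame,
                     registry: FeatureRegistry | None = None) -> pd.DataFrame:
    """Aggregate a tile-feature table into a patients x 4,200 matrix.

    ``tile_features`` must carry ``patient_id``, ``compartment`` and the
    350 registry-named feature columns (the output of
    :func:`tilarch.features.extract_features_frame` plus a patient id).
    """
    registry = registry or default_registry()
    rows = []
    for pid, grp in tile_features.groupby("patient_id", sort=True):
        tvs = [TileFeatureVector(str(r.get("tile_id", "")), r["compartment"],
                                 r[registry.names].to_numpy(dtype=float))
               for _, r in grp.iterrows()]
        rows.append(aggregate_patient(tvs, str(pid), registry))
    return pd.DataFrame(rows)
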