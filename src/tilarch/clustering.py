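"""Consensus clustering of prognostic TIL features vs molecular subtype.

The unique features supporting the three risk models are merged into one
patient matrix, consensus-clustered (subsampled k-means runs aggregated
into a co-assignment matrix, cut hierarchically at a forced K), and the
resulting clusters are scored against the molecular subtype labels with
per-subtype recall and precision under an optimal one-to-one matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .errors import ValidationError
from .survival import RiskModel


def merge_model_features(models: list[RiskModel], X: pd.DataFrame) -> pd.DataFrame:
    """Z-scored matrix over the deduplicated union of model supports.

    Column order is deterministic: first appearance across the models in
    the order given.
    """
    cols: list[str] = []
    for m in models:
        for name in m.support:
            if name not in cols:
                cols.append(name)
    missing = [c for c in cols if c not in X.columns]
    if missing:
        raise ValidationError(f"feature matrix lacks columns {missing[:5]}")
    mat = X[cols].to_numpy(float)
    med = np.nanmedian(mat, axis=0)
    mat = np.where(np.isfinite(mat), mat, med)
    sd = mat.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (mat - mat.mean(axis=0)) / sd
    return pd.DataFrame(z, index=X.index, columns=cols)


#: patient-level summaries describing a TIL profile, per compartment
TIL_PROFILE_BASES = (
    "mean_til_density", "mean_til_cluster_count",
    "mean_til_cluster_hull_area", "mean_til_clustered_fraction",
    "mean_til_cluster_size", "mean_mixing_k5_til", "mean_til_fraction",
)


def til_profile_matrix(features: pd.DataFrame,
                       log_transform: bool = True,
                       clip: float | None = 3.0) -> pd.DataFrame:
    """Fourteen z-scored TIL-profile summaries (7 per compartment).

    TIL density and cluster geometry vary multiplicatively across immune
    phenotypes, so columns are log1p-transformed before z-scoring by
    default, and z-scores are winsorized at ``clip`` standard deviations
    so a few immune-cold patients with unstable fraction estimates cannot
    dominate distance computations.  Missing values are median-imputed.
    """
    cols = [f"mean_{comp}_{b}" for comp in ("epithelium", "stroma")
            for b in TIL_PROFILE_BASES]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValidationError(f"feature matrix lacks columns {missing[:5]}")
    mat = features[cols].to_numpy(float)
    med = np.nanmedian(mat, axis=0)
    mat = np.where(np.isfinite(mat), mat, med)
    if log_transform:
        mat = np.log1p(np.maximum(mat, 0.0))
    sd = mat.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (mat - mat.mean(axis=0)) / sd
    if clip is not None:
        z = np.clip(z, -clip, clip)
    return pd.DataFrame(z, index=features.index, columns=cols)


@dataclass
class ConsensusResult:
    """Labels, co-assignment consensus matrix and the forced K."""

    labels: pd.Series  # patient -> 1..K
    consensus: pd.DataFrame  # patients x patients in [0, 1]
    K: int


def consensus_cluster(X: pd.DataFrame, K: int, n_resamples: int = 500,
                      subsample_frac: float = 0.8, seed: int = 17) -> ConsensusResult:
    """Consensus clustering with a k-means base learner at forced K.

    Each resample clusters a random ``subsample_frac`` of patients; the
    consensus matrix holds, per patient pair, the fraction of co-sampled
    runs in which they landed in the same base cluster.  Final labels cut
    the average-linkage dendrogram of (1 - consensus) into K groups.
    """
    n = len(X)
    mat = X.to_numpy(float)
    if K < 2:
        raise ValidationError("K must be at least 2")
    if K > len(np.unique(mat, axis=0)):
        raise ValidationError("K exceeds the number of distinct points")
    rng = np.random.default_rng(seed)
    co = np.zeros((n, n))
    cnt = np.zeros((n, n))
    m = max(K, int(np.floor(subsample_frac * n)))
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(n_clusters=K, n_init=3,
                    random_state=int(rng.integers(2 ** 31)))
        lab = km.fit_predict(mat[idx])
        sampled = np.zeros(n, dtype=bool)
        sampled[idx] = True
        cnt[np.ix_(idx, idx)] += 1
        for c in range(K):
            members = idx[lab == c]
            co[np.ix_(members, members)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(cnt > 0, co / np.maximum(cnt, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2
    dist = squareform(1.0 - consensus, checks=False)
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=K, criterion="maxclust")
    return ConsensusResult(
        labels=pd.Series(labels, index=X.index, name="cluster"),
        consensus=pd.DataFrame(consensus, index=X.index, columns=X.index),
        K=K)


def subtype_agreement(labels: pd.Series, subtypes: pd.Series) -> pd.DataFrame:
    """Per-subtype recall and precision under optimal one-to-one matching.

    Clusters are assigned to subtypes by maximizing total agreement on the
    contingency table (Hungarian algorithm), which makes the scores
    invariant to cluster relabeling.  Subtypes left unmatched (fewer
    clusters than subtypes) or empty report NaN.
    """
    labels, subtypes = labels.align(subtypes, join="inner")
    tab = pd.crosstab(labels, subtypes)
    cost = np.zeros((max(tab.shape), max(tab.shape)))
    cost[: tab.shape[0], : tab.shape[1]] = tab.to_numpy()
    ri, ci = linear_sum_assignment(cost, maximize=True)
    match = {int(c): int(r) for r, c in zip(ri, ci)
             if r < tab.shape[0] and c < tab.shape[1]}
    rows = []
    for j, subtype in enumerate(tab.columns):
        size = int(tab[subtype].sum())
        if j not in match or size == 0:
            rows.append({"subtype": subtype, "recall": np.nan,
                         "precision": np.nan, "n": size})
            continue
        r = match[j]
        hits = int(tab.iloc[r, j])
        cluster_size = int(tab.iloc[r].sum())
        rows.append({"subtype": subtype,
                     "recall": hits / size,
                     "precision": hits / cluster_size if cluster_size else np.nan,
                     "n": size})
    return pd.DataFrame(rows).set_index("subtype")
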