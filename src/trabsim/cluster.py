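"""Osteocyte single-cell mechanomics cluster analysis.

Each osteocyte is described by the local RANKL, OPG and sclerostin levels
at its 3D position at the first time point.  Osteocytes are labeled by the
strain regime of their voxel (high / medium / low, split at the 75th and
25th percentiles of the dilated effective strain over the analysis region),
and by the nearest remodeling event in the Formed/Quiescent/Resorbed
overlay of the last versus first frame (ties at exactly equal squared
distance are labeled "Multiple"; with no events the label is
"Quiescence").  K-means clusters the protein levels for k = 1..10 with a
fixed seed; the knee of the inertia curve (maximum-curvature, kneedle-style
on the normalized curve) selects k, and within-cluster conditional
frequencies of the event and strain labels are tabulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .morphometry import FQR_FORMED, FQR_RESORBED

FEATURES = ("rankl", "opg", "scl")


def label_strain(ot_positions, eps: np.ndarray, region_mask: np.ndarray = None):
    """High/medium/low strain labels for osteocyte positions.

    Percentiles (75th / 25th) are computed over the analysis-region voxels
    of the dilated strain field (all voxels if no mask given); labels use
    strict comparisons, so ties at the percentile value fall into "medium".
    """
    vals = eps[region_mask] if region_mask is not None else eps.ravel()
    hi = np.percentile(vals, 75)
    lo = np.percentile(vals, 25)
    labels = []
    for pos in ot_positions:
        v = eps[tuple(pos)]
        labels.append("high" if v > hi else ("low" if v < lo else "medium"))
    return labels


def label_events(ot_positions, fqr: np.ndarray):
    """Nearest-remodeling-event labels from an FQR overlay map.

    Distances are Euclidean between voxel indices; "same distance" means
    equal squared integer distance (exact, no float tolerance).
    """
    formed = np.argwhere(fqr == FQR_FORMED)
    resorbed = np.argwhere(fqr == FQR_RESORBED)
    labels = []
    for pos in ot_positions:
        p = np.asarray(pos)
        d_f = _min_sqdist(p, formed)
        d_r = _min_sqdist(p, resorbed)
        if d_f is None and d_r is None:
            labels.append("Quiescence")
        elif d_r is None or (d_f is not None and d_f < d_r):
            labels.append("Formation")
        elif d_f is None or d_r < d_f:
            labels.append("Resorption")
        else:
            labels.append("Multiple")
    return labels


def _min_sqdist(p, targets):
    if len(targets) == 0:
        return None
    d = targets - p
    return int(np.min(np.einsum("ij,ij->i", d, d)))


def knee_point(x, y) -> int:
    """Knee of a decreasing convex curve by the kneedle criterion.

    Both coordinates are normalized to [0, 1]; the knee is the x with the
    maximum vertical difference between the flipped normalized curve and
    the diagonal.  Returns the x value (not the index).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for knee detection")
    span = y.max() - y.min()
    if span == 0:
        raise ValueError("flat curve has no knee")
    xn = (x - x.min()) / (x.max() - x.min())
    yn = (y - y.min()) / span
    diff = (1.0 - yn) - xn
    return int(x[np.argmax(diff)])


def kmeans_with_knee(features: np.ndarray, k_range=range(1, 11),
                     seed: int = 0, standardize: bool = False):
    """Cluster feature vectors at the knee of the k-means inertia curve.

    Returns ``(labels, k_knee, inertias)``.  The same fixed seed is used for
    every k, so the whole procedure is deterministic.  Features may
    optionally be z-scored first (off by default).
    """
    X = np.asarray(features, dtype=float)
    if len(X) < 10:
        raise ValueError("need at least 10 records for the cluster analysis")
    if standardize:
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant feature; cannot standardize")
        X = (X - X.mean(axis=0)) / sd
    ks = list(k_range)
    inertias = []
    fits = {}
    for k in ks:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
        inertias.append(km.inertia_)
        fits[k] = km
    k_knee = knee_point(ks, inertias)
    return fits[k_knee].labels_.copy(), k_knee, np.array(inertias)


def fill_from_nearest(field: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace values outside ``valid`` by the nearest valid voxel's value.

    Cytokine fields are defined on the marrow + bone-surface domain;
    osteocytes embedded deeper in bone sample the level at the nearest
    domain voxel (implicit canalicular transport), mirroring how their
    production is routed into the domain.
    """
    from scipy import ndimage

    _, idx = ndimage.distance_transform_edt(~valid, return_indices=True)
    return field[tuple(idx)]


def build_osteocyte_records(cells, cytokines: dict, eps: np.ndarray,
                            fqr: np.ndarray, region_mask: np.ndarray = None,
                            seed: int = 0) -> pd.DataFrame:
    """Assemble the per-osteocyte analysis table and cluster it.

    ``cytokines`` maps the species name to its concentration volume at the
    first time point.  Returns a DataFrame with columns id, z, y, x,
    rankl, opg, scl, strain_label, event_label, cluster.
    """
    ots = [c for c in cells if c.kind == "Ot"]
    positions = [c.position for c in ots]
    df = pd.DataFrame(
        {
            "id": [c.id for c in ots],
            "z": [p[0] for p in positions],
            "y": [p[1] for p in positions],
            "x": [p[2] for p in positions],
            "rankl": [cytokines["RANKL"][p] for p in positions],
            "opg": [cytokines["OPG"][p] for p in positions],
            "scl": [cytokines["Scl"][p] for p in positions],
        }
    )
    df["strain_label"] = label_strain(positions, eps, region_mask)
    df["event_label"] = label_events(positions, fqr)
    labels, k, _ = kmeans_with_knee(df[list(FEATURES)].to_numpy(), seed=seed)
    df["cluster"] = labels
    return df


def cluster_probability_table(records: pd.DataFrame):
    """Within-cluster conditional frequencies of event and strain labels.

    Returns ``(event_table, strain_table)``: DataFrames indexed by cluster
    whose rows sum to 1.
    """
    def _cond(col):
        counts = records.groupby(["cluster", col], observed=True).size().unstack(fill_value=0)
        return counts.div(counts.sum(axis=1), axis=0)

    return _cond("event_label"), _cond("strain_label")


def select_cross_section(positions, z_start: int, thickness: int = 5):
    """Boolean selector for records inside a longitudinal slab of voxels."""
    z = np.asarray([p[0] for p in positions])
    return (z >= z_start) & (z < z_start + thickness)
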