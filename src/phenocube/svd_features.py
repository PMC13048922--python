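"""Truncated SVD of index matrices and per-pixel feature assembly.

With rows = acquisition dates and columns = pixels, the left singular
vectors of a spatiotemporal matrix are temporal modes (how an index varies
through time) and the right singular vectors are spatial loadings (how
strongly each pixel expresses that mode).  The leading spatial loadings of
each vegetation index summarise the pixel's phenological history and are
the classifier inputs: six components for each of four indices gives the
24-column feature table.

Loadings are kept unit-norm (not scaled by singular values) by default; the
sign of every component pair is canonicalised so that coefficients fitted
on the features are stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import svd as _exact_svd
from sklearn.utils.extmath import randomized_svd

from .indices_cube import GridGeoreference, SpatioTemporalMatrix


@dataclass
class DecompositionResult:
    """Rank-k truncated SVD of one index matrix.

    temporal_modes has shape (k, n_dates); spatial_loadings has shape
    (k, n_pixels); variance_fractions[i] = sigma_i^2 / ||M||_F^2 with the
    denominator taken over the FULL matrix, so the fractions of a truncation
    sum to less than one.
    """

    index_name: str
    singular_values: np.ndarray
    temporal_modes: np.ndarray
    spatial_loadings: np.ndarray
    variance_fractions: np.ndarray
    grid_shape: tuple
    dates: np.ndarray
    method: str = "exact"

    def __post_init__(self):
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(s) > 1e-9 * max(s[0], 1.0) if s.size else False):
            raise ValueError("singular values must be nonincreasing")
        if np.any(s < 0):
            raise ValueError("singular values must be nonnegative")

    @property
    def k(self) -> int:
        return self.singular_values.size

    def reconstruct(self) -> np.ndarray:
        return (self.temporal_modes.T * self.singular_values) @ self.spatial_loadings


def decompose(matrix: SpatioTemporalMatrix, k: int, method: str = "exact",
              seed: int | None = 0) -> DecompositionResult:
    """Truncated rank-k SVD of an index matrix.

    ``method='exact'`` uses a full LAPACK decomposition truncated to k;
    ``'randomized'`` uses a seeded randomized range finder (oversampling 10,
    4 power iterations) that matches the exact singular values to ~1e-6
    relative on the matrix sizes this pipeline produces.
    """
    m = matrix.values
    if not 1 <= k <= min(m.shape):
        raise ValueError(f"k={k} must lie in [1, min(rows, cols)] = "
                         f"[1, {min(m.shape)}]")
    total_sq = float(np.sum(m * m))
    if method == "exact":
        u, s, vt = _exact_svd(m, full_matrices=False)
        u, s, vt = u[:, :k], s[:k], vt[:k]
    elif method == "randomized":
        u, s, vt = randomized_svd(m, n_components=k, n_oversamples=10,
                                  n_iter=4, random_state=seed)
    else:
        raise ValueError(f"unknown method {method!r}")
    var_frac = (s ** 2) / total_sq if total_sq > 0 else np.zeros_like(s)
    return DecompositionResult(
        index_name=matrix.index_name,
        singular_values=s,
        temporal_modes=u.T,
        spatial_loadings=vt,
        variance_fractions=var_frac,
        grid_shape=matrix.grid_shape,
        dates=matrix.dates,
        method=method,
    )


def sign_normalize(result: DecompositionResult) -> DecompositionResult:
    """Fix the sign ambiguity of every singular-vector pair.

    Each component is flipped (temporal mode and spatial loading together,
    so the reconstruction is unchanged) so that the maximum-absolute entry
    of its temporal mode is positive.  Idempotent.
    """
    u = result.temporal_modes.copy()
    v = result.spatial_loadings.copy()
    for i in range(u.shape[0]):
        j = int(np.argmax(np.abs(u[i])))
        if u[i, j] < 0:
            u[i] = -u[i]
            v[i] = -v[i]
    return replace(result, temporal_modes=u, spatial_loadings=v)


def extract_features(results: dict, retained_k: int = 6,
                     scale_by_singular_values: bool = False) -> pd.DataFrame:
    """Concatenate retained spatial loadings into the per-pixel feature table.

    ``results`` maps index name -> DecompositionResult (all sharing one pixel
    grid).  Columns are named ``<index>_<component>`` in lower case, e.g.
    ``ndvi_3``; rows follow the row-major pixel order of the matrices.
    """
    grids = {name: r.grid_shape for name, r in results.items()}
    if len(set(grids.values())) > 1:
        raise ValueError(f"decompositions disagree on the pixel grid: {grids}")
    cols = {}
    for name, res in results.items():
        if res.k < retained_k:
            raise ValueError(
                f"{name}: only {res.k} components available, need {retained_k}")
        for i in range(retained_k):
            load = res.spatial_loadings[i]
            if scale_by_singular_values:
                load = load * res.singular_values[i]
            cols[f"{name.lower()}_{i + 1}"] = load
    return pd.DataFrame(cols)


def features_at_waypoints(table: pd.DataFrame, waypoints: pd.DataFrame,
                          geo: GridGeoreference, grid_shape) -> pd.DataFrame:
    """Look up the feature row of each waypoint's nearest pixel center.

    Returns the feature columns plus ``label`` (1 = buffel present, 0 =
    buffel-free), ``stratum`` when available, and the resolved pixel
    (row, col).  Multiple waypoints landing in one pixel are deduplicated
    with a warning, keeping the first.
    """
    rows, cols = geo.pixel_of(waypoints["x"].to_numpy(),
                              waypoints["y"].to_numpy(), grid_shape)
    flat = rows * grid_shape[1] + cols
    lab = waypoints["label"]
    if lab.dtype == object or str(lab.dtype).startswith("str"):
        y = (lab == "buffel").astype(int).to_numpy()
    else:
        y = lab.astype(int).to_numpy()

    out = table.iloc[flat].reset_index(drop=True)
    out.insert(0, "pixel_row", rows)
    out.insert(1, "pixel_col", cols)
    out["label"] = y
    if "stratum" in waypoints:
        out["stratum"] = waypoints["stratum"].to_numpy()

    dup = pd.Series(flat).duplicated()
    if dup.any():
        warnings.warn(f"{int(dup.sum())} waypoint(s) share a pixel with an "
                      "earlier waypoint; keeping the first of each",
                      stacklevel=2)
        out = out[~dup.to_numpy()].reset_index(drop=True)
    return out


def decomposition_summary(results: dict) -> pd.DataFrame:
    """Singular values and variance fractions of each index, long format."""
    rows = []
    for name, res in results.items():
        cum = np.cumsum(res.variance_fractions)
        for i in range(res.k):
            rows.append({
                "index": name, "component": i + 1,
                "singular_value": float(res.singular_values[i]),
                "variance_fraction": float(res.variance_fractions[i]),
                "cumulative_variance_fraction": float(cum[i]),
            })
    return pd.DataFrame(rows)
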