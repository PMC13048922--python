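"""Per-pixel probability surfaces, occurrence maps and stratum summaries.

A fitted :class:`~phenocube.classifiers.LogisticModel` applied to the
feature table yields a continuous occurrence-probability surface on the
pixel grid; thresholding it gives a thematic presence/absence map, and the
landscape-stratum raster partitions both into per-stratum area fractions
(p50/p75) and per-stratum accuracy against ground-truth waypoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifiers import LogisticModel, confusion_metrics
from .indices_cube import GridGeoreference
from .svd_features import features_at_waypoints


@dataclass
class ProbabilitySurface:
    """Grid of P(buffel presence) in [0, 1] with its georeference."""

    values: np.ndarray
    geo: GridGeoreference
    model_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(v)) or v.min() < 0 or v.max() > 1:
            raise ValueError("probabilities must be finite and in [0, 1]")
        self.values = v


def predict_surface(model: LogisticModel, table: pd.DataFrame, grid_shape,
                    geo: GridGeoreference | None = None,
                    logit_sign: str = "standard") -> ProbabilitySurface:
    """Apply the logistic model to every pixel of the feature table.

    ``logit_sign`` selects the orientation of the logistic transform:
    ``standard`` is P = 1/(1 + exp(-Lin)) (probability rises with the linear
    predictor); ``inverted`` is P = 1/(1 + exp(+Lin)), the mirror-image
    convention occasionally seen in print, which flips every probability to
    1 - P.
    """
    if logit_sign not in ("standard", "inverted"):
        raise ValueError("logit_sign must be 'standard' or 'inverted'")
    lin = model.linear_predictor(table)
    if logit_sign == "inverted":
        warnings.warn("using inverted logistic convention P = 1/(1+exp(+Lin))",
                      stacklevel=2)
        lin = -lin
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-lin))
    return ProbabilitySurface(values=p.reshape(grid_shape),
                              geo=geo or GridGeoreference(),
                              model_id=",".join(model.selected_features))


def threshold_map(surface: ProbabilitySurface, t: float = 0.5) -> np.ndarray:
    """Thematic occurrence map: True where P >= t (boundary included)."""
    if not 0.0 < t < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return surface.values >= t


def strata_summary(surface: ProbabilitySurface, strata: np.ndarray,
                   pixel_area_km2: float | None = None,
                   stratum_names: dict | None = None) -> pd.DataFrame:
    """Per-stratum area and p50/p75 occurrence fractions.

    p50/p75 are the fractions of the stratum's own pixels with P >= 0.50
    and P >= 0.75.  Empty strata are omitted with a warning.
    """
    strata = np.asarray(strata)
    if strata.shape != surface.values.shape:
        raise ValueError("strata grid does not conform to the surface")
    if pixel_area_km2 is None:
        pixel_area_km2 = surface.geo.pixel_area_km2
    rows = []
    for s in np.unique(strata):
        sel = strata == s
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"stratum {s} has no pixels; omitted", stacklevel=2)
            continue
        p = surface.values[sel]
        rows.append({
            "stratum": int(s),
            "name": (stratum_names or {}).get(int(s), str(int(s))),
            "pixels": n,
            "area_km2": n * pixel_area_km2,
            "p50": float(np.mean(p >= 0.50)),
            "p75": float(np.mean(p >= 0.75)),
        })
    return pd.DataFrame(rows)


def strata_accuracy(surface: ProbabilitySurface, waypoints: pd.DataFrame,
                    strata: np.ndarray, t: float = 0.5,
                    stratum_names: dict | None = None) -> pd.DataFrame:
    """Confusion metrics of the thresholded surface per landscape stratum.

    Waypoints are assigned to pixels by nearest-center lookup; strata with
    no waypoints are omitted.  Metrics with empty denominators are NaN.
    """
    strata = np.asarray(strata)
    shape = surface.values.shape
    prob_table = pd.DataFrame({"p": surface.values.ravel()})
    looked = features_at_waypoints(prob_table, waypoints, surface.geo, shape)
    pred = looked["p"].to_numpy() >= t
    truth = looked["label"].to_numpy().astype(bool)
    sid = strata[looked["pixel_row"].to_numpy(), looked["pixel_col"].to_numpy()]
    rows = []
    for s in np.unique(sid):
        sel = sid == s
        cm = confusion_metrics(pred[sel], truth[sel])
        rows.append({
            "stratum": int(s),
            "name": (stratum_names or {}).get(int(s), str(int(s))),
            "waypoints": int(sel.sum()),
            "specificity": np.nan if cm.specificity is None else cm.specificity,
            "sensitivity": np.nan if cm.sensitivity is None else cm.sensitivity,
            "accuracy": np.nan if cm.accuracy is None else cm.accuracy,
        })
    return pd.DataFrame(rows)
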