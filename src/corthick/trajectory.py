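"""Lifespan curves, derivative color bands, clustering, and summaries.

A fitted region network plus its scalers defines a thickness curve in mm
over an age grid.  Its rate of change (mm/year) is estimated with 7-point
finite-difference stencils, dynamically one-sided at the ends of the grid,
and rendered as a diverging color band: blue for thickness gain, green for
no change (derivative exactly 0 maps to the neutral green), red for loss.
Regions with similar derivative profiles are grouped by agglomerative
clustering (correlation distance, average linkage) so related bands sit
next to each other, and lifespan summary tables report, per age window,
the regions with extreme mean thickness, extreme variability (curve SD —
this package's choice of metric), and extreme linearity (R-squared of a
least-squares line to the curve, again this package's metric), alongside a
per-region comparison of the network fit with a plain linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from . import fdiff
from .neuralnet import MLPModel
from .synthetic_cohort import Cohort

# Diverging scale anchors: loss (red) / no change (green) / gain (blue).
_COLOR_NEG = np.array([0.698, 0.094, 0.169])
_COLOR_NEUTRAL = np.array([0.102, 0.596, 0.314])
_COLOR_POS = np.array([0.129, 0.400, 0.675])

SPEED_CMAP = LinearSegmentedColormap.from_list(
    "thickness_speed", [_COLOR_NEG, _COLOR_NEUTRAL, _COLOR_POS], N=511
)


@dataclass(frozen=True)
class AgeGrid:
    """Uniform age grid (years); must carry at least 7 nodes for stencils."""

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.stop <= self.start or self.step <= 0:
            raise ValueError("need stop > start and step > 0")
        if len(self.ages) < 7:
            raise ValueError("age grid must have at least 7 nodes")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.start, self.stop + self.step / 2, self.step)

    def __len__(self) -> int:
        return len(self.ages)


@dataclass
class TrajectoryCurve:
    region: Optional[str]
    hemisphere: Optional[str]
    grid: AgeGrid
    thickness: np.ndarray  # mm per grid node
    extrapolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != (len(self.grid),):
            raise ValueError("curve length must match the grid")
        if not np.all(np.isfinite(self.thickness)):
            raise ValueError("non-finite curve values")
        if self.extrapolated is None:
            self.extrapolated = np.zeros(len(self.grid), dtype=bool)


@dataclass
class DerivativeBand:
    region: Optional[str]
    hemisphere: Optional[str]
    grid: AgeGrid
    derivative: np.ndarray  # mm/year per grid node
    color_codes: np.ndarray  # (n, 3) RGB in [0, 1]
    vmax: float = 0.0

    def __post_init__(self) -> None:
        if self.derivative.shape != (len(self.grid),):
            raise ValueError("derivative length must match the grid")
        if self.color_codes.shape != (len(self.grid), 3):
            raise ValueError("color_codes must be (n, 3)")


def predict_curve(model: MLPModel, grid: AgeGrid) -> TrajectoryCurve:
    """Evaluate a fitted network over an age grid, in mm vs years.

    Ages outside the range the input scaler was fitted on extrapolate the
    affine scaling; those nodes are flagged in ``extrapolated``.
    """
    if model.input_scaler is None or model.output_scaler is None:
        raise ValueError("model must carry input and output scalers")
    ages = grid.ages
    x = model.input_scaler.apply(ages)
    y = model.forward(x)
    thickness = model.output_scaler.invert(y)
    return TrajectoryCurve(
        region=model.region,
        hemisphere=model.hemisphere,
        grid=grid,
        thickness=np.asarray(thickness, dtype=float),
        extrapolated=~model.input_scaler.contains(ages),
    )


def analytic_curve_derivative(model: MLPModel, grid: AgeGrid) -> np.ndarray:
    """Closed-form d(thickness)/d(age) in mm/year via the chain rule.

    Serves as the exact reference the finite-difference band should match
    on smooth model curves.
    """
    if model.input_scaler is None or model.output_scaler is None:
        raise ValueError("model must carry input and output scalers")
    x = np.asarray(model.input_scaler.apply(grid.ages), dtype=float)
    if model.n_hidden == 0:
        z = model.output_bias + model.direct_weight * x
        dy_dx = (1.0 - np.tanh(z) ** 2) * model.direct_weight
    else:
        a = np.tanh(model.input_biases + np.multiply.outer(x, model.input_weights))
        z = model.output_bias + a @ model.output_weights
        dy_dx = (1.0 - np.tanh(z) ** 2) * (
            (1.0 - a**2) @ (model.output_weights * model.input_weights)
        )
    dx_dage = 2.0 / (model.input_scaler.hi - model.input_scaler.lo)
    dthick_dy = (model.output_scaler.hi - model.output_scaler.lo) / 2.0
    return dy_dx * dx_dage * dthick_dy


def band_colors(derivative: np.ndarray, vmax: float) -> np.ndarray:
    """Map derivatives onto the diverging red/green/blue scale.

    The scale is symmetric about zero (limits are +-vmax) and a derivative
    of exactly 0 maps to the neutral green.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    u = np.clip(np.asarray(derivative, dtype=float) / vmax, -1.0, 1.0)
    colors = np.empty((u.size, 3))
    neg = u < 0
    colors[neg] = _COLOR_NEUTRAL + (-u[neg, None]) * (_COLOR_NEG - _COLOR_NEUTRAL)
    colors[~neg] = _COLOR_NEUTRAL + (u[~neg, None]) * (_COLOR_POS - _COLOR_NEUTRAL)
    return colors


def derivative_band(
    curve: TrajectoryCurve, n_points: int = 7, vmax: Optional[float] = None
) -> DerivativeBand:
    """Finite-difference derivative of a curve plus its color codes.

    ``vmax`` sets the color-scale limit; pass a shared value to make several
    bands comparable (default: this band's own max absolute derivative).
    """
    deriv = fdiff.differentiate(
        curve.thickness, step=curve.grid.step, n_points=n_points, order=1
    )
    if vmax is None:
        vmax = float(np.max(np.abs(deriv))) or 1.0
    return DerivativeBand(
        region=curve.region,
        hemisphere=curve.hemisphere,
        grid=curve.grid,
        derivative=deriv,
        color_codes=band_colors(deriv, vmax),
        vmax=vmax,
    )


def make_bands(
    curves: Sequence[TrajectoryCurve], n_points: int = 7
) -> list[DerivativeBand]:
    """Bands for a set of curves on one shared symmetric color scale."""
    derivs = [
        fdiff.differentiate(c.thickness, step=c.grid.step, n_points=n_points, order=1)
        for c in curves
    ]
    vmax = max(float(np.max(np.abs(d))) for d in derivs) or 1.0
    return [
        DerivativeBand(
            region=c.region,
            hemisphere=c.hemisphere,
            grid=c.grid,
            derivative=d,
            color_codes=band_colors(d, vmax),
            vmax=vmax,
        )
        for c, d in zip(curves, derivs)
    ]


def extreme_derivative_age(
    band: DerivativeBand, sign: int = -1, boundary_trim: int = 3
) -> float:
    """Age at which the derivative is most extreme in the given direction.

    The outermost ``boundary_trim`` nodes on each side are excluded: there
    the model sits at the edge of its data support and the stencil is fully
    one-sided, so small fit wobble can masquerade as the steepest change.
    """
    d = band.derivative
    if boundary_trim and 2 * boundary_trim < d.size:
        sl = slice(boundary_trim, d.size - boundary_trim)
    else:
        sl = slice(None)
    idx = np.argmin(d[sl]) if sign < 0 else np.argmax(d[sl])
    return float(band.grid.ages[sl][idx])


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster id per band, ids ordered by extreme age
    order: list  # band indices, same-cluster bands contiguous


def _extreme_age(grid: AgeGrid, profile: np.ndarray) -> float:
    return float(grid.ages[int(np.argmax(np.abs(profile)))])


def cluster_regions(bands: Sequence[DerivativeBand], k: int = 6) -> ClusterResult:
    """Group regions by similarity of their derivative profiles.

    Agglomerative clustering with correlation distance and average linkage,
    cut into ``k`` clusters.  Clusters are renumbered by the age at which
    their mean profile is most extreme, and the returned ordering keeps
    same-cluster regions contiguous (sorted within a cluster by each
    region's own extreme-derivative age, then name) — deterministic with no
    random state.
    """
    n = len(bands)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= {n} bands, got k={k}")
    profiles = np.vstack([b.derivative for b in bands])
    if k == 1 or n == 1:
        raw = np.ones(n, dtype=int)
    else:
        dist = pdist(profiles, metric="correlation")
        raw = fcluster(linkage(dist, method="average"), t=k, criterion="maxclust")
    grid = bands[0].grid
    centroid_age = {
        c: _extreme_age(grid, profiles[raw == c].mean(axis=0)) for c in np.unique(raw)
    }
    relabel = {
        c: i + 1
        for i, c in enumerate(sorted(centroid_age, key=lambda c: centroid_age[c]))
    }
    labels = np.array([relabel[c] for c in raw])
    order = sorted(
        range(n),
        key=lambda i: (
            labels[i],
            _extreme_age(grid, profiles[i]),
            str(bands[i].region),
            str(bands[i].hemisphere),
        ),
    )
    return ClusterResult(labels=labels, order=order)


@dataclass
class SummaryTables:
    extremes: pd.DataFrame  # window, lowest/highest mean-thickness region
    variability: pd.DataFrame  # window, lowest/highest curve-SD region
    linearity: pd.DataFrame  # window, lowest/highest line-R2 region
    per_region: pd.DataFrame  # column, ann_mse, linear_mse (scaled units)


def _line_r2(x: np.ndarray, y: np.ndarray) -> float:
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0  # a constant curve is fit exactly by a line
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def summarize(
    models: Mapping[str, MLPModel],
    grid: AgeGrid,
    cohort: Optional[Cohort] = None,
    windows: Optional[Mapping[str, float]] = None,
) -> SummaryTables:
    """Lifespan summary tables over the model set.

    ``windows`` maps a label to a minimum age (the window is age >= that
    value intersected with the grid); the default mirrors the whole-life,
    40-plus and 60-plus windows.  When a cohort is given, the per-region
    table also reports each network's MSE against the scaled data next to
    the MSE of an ordinary least-squares line fit to the same scaled data.
    """
    if windows is None:
        windows = {"all": grid.start, "ge40": 40.0, "ge60": 60.0}
    ages = grid.ages
    curves = {col: predict_curve(m, grid).thickness for col, m in models.items()}
    cols = list(models)

    ext_rows, var_rows, lin_rows = [], [], []
    for label, age_min in windows.items():
        mask = ages >= age_min
        if not mask.any():
            raise ValueError(f"window {label!r} (age >= {age_min}) misses the grid")
        means = {c: float(curves[c][mask].mean()) for c in cols}
        sds = {c: float(curves[c][mask].std()) for c in cols}
        r2s = {c: _line_r2(ages[mask], curves[c][mask]) for c in cols}
        ext_rows.append(
            {
                "window": label,
                "lowest_thickness": min(means, key=means.get),
                "highest_thickness": max(means, key=means.get),
            }
        )
        var_rows.append(
            {
                "window": label,
                "metric": "curve_sd",
                "lowest_variability": min(sds, key=sds.get),
                "highest_variability": max(sds, key=sds.get),
            }
        )
        lin_rows.append(
            {
                "window": label,
                "metric": "line_r2",
                "lowest_linearity": min(r2s, key=r2s.get),
                "highest_linearity": max(r2s, key=r2s.get),
            }
        )

    per_rows = []
    if cohort is not None:
        cohort_ages = cohort.ages
        for col in cols:
            m = models[col]
            x = m.input_scaler.apply(cohort_ages)
            t = m.output_scaler.apply(cohort.frame[col].to_numpy(dtype=float))
            ann_mse = float(np.mean((m.forward(x) - t) ** 2))
            coef = np.polyfit(x, t, 1)
            linear_mse = float(np.mean((np.polyval(coef, x) - t) ** 2))
            per_rows.append(
                {"column": col, "ann_mse": ann_mse, "linear_mse": linear_mse}
            )
    return SummaryTables(
        extremes=pd.DataFrame(ext_rows),
        variability=pd.DataFrame(var_rows),
        linearity=pd.DataFrame(lin_rows),
        per_region=pd.DataFrame(per_rows, columns=["column", "ann_mse", "linear_mse"]),
    )
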