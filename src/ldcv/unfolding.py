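"""Unfolding: recover true vesicle-size distributions from section data.

The observed histogram of apparent section diameters is modelled as a
weighted mixture of the forward template's columns — each column being
the section-diameter distribution of one true-diameter subpopulation.
The weights are estimated by nonnegative least squares (negative
subpopulation fractions being meaningless) and goodness of fit is
summarised by the squared Pearson correlation between observed and
predicted bin frequencies, the "linear-regression R^2" convention used
for this corpuscle-style deconvolution.

No smoothing or explicit regularisation is applied; the coarse 25-nm
binning itself conditions the problem, and the template's condition
number is recorded in the fit metadata for diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .geometry import ApparentHistogram, DiameterGrid, ForwardTemplate, PopulationWeights

__all__ = [
    "UnfoldFit",
    "BandFractionSummary",
    "Peak",
    "fit_weights",
    "band_fractions",
    "population_peaks",
    "write_fit",
    "read_fit",
]

#: Weights smaller than this after normalisation are reported as exactly 0.
WEIGHT_FLOOR = 1e-9

#: Default diameter-band edges (nm) for population summaries.
DEFAULT_BAND_EDGES = (150.0, 250.0, 350.0, 450.0, 650.0)


@dataclass
class UnfoldFit:
    """Fitted subpopulation weights plus fit diagnostics."""

    weights: PopulationWeights
    predicted: ApparentHistogram
    residual_norm: float
    r_squared: float
    n_observed: float
    metadata: dict = field(default_factory=dict)


def _pearson_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(np.clip(r * r, 0.0, 1.0))


def _uncentered_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    denom = np.linalg.norm(y) * np.linalg.norm(yhat)
    if denom == 0:
        return 0.0
    return float((np.dot(y, yhat) / denom) ** 2)


def fit_weights(
    observed: ApparentHistogram,
    template: ForwardTemplate,
    nonnegative: bool = True,
) -> UnfoldFit:
    """Least-squares mixture weights matching an observed histogram.

    Minimises ``|| template @ w - observed_frequencies ||`` subject to
    ``w >= 0`` (default; set ``nonnegative=False`` for an unconstrained
    diagnostic fit).  Weights are normalised to sum to 1.  ``r_squared``
    is the squared Pearson correlation between observed and predicted
    normalised bin frequencies; an intercept-free (uncentered) variant is
    recorded in the metadata.
    """
    if observed.grid != template.apparent_grid:
        raise ValueError("observed histogram and template use different apparent grids")
    if observed.total <= 0:
        raise ValueError("observed histogram has no counts")

    y = observed.frequencies
    A = template.matrix
    if nonnegative:
        w_raw, residual = nnls(A, y)
    else:
        w_raw, *_ = np.linalg.lstsq(A, y, rcond=None)
        residual = float(np.linalg.norm(A @ w_raw - y))
        w_raw = np.clip(w_raw, 0.0, None)  # reporting convention only

    total = w_raw.sum()
    if total <= 0:
        raise ValueError("fit degenerated to all-zero weights")
    w = w_raw / total
    w[w < WEIGHT_FLOOR] = 0.0
    w = w / w.sum()

    pred_raw = A @ w_raw
    pred = pred_raw / pred_raw.sum()
    r2 = _pearson_r2(y, pred)
    return UnfoldFit(
        weights=PopulationWeights(template.true_grid, w),
        predicted=ApparentHistogram(template.apparent_grid, pred),
        residual_norm=float(residual),
        r_squared=r2,
        n_observed=observed.total,
        metadata={
            "nonnegative": nonnegative,
            "r_squared_uncentered": _uncentered_r2(y, pred),
            "template_condition_number": template.condition_number(),
            "template_hash": template.content_hash(),
            "detection_floor_nm": template.model.min_detectable_diameter,
        },
    )


@dataclass
class BandFractionSummary:
    """Population weight aggregated into named diameter bands (percent).

    ``band_edges`` of length k define k-1 half-open bands
    [e_i, e_{i+1}); weight whose bin representative falls below the first
    edge or at/above the last edge is reported separately so the three
    parts always total 100%.
    """

    band_edges: tuple
    percents: np.ndarray
    below_percent: float
    above_percent: float

    def as_dict(self) -> dict:
        d = {
            f"{lo:g}-{hi:g} nm": float(p)
            for (lo, hi), p in zip(
                zip(self.band_edges[:-1], self.band_edges[1:]), self.percents
            )
        }
        d[f"<{self.band_edges[0]:g} nm"] = self.below_percent
        d[f">={self.band_edges[-1]:g} nm"] = self.above_percent
        return d


def band_fractions(
    weights: PopulationWeights,
    band_edges=DEFAULT_BAND_EDGES,
) -> BandFractionSummary:
    """Aggregate normalised weight into diameter bands, as percentages.

    Band membership is decided by each bin's representative diameter.
    """
    edges = np.asarray(band_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be increasing with at least two values")
    grid_lo = weights.grid.bin_edges[0]
    grid_hi = weights.grid.bin_edges[-1]
    if edges[0] < grid_lo or edges[-1] > grid_hi:
        raise ValueError(
            f"bands [{edges[0]:g}, {edges[-1]:g}] fall outside the grid "
            f"range [{grid_lo:g}, {grid_hi:g}]"
        )
    w = weights.normalized()
    reps = weights.grid.representatives
    percents = np.empty(edges.size - 1)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        percents[i] = 100.0 * w[(reps >= lo) & (reps < hi)].sum()
    below = 100.0 * w[reps < edges[0]].sum()
    above = 100.0 * w[reps >= edges[-1]].sum()
    return BandFractionSummary(tuple(edges), percents, float(below), float(above))


@dataclass
class Peak:
    """A local maximum of the fitted weight vector."""

    bin_index: int
    lower: float
    upper: float
    representative: float
    weight: float


def population_peaks(weights: PopulationWeights) -> list[Peak]:
    """Local maxima of the weight vector, ordered by decreasing weight.

    A bin is a peak when strictly greater than both neighbours; a flat
    run of equal maximal bins counts once, at its leftmost bin; the grid
    boundaries act as minus infinity (a monotone increasing profile peaks
    at its last bin).  Bins with zero weight are never peaks.
    """
    w = weights.normalized()
    n = w.size
    peaks: list[Peak] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and w[j + 1] == w[i]:
            j += 1  # plateau [i, j]
        left = w[i - 1] if i > 0 else -np.inf
        right = w[j + 1] if j + 1 < n else -np.inf
        if w[i] > 0 and w[i] > left and w[i] > right:
            grid = weights.grid
            peaks.append(
                Peak(
                    bin_index=i,
                    lower=float(grid.lower_edges[i]),
                    upper=float(grid.upper_edges[i]),
                    representative=float(grid.representatives[i]),
                    weight=float(w[i]),
                )
            )
        i = j + 1
    peaks.sort(key=lambda p: (-p.weight, p.bin_index))
    return peaks


def write_fit(fit: UnfoldFit, path, metadata_path=None) -> None:
    """Serialise a fit as delimited text plus a JSON metadata sidecar."""
    grid = fit.weights.grid
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("bin_lower_nm,bin_upper_nm,weight\n")
        for lo, hi, w in zip(grid.lower_edges, grid.upper_edges, fit.weights.weights):
            fh.write(f"{lo:g},{hi:g},{float(w)!r}\n")
    meta = dict(fit.metadata)
    meta.update(
        r_squared=fit.r_squared,
        residual_norm=fit.residual_norm,
        n_observed=fit.n_observed,
        representative=grid.representative,
    )
    sidecar = metadata_path or (str(path) + ".meta.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_fit(path, metadata_path=None) -> tuple[PopulationWeights, dict]:
    """Read back a serialised fit: (weights, metadata)."""
    rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    edges = np.append(rows[:, 0], rows[-1, 1])
    sidecar = metadata_path or (str(path) + ".meta.json")
    with open(sidecar, "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    grid = DiameterGrid(edges, representative=meta.get("representative", "upper"))
    return PopulationWeights(grid, rows[:, 2]), meta
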