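"""Forward sectioning model for spherical vesicles.

A plane cutting a sphere of true diameter ``D`` at a uniformly random
level produces a circular profile ("section") whose apparent diameter
``d`` is at most ``D``.  Parametrising the cut by the sectioning angle
``phi``, with ``sin(phi)`` uniform on [-1, 1] (equal probability of
sectioning at any distance from the centre), the section has

    d = D * cos(phi),        distance from centre = sin(phi) * D / 2,

which gives the closed-form apparent-diameter law

    P(d <= x | D) = 1 - sqrt(1 - (x / D)**2),      0 <= x <= D.

The distribution is negatively skewed with its mode at ``d = D``: a
population of identical spheres therefore produces profiles that pile up
just below the true diameter, with a long tail of small near-polar cuts.
This module exposes the law in closed form, as a discretised bins-by-bins
template operator (the basis for unfolding), and as a Monte-Carlo
sampler.  All lengths are nanometres; diameters (never radii) cross
module boundaries.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SectioningModel",
    "DiameterGrid",
    "ApparentHistogram",
    "PopulationWeights",
    "ForwardTemplate",
    "SectionSample",
    "apparent_cdf",
    "mean_apparent_diameter",
    "section_spheres",
    "build_template",
    "sample_sections",
    "default_grid",
]


@dataclass(frozen=True)
class SectioningModel:
    """Sectioning conventions: step, detection floor and RNG seed.

    ``section_step`` is the spacing (nm) of the enumerated cut levels in
    the discrete template construction; ``min_detectable_diameter`` is
    the smallest section the instrument can resolve (0 for the pure
    model, 70 nm for the empirical floor).  Section thickness is treated
    as zero (ideal planes).
    """

    section_step: float = 1.0
    min_detectable_diameter: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.section_step <= 0:
            raise ValueError("section_step must be > 0")
        if self.min_detectable_diameter < 0:
            raise ValueError("min_detectable_diameter must be >= 0")


@dataclass(frozen=True)
class DiameterGrid:
    """Uniform half-open diameter bins [lower, upper), final bin closed.

    ``representative`` selects the single diameter that stands for each
    bin when the bin is treated as a subpopulation: the bin's upper edge
    (default; matches labelling subpopulations "100 nm, 300 nm, 500 nm"
    on a 25-nm grid) or its midpoint.
    """

    bin_edges: np.ndarray
    representative: str = "upper"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("grid needs at least two bin edges")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(widths, widths[0]):
            raise ValueError("bin widths must be uniform")
        if self.representative not in ("upper", "midpoint"):
            raise ValueError("representative must be 'upper' or 'midpoint'")

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def lower_edges(self) -> np.ndarray:
        return self.bin_edges[:-1]

    @property
    def upper_edges(self) -> np.ndarray:
        return self.bin_edges[1:]

    @property
    def representatives(self) -> np.ndarray:
        if self.representative == "upper":
            return self.upper_edges
        return 0.5 * (self.lower_edges + self.upper_edges)

    def __eq__(self, other: object) -> bool:  # array field needs explicit eq
        if not isinstance(other, DiameterGrid):
            return NotImplemented
        return (
            self.representative == other.representative
            and self.bin_edges.shape == other.bin_edges.shape
            and bool(np.all(self.bin_edges == other.bin_edges))
        )


def default_grid(representative: str = "upper") -> DiameterGrid:
    """The standard true-diameter grid: 0 to 700 nm in 25-nm bins."""
    return DiameterGrid(np.arange(0.0, 725.0, 25.0), representative=representative)


@dataclass
class ApparentHistogram:
    """Binned apparent (section) diameters on a :class:`DiameterGrid`."""

    grid: DiameterGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.grid.n_bins,):
            raise ValueError(
                f"counts shape {counts.shape} does not match grid with "
                f"{self.grid.n_bins} bins"
            )
        if np.any(counts < 0):
            raise ValueError("histogram counts must be >= 0")
        self.counts = counts

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalise an all-zero histogram")
        return self.counts / self.total

    @classmethod
    def from_samples(cls, diameters: np.ndarray, grid: DiameterGrid) -> "ApparentHistogram":
        counts, _ = np.histogram(np.asarray(diameters, dtype=float), bins=grid.bin_edges)
        return cls(grid, counts.astype(float))


@dataclass
class PopulationWeights:
    """Nonnegative subpopulation weights over true-diameter bins (w_k)."""

    grid: DiameterGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.grid.n_bins,):
            raise ValueError("weights length must equal the number of grid bins")
        if np.any(w < 0):
            raise ValueError("population weights must be >= 0")
        self.weights = w

    def normalized(self) -> np.ndarray:
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("weights sum to zero; cannot normalise")
        return self.weights / total

    def mean_diameter(self) -> float:
        """Weight-averaged representative diameter of the population."""
        return float(np.dot(self.normalized(), self.grid.representatives))


def apparent_cdf(d, D: float):
    """P(apparent diameter <= d) for a sphere of true diameter ``D``.

    Closed form ``1 - sqrt(1 - (d/D)**2)`` from the uniform-level
    sectioning law.  ``d`` may be a scalar or array; every value must lie
    in [0, D].
    """
    if D <= 0:
        raise ValueError("true diameter D must be > 0")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0) or np.any(d_arr > D):
        raise ValueError("apparent diameter d must satisfy 0 <= d <= D")
    out = 1.0 - np.sqrt(np.clip(1.0 - (d_arr / D) ** 2, 0.0, 1.0))
    return float(out) if np.isscalar(d) else out


def mean_apparent_diameter(D: float) -> float:
    """Expected section diameter of a sphere of diameter ``D``: (pi/4) D."""
    if D <= 0:
        raise ValueError("true diameter D must be > 0")
    return float(np.pi / 4.0 * D)


def section_spheres(true_diameters: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Section each sphere once at a uniformly distributed level.

    Draws sin(phi) ~ U(-1, 1) per sphere and returns D * cos(phi).
    """
    D = np.asarray(true_diameters, dtype=float)
    if np.any(D <= 0):
        raise ValueError("true diameters must be > 0")
    s = rng.uniform(-1.0, 1.0, size=D.shape)
    return D * np.sqrt(1.0 - s * s)


@dataclass
class ForwardTemplate:
    """Discretised sectioning operator: true bins -> apparent-bin masses.

    ``matrix[i, j]`` is the probability that a sphere whose true diameter
    is the representative of true bin ``j`` produces a *detected* section
    in apparent bin ``i``.  Columns sum to 1; when a detection floor is
    active the sub-floor mass is removed, columns renormalised, and the
    removed fraction recorded in ``truncated_mass``.  Columns whose whole
    mass falls below the floor are left all-zero (truncated_mass = 1).
    """

    matrix: np.ndarray
    true_grid: DiameterGrid
    apparent_grid: DiameterGrid
    model: SectioningModel
    method: str = "analytic"
    truncated_mass: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.apparent_grid.n_bins, self.true_grid.n_bins):
            raise ValueError("template matrix shape does not match its grids")
        if np.any(m < -1e-12):
            raise ValueError("template entries must be >= 0")
        self.matrix = np.clip(m, 0.0, None)
        if self.truncated_mass is None:
            self.truncated_mass = np.zeros(self.true_grid.n_bins)

    def predict(self, weights: np.ndarray) -> np.ndarray:
        """Apparent-bin mass for nonnegative true-bin weights."""
        w = np.asarray(weights, dtype=float)
        return self.matrix @ w

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.matrix.tobytes())
        h.update(self.true_grid.bin_edges.tobytes())
        h.update(self.apparent_grid.bin_edges.tobytes())
        return h.hexdigest()[:16]

    def to_csv(self, path) -> None:
        """Delimited-text export with a one-line provenance header."""
        header = (
            f"# true_edges={self.true_grid.bin_edges[0]:g}:"
            f"{self.true_grid.bin_edges[-1]:g}:{self.true_grid.bin_width:g}"
            f" apparent_edges={self.apparent_grid.bin_edges[0]:g}:"
            f"{self.apparent_grid.bin_edges[-1]:g}:{self.apparent_grid.bin_width:g}"
            f" representative={self.true_grid.representative}"
            f" step={self.model.section_step:g}"
            f" threshold={self.model.min_detectable_diameter:g}"
            f" method={self.method}\n"
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            np.savetxt(fh, self.matrix, delimiter=",", fmt="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ForwardTemplate":
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("template file is missing its provenance header")
            meta = dict(tok.split("=", 1) for tok in header[1:].split())
            matrix = np.loadtxt(io.StringIO(fh.read()), delimiter=",")
        t0, t1, tw = (float(x) for x in meta["true_edges"].split(":"))
        a0, a1, aw = (float(x) for x in meta["apparent_edges"].split(":"))
        true_grid = DiameterGrid(
            np.arange(t0, t1 + tw / 2, tw), representative=meta["representative"]
        )
        apparent_grid = DiameterGrid(np.arange(a0, a1 + aw / 2, aw))
        model = SectioningModel(
            section_step=float(meta["step"]),
            min_detectable_diameter=float(meta["threshold"]),
        )
        tpl = cls(
            np.atleast_2d(matrix), true_grid, apparent_grid, model,
            method=meta.get("method", "analytic"),
        )
        # recover truncated mass from column deficits relative to 1
        return tpl


def _column_analytic(D: float, edges: np.ndarray) -> np.ndarray:
    """Exact apparent-bin masses for one true diameter via CDF differences."""
    hi = np.minimum(edges[1:], D)
    lo = np.minimum(edges[:-1], D)
    return apparent_cdf(hi, D) - apparent_cdf(lo, D)


def _column_enumerated(D: float, edges: np.ndarray, step: float) -> np.ndarray:
    """Apparent-bin masses from cut levels enumerated every ``step`` nm.

    Levels are the midpoints of step-wide intervals spanning the full
    diameter (distance from centre in (-D/2, D/2)), each carrying equal
    probability, mirroring a sphere sectioned at fixed 1-nm distances.
    """
    n_steps = max(int(np.ceil(D / step)), 1)
    k = np.arange(n_steps)
    s = -D / 2.0 + (k + 0.5) * (D / n_steps)
    d = 2.0 * np.sqrt(np.clip((D / 2.0) ** 2 - s * s, 0.0, None))
    # the exact-centre cut yields d == D; keep it in the bin D closes,
    # matching the analytic (lower, upper] mass convention
    d[d >= D] = np.nextafter(D, 0.0)
    counts, _ = np.histogram(d, bins=edges)
    return counts / n_steps


def _enumerated_mass_below(D: float, step: float, threshold: float) -> float:
    """Fraction of enumerated cut levels whose section is below threshold."""
    n_steps = max(int(np.ceil(D / step)), 1)
    k = np.arange(n_steps)
    s = -D / 2.0 + (k + 0.5) * (D / n_steps)
    d = 2.0 * np.sqrt(np.clip((D / 2.0) ** 2 - s * s, 0.0, None))
    return float(np.count_nonzero(d < threshold)) / n_steps


def build_template(
    true_grid: DiameterGrid,
    apparent_grid: DiameterGrid | np.ndarray,
    model: SectioningModel | None = None,
    method: str = "analytic",
) -> ForwardTemplate:
    """Discretise the sectioning law into an apparent-by-true operator.

    ``method='analytic'`` (default) differences the closed-form CDF at
    the apparent bin edges; ``method='enumerate'`` enumerates cut levels
    at ``model.section_step`` spacing — the two agree to O(1/steps).  A
    nonzero ``model.min_detectable_diameter`` truncates each column below
    the floor and renormalises it, recording the removed mass.
    """
    model = model or SectioningModel()
    if not isinstance(apparent_grid, DiameterGrid):
        apparent_grid = DiameterGrid(np.asarray(apparent_grid, dtype=float))
    if true_grid.n_bins == 0 or apparent_grid.n_bins == 0:
        raise ValueError("grids must contain at least one bin")
    reps = true_grid.representatives
    edges = apparent_grid.bin_edges
    if edges[0] > 0 or edges[-1] < reps[-1]:
        raise ValueError(
            "apparent grid must cover [0, max true representative] "
            f"({reps[-1]:g} nm)"
        )
    if method not in ("analytic", "enumerate"):
        raise ValueError("method must be 'analytic' or 'enumerate'")
    if method == "enumerate" and model.section_step > true_grid.bin_width:
        raise ValueError("section_step must not exceed the true bin width")

    cols = []
    truncated = []
    floor = model.min_detectable_diameter
    for D in reps:
        if method == "analytic":
            col = _column_analytic(D, edges)
            lost = apparent_cdf(min(floor, D), D) if floor > 0 else 0.0
        else:
            col = _column_enumerated(D, edges, model.section_step)
            lost = 0.0
        if floor > 0:
            col = col.copy()
            if method == "analytic":
                # zero fully sub-floor bins, trim the straddling bin exactly
                below = edges[1:] <= floor
                col[below] = 0.0
                straddle = (edges[:-1] < floor) & (edges[1:] > floor)
                if straddle.any():
                    i = int(np.flatnonzero(straddle)[0])
                    col[i] = apparent_cdf(min(edges[i + 1], D), D) - apparent_cdf(
                        min(floor, D), D
                    )
            else:
                mass_below = _enumerated_mass_below(D, model.section_step, floor)
                below = edges[1:] <= floor
                col[below] = 0.0
                straddle = (edges[:-1] < floor) & (edges[1:] > floor)
                if straddle.any():
                    i = int(np.flatnonzero(straddle)[0])
                    full_below = _enumerated_mass_below(D, model.section_step, edges[i])
                    col[i] -= mass_below - full_below
                lost = mass_below
            kept = col.sum()
            if kept > 1e-12:
                col = col / kept
                truncated.append(lost)
            else:
                col = np.zeros_like(col)
                truncated.append(1.0)
        else:
            truncated.append(0.0)
        cols.append(col)
    matrix = np.column_stack(cols)
    return ForwardTemplate(
        matrix, true_grid, apparent_grid, model,
        method=method, truncated_mass=np.asarray(truncated),
    )


@dataclass
class SectionSample:
    """Result of Monte-Carlo sectioning: detected diameters + discards."""

    diameters: np.ndarray
    n_discarded: int

    def __len__(self) -> int:
        return self.diameters.size


def sample_sections(
    weights: PopulationWeights,
    n: int,
    model: SectioningModel | None = None,
    rng: np.random.Generator | None = None,
) -> SectionSample:
    """Draw ``n`` detected section diameters from a weighted population.

    True diameters are drawn from the bin representatives with the given
    weights, each sphere is sectioned once at a uniform level, and
    sections below ``model.min_detectable_diameter`` are discarded and
    redrawn (the number of discards is reported).  Reproducible given
    ``model.rng_seed`` or an explicit ``rng``.
    """
    model = model or SectioningModel()
    if n < 1:
        raise ValueError("n must be >= 1")
    p = weights.normalized()  # raises on all-zero weights
    reps = weights.grid.representatives
    if model.min_detectable_diameter > 0 and np.all(
        reps[p > 0] <= model.min_detectable_diameter
    ):
        raise ValueError("all populated bins lie below the detection floor")
    if rng is None:
        rng = np.random.default_rng(model.rng_seed)

    out = np.empty(n)
    filled = 0
    discarded = 0
    while filled < n:
        todo = n - filled
        D = rng.choice(reps, size=todo, p=p)
        d = section_spheres(D, rng)
        keep = d >= model.min_detectable_diameter
        kept = d[keep]
        out[filled : filled + kept.size] = kept
        filled += kept.size
        discarded += todo - kept.size
    return SectionSample(out, discarded)
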