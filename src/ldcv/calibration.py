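"""Calibration of true-diameter mixtures against printed group summaries.

The generator's true populations are truncated-Gaussian mixtures whose
parameters were chosen — once, by the search implemented here — so that
after forward sectioning and the 70–650 nm detection window the
*detected section* diameters reproduce a target (mean, median) pair.
The search uses common random numbers (a fixed standard-normal /
uniform-level sample reused across candidate parameters) so the
objective is smooth enough for Nelder–Mead.

Only summary statistics are emulated: the calibrated mixtures are a
stated world consistent with printed group means/medians, not a
reconstruction of unpublished raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "MixtureComponent",
    "sample_true_diameters",
    "sample_detected_sections",
    "detected_section_stats",
    "calibrate_mixture",
    "DETECTION_FLOOR",
    "DETECTION_CEILING",
    "TRUE_DIAMETER_MAX",
]

DETECTION_FLOOR = 70.0     # nm, smallest measurable section
DETECTION_CEILING = 650.0  # nm, largest measured section
TRUE_DIAMETER_MAX = 700.0  # nm, upper edge of the unfolding grid


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian subpopulation of true vesicle diameters."""

    mean: float
    sd: float
    fraction: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("component sd must be > 0")
        if not 0 < self.fraction <= 1:
            raise ValueError("component fraction must be in (0, 1]")


def _validate(components) -> list[MixtureComponent]:
    comps = list(components)
    if not comps:
        raise ValueError("mixture needs at least one component")
    total = sum(c.fraction for c in comps)
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"mixture fractions sum to {total:g}, not 1")
    return comps


def sample_true_diameters(components, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw true diameters, truncated by redraw to (0, 700] nm."""
    comps = _validate(components)
    means = np.array([c.mean for c in comps])
    sds = np.array([c.sd for c in comps])
    fracs = np.array([c.fraction for c in comps])
    out = np.empty(n)
    filled = 0
    while filled < n:
        todo = n - filled
        idx = rng.choice(len(comps), size=todo, p=fracs)
        D = rng.normal(means[idx], sds[idx])
        D = D[(D > 0) & (D <= TRUE_DIAMETER_MAX)]
        out[filled : filled + D.size] = D
        filled += D.size
    return out


def sample_detected_sections(
    components,
    n: int,
    rng: np.random.Generator,
    floor: float = DETECTION_FLOOR,
    ceiling: float = DETECTION_CEILING,
):
    """Draw ``n`` detected (true, apparent) pairs; count the discards.

    Each sphere is sectioned once at a uniform level; sections outside
    the detection window are discarded and a fresh sphere is drawn, so
    the output reflects what the microscope would deliver.
    Returns ``(true_diameters, apparent_diameters, n_discarded)``.
    """
    true_out = np.empty(n)
    app_out = np.empty(n)
    filled = 0
    discarded = 0
    guard = 0
    while filled < n:
        todo = n - filled
        D = sample_true_diameters(components, todo, rng)
        u = rng.uniform(-1.0, 1.0, size=todo)
        d = D * np.sqrt(1.0 - u * u)
        keep = (d >= floor) & (d <= ceiling)
        kept = int(keep.sum())
        true_out[filled : filled + kept] = D[keep]
        app_out[filled : filled + kept] = d[keep]
        filled += kept
        discarded += todo - kept
        guard += 1
        if guard > 1000 and filled == 0:
            raise ValueError(
                "mixture places essentially no sections inside the "
                f"detection window [{floor:g}, {ceiling:g}] nm"
            )
    return true_out, app_out, discarded


def _crn_apparent(means, sds, comp_idx, z, u, floor, ceiling):
    D = means[comp_idx] + sds[comp_idx] * z
    ok = (D > 0) & (D <= TRUE_DIAMETER_MAX)
    d = D * np.sqrt(1.0 - u * u)
    ok &= (d >= floor) & (d <= ceiling)
    return d[ok]


def detected_section_stats(
    components,
    n: int = 400_000,
    seed: int = 20_240_901,
    floor: float = DETECTION_FLOOR,
    ceiling: float = DETECTION_CEILING,
) -> tuple[float, float]:
    """(mean, median) of detected sections, by fixed-seed Monte Carlo."""
    comps = _validate(components)
    rng = np.random.default_rng(seed)
    fracs = np.array([c.fraction for c in comps])
    comp_idx = rng.choice(len(comps), size=n, p=fracs)
    z = rng.standard_normal(n)
    u = rng.uniform(-1.0, 1.0, size=n)
    means = np.array([c.mean for c in comps])
    sds = np.array([c.sd for c in comps])
    d = _crn_apparent(means, sds, comp_idx, z, u, floor, ceiling)
    return float(d.mean()), float(np.median(d))


def calibrate_mixture(
    components,
    target_mean: float,
    target_median: float,
    vary: str = "means",
    n: int = 400_000,
    seed: int = 20_240_901,
) -> list[MixtureComponent]:
    """Adjust a mixture so detected sections hit a (mean, median) target.

    ``vary='means'`` shifts the component means (fractions and SDs
    fixed); ``vary='mean_sd'`` adjusts the single component's mean and
    SD.  The objective is evaluated on a fixed common-random-numbers
    sample and minimised by Nelder–Mead.
    """
    comps = _validate(components)
    rng = np.random.default_rng(seed)
    fracs = np.array([c.fraction for c in comps])
    comp_idx = rng.choice(len(comps), size=n, p=fracs)
    z = rng.standard_normal(n)
    u = rng.uniform(-1.0, 1.0, size=n)
    sds = np.array([c.sd for c in comps])
    means0 = np.array([c.mean for c in comps])

    if vary == "means":
        def unpack(x):
            return x, sds
        x0 = means0
    elif vary == "mean_sd":
        if len(comps) != 1:
            raise ValueError("vary='mean_sd' requires a single component")
        def unpack(x):
            return np.array([x[0]]), np.array([abs(x[1])])
        x0 = np.array([means0[0], sds[0]])
    else:
        raise ValueError("vary must be 'means' or 'mean_sd'")

    def objective(x):
        means, s = unpack(x)
        d = _crn_apparent(means, s, comp_idx, z, u, DETECTION_FLOOR, DETECTION_CEILING)
        if d.size < n // 10:
            return 1e6
        return (d.mean() - target_mean) ** 2 + (np.median(d) - target_median) ** 2

    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"xatol": 0.01, "fatol": 1e-4, "maxiter": 2000})
    means, s = unpack(res.x)
    return [
        replace(c, mean=float(m), sd=float(sd_))
        for c, m, sd_ in zip(comps, means, s)
    ]
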