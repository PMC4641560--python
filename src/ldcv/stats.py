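"""Distribution comparisons and colocalization summaries.

Two-sample Kolmogorov–Smirnov tests compare section-diameter
distributions between strains or regions (D = sup |ECDF_x - ECDF_y|,
two-tailed p asymptotic by default, exact optionally for small samples).
Descriptive group summaries use linear-interpolation quartiles.
Vesicle-level colocalization is the percentage of profiles carrying both
an N/E marker and NPY, with the denominator convention (all N/E-labeled
or all NPY-labeled profiles) recorded in every result.  Cell-level
coexpression compares per-animal percentages of DbH-immunoreactive cell
bodies that also express NPY, by unpaired two-tailed t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .measurements import CellCountRecord, MeasurementSet

__all__ = [
    "KSResult",
    "GroupSummary",
    "ColocalizationFraction",
    "CoexpressionComparison",
    "ks_two_sample",
    "summarize",
    "colocalization_fraction",
    "cell_coexpression_stats",
]

#: Exact KS p-values are offered only when n_x * n_y is at most this.
EXACT_KS_LIMIT = 10_000


@dataclass(frozen=True)
class KSResult:
    d_statistic: float
    p_value: float
    n_x: int
    n_y: int
    method: str  # "asymptotic" or "exact"

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def ks_two_sample(x, y, method: str = "asymptotic") -> KSResult:
    """Two-sample two-tailed Kolmogorov–Smirnov test.

    ``method='asymptotic'`` (default) uses the Kolmogorov limiting
    distribution with the standard effective-sample-size scaling;
    ``'exact'`` enumerates the null distribution and is allowed only for
    ``n_x * n_y <= 10_000``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires at least one observation per sample")
    if method not in ("asymptotic", "exact"):
        raise ValueError("method must be 'asymptotic' or 'exact'")
    if method == "exact" and x.size * y.size > EXACT_KS_LIMIT:
        raise ValueError(
            f"exact KS enumeration limited to n_x*n_y <= {EXACT_KS_LIMIT}"
        )
    scipy_method = {"asymptotic": "asymp", "exact": "exact"}[method]
    res = sps.ks_2samp(x, y, alternative="two-sided", method=scipy_method)
    return KSResult(
        d_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_x=int(x.size),
        n_y=int(y.size),
        method=method,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary of one diameter sample (box-plot quantities)."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float


def summarize(x) -> GroupSummary:
    """Mean/median/quartiles/range; quartiles by linear interpolation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return GroupSummary(
        n=int(x.size),
        mean=float(x.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        minimum=float(x.min()),
        maximum=float(x.max()),
    )


@dataclass(frozen=True)
class ColocalizationFraction:
    """Share of vesicle profiles carrying both an N/E marker and NPY."""

    numerator: int
    denominator: int
    denominator_convention: str  # "of_NE_labeled" or "of_NPY_labeled"

    @property
    def percent(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def percent_rounded(self) -> int:
        """Nearest-integer percent for headline tables."""
        return int(round(self.percent))


def colocalization_fraction(
    mset: MeasurementSet,
    region: str | None = None,
    strain: str | None = None,
    convention: str = "of_NE_labeled",
) -> ColocalizationFraction:
    """Colabeled fraction in a (region, strain) cell of the data.

    The numerator is always profiles with both an N/E marker and NPY;
    the denominator is either all N/E-labeled or all NPY-labeled
    profiles, per ``convention`` (the printed headline fractions use the
    N/E-labeled denominator).
    """
    if convention not in ("of_NE_labeled", "of_NPY_labeled"):
        raise ValueError(f"unknown denominator convention {convention!r}")
    sub = mset.subset(strain=strain, region=region).df
    ne = sub["ne_marker"].isin(("DbH", "VMAT2"))
    npy = sub["npy_label"].astype(bool)
    numerator = int((ne & npy).sum())
    denominator = int(ne.sum() if convention == "of_NE_labeled" else npy.sum())
    if denominator == 0:
        raise ValueError(
            f"no profiles in the denominator class ({convention}) for "
            f"region={region}, strain={strain}"
        )
    return ColocalizationFraction(numerator, denominator, convention)


@dataclass(frozen=True)
class CoexpressionComparison:
    """Cell-level NPY coexpression in DbH-ir cells, WR vs SHR."""

    region: str
    percents_wr: tuple
    percents_shr: tuple
    mean_wr: float
    sem_wr: float
    mean_shr: float
    sem_shr: float
    t_statistic: float
    p_value: float
    n_excluded: int


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def cell_coexpression_stats(
    records: list[CellCountRecord], region: str
) -> CoexpressionComparison:
    """Per-strain coexpression mean ± SEM and unpaired two-tailed t test.

    The per-animal statistic is 100 * n_coloc / (n_dbh_only + n_coloc).
    Animals with no DbH-ir cells are excluded with a warning.  Requires
    at least two animals per strain.
    """
    excluded = 0
    per_strain: dict[str, list[float]] = {"WR": [], "SHR": []}
    for rec in records:
        if rec.region != region:
            continue
        if rec.n_dbh_total == 0:
            warnings.warn(
                f"animal {rec.animal_id} ({rec.strain}, {region}) has no "
                "DbH-ir cells; excluded from coexpression stats",
                stacklevel=2,
            )
            excluded += 1
            continue
        per_strain[rec.strain].append(rec.coexpression_percent)
    wr = np.asarray(per_strain["WR"])
    shr = np.asarray(per_strain["SHR"])
    if wr.size < 2 or shr.size < 2:
        raise ValueError(
            f"need >= 2 animals per strain in {region}; "
            f"got WR={wr.size}, SHR={shr.size}"
        )
    if np.allclose(wr, wr[0]) and np.allclose(shr, shr[0]) and np.isclose(wr[0], shr[0]):
        t_stat, p_val = 0.0, 1.0  # degenerate: all animals identical
    else:
        res = sps.ttest_ind(wr, shr, equal_var=True, alternative="two-sided")
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return CoexpressionComparison(
        region=region,
        percents_wr=tuple(wr),
        percents_shr=tuple(shr),
        mean_wr=float(wr.mean()),
        sem_wr=_sem(wr),
        mean_shr=float(shr.mean()),
        sem_shr=_sem(shr),
        t_statistic=t_stat,
        p_value=p_val,
        n_excluded=excluded,
    )
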