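"""End-to-end analysis orchestration.

Reads (or generates) section measurements and confocal cell counts,
pools the N/E markers, applies the detection window, builds the forward
template, unfolds each region-by-strain group, and emits: group
summaries, unfolding fits with band fractions and peaks, the nine
WR-vs-SHR KS contrasts (three regions by three label classes),
vesicle-level colocalization under both denominator conventions, and
cell-level coexpression t tests — as tidy CSV tables plus a plain-text
summary and a JSON manifest.  Given the same config and seed the output
bundle is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .calibration import DETECTION_CEILING, DETECTION_FLOOR
from .geometry import (
    ApparentHistogram,
    SectioningModel,
    build_template,
    default_grid,
)
from .measurements import (
    MeasurementSet,
    filter_diameter_range,
    pool_ne_markers,
    read_cell_counts,
    read_sections,
    sections_from_frame,
    to_histogram,
    CELL_COUNT_REGIONS,
)
from .stats import (
    cell_coexpression_stats,
    colocalization_fraction,
    ks_two_sample,
    summarize,
)
from .unfolding import band_fractions, fit_weights, population_peaks, write_fit

__all__ = ["RunConfig", "ReportBundle", "run_analysis", "validate_inputs", "read_config"]

EM_REGIONS = ("NTS", "RVLM", "LC")
STRAINS = ("WR", "SHR")
LABEL_CLASSES = ("NE", "NPY", "coloc")


@dataclass
class RunConfig:
    """Validated settings for one analysis run.

    Either ``sections_path``/``cell_counts_path`` point at measurement
    files, or ``generate=True`` synthesises the default scenario from
    ``seed``.  All settings are serialised into the output manifest.
    """

    out_dir: str = "results/run"
    generate: bool = True
    seed: int = 1
    sections_path: str | None = None
    cell_counts_path: str | None = None
    bin_width: float = 25.0
    grid_max: float = 700.0
    detection_floor: float = DETECTION_FLOOR
    detection_ceiling: float = DETECTION_CEILING
    representative: str = "upper"
    denominator_convention: str = "of_NE_labeled"
    alpha: float = 0.05
    verbosity: int = 1

    def validate(self) -> None:
        if not self.generate and not self.sections_path:
            raise ValueError("either generate=True or sections_path is required")
        if self.bin_width <= 0 or self.grid_max <= 0:
            raise ValueError("bin_width and grid_max must be > 0")
        if self.grid_max % self.bin_width:
            raise ValueError("grid_max must be a multiple of bin_width")
        if not 0 <= self.detection_floor < self.detection_ceiling:
            raise ValueError("need 0 <= detection_floor < detection_ceiling")
        if self.representative not in ("upper", "midpoint"):
            raise ValueError("representative must be 'upper' or 'midpoint'")
        if self.denominator_convention not in ("of_NE_labeled", "of_NPY_labeled"):
            raise ValueError("unknown denominator convention")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig."""
    kwargs: dict = {}
    field_types = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line (need key = value): {raw!r}")
            key, value = (tok.strip() for tok in line.split("=", 1))
            if key not in field_types:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("generate",):
                kwargs[key] = value.lower() in ("true", "1", "yes")
            elif key in ("seed", "verbosity"):
                kwargs[key] = int(value)
            elif key in (
                "bin_width", "grid_max", "detection_floor",
                "detection_ceiling", "alpha",
            ):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    n_sections: int = 0
    n_cell_counts: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema and invariant checks with row-level diagnostics; read-only."""
    config.validate()
    report = ValidationReport()
    if config.generate:
        return report
    try:
        mset = read_sections(config.sections_path)
    except (OSError, ValueError) as exc:
        report.violations.append(f"sections: fatal: {exc}")
        return report
    if len(mset) == 0:
        report.violations.append("sections: fatal: file contains no valid rows")
    report.n_sections = len(mset)
    report.violations.extend(f"sections: {d}" for d in mset.diagnostics)
    if config.cell_counts_path:
        try:
            counts = read_cell_counts(config.cell_counts_path)
            report.n_cell_counts = len(counts)
        except (OSError, ValueError) as exc:
            report.violations.append(f"cell_counts: fatal: {exc}")
    return report


@dataclass
class ReportBundle:
    out_dir: Path
    group_fits: dict
    ks_contrasts: pd.DataFrame
    colocalization: pd.DataFrame
    summaries: pd.DataFrame
    manifest: dict

    def content_hash(self) -> str:
        """SHA-256 over every file written in the bundle, order-stable."""
        h = hashlib.sha256()
        for p in sorted(self.out_dir.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
        return h.hexdigest()


def _class_mask(df: pd.DataFrame, label_class: str) -> pd.Series:
    ne = df["ne_marker"].isin(("DbH", "VMAT2"))
    npy = df["npy_label"].astype(bool)
    return {"NE": ne, "NPY": npy, "coloc": ne & npy}[label_class]


def run_analysis(config: RunConfig) -> ReportBundle:
    """Run the full pipeline and write the report bundle.

    Produces, per region-by-strain group: descriptive summary, apparent
    histogram, unfolding fit (weights, R^2), band fractions and peaks;
    per region: WR-vs-SHR KS contrasts for the N/E-labeled, NPY-labeled
    and colabeled classes; plus colocalization and confocal coexpression
    tables.  Also fits the strain-pooled distributions (all regions
    combined), mirroring the whole-population reconstruction.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ inputs
    if config.generate:
        scenario = synthetic.default_paper_scenario(config.seed, out_dir=out / "data")
        sections, cell_counts = scenario.sections, scenario.cell_counts
    else:
        sections = read_sections(config.sections_path)
        cell_counts = (
            read_cell_counts(config.cell_counts_path)
            if config.cell_counts_path
            else []
        )
    if len(sections) == 0:
        raise ValueError("no valid section records to analyse")

    sections = pool_ne_markers(sections)
    sections = filter_diameter_range(
        sections, config.detection_floor, config.detection_ceiling
    )

    # ---------------------------------------------------------------- template
    grid = default_grid(config.representative)
    if config.grid_max != 700.0 or config.bin_width != 25.0:
        edges = np.arange(0.0, config.grid_max + config.bin_width / 2, config.bin_width)
        from .geometry import DiameterGrid

        grid = DiameterGrid(edges, representative=config.representative)
    model = SectioningModel(min_detectable_diameter=config.detection_floor)
    template = build_template(grid, grid, model)

    # ---------------------------------------------------- per-group unfolding
    fits_dir = out / "unfold_fits"
    fits_dir.mkdir(exist_ok=True)
    group_fits: dict = {}
    summary_rows = []
    band_rows = []
    peak_rows = []

    def analyse_group(key: str, mset: MeasurementSet):
        hist = to_histogram(mset, grid)
        fit = fit_weights(hist, template)
        gsum = summarize(mset.diameters)
        bands = band_fractions(fit.weights)
        peaks = population_peaks(fit.weights)
        group_fits[key] = fit
        write_fit(fit, fits_dir / f"{key}.csv")
        summary_rows.append(
            dict(group=key, n=gsum.n, mean_nm=gsum.mean, median_nm=gsum.median,
                 q1_nm=gsum.q1, q3_nm=gsum.q3, min_nm=gsum.minimum,
                 max_nm=gsum.maximum, r_squared=fit.r_squared)
        )
        band_rows.append({"group": key, **bands.as_dict()})
        for rank, pk in enumerate(peaks, start=1):
            peak_rows.append(
                dict(group=key, rank=rank, bin_lower_nm=pk.lower,
                     bin_upper_nm=pk.upper, weight=pk.weight)
            )

    ne_only = MeasurementSet(
        sections.df[sections.df["ne_labeled"]].reset_index(drop=True),
        source=sections.source, filters=sections.filters + ["ne_labeled only"],
    )
    for strain in STRAINS:
        for region in EM_REGIONS:
            sub = ne_only.subset(strain=strain, region=region)
            if len(sub) == 0:
                continue
            analyse_group(f"{strain}_{region}", sub)
        pooled = ne_only.subset(strain=strain)
        if len(pooled):
            analyse_group(f"{strain}_pooled", pooled)

    # ----------------------------------------------------------- KS contrasts
    ks_rows = []
    for region in EM_REGIONS:
        regional = sections.df[sections.df["region"] == region]
        for label_class in LABEL_CLASSES:
            mask = _class_mask(regional, label_class)
            x = regional[mask & (regional["strain"] == "WR")]["diameter"].to_numpy()
            y = regional[mask & (regional["strain"] == "SHR")]["diameter"].to_numpy()
            if x.size == 0 or y.size == 0:
                continue
            res = ks_two_sample(x, y)
            ks_rows.append(
                dict(region=region, label_class=label_class, n_wr=res.n_x,
                     n_shr=res.n_y, d_statistic=res.d_statistic,
                     p_value=res.p_value, method=res.method,
                     rejects=bool(res.rejects(config.alpha)))
            )
    ks_df = pd.DataFrame(ks_rows)

    # -------------------------------------------------------- colocalization
    coloc_rows = []
    for strain in STRAINS:
        for region in EM_REGIONS:
            for convention in ("of_NE_labeled", "of_NPY_labeled"):
                try:
                    frac = colocalization_fraction(
                        sections, region=region, strain=strain, convention=convention
                    )
                except ValueError:
                    continue
                coloc_rows.append(
                    dict(strain=strain, region=region, convention=convention,
                         n_coloc=frac.numerator, n_denominator=frac.denominator,
                         percent=round(frac.percent, 1),
                         percent_rounded=frac.percent_rounded,
                         is_default=convention == config.denominator_convention)
                )
    coloc_df = pd.DataFrame(coloc_rows)

    # --------------------------------------------------- confocal cell level
    coexp_rows = []
    for region in CELL_COUNT_REGIONS:
        try:
            cmp_ = cell_coexpression_stats(cell_counts, region)
        except ValueError:
            continue
        coexp_rows.append(
            dict(region=region, mean_wr=cmp_.mean_wr, sem_wr=cmp_.sem_wr,
                 mean_shr=cmp_.mean_shr, sem_shr=cmp_.sem_shr,
                 t_statistic=cmp_.t_statistic, p_value=cmp_.p_value,
                 n_wr=len(cmp_.percents_wr), n_shr=len(cmp_.percents_shr))
        )
    coexp_df = pd.DataFrame(coexp_rows)

    # ----------------------------------------------------------------- output
    summaries = pd.DataFrame(summary_rows)
    summaries.to_csv(out / "group_summaries.csv", index=False)
    pd.DataFrame(band_rows).to_csv(out / "band_fractions.csv", index=False)
    pd.DataFrame(peak_rows).to_csv(out / "population_peaks.csv", index=False)
    ks_df.to_csv(out / "ks_contrasts.csv", index=False)
    coloc_df.to_csv(out / "colocalization.csv", index=False)
    if len(coexp_df):
        coexp_df.to_csv(out / "confocal_coexpression.csv", index=False)

    manifest = {
        "config": dataclasses.asdict(config),
        "template_hash": template.content_hash(),
        "template_condition_number": template.condition_number(),
        "n_sections_analysed": len(sections),
        "n_removed_below": getattr(sections, "n_removed_below", 0),
        "n_removed_above": getattr(sections, "n_removed_above", 0),
        "groups": sorted(group_fits),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    lines = [
        "LDCV section analysis",
        f"sections analysed: {len(sections)} "
        f"(window {config.detection_floor:g}-{config.detection_ceiling:g} nm)",
        "",
        "group summaries (nm):",
    ]
    for row in summary_rows:
        lines.append(
            f"  {row['group']:>12}: n={row['n']:>4} mean={row['mean_nm']:6.1f} "
            f"median={row['median_nm']:6.1f} unfold R^2={row['r_squared']:.3f}"
        )
    lines.append("")
    lines.append(f"KS contrasts WR vs SHR (alpha={config.alpha:g}):")
    for row in ks_rows:
        verdict = "DIFFERENT" if row["rejects"] else "similar"
        lines.append(
            f"  {row['region']:>5} {row['label_class']:>6}: D={row['d_statistic']:.3f} "
            f"p={row['p_value']:.3g} ({verdict})"
        )
    lines.append("")
    lines.append(f"colocalization ({config.denominator_convention}):")
    for row in coloc_rows:
        if row["is_default"]:
            lines.append(
                f"  {row['strain']:>3} {row['region']:>5}: "
                f"{row['n_coloc']}/{row['n_denominator']} = {row['percent_rounded']}%"
            )
    (out / "summary.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")

    bundle = ReportBundle(
        out_dir=out, group_fits=group_fits, ks_contrasts=ks_df,
        colocalization=coloc_df, summaries=summaries, manifest=manifest,
    )
    if config.verbosity:
        print("\n".join(lines))
    return bundle
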