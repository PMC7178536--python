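"""File I/O, configuration and the end-to-end pipeline runner.

CSV is the sole tabular interchange format (decimal point, UTF-8, mandatory
header row); the configuration is a single human-editable key-value file in
INI syntax. ``run_pipeline`` composes simulation, calibration, relative
correction factors, retention-time peak location, dual-route quantification,
method comparison and chemometric grading into one reproducible run whose
outputs are byte-identical for a fixed config and seed.
"""
from __future__ import annotations

import configparser
import logging
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import chemometrics as chem
from . import quantification as quant
from . import synthetic_data as synth
from .calibration import CalibrationCurve, PeakRecord, PeakTable, RCFEntry, RCFSet, RRTable
from .errors import ConfigError, InvalidInputError, QAMSError, SchemaError, TableParseError
from .quantification import SamplePrep

logger = logging.getLogger("qams.interface")

_PEAK_META = ("instrument", "column", "flow_rate_ml_min",
              "column_temperature_c")
_PEAK_REQUIRED = ("sample_id", "rt_min", "area")


# ---------------------------------------------------------------------------
# peak-table CSV
# ---------------------------------------------------------------------------

def write_peak_table(table: PeakTable, path) -> None:
    """One row per peak with columns sample_id, rt_min, area, analyte plus
    the run metadata columns; extra columns are carried through."""
    rows = []
    for i, p in enumerate(table.peaks):
        row = {"sample_id": table.sample_id,
               "rt_min": p.retention_time,
               "area": p.area,
               "analyte": p.assigned_analyte or "",
               "instrument": table.instrument,
               "column": table.column,
               "flow_rate_ml_min": table.flow_rate_ml_min,
               "column_temperature_c": table.column_temperature_c}
        for key, values in table.extra.items():
            row[key] = values[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peak_table(path) -> PeakTable:
    """Inverse of :func:`write_peak_table`; unknown columns are preserved in
    ``PeakTable.extra``. Missing required columns raise a schema error; a
    non-numeric rt/area cell raises a parse error naming its row."""
    df = pd.read_csv(path, dtype={"analyte": str})
    for col in _PEAK_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in ("rt_min", "area"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise TableParseError(
                f"{path}: non-numeric {col!r} in data row "
                f"{int(bad.idxmax()) + 1}")
        df[col] = parsed
    known = set(_PEAK_REQUIRED) | set(_PEAK_META) | {"analyte"}
    extra = {c: tuple(df[c]) for c in df.columns if c not in known}
    peaks = tuple(
        PeakRecord(float(r.rt_min), float(r.area),
                   assigned_analyte=(str(r.analyte)
                                     if "analyte" in df.columns
                                     and pd.notna(r.analyte)
                                     and str(r.analyte) != "" else None))
        for r in df.itertuples())
    meta = {}
    for col, default in zip(_PEAK_META, ("default", "default", 1.0, 25.0)):
        meta[col] = type(default)(df[col].iloc[0]) if col in df.columns \
            else default
    return PeakTable(sample_id=str(df["sample_id"].iloc[0]), peaks=peaks,
                     extra=extra, **meta)


# ---------------------------------------------------------------------------
# other tabular serializations
# ---------------------------------------------------------------------------

def write_content_matrix(contents: pd.DataFrame, path) -> None:
    contents.rename_axis("batch").to_csv(path)


def read_content_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "batch" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'batch'")
    return df.set_index("batch")


def write_standard_series(series: Mapping[str, cal.StandardSeries],
                          path) -> None:
    rows = [{"analyte": code, "conc_ugml": c, "area": a}
            for code, s in series.items()
            for c, a in zip(s.concentrations, s.areas)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_standard_series(path) -> dict[str, cal.StandardSeries]:
    df = pd.read_csv(path)
    for col in ("analyte", "conc_ugml", "area"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = {}
    for code, grp in df.groupby("analyte", sort=False):
        grp = grp.sort_values("conc_ugml")
        out[str(code)] = cal.StandardSeries(
            str(code), tuple(grp["conc_ugml"].astype(float)),
            tuple(grp["area"].astype(float)))
    return out


def curves_to_frame(curves: Mapping[str, CalibrationCurve]) -> pd.DataFrame:
    return pd.DataFrame([
        {"analyte": c.analyte, "slope": c.slope, "intercept": c.intercept,
         "r": c.r, "range_min_ugml": c.linear_range[0],
         "range_max_ugml": c.linear_range[1], "lod_ugml": c.lod,
         "loq_ugml": c.loq}
        for c in curves.values()]).set_index("analyte")


def frame_to_curves(df: pd.DataFrame) -> dict[str, CalibrationCurve]:
    if df.index.name != "analyte":
        df = df.set_index("analyte")
    out = {}
    for code, row in df.iterrows():
        lod = row.get("lod_ugml")
        loq = row.get("loq_ugml")
        out[str(code)] = CalibrationCurve(
            str(code), float(row["slope"]), float(row["intercept"]),
            float(row["r"]),
            (float(row["range_min_ugml"]), float(row["range_max_ugml"])),
            None if pd.isna(lod) else float(lod),
            None if pd.isna(loq) else float(loq))
    return out


def rcf_to_frame(rcf: RCFSet) -> pd.DataFrame:
    frame = rcf.to_frame()
    frame.attrs["internal_standard"] = rcf.internal_standard
    frame.insert(0, "internal_standard", rcf.internal_standard)
    return frame


def frame_to_rcf(df: pd.DataFrame) -> RCFSet:
    if df.index.name != "analyte":
        df = df.set_index("analyte")
    internal = str(df["internal_standard"].iloc[0])
    entries = {
        str(code): RCFEntry(str(code), (float(row["mean_f"]),),
                            float(row["mean_f"]), float(row["rsd_f_pct"]))
        for code, row in df.iterrows()}
    return RCFSet(internal, entries)


def rrt_to_frame(rrt: RRTable) -> pd.DataFrame:
    frame = rrt.to_frame()
    frame.insert(0, "reference", rrt.reference_analyte)
    frame.insert(1, "tolerance_min", rrt.tolerance)
    return frame


def frame_to_rrt(df: pd.DataFrame) -> RRTable:
    if df.index.name != "analyte":
        df = df.set_index("analyte")
    return RRTable(str(df["reference"].iloc[0]),
                   {str(c): (float(r["mean_dt_min"]), float(r["rsd_pct"]))
                    for c, r in df.iterrows()},
                   float(df["tolerance_min"].iloc[0]))


# ---------------------------------------------------------------------------
# optional trace integrator
# ---------------------------------------------------------------------------

def integrate_trace(time: Sequence[float],
                    intensity: Sequence[float],
                    peak_windows: Sequence[tuple[float, float]],
                    sample_id: str = "trace") -> PeakTable:
    """Trapezoidal peak areas above a linear baseline per window.

    The baseline is the straight line between the signal at the window
    endpoints; negative net areas are clamped to 0 (and logged). The peak's
    retention time is the apex of the net signal. Instrument software does
    this on real data; this utility exists for synthetic traces only.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise InvalidInputError("time and intensity must be 1-D and equal")
    if not (np.diff(t) > 0).all():
        raise InvalidInputError("time must be strictly increasing")
    windows = sorted(peak_windows)
    for (s1, e1), (s2, _) in zip(windows, windows[1:]):
        if s2 < e1:
            raise InvalidInputError(
                f"overlapping windows: ({s1}, {e1}) and starts {s2}")
    peaks = []
    for start, end in windows:
        if start >= end or start < t[0] or end > t[-1]:
            raise InvalidInputError(f"window ({start}, {end}) out of range")
        inner = (t > start) & (t < end)
        tw = np.concatenate(([start], t[inner], [end]))
        yw = np.concatenate(([np.interp(start, t, y)], y[inner],
                             [np.interp(end, t, y)]))
        baseline = np.interp(tw, [start, end], [yw[0], yw[-1]])
        net = yw - baseline
        area = float(np.trapezoid(net, tw))
        if area < 0:
            logger.warning("window (%g, %g): negative net area %.4g "
                           "clamped to 0", start, end, area)
            area = 0.0
        peaks.append(PeakRecord(float(tw[np.argmax(net)]), area))
    return PeakTable(sample_id, tuple(peaks))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline with its reference default."""

    analytes: tuple[str, ...] = ("GC", "C", "GV", "V", "GH", "H")
    internal_standard: str = "GV"
    sample_mass_g: float = 0.25
    extract_volume_ml: float = 10.0
    dilution_factor: float = 1.0
    rt_tolerance_min: float = 0.5
    qualified_min_total: float = 3.0
    superior_min_total: float = 8.0
    superior_min_ratio: float = 10.0
    re_bound_pct: float = 5.0
    rsd_bound_pct: float = 3.0
    durability_rsd_bound_pct: float = 5.0
    component_weights: tuple[float, float] = chem.DEFAULT_COMPONENT_WEIGHTS
    hca_k: int = 2
    hca_linkage: str = "average"
    grading: str = "clusters"
    total_exclusions: tuple = ()
    ratio_exclusions: tuple = ()
    n_batches: int = 55
    population_family: str = "lognormal"
    n_reference_runs: int = 5
    area_cv_pct: float = 1.0
    rt_jitter_sd_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.internal_standard not in self.analytes:
            raise ConfigError(
                f"internal standard {self.internal_standard!r} is not in "
                f"the panel {self.analytes}")
        for name in ("sample_mass_g", "extract_volume_ml", "dilution_factor",
                     "rt_tolerance_min", "qualified_min_total",
                     "superior_min_total", "superior_min_ratio",
                     "re_bound_pct", "rsd_bound_pct",
                     "durability_rsd_bound_pct"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.component_weights) != 2:
            raise ConfigError("component_weights must have two entries")

    @property
    def prep(self) -> SamplePrep:
        return SamplePrep(self.sample_mass_g, self.extract_volume_ml,
                          self.dilution_factor)

    @property
    def thresholds(self) -> chem.GradeThresholds:
        return chem.GradeThresholds(self.qualified_min_total,
                                    self.superior_min_total,
                                    self.superior_min_ratio)


def write_config(config: PipelineConfig, path) -> None:
    parser = configparser.ConfigParser()
    parser["pipeline"] = {
        k: (", ".join(str(x) for x in v) if isinstance(v, tuple) else str(v))
        for k, v in asdict(config).items()}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# qams pipeline configuration (key = value)\n")
        parser.write(fh)


def read_config(path) -> PipelineConfig:
    parser = configparser.ConfigParser()
    if not parser.read(path, encoding="utf-8"):
        raise ConfigError(f"cannot read config file {path}")
    if "pipeline" not in parser:
        raise ConfigError(f"{path}: missing [pipeline] section")
    raw = dict(parser["pipeline"])
    kwargs = {}
    for f in fields(PipelineConfig):
        if f.name not in raw:
            continue
        text = raw.pop(f.name)
        if f.name in ("analytes",):
            kwargs[f.name] = tuple(s.strip() for s in text.split(",")
                                   if s.strip())
        elif f.name == "component_weights":
            kwargs[f.name] = tuple(float(s) for s in text.split(","))
        elif f.name in ("total_exclusions", "ratio_exclusions"):
            kwargs[f.name] = tuple(int(s) for s in text.split(",")
                                   if s.strip())
        elif f.type in ("int", int) or f.name in ("hca_k", "n_batches",
                                                  "n_reference_runs", "seed"):
            kwargs[f.name] = int(text)
        elif f.name in ("internal_standard", "hca_linkage", "grading",
                        "population_family"):
            kwargs[f.name] = text.strip()
        else:
            kwargs[f.name] = float(text)
    if raw:
        raise ConfigError(f"{path}: unknown keys {sorted(raw)}")
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, QAMSError):
                exc.args = (f"[stage {name}] {exc}",)
                logger.error("stage %s: failed: %s", name, exc)
            elif exc is None:
                logger.info("stage %s: ok", name)
            return False
    return _Ctx()


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run (written to disk at the end)."""

    curves: Mapping[str, CalibrationCurve]
    rcf: RCFSet
    rrt: RRTable
    true_contents: pd.DataFrame
    located: list[PeakTable]
    esm_contents: pd.DataFrame
    qams_contents: pd.DataFrame
    comparison: quant.MethodComparison
    pca: chem.PCAModel
    scores: pd.DataFrame
    score_total_r: float
    report: str = ""
    paths: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 out_dir=None,
                 seed: int | None = None) -> PipelineResult:
    """Run the full simulated workflow under one seed.

    Standards and batch samples are generated from the packaged response and
    population truths, then pushed through calibration, RCFs, retention-time
    location, dual-route quantification, method comparison and chemometric
    grading. Outputs are only written (to ``out_dir``) once every stage has
    succeeded, so a failing run leaves no partial results behind.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(4)

    with _stage("simulate"):
        truth = synth.ResponseTruth.default(
            area_cv_pct=config.area_cv_pct,
            rt_jitter_sd_min=config.rt_jitter_sd_min)
        standards = synth.make_standard_series(
            truth, seed=np.random.default_rng(seeds[0]))
        population = synth.PopulationTruth.default(
            family=config.population_family)
        true_contents = synth.make_content_matrix(
            population, config.n_batches, seed=np.random.default_rng(seeds[1]))
        sample_rng = np.random.default_rng(seeds[2])
        raw_tables = [
            synth.make_sample_peak_table(
                row, config.prep, truth, seed=sample_rng,
                sample_id=f"S{batch}")
            for batch, row in true_contents.iterrows()]

    with _stage("calibrate"):
        curves = {code: cal.fit_calibration(s)
                  for code, s in standards.items()}

    with _stage("rcf"):
        rcf = cal.compute_rcf_set(standards, config.internal_standard)

    with _stage("rrt"):
        ref_runs = synth.make_reference_runs(
            truth, config.n_reference_runs,
            seed=np.random.default_rng(seeds[3]))
        rrt = cal.compute_rrt(ref_runs, config.internal_standard,
                              tolerance=config.rt_tolerance_min)

    with _stage("locate"):
        expected_ref = truth.retention_times[config.internal_standard]
        located = [cal.locate_peaks(t, rrt, expected_ref)
                   for t in raw_tables]

    with _stage("quantify"):
        per_sample = {t.sample_id: quant.quantify_sample(
            t, curves, rcf, config.prep) for t in located}
        esm = pd.DataFrame({sid: f["esm_mgg"]
                            for sid, f in per_sample.items()}).T
        qams = pd.DataFrame({sid: f["qams_mgg"]
                             for sid, f in per_sample.items()}).T
        esm.index.name = qams.index.name = "batch"

    with _stage("compare"):
        comparison = quant.compare_methods(esm, qams, config.re_bound_pct)

    with _stage("score"):
        pca = chem.fit_pca(qams)
        scores = chem.build_score_table(
            qams, component_weights=config.component_weights,
            thresholds=config.thresholds,
            total_exclusions=config.total_exclusions,
            ratio_exclusions=config.ratio_exclusions,
            k=config.hca_k, method=config.hca_linkage,
            grading=config.grading)
        score_total_r = chem.correlation_with_total(scores)

    result = PipelineResult(curves, rcf, rrt, true_contents, located, esm,
                            qams, comparison, pca, scores, score_total_r)
    result.report = _render_report(config, result, seed)
    if out_dir is not None:
        result.paths = _write_outputs(config, result, Path(out_dir))
    return result


def _render_report(config: PipelineConfig, r: PipelineResult,
                   seed: int) -> str:
    totals = r.scores["total"]
    grades = r.scores["grade"].value_counts().to_dict()
    lines = [
        "qams pipeline report",
        f"seed: {seed}  batches: {len(r.scores)}",
        f"panel: {', '.join(config.analytes)} "
        f"(internal standard {config.internal_standard})",
        "",
        "calibration R: " + ", ".join(
            f"{c}={r.curves[c].r:.5f}" for c in config.analytes),
        "mean RCF: " + ", ".join(
            f"f_{c}={r.rcf.f(c):.4f}" for c in config.analytes),
        "",
        f"ESM-vs-QAMS relative errors all within "
        f"{config.re_bound_pct}%: {r.comparison.within_bound}",
        "method correlations: " + ", ".join(
            f"{c}={v:.6f}" for c, v in r.comparison.correlations.items()),
        "",
        f"totals (mg/g): min {totals.min():.4g}, max {totals.max():.4g}",
        f"PCA variance: PC1 {r.pca.variance_explained.iloc[0]:.3f}%, "
        f"PC2 {r.pca.variance_explained.iloc[1]:.3f}%, "
        f"cumulative {r.pca.cumulative_variance(2):.3f}%",
        f"Pearson r(Z, total): {r.score_total_r:.3f}",
        "grades: " + ", ".join(f"{k}={v}" for k, v in sorted(grades.items())),
    ]
    return "\n".join(lines) + "\n"


def _write_outputs(config: PipelineConfig, r: PipelineResult,
                   out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def save(name, frame, **kw):
        p = out_dir / f"{name}.csv"
        frame.to_csv(p, **kw)
        paths[name] = p

    save("curves", curves_to_frame(r.curves))
    save("rcf", rcf_to_frame(r.rcf))
    save("rrt", rrt_to_frame(r.rrt))
    save("true_contents", r.true_contents.rename_axis("batch"))
    save("contents_esm", r.esm_contents)
    save("contents_qams", r.qams_contents)
    save("comparison", r.comparison.cells, index=False)
    save("method_correlations", r.comparison.correlations.rename_axis(
        "analyte").to_frame())
    save("pca_variance", r.pca.variance_explained.rename_axis(
        "component").to_frame())
    save("pca_loadings", r.pca.loadings.rename_axis("analyte"))
    save("scores", r.scores.rename_axis("batch"))
    peaks = out_dir / "peaks"
    peaks.mkdir(exist_ok=True)
    for t in r.located:
        write_peak_table(t, peaks / f"{t.sample_id}.csv")
    paths["peaks"] = peaks
    report_path = out_dir / "report.txt"
    report_path.write_text(r.report, encoding="utf-8")
    paths["report"] = report_path
    write_config(config, out_dir / "config.ini")
    paths["config"] = out_dir / "config.ini"
    return paths
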