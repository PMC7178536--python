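"""Peak-area quantification by ESM and QAMS, plus method-validation statistics.

Two quantification routes are implemented:

* ESM (external standard method): each analyte is converted with its own
  calibration curve, either through the regression line or through a
  single-point unit response A_s/C_s.
* QAMS (quantitative analysis of multicomponents by single marker): only the
  internal standard's unit response is used; each analyte k is converted as
  C_k = A_k / (A_s/C_s) * f_k with its relative correction factor f_k.

Concentrations (ug/mL of extract) are bridged to mass fractions (mg/g of
dried material) through the sample-preparation constants (0.25 g of powder
refluxed in 10 mL of methanol by default).
"""
from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rsd, rsd_abs
from .calibration import CalibrationCurve, PeakTable, RCFSet
from .errors import InvalidInputError, UndefinedStatisticError, ZeroResponseError

__all__ = [
    "SamplePrep", "MethodComparison", "ValidationReport",
    "esm_quantify", "qams_quantify", "mass_fraction", "quantify_sample",
    "compare_methods", "rsd", "recovery", "validate",
]

logger = logging.getLogger("qams.quantification")


@dataclass(frozen=True)
class SamplePrep:
    """Extraction constants linking extract concentration to dry content."""

    sample_mass_g: float = 0.25
    extract_volume_ml: float = 10.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sample_mass_g, self.extract_volume_ml,
               self.dilution_factor) <= 0:
            raise InvalidInputError("all prep constants must be positive")


def esm_quantify(area: float,
                 curve: CalibrationCurve | None = None,
                 mode: str = "regression",
                 single_point_ratio: float | None = None,
                 *,
                 return_clamped: bool = False):
    """Concentration (ug/mL) from a peak area by the external standard method.

    ``regression`` mode inverts the analyte's own calibration line,
    (area - intercept) / slope, flooring negative results at zero;
    ``single_point`` divides by the unit response A_s/C_s. With
    ``return_clamped=True`` a ``(value, clamped)`` pair is returned so
    callers can propagate the below-intercept flag.
    """
    if mode == "regression":
        if curve is None:
            raise InvalidInputError("regression mode requires a fitted curve")
        if curve.slope == 0:
            raise ZeroResponseError("zero calibration slope")
        conc = (area - curve.intercept) / curve.slope
    elif mode == "single_point":
        if single_point_ratio is None:
            raise InvalidInputError(
                "single_point mode requires the unit response A_s/C_s")
        if single_point_ratio == 0:
            raise ZeroResponseError("zero unit response A_s/C_s")
        conc = area / single_point_ratio
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")
    clamped = conc < 0
    if clamped:
        logger.warning("negative concentration %.4g clamped to 0", conc)
        conc = 0.0
    return (float(conc), bool(clamped)) if return_clamped else float(conc)


def qams_quantify(area_k: float,
                  internal_unit_response: float,
                  f_k: float) -> float:
    """Concentration (ug/mL) of analyte k from the internal standard's unit
    response and the relative correction factor: A_k / (A_s/C_s) * f_k."""
    if internal_unit_response <= 0:
        raise InvalidInputError("internal unit response must be positive")
    if f_k <= 0:
        raise InvalidInputError("relative correction factor must be positive")
    if area_k < 0:
        raise InvalidInputError("peak area must be >= 0")
    return float(area_k / internal_unit_response * f_k)


def mass_fraction(conc_ugml: float, prep: SamplePrep = SamplePrep()) -> float:
    """Extract concentration (ug/mL) -> dry-material content (mg/g)."""
    return (conc_ugml * prep.extract_volume_ml * prep.dilution_factor
            / (prep.sample_mass_g * 1000.0))


def quantify_sample(table: PeakTable,
                    curves: Mapping[str, CalibrationCurve],
                    rcf: RCFSet,
                    prep: SamplePrep = SamplePrep()) -> pd.DataFrame:
    """Quantify one located peak table by both routes.

    Returns a frame indexed by analyte code with columns ``esm_mgg``,
    ``qams_mgg``, ``clamped`` and ``absent``. Analytes flagged absent by
    peak location are reported as 0 content (the convention used for
    batches in which a marker is genuinely below detection).
    """
    internal = rcf.internal_standard
    unit_response = curves[internal].unit_response
    rows = {}
    for code in rcf.codes:
        area = table.area_of(code)
        if area is None:
            rows[code] = {"esm_mgg": 0.0, "qams_mgg": 0.0,
                          "clamped": False, "absent": True}
            continue
        esm_conc, clamped = esm_quantify(area, curves[code],
                                         return_clamped=True)
        if code == internal:
            qams_conc = esm_conc  # the marker itself is read off its curve
        else:
            qams_conc = qams_quantify(area, unit_response, rcf.f(code))
        rows[code] = {"esm_mgg": mass_fraction(esm_conc, prep),
                      "qams_mgg": mass_fraction(qams_conc, prep),
                      "clamped": clamped, "absent": False}
    out = pd.DataFrame.from_dict(rows, orient="index").rename_axis("analyte")
    out.attrs["sample_id"] = table.sample_id
    return out


@dataclass(frozen=True)
class MethodComparison:
    """Cellwise ESM-vs-QAMS agreement and per-analyte correlations.

    ``cells`` holds one row per (batch, analyte) with the two contents, the
    relative error in percent ((qams - esm)/esm * 100; NaN where esm = 0),
    and a ``defined`` flag. ``correlations`` is the per-analyte Pearson r
    between the two content columns across batches.
    """

    cells: pd.DataFrame
    correlations: pd.Series
    re_bound_pct: float = 5.0

    @property
    def within_bound(self) -> bool:
        defined = self.cells.loc[self.cells["defined"], "re_pct"]
        return bool((defined.abs() <= self.re_bound_pct).all())


def compare_methods(esm: pd.DataFrame, qams: pd.DataFrame,
                    re_bound_pct: float = 5.0) -> MethodComparison:
    """Compare two content matrices (batches x analytes, mg/g)."""
    if not esm.index.equals(qams.index) or not esm.columns.equals(qams.columns):
        raise InvalidInputError(
            "ESM and QAMS matrices must share batches and analytes")
    records = []
    for batch in esm.index:
        for code in esm.columns:
            e, q = float(esm.at[batch, code]), float(qams.at[batch, code])
            defined = e > 0
            re_pct = (q - e) / e * 100.0 if defined else np.nan
            if not defined:
                logger.info("RE undefined for batch %s analyte %s (ESM = 0)",
                            batch, code)
            records.append({"batch": batch, "analyte": code, "esm_mgg": e,
                            "qams_mgg": q, "re_pct": re_pct,
                            "defined": defined})
    cells = pd.DataFrame.from_records(records)
    corrs = {}
    for code in esm.columns:
        x, y = esm[code].to_numpy(float), qams[code].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise UndefinedStatisticError(
                f"correlation undefined for constant column {code}")
        corrs[code] = float(stats.pearsonr(x, y).statistic)
    return MethodComparison(cells, pd.Series(corrs, name="pearson_r"),
                            re_bound_pct)


def recovery(original_amount: float, added_amount: float,
             found_amount: float) -> float:
    """Spike recovery in percent: 100 * (found - original) / added."""
    if added_amount <= 0:
        raise InvalidInputError("added amount must be positive")
    return 100.0 * (found_amount - original_amount) / added_amount


_RSD_CATEGORIES = ("instrument_precision", "intermediate_precision",
                   "stability", "repeatability")


@dataclass(frozen=True)
class ValidationReport:
    """Per-analyte validation statistics with threshold verdicts.

    ``table`` is indexed by analyte with one RSD column per replicate
    category plus ``mean_recovery`` / ``recovery_rsd``; ``passes`` holds the
    matching boolean verdicts; ``missing`` lists categories that were not
    supplied (the report is explicit about gaps rather than silently
    complete).
    """

    table: pd.DataFrame
    passes: pd.DataFrame
    missing: tuple[str, ...]
    rsd_threshold: float
    recovery_window: tuple[float, float]

    def summary(self) -> str:
        lines = [f"validation thresholds: RSD < {self.rsd_threshold}%, "
                 f"recovery in [{self.recovery_window[0]}, "
                 f"{self.recovery_window[1]}]%"]
        if self.missing:
            lines.append("missing categories: " + ", ".join(self.missing))
        for code, row in self.table.iterrows():
            verdict = "pass" if self.passes.loc[code].all() else "FAIL"
            lines.append(f"  {code}: " + ", ".join(
                f"{k}={v:.3g}" for k, v in row.dropna().items())
                + f" -> {verdict}")
        return "\n".join(lines)


def validate(replicate_sets: Mapping[str, pd.DataFrame],
             recovery_sets: pd.DataFrame | None = None,
             rsd_threshold: float = 3.0,
             recovery_window: tuple[float, float] = (95.0, 105.0),
             ) -> ValidationReport:
    """Summarize replicate measurements into a validation report.

    ``replicate_sets`` maps category names (instrument_precision,
    intermediate_precision, stability, repeatability) to frames of
    replicates (rows) x analytes (columns); each supplied category needs
    >= 2 replicates. ``recovery_sets`` is a long frame with columns
    analyte, original, added, found. Missing categories yield a partial
    report with the gap recorded in ``missing``.
    """
    unknown = set(replicate_sets) - set(_RSD_CATEGORIES)
    if unknown:
        raise InvalidInputError(f"unknown categories: {sorted(unknown)}")
    codes: list[str] = []
    for frame in replicate_sets.values():
        codes += [c for c in frame.columns if c not in codes]
    if recovery_sets is not None:
        codes += [c for c in recovery_sets["analyte"].unique()
                  if c not in codes]
    if not codes:
        raise InvalidInputError("no analytes supplied")

    table = pd.DataFrame(index=pd.Index(codes, name="analyte"), dtype=float)
    for cat in _RSD_CATEGORIES:
        frame = replicate_sets.get(cat)
        col = f"{cat}_rsd"
        if frame is None:
            table[col] = np.nan
            continue
        if len(frame) < 2:
            raise InvalidInputError(f"{cat}: needs >= 2 replicates")
        table[col] = pd.Series(
            {c: rsd_abs(frame[c].to_numpy(float)) for c in frame.columns})
    if recovery_sets is not None:
        mean_rec, rec_rsd = {}, {}
        for code, grp in recovery_sets.groupby("analyte"):
            recs = [recovery(o, a, f) for o, a, f in
                    zip(grp["original"], grp["added"], grp["found"])]
            mean_rec[code] = float(np.mean(recs))
            rec_rsd[code] = rsd_abs(recs) if len(recs) > 1 else 0.0
        table["mean_recovery"] = pd.Series(mean_rec)
        table["recovery_rsd"] = pd.Series(rec_rsd)
    else:
        table["mean_recovery"] = np.nan
        table["recovery_rsd"] = np.nan

    missing = tuple(c for c in _RSD_CATEGORIES if c not in replicate_sets)
    if recovery_sets is None:
        missing += ("recovery",)
    passes = pd.DataFrame(index=table.index)
    for cat in _RSD_CATEGORIES:
        passes[f"{cat}_rsd"] = table[f"{cat}_rsd"].isna() | (
            table[f"{cat}_rsd"] < rsd_threshold)
    lo, hi = recovery_window
    passes["mean_recovery"] = table["mean_recovery"].isna() | (
        (table["mean_recovery"] >= lo) & (table["mean_recovery"] <= hi))
    passes["recovery_rsd"] = table["recovery_rsd"].isna() | (
        table["recovery_rsd"] < rsd_threshold)
    return ValidationReport(table, passes, missing, rsd_threshold,
                            recovery_window)
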