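"""Calibration, relative correction factors, and retention-time peak location.

This module covers the standards side of a single-marker multicomponent
(QAMS) HPLC workflow for the six chromone markers of Saposhnikoviae Radix:

* ordinary least-squares calibration curves (detector area vs concentration),
* LOD/LOQ from a baseline noise level at signal-to-noise 3 and 10,
* relative correction factors (RCF) of each analyte against the internal
  standard, computed level-by-level from a shared dilution ladder,
* relative retention times (signed offsets from the internal-standard peak)
  and tolerance-based assignment of chromatographic peaks to analytes.

The six analytes are the chromone glycosides prim-O-glucosylcimifugin (GC),
4'-O-beta-D-glucosyl-5-O-methylvisamminol (GV, the internal standard) and
sec-O-glucosylhamaudol (GH), and their aglycones cimifugin (C),
5-O-methylvisamminol (V) and hamaudol (H).
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import rsd, rsd_abs
from .errors import (
    DegenerateFitError,
    InvalidInputError,
    PairingError,
    PeakLocationError,
    ZeroResponseError,
)

logger = logging.getLogger("qams.calibration")

GLYCOSIDE = "glycoside"
AGLYCONE = "aglycone"

#: Mixed-stock concentrations of the reference standards, in ug/mL.
STOCK_CONC_UGML: dict[str, float] = {
    "GC": 209.6, "C": 122.0, "GV": 334.0, "V": 80.8, "GH": 163.6, "H": 36.9,
}

#: Dilution ladder applied to the mixed stock to build the calibration series.
DILUTION_FACTORS: tuple[float, ...] = (1, 2, 5, 10, 20, 50, 100)

#: Nominal retention times (min) consistent with the elution order
#: GC < C < GV < V < GH < H on the reference gradient.
DEFAULT_RETENTION_TIMES: dict[str, float] = {
    "GC": 10.5, "C": 14.2, "GV": 20.0, "V": 25.5, "GH": 32.0, "H": 40.5,
}


@dataclass(frozen=True)
class Analyte:
    """One compound of the marker panel."""

    code: str
    name: str
    compound_class: str
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.compound_class not in (GLYCOSIDE, AGLYCONE):
            raise InvalidInputError(
                f"compound_class must be '{GLYCOSIDE}' or '{AGLYCONE}', "
                f"got {self.compound_class!r}")


@dataclass(frozen=True)
class Panel:
    """An ordered analyte panel with exactly one internal standard."""

    analytes: tuple[Analyte, ...]

    def __post_init__(self) -> None:
        codes = [a.code for a in self.analytes]
        if len(set(codes)) != len(codes):
            raise InvalidInputError("analyte codes must be unique in a panel")
        n_is = sum(a.is_internal_standard for a in self.analytes)
        if n_is != 1:
            raise InvalidInputError(
                f"exactly one internal standard required, found {n_is}")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(a.code for a in self.analytes)

    @property
    def internal_standard(self) -> str:
        return next(a.code for a in self.analytes if a.is_internal_standard)

    @property
    def aglycones(self) -> tuple[str, ...]:
        return tuple(a.code for a in self.analytes
                     if a.compound_class == AGLYCONE)

    @property
    def glycosides(self) -> tuple[str, ...]:
        return tuple(a.code for a in self.analytes
                     if a.compound_class == GLYCOSIDE)

    def __getitem__(self, code: str) -> Analyte:
        for a in self.analytes:
            if a.code == code:
                return a
        raise KeyError(code)


DEFAULT_PANEL = Panel((
    Analyte("GC", "prim-O-glucosylcimifugin", GLYCOSIDE),
    Analyte("C", "cimifugin", AGLYCONE),
    Analyte("GV", "4'-O-beta-D-glucosyl-5-O-methylvisamminol", GLYCOSIDE,
            is_internal_standard=True),
    Analyte("V", "5-O-methylvisamminol", AGLYCONE),
    Analyte("GH", "sec-O-glucosylhamaudol", GLYCOSIDE),
    Analyte("H", "hamaudol", AGLYCONE),
))


@dataclass(frozen=True)
class StandardSeries:
    """A dilution series of one analyte: (concentration ug/mL, area) pairs,
    ordered by strictly increasing concentration."""

    analyte: str
    concentrations: tuple[float, ...]
    areas: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        if c.size != a.size:
            raise InvalidInputError("concentrations and areas differ in length")
        if c.size < 2:
            raise InvalidInputError("a standard series needs >= 2 levels")
        if not (c > 0).all():
            raise InvalidInputError("concentrations must be strictly positive")
        if not (np.diff(c) > 0).all():
            raise InvalidInputError("concentrations must be strictly increasing")
        if not (a > 0).all():
            raise InvalidInputError("areas must be strictly positive")

    @property
    def n_levels(self) -> int:
        return len(self.concentrations)


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear detector response y = slope * x + intercept for one analyte."""

    analyte: str
    slope: float
    intercept: float
    r: float
    linear_range: tuple[float, float]
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidInputError(f"{self.analyte}: slope must be positive")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise InvalidInputError(f"{self.analyte}: |R| cannot exceed 1")
        if self.linear_range[0] >= self.linear_range[1]:
            raise InvalidInputError(f"{self.analyte}: empty linear range")
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise InvalidInputError(f"{self.analyte}: LOD must not exceed LOQ")

    @property
    def unit_response(self) -> float:
        """Fitted detector response per unit concentration (area per ug/mL)."""
        return self.slope


@dataclass(frozen=True)
class RCFEntry:
    """Relative correction factor of one analyte against the internal
    standard: per-level values, their arithmetic mean, and RSD (%)."""

    analyte: str
    per_level_f: tuple[float, ...]
    mean_f: float
    rsd_f: float


@dataclass(frozen=True)
class RCFSet:
    """RCF entries for a panel, all relative to one internal standard."""

    internal_standard: str
    entries: Mapping[str, RCFEntry]

    def __post_init__(self) -> None:
        for code, e in self.entries.items():
            if e.mean_f <= 0:
                raise InvalidInputError(f"mean f for {code} must be positive")
            if e.rsd_f < 0:
                raise InvalidInputError(f"RSD of f for {code} must be >= 0")
        own = self.entries.get(self.internal_standard)
        if own is not None and not (
                np.isclose(own.mean_f, 1.0) and np.isclose(own.rsd_f, 0.0)):
            raise InvalidInputError(
                "internal standard vs itself must have f = 1, RSD = 0")

    def f(self, code: str) -> float:
        return self.entries[code].mean_f

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_f": {c: e.mean_f for c, e in self.entries.items()},
             "rsd_f_pct": {c: e.rsd_f for c, e in self.entries.items()}}
        ).rename_axis("analyte")


@dataclass(frozen=True)
class PeakRecord:
    """One integrated chromatographic peak."""

    retention_time: float
    area: float
    assigned_analyte: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise InvalidInputError("retention time must be positive")
        if self.area < 0:
            raise InvalidInputError("peak area must be >= 0")


@dataclass(frozen=True)
class PeakTable:
    """Peaks of one chromatographic run plus run metadata.

    ``absent`` lists panel analytes that peak location could not match;
    it is populated by :func:`locate_peaks`.
    """

    sample_id: str
    peaks: tuple[PeakRecord, ...]
    instrument: str = "default"
    column: str = "default"
    flow_rate_ml_min: float = 1.0
    column_temperature_c: float = 25.0
    absent: tuple[str, ...] = ()
    extra: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [p.retention_time for p in self.peaks]
        if len(set(times)) != len(times):
            raise InvalidInputError(
                f"{self.sample_id}: retention times must be unique")

    def assigned(self) -> dict[str, PeakRecord]:
        return {p.assigned_analyte: p for p in self.peaks
                if p.assigned_analyte is not None}

    def area_of(self, code: str) -> float | None:
        rec = self.assigned().get(code)
        return None if rec is None else rec.area


@dataclass(frozen=True)
class RRTable:
    """Mean signed retention-time offsets from the reference analyte.

    ``offsets`` maps analyte code to (mean delta-t in minutes, RSD %); the
    reference row is identically (0, 0). ``tolerance`` is the maximum
    |observed offset - mean offset| accepted during peak assignment.
    """

    reference_analyte: str
    offsets: Mapping[str, tuple[float, float]]
    tolerance: float = 0.5

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise InvalidInputError("matching tolerance must be positive")
        ref = self.offsets.get(self.reference_analyte)
        if ref is not None and ref[0] != 0.0:
            raise InvalidInputError("reference analyte offset must be 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_dt_min": {c: v[0] for c, v in self.offsets.items()},
             "rsd_pct": {c: v[1] for c, v in self.offsets.items()}}
        ).rename_axis("analyte")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def fit_calibration(series: StandardSeries) -> CalibrationCurve:
    """Fit an unweighted OLS line area = slope * conc + intercept.

    R is the Pearson correlation of (concentration, area); the linear range
    is the observed concentration span.
    """
    x = np.asarray(series.concentrations, dtype=float)
    y = np.asarray(series.areas, dtype=float)
    if x.size < 2:
        raise InvalidInputError("calibration needs >= 2 levels")
    if np.ptp(x) == 0:
        raise DegenerateFitError(
            f"{series.analyte}: zero concentration variance")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=series.analyte,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        linear_range=(float(x.min()), float(x.max())),
    )


def estimate_lod_loq(curve: CalibrationCurve,
                     noise_sd: float) -> tuple[float, float]:
    """LOD and LOQ (ug/mL) from baseline noise at S/N = 3 and 10.

    ``noise_sd`` is the baseline noise level in detector units; the printed
    instrument tables never publish it, so it is always user-supplied.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    lod = 3.0 * noise_sd / curve.slope
    loq = 10.0 * noise_sd / curve.slope
    return lod, loq


def compute_rcf(internal: StandardSeries,
                analyte: StandardSeries) -> RCFEntry:
    """Relative correction factor f = (A_s/C_s) / (A_k/C_k), level by level.

    The two series must come from the same dilution ladder so that levels
    pair up one-to-one. The reported f is the arithmetic mean over levels
    with its RSD (%, n-1 standard deviation). An analyte paired with itself
    yields f = 1 at every level and RSD 0 by construction.
    """
    if internal.n_levels != analyte.n_levels:
        raise PairingError(
            f"level count mismatch: {internal.analyte} has "
            f"{internal.n_levels}, {analyte.analyte} has {analyte.n_levels}")
    fs = []
    pairs = zip(internal.concentrations, internal.areas,
                analyte.concentrations, analyte.areas)
    for level, (cs, as_, ck, ak) in enumerate(pairs, start=1):
        if 0.0 in (cs, as_, ck, ak):
            raise ZeroResponseError(
                f"zero area or concentration at level {level} "
                f"({internal.analyte} vs {analyte.analyte})")
        fs.append((as_ / cs) / (ak / ck))
    fs_arr = np.asarray(fs)
    if internal.analyte == analyte.analyte:
        # identical series: force the exact identity, immune to rounding
        return RCFEntry(analyte.analyte, tuple(1.0 for _ in fs), 1.0, 0.0)
    return RCFEntry(analyte.analyte, tuple(fs),
                    float(fs_arr.mean()),
                    rsd_abs(fs_arr) if len(fs) > 1 else 0.0)


def compute_rcf_set(series: Mapping[str, StandardSeries],
                    internal_standard: str) -> RCFSet:
    """RCF entries of every series in ``series`` against the internal one."""
    if internal_standard not in series:
        raise InvalidInputError(
            f"no series for internal standard {internal_standard!r}")
    internal = series[internal_standard]
    entries = {code: compute_rcf(internal, s) for code, s in series.items()}
    return RCFSet(internal_standard, entries)


@dataclass(frozen=True)
class DurabilityResult:
    """Cross-condition RSD of the mean RCFs plus the <5% pass verdict."""

    table: pd.DataFrame  # index analyte, columns rsd_pct, passes
    all_pass: bool
    threshold: float


def durability_rcf(rcf_sets: Sequence[RCFSet],
                   threshold: float = 5.0) -> DurabilityResult:
    """RSD of each analyte's mean f across instrument/column/flow/temperature
    conditions; the method is durable when every RSD is below ``threshold``.
    """
    if len(rcf_sets) < 2:
        raise InvalidInputError("durability needs >= 2 conditions")
    panels = {tuple(sorted(s.codes)) for s in rcf_sets}
    if len(panels) != 1:
        raise InvalidInputError("all conditions must cover the same panel")
    rows = {}
    for code in rcf_sets[0].codes:
        means = [s.entries[code].mean_f for s in rcf_sets]
        rows[code] = 0.0 if len(set(means)) == 1 else rsd_abs(means)
    table = pd.DataFrame({"rsd_pct": rows}).rename_axis("analyte")
    table["passes"] = table["rsd_pct"] < threshold
    return DurabilityResult(table, bool(table["passes"].all()), threshold)


def compute_rrt(assigned_tables: Sequence[PeakTable],
                reference: str,
                tolerance: float = 0.5) -> RRTable:
    """Mean signed offsets delta-t = t_analyte - t_reference across runs.

    Every run must contain an assigned reference peak; analytes seen in any
    run contribute a row (mean offset and cross-run RSD of the offset,
    relative to |mean|). The reference row is identically zero.
    """
    if not assigned_tables:
        raise InvalidInputError("need at least one assigned run")
    deltas: dict[str, list[float]] = {}
    for table in assigned_tables:
        assigned = table.assigned()
        if reference not in assigned:
            raise PeakLocationError(
                f"run {table.sample_id!r} has no assigned {reference} peak")
        t_ref = assigned[reference].retention_time
        others = {c: p for c, p in assigned.items() if c != reference}
        if not others:
            raise PeakLocationError(
                f"run {table.sample_id!r} has no analyte besides {reference}")
        for code, peak in others.items():
            deltas.setdefault(code, []).append(peak.retention_time - t_ref)
    offsets: dict[str, tuple[float, float]] = {reference: (0.0, 0.0)}
    for code, ds in deltas.items():
        mean = float(np.mean(ds))
        spread = 0.0 if len(ds) < 2 or len(set(ds)) == 1 else rsd_abs(ds)
        offsets[code] = (mean, spread)
    return RRTable(reference, offsets, tolerance)


def locate_peaks(table: PeakTable,
                 rrt: RRTable,
                 expected_reference_time: float) -> PeakTable:
    """Assign peaks to analytes by relative retention time.

    The reference peak is the one nearest ``expected_reference_time`` (it
    must fall within the table's tolerance). Remaining analytes are matched
    greedily to unassigned peaks by smallest |(t - t_ref) - mean offset|,
    ties broken by analyte code; deviations above the tolerance are never
    matched, and unmatched analytes are flagged in ``absent`` instead of
    being silently dropped. Re-running on an already assigned table yields
    the same assignment (existing assignments are discarded first).
    """
    if not table.peaks:
        raise InvalidInputError(f"{table.sample_id}: empty peak table")
    times = np.array([p.retention_time for p in table.peaks])
    ref_idx = int(np.argmin(np.abs(times - expected_reference_time)))
    if abs(times[ref_idx] - expected_reference_time) > rrt.tolerance:
        raise PeakLocationError(
            f"{table.sample_id}: no peak within {rrt.tolerance} min of the "
            f"expected {rrt.reference_analyte} position "
            f"{expected_reference_time} min")
    t_ref = times[ref_idx]
    assignment: dict[int, str] = {ref_idx: rrt.reference_analyte}

    candidates = []
    for code, (mean_dt, _) in rrt.offsets.items():
        if code == rrt.reference_analyte:
            continue
        for idx, t in enumerate(times):
            if idx == ref_idx:
                continue
            dev = abs((t - t_ref) - mean_dt)
            if dev <= rrt.tolerance:
                candidates.append((dev, code, idx))
    taken_codes: set[str] = set()
    for dev, code, idx in sorted(candidates):
        if code in taken_codes or idx in assignment:
            continue
        assignment[idx] = code
        taken_codes.add(code)
    absent = tuple(sorted(set(rrt.offsets) - set(assignment.values())))
    if absent:
        logger.info("%s: analytes flagged absent: %s",
                    table.sample_id, ", ".join(absent))
    new_peaks = tuple(
        replace(p, assigned_analyte=assignment.get(i))
        for i, p in enumerate(table.peaks))
    return replace(table, peaks=new_peaks, absent=absent)


def reconstruct_linear_ranges(
        stock_concentrations: Mapping[str, float] = STOCK_CONC_UGML,
        dilution_factors: Iterable[float] = DILUTION_FACTORS,
) -> pd.DataFrame:
    """Concentration span (ug/mL) of the dilution ladder per analyte."""
    factors = np.asarray(sorted(dilution_factors), dtype=float)
    if (factors < 1).any():
        raise InvalidInputError("dilution factors must be >= 1")
    rows = {code: (stock / factors.max(), stock / factors.min())
            for code, stock in stock_concentrations.items()}
    return pd.DataFrame(rows, index=["range_min_ugml", "range_max_ugml"]).T
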