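"""Synthetic inputs for the pipeline, plus the packaged printed-table fixtures.

No raw chromatograms are published for the reference dataset, so every input
the pipeline consumes can be generated here with the statistical structure
the analysis assumes:

* dilution-ladder standard series with a linear detector response per
  analyte (slopes/intercepts default to the printed calibration table) and
  multiplicative Gaussian area noise (CV-parameterized, reflecting HPLC
  peak-area variability), optionally plus additive detector noise;
* sample peak tables obtained by inverting the quantification chain from a
  true content vector, with retention-time jitter around analyte positions;
* batch content matrices drawn from a truncated-normal (or lognormal)
  population with a user-specified correlation structure, defaulting to the
  moments and correlations of the packaged 55-batch content table.

All generators are bit-reproducible under a fixed seed and change under a
different one.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import (
    DEFAULT_RETENTION_TIMES,
    DILUTION_FACTORS,
    STOCK_CONC_UGML,
    CalibrationCurve,
    PeakRecord,
    PeakTable,
    StandardSeries,
)
from .errors import DecompositionError, InvalidInputError
from .quantification import SamplePrep

_FIXTURE_FILES = {
    "table1": "table1_calibration.csv",
    "table2": "table2_validation.csv",
    "table3": "table3_method_comparison.csv",
    "table3_correlations": "table3_correlations.csv",
    "table4": "table4_contents.csv",
    "table5": "table5_loadings.csv",
    "table6": "table6_scores.csv",
    "table7": "table7_ratios.csv",
}


def load_fixture(name: str):
    """Load one packaged printed table as a typed pandas object.

    ``table1`` (calibration constants) / ``table2`` (validation statistics) /
    ``table5`` (score coefficients) are frames indexed by analyte code;
    ``table4`` is the 55 x 6 content matrix (mg/g) plus its printed totals
    column, indexed by batch; ``table6`` / ``table7`` are per-batch Series of
    composite scores and aglycone ratios; ``table3`` is the long
    ESM-vs-QAMS comparison with its printed relative errors, and
    ``table3_correlations`` the printed per-analyte correlations.

    The tables are stored verbatim as printed, including their known
    misprints (see the package methods note); nothing is corrected.
    """
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise LookupError(
            f"unknown fixture {name!r}; available: "
            f"{', '.join(sorted(_FIXTURE_FILES))}") from None
    path = resources.files("qams.fixtures").joinpath(fname)
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    if name in ("table1", "table2", "table5"):
        return df.set_index("code")
    if name == "table4":
        return df.set_index("batch")
    if name == "table6":
        return df.set_index("batch")["z"]
    if name == "table7":
        return df.set_index("batch")["ratio_pct"]
    if name == "table3_correlations":
        return df.set_index("analyte")["pearson_r"]
    return df  # table3, long format


def fixture_content_matrix() -> pd.DataFrame:
    """The 55-batch content matrix without its printed totals column."""
    return load_fixture("table4").drop(columns=["total"])


def fixture_calibration_curves() -> dict[str, CalibrationCurve]:
    """The printed calibration constants as typed curves."""
    t1 = load_fixture("table1")
    return {
        code: CalibrationCurve(
            analyte=code,
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r=float(row["r"]),
            linear_range=(float(row["range_min_ugml"]),
                          float(row["range_max_ugml"])),
            lod=float(row["lod_ugml"]),
            loq=float(row["loq_ugml"]),
        )
        for code, row in t1.iterrows()
    }


# ---------------------------------------------------------------------------
# generative truths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseTruth:
    """True detector response and retention position per analyte.

    Area noise is multiplicative Gaussian with the given CV (%); an optional
    additive detector noise (SD in area units) supports LOD/LOQ experiments.
    Retention times receive additive Gaussian jitter (SD in minutes).
    """

    slopes: Mapping[str, float]
    intercepts: Mapping[str, float]
    retention_times: Mapping[str, float]
    area_cv_pct: float = 1.0
    rt_jitter_sd_min: float = 0.05
    additive_area_sd: float = 0.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.slopes.values()):
            raise InvalidInputError("true slopes must be positive")
        if min(self.area_cv_pct, self.rt_jitter_sd_min,
               self.additive_area_sd) < 0:
            raise InvalidInputError("noise parameters must be >= 0")

    @classmethod
    def default(cls, **overrides) -> "ResponseTruth":
        """Printed calibration constants plus nominal retention times."""
        t1 = load_fixture("table1")
        return cls(slopes=dict(t1["slope"]),
                   intercepts=dict(t1["intercept"]),
                   retention_times=dict(DEFAULT_RETENTION_TIMES),
                   **overrides)

    def noiseless(self) -> "ResponseTruth":
        return replace(self, area_cv_pct=0.0, rt_jitter_sd_min=0.0,
                       additive_area_sd=0.0)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.slopes)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _noisy_area(truth: ResponseTruth, true_area: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    area = true_area * (1.0 + truth.area_cv_pct / 100.0
                        * rng.standard_normal(true_area.shape))
    if truth.additive_area_sd > 0:
        area = area + truth.additive_area_sd * rng.standard_normal(area.shape)
    return area


def make_standard_series(truth: ResponseTruth,
                         dilution_factors: Sequence[float] = DILUTION_FACTORS,
                         stock_concentrations: Mapping[str, float] | None = None,
                         seed=None) -> dict[str, StandardSeries]:
    """Dilution-ladder standard series for every analyte in the truth.

    Concentrations are stock / factor; areas lie on the true line perturbed
    by the truth's noise model. Reproducible under a fixed seed.
    """
    stocks = dict(STOCK_CONC_UGML if stock_concentrations is None
                  else stock_concentrations)
    factors = np.asarray(dilution_factors, dtype=float)
    if (factors < 1).any():
        raise InvalidInputError("dilution factors must be >= 1")
    if len(set(factors)) != len(factors):
        raise InvalidInputError("dilution factors must be distinct")
    rng = _rng(seed)
    out = {}
    for code in truth.codes:
        stock = stocks[code]
        if stock <= 0:
            raise InvalidInputError(f"non-positive stock for {code}")
        conc = np.sort(stock / factors)
        area = _noisy_area(
            truth, truth.slopes[code] * conc + truth.intercepts[code], rng)
        out[code] = StandardSeries(code, tuple(conc), tuple(area))
    return out


def make_sample_peak_table(true_contents: Mapping[str, float],
                           prep: SamplePrep = SamplePrep(),
                           truth: ResponseTruth | None = None,
                           seed=None,
                           sample_id: str = "sample") -> PeakTable:
    """Peak table of one extracted sample, inverted from true contents (mg/g).

    The extract concentration of analyte k is
    content * mass * 1000 / (volume * dilution) ug/mL; its peak lies on the
    true response line with the truth's noise, at the analyte's jittered
    retention time. Zero-content analytes emit no peak.
    """
    if truth is None:
        truth = ResponseTruth.default()
    true_contents = dict(true_contents)
    if any(v < 0 for v in true_contents.values()):
        raise InvalidInputError("contents must be >= 0")
    rng = _rng(seed)
    peaks = []
    for code in truth.codes:
        content = float(true_contents.get(code, 0.0))
        if content == 0.0:
            continue
        conc = (content * prep.sample_mass_g * 1000.0
                / (prep.extract_volume_ml * prep.dilution_factor))
        area = float(_noisy_area(
            truth,
            np.asarray(truth.slopes[code] * conc + truth.intercepts[code]),
            rng))
        rt = truth.retention_times[code]
        if truth.rt_jitter_sd_min > 0:
            rt += truth.rt_jitter_sd_min * rng.standard_normal()
        peaks.append(PeakRecord(rt, area))
    return PeakTable(sample_id, tuple(peaks))


def make_reference_runs(truth: ResponseTruth,
                        n_runs: int = 5,
                        concentration_ugml: float = 20.0,
                        seed=None) -> list[PeakTable]:
    """Assigned standard-solution runs for building a retention-time table.

    Peak identities are known in a standards run, so the returned tables
    carry assignments; they are the calibration input of
    :func:`qams.calibration.compute_rrt`.
    """
    rng = _rng(seed)
    runs = []
    for i in range(n_runs):
        peaks = []
        for code in truth.codes:
            rt = truth.retention_times[code]
            if truth.rt_jitter_sd_min > 0:
                rt += truth.rt_jitter_sd_min * rng.standard_normal()
            area = float(_noisy_area(
                truth,
                np.asarray(truth.slopes[code] * concentration_ugml
                           + truth.intercepts[code]), rng))
            peaks.append(PeakRecord(rt, area, assigned_analyte=code))
        runs.append(PeakTable(f"ref_run_{i + 1}", tuple(peaks)))
    return runs


@dataclass(frozen=True)
class PopulationTruth:
    """Population model behind a batch content matrix.

    ``family`` is ``truncated-normal`` (multivariate normal with the target
    moments and correlations, negatives truncated to 0) or ``lognormal``
    (moment-matched marginals coupled by a Gaussian copula on the log
    scale — correlations are then approximate).
    """

    means: pd.Series
    sds: pd.Series
    correlation: pd.DataFrame
    family: str = "truncated-normal"

    def __post_init__(self) -> None:
        if self.family not in ("truncated-normal", "lognormal"):
            raise InvalidInputError(f"unknown family {self.family!r}")
        if (self.means < 0).any():
            raise InvalidInputError("population means must be >= 0")
        if (self.sds < 0).any():
            raise InvalidInputError("population SDs must be >= 0")
        R = self.correlation.to_numpy(float)
        if not np.allclose(R, R.T):
            raise InvalidInputError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise InvalidInputError("correlation diagonal must be 1")

    @classmethod
    def from_contents(cls, contents: pd.DataFrame,
                      family: str = "truncated-normal") -> "PopulationTruth":
        contents = contents.drop(columns=["total"], errors="ignore")
        return cls(means=contents.mean(), sds=contents.std(ddof=1),
                   correlation=contents.corr(), family=family)

    @classmethod
    def default(cls, family: str = "truncated-normal") -> "PopulationTruth":
        """Moments and correlations of the packaged 55-batch content table
        (computed from the fixture at call time, so fixture corrections
        propagate)."""
        return cls.from_contents(fixture_content_matrix(), family=family)


def _correlation_factor(R: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(R)
    if w.min() < -1e-8:
        raise DecompositionError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})")
    return v * np.sqrt(np.clip(w, 0.0, None))


def make_content_matrix(truth: PopulationTruth,
                        n_batches: int,
                        seed=None) -> pd.DataFrame:
    """Draw a batches x analytes content matrix from the population truth."""
    if n_batches < 2:
        raise InvalidInputError("need n_batches >= 2")
    rng = _rng(seed)
    codes = list(truth.means.index)
    mu = truth.means.to_numpy(float)
    sd = truth.sds.to_numpy(float)
    L = _correlation_factor(truth.correlation.to_numpy(float))
    z = rng.standard_normal((n_batches, len(codes))) @ L.T
    if truth.family == "truncated-normal":
        X = np.clip(mu + z * sd, 0.0, None)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            sigma2 = np.log1p((sd / np.where(mu > 0, mu, np.nan)) ** 2)
            m = np.log(np.where(mu > 0, mu, np.nan)) - sigma2 / 2.0
        X = np.where(np.isnan(m), 0.0, np.exp(m + z * np.sqrt(sigma2)))
    index = pd.RangeIndex(1, n_batches + 1, name="batch")
    return pd.DataFrame(X, index=index, columns=codes)
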