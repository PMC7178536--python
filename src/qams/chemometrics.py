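"""Batch scoring and quality grading from a content matrix.

Given a batches x analytes matrix of mass fractions (mg/g), this module
computes per-batch totals, aglycone ratios, a correlation-matrix PCA, the
composite quality score Z (variance-fraction-weighted sum of the first two
component scores), agglomerative clustering of quality indicators, and the
qualified / superior grading rules:

* unqualified when the six-marker total is below 3 mg/g;
* superior when the total exceeds 8 mg/g AND the aglycone share of the
  total exceeds 10%;
* qualified otherwise.

PCA operates on standardized contents (z-scores), so eigenvalues sum to the
number of analytes and loadings are analyte-component correlations.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .errors import (
    DegenerateFitError,
    InvalidInputError,
    UndefinedStatisticError,
)

logger = logging.getLogger("qams.chemometrics")

AGLYCONES: tuple[str, ...] = ("C", "V", "H")

#: Weights of the two component scores in Z (their variance fractions).
DEFAULT_COMPONENT_WEIGHTS: tuple[float, float] = (0.62614, 0.17646)

GRADE_UNQUALIFIED = "unqualified"
GRADE_QUALIFIED = "qualified"
GRADE_SUPERIOR = "superior"
EXCLUDED = "excluded"


def _contents_only(contents: pd.DataFrame) -> pd.DataFrame:
    """Drop a precomputed total column if the caller left one in."""
    return contents.drop(columns=["total"], errors="ignore")


def batch_totals(contents: pd.DataFrame) -> pd.Series:
    """Row sums of the content matrix (mg/g)."""
    totals = _contents_only(contents).sum(axis=1)
    totals.name = "total"
    return totals


def aglycone_ratio(contents: pd.DataFrame,
                   aglycones: Sequence[str] = AGLYCONES) -> pd.Series:
    """Aglycone share of the total content, in percent per batch.

    Batches with zero total get NaN (logged) rather than an arbitrary value.
    """
    values = _contents_only(contents)
    missing = set(aglycones) - set(values.columns)
    if missing:
        raise InvalidInputError(f"aglycones not in panel: {sorted(missing)}")
    totals = values.sum(axis=1)
    ratio = 100.0 * values[list(aglycones)].sum(axis=1) / totals
    zero = totals == 0
    if zero.any():
        logger.warning("aglycone ratio undefined for zero-total batches: %s",
                       list(values.index[zero]))
        ratio[zero] = np.nan
    ratio.name = "aglycone_ratio_pct"
    return ratio


@dataclass(frozen=True)
class PCAModel:
    """Correlation-matrix PCA of a standardized content matrix.

    ``loadings`` are analyte-component correlations (eigenvector times the
    square root of the eigenvalue), signed so that each component's loading
    sum is non-negative; retaining all components reproduces the correlation
    matrix as ``loadings @ loadings.T``.
    """

    means: pd.Series
    sds: pd.Series
    eigenvalues: np.ndarray
    variance_explained: pd.Series  # percent per component
    loadings: pd.DataFrame  # analytes x components

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def cumulative_variance(self, k: int) -> float:
        return float(self.variance_explained.iloc[:k].sum())

    def standardize(self, contents: pd.DataFrame) -> pd.DataFrame:
        values = _contents_only(contents)[self.means.index]
        return (values - self.means) / self.sds


def fit_pca(contents: pd.DataFrame, ddof: int = 1) -> PCAModel:
    """PCA on the analyte correlation matrix of the content matrix.

    Columns are standardized to z-scores (sample SD by default), the 6x6
    correlation matrix is eigendecomposed, and each component explains
    100 * eigenvalue / n_analytes percent of the variance.
    """
    values = _contents_only(contents)
    if len(values) < 3:
        raise InvalidInputError("PCA needs >= 3 batches")
    constant = values.columns[values.nunique() <= 1]
    if len(constant):
        raise DegenerateFitError(
            f"constant column(s) make the correlation matrix degenerate: "
            f"{', '.join(constant)}")
    X = values.to_numpy(dtype=float)
    corr = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)  # guard tiny negative roundoff
    load = eigvec * np.sqrt(eigval)
    for j in range(load.shape[1]):
        if load[:, j].sum() < 0:
            load[:, j] *= -1.0
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    return PCAModel(
        means=values.mean(),
        sds=values.std(ddof=ddof),
        eigenvalues=eigval,
        variance_explained=pd.Series(100.0 * eigval / len(eigval),
                                     index=comps, name="variance_pct"),
        loadings=pd.DataFrame(load, index=values.columns, columns=comps),
    )


def comprehensive_score(contents: pd.DataFrame,
                        coefficients: pd.DataFrame | None = None,
                        component_weights: tuple[float, float]
                        = DEFAULT_COMPONENT_WEIGHTS,
                        ddof: int = 1) -> pd.DataFrame:
    """Component scores Z1, Z2 and the composite Z per batch.

    Z1 and Z2 are weighted sums of the standardized contents with the
    supplied analyte coefficients (columns ``z1``, ``z2``; defaults to the
    packaged first-two-component loadings), and
    Z = w1 * Z1 + w2 * Z2 with the component weights (defaults to the two
    variance fractions). All batches sitting exactly at the column means
    score zero by construction.
    """
    values = _contents_only(contents)
    if coefficients is None:
        from .synthetic_data import load_fixture
        coefficients = load_fixture("table5")
    missing = set(values.columns) ^ set(coefficients.index)
    if missing:
        raise InvalidInputError(
            f"coefficient panel mismatch: {sorted(missing)}")
    coefficients = coefficients.loc[values.columns]
    sds = values.std(ddof=ddof).replace(0.0, np.inf)  # constant -> z = 0
    zs = (values - values.mean()) / sds
    w1, w2 = component_weights
    out = pd.DataFrame(index=values.index)
    out["Z1"] = zs.to_numpy() @ coefficients["z1"].to_numpy(float)
    out["Z2"] = zs.to_numpy() @ coefficients["z2"].to_numpy(float)
    out["Z"] = w1 * out["Z1"] + w2 * out["Z2"]
    return out


def correlation_with_total(scores: pd.DataFrame) -> float:
    """Pearson correlation between the Z and total columns of a score table."""
    if len(scores) < 3:
        raise InvalidInputError("correlation needs >= 3 batches")
    z = scores["Z"].to_numpy(float)
    t = scores["total"].to_numpy(float)
    if np.ptp(z) == 0 or np.ptp(t) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for a constant column")
    return float(stats.pearsonr(z, t).statistic)


def hca_split(values: pd.Series | pd.DataFrame,
              k: int = 2,
              exclusions: Iterable = (),
              method: str = "average",
              standardize: bool | None = None) -> pd.Series:
    """Agglomerative clustering of a quality indicator, cut at ``k`` clusters.

    ``values`` is either a per-batch 1-D indicator (Series) or a full
    batches x analytes matrix (DataFrame). Matrix input is z-scored by
    column before clustering unless ``standardize`` says otherwise; 1-D
    input is used as is. Distances are Euclidean; the default linkage is
    between-groups average, the convention under which the well-separated
    printed partitions of the reference dataset reproduce (Ward is
    available via ``method="ward"``).

    Excluded batches are labelled ``"excluded"``; the remaining clusters are
    labelled 1..k in increasing order of their mean indicator (mean row sum
    for matrix input). On a 1-D indicator the clusters are contiguous in
    sorted order.
    """
    if k < 2:
        raise InvalidInputError("k must be >= 2")
    exclusions = list(exclusions)
    unknown = [e for e in exclusions if e not in values.index]
    if unknown:
        raise InvalidInputError(f"exclusions not in index: {unknown}")
    kept = values.drop(index=exclusions)
    if len(kept) < k:
        raise InvalidInputError(
            f"k={k} exceeds the {len(kept)} batches left after exclusions")
    if isinstance(kept, pd.Series):
        X = kept.to_numpy(dtype=float).reshape(-1, 1)
        magnitude = kept.astype(float)
        if standardize:
            X = (X - X.mean()) / X.std(ddof=1)
    else:
        if standardize is None:
            standardize = True
        X = kept.to_numpy(dtype=float)
        if standardize:
            X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        magnitude = kept.sum(axis=1).astype(float)
    Z = linkage(X, method=method, metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # relabel 1..k by ascending cluster mean of the indicator
    means = {c: magnitude[raw == c].mean() for c in np.unique(raw)}
    relabel = {c: i + 1 for i, c in enumerate(sorted(means, key=means.get))}
    labels = pd.Series([relabel[c] for c in raw], index=kept.index,
                       dtype=object, name="cluster")
    out = pd.Series(EXCLUDED, index=values.index, dtype=object, name="cluster")
    out.loc[labels.index] = labels
    return out


def flag_singletons(values: pd.Series, factor: float = 3.0) -> list:
    """Advisory outlier flag: batches whose nearest-neighbour distance
    exceeds ``factor`` times the median nearest-neighbour distance.

    This is a helper for choosing HCA exclusions; exclusions themselves are
    always an explicit user decision.
    """
    if len(values) < 3:
        return []
    d = squareform(pdist(values.to_numpy(float).reshape(-1, 1)))
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    cutoff = factor * np.median(nn)
    return list(values.index[nn > cutoff])


@dataclass(frozen=True)
class GradeThresholds:
    """Grading cut-offs; qualification is inclusive (>=), superiority strict."""

    qualified_min_total: float = 3.0
    superior_min_total: float = 8.0
    superior_min_ratio: float = 10.0

    def __post_init__(self) -> None:
        if min(self.qualified_min_total, self.superior_min_total,
               self.superior_min_ratio) <= 0:
            raise InvalidInputError("thresholds must be positive")


def grade(total: float, ratio: float,
          thresholds: GradeThresholds = GradeThresholds()) -> str:
    """Threshold grading of one batch from its total (mg/g) and aglycone
    ratio (%)."""
    if total < thresholds.qualified_min_total:
        return GRADE_UNQUALIFIED
    if (total > thresholds.superior_min_total
            and ratio > thresholds.superior_min_ratio):
        return GRADE_SUPERIOR
    return GRADE_QUALIFIED


def build_score_table(contents: pd.DataFrame,
                      coefficients: pd.DataFrame | None = None,
                      component_weights: tuple[float, float]
                      = DEFAULT_COMPONENT_WEIGHTS,
                      thresholds: GradeThresholds = GradeThresholds(),
                      total_exclusions: Iterable = (),
                      ratio_exclusions: Iterable = (),
                      k: int = 2,
                      method: str = "average",
                      grading: str = "clusters") -> pd.DataFrame:
    """Full per-batch score table: Z1/Z2/Z, total, aglycone ratio, the two
    cluster labels, and the grade.

    The totals clustering runs on the standardized content matrix (the
    multivariate structure behind the totals split); the ratio clustering
    runs on the 1-D aglycone ratios. With ``grading="clusters"`` a batch is
    superior when it sits in the top cluster of both partitions (excluded
    batches can never be superior); ``grading="threshold"`` applies the
    plain cut-offs instead. Unqualified always means a total below the
    qualification bound.
    """
    if grading not in ("clusters", "threshold"):
        raise InvalidInputError(f"unknown grading mode {grading!r}")
    values = _contents_only(contents)
    out = comprehensive_score(values, coefficients, component_weights)
    out["total"] = batch_totals(values)
    out["aglycone_ratio_pct"] = aglycone_ratio(values)
    out["cluster_total"] = hca_split(values, k=k,
                                     exclusions=total_exclusions,
                                     method=method)
    out["cluster_ratio"] = hca_split(out["aglycone_ratio_pct"], k=k,
                                     exclusions=ratio_exclusions,
                                     method=method)
    if grading == "threshold":
        out["grade"] = [grade(t, r, thresholds)
                        for t, r in zip(out["total"],
                                        out["aglycone_ratio_pct"])]
    else:
        top_total = out["cluster_total"] == k
        top_ratio = out["cluster_ratio"] == k
        grades = []
        for batch in out.index:
            if out.at[batch, "total"] < thresholds.qualified_min_total:
                grades.append(GRADE_UNQUALIFIED)
            elif top_total[batch] and top_ratio[batch]:
                grades.append(GRADE_SUPERIOR)
            else:
                grades.append(GRADE_QUALIFIED)
        out["grade"] = grades
    for batch, g in out["grade"].items():
        logger.debug("batch %s: total=%.4g ratio=%.4g grade=%s",
                     batch, out.at[batch, "total"],
                     out.at[batch, "aglycone_ratio_pct"], g)
    return out
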