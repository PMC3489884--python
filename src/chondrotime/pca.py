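"""Temporal-profile PCA, factor scores and outlier-based probe selection.

The procedure identifies probes whose expression changes during a replicated
time course:

1. collapse replicates to per-probe time-point means and eigendecompose the
   time-point x time-point covariance matrix (columns centred across
   probes).  With level differences between probes dominating, component 1
   is the general expression level, component 2 a monotone time trend and
   component 3 a transient mid-course excursion;
2. orient the components deterministically so that a positive component-2
   score means increasing expression and a positive component-3 score a
   transient elevation;
3. regress every probe's individual array values (replicates included) on
   an intercept plus the leading components, standardize each coefficient
   column across probes into *factor scores* (mean 0, SD 1 by
   construction), and keep the per-coefficient t-test p-values that the
   replication affords;
4. select probes whose component-2 or component-3 factor score is an
   outlier (|score| >= 3.29, the two-sided 0.1% point of the standard
   normal) and, optionally, whose triggering coefficient is significant at
   the 5% level;
5. classify selected probes into four temporal subgroups (sustained
   decrease / sustained increase / transient peak / transient dip) and
   discard probes without a gene annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .io import TimeCourseDesign
from .preprocess import standardize_rows, timepoint_means

__all__ = [
    "ComponentSet",
    "FactorScoreTable",
    "SelectionResult",
    "fit_pca",
    "orient_components",
    "factor_scores",
    "expected_null_fraction",
    "select_probes",
    "classify_subgroups",
    "annotate_selection",
    "TimeCourseProfileSelector",
]

logger = logging.getLogger(__name__)

#: Two-sided 0.1% point of the standard normal; the default outlier cut-off.
DEFAULT_CUTOFF = 3.29


@dataclass(frozen=True)
class ComponentSet:
    """Orthonormal time profiles from the time-point covariance PCA.

    ``components`` is a time-point x component DataFrame (columns
    ``PC1``..); eigenvalues are non-increasing and ``variance_fraction``
    sums to 1.
    """

    components: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    oriented: bool = False

    @property
    def n_timepoints(self) -> int:
        return self.components.shape[0]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


@dataclass(frozen=True)
class FactorScoreTable:
    """Per-probe regression coefficients, factor scores and p-values.

    ``coefficients`` holds the raw OLS coefficients on the oriented
    components, ``scores`` the same columns standardized across probes
    (mean 0, SD 1), and ``pvalues`` two-sided t-test p-values for each
    coefficient with ``df_resid`` residual degrees of freedom.
    """

    coefficients: pd.DataFrame
    scores: pd.DataFrame
    pvalues: pd.DataFrame
    df_resid: int


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the outlier selection over factor scores.

    ``table`` is indexed by probe with columns ``selected`` (bool),
    ``component`` (2 or 3, the triggering component; <NA> if unselected),
    ``score`` (the triggering factor score), ``pvalue`` (of the triggering
    coefficient) and ``subgroup`` (1-4 after classification, <NA>
    otherwise).
    """

    table: pd.DataFrame
    cutoff: float
    alpha: float
    require_significance: bool

    @property
    def selected_probes(self) -> pd.Index:
        return self.table.index[self.table["selected"]]

    def subgroup_sizes(self) -> dict[int, int]:
        counts = self.table["subgroup"].value_counts()
        return {g: int(counts.get(g, 0)) for g in (1, 2, 3, 4)}


def fit_pca(mean_profiles: pd.DataFrame) -> ComponentSet:
    """Eigendecompose the time-point covariance of per-probe mean profiles.

    Columns (time points) are centred across probes; eigenvalues are
    returned in non-increasing order and sum to the covariance trace.
    """
    X = mean_profiles.to_numpy(dtype=float)
    n_probes, n_tp = X.shape
    if n_probes < 2:
        raise ValueError("need at least 2 probes to estimate a covariance")
    if n_tp < 2:
        raise ValueError("need at least 2 time points")
    cov = np.cov(X, rowvar=False, ddof=1)
    total = float(np.trace(cov))
    if not total > 0:
        raise ValueError("zero total variance across probes; PCA undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    components = pd.DataFrame(
        eigvecs,
        index=mean_profiles.columns,
        columns=[f"PC{i + 1}" for i in range(n_tp)],
    )
    components.index.name = "timepoint"
    return ComponentSet(
        components=components,
        eigenvalues=eigvals,
        variance_fraction=eigvals / eigvals.sum(),
        oriented=False,
    )


def orient_components(cs: ComponentSet) -> ComponentSet:
    """Fix the sign of each component deterministically.

    Component 1 gets a positive mean entry (general level up); component 2 a
    positive dot product with the ascending time index (positive score =>
    increasing expression); component 3 a higher mean over interior time
    points than over the endpoints (positive score => transient elevation).
    Higher components get a positive maximal-magnitude entry.  Exact ties
    are resolved toward +1 and logged.  The map is idempotent.
    """
    V = cs.components.to_numpy(dtype=float).copy()
    n_tp, n_comp = V.shape
    t_idx = np.arange(n_tp, dtype=float)

    def criterion(j: int) -> float:
        v = V[:, j]
        if j == 0:
            return float(v.mean())
        if j == 1:
            return float(v @ t_idx - v.mean() * t_idx.sum())  # centred ramp
        if j == 2 and n_tp >= 3:
            interior = v[1:-1].mean()
            endpoints = (v[0] + v[-1]) / 2.0
            return float(interior - endpoints)
        k = int(np.argmax(np.abs(v)))
        return float(v[k])

    for j in range(n_comp):
        c = criterion(j)
        if c < 0:
            V[:, j] = -V[:, j]
        elif c == 0:
            logger.warning(
                "orientation tie for component %d; resolved toward +1", j + 1
            )
    components = pd.DataFrame(
        V, index=cs.components.index, columns=cs.components.columns
    )
    components.index.name = cs.components.index.name
    return replace(cs, components=components, oriented=True)


def factor_scores(
    em: pd.DataFrame,
    design: TimeCourseDesign,
    cs: ComponentSet,
    k: int = 3,
) -> FactorScoreTable:
    """OLS of each probe's array values on the leading ``k`` components.

    The design matrix holds components 1..k evaluated at every sample's
    time point (replicates share the regressor value); component 1 is
    nearly constant and carries the probe's general level, so no separate
    intercept is included — adding one would make the design matrix
    near-singular and leak amplified noise into the trend and transient
    coefficients.  All probes share the design matrix, so the fit is
    vectorised.  Coefficient p-values are two-sided t-tests with
    ``n_samples - k`` residual degrees of freedom.  Each coefficient
    column is then standardized across probes into factor scores with
    mean 0 and SD 1.
    """
    if not cs.oriented:
        raise ValueError("components must be oriented before scoring "
                         "(run orient_components)")
    if cs.n_components < k:
        raise ValueError(f"component set has {cs.n_components} < k={k} components")
    design.validate_matrix(em)
    em = em[design.sample_ids]

    tp_sorted = design.timepoints
    tp_pos = pd.Series(np.arange(tp_sorted.size), index=tp_sorted)
    sample_pos = design.timepoint_of().map(tp_pos).to_numpy()

    C = cs.components.to_numpy(dtype=float)[:, :k]
    n_samples = em.shape[1]
    X = C[sample_pos]                   # n_samples x k
    df_resid = n_samples - k
    if df_resid <= 0:
        raise ValueError(
            f"no residual degrees of freedom: {n_samples} samples for "
            f"{k} regression parameters"
        )

    Y = em.to_numpy(dtype=float)
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T                      # probes x k
    resid = Y - B @ X.T
    s2 = (resid ** 2).sum(axis=1) / df_resid
    xtx_inv_diag = np.diag(np.linalg.pinv(X.T @ X))
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.outer(s2, xtx_inv_diag))
        tstat = B / se
    tstat = np.where((se == 0) & (B == 0), 0.0, tstat)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df_resid)

    cols = [f"PC{i + 1}" for i in range(k)]
    coef = pd.DataFrame(B, index=em.index, columns=cols)
    pv = pd.DataFrame(pvals, index=em.index, columns=cols)

    sd = coef.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = sd.index[sd <= 0].tolist()
        raise ValueError(f"zero variance in coefficient column(s) {bad}; "
                         "cannot standardize factor scores")
    scores = (coef - coef.mean(axis=0)) / sd
    return FactorScoreTable(
        coefficients=coef, scores=scores, pvalues=pv, df_resid=df_resid
    )


def expected_null_fraction(cutoff: float, sided: str = "two") -> float:
    """Fraction of probes a |score| >= cutoff rule selects under pure noise.

    Factor scores are standardized, so under the null they follow a standard
    normal: the expected selected fraction is ``2 * (1 - Phi(cutoff))``
    two-sided and ``1 - Phi(cutoff)`` one-sided.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    tail = float(stats.norm.sf(cutoff))
    return 2.0 * tail if sided == "two" else tail


def select_probes(
    fst: FactorScoreTable,
    cutoff: float = DEFAULT_CUTOFF,
    alpha: float = 0.05,
    require_significance: bool = True,
) -> SelectionResult:
    """Select probes with outlying component-2 or component-3 factor scores.

    A probe is selected iff ``max(|f2|, |f3|) >= cutoff`` (inclusive) and,
    when ``require_significance``, the triggering coefficient's replicate
    t-test p-value is below ``alpha``.  Component 2 takes precedence over
    component 3 when both exceed the cut-off; component 1 (general level)
    never triggers selection.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    for col in ("PC2", "PC3"):
        if col not in fst.scores.columns:
            raise ValueError("selection requires factor scores for components 2 and 3")

    f2 = fst.scores["PC2"]
    f3 = fst.scores["PC3"]
    hit2 = f2.abs() >= cutoff
    hit3 = f3.abs() >= cutoff

    component = pd.Series(pd.NA, index=fst.scores.index, dtype="Int64")
    component[hit3] = 3
    component[hit2] = 2  # precedence: component 2 overrides

    score = pd.Series(np.nan, index=fst.scores.index, dtype=float)
    score[component == 2] = f2[component == 2]
    score[component == 3] = f3[component == 3]

    pvalue = pd.Series(np.nan, index=fst.scores.index, dtype=float)
    pvalue[component == 2] = fst.pvalues.loc[component == 2, "PC2"]
    pvalue[component == 3] = fst.pvalues.loc[component == 3, "PC3"]

    selected = component.notna()
    if require_significance:
        selected &= pvalue < alpha
    component = component.where(selected, pd.NA)
    score = score.where(selected, np.nan)
    pvalue = pvalue.where(selected, np.nan)

    table = pd.DataFrame(
        {
            "selected": selected.astype(bool),
            "component": component,
            "score": score,
            "pvalue": pvalue,
            "subgroup": pd.Series(pd.NA, index=fst.scores.index, dtype="Int64"),
        }
    )
    table.index.name = "probe_id"
    return SelectionResult(
        table=table,
        cutoff=cutoff,
        alpha=alpha,
        require_significance=require_significance,
    )


def classify_subgroups(fst: FactorScoreTable, sel: SelectionResult) -> SelectionResult:
    """Assign each selected probe to one of four temporal subgroups.

    With oriented components: subgroup 1 = sustained decrease (f2 <=
    -cutoff), subgroup 2 = sustained increase (f2 >= cutoff), subgroup 3 =
    transient peak (else f3 >= cutoff), subgroup 4 = transient dip (else f3
    <= -cutoff).  Subgroups are disjoint and cover all selected probes.
    """
    c = sel.cutoff
    f2 = fst.scores["PC2"]
    f3 = fst.scores["PC3"]
    table = sel.table.copy()
    subgroup = pd.Series(pd.NA, index=table.index, dtype="Int64")
    selected = table["selected"]
    subgroup[selected & (f3 <= -c)] = 4
    subgroup[selected & (f3 >= c)] = 3
    subgroup[selected & (f2 <= -c)] = 1
    subgroup[selected & (f2 >= c)] = 2
    # probes triggered by component 2 keep the component-2 label even when
    # their |f3| also clears the cut-off
    subgroup[selected & (table["component"] == 3) & (f3 >= c)] = 3
    subgroup[selected & (table["component"] == 3) & (f3 <= -c)] = 4
    table["subgroup"] = subgroup
    return replace(sel, table=table)


def annotate_selection(
    sel: SelectionResult, annotation: pd.Series
) -> tuple[pd.DataFrame, int]:
    """Attach gene symbols to selected probes, dropping unannotated ones.

    Returns the annotated gene table (probe-indexed, with ``gene_symbol``,
    ``subgroup``, ``component``, ``score``, ``pvalue``) and the count of
    selected probes that had no annotation.  A probe absent from the
    annotation table altogether is an error, distinct from a probe present
    with an empty symbol.
    """
    picked = sel.table[sel.table["selected"]]
    missing = picked.index.difference(annotation.index)
    if len(missing):
        raise ValueError(
            f"selected probe(s) absent from annotation table: {missing.tolist()[:10]}"
        )
    symbols = annotation.reindex(picked.index)
    unannotated = symbols.isna()
    genes = picked.loc[~unannotated].copy()
    genes.insert(0, "gene_symbol", symbols[~unannotated])
    genes = genes.drop(columns=["selected"])
    return genes, int(unannotated.sum())


class TimeCourseProfileSelector(BaseEstimator):
    """End-to-end temporal-profile selection as an sklearn-style estimator.

    Fits the covariance PCA on per-probe time-point means, computes factor
    scores by replicate regression, applies the outlier cut-off and the
    replicate-based significance filter, and classifies the selected probes
    into four temporal subgroups.

    Parameters
    ----------
    n_components : int
        Number of leading components used in the factor-score regression.
    cutoff : float
        Outlier threshold on |factor score| (inclusive); 3.29 selects 0.1%
        of probes two-sided under a pure-noise normal null.
    alpha : float
        Significance level of the per-coefficient replicate t-test.
    require_significance : bool
        Whether the t-test filter is applied on top of the cut-off.
    standardize : bool
        Rescale every probe row to mean 0 / SD 1 before the analysis.  The
        default (False) keeps per-probe level differences, so component 1
        describes the general expression level.

    Attributes
    ----------
    components_ : DataFrame, time point x component oriented profiles.
    eigenvalues_ : ndarray, non-increasing.
    explained_variance_ratio_ : ndarray.
    coefficients_, factor_scores_, pvalues_ : DataFrames, probe x component.
    selection_ : SelectionResult.
    subgroup_sizes_ : dict mapping subgroup 1-4 to probe counts.
    """

    def __init__(
        self,
        n_components: int = 3,
        cutoff: float = DEFAULT_CUTOFF,
        alpha: float = 0.05,
        require_significance: bool = True,
        standardize: bool = False,
    ):
        self.n_components = n_components
        self.cutoff = cutoff
        self.alpha = alpha
        self.require_significance = require_significance
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, design: TimeCourseDesign):
        em = standardize_rows(X) if self.standardize else X
        mpm = timepoint_means(em, design)
        cs = orient_components(fit_pca(mpm))
        fst = factor_scores(em, design, cs, k=self.n_components)
        sel = select_probes(
            fst,
            cutoff=self.cutoff,
            alpha=self.alpha,
            require_significance=self.require_significance,
        )
        sel = classify_subgroups(fst, sel)

        self.component_set_ = cs
        self.components_ = cs.components
        self.eigenvalues_ = cs.eigenvalues
        self.explained_variance_ratio_ = cs.variance_fraction
        self.factor_score_table_ = fst
        self.coefficients_ = fst.coefficients
        self.factor_scores_ = fst.scores
        self.pvalues_ = fst.pvalues
        self.selection_ = sel
        self.subgroup_sizes_ = sel.subgroup_sizes()
        return self

    def get_support(self) -> pd.Index:
        """Probe IDs of the selected rows."""
        return self.selection_.selected_probes

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a probes x samples matrix to the selected probes."""
        return X.loc[self.get_support()]

    def annotate(self, annotation: pd.Series) -> tuple[pd.DataFrame, int]:
        """Gene table for the selection; see :func:`annotate_selection`."""
        return annotate_selection(self.selection_, annotation)
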