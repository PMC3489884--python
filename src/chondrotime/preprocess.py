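"""Per-probe standardization and replicate averaging.

Each probe's trajectory can be linearly rescaled to mean 0 / SD 1 across all
arrays of the time course (a reporting transform that removes the overall
expression level), and replicate arrays can be collapsed to one mean value
per time point — the input to the temporal PCA.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import TimeCourseDesign

__all__ = ["standardize_rows", "timepoint_means", "RowStandardizer"]


def standardize_rows(em: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Linearly scale every probe row to mean 0 and SD 1.

    Parameters
    ----------
    em : DataFrame
        Probes x samples matrix of finite values.
    ddof : int
        Delta degrees of freedom for the row SD (1 = sample SD).

    Raises
    ------
    ValueError
        If any row has zero variance; the offending probe IDs are listed.
    """
    values = em.to_numpy(dtype=float)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    zero = ~(sd > 0)
    if zero.any():
        probes = em.index[zero].tolist()
        shown = probes[:10]
        more = f" (+{len(probes) - 10} more)" if len(probes) > 10 else ""
        raise ValueError(f"zero-variance probe row(s): {shown}{more}")
    out = (values - mean[:, None]) / sd[:, None]
    return pd.DataFrame(out, index=em.index, columns=em.columns)


def timepoint_means(em: pd.DataFrame, design: TimeCourseDesign) -> pd.DataFrame:
    """Arithmetic mean over replicate arrays, one column per time point."""
    design.validate_matrix(em)
    cols = {
        t: em[design.samples_at(t)].mean(axis=1) for t in design.timepoints
    }
    mpm = pd.DataFrame(cols)
    mpm.columns.name = "timepoint"
    return mpm


class RowStandardizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping :func:`standardize_rows`.

    Stateless per row: every row is rescaled using its own mean and SD, so
    ``fit`` only validates the input.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return standardize_rows(X, ddof=self.ddof)
        frame = pd.DataFrame(np.asarray(X, dtype=float))
        return standardize_rows(frame, ddof=self.ddof).to_numpy()
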