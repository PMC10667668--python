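"""Per-sample total-count normalization of spectral counts.

Spectral counts are semi-quantitative and the total number of identified
spectra varies between runs, so columns are rescaled to a common total
(10,000 spectra per sample by default) before abundances are compared across
samples.  Rescaling preserves within-sample proportions and rank order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import DEFAULT_TOTAL, SpectralCountMatrix


class SpectralCountNormalizer(BaseEstimator, TransformerMixin):
    """Rescale each sample column to a fixed total.

    Parameters
    ----------
    total : float, default 10000
        Target column sum.

    Attributes
    ----------
    scale_factors_ : pandas.Series
        Per-sample factor ``total / column_sum`` computed during :meth:`fit`.
    """

    def __init__(self, total: float = DEFAULT_TOTAL):
        self.total = total

    def _frame(self, X) -> pd.DataFrame:
        return X.counts if isinstance(X, SpectralCountMatrix) else pd.DataFrame(X)

    def fit(self, X, y=None):
        if self.total <= 0:
            raise ValueError(f"total must be > 0, got {self.total}")
        frame = self._frame(X)
        sums = frame.sum(axis=0)
        zero = list(sums.index[sums == 0])
        if zero:
            raise ValueError(
                f"cannot normalize samples with zero total counts: {zero}"
            )
        self.scale_factors_ = self.total / sums
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X):
        frame = self._frame(X)
        scaled = frame.astype(float) * self.scale_factors_.loc[frame.columns]
        if isinstance(X, SpectralCountMatrix):
            return SpectralCountMatrix(
                counts=scaled,
                samples=X.samples,
                normalized=True,
                total=self.total,
                raw=X.raw_counts().copy(),
            )
        return scaled


def normalize_counts(
    matrix: SpectralCountMatrix, total: float = DEFAULT_TOTAL
) -> SpectralCountMatrix:
    """Return a copy of ``matrix`` with every sample column summing to ``total``.

    Idempotent: normalizing an already-normalized matrix is a no-op (all scale
    factors are 1).  A sample with zero total counts raises ``ValueError``
    naming the sample, rather than propagating NaNs.
    """
    return SpectralCountNormalizer(total=total).fit_transform(matrix)
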