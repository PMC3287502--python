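"""Array-generation based gene centering (AGC).

Microarray cohorts profiled in separate timeframes carry additive
per-generation intensity offsets.  AGC removes them by centering each probe
within each batch: every (probe, batch) cell of the matrix has that batch's
probe mean (or median) subtracted, leaving within-batch contrasts intact.

AGC is applied as a fixed preprocessing of the whole dataset before any CV
split, mirroring its role as dataset-level background-noise removal.  Note
the caveat: because centering sees all samples of a batch, label-free
though it is, it couples samples across future CV folds.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import LabeledExpressionDataset, ValidationError


class AGCCenterer(BaseEstimator, TransformerMixin):
    """Per-(probe, batch) centering transformer.

    Parameters
    ----------
    center : {"mean", "median"}
        Location statistic subtracted within each batch.

    Attributes
    ----------
    offsets_ : dict batch -> ndarray of shape (n_probes,)
        Per-batch probe centers learned by :meth:`fit`.
    """

    def __init__(self, center: str = "mean"):
        self.center = center

    def fit(self, X, y=None, *, batch=None):
        X = np.asarray(X, dtype=float)
        if batch is None:
            raise ValidationError(
                "AGC requires batch labels; pass batch= or disable AGC"
            )
        batch = np.asarray(batch)
        if len(batch) != X.shape[0]:
            raise ValidationError("one batch label required per sample")
        if self.center not in ("mean", "median"):
            raise ValidationError(f"unknown center {self.center!r}")
        stat = np.mean if self.center == "mean" else np.median
        self.offsets_ = {}
        for b in np.unique(batch):
            rows = batch == b
            if rows.sum() < 2:
                warnings.warn(
                    f"batch {b!r} has {int(rows.sum())} sample(s); "
                    "centering it anyway",
                    stacklevel=2,
                )
            self.offsets_[b] = stat(X[rows], axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X, *, batch=None):
        X = np.asarray(X, dtype=float)
        if batch is None:
            raise ValidationError("AGC transform requires batch labels")
        batch = np.asarray(batch)
        out = X.copy()
        for b in np.unique(batch):
            if b not in self.offsets_:
                raise ValidationError(f"batch {b!r} was not seen during fit")
            out[batch == b] -= self.offsets_[b]
        return out

    def fit_transform(self, X, y=None, *, batch=None):
        return self.fit(X, batch=batch).transform(X, batch=batch)


def agc_center(
    ds: LabeledExpressionDataset, center: str = "mean"
) -> LabeledExpressionDataset:
    """Batch-center a dataset; labels, ordering and batch labels untouched.

    A dataset without batch labels is rejected — either attach batch labels
    or skip AGC.
    """
    if ds.batch is None:
        raise ValidationError(
            "dataset has no batch labels; AGC not applicable (use --no-agc)"
        )
    values = AGCCenterer(center=center).fit_transform(ds.values, batch=ds.batch)
    return LabeledExpressionDataset(
        sample_ids=list(ds.sample_ids),
        probe_ids=list(ds.probe_ids),
        values=values,
        labels=list(ds.labels),
        positive_class=ds.positive_class,
        batch=list(ds.batch),
    )
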