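"""Shared feature-matrix container used by all feature models.

A :class:`FeatureMatrix` holds a stimuli x features array for one named
model together with its column labels and (lazily computed) z-scored
version.  Encoding models are always fit on z-scored columns; RDM-based
stimulus selection uses the raw values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureMatrix", "zscore_columns"]


def zscore_columns(values: np.ndarray, eps: float = 1e-12):
    """Z-score each column of ``values``.

    Returns ``(zscored, means, sds, constant_mask)``.  Columns whose
    standard deviation is (numerically) zero are set to 0 and flagged in
    ``constant_mask`` rather than producing NaNs.
    """
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0)
    constant = sds <= eps
    safe_sds = np.where(constant, 1.0, sds)
    z = (values - means) / safe_sds
    z[:, constant] = 0.0
    return z, means, sds, constant


@dataclass
class FeatureMatrix:
    """Stimuli x features matrix for one feature model.

    Parameters
    ----------
    values:
        Raw (pre z-scoring) feature values, shape ``(n_stimuli, n_features)``.
    model_name:
        Name of the feature model (e.g. ``"gabor"``, ``"3d-global"``).
    feature_labels:
        One label per column.
    stimulus_ids:
        One identifier per row, aligned with the stimulus set ordering.
    """

    values: np.ndarray
    model_name: str
    feature_labels: list[str]
    stimulus_ids: list[str]
    _z: np.ndarray | None = field(default=None, repr=False)
    _means: np.ndarray | None = field(default=None, repr=False)
    _sds: np.ndarray | None = field(default=None, repr=False)
    _constant: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (stimuli x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite feature values in model {self.model_name!r}")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("feature_labels length does not match number of columns")
        if len(self.stimulus_ids) != self.values.shape[0]:
            raise ValueError("stimulus_ids length does not match number of rows")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def zscored(self) -> np.ndarray:
        """Column z-scored values (constant columns set to 0)."""
        if self._z is None:
            self._z, self._means, self._sds, self._constant = zscore_columns(self.values)
        return self._z

    @property
    def column_means(self) -> np.ndarray:
        self.zscored
        return self._means

    @property
    def column_sds(self) -> np.ndarray:
        self.zscored
        return self._sds

    @property
    def constant_columns(self) -> np.ndarray:
        """Boolean mask of columns that were constant before z-scoring."""
        self.zscored
        return self._constant

    def subset(self, row_idx) -> "FeatureMatrix":
        """New FeatureMatrix restricted to the given stimulus rows."""
        row_idx = np.asarray(row_idx)
        return FeatureMatrix(
            values=self.values[row_idx],
            model_name=self.model_name,
            feature_labels=list(self.feature_labels),
            stimulus_ids=[self.stimulus_ids[i] for i in row_idx],
        )
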