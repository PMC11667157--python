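"""Lightweight reference classifiers for feature tensors.

These are not the decoding contribution — they are fast baselines used
where training the full network per candidate configuration would be
wasteful, e.g. one fit per band in the frequency scan.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = ["BandPowerLogistic"]


class BandPowerLogistic:
    """Logistic regression on coarsely pooled log-power images.

    Each 110 x 100 frame is block-averaged back to the 11 x 10 electrode
    grid (undoing the interpolation upsampling), log-transformed and
    standardized, giving 11*10*n_bands features per trial.
    """

    def __init__(self, c: float = 1.0, max_iter: int = 2000) -> None:
        self._clf = make_pipeline(
            StandardScaler(), LogisticRegression(C=c, max_iter=max_iter)
        )

    @staticmethod
    def _features(tensors: np.ndarray) -> np.ndarray:
        n, nx, ny, nb = tensors.shape
        fx, fy = nx // 11, ny // 10
        pooled = (
            tensors[:, : 11 * fx, : 10 * fy]
            .reshape(n, 11, fx, 10, fy, nb)
            .mean(axis=(2, 4))
        )
        return np.log10(np.maximum(pooled, 1e-12)).reshape(n, -1)

    def fit(self, tensors: np.ndarray, labels: np.ndarray) -> "BandPowerLogistic":
        self._clf.fit(self._features(tensors), labels)
        return self

    def predict(self, tensors: np.ndarray) -> np.ndarray:
        return self._clf.predict(self._features(tensors))
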