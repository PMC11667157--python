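"""Welch power spectral density, sub-band powers, and band-scan selection.

The PSD estimator is written out from first principles: the trial is cut
into L contiguous blocks of M samples, each block is tapered, its
periodogram is normalized by the window power U = (1/M) sum w(n)^2, and
the L periodograms are averaged.  Periodograms are additionally scaled
by 1/(M fs) (with the usual factor 2 on interior one-sided bins) so the
output is a density in uV^2/Hz whose integral recovers signal power.

Defaults are chosen for 4-s trials at 160 Hz: M = 320 gives L = 2 blocks
and a 0.5 Hz bin spacing, exactly one bin per sub-band when the 10-15 Hz
mu band is split into ten 0.5 Hz sub-bands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.signal import get_window

from .eeg_io import Segment

__all__ = [
    "WelchConfig",
    "PSDEstimate",
    "SubBandPower",
    "BandScanResult",
    "welch_psd",
    "segment_psd",
    "subband_power",
    "band_scan",
]


@dataclass(frozen=True)
class WelchConfig:
    """Block structure and taper of the Welch estimator.

    ``segment_length`` is M (samples per block); ``n_segments`` is L, or
    None to use as many full non-overlapping blocks as fit.  ``overlap``
    is the fractional block overlap (0 = contiguous blocks, the default;
    0.5 is the common alternative).
    """

    segment_length: int = 320
    n_segments: int | None = None
    window: str = "hamming"
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length M must be positive")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")

    def taper(self) -> np.ndarray:
        if self.window == "rectangular":
            return np.ones(self.segment_length)
        return get_window(self.window, self.segment_length, fftbins=True)

    def normalization(self) -> float:
        """U = (1/M) sum w(n)^2; positive for any admissible taper."""
        w = self.taper()
        return float(np.sum(w**2) / self.segment_length)


@dataclass
class PSDEstimate:
    """One-sided power spectral density, ``power[channels x bins]``."""

    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray        # uV^2/Hz, >= 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=np.float64))
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.power.shape[-1] != self.frequencies.size:
            raise ValueError("power/frequency bin mismatch")
        if np.any(self.power < -1e-12):
            raise ValueError("negative power")

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class SubBandPower:
    """Per-channel mean PSD in contiguous equal-width sub-bands."""

    band_edges: list[tuple[float, float]]
    power: np.ndarray  # [channels x n_bands]

    @property
    def n_bands(self) -> int:
        return len(self.band_edges)


def welch_psd(
    x: np.ndarray,
    sampling_rate: float,
    config: WelchConfig | None = None,
) -> PSDEstimate:
    """Welch PSD of one or more channels (last axis = time).

    Blocks are ``x[n + iM - M]`` for i = 1..L (contiguous, or overlapped
    per config); each is tapered, periodogram-normalized by U, scaled to
    density units, and the blocks are averaged.
    """
    config = config or WelchConfig()
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    n = x.shape[-1]
    m = config.segment_length
    step = max(1, int(round(m * (1 - config.overlap))))
    max_blocks = (n - m) // step + 1 if n >= m else 0
    L = config.n_segments if config.n_segments is not None else max_blocks
    if L < 1 or L > max_blocks:
        raise ValueError(
            f"cannot cut {L if config.n_segments else 1} block(s) of "
            f"M={m} from N={n} samples at overlap {config.overlap}"
        )

    w = config.taper()
    u = config.normalization()
    n_bins = m // 2 + 1
    acc = np.zeros(x.shape[:-1] + (n_bins,))
    for i in range(L):
        block = x[..., i * step : i * step + m]
        spec = np.fft.rfft(block * w, axis=-1)
        periodogram = (np.abs(spec) ** 2) / (u * m * sampling_rate)
        periodogram[..., 1:] *= 2.0
        if m % 2 == 0:
            periodogram[..., -1] /= 2.0
        acc += periodogram
    acc /= L
    freqs = np.fft.rfftfreq(m, d=1.0 / sampling_rate)
    return PSDEstimate(frequencies=freqs, power=acc)


def segment_psd(seg: Segment, config: WelchConfig | None = None) -> PSDEstimate:
    """All-channel Welch PSD of one trial."""
    return welch_psd(seg.samples, seg.sampling_rate, config)


def subband_power(
    psd: PSDEstimate,
    band: tuple[float, float] = (10.0, 15.0),
    n_subbands: int = 10,
) -> SubBandPower:
    """Split ``band`` into equal sub-bands and average PSD bins in each.

    A bin belongs to the sub-band whose half-open interval [low, high)
    contains its center frequency.  Each sub-band must contain at least
    one bin, i.e. the sub-band width must not fall below the frequency
    resolution.
    """
    low, high = band
    if not (psd.frequencies[0] <= low < high <= psd.frequencies[-1] + 1e-9):
        raise ValueError(f"band {band} outside PSD range")
    width = (high - low) / n_subbands
    edges = [(low + k * width, low + (k + 1) * width) for k in range(n_subbands)]
    values = np.empty(psd.power.shape[:-1] + (n_subbands,))
    for k, (lo, hi) in enumerate(edges):
        mask = (psd.frequencies >= lo - 1e-9) & (psd.frequencies < hi - 1e-9)
        if not mask.any():
            raise ValueError(
                f"sub-band [{lo:g}, {hi:g}) Hz contains no PSD bin at "
                f"resolution {psd.resolution:g} Hz; use a larger "
                "segment_length M"
            )
        values[..., k] = psd.power[..., mask].mean(axis=-1)
    return SubBandPower(band_edges=edges, power=values)


class ClassifierProtocol(Protocol):
    """Anything that fits on feature tensors and predicts class labels."""

    def fit(self, tensors: np.ndarray, labels: np.ndarray) -> "ClassifierProtocol": ...

    def predict(self, tensors: np.ndarray) -> np.ndarray: ...


@dataclass
class BandScanResult:
    """Per-band accuracies of the scan; ``selected_band`` is the argmax
    (ties broken toward the lower band edge)."""

    bands: list[tuple[float, float]]
    mean_accuracy: np.ndarray
    std_accuracy: np.ndarray
    selected_band: tuple[float, float]


def band_scan(
    segments: Sequence[Segment],
    scan_low: float = 5.0,
    scan_high: float = 35.0,
    width: float = 5.0,
    eval_fn: ClassifierProtocol | Callable[[], ClassifierProtocol] | None = None,
    n_subbands: int = 10,
    welch: WelchConfig | None = None,
    n_splits: int = 3,
    split_seed: int = 42,
) -> BandScanResult:
    """Scan contiguous frequency bands and pick the most decodable one.

    For each band, trials are imaged into spatial-spectral tensors and a
    classifier is trained/evaluated under the 75/25 shuffle-split
    protocol; mean and std accuracy are taken over ``n_splits`` repeated
    splits (seeds derived from ``split_seed``).  ``eval_fn`` supplies the
    classifier (a factory or instance); default is a compact pseudo-3D
    CNN with reduced training (see ``mitopo.model.reduced_configs``).
    """
    from .evaluation import SplitSpec, split as split_data
    from .topomap import segments_to_tensors

    n_bands_f = (scan_high - scan_low) / width
    if abs(n_bands_f - round(n_bands_f)) > 1e-9:
        raise ValueError("scan range must be divisible by band width")
    labels_all = {s.class_label for s in segments}
    if len(labels_all) < 2:
        raise ValueError("band scan needs at least two classes")

    bands = [
        (scan_low + k * width, scan_low + (k + 1) * width)
        for k in range(int(round(n_bands_f)))
    ]

    def make_classifier() -> ClassifierProtocol:
        if eval_fn is None:
            from .model import P3DCNNClassifier

            return P3DCNNClassifier.reduced(seed=split_seed)
        if isinstance(eval_fn, type) or (
            callable(eval_fn) and not hasattr(eval_fn, "fit")
        ):
            return eval_fn()  # class or factory
        return eval_fn  # ready-made instance, refit per band/split

    means, stds = [], []
    for band in bands:
        tensors, labels = segments_to_tensors(
            segments, band=band, n_subbands=n_subbands, welch=welch
        )
        accs = []
        for rep in range(n_splits):
            spec = SplitSpec(shuffle_seed=split_seed + rep)
            (x_tr, y_tr), (x_te, y_te) = split_data(tensors, labels, spec)
            if len(np.unique(y_tr)) < 2:
                raise ValueError("a split left a class empty; need more trials")
            clf = make_classifier()
            clf.fit(x_tr, y_tr)
            accs.append(float(np.mean(clf.predict(x_te) == y_te)))
        means.append(float(np.mean(accs)))
        stds.append(float(np.std(accs)))

    means_arr = np.asarray(means)
    best = int(np.argmax(means_arr))  # argmax returns first max -> lowest band
    return BandScanResult(
        bands=bands,
        mean_accuracy=means_arr,
        std_accuracy=np.asarray(stds),
        selected_band=bands[best],
    )
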