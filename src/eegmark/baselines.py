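"""Conventional EEG features and a ten-learner classical benchmark.

Features per subject: band power in Delta (0.5-4), Theta (4-8), Alpha
(8-12), Beta (12-20) and Gamma (20-45 Hz) at each of the 10 channels, the
alpha peak frequency, and six lagged linear connectivity values between the
frontal, central, parietal and occipital lobe averages.  The connectivity
estimator is the lagged-coherence family: per frequency
Im(Sxy)^2 / (Sxx*Syy - Re(Sxy)^2), which removes instantaneous (zero-lag)
dependence such as volume conduction, band-averaged over 0.5-45 Hz.

The benchmark runs ten established learners with leave-one-subject-out
cross-validation at library defaults with fixed seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from eegmark.channels import CANONICAL_CHANNELS, LOBE_MAP, LOBES

__all__ = [
    "BANDS", "FeatureVector", "band_powers", "alpha_peak_frequency",
    "lagged_connectivity", "subject_features", "feature_matrix",
    "default_algorithms", "loo_benchmark",
]

#: Frequency bands (Hz), contiguous and within the 0.5-45 Hz passband.
BANDS: dict[str, tuple[float, float]] = {
    "Delta": (0.5, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 12.0),
    "Beta": (12.0, 20.0),
    "Gamma": (20.0, 45.0),
}


@dataclass
class FeatureVector:
    subject_id: str
    band_powers: np.ndarray        # 5 bands x 10 channels
    alpha_peak: float              # Hz
    connectivity: np.ndarray       # 6 lobe-pair values
    label: int | None = None

    def flat(self) -> np.ndarray:
        return np.concatenate([self.band_powers.ravel(),
                               [self.alpha_peak], self.connectivity])


def _mean_periodogram(segments: np.ndarray, fs: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Average one-sided periodogram over segments; (freqs, ch x freq power)."""
    n = segments.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    x = segments - segments.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2 / (fs * n)
    if n % 2 == 0:
        spec[..., 1:-1] *= 2.0
    else:
        spec[..., 1:] *= 2.0
    return freqs, spec.mean(axis=0)


def band_powers(segments: np.ndarray, fs: float = 250.0) -> np.ndarray:
    """5 x 10 table: per-band integrated power of the segment-average spectrum."""
    if len(segments) == 0:
        raise ValueError("no segments supplied")
    freqs, psd = _mean_periodogram(segments, fs)
    df = freqs[1] - freqs[0]
    out = np.empty((len(BANDS), segments.shape[1]))
    for bi, (lo, hi) in enumerate(BANDS.values()):
        mask = (freqs >= lo) & (freqs < hi)
        out[bi] = psd[:, mask].sum(axis=1) * df
    return out


def alpha_peak_frequency(freqs: np.ndarray, psd: np.ndarray
                         ) -> tuple[float, bool]:
    """Frequency of maximum power within [8, 12] Hz of an average spectrum.

    Returns (peak, flat_flag); a flat window returns the midpoint flagged.
    Ties resolve to the lower frequency.
    """
    mask = (freqs >= 8.0) & (freqs <= 12.0)
    if not mask.any():
        raise ValueError("spectrum does not cover the 8-12 Hz window")
    window = psd[mask]
    if np.allclose(window, window[0]):
        return 10.0, True
    return float(freqs[mask][np.argmax(window)]), False


def lagged_connectivity(segments: np.ndarray, fs: float = 250.0,
                        channels: tuple[str, ...] = CANONICAL_CHANNELS,
                        band: tuple[float, float] = (0.5, 45.0)
                        ) -> dict[tuple[str, str], float]:
    """Lagged linear dependence between lobe-average signals, band-averaged.

    Cross-spectra are averaged over segments; the instantaneous component is
    excluded by construction, so identical zero-lag signals score ~0 while a
    time-shifted copy scores high.  Values are clipped to [0, 1].
    """
    lobe_signals = {}
    for lobe in LOBES:
        idx = [i for i, c in enumerate(channels) if LOBE_MAP.get(c) == lobe]
        if not idx:
            warnings.warn(f"no channels in lobe {lobe}; its pairs are omitted")
            continue
        lobe_signals[lobe] = segments[:, idx, :].mean(axis=1)
    n = segments.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    ffts = {lobe: np.fft.rfft(x - x.mean(axis=-1, keepdims=True), axis=-1)
            for lobe, x in lobe_signals.items()}
    out = {}
    for a, b in combinations([l for l in LOBES if l in lobe_signals], 2):
        Fa, Fb = ffts[a], ffts[b]
        Sxy = (Fa * np.conj(Fb)).mean(axis=0)
        Sxx = (np.abs(Fa) ** 2).mean(axis=0)
        Syy = (np.abs(Fb) ** 2).mean(axis=0)
        num = Sxy.imag ** 2
        den = Sxx * Syy - Sxy.real ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            lagged = np.where(den > 1e-20, num / np.maximum(den, 1e-20), 0.0)
        out[(a, b)] = float(np.clip(lagged[mask], 0.0, 1.0).mean())
    return out


def subject_features(subject_id: str, segments: np.ndarray, fs: float = 250.0,
                     label: int | None = None) -> FeatureVector:
    """The full conventional feature vector of one subject."""
    bp = band_powers(segments, fs)
    freqs, psd = _mean_periodogram(segments, fs)
    peak, _ = alpha_peak_frequency(freqs, psd.mean(axis=0))
    conn = lagged_connectivity(segments, fs)
    conn_vec = np.array([conn[pair] for pair in sorted(conn)])
    return FeatureVector(subject_id, bp, peak, conn_vec, label)


def feature_matrix(segs, fs: float = 250.0) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-subject feature vectors from a labelled SegmentSet."""
    X, y, ids = [], [], []
    for sid in np.unique(segs.subject_ids):
        mask = segs.subject_ids == sid
        fv = subject_features(str(sid), segs.data[mask], fs,
                              int(segs.labels[mask][0]))
        X.append(fv.flat())
        y.append(fv.label)
        ids.append(str(sid))
    return np.array(X), np.array(y), ids


def default_algorithms(seed: int = 0) -> dict[str, object]:
    """The ten classical learners of the benchmark, at library defaults."""
    from lightgbm import LGBMClassifier
    from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    return {
        "LogisticRegression": LogisticRegression(max_iter=2000),
        "NaiveBayes": GaussianNB(),
        "DecisionTree": DecisionTreeClassifier(random_state=seed),
        "RandomForest": RandomForestClassifier(random_state=seed),
        "GradientBoosting": GradientBoostingClassifier(random_state=seed),
        "LightGBM": LGBMClassifier(random_state=seed, verbose=-1),
        "XGBoost": XGBClassifier(random_state=seed, verbosity=0),
        "KNN": KNeighborsClassifier(),
        "SVM": SVC(random_state=seed),
        "AdaBoost": AdaBoostClassifier(random_state=seed),
    }


def loo_benchmark(X: np.ndarray, y: np.ndarray,
                  algorithms: dict[str, object] | None = None,
                  seed: int = 0) -> dict[str, float]:
    """Leave-one-subject-out accuracy per algorithm.

    Features are standardized inside each fold (fit on the training part);
    zero-variance features are dropped with a notice.
    """
    from sklearn.base import clone
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per class")
    var = X.var(axis=0)
    if (var == 0).any():
        warnings.warn(f"dropping {int((var == 0).sum())} zero-variance features")
        X = X[:, var > 0]
    if algorithms is None:
        algorithms = default_algorithms(seed)
    results = {}
    for name, est in algorithms.items():
        correct = 0
        for i in range(len(y)):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            model = make_pipeline(StandardScaler(), clone(est))
            model.fit(X[mask], y[mask])
            correct += int(model.predict(X[i:i + 1])[0] == y[i])
        results[name] = correct / len(y)
    return results
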