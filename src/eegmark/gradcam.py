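"""Grad-CAM interpretation of the EEG classifier in channel and frequency space.

For each 2-s segment, a relevance map is the layer-average of rectified,
gradient-weighted convolutional activation maps, upsampled to the 10 x 500
input grid and min-max normalized to [0, 1].  Binarizing at tau = 0.3 yields
contiguous marked spans per channel; span-wise periodograms of the *raw*
(microvolt) segments, averaged per channel, expose the frequencies the model
relies on, and the per-channel mean relevance gives the importance
topography.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from eegmark.channels import CANONICAL_CHANNELS
from eegmark.cnn import TrainedClassifier
from eegmark.nn import Conv2D
from eegmark.preprocess import SegmentSet

__all__ = [
    "GradCamConfig", "RelevanceMap", "MarkedSpan", "ChannelSpectrumReport",
    "compute_relevance", "binarize_and_extract", "spectra_of_spans",
    "channel_importance", "relevance_for_segments",
]


@dataclass(frozen=True)
class GradCamConfig:
    tau: float = 0.3              # binarization threshold on normalized maps
    layers: tuple[int, ...] | None = None   # conv block indices, default all
    min_span: int = 32            # samples; 128 ms at 250 Hz
    target_class: int | None = None  # None = each segment's predicted class
    layer_weights: tuple[float, ...] | None = None  # default unweighted mean
    pooled_weights: bool = False  # True: spatially pooled filter weights
    # (the GAP-head formulation); False: elementwise gradient weighting,
    # which preserves localization under this network's dense head

    def __post_init__(self) -> None:
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie strictly between 0 and 1")
        if self.min_span < 1:
            raise ValueError("min_span must be at least 1")


@dataclass
class RelevanceMap:
    map: np.ndarray               # 10 x 500 in [0, 1]
    segment_id: int
    class_target: int


@dataclass(frozen=True)
class MarkedSpan:
    channel: str
    start: int                    # 0-based, half-open [start, end)
    end: int
    mean_relevance: float


@dataclass
class ChannelSpectrumReport:
    freqs: np.ndarray                             # Hz grid
    spectra: dict[str, np.ndarray]                # channel -> power (uV^2/Hz)
    peak_frequency: dict[str, float]              # argmax within 0.5-45 Hz
    importance: dict[str, float] = field(default_factory=dict)


def _spread_channels(m: np.ndarray, span: int) -> np.ndarray:
    """Distribute relevance over the receptive field along the channel axis.

    With bottom-padded 'same' convolutions, the output at row h summarizes
    input rows [h, h+span-1]; spreading uniformly re-centres the map on the
    input grid (the channel axis is categorical, so no interpolation).
    """
    if span <= 1:
        return m
    out = np.zeros_like(m)
    counts = np.zeros(m.shape[0])
    for s in range(span):
        hi = m.shape[0] - s
        out[s:] += m[:hi]
        counts[s:] += 1
    return out / counts[:, None]


def _upsample_time(m: np.ndarray, n_out: int) -> np.ndarray:
    """Linear interpolation along time; channel axis is categorical (kept)."""
    n_in = m.shape[1]
    if n_in == n_out:
        return m
    x_out = np.arange(n_out) * (n_in / n_out) + (n_in / n_out - 1) / 2.0
    x_in = np.arange(n_in, dtype=float)
    return np.vstack([np.interp(x_out, x_in, row) for row in m])


def relevance_for_segments(model: TrainedClassifier, segs: SegmentSet,
                           cfg: GradCamConfig = GradCamConfig(),
                           batch_size: int = 64) -> list[RelevanceMap]:
    """Grad-CAM maps for a stack of normalized segments (batched)."""
    if not segs.normalized:
        raise ValueError("Grad-CAM runs on segments normalized as at inference")
    net = model.network
    all_conv = [i for i, l in enumerate(net.layers) if isinstance(l, Conv2D)]
    # receptive-field extent along the channel axis after each block
    spans = list(np.cumsum([kh for kh, _ in model.spec.kernel_schedule]
                           ) - np.arange(len(all_conv)) + 0)
    span_of = {i: int(s) for i, s in zip(all_conv, spans)}
    conv_idx = all_conv if cfg.layers is None else [all_conv[b]
                                                    for b in cfg.layers]
    weights = (np.ones(len(conv_idx)) if cfg.layer_weights is None
               else np.asarray(cfg.layer_weights, dtype=float))
    if len(weights) != len(conv_idx):
        raise ValueError("one layer weight per selected conv layer required")
    n_ch, n_t = model.spec.input_shape[:2]

    maps: list[RelevanceMap] = []
    x = np.ascontiguousarray(segs.data[:, None, :, :], dtype=np.float32)
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        logits, acts = net.forward_with_activations(xb)
        if cfg.target_class is None:
            targets = (logits >= 0).astype(int)
        else:
            targets = np.full(len(xb), cfg.target_class, dtype=int)
        # gradient of the target-class logit: +1 for class 1, -1 for class 0
        sign = np.where(targets == 1, 1.0, -1.0)
        conv_grads = net.backward(sign, record_conv_grads=True)
        batch_maps = np.zeros((len(xb), n_ch, n_t))
        for w, li in zip(weights, conv_idx):
            A = acts[li]                       # (B, F, H, W_l)
            G = conv_grads[li]
            if cfg.pooled_weights:
                alpha = G.mean(axis=(2, 3))    # (B, F) pooled filter weights
                cam = np.maximum(np.einsum("bf,bfhw->bhw", alpha, A), 0.0)
            else:
                cam = np.maximum((G * A).sum(axis=1), 0.0)
            for b in range(len(xb)):
                m = _spread_channels(cam[b], span_of[li])
                batch_maps[b] += w * _upsample_time(m, n_t)
        batch_maps /= weights.sum()
        for b in range(len(xb)):
            m = batch_maps[b]
            peak = m.max()
            if peak <= 0:
                warnings.warn("all-zero Grad-CAM gradient field; uniform zero map")
                norm = np.zeros_like(m)
            else:
                lo = m.min()
                norm = (m - lo) / (peak - lo) if peak > lo else np.ones_like(m)
            maps.append(RelevanceMap(norm, segment_id=start + b,
                                     class_target=int(targets[b])))
    return maps


def compute_relevance(model: TrainedClassifier, segment: np.ndarray,
                      cfg: GradCamConfig = GradCamConfig()) -> RelevanceMap:
    """Grad-CAM map for a single normalized 10 x 500 segment."""
    segs = SegmentSet(segment[None], np.array(["_one"], dtype=object),
                      normalized=True)
    return relevance_for_segments(model, segs, cfg)[0]


def binarize_and_extract(rmap: RelevanceMap,
                         cfg: GradCamConfig = GradCamConfig(),
                         channels: tuple[str, ...] = CANONICAL_CHANNELS
                         ) -> list[MarkedSpan]:
    """Contiguous supra-threshold runs per channel; short runs are discarded."""
    spans: list[MarkedSpan] = []
    m = rmap.map
    for ci, name in enumerate(channels):
        above = m[ci] > cfg.tau
        padded = np.concatenate([[False], above, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        for start, end in zip(edges[::2], edges[1::2]):
            if end - start >= cfg.min_span:
                spans.append(MarkedSpan(name, int(start), int(end),
                                        float(m[ci, start:end].mean())))
    return spans


def spectra_of_spans(spans_per_segment: list[list[MarkedSpan]],
                     raw_segments: np.ndarray, fs: float = 250.0,
                     nfft: int = 512,
                     channels: tuple[str, ...] = CANONICAL_CHANNELS
                     ) -> ChannelSpectrumReport:
    """Span-length-weighted average periodogram per channel.

    Each marked span of the raw (microvolt) segment is detrended, Hann
    tapered and zero-padded onto a common ``nfft`` grid.  Channels with no
    spans are omitted from the report.
    """
    if len(spans_per_segment) != len(raw_segments):
        raise ValueError("one span list per raw segment required")
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    accum = {c: np.zeros(len(freqs)) for c in channels}
    weight = {c: 0.0 for c in channels}
    ch_index = {c: i for i, c in enumerate(channels)}
    for spans, seg in zip(spans_per_segment, raw_segments):
        for span in spans:
            x = seg[ch_index[span.channel], span.start:span.end]
            x = x - x.mean()
            taper = np.hanning(len(x))
            xt = x * taper
            # one-sided periodogram normalized by the taper power
            scale = 1.0 / (fs * (taper ** 2).sum())
            p = np.abs(np.fft.rfft(xt, n=nfft)) ** 2 * scale
            if nfft % 2 == 0:
                p[1:-1] *= 2.0
            else:
                p[1:] *= 2.0
            n = len(x)
            accum[span.channel] += n * p
            weight[span.channel] += n
    spectra, peaks = {}, {}
    band = (freqs >= 0.5) & (freqs <= 45.0)
    for c in channels:
        if weight[c] == 0:
            continue
        s = accum[c] / weight[c]
        spectra[c] = s
        peaks[c] = float(freqs[band][np.argmax(s[band])])
    missing = [c for c in channels if c not in spectra]
    if missing:
        warnings.warn(f"no marked spans on channels {missing}; spectra omitted")
    return ChannelSpectrumReport(freqs, spectra, peaks)


def channel_importance(maps: list[RelevanceMap],
                       channels: tuple[str, ...] = CANONICAL_CHANNELS
                       ) -> tuple[dict[str, float], list[str]]:
    """Mean relevance per channel over all maps, plus a descending ranking.

    Ties break by canonical channel order.
    """
    if not maps:
        raise ValueError("at least one relevance map required")
    stack = np.stack([m.map for m in maps])
    imp = stack.mean(axis=(0, 2))
    importance = {c: float(v) for c, v in zip(channels, imp)}
    ranking = [channels[i] for _, i in sorted(
        ((-importance[c], i) for i, c in enumerate(channels)))]
    return importance, ranking
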