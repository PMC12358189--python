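"""Response-window derivation and windowed spike counting.

Response windows are derived from relative-frequency latency histograms
pooled across recordings: the window runs from the first to the last
post-stimulus bin whose frequency reaches 1.5x the pre-stimulus baseline
frequency, and each edge is then rounded away from the peak-frequency bin by
one significant digit (e.g. 38 -> 40, 1480 -> 1500, 820 -> 800, 2 -> 0).

The pipeline normally runs with the fixed canonical windows below (pre/post
in ms relative to the trigger); "derived" mode recomputes the post windows
from data.  Counting uses half-open intervals [start, end).  The sustained
noxious-thermal window has only 1 s of usable pre-stimulus data for a 3 s
post window, so its pre-stimulus counts are multiplied by 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class NoWindowError(ValueError):
    """No post-stimulus bin reaches the threshold; the unit cannot be windowed."""


@dataclass(frozen=True)
class ResponseWindow:
    modality: str
    pre_ms: tuple[float, float]
    post_ms: tuple[float, float]
    count_multiplier: int = 1          # 3 only for the sustained-thermal window
    bin_width_ms: float = 10.0

    def __post_init__(self):
        if not self.pre_ms[0] < self.pre_ms[1] <= 0:
            raise ValueError("pre window must be negative-time and end at or before 0")
        if not self.post_ms[0] < self.post_ms[1]:
            raise ValueError("post window start must precede its end")


#: canonical window timings (ms after trigger) and histogram bin widths
FIXED_WINDOWS: dict[str, ResponseWindow] = {
    "noxious_thermal": ResponseWindow("noxious_thermal", (-700, 0), (800, 1500), 1, 50),
    "noxious_thermal_sustained":
        ResponseWindow("noxious_thermal", (-1000, 0), (1500, 4500), 3, 50),
    "noxious_press": ResponseWindow("noxious_press", (-500, 0), (0, 500), 1, 10),
    "tactile": ResponseWindow("tactile", (-40, 0), (0, 40), 1, 1),
    "proprioceptive": ResponseWindow("proprioceptive", (-400, 0), (0, 400), 1, 10),
}

DEFAULT_BIN_WIDTH_MS = {
    "noxious_thermal": 50.0, "noxious_press": 10.0,
    "tactile": 1.0, "proprioceptive": 10.0,
}


@dataclass
class LatencyHistogram:
    edges_ms: np.ndarray        # len = n_bins + 1, tiling the span with an edge at 0
    frequencies: np.ndarray     # relative frequencies, sum to 1
    n: int                      # pooled spike count
    modality: str
    baseline: float             # mean per-bin frequency over the pre-stimulus span

    @property
    def centres_ms(self) -> np.ndarray:
        return (self.edges_ms[:-1] + self.edges_ms[1:]) / 2.0


def build_latency_histogram(spikes_ms: np.ndarray, modality: str,
                            bin_width_ms: float | None = None,
                            span_ms: tuple[float, float] = (-1000.0, 1000.0)
                            ) -> LatencyHistogram:
    """Relative-frequency histogram of pooled trial-aligned spike times.

    Bins tile ``span_ms`` with an edge exactly at t = 0; the baseline is the
    mean per-bin frequency over the pre-stimulus (t < 0) span.
    """
    spikes_ms = np.asarray(spikes_ms, dtype=float)
    if spikes_ms.size == 0:
        raise ValueError("empty spike pool")
    w = bin_width_ms if bin_width_ms is not None else DEFAULT_BIN_WIDTH_MS[modality]
    lo = math.floor(span_ms[0] / w) * w
    hi = math.ceil(span_ms[1] / w) * w
    edges = np.arange(lo, hi + w / 2, w)
    counts, _ = np.histogram(spikes_ms, bins=edges)
    freqs = counts / counts.sum() if counts.sum() else counts.astype(float)
    pre = edges[:-1] < 0
    baseline = float(freqs[pre].mean()) if pre.any() else 0.0
    return LatencyHistogram(edges, freqs, int(spikes_ms.size), modality, baseline)


def _round_one_sig_away(x: float, upward: bool) -> float:
    """Round ``x`` (>= 0, ms) away from the peak by one significant digit:
    drop the last significant decimal digit, rounding toward -inf (downward)
    or +inf (upward).  Zero stays zero; a single-significant-digit value
    rounds down to 0 or up to the next power of ten."""
    if x == 0:
        return 0.0
    if x < 0:
        return -_round_one_sig_away(-x, not upward)
    from decimal import Decimal

    d = Decimal(repr(float(x))).normalize()
    q = 10.0 ** (d.as_tuple().exponent + 1)
    return (math.ceil(x / q) if upward else math.floor(x / q)) * q


def derive_window(hist: LatencyHistogram, factor: float = 1.5
                  ) -> tuple[float, float]:
    """Derive the post-stimulus response window from a latency histogram.

    Let a/b be the left/right edge of the first/last post-stimulus bin with
    frequency >= ``factor`` x baseline and p the centre of the maximum-
    frequency post bin (ties toward the earlier bin); each edge is rounded
    away from p by one significant digit.  Raises :class:`NoWindowError` if
    no bin reaches the threshold.
    """
    if hist.baseline <= 0:
        raise ValueError("baseline frequency must be positive to derive a window")
    post = hist.edges_ms[:-1] >= 0
    freqs = hist.frequencies[post]
    lefts = hist.edges_ms[:-1][post]
    rights = hist.edges_ms[1:][post]
    crossing = freqs >= factor * hist.baseline - 1e-15
    if not crossing.any():
        raise NoWindowError("no post-stimulus bin reaches the threshold frequency")
    a = float(lefts[crossing][0])
    b = float(rights[crossing][-1])
    p = float((lefts[np.argmax(freqs)] + rights[np.argmax(freqs)]) / 2.0)
    start = _round_one_sig_away(a, upward=a > p)
    end = _round_one_sig_away(b, upward=b > p)
    return start, end


def windowed_counts(unit_times_s: np.ndarray, triggers_s: np.ndarray,
                    window: ResponseWindow,
                    span_s: tuple[float, float] | None = None) -> np.ndarray:
    """Per-trial (pre_count, post_count) pairs for one unit in one set.

    Counting is inclusive of the window start and exclusive of the end; the
    pre count is multiplied by the window's count multiplier (x3 for the
    sustained-thermal window).  Returns an (n_triggers, 2) integer array.
    """
    if span_s is not None:
        lo, hi = span_s[0] * 1000.0, span_s[1] * 1000.0
        if window.pre_ms[0] < lo or window.post_ms[1] > hi:
            raise ValueError("window extends beyond the trial segment")
    t = np.asarray(unit_times_s, dtype=float)
    out = np.empty((len(triggers_s), 2), dtype=int)
    for i, trig in enumerate(np.asarray(triggers_s, dtype=float)):
        # sub-ns rounding keeps the half-open boundary rule exact for times
        # that are whole milliseconds up to floating-point error
        rel = np.round((t - trig) * 1000.0, 6)
        pre = np.count_nonzero((rel >= window.pre_ms[0]) & (rel < window.pre_ms[1]))
        post = np.count_nonzero((rel >= window.post_ms[0]) & (rel < window.post_ms[1]))
        out[i] = (window.count_multiplier * pre, post)
    return out


def window_for(modality: str, sustained: bool = False) -> ResponseWindow:
    key = "noxious_thermal_sustained" if sustained and modality == "noxious_thermal" \
        else modality
    return FIXED_WINDOWS[key]
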