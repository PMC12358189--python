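"""Evoked-response classification and derived measures.

A response is 'evoked' when the mean post-stimulus windowed spike count
significantly exceeds the pre-stimulus count (paired one-sided t-test on the
per-trial differences, alpha = .05; a two-sample variant is available).
On top of this criterion the module computes the EMM-based percent reduction
of windowed activity during DC, per-unit post-DC recovery times, multi- and
single-unit spontaneous rates, and response peak latencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .windows import ResponseWindow, windowed_counts


@dataclass
class EvokedResult:
    unit_id: int | None
    set_id: str | None
    t: float
    p: float
    evoked: bool
    n_trials: int


@dataclass
class RecoveryResult:
    unit_id: int | None
    modality: str
    blocked_during_dc: bool
    recovery_time_min: float | None = None
    censored: bool = False


def classify_evoked(pre_counts, post_counts, alpha: float = 0.05,
                    paired: bool = True, unit_id=None, set_id=None) -> EvokedResult:
    """Classify a response as evoked from per-trial (pre, post) window counts.

    Paired one-sided t-test on post - pre ("significantly more" implies the
    direction; pairing matches the per-trial structure).  Zero-variance
    differences are decided by sign: positive mean -> evoked (t = inf,
    p = 0), otherwise not evoked (p = 1).
    """
    pre = np.asarray(pre_counts, dtype=float)
    post = np.asarray(post_counts, dtype=float)
    n = pre.size
    if n < 2 or post.size < 2:
        raise ValueError("need at least 2 trials to test")
    if paired:
        if post.size != n:
            raise ValueError("paired test requires equal trial counts")
        d = post - pre
        mean = d.mean()
        if np.all(d == d[0]):
            t, p = (math.inf, 0.0) if mean > 0 else (-math.inf if mean < 0 else 0.0, 1.0)
        else:
            t, p = sps.ttest_1samp(d, 0.0, alternative="greater")
            t, p = float(t), float(p)
    else:
        mean = post.mean() - pre.mean()
        if pre.std() == 0 and post.std() == 0:
            t, p = (math.inf, 0.0) if mean > 0 else (-math.inf if mean < 0 else 0.0, 1.0)
        else:
            t, p = sps.ttest_ind(post, pre, alternative="greater")
            t, p = float(t), float(p)
    return EvokedResult(unit_id, set_id, t, p, bool(mean > 0 and p < alpha),
                        int(n))


def percent_reduction(emm_pre: float, emm_dc: float) -> float:
    """100 x (1 - EMM_during / EMM_pre); increases come out negative."""
    if emm_pre <= 0:
        raise ValueError("percent reduction undefined for non-positive baseline EMM")
    return 100.0 * (1.0 - emm_dc / emm_pre)


def recovery_time(during_results: list[EvokedResult],
                  post_results: list[tuple[float, EvokedResult]],
                  modality: str, unit_id=None,
                  evoked_pre: bool = True,
                  horizon_min: float = 45.0) -> RecoveryResult:
    """Recovery time of one unit: minutes from DC cessation to the first
    post-DC set passing the evoked criterion.

    Only defined for units evoked pre-DC that were blocked (no evoked
    activity in any during-DC set); units not re-evoked within the horizon
    are censored.  ``post_results`` is an ordered list of
    (time_since_dc_end_min, EvokedResult).
    """
    if not evoked_pre:
        raise ValueError("recovery is only defined for units evoked pre-DC")
    if not post_results:
        raise ValueError("no post-DC recording sets")
    blocked = not any(r.evoked for r in during_results)
    if not blocked:
        return RecoveryResult(unit_id, modality, blocked_during_dc=False)
    for t_min, res in sorted(post_results, key=lambda x: x[0]):
        if res.evoked and t_min <= horizon_min:
            return RecoveryResult(unit_id, modality, True, recovery_time_min=float(t_min))
    return RecoveryResult(unit_id, modality, True, censored=True)


def multiunit_rate(channel_event_times: dict[int, np.ndarray],
                   baseline_end_s: float, baseline_start_s: float = 0.0) -> dict[int, float]:
    """Multi-unit spontaneous rate per channel (spikes/s) from detector events
    (before spike sorting) in the stimulus-free period before the first
    trigger."""
    dur = baseline_end_s - baseline_start_s
    if dur < 1.0:
        raise ValueError("need a pre-stimulus period of at least 1 s")
    return {ch: float(np.count_nonzero(
        (t >= baseline_start_s) & (t < baseline_end_s)) / dur)
        for ch, t in channel_event_times.items()}


def singleunit_rate(unit_times_s: np.ndarray, triggers_s: np.ndarray,
                    window: ResponseWindow) -> float:
    """Single-unit spontaneous rate: spikes in the per-trial pre-stimulus
    windows divided by total pre-window time (multiplier not applied)."""
    counts = windowed_counts(unit_times_s, triggers_s, window)
    total_pre = counts[:, 0].sum() / window.count_multiplier
    dur = len(triggers_s) * (window.pre_ms[1] - window.pre_ms[0]) / 1000.0
    if dur <= 0:
        raise ValueError("no pre-stimulus period")
    return float(total_pre / dur)


def peak_latency(unit_times_s: np.ndarray, triggers_s: np.ndarray,
                 bin_width_ms: float, post_span_ms: tuple[float, float] = (0.0, 1000.0)
                 ) -> float:
    """Latency (ms) of the response peak: the centre of the post-stimulus
    histogram bin with the maximum spike count, ties broken toward the
    earlier bin."""
    t = np.asarray(unit_times_s, dtype=float)
    rel = (t[None, :] - np.asarray(triggers_s, dtype=float)[:, None]) * 1000.0
    rel = rel[(rel >= post_span_ms[0]) & (rel < post_span_ms[1])]
    if rel.size == 0:
        raise ValueError("no post-stimulus spikes")
    edges = np.arange(post_span_ms[0], post_span_ms[1] + bin_width_ms / 2, bin_width_ms)
    counts, _ = np.histogram(rel, bins=edges)
    i = int(np.argmax(counts))
    return float(edges[i] + bin_width_ms / 2.0)
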