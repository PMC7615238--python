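"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths (and scipy's peak
machinery) so they can serve as oracles for the detector, the segmentation
rules, the mode baseline and the coastline.
"""

from __future__ import annotations

import numpy as np


def brute_force_peaks(
    x: np.ndarray, threshold: float, min_distance: int
) -> list[int]:
    """Local maxima >= threshold; largest-first suppression within distance."""
    candidates = [
        i
        for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= threshold
    ]
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: -x[i]):
        if all(abs(i - k) >= min_distance for k in kept):
            kept.append(i)
    return sorted(kept)


def brute_force_trains(
    times: list[float],
    min_spikes: int = 3,
    min_rate_hz: float = 1.33,
    min_train_s: float = 1.0,
    hpd_min_s: float = 10.0,
    max_isi_s: float = 1.0 / 1.33,
) -> list[tuple[tuple[float, ...], str]]:
    """Enumerate chains split at ISI > max_isi and filter by the criteria."""
    times = sorted(times)
    chains: list[list[float]] = []
    for t in times:
        if chains and t - chains[-1][-1] <= max_isi_s:
            chains[-1].append(t)
        else:
            chains.append([t])
    out = []
    for chain in chains:
        n = len(chain)
        duration = chain[-1] - chain[0]
        if n < min_spikes or duration < min_train_s:
            continue
        if (n - 1) / duration < min_rate_hz:
            continue
        klass = "HPD" if duration >= hpd_min_s else "SPIKE_TRAIN"
        out.append((tuple(chain), klass))
    return out


def brute_force_mode(extrema: np.ndarray, step: float) -> float:
    """Histogram argmax with bins centered on multiples of step."""
    lo = int(np.floor(extrema.min() / step + 0.5))
    hi = int(np.floor(extrema.max() / step + 0.5))
    centers = np.arange(lo, hi + 1) * step
    edges = np.concatenate([centers - step / 2, [centers[-1] + step / 2]])
    counts, _ = np.histogram(extrema, bins=edges)
    return float(centers[np.argmax(counts)])


def brute_force_coastline(x: np.ndarray) -> float:
    import math

    terms = []
    for i in range(len(x) - 1):
        terms.append(abs(float(x[i + 1]) - float(x[i])))
    return math.fsum(terms)
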