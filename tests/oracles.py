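"""Independent brute-force reference implementations used as test oracles.

These are written as plain, literal translations of the pull-event rules
and the metric definitions, deliberately separate from the package's
implementation, so the two can be compared on random inputs.
"""

import numpy as np


def oracle_scan(force, threshold):
    """Reference single-pass pull-event scanner.

    Returns a list of (start, end, peak_index, peak_force) with half-open
    [start, end) windows.  Rules, applied sample by sample:

    * an event starts at a sample strictly above the threshold when no
      event is open;
    * it ends (exclusively) at the first sample strictly below the
      threshold, or at the first sample whose gradient is strictly
      positive after an earlier strictly negative gradient within the
      event — that sample starts the next event;
    * zero gradients carry no sign; ties at the threshold do not close
      an event; an event still open at the last sample closes there.
    """
    f = list(map(float, force))
    n = len(f)
    events = []
    i = 0
    while i < n:
        if f[i] <= threshold:
            i += 1
            continue
        # find the maximal above-threshold run [i, j)
        j = i + 1
        while j < n and f[j] >= threshold:
            j += 1
        # split the run at rising-after-falling samples
        bounds = [i]
        sign = 0
        for k in range(i + 1, j):
            d = f[k] - f[k - 1]
            if d > 0:
                if sign < 0:
                    bounds.append(k)
                    sign = 0
                else:
                    sign = 1
            elif d < 0:
                sign = -1
        bounds.append(j)
        for s, e in zip(bounds, bounds[1:]):
            peak_idx = s
            for k in range(s, e):
                if f[k] > f[peak_idx]:
                    peak_idx = k
            events.append((s, e, peak_idx, f[peak_idx]))
        i = j
    return events


def oracle_metrics(events, duration):
    """Recompute walk metrics directly from an event list.

    ``events`` is a list of (peak_force, direction) pairs with direction in
    {"dog", "handler", "both"}.
    """
    peaks = [p for p, _ in events]
    dog = [p for p, d in events if d == "dog"]
    hand = [p for p, d in events if d == "handler"]
    both = [p for p, d in events if d == "both"]
    mx = lambda xs: max(xs) if xs else 0.0
    mn = lambda xs: sum(xs) / len(xs) if xs else 0.0
    return {
        "nt_max": mx(peaks), "nt_mean": mn(peaks),
        "dt_max": mx(dog), "dt_mean": mn(dog),
        "ht_max": mx(hand), "ht_mean": mn(hand),
        "dpf": len(dog) / duration, "hpf": len(hand) / duration,
        "n_events": len(peaks), "n_dog": len(dog),
        "n_handler": len(hand), "n_both": len(both),
    }


def random_trace(rng, n=1000, threshold=0.02):
    """A random tarred force series mixing bursts, noise and quiet spells."""
    f = np.zeros(n)
    i = 0
    while i < n:
        kind = rng.integers(0, 3)
        if kind == 0:  # quiet
            span = int(rng.integers(5, 50))
        elif kind == 1:  # burst
            span = int(rng.integers(3, 30))
            peak = rng.uniform(threshold * 1.5, 2.0)
            x = np.linspace(0, np.pi, min(span, n - i))
            f[i:i + len(x)] += peak * np.sin(x)
        else:  # rough noise around the threshold
            span = int(rng.integers(5, 40))
            f[i:min(n, i + span)] += rng.uniform(0, threshold * 3, min(span, n - i))
        i += span
    f = np.maximum(f, 0.0)
    f -= f.min()
    return f
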