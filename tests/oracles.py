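"""Brute-force reference implementations used to cross-check the package.

Everything here is written as plain nested loops over explicit definitions,
independently of the vectorised implementations under test.
"""

from __future__ import annotations

import numpy as np


def brute_classify(alarm_hours, episodes, window, first_only=False):
    """Classify each alarm hour by scanning episodes directly.

    ``episodes``: list of dicts with onset/end/is_first, any order.
    Returns list of (hour, cls, matched_onset_or_None).
    """
    earliest, latest = window
    ordered = sorted(episodes, key=lambda e: e["onset"])
    eligible = [e for e in ordered if e["is_first"]] if first_only else ordered
    out = []
    for h in alarm_hours:
        cls, matched = "false", None
        for e in eligible:
            if e["onset"] + earliest <= h <= e["onset"] + latest:
                cls, matched = "timely", e["onset"]
                break
        if cls == "false":
            for e in ordered:
                if e["onset"] < h <= e["end"]:
                    cls = "in_shock_excluded"
                    break
        out.append((h, cls, matched))
    return out


def brute_timeliness(stay_data, window, first_only=False):
    """Event-based metrics by pairwise enumeration.

    ``stay_data``: dict stay_id -> (alarm_hours, episodes) with episodes as in
    :func:`brute_classify`.  Returns a dict with ter/tar/ter_stay/tar_stay and
    the classification counts.
    """
    earliest, latest = window
    n_events = n_warned = 0
    n_timely = n_false = n_excluded = 0
    per_stay_ter, per_stay_tar = [], []
    for alarm_hours, episodes in stay_data.values():
        cls = brute_classify(alarm_hours, episodes, window, first_only)
        nt = sum(1 for _, c, _ in cls if c == "timely")
        nf = sum(1 for _, c, _ in cls if c == "false")
        nx = sum(1 for _, c, _ in cls if c == "in_shock_excluded")
        n_timely += nt
        n_false += nf
        n_excluded += nx
        ordered = sorted(episodes, key=lambda e: e["onset"])
        eligible = [e for e in ordered if e["is_first"]] if first_only \
            else ordered
        warned_here = 0
        for e in eligible:
            warned = any(e["onset"] + earliest <= h <= e["onset"] + latest
                         for h in alarm_hours)
            n_events += 1
            warned_here += warned
        n_warned += warned_here
        if episodes:  # a shock stay
            if eligible:
                per_stay_ter.append(warned_here / len(eligible))
            if nt + nf > 0:
                per_stay_tar.append(nt / (nt + nf))
    return {
        "ter": n_warned / n_events if n_events else None,
        "tar": n_timely / (n_timely + n_false)
               if (n_timely + n_false) else 0.0,
        "ter_stay": float(np.mean(per_stay_ter)) if per_stay_ter else None,
        "tar_stay": float(np.mean(per_stay_tar)) if per_stay_tar else None,
        "n_timely": n_timely, "n_false": n_false, "n_excluded": n_excluded,
        "n_events": n_events, "n_events_warned": n_warned,
    }


def brute_labels(onsets, n_hours, pw):
    labels = [0] * n_hours
    for h in range(n_hours):
        for o in onsets:
            if o - pw <= h <= o - 1:
                labels[h] = 1
    return labels


def brute_mask(episodes, n_hours, tw, fsf):
    mask = [1] * n_hours
    ordered = sorted(episodes, key=lambda e: e["onset"])
    if tw != "all":
        for e in ordered:
            for h in range(n_hours):
                if e["onset"] <= h <= e["end"] and h > e["onset"] + tw:
                    mask[h] = 0
    if fsf and ordered:
        first = ordered[0]
        cutoff = first["onset"] + (tw if tw != "all"
                                   else first["end"] - first["onset"])
        for h in range(n_hours):
            if h > cutoff:
                mask[h] = 0
    return mask


def random_episodes(rng, n_hours, max_episodes=3):
    """Disjoint episodes separated by at least one non-shock hour."""
    episodes = []
    cursor = int(rng.integers(2, max(3, n_hours // 3)))
    for _ in range(int(rng.integers(0, max_episodes + 1))):
        if cursor >= n_hours - 1:
            break
        onset = cursor
        end = min(n_hours - 1, onset + int(rng.integers(0, 6)))
        episodes.append({"onset": onset, "end": end, "is_first": False})
        cursor = end + 2 + int(rng.integers(0, 8))
    if episodes:
        episodes[0]["is_first"] = True
    return episodes


def random_instance(rng, max_stays=5):
    """A random (alarm streams, episode sets, window) evaluation instance."""
    stay_data = {}
    for s in range(int(rng.integers(1, max_stays + 1))):
        n_hours = int(rng.integers(12, 72))
        episodes = random_episodes(rng, n_hours)
        n_alarms = int(rng.integers(0, n_hours // 2))
        hours = sorted(rng.choice(n_hours, size=n_alarms, replace=False)
                       .tolist()) if n_alarms else []
        stay_data[f"S{s}"] = (hours, episodes)
    earliest = -int(rng.integers(1, 13))
    latest = -int(rng.integers(0, -earliest + 1))
    return stay_data, (earliest, latest)
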