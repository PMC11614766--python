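"""Data-task engineering: labels, training-sample selection, cohort split.

Three dials shape what the scorer learns:

* **prediction window (pw)** — hours before each shock onset labelled positive
  (``onset - pw .. onset - 1``); the onset hour itself is labelled 0 because at
  onset the event is no longer in the future.
* **training window (tw)** — how many post-onset in-shock hours stay in the
  training set (0, 1, 2 or ``"all"``).
* **first shock focus (fsf)** — whether everything after the first episode
  (plus its training window) is dropped from training.

The split is stay-grouped (every hour of a stay shares a partition) and
stratified by shock status, with 70/10/10/10 train/validation/calibration/test
fractions by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PARTITIONS = ("train", "validation", "calibration", "test")
DEFAULT_FRACTIONS = (0.7, 0.1, 0.1, 0.1)

TW_CHOICES = (0, 1, 2, "all")


@dataclass(frozen=True)
class DataTaskConfig:
    pw: int = 8
    tw: object = "all"
    fsf: bool = False

    def __post_init__(self):
        if not (1 <= int(self.pw)):
            raise ConfigurationError("prediction window must be >= 1")
        if self.tw not in TW_CHOICES:
            raise ConfigurationError(f"training window must be one of {TW_CHOICES}")

    def tag(self) -> str:
        return f"pw{self.pw}_tw{self.tw}_fsf{int(self.fsf)}"


def build_labels(episodes: pd.DataFrame, n_hours: int, pw: int) -> np.ndarray:
    """Per-hour binary labels: 1 on hours ``onset-pw .. onset-1`` of any episode."""
    labels = np.zeros(n_hours, dtype=np.int8)
    for onset in episodes["onset"]:
        lo = max(0, int(onset) - int(pw))
        hi = min(n_hours, int(onset))  # exclusive; onset hour itself stays 0
        labels[lo:hi] = 1
    return labels


def select_training_samples(episodes: pd.DataFrame, n_hours: int,
                            tw, fsf: bool) -> np.ndarray:
    """Per-hour training inclusion mask.

    With ``tw != "all"`` the in-shock hours of each episode beyond
    ``onset + tw`` are dropped.  With ``fsf`` everything strictly after
    ``first_onset + tw_effective`` is dropped, where ``tw_effective`` is ``tw``
    for finite windows and the first episode's full extent for ``"all"``.
    """
    if tw not in TW_CHOICES:
        raise ConfigurationError(f"training window must be one of {TW_CHOICES}")
    mask = np.ones(n_hours, dtype=np.int8)
    if episodes.empty:
        return mask
    eps = episodes.sort_values("onset")
    if tw != "all":
        for onset, end in zip(eps["onset"], eps["end"]):
            lo = min(n_hours, int(onset) + int(tw) + 1)
            hi = min(n_hours, int(end) + 1)
            if lo < hi:
                mask[lo:hi] = 0
    if fsf:
        first_onset = int(eps["onset"].iloc[0])
        if tw != "all":
            cutoff = first_onset + int(tw)
        else:
            cutoff = int(eps["end"].iloc[0])
        mask[min(n_hours, cutoff + 1):] = 0
    return mask


def apply_datatask(matrix: pd.DataFrame, episodes: pd.DataFrame,
                   cfg: DataTaskConfig) -> pd.DataFrame:
    """Attach ``label`` and ``train_mask`` columns to a cohort feature matrix."""
    out = matrix.copy()
    out["label"] = np.int8(0)
    out["train_mask"] = np.int8(1)
    eps_by_stay = dict(tuple(episodes.groupby("stay_id", sort=False))) \
        if not episodes.empty else {}
    empty = episodes.iloc[0:0] if not episodes.empty else \
        pd.DataFrame(columns=["stay_id", "onset", "end", "is_first"])
    labels = []
    masks = []
    for stay_id, grp in out.groupby(level="stay_id", sort=False):
        eps = eps_by_stay.get(stay_id, empty)
        n = len(grp)
        labels.append(build_labels(eps, n, cfg.pw))
        masks.append(select_training_samples(eps, n, cfg.tw, cfg.fsf))
    out["label"] = np.concatenate(labels)
    out["train_mask"] = np.concatenate(masks)
    return out


def split_cohort(stay_ids, fractions=DEFAULT_FRACTIONS, seed: int = 0,
                 shock_flags=None) -> pd.Series:
    """Deterministic stay-level partition, stratified by shock status.

    Returns a Series mapping stay_id -> partition name.  Global partition sizes
    follow largest-remainder apportionment of the fractions (each within one
    stay of ``fraction * N``); within that constraint stays are allocated
    per stratum so each partition's shock prevalence tracks the cohort's.
    """
    stay_ids = list(stay_ids)
    n = len(stay_ids)
    if n < len(PARTITIONS):
        raise ConfigurationError(
            f"need at least {len(PARTITIONS)} stays to split, got {n}")
    if not np.isclose(sum(fractions), 1.0):
        raise ConfigurationError("split fractions must sum to 1")

    targets = _largest_remainder(np.asarray(fractions, dtype=float) * n, n)

    if shock_flags is None:
        flags = np.zeros(n, dtype=bool)
    else:
        flags = np.asarray([bool(shock_flags[s]) for s in stay_ids])

    rng = np.random.default_rng(seed)
    assignment: dict[object, str] = {}
    remaining = targets.copy()
    strata = [np.flatnonzero(flags), np.flatnonzero(~flags)]
    for stratum in strata:
        if len(stratum) == 0:
            continue
        order = rng.permutation(stratum)
        quota = _largest_remainder(
            remaining / max(1, remaining.sum()) * len(order), len(order))
        # never exceed what partitions still need overall
        quota = np.minimum(quota, remaining)
        deficit = len(order) - quota.sum()
        while deficit > 0:  # give leftovers to the partitions furthest behind
            p = int(np.argmax(remaining - quota))
            quota[p] += 1
            deficit -= 1
        pos = 0
        for p, name in enumerate(PARTITIONS):
            for idx in order[pos:pos + quota[p]]:
                assignment[stay_ids[idx]] = name
            pos += quota[p]
        remaining = remaining - quota

    return pd.Series(assignment, name="partition")


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(quotas - floors), kind="stable")
    for i in range(short):
        floors[order[i]] += 1
    return floors


def split_to_frame(split: pd.Series) -> pd.DataFrame:
    return split.rename_axis("stay_id").reset_index()
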