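"""Synthetic melatonin release series from a cyclized day/night co-culture.

The culture runs on a 24 h cycle: an 8 h day phase followed by a 16 h night
phase.  Supernatant is sampled 30 min before each night onset and 2 h, 5 h
and 8 h after the shift to night.  Release follows a constant day baseline
plus a raised-cosine night induction scaled by ``(1 - suppression)``:
``suppression = 0`` reproduces the unstressed profile, ``suppression = 1``
removes the night induction entirely (the chronic blue-light phenotype).

The night bump is normalized so that the mean of the three night samples
minus the baseline sample equals ``amplitude * (1 - suppression)`` exactly at
zero noise — the within-replicate induction statistic is therefore unbiased
by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

DAY_HOURS = 8.0
NIGHT_HOURS = 16.0
CYCLE_HOURS = DAY_HOURS + NIGHT_HOURS
#: sampling offsets relative to night onset (h): 30 min before, then +2/+5/+8
SAMPLING_OFFSETS = (-0.5, 2.0, 5.0, 8.0)


@dataclasses.dataclass(frozen=True)
class CycleTruth:
    baseline: float
    amplitude: float
    suppression: dict[str, float]  # per condition label
    n_days: int
    n_replicates: int
    noise_sd: float
    offsets: tuple[float, ...]
    seed: int


def _night_weight(offset_h: np.ndarray | float) -> np.ndarray:
    """Raised-cosine bump over the night phase, 0 during the day."""
    offset_h = np.asarray(offset_h, dtype=float)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * offset_h / NIGHT_HOURS))
    return np.where((offset_h > 0) & (offset_h < NIGHT_HOURS), w, 0.0)


def _bump_scale(offsets: tuple[float, ...]) -> float:
    night = [o for o in offsets if o > 0]
    return float(np.mean(_night_weight(np.array(night))))


def gen_melatonin_series(
    *,
    suppression: dict[str, float],
    seed: int,
    baseline: float = 20.0,
    amplitude: float = 30.0,
    n_days: int = 3,
    n_replicates: int = 3,
    noise_sd: float = 5.0,
    offsets: tuple[float, ...] = SAMPLING_OFFSETS,
) -> tuple[pd.DataFrame, CycleTruth]:
    """Generate per-condition melatonin series.

    Parameters
    ----------
    suppression:
        Mapping of condition label to suppression ``s`` in [0, 1] (e.g.
        ``{"untreated": 0.0, "blue light": 0.9, "blue light + extract": 0.2}``).
    baseline, amplitude:
        Day baseline level and night induction amplitude, in assay units
        (ELISA concentrations are treated as arbitrary units).
    noise_sd:
        Additive Gaussian measurement noise (same units); must be >= 0.

    Returns a tidy table with columns ``condition, replicate, day, offset_h,
    time_h, phase, value`` (``time_h`` counts from the start of the day phase
    of day 0) and the ground truth.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if baseline < 0:
        raise ValueError("baseline must be >= 0")
    for label, s in suppression.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"suppression for {label!r} must lie in [0, 1]")
    for o in offsets:
        if not -DAY_HOURS <= o <= NIGHT_HOURS:
            raise ValueError(f"offset {o} h falls outside the day/night schedule")

    rng = np.random.default_rng(seed)
    scale = _bump_scale(offsets)
    rows = []
    for label in suppression:
        s = suppression[label]
        for rep in range(n_replicates):
            for day in range(n_days):
                for off in offsets:
                    clean = baseline + (1.0 - s) * amplitude * float(_night_weight(off)) / scale
                    value = clean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    rows.append(
                        {
                            "condition": label,
                            "replicate": rep,
                            "day": day,
                            "offset_h": off,
                            "time_h": day * CYCLE_HOURS + DAY_HOURS + off,
                            "phase": "night" if off > 0 else "day",
                            "value": max(value, 0.0),
                        }
                    )
    truth = CycleTruth(
        baseline=baseline,
        amplitude=amplitude,
        suppression=dict(suppression),
        n_days=n_days,
        n_replicates=n_replicates,
        noise_sd=noise_sd,
        offsets=tuple(offsets),
        seed=seed,
    )
    return pd.DataFrame(rows), truth
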