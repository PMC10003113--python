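"""Phase alignment and night-induction analysis of melatonin series.

Samples are taken 30 min before each night onset and 2/5/8 h after it.  The
*night induction* of a replicate on a given day is the mean of its night
samples minus its pre-night baseline sample — a within-replicate delta that
is zero when blue light fully suppresses the night rise.  Day 1 is the
default analysis window.  Condition comparisons delegate to the statistics
ladder (Kruskal-Wallis followed by pairwise Mann-Whitney vs the control for
non-parametric data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from photoskin.stats import ComparisonResult, compare_groups
from photoskin.synth.melatonin import CYCLE_HOURS, DAY_HOURS, NIGHT_HOURS, SAMPLING_OFFSETS


def phase_align(
    raw: pd.DataFrame,
    offsets: tuple[float, ...] = SAMPLING_OFFSETS,
    *,
    tol_h: float = 1e-6,
) -> pd.DataFrame:
    """Label a raw time series (``time_h`` since day-0 day-phase start).

    Adds ``day`` (0-based day index), ``offset_h`` (relative to that day's
    night onset) and ``phase`` columns.  Every timestamp must map onto one of
    the design offsets; offenders are reported in the error.
    """
    out = raw.copy()
    if len(out) == 0:
        for col in ("day", "offset_h", "phase"):
            out[col] = pd.Series(dtype=float if col != "phase" else object)
        return out
    t = np.asarray(out["time_h"], dtype=float)
    day = np.floor(t / CYCLE_HOURS).astype(int)
    offset = t - day * CYCLE_HOURS - DAY_HOURS
    # a pre-night sample (-0.5 h) belongs to the upcoming night of its own day
    design = np.asarray(offsets, dtype=float)
    matched = np.abs(offset[:, None] - design[None, :]) <= tol_h
    ok = matched.any(axis=1)
    if not ok.all():
        bad = sorted(set(np.round(t[~ok], 3)))
        raise ValueError(f"timestamps outside the sampling schedule: {bad}")
    out["day"] = day
    out["offset_h"] = design[np.argmax(matched, axis=1)]
    out["phase"] = np.where(out["offset_h"] > 0, "night", "day")
    return out


def night_induction(series: pd.DataFrame, day: int = 1) -> pd.DataFrame:
    """Per-replicate night induction on ``day``.

    Returns a table ``condition, replicate, induction`` where induction is
    mean(night samples) - baseline (the -0.5 h sample).  Missing baseline or
    missing night samples are errors.
    """
    sub = series[series["day"] == day]
    if len(sub) == 0:
        raise ValueError(f"no samples on day {day}")
    rows = []
    for (cond, rep), grp in sub.groupby(["condition", "replicate"], sort=True):
        base = grp.loc[grp["offset_h"] < 0, "value"]
        night = grp.loc[grp["offset_h"] > 0, "value"]
        if len(base) == 0:
            raise ValueError(f"missing pre-night baseline for {cond!r} replicate {rep} on day {day}")
        if len(night) == 0:
            raise ValueError(f"no night samples for {cond!r} replicate {rep} on day {day}")
        rows.append({"condition": cond, "replicate": rep, "induction": float(night.mean() - base.mean())})
    return pd.DataFrame(rows)


def estimate_suppression(series: pd.DataFrame, amplitude: float, day: int = 1) -> pd.Series:
    """Per-condition suppression estimate: 1 - mean(induction) / amplitude."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    ind = night_induction(series, day=day)
    return 1.0 - ind.groupby("condition")["induction"].mean() / amplitude


def compare_conditions(
    series: pd.DataFrame,
    pairs: list[tuple[str, str]],
    day: int = 1,
    *,
    min_replicates: int = 3,
) -> list[ComparisonResult]:
    """Compare night induction between condition pairs via the stats ladder.

    Each pair is (treated, reference).  Uses the non-parametric unpaired
    route (Kruskal-Wallis / Mann-Whitney), matching how small-replicate
    release data are analyzed.
    """
    ind = night_induction(series, day=day)
    results = []
    for treated, reference in pairs:
        groups = {}
        for label in (treated, reference):
            vals = ind.loc[ind["condition"] == label, "induction"].to_numpy()
            if len(vals) < min_replicates:
                raise ValueError(f"condition {label!r} has fewer than {min_replicates} replicates")
            groups[label] = vals
        results.extend(
            compare_groups(groups, design="unpaired", reference=reference, gate="nonparametric")
        )
    return results
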