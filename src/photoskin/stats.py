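"""The statistical ladder for condition-vs-control comparisons.

Route selection follows the study convention: a Shapiro-Wilk test on every
group decides parametric vs non-parametric.  Parametric data take an
unpaired t-test (two groups) or a one-way ANOVA followed by Dunnett's
multiple-comparison test against the reference with a single pooled
variance; non-parametric unpaired data take a Kruskal-Wallis test followed
by pairwise Mann-Whitney U tests against the reference; non-parametric
paired data take a Wilcoxon signed-rank test.

Effect sizes are percent changes of the treated mean versus the reference
mean, reported raw and rounded to the nearest integer (half away from zero).
Significance flags: # for p < 0.1 (trend), * for p < 0.05, ** for p < 0.01,
*** for p < 0.001, ns otherwise.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA_SHAPIRO = 0.05

FLAG_THRESHOLDS = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
    (0.1, "#"),
)


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    group: str
    reference: str
    effect_percent_raw: float
    effect_percent: int
    test: str
    p_value: float
    flag: str
    design: str
    omnibus_p: float | None = None
    metric: str | None = None


def significance_flag(p: float) -> str:
    """Most significant applicable flag for a p-value."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for threshold, flag in FLAG_THRESHOLDS:
        if p < threshold:
            return flag
    return "ns"


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def percent_change(treated: float, reference: float) -> tuple[float, int]:
    """Signed percent change of ``treated`` vs ``reference``.

    Returns ``(raw, rounded)`` where raw = 100 * (treated - reference) /
    reference and rounded is the nearest integer, half away from zero.
    """
    if reference == 0:
        raise ValueError("reference mean must be non-zero")
    raw = 100.0 * (treated - reference) / reference
    return raw, _round_half_away(raw)


def _as_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {label: np.asarray(vals, dtype=float) for label, vals in groups.items()}


def normality_gate(groups: dict[str, np.ndarray], alpha: float = ALPHA_SHAPIRO) -> str:
    """Shapiro-Wilk gate: ``"parametric"`` iff every group passes at ``alpha``.

    Groups with fewer than 3 observations or zero variance are degenerate
    and rejected as errors.
    """
    groups = _as_groups(groups)
    for label, vals in groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {label!r} has n < 3")
        if np.ptp(vals) == 0:
            raise ValueError(f"group {label!r} is constant (degenerate for Shapiro-Wilk)")
    for vals in groups.values():
        if sps.shapiro(vals).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def _pairwise_p(treated: np.ndarray, reference: np.ndarray, test: str) -> float:
    if np.array_equal(treated, reference):
        return 1.0  # identical data: boundary case, no evidence of difference
    if test == "mannwhitney":
        return float(sps.mannwhitneyu(treated, reference, alternative="two-sided").pvalue)
    if test == "wilcoxon":
        diffs = treated - reference
        if np.all(diffs == 0):
            return 1.0
        return float(sps.wilcoxon(treated, reference).pvalue)
    if test == "ttest":
        return float(sps.ttest_ind(treated, reference).pvalue)
    if test == "ttest_paired":
        return float(sps.ttest_rel(treated, reference).pvalue)
    raise ValueError(test)


def compare_groups(
    groups: dict[str, np.ndarray],
    *,
    design: str = "unpaired",
    reference: str,
    gate: str | None = None,
    metric: str | None = None,
) -> list[ComparisonResult]:
    """Compare every non-reference group against ``reference`` via the ladder.

    ``gate`` forces the route ("parametric" / "nonparametric"); by default it
    is decided by :func:`normality_gate`.  Returns one
    :class:`ComparisonResult` per treated group, in input order.
    """
    if design not in ("paired", "unpaired"):
        raise ValueError(f"unknown design {design!r}")
    groups = _as_groups(groups)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} missing")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if gate is None:
        gate = normality_gate(groups)
    if gate not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown gate {gate!r}")

    ref_vals = groups[reference]
    treated_labels = [label for label in groups if label != reference]
    samples = [groups[label] for label in treated_labels]
    two_groups = len(groups) == 2

    omnibus_p: float | None = None
    if gate == "parametric":
        if design == "paired":
            test_name = "paired t-test"
            p_values = [_pairwise_p(s, ref_vals, "ttest_paired") for s in samples]
        elif two_groups:
            test_name = "unpaired t-test"
            p_values = [_pairwise_p(samples[0], ref_vals, "ttest")]
        else:
            omnibus_p = float(sps.f_oneway(*groups.values()).pvalue)
            test_name = "one-way ANOVA + Dunnett"
            if all(np.array_equal(s, ref_vals) for s in samples):
                p_values = [1.0] * len(samples)
            else:
                dunnett = sps.dunnett(*samples, control=ref_vals)
                p_values = [float(p) for p in dunnett.pvalue]
    else:
        if design == "paired":
            test_name = "Wilcoxon signed-rank"
            p_values = [_pairwise_p(s, ref_vals, "wilcoxon") for s in samples]
        else:
            if not two_groups:
                try:
                    omnibus_p = float(sps.kruskal(*groups.values()).pvalue)
                except ValueError:  # all values identical across groups
                    omnibus_p = 1.0
                test_name = "Kruskal-Wallis + Mann-Whitney U"
            else:
                test_name = "Mann-Whitney U"
            p_values = [_pairwise_p(s, ref_vals, "mannwhitney") for s in samples]

    results = []
    for label, p in zip(treated_labels, p_values):
        raw, rounded = percent_change(float(groups[label].mean()), float(ref_vals.mean()))
        results.append(
            ComparisonResult(
                group=label,
                reference=reference,
                effect_percent_raw=raw,
                effect_percent=rounded,
                test=test_name,
                p_value=p,
                flag=significance_flag(p),
                design=design,
                omnibus_p=omnibus_p,
                metric=metric,
            )
        )
    return results


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _format_percent(cr: ComparisonResult) -> str:
    sign = "+" if cr.effect_percent >= 0 else ""
    return f"({sign}{cr.effect_percent}% {cr.flag} vs. {cr.reference})"


def render_report(
    means: pd.DataFrame,
    comparisons: list[ComparisonResult],
    reference: str,
) -> str:
    """Render a per-metric, per-condition table with percent annotations.

    ``means`` has metrics as the index and condition labels as columns;
    ``comparisons`` carry their ``metric`` and ``group`` so each lands in the
    right cell as ``value (+X% flag vs. reference)``.  Values are written in
    full float precision so the table parses back exactly.
    """
    if reference not in means.columns:
        raise ValueError(f"reference column {reference!r} missing from the table")
    lookup = {(cr.metric, cr.group): cr for cr in comparisons}
    lines = ["Category\t" + "\t".join(str(c) for c in means.columns)]
    for metric, row in means.iterrows():
        cells = []
        for cond in means.columns:
            cell = f"{row[cond]:.17g}"
            cr = lookup.get((metric, cond))
            if cr is not None:
                cell += " " + _format_percent(cr)
            cells.append(cell)
        lines.append(str(metric) + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> pd.DataFrame:
    """Recover the numeric means from a rendered report table."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    data: dict[str, list[float]] = {}
    index = []
    for line in lines[1:]:
        parts = line.split("\t")
        index.append(parts[0])
        for cond, cell in zip(header, parts[1:]):
            value = float(cell.split(" (")[0])
            data.setdefault(cond, []).append(value)
    return pd.DataFrame(data, index=index)
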