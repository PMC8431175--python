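"""Per-subject longitudinal change metrics and cachexia classification.

Change against baseline is computed at every follow-up and the "maximum
change" is the one with the largest magnitude, with its sign preserved
(losses stay negative).  PDFF changes are reported absolutely (percentage
points); volume changes relatively (% of baseline).  Cachexia follows the
Fearon consensus definition: >5% unintentional weight loss within 6 months,
or >2% loss with BMI < 20 kg/m2, or sarcopenia with >2% loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChangeRecord",
    "compute_bmi",
    "max_change",
    "classify_cachexia",
    "weight_history_from_self_report",
    "SIX_MONTHS_DAYS",
]

#: Operationalisation of the Fearon "6 months" window, days.
SIX_MONTHS_DAYS = 183


@dataclass(frozen=True)
class ChangeRecord:
    """Change of one metric at the follow-up where |change| is largest.

    ``absolute_change`` is in the metric's units; ``relative_change_pct`` is
    100 * (follow - baseline) / baseline (None when the baseline is zero).
    ``followup_index`` is 1-based among the follow-ups (baseline excluded).
    """

    metric: str
    absolute_change: float
    relative_change_pct: float | None
    followup_index: int
    followup_day: float
    mode: str


def compute_bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight (kg) divided by height (m) squared."""
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


def max_change(
    days: "list[float] | np.ndarray",
    values: "list[float] | np.ndarray",
    mode: str = "absolute",
    metric: str = "",
) -> ChangeRecord:
    """Maximum change versus baseline across follow-ups.

    Parameters
    ----------
    days : sequence
        Scan-day offsets; the first entry is the baseline (day 0) and
        offsets must be strictly increasing with at least one follow-up.
    values : sequence
        Metric values at those days.
    mode : {"absolute", "relative"}
        Which change the maximum ranks on: absolute difference (used for
        PDFF, percentage points) or percent of baseline (used for volumes).

    Returns
    -------
    ChangeRecord
        The follow-up with the largest |change| (signed value preserved;
        ties broken by the earliest follow-up).

    Raises
    ------
    ValueError
        For missing follow-ups, non-increasing days, or relative mode with
        a zero baseline.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size != values.size:
        raise ValueError("days and values must have equal length")
    if days.size < 2:
        raise ValueError("need a baseline and at least one follow-up")
    if np.any(np.diff(days) <= 0):
        raise ValueError("day offsets must be strictly increasing")
    if mode not in ("absolute", "relative"):
        raise ValueError(f"mode must be 'absolute' or 'relative', got {mode!r}")
    base = values[0]
    abs_changes = values[1:] - base
    if mode == "relative":
        if base == 0:
            raise ValueError("relative change undefined: baseline value is 0")
        ranking = 100.0 * abs_changes / base
    else:
        ranking = abs_changes
    idx = int(np.argmax(np.abs(ranking)))  # argmax returns the first (earliest) tie
    rel = 100.0 * abs_changes[idx] / base if base != 0 else None
    return ChangeRecord(
        metric=metric,
        absolute_change=float(abs_changes[idx]),
        relative_change_pct=None if rel is None else float(rel),
        followup_index=idx + 1,
        followup_day=float(days[idx + 1]),
        mode=mode,
    )


def weight_history_from_self_report(
    baseline_weight_kg: float,
    self_reported_loss_kg: float,
    days_before_baseline: float = SIX_MONTHS_DAYS,
) -> list[tuple[float, float]]:
    """Turn a self-reported pre-baseline loss into a (day, kg) history.

    A reported loss of L kg is encoded as a pseudo-observation of
    ``baseline + L`` kg, ``days_before_baseline`` days before the baseline
    scan, so that baseline cachexia can be classified from the same windowed
    criteria as measured weights.
    """
    loss = abs(self_reported_loss_kg)
    return [(-float(days_before_baseline), baseline_weight_kg + loss), (0.0, baseline_weight_kg)]


def classify_cachexia(
    weight_history: "list[tuple[float, float]]",
    bmi: float | None = None,
    sarcopenia: bool | None = None,
    window_days: float = SIX_MONTHS_DAYS,
) -> tuple[bool, str]:
    """Fearon consensus cachexia classification.

    Parameters
    ----------
    weight_history : list of (day, kg)
        At least two observations (a self-reported pre-baseline loss can be
        encoded with :func:`weight_history_from_self_report`).
    bmi : float, optional
        BMI for the low-BMI criterion; if None that criterion is skipped.
    sarcopenia : bool, optional
        External sarcopenia flag (appendicular lean-mass indices are not
        computed here); if None the sarcopenia criterion is skipped.
    window_days : float
        The "6 month" window length, default 183 days.

    Returns
    -------
    (cachectic, criterion)
        ``criterion`` is ``"weight_loss_gt5pct"``, ``"low_bmi_loss_gt2pct"``,
        ``"sarcopenia_loss_gt2pct"`` or ``"none"``.  The criteria are
        evaluated over every pair of observations at most ``window_days``
        apart, in the order above.
    """
    hist = sorted((float(d), float(w)) for d, w in weight_history)
    if len(hist) < 2:
        raise ValueError("need at least two weight observations (or a self-reported loss)")
    if any(w <= 0 for _, w in hist):
        raise ValueError("weights must be positive")

    max_loss_pct = 0.0
    for i in range(len(hist)):
        for j in range(i + 1, len(hist)):
            d_i, w_i = hist[i]
            d_j, w_j = hist[j]
            if d_j - d_i > window_days:
                continue
            loss_pct = 100.0 * (w_i - w_j) / w_i
            max_loss_pct = max(max_loss_pct, loss_pct)

    if max_loss_pct > 5.0:
        return True, "weight_loss_gt5pct"
    if bmi is not None and bmi < 20.0 and max_loss_pct > 2.0:
        return True, "low_bmi_loss_gt2pct"
    if sarcopenia and max_loss_pct > 2.0:
        return True, "sarcopenia_loss_gt2pct"
    return False, "none"
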