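"""BSP variability at constant anesthetic infusion rates.

Within-patient: segments where all infusion rates are constant for at least two
hours (excluding 30 minutes around every recorded rate change and any window
containing a bolus) are extracted, and a linear regression of BSP on time
quantifies drift — a direct readout of intra-patient pharmacokinetic/
pharmacodynamic variation, since the input is fixed while the response moves.

Between-patient: segments from different subjects with identical weight-
normalized dose combinations (rates rounded to 0.1 mg/kg/hr) are compared with
an exceedance probability — the chance that a BSP sample drawn from the
lower-median distribution falls below one drawn from the higher-median
distribution. Values near 1 mean matched doses produced clearly different
depths of suppression in different patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .bsp import BSPTrajectory
from .records import MedicationRecord

#: |slope| above 0.1 BSP units per hour (2.4 per day) counts as directed drift.
SLOPE_THRESHOLD_PER_DAY = 2.4
#: BSP standard deviation above this, without directed drift, counts as "varying".
SD_THRESHOLD = 0.1


@dataclass
class ConstantDoseSegment:
    """A trimmed constant-dose interval with the BSP series observed inside it.

    ``start``/``end`` are the trimmed (guard-excluded) bounds in seconds;
    ``dose_combo`` maps drug name to its constant rate in mg/kg/hr (zero-rate
    drugs omitted); ``times``/``bsp`` are the valid trajectory epochs inside.
    """

    start: float
    end: float
    dose_combo: dict[str, float]
    times: np.ndarray
    bsp: np.ndarray
    subject_id: str | None = None
    slope_per_day: float | None = None
    intercept: float | None = None
    trend: str | None = None

    @property
    def median_bsp(self) -> float:
        return float(np.median(self.bsp))

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / 3600.0


def extract_constant_segments(
    meds: MedicationRecord,
    traj: BSPTrajectory,
    min_raw: float = 7200.0,
    guard: float = 1800.0,
    min_median_bsp: float = 0.05,
    end_time: float | None = None,
) -> list[ConstantDoseSegment]:
    """Maximal non-overlapping constant-dose segments satisfying all study rules.

    A raw window runs between consecutive recorded rate changes (or the record
    boundaries). It is kept only if it lasts at least ``min_raw`` (2 h) and
    contains no bolus; ``guard`` (30 min) is then trimmed from each end — so the
    shortest emitted segment is 1 h — and the segment is dropped unless the
    median BSP of its valid epochs reaches ``min_median_bsp``.
    """
    if end_time is None:
        end_time = len(traj) * traj.epoch_len
    cuts = [t for t in meds.change_times() if 0.0 < t < end_time]
    edges = [0.0, *cuts, end_time]
    boluses = np.asarray(meds.bolus_times())
    out: list[ConstantDoseSegment] = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < min_raw:
            continue
        if boluses.size and np.any((boluses >= a) & (boluses < b)):
            continue
        s, e = a + guard, b - guard
        starts = traj.times
        sel = (starts >= s) & (starts + traj.epoch_len <= e)
        if traj.counts is not None:
            sel &= traj.counts.valid
        if not sel.any():
            continue
        seg = ConstantDoseSegment(
            start=s,
            end=e,
            dose_combo=meds.combo_at(a),
            times=starts[sel],
            bsp=traj.bsp[sel],
            subject_id=meds.subject_id,
        )
        if seg.median_bsp < min_median_bsp:
            continue
        seg.slope_per_day, seg.intercept, seg.trend = fit_drift(seg)
        out.append(seg)
    return out


def fit_drift(seg: ConstantDoseSegment) -> tuple[float, float, str]:
    """Ordinary least squares of BSP against time (in days) within a segment.

    The intercept is referenced to the segment's first epoch. The four observed
    trend shapes are operationalized as: *increasing*/*decreasing* when
    |slope| > 2.4 per day (0.1 BSP per hour); otherwise *constant* when the BSP
    standard deviation is ≤ 0.1, else *varying*.
    """
    t = np.asarray(seg.times, dtype=float)
    y = np.asarray(seg.bsp, dtype=float)
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("drift fit needs at least two distinct time points")
    days = (t - t[0]) / 86400.0
    res = stats.linregress(days, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if abs(slope) > SLOPE_THRESHOLD_PER_DAY:
        trend = "increasing" if slope > 0 else "decreasing"
    elif float(np.std(y)) <= SD_THRESHOLD:
        trend = "constant"
    else:
        trend = "varying"
    return slope, intercept, trend


def slope_to_delta(slope_per_day: float, interval_min: float) -> float:
    """BSP change implied by a drift slope over ``interval_min`` minutes."""
    if interval_min <= 0:
        raise ValueError("interval must be positive")
    return slope_per_day * interval_min / 1440.0


def exceedance_probability(
    x: np.ndarray,
    y: np.ndarray,
    max_pairs: int = 10**7,
    seed: int | None = None,
) -> float:
    """P(X < Y) + 0.5·P(X = Y) over all pairs — the normalized Mann-Whitney
    U statistic. Exact by pair counting while |x|·|y| ≤ ``max_pairs``; above
    that, a seeded random subsample of pairs is used. Antisymmetric:
    P(x, y) = 1 − P(y, x) in the absence of ties."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("exceedance probability of an empty sample set is undefined")
    if x.size * y.size <= max_pairs:
        xs = np.sort(x)
        less = np.searchsorted(xs, y, side="left")
        leq = np.searchsorted(xs, y, side="right")
        return float(np.sum(less + 0.5 * (leq - less)) / (x.size * y.size))
    rng = np.random.default_rng(seed)
    xi = rng.integers(0, x.size, max_pairs)
    yi = rng.integers(0, y.size, max_pairs)
    xv, yv = x[xi], y[yi]
    return float(np.mean((xv < yv) + 0.5 * (xv == yv)))


@dataclass
class DoseMatchGroup:
    """Subjects who received an identical (rounded) dose combination.

    ``members`` pools each subject's BSP samples across their segments at this
    combination; ``comparisons`` holds (lower-median subject, higher-median
    subject, exceedance probability) for every pair of distinct subjects.
    """

    combo: tuple[tuple[str, float], ...]
    members: dict[str, np.ndarray]
    comparisons: list[tuple[str, str, float]] = field(default_factory=list)


def _combo_key(combo: dict[str, float], decimals: int = 1) -> tuple[tuple[str, float], ...]:
    key = tuple(
        sorted((d, round(r, decimals)) for d, r in combo.items() if round(r, decimals) > 0)
    )
    return key


def match_dose_groups(
    segments: list[ConstantDoseSegment],
    decimals: int = 1,
    seed: int | None = None,
) -> list[DoseMatchGroup]:
    """Group constant-dose segments across subjects by identical dose combination.

    Rates are rounded to ``decimals`` (default 0.1 mg/kg/hr) before matching;
    combinations must agree on the drug set and every rate. Combinations seen in
    fewer than two distinct subjects are dropped. Within each group the
    exceedance probability is reported lower-median subject first.
    """
    pools: dict[tuple, dict[str, list[np.ndarray]]] = {}
    for seg in segments:
        if seg.subject_id is None:
            raise ValueError("segments must carry subject ids for dose matching")
        key = _combo_key(seg.dose_combo, decimals)
        if not key:
            continue
        pools.setdefault(key, {}).setdefault(seg.subject_id, []).append(seg.bsp)
    groups: list[DoseMatchGroup] = []
    for key in sorted(pools):
        members = {s: np.concatenate(chunks) for s, chunks in pools[key].items()}
        if len(members) < 2:
            continue
        g = DoseMatchGroup(key, members)
        for sa, sb in combinations(sorted(members), 2):
            lo_id, hi_id = sa, sb
            if np.median(members[sa]) > np.median(members[sb]):
                lo_id, hi_id = sb, sa
            p = exceedance_probability(members[lo_id], members[hi_id], seed=seed)
            g.comparisons.append((lo_id, hi_id, p))
        groups.append(g)
    return groups
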