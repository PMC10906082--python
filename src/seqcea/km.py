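"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published survival figures only give the curve and the numbers-at-risk row.
`reconstruct_ipd` inverts the product-limit estimator: within each interval
between consecutive risk-table times it allocates integer event and censoring
counts so that (a) the KM estimator of the reconstructed records tracks the
digitized coordinates and (b) the number at risk at every risk-table time is
matched exactly.  Censoring is spread uniformly within each interval and, at
tied times, events precede censorings.  This is the standard Guyot-type
reconstruction; the variant here solves each interval's censoring count by
integer bisection, which is robust to digitization rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DigitizedKM", "PseudoIPD", "reconstruct_ipd", "km_estimate"]


@dataclass
class DigitizedKM:
    """Digitized KM coordinates plus the numbers-at-risk row.

    ``times``/``survival`` are the curve coordinates starting at (0, 1);
    ``risk_times``/``n_at_risk`` give the risk table.  Survival values may
    wobble slightly upward from hand digitization; they are clipped to
    non-increasing before reconstruction.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    total_events_reported: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if len(self.times) != len(self.survival):
            raise ValueError("times and survival must have equal length")
        if len(self.risk_times) != len(self.n_at_risk):
            raise ValueError("risk_times and n_at_risk must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("coordinate times must be strictly increasing")
        if self.times[0] != 0 or abs(self.survival[0] - 1.0) > 1e-9:
            raise ValueError("coordinates must start at (0, 1.0)")
        if np.any((self.survival < -1e-9) | (self.survival > 1 + 1e-9)):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(self.risk_times) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if self.risk_times[0] < self.times[0] or self.risk_times[-1] > self.times[-1]:
            raise ValueError("risk-table times must lie within the observed range")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("numbers at risk must be non-increasing")
        if np.any(self.n_at_risk < 0):
            raise ValueError("numbers at risk must be non-negative")

    def survival_at(self, t) -> np.ndarray:
        """Step-function (right-continuous) lookup of the digitized curve."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return self.survival[np.clip(idx, 0, len(self.times) - 1)]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        coords = pd.DataFrame({"time": self.times, "survival": self.survival})
        risk = pd.DataFrame({"time": self.risk_times, "n_at_risk": self.n_at_risk})
        return coords, risk


@dataclass
class PseudoIPD:
    """Reconstructed patient-level records: time in months, event in {0, 1}."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.time) == 0:
            raise ValueError("pseudo-IPD must contain at least one record")
        if len(self.time) != len(self.event):
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all record times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PseudoIPD":
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


def _walk_block(
    times: np.ndarray,
    surv: np.ndarray,
    idxs: np.ndarray,
    start: float,
    end: float,
    n_censor: int,
    n0: int,
    prod0: float,
):
    """Allocate events at coordinates ``idxs`` and ``n_censor`` uniform
    censorings over [start, end), starting from ``n0`` at risk and a running
    KM level ``prod0``.  Returns (events, censor_times, n_end, prod_end)."""
    if n_censor > 0:
        ct = start + (np.arange(n_censor) + 0.5) * (end - start) / n_censor
    else:
        ct = np.empty(0)
    events: list[tuple[float, int]] = []
    used_cens: list[float] = []
    n, prod = n0, prod0
    pos = 0
    prev_t = start
    for j in idxs:
        tj = times[j]
        # a drop digitized at tj is only known to lie in the gap since the
        # previous coordinate; placing it at the gap midpoint removes the
        # half-gap bias that putting every event on the grid would induce
        ev_t = 0.5 * (max(prev_t, start) + tj)
        # censorings before the event time leave first
        k = int(np.searchsorted(ct, ev_t, side="left")) - pos
        k = min(k, n)
        used_cens.extend(ct[pos : pos + k])
        n -= k
        pos += k
        if n > 0 and prod > 0 and surv[j] < prod:
            d = int(round(n * (1.0 - surv[j] / prod)))
            d = min(max(d, 0), n)
        else:
            d = 0
        if d > 0:
            prod *= 1.0 - d / n
            n -= d
            events.append((ev_t, d))
        prev_t = tj
    k = min(len(ct) - pos, n)
    used_cens.extend(ct[pos : pos + k])
    n -= k
    return events, used_cens, n, prod


def reconstruct_ipd(km: DigitizedKM) -> PseudoIPD:
    """Reconstruct pseudo patient-level records from a digitized KM curve.

    Raises ``ValueError`` naming the interval when the risk table is
    inconsistent with any non-negative allocation.  Records remaining at risk
    after the last coordinate are censored administratively at that time.
    """
    if len(km.risk_times) < 2:
        raise ValueError("need at least two risk-table entries")
    surv = np.minimum.accumulate(np.clip(km.survival, 0.0, 1.0))
    times = km.times
    rt = km.risk_times
    nr = km.n_at_risk

    events: list[tuple[float, int]] = []
    cens: list[float] = []
    n = int(nr[0])
    prod = 1.0
    # a coordinate exactly at a risk-table time carries the drop accumulated
    # just before it, so intervals are left-open: (rt[i], rt[i+1]]
    for i in range(len(rt) - 1):
        lo, hi = rt[i], rt[i + 1]
        idxs = np.where((times > lo) & (times <= hi) & (times > 0))[0]
        target = int(nr[i + 1])

        def n_end(c: int) -> int:
            return _walk_block(times, surv, idxs, lo, hi, c, n, prod)[2]

        if n_end(0) < target:
            raise ValueError(
                f"risk table inconsistent with the curve in interval "
                f"[{lo:g}, {hi:g}): cannot retain {target} at risk"
            )
        lo_c, hi_c = 0, n
        while lo_c < hi_c:
            mid = (lo_c + hi_c) // 2
            if n_end(mid) <= target:
                hi_c = mid
            else:
                lo_c = mid + 1
        ev, ce, n2, prod2 = _walk_block(times, surv, idxs, lo, hi, lo_c, n, prod)
        if n2 > target:
            # event rounding left a surplus; censor it just inside the interval
            pad_t = hi - (hi - lo) * 1e-9
            ce = ce + [pad_t] * (n2 - target)
            n2 = target
        elif n2 < target:
            raise ValueError(
                f"risk table inconsistent in interval [{lo:g}, {hi:g})"
            )
        events.extend(ev)
        cens.extend(ce)
        n, prod = n2, prod2

    # beyond the last risk-table time: events per the curve, then
    # administrative censoring of everyone still at risk
    idxs = np.where((times > rt[-1]) & (times > 0))[0]
    ev, ce, n, prod = _walk_block(
        times, surv, idxs, rt[-1], times[-1] + 1.0, 0, n, prod
    )
    events.extend(ev)
    cens.extend(ce)
    if n > 0:
        cens.extend([float(times[-1])] * n)

    if km.total_events_reported is not None:
        events, cens = _rescale_events(events, cens, km.total_events_reported)

    t_list: list[float] = []
    e_list: list[int] = []
    for tv, d in events:
        t_list.extend([tv] * d)
        e_list.extend([1] * d)
    t_list.extend(cens)
    e_list.extend([0] * len(cens))
    order = np.argsort(t_list, kind="stable")
    return PseudoIPD(np.asarray(t_list)[order], np.asarray(e_list)[order])


def _rescale_events(
    events: list[tuple[float, int]], cens: list[float], reported: int
):
    """Secondary constraint: nudge the allocation toward the reported total
    event count by relabelling the latest records, keeping counts fixed."""
    total = sum(d for _, d in events)
    if total == reported:
        return events, cens
    if total > reported:
        excess = total - reported
        out = []
        for tv, d in sorted(events, key=lambda x: -x[0]):
            take = min(d, excess)
            excess -= take
            if take:
                cens = cens + [tv] * take
            if d - take:
                out.append((tv, d - take))
        if excess:
            warnings.warn(
                f"could not fully match reported events ({reported}); "
                f"{excess} surplus events remain",
                RuntimeWarning,
                stacklevel=3,
            )
        return sorted(out), cens
    deficit = reported - total
    cens_sorted = sorted(cens, reverse=True)
    promote = cens_sorted[:deficit]
    if len(promote) < deficit:
        warnings.warn(
            f"could not fully match reported events ({reported}); "
            f"{deficit - len(promote)} missing",
            RuntimeWarning,
            stacklevel=3,
        )
    remaining = cens_sorted[len(promote):]
    events = sorted(events + [(tv, 1) for tv in promote])
    return events, remaining


def km_estimate(ipd: PseudoIPD) -> DigitizedKM:
    """Product-limit estimator of reconstructed (or any) patient-level data.

    At tied times events are processed before censorings.  The returned
    risk table holds the number at risk just before each coordinate time.
    """
    t = ipd.time
    e = ipd.event
    order = np.lexsort((1 - e, t))
    t, e = t[order], e[order]
    n = len(t)
    coords_t = [0.0]
    coords_s = [1.0]
    risk_t = [0.0]
    risk_n = [n]
    s = 1.0
    i = 0
    at_risk = n
    while i < n:
        tv = t[i]
        j = i
        d = c = 0
        while j < n and t[j] == tv:
            if e[j] == 1:
                d += 1
            else:
                c += 1
            j += 1
        if d > 0:
            s *= 1.0 - d / at_risk
            coords_t.append(tv)
            coords_s.append(s)
            risk_t.append(tv)
            risk_n.append(at_risk)
        at_risk -= d + c
        i = j
    return DigitizedKM(
        np.asarray(coords_t),
        np.asarray(coords_s),
        np.asarray(risk_t),
        np.asarray(risk_n),
    )
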