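"""Laser-trap mechanics: sliding friction and force-ramp rupture.

Records are DataFrames with columns ``time_s, position_nm, force_pN``;
position and force are signed, positive toward the microtubule plus
end, and arrive pre-calibrated (no stiffness calibration here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simgen import TOWARD_MINUS, TOWARD_PLUS


@dataclass(frozen=True)
class SlidingEvent:
    """One constant-force sliding excursion."""

    direction: str
    mean_force_pN: float  # magnitude
    speed_nm_s: float  # >= 0
    r_squared: float
    excursion_nm: float
    duration_s: float
    constant_force: bool
    pair_id: str = ""


@dataclass(frozen=True)
class RuptureEvent:
    peak_force_pN: float
    censored: bool
    censor_reason: str = ""  # "load_limit" | "surface_failure" | ""
    end: str = ""  # "plus" | "minus"
    bead_id: str = ""


def segment_force_epochs(
    record: pd.DataFrame,
    min_duration_s: float = 0.25,
    min_force_pN: float = 0.1,
    force_tolerance: float = 0.10,
) -> list[pd.DataFrame]:
    """Split a record into constant-force epochs at force sign changes.

    Within-epoch force must stay within ``force_tolerance`` (fractional)
    of its mean; epochs that drift beyond it are flagged via the
    ``constant_force`` attribute on the returned frame. Epochs shorter
    than ``min_duration_s`` or weaker than ``min_force_pN`` are dropped.
    Raises ValueError if nothing remains.
    """
    f = record["force_pN"].to_numpy(dtype=float)
    sign = np.sign(f)
    # treat zero-force samples as continuation of the previous sign
    nz = sign != 0
    if not nz.any():
        raise ValueError("record has no applied force")
    s = sign.copy()
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    bounds = [0] + (np.flatnonzero(np.diff(s) != 0) + 1).tolist() + [len(f)]
    epochs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = record.iloc[a:b]
        dur = seg.time_s.iloc[-1] - seg.time_s.iloc[0]
        mean_f = seg.force_pN.mean()
        if dur < min_duration_s or abs(mean_f) < min_force_pN:
            continue
        const = bool(np.max(np.abs(seg.force_pN - mean_f)) <= force_tolerance * abs(mean_f))
        seg = seg.copy()
        seg.attrs["constant_force"] = const
        seg.attrs["mean_force_pN"] = float(mean_f)
        epochs.append(seg)
    if not epochs:
        raise ValueError("no valid constant-force epoch found")
    return epochs


def event_speed(epoch: pd.DataFrame, pair_id: str = "") -> SlidingEvent:
    """Sliding speed of one epoch by ordinary least-squares regression.

    Speed is the slope magnitude; direction comes from the slope sign
    (positive = toward the plus end). Requires >= 10 samples.
    """
    if len(epoch) < 10:
        raise ValueError("need >= 10 samples for speed regression")
    t = epoch.time_s.to_numpy(dtype=float)
    x = epoch.position_nm.to_numpy(dtype=float)
    res = stats.linregress(t, x)
    direction = TOWARD_PLUS if res.slope >= 0 else TOWARD_MINUS
    return SlidingEvent(
        direction=direction,
        mean_force_pN=float(abs(epoch.force_pN.mean())),
        speed_nm_s=float(abs(res.slope)),
        r_squared=float(res.rvalue**2),
        excursion_nm=float(x[-1] - x[0]),
        duration_s=float(t[-1] - t[0]),
        constant_force=bool(epoch.attrs.get("constant_force", True)),
        pair_id=pair_id,
    )


def friction_coefficient(
    events: list[SlidingEvent],
    bin_center_pN: float = 1.0,
    half_width_pN: float = 0.5,
) -> dict:
    """Direction-resolved frictional drag gamma = F / v per event.

    Events whose mean force magnitude falls in
    [center - w, center + w) are kept; each contributes
    gamma = mean_force / speed (pN*s/nm). Returns per-pair,
    per-direction mean +/- SEM of gamma, pooled per-direction gamma and
    speed summaries, and the per-event table. Zero-speed events are
    excluded with a warning.
    """
    lo, hi = bin_center_pN - half_width_pN, bin_center_pN + half_width_pN
    rows = []
    for ev in events:
        if not (lo <= ev.mean_force_pN < hi) or not ev.constant_force:
            continue
        if ev.speed_nm_s == 0:
            warnings.warn("zero-speed event excluded from friction", stacklevel=2)
            continue
        rows.append(
            {
                "pair_id": ev.pair_id,
                "direction": ev.direction,
                "force_pN": ev.mean_force_pN,
                "speed_nm_s": ev.speed_nm_s,
                "gamma": ev.mean_force_pN / ev.speed_nm_s,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) == 0:
        raise ValueError("no events in the force bin")

    def agg(g):
        return pd.Series(
            {
                "gamma_mean": g.gamma.mean(),
                "gamma_sem": g.gamma.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0,
                "speed_mean": g.speed_nm_s.mean(),
                "speed_sem": g.speed_nm_s.std(ddof=1) / np.sqrt(len(g)) if len(g) > 1 else 0.0,
                "n_events": len(g),
            }
        )

    per_pair = table.groupby(["pair_id", "direction"]).apply(agg, include_groups=False)
    pooled = table.groupby("direction").apply(agg, include_groups=False)
    return {"events": table, "per_pair": per_pair, "pooled": pooled,
            "bin_pN": (bin_center_pN, half_width_pN)}


def detect_rupture(
    record: pd.DataFrame,
    drop_threshold_nm: float = 15.0,
    load_limit_pN: float = 23.0,
    window: int = 5,
    limit_tolerance_pN: float = 1.0,
    end: str = "",
    bead_id: str = "",
) -> RuptureEvent:
    """Find the rupture (or censoring) point in a force-ramp record.

    The ramp is the region where force rises monotonically above the
    preload. Rupture is the first sample where position snaps back
    toward the trap center by more than ``drop_threshold_nm`` within
    ``window`` samples; the peak force is the force at that sample. If
    no snap-back occurs before the trap's load limit the event is
    censored at the limit.
    """
    f = record["force_pN"].to_numpy(dtype=float)
    x = record["position_nm"].to_numpy(dtype=float)
    if len(f) < 2 * window:
        raise ValueError("record too short")
    fmax = f.max()
    preload = float(np.median(f[: 4 * window]))
    if fmax < preload + 0.3:
        raise ValueError("no force ramp found in record")

    # smooth localization noise before the drop test; the snap-back is a
    # persistent level change, so a short mean filter preserves it
    from scipy.ndimage import uniform_filter1d

    xs = uniform_filter1d(x, size=window, mode="nearest")
    # forward-looking drop: xs[i] - min(xs[i+1 .. i+window])
    n = len(x)
    drops = np.full(n, 0.0)
    for k in range(1, window + 1):
        shifted = np.empty(n)
        shifted[: n - k] = xs[k:]
        shifted[n - k :] = xs[-1]
        drops = np.maximum(drops, xs - shifted)
    snapped = np.flatnonzero(drops > drop_threshold_nm)
    # only accept snap-backs while under ramp load (force above preload)
    snapped = snapped[f[snapped] > preload + 0.05]
    if len(snapped):
        i = int(snapped[0])
        # average the measurement noise out of the peak force by regressing
        # the ramp over the ~50 samples leading up to the rupture
        lo = max(0, i - 50)
        t = record["time_s"].to_numpy(dtype=float)
        idx = np.arange(lo, i + 1)
        idx = idx[f[idx] > preload + 0.2]  # stay on the ramp, off the dwell
        if len(idx) >= 10 and np.ptp(t[idx]) > 0:
            fit = stats.linregress(t[idx], f[idx])
            peak = float(fit.intercept + fit.slope * t[i])
        else:
            peak = float(f[i])
        return RuptureEvent(peak, censored=False, end=end, bead_id=bead_id)
    if fmax >= load_limit_pN - limit_tolerance_pN:
        return RuptureEvent(
            float(fmax), censored=True, censor_reason="load_limit", end=end,
            bead_id=bead_id,
        )
    raise ValueError("no rupture and load limit never reached")


def summarize_strengths(events: list[RuptureEvent]) -> dict:
    """Summary of rupture strengths with censoring handled explicitly.

    Uncensored strengths give mean +/- SEM, median, quartiles (linear
    interpolation), and whiskers at mean +/- 1 SD; censored events are
    counted separately, never pooled into the mean. When a bead was
    measured at both microtubule ends, the paired plus-minus strength
    differences are reported. Requires >= 2 uncensored events.
    """
    unc = np.array([e.peak_force_pN for e in events if not e.censored])
    if len(unc) < 2:
        raise ValueError("need >= 2 uncensored rupture events")
    mean = float(unc.mean())
    sd = float(unc.std(ddof=1))
    q1, med, q3 = np.percentile(unc, [25, 50, 75])

    pairs = []
    by_bead: dict[str, dict[str, float]] = {}
    for e in events:
        if e.bead_id and e.end and not e.censored:
            by_bead.setdefault(e.bead_id, {})[e.end] = e.peak_force_pN
    for bead, d in by_bead.items():
        if "plus" in d and "minus" in d:
            pairs.append({"bead_id": bead, "plus_pN": d["plus"],
                          "minus_pN": d["minus"],
                          "difference_pN": d["plus"] - d["minus"]})

    return {
        "n_uncensored": int(len(unc)),
        "n_censored": int(sum(e.censored for e in events)),
        "mean_pN": mean,
        "sem_pN": sd / np.sqrt(len(unc)),
        "sd_pN": sd,
        "median_pN": float(med),
        "q1_pN": float(q1),
        "q3_pN": float(q3),
        "whisker_low_pN": mean - sd,
        "whisker_high_pN": mean + sd,
        "paired_by_bead": pd.DataFrame(pairs),
    }
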