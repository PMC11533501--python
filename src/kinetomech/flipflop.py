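"""Flip-flop nanometry of intra-kinetochore architecture.

A surface-assembled kinetochore reorients 180 degrees about its
coverslip tether with each reversal of a gentle buffer flow. Averaging
a fluorescent subunit's tracked position over the steady interval of
each flow epoch, and taking midpoints of the interval means flanking
each reversal, locates the tether; the distance from each interval mean
to the tether (projected on the flow axis) measures how far that
subunit sits from the anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simgen import FlowSchedule
from .statcore import ks_two_sample


@dataclass(frozen=True)
class IntervalEstimate:
    """Mean tracked position over one steady flow interval."""

    interval_id: int
    sign: int
    direction: str
    mean_xy: tuple  # nm
    sd_proj: float  # SD of the flow-axis projection, nm
    n_frames: int
    used: bool


def link_trajectory(
    spots: pd.DataFrame, max_jump: float, start_xy: tuple | None = None
) -> pd.DataFrame:
    """Nearest-neighbor linking of per-frame detections into one track.

    ``spots`` has columns ``frame, x_nm, y_nm`` (possibly several
    candidate detections per frame). The candidate nearest to the last
    linked position is accepted if within ``max_jump`` nm; otherwise the
    frame is left as a gap (NaN) and the anchor position is kept.
    Returns a frame-indexed DataFrame (frame, x_nm, y_nm) covering the
    full frame range; empty input yields an empty trajectory.
    """
    if len(spots) == 0:
        return pd.DataFrame(columns=["frame", "x_nm", "y_nm"])
    frames = np.arange(spots.frame.min(), spots.frame.max() + 1)
    out = np.full((len(frames), 2), np.nan)
    last = np.asarray(start_xy, dtype=float) if start_xy is not None else None
    by_frame = dict(tuple(spots.groupby("frame")))
    for i, f in enumerate(frames):
        cand = by_frame.get(f)
        if cand is None or len(cand) == 0:
            continue
        xy = cand[["x_nm", "y_nm"]].to_numpy(dtype=float)
        if last is None:
            pick = int(np.argmax(cand["intensity"])) if "intensity" in cand else 0
            last = xy[pick]
            out[i] = last
            continue
        d = np.linalg.norm(xy - last, axis=1)
        j = int(np.argmin(d))
        if d[j] <= max_jump:
            last = xy[j]
            out[i] = last
    return pd.DataFrame({"frame": frames, "x_nm": out[:, 0], "y_nm": out[:, 1]})


def segment_intervals(
    trajectory: pd.DataFrame,
    schedule: FlowSchedule,
    min_frames: int = 10,
    exclusion_s: float | None = None,
) -> list[IntervalEstimate]:
    """Average the trajectory over the steady part of each flow epoch.

    Frames within ``exclusion_s`` (default: the schedule's reorientation
    window) after each reversal are omitted, matching the exclusion of
    the reorientation transient from the averaging. Intervals with fewer
    than ``min_frames`` usable frames are flagged unused.
    """
    if exclusion_s is None:
        exclusion_s = schedule.exclusion_s
    t = trajectory["time_s"].to_numpy()
    xy = trajectory[["x_nm", "y_nm"]].to_numpy(dtype=float)
    u = np.asarray(schedule.flow_axis, dtype=float)
    u = u / np.linalg.norm(u)
    out = []
    for i, ep in enumerate(schedule.epochs):
        sel = (t >= ep.t_start + exclusion_s) & (t < ep.t_end)
        pts = xy[sel]
        pts = pts[np.all(np.isfinite(pts), axis=1)]
        n = len(pts)
        if n == 0:
            continue
        proj = pts @ u
        out.append(
            IntervalEstimate(
                interval_id=i,
                sign=ep.sign,
                direction=ep.direction,
                mean_xy=tuple(pts.mean(axis=0)),
                sd_proj=float(proj.std(ddof=1)) if n > 1 else 0.0,
                n_frames=n,
                used=n >= min_frames,
            )
        )
    if not any(iv.used for iv in out):
        raise ValueError("no usable intervals (all below min_frames)")
    return out


def infer_tether_and_displacements(
    intervals: list[IntervalEstimate],
    flow_axis: tuple,
    component: str = "",
    geometry: str = "tip",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Locate the tether from reversal midpoints; measure displacements.

    The tether is estimated for each flow reversal as the midpoint of
    the two flanking interval means, and at the assembly level as the
    average of these per-reversal midpoints (a median-of-midpoints
    robust variant is also computed; a warning flags disagreement beyond
    5 nm, which arises for asymmetric side-attached assemblies). Each
    used interval's displacement is the magnitude of the projection of
    (interval mean - tether) onto the flow axis; the perpendicular
    residual is kept as a QC column.

    Returns (tether_xy, DisplacementSet DataFrame with columns
    interval_id, displacement_nm, perp_nm, direction, component,
    geometry).
    """
    used = [iv for iv in intervals if iv.used]
    if len(used) < 2 or len({iv.sign for iv in used}) < 2:
        raise ValueError("need >= 2 used intervals of opposite sign")
    u = np.asarray(flow_axis, dtype=float)
    u = u / np.linalg.norm(u)

    mids = []
    for a, b in zip(used[:-1], used[1:]):
        if a.sign != b.sign:
            mids.append(0.5 * (np.asarray(a.mean_xy) + np.asarray(b.mean_xy)))
    mids = np.asarray(mids)
    tether = mids.mean(axis=0)
    tether_robust = np.median(mids, axis=0)
    if np.linalg.norm(tether - tether_robust) > 5.0:
        warnings.warn(
            "mean and median-of-midpoints tether estimates disagree by "
            f"{np.linalg.norm(tether - tether_robust):.1f} nm; asymmetric "
            "displacements likely bias the midpoint tether",
            stacklevel=2,
        )

    return tether, displacements_from_tether(
        used, tether, u, component=component, geometry=geometry
    )


def displacements_from_tether(
    intervals: list[IntervalEstimate],
    tether,
    flow_axis,
    component: str = "",
    geometry: str = "tip",
) -> pd.DataFrame:
    """Displacement of each used interval mean from a given tether point.

    Useful when the tether is located independently — e.g. from the
    co-tracked centromeric-DNA marker, whose flips are symmetric — which
    avoids the midpoint bias that an asymmetrically displaced subunit
    (side-attached geometry) imposes on its own midpoint tether.
    """
    u = np.asarray(flow_axis, dtype=float)
    u = u / np.linalg.norm(u)
    tether = np.asarray(tether, dtype=float)
    rows = []
    for iv in intervals:
        if not iv.used:
            continue
        rel = np.asarray(iv.mean_xy) - tether
        proj = float(rel @ u)
        perp = float(np.linalg.norm(rel - proj * u))
        rows.append(
            {
                "interval_id": iv.interval_id,
                "displacement_nm": abs(proj),
                "perp_nm": perp,
                "direction": iv.direction,
                "component": component,
                "geometry": geometry,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian / two-component mixture fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Gaussian (k=1) or two-Gaussian mixture (k=2) fit of displacements."""

    k: int
    means: tuple  # nm, ascending for k=2
    sds: tuple
    weights: tuple
    sem_means: tuple  # bootstrap SEM of each mean
    log_likelihood: float
    bic: float
    selected: bool = False
    converged: bool = True


def _normal_logpdf(x, mu, sd):
    return -0.5 * np.log(2 * np.pi * sd**2) - (x - mu) ** 2 / (2 * sd**2)


def _em_two_gaussian(x: np.ndarray, init, max_iter=500, tol=1e-10):
    """EM for a 1-D two-component Gaussian mixture from a given init."""
    w, mu, sd = (np.array(v, dtype=float) for v in init)
    ll_old = -np.inf
    for _ in range(max_iter):
        logp = np.log(w)[:, None] + _normal_logpdf(x[None, :], mu[:, None], sd[:, None])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        r = np.exp(logp - lse)  # responsibilities (2, n)
        ll = float(lse.sum())
        nk = r.sum(axis=1)
        if np.any(nk < 1e-9):
            return w, mu, sd, ll, False
        w = nk / len(x)
        mu = (r @ x) / nk
        sd = np.sqrt(np.maximum((r * (x[None, :] - mu[:, None]) ** 2).sum(axis=1) / nk, 1e-12))
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    degenerate = (w.min() < 0.05) or (sd.min() < 1e-3 * max(np.std(x), 1e-12))
    return w, mu, sd, ll, not degenerate


def _fit_k1(x: np.ndarray):
    mu = float(np.mean(x))
    sd = float(np.std(x))
    ll = float(np.sum(_normal_logpdf(x, mu, max(sd, 1e-12))))
    bic = -2 * ll + 2 * np.log(len(x))
    return mu, sd, ll, bic


def _fit_k2_ml(x: np.ndarray, n_restarts: int = 20):
    """Best-of-restarts EM; inits split the sample at sliding quantiles."""
    best = None
    qs = np.linspace(0.15, 0.85, n_restarts)
    floor = max(np.std(x) * 0.05, 1e-9)
    for q in qs:
        cut = np.quantile(x, q)
        lo, hi = x[x <= cut], x[x > cut]
        if len(lo) < 2 or len(hi) < 2:
            continue
        init = (
            [len(lo) / len(x), len(hi) / len(x)],
            [lo.mean(), hi.mean()],
            [max(lo.std(), floor), max(hi.std(), floor)],
        )
        w, mu, sd, ll, ok = _em_two_gaussian(x, init)
        if best is None or ll > best[3]:
            best = (w, mu, sd, ll, ok)
    return best


def fit_displacement_model(
    displacements: np.ndarray | pd.Series,
    k: int | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> FitResult:
    """Fit displacement distribution with k=1 or k=2 Gaussians (ML).

    With ``k=None`` both models are fit and the lower-BIC model is
    flagged selected. k=1 uses the closed form; k=2 runs EM from 20
    quantile-split initializations. A degenerate k=2 fit (component
    weight < 0.05 or vanishing SD) falls back to k=1 with a warning.
    SEMs of the component means come from a 200-resample bootstrap.
    Requires >= 10 points for k=1 and >= 20 for k=2.
    """
    x = np.asarray(displacements, dtype=float)
    if k in (1, None) and len(x) < 10:
        raise ValueError("need >= 10 displacements for k=1")
    if k == 2 and len(x) < 20:
        raise ValueError("need >= 20 displacements for k=2")

    rng = np.random.default_rng(seed)

    def boot_sems(fit_fn, point):
        est = []
        for _ in range(n_boot):
            xb = rng.choice(x, size=len(x), replace=True)
            try:
                est.append(fit_fn(xb))
            except Exception:
                continue
        est = np.asarray(est)
        return tuple(est.std(axis=0, ddof=1)) if len(est) > 1 else tuple(
            np.full(len(point), np.nan)
        )

    def make_k1() -> FitResult:
        mu, sd, ll, bic = _fit_k1(x)
        sems = boot_sems(lambda xb: [np.mean(xb)], [mu])
        return FitResult(1, (mu,), (sd,), (1.0,), sems, ll, bic)

    def make_k2() -> FitResult | None:
        res = _fit_k2_ml(x)
        if res is None:
            return None
        w, mu, sd, ll, ok = res
        order = np.argsort(mu)
        w, mu, sd = w[order], mu[order], sd[order]
        bic = -2 * ll + 5 * np.log(len(x))

        def refit(xb):
            rb = _em_two_gaussian(xb, (w, mu, sd))
            mub = np.sort(rb[1])
            return mub

        sems = boot_sems(refit, mu)
        return FitResult(
            2, tuple(mu), tuple(sd), tuple(w), sems, ll, bic, converged=ok
        )

    if k == 1:
        f = make_k1()
        return FitResult(**{**f.__dict__, "selected": True})
    if k == 2:
        f = make_k2()
        if f is None or not f.converged:
            warnings.warn("k=2 fit degenerate; falling back to k=1", stacklevel=2)
            f1 = make_k1()
            return FitResult(**{**f1.__dict__, "selected": True})
        return FitResult(**{**f.__dict__, "selected": True})

    f1 = make_k1()
    if len(x) < 20:
        return FitResult(**{**f1.__dict__, "selected": True})
    f2 = make_k2()
    if f2 is None or not f2.converged or f1.bic <= f2.bic:
        return FitResult(**{**f1.__dict__, "selected": True})
    return FitResult(**{**f2.__dict__, "selected": True})


def compare_displacements(a, b):
    """Two-sample KS comparison of raw displacement values."""
    return ks_two_sample(a, b)
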