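"""Synthetic-data generators with ground truth for every assay.

Each generator consumes a frozen config dataclass carrying an explicit
seed and returns ``(data, GroundTruth)``. Identical config + seed gives
bit-identical output; there is no hidden global random state.

Sign convention (global): motion, displacement, and force toward the
microtubule plus end are positive.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

TOWARD_PLUS = "toward_plus"
TOWARD_MINUS = "toward_minus"


def _require_finite(cfg) -> None:
    for key, val in asdict(cfg).items():
        arr = np.asarray(val, dtype=object).ravel()
        for v in arr:
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"non-finite config value: {key}={v!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Latent values behind one generated artifact, keyed by seed."""

    kind: str
    seed: int
    values: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating, np.bool_)):
                return o.item()
            raise TypeError(type(o))

        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "values": self.values},
            default=default,
        )


# ---------------------------------------------------------------------------
# CoSMoS two-channel fields
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CosmosFieldConfig:
    """Two-channel TIRF field of diffraction-limited spots.

    The reference (DNA) channel carries one spot per tether site; the
    target (GFP) channel carries spots at a misregistered copy of the
    colocalized subset, plus uniformly scattered false spots.
    """

    field_size: int = 256
    n_sites: int = 120
    p_coloc: float = 0.28
    psf_sigma: float = 1.1
    photons_per_spot: float = 4000.0
    background: float = 20.0
    read_noise_sd: float = 2.0
    misregistration: tuple = ((1.0, 0.0, 0.6), (0.0, 1.0, -0.4))
    false_spot_density: float = 2e-5
    margin: int = 8
    min_site_separation: float = 6.0  # px; DNAs are tethered sparsely enough
    # that neighboring sites are optically resolvable
    seed: int = 0

    def validate(self) -> None:
        _require_finite(self)
        if not 0.0 <= self.p_coloc <= 1.0:
            raise ValueError("p_coloc must be in [0, 1]")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")


def _render(shape, xy, photons, sigma):
    """Gaussian PSF rendering: each spot integrates to ``photons`` counts."""
    img = np.zeros(shape, dtype=float)
    half = max(4, int(np.ceil(4 * sigma)))
    norm = 2 * np.pi * sigma**2
    for (x, y), n in zip(np.atleast_2d(xy) if len(xy) else [], photons):
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(0, xi - half), min(shape[1], xi + half + 1)
        y0, y1 = max(0, yi - half), min(shape[0], yi + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
        gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
        img[y0:y1, x0:x1] += (n / norm) * np.outer(gy, gx)
    return img


def apply_affine(coeffs, xy: np.ndarray) -> np.ndarray:
    """Apply a 2x3 affine (rows: x' and y' in terms of [x, y, 1])."""
    A = np.asarray(coeffs, dtype=float)
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    return xy @ A[:, :2].T + A[:, 2]


def make_cosmos_field(cfg: CosmosFieldConfig):
    """Simulate one two-channel field; returns ((dna_image, gfp_image), truth).

    DNA-channel spots sit at every tether site. GFP-channel spots sit at
    the misregistered positions of the colocalized subset plus Poisson
    false spots. Camera model: Poisson shot noise on photon rate
    (spots + background) plus Gaussian read noise.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L, m = cfg.field_size, cfg.margin
    shape = (L, L)

    # dart-throwing placement honoring the minimum site separation
    sites = np.empty((cfg.n_sites, 2))
    placed = 0
    attempts = 0
    min_sep2 = cfg.min_site_separation**2
    while placed < cfg.n_sites:
        cand = rng.uniform(m, L - 1 - m, size=2)
        if placed == 0 or np.min(
            np.sum((sites[:placed] - cand) ** 2, axis=1)
        ) >= min_sep2:
            sites[placed] = cand
            placed += 1
        attempts += 1
        if attempts > 200 * max(cfg.n_sites, 1):
            raise ValueError(
                "cannot place n_sites at min_site_separation in this field"
            )
    coloc = rng.random(cfg.n_sites) < cfg.p_coloc

    n_false = rng.poisson(cfg.false_spot_density * L * L)
    false_xy = rng.uniform(m, L - 1 - m, size=(n_false, 2))

    gfp_xy = np.vstack([apply_affine(cfg.misregistration, sites[coloc]).reshape(-1, 2),
                        false_xy.reshape(-1, 2)])

    photons_dna = rng.gamma(20.0, cfg.photons_per_spot / 20.0, size=cfg.n_sites)
    photons_gfp = rng.gamma(20.0, cfg.photons_per_spot / 20.0, size=len(gfp_xy))

    def camera(rate):
        counts = rng.poisson(np.clip(rate + cfg.background, 0, None)).astype(float)
        return counts + rng.normal(0.0, cfg.read_noise_sd, size=rate.shape)

    dna_img = camera(_render(shape, sites, photons_dna, cfg.psf_sigma))
    gfp_img = camera(_render(shape, gfp_xy, photons_gfp, cfg.psf_sigma))

    truth = GroundTruth(
        kind="cosmos_field",
        seed=cfg.seed,
        values={
            "site_xy": sites,
            "coloc_flags": coloc,
            "n_coloc": int(coloc.sum()),
            "false_xy": false_xy,
            "misregistration": np.asarray(cfg.misregistration),
        },
    )
    return (dna_img, gfp_img), truth


# ---------------------------------------------------------------------------
# Photobleach traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BleachTraceConfig:
    """Stepwise photobleaching intensity trace for ``n_fluors`` fluorophores."""

    n_fluors: int = 2
    step_height: float = 100.0
    bleach_rate: float = 0.05  # 1/s per fluorophore
    noise_sd: float = 20.0
    frame_interval: float = 0.5
    n_frames: int = 240
    seed: int = 0

    def validate(self) -> None:
        _require_finite(self)
        if self.n_fluors < 0:
            raise ValueError("n_fluors must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")


def make_bleach_trace(cfg: BleachTraceConfig):
    """Piecewise-constant trace with exponential bleach times plus noise.

    Returns a DataFrame (time_s, intensity) and truth with the sorted
    step times and the noiseless level sequence.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_frames) * cfg.frame_interval
    lifetimes = np.sort(rng.exponential(1.0 / cfg.bleach_rate, size=cfg.n_fluors))
    surviving = cfg.n_fluors - np.searchsorted(lifetimes, t, side="right")
    clean = surviving * cfg.step_height
    intensity = clean + rng.normal(0.0, cfg.noise_sd, size=cfg.n_frames)
    trace = pd.DataFrame({"time_s": t, "intensity": intensity})
    truth = GroundTruth(
        kind="bleach_trace",
        seed=cfg.seed,
        values={
            "step_times_s": lifetimes,
            "n_steps": int(cfg.n_fluors),
            "step_height": cfg.step_height,
            "clean_levels": clean,
            "frame_interval": cfg.frame_interval,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Flip-flop trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlipFlopConfig:
    """Spot trajectory flipping 180 degrees about a tether on a flow schedule.

    ``displacement_by_direction`` maps pull direction to the true tether
    distance in nm; equal values model a tip-attached assembly, unequal
    values a side-attached one.
    """

    tether_xy: tuple = (500.0, 500.0)
    displacement_by_direction: tuple = ((TOWARD_PLUS, 37.0), (TOWARD_MINUS, 37.0))
    flow_axis: tuple = (1.0, 0.0)
    dwell_s: float = 13.0
    reorient_s: float = 1.0
    loc_noise_sd: float = 10.0
    frame_interval: float = 0.2
    n_cycles: int = 3
    seed: int = 0

    def validate(self) -> None:
        _require_finite(self)
        d = dict(self.displacement_by_direction)
        if any(v < 0 for v in d.values()):
            raise ValueError("displacements must be >= 0")
        if not self.dwell_s > self.reorient_s >= 0:
            raise ValueError("require dwell_s > reorient_s >= 0")


@dataclass(frozen=True)
class FlowEpoch:
    t_start: float
    t_end: float
    sign: int  # +1: spot displaced toward plus end of the flow axis
    direction: str  # pull-direction label for this epoch


@dataclass(frozen=True)
class FlowSchedule:
    """Ordered, contiguous, alternating-sign flow epochs."""

    epochs: tuple
    flow_axis: tuple
    exclusion_s: float

    def validate(self) -> None:
        for a, b in zip(self.epochs, self.epochs[1:]):
            if not np.isclose(a.t_end, b.t_start):
                raise ValueError("epochs must be contiguous")
            if a.sign == b.sign:
                raise ValueError("epoch signs must alternate")


def make_flipflop_trajectory(cfg: FlipFlopConfig):
    """Simulate flip-flop nanometry; returns (trajectory, schedule, truth).

    Within each epoch the spot sits at ``tether + sign * d(direction) * u``
    with isotropic Gaussian localization noise; the flow-reversal transit
    is a linear sweep over ``reorient_s`` after each epoch start.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    u = np.asarray(cfg.flow_axis, dtype=float)
    u = u / np.linalg.norm(u)
    tether = np.asarray(cfg.tether_xy, dtype=float)
    dmap = dict(cfg.displacement_by_direction)

    n_epochs = 2 * cfg.n_cycles
    epochs = []
    for i in range(n_epochs):
        sign = 1 if i % 2 == 0 else -1
        direction = TOWARD_PLUS if sign > 0 else TOWARD_MINUS
        epochs.append(
            FlowEpoch(i * cfg.dwell_s, (i + 1) * cfg.dwell_s, sign, direction)
        )
    schedule = FlowSchedule(tuple(epochs), tuple(u), cfg.reorient_s)

    t = np.arange(int(round(n_epochs * cfg.dwell_s / cfg.frame_interval))) * cfg.frame_interval
    pos = np.empty((len(t), 2))
    for i, ep in enumerate(epochs):
        target = tether + ep.sign * dmap[ep.direction] * u
        prev = (
            tether + epochs[i - 1].sign * dmap[epochs[i - 1].direction] * u
            if i > 0
            else target
        )
        in_ep = (t >= ep.t_start) & (t < ep.t_end)
        tt = t[in_ep]
        frac = np.clip((tt - ep.t_start) / max(cfg.reorient_s, 1e-12), 0.0, 1.0)
        pos[in_ep] = prev + np.outer(frac, target - prev)
    pos += rng.normal(0.0, cfg.loc_noise_sd, size=pos.shape)

    traj = pd.DataFrame({"time_s": t, "x_nm": pos[:, 0], "y_nm": pos[:, 1]})
    truth = GroundTruth(
        kind="flipflop_trajectory",
        seed=cfg.seed,
        values={
            "tether_xy": tether,
            "displacement_by_direction": dmap,
            "flow_axis": u,
            "epoch_signs": np.array([e.sign for e in epochs]),
        },
    )
    return traj, schedule, truth


# ---------------------------------------------------------------------------
# Laser-trap sliding records
# ---------------------------------------------------------------------------

BOLTZMANN_KT = 4.114  # pN*nm at 25 C


@dataclass(frozen=True)
class SlidingConfig:
    """Constant-force sliding record with direction-dependent drag.

    gamma_plus applies when the bead is pulled toward the plus end,
    gamma_minus toward the minus end (pN*s/nm). ``force_schedule`` is a
    sequence of (duration_s, signed_force_pN) epochs; force sign follows
    the global convention (positive = toward plus end).
    """

    gamma_plus: float = 1.0 / 109.0
    gamma_minus: float = 1.0 / 674.0
    force_schedule: tuple = ((9.0, 1.0), (2.0, -1.0)) * 3
    brownian_diffusion: float | None = None  # nm^2/s; None -> kT/gamma
    sample_rate: float = 200.0
    detach_hazard: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        _require_finite(self)
        if self.gamma_plus <= 0 or self.gamma_minus <= 0:
            raise ValueError("drag coefficients must be > 0")
        for dur, f in self.force_schedule:
            if dur <= 0:
                raise ValueError("schedule durations must be > 0")
            if abs(f) > 4.0:
                raise ValueError("forces limited to +/-4 pN in this assay")


def make_sliding_record(cfg: SlidingConfig):
    """Simulate bidirectional sliding; returns (TrapRecord frame, truth).

    Within each epoch the bead drifts at v = F / gamma(direction) with
    Brownian noise (D = kT/gamma unless overridden).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.sample_rate
    times, positions, forces = [], [], []
    x = 0.0
    t0 = 0.0
    detach_t = np.inf
    if cfg.detach_hazard > 0:
        detach_t = rng.exponential(1.0 / cfg.detach_hazard)
    true_epochs = []
    for dur, f in cfg.force_schedule:
        gamma = cfg.gamma_plus if f > 0 else cfg.gamma_minus
        v = f / gamma
        D = cfg.brownian_diffusion
        if D is None:
            D = BOLTZMANN_KT / gamma
        n = int(round(dur / dt))
        steps = v * dt + np.sqrt(2 * D * dt) * rng.standard_normal(n)
        xs = x + np.cumsum(steps)
        ts = t0 + dt * (1 + np.arange(n))
        keep = ts <= detach_t
        times.append(ts[keep])
        positions.append(xs[keep])
        forces.append(np.full(keep.sum(), f))
        true_epochs.append({"duration_s": dur, "force_pN": f, "v_nm_s": v})
        if not keep.all():
            break
        x = xs[-1]
        t0 = ts[-1]
    record = pd.DataFrame(
        {
            "time_s": np.concatenate(times),
            "position_nm": np.concatenate(positions),
            "force_pN": np.concatenate(forces),
        }
    )
    truth = GroundTruth(
        kind="sliding_record",
        seed=cfg.seed,
        values={
            "gamma_plus": cfg.gamma_plus,
            "gamma_minus": cfg.gamma_minus,
            "epochs": true_epochs,
            "detach_time_s": detach_t,
        },
    )
    return record, truth


# ---------------------------------------------------------------------------
# Force-ramp rupture records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RuptureConfig:
    """Force-ramp record: preload dwell, constant-rate ramp, rupture or censor.

    ``strength_distribution`` is ("gamma", shape, scale) or
    ("normal", mean, sd); the drawn strength is the true rupture force.
    """

    preload_pN: float = 1.5
    preload_dwell_s: float = 4.0
    ramp_rate: float = 0.25
    load_limit: float = 23.0
    strength_distribution: tuple = ("gamma", 9.0, 9.7 / 9.0)
    trap_stiffness: float = 0.05  # pN/nm, position = force / stiffness
    noise_sd: float = 0.1  # pN-equivalent
    sample_rate: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        _require_finite(self)
        if self.ramp_rate <= 0:
            raise ValueError("ramp_rate must be > 0")
        if self.load_limit <= self.preload_pN:
            raise ValueError("load_limit must exceed preload")


def _draw_strength(rng, dist):
    name, *params = dist
    if name == "gamma":
        return float(rng.gamma(params[0], params[1]))
    if name == "normal":
        return float(abs(rng.normal(params[0], params[1])))
    raise ValueError(f"unknown strength distribution {name!r}")


def make_rupture_record(cfg: RuptureConfig, strength: float | None = None):
    """Simulate one force ramp; returns (TrapRecord frame, truth).

    Force holds at the preload, then rises at ``ramp_rate``. At the drawn
    strength the bead snaps back toward the trap center and force
    collapses; if the strength exceeds the trap's load limit the record
    ends there with the censor flag set.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if strength is None:
        strength = _draw_strength(rng, cfg.strength_distribution)
    if strength <= cfg.preload_pN:
        raise ValueError(
            "drawn strength below the preload: attachment fails before the "
            "ramp begins; condition the strength draw on preload survival"
        )
    dt = 1.0 / cfg.sample_rate

    censored = strength >= cfg.load_limit
    peak = min(strength, cfg.load_limit)
    ramp_dur = (peak - cfg.preload_pN) / cfg.ramp_rate
    t_total = cfg.preload_dwell_s + ramp_dur + 1.0  # 1 s tail after the event
    t = np.arange(int(round(t_total / dt))) * dt
    force = np.where(
        t < cfg.preload_dwell_s,
        cfg.preload_pN,
        cfg.preload_pN + cfg.ramp_rate * (t - cfg.preload_dwell_s),
    )
    t_event = cfg.preload_dwell_s + ramp_dur
    after = t >= t_event
    if censored:
        force[after] = cfg.load_limit
        position = force / cfg.trap_stiffness
    else:
        force[after] = 0.0
        position = force / cfg.trap_stiffness  # snaps back with the force collapse
    noise_nm = cfg.noise_sd / cfg.trap_stiffness
    position = position + rng.normal(0.0, noise_nm, size=len(t))
    force = np.clip(force + rng.normal(0.0, cfg.noise_sd, size=len(t)), 0, None)

    record = pd.DataFrame({"time_s": t, "position_nm": position, "force_pN": force})
    truth = GroundTruth(
        kind="rupture_record",
        seed=cfg.seed,
        values={
            "strength_pN": float(strength),
            "censored": bool(censored),
            "t_event_s": float(t_event),
            "load_limit": cfg.load_limit,
        },
    )
    return record, truth
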