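"""Spot detection, channel registration, and colocalization (CoSMoS).

Coordinates are in pixels with the origin at the top-left pixel center,
x rightward, y downward. Spot tables are pandas DataFrames with columns
``frame, channel, x, y, intensity, background``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

SPOT_COLUMNS = ["frame", "channel", "x", "y", "intensity", "background"]


@dataclass(frozen=True)
class DetectionConfig:
    """Bandpass + threshold + subpixel Gaussian refinement parameters."""

    psf_sigma: float = 1.1
    bandpass_low: float = 1.0  # sigma of the smoothing (spot-scale) Gaussian
    bandpass_high: float = 4.0  # sigma of the background Gaussian
    threshold: float = 25.0  # on the bandpassed image, same units as input
    min_separation: int = 3  # px, duplicate suppression distance
    fit_window: int = 9  # odd, px


def _gaussian_refine(image: np.ndarray, peaks: np.ndarray, sigma: float, w: int):
    """Vectorized least-squares 2-D Gaussian refinement at integer peaks.

    Model per window: A*exp(-((x-x0)^2+(y-y0)^2)/(2 sigma^2)) + b with
    sigma fixed. Gauss-Newton on (x0, y0, A, b), all windows at once.
    Returns x0, y0, amplitude, background, converged mask.
    """
    half = w // 2
    H, W = image.shape
    ys, xs = peaks[:, 0], peaks[:, 1]
    ok = (xs >= half) & (xs < W - half) & (ys >= half) & (ys < H - half)
    ys, xs = ys[ok], xs[ok]
    n = len(xs)
    if n == 0:
        return (np.empty(0),) * 4 + (ok,)

    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    dx = dx.ravel()[None, :].astype(float)  # (1, w*w)
    dy = dy.ravel()[None, :].astype(float)
    win = np.stack(
        [image[y - half : y + half + 1, x - half : x + half + 1].ravel()
         for y, x in zip(ys, xs)]
    ).astype(float)  # (n, w*w)

    b = np.median(win, axis=1)
    A = win.max(axis=1) - b
    A = np.maximum(A, 1e-6)
    x0 = np.zeros(n)
    y0 = np.zeros(n)

    for _ in range(25):
        ex = np.exp(-((dx - x0[:, None]) ** 2 + (dy - y0[:, None]) ** 2) / (2 * sigma**2))
        model = A[:, None] * ex + b[:, None]
        r = win - model
        # Jacobian columns
        j_x0 = A[:, None] * ex * (dx - x0[:, None]) / sigma**2
        j_y0 = A[:, None] * ex * (dy - y0[:, None]) / sigma**2
        j_A = ex
        j_b = np.ones_like(ex)
        J = np.stack([j_x0, j_y0, j_A, j_b], axis=2)  # (n, m, 4)
        JTJ = np.einsum("nmi,nmj->nij", J, J)
        JTr = np.einsum("nmi,nm->ni", J, r)
        JTJ += 1e-9 * np.eye(4)[None]
        try:
            step = np.linalg.solve(JTJ, JTr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, [-1, -1, -np.inf, -np.inf], [1, 1, np.inf, np.inf])
        x0 += step[:, 0]
        y0 += step[:, 1]
        A = np.maximum(A + step[:, 2], 1e-6)
        b += step[:, 3]
        if np.max(np.abs(step[:, :2])) < 1e-7:
            break

    # reject fits that wandered out of the window
    good = (np.abs(x0) <= half) & (np.abs(y0) <= half) & (A > 0)
    return xs + x0, ys + y0, A, b, _expand_mask(ok, good)


def _expand_mask(outer: np.ndarray, inner: np.ndarray) -> np.ndarray:
    full = np.zeros(len(outer), dtype=bool)
    full[np.flatnonzero(outer)[inner]] = True
    return full


def detect_spots(
    image: np.ndarray,
    config: DetectionConfig = DetectionConfig(),
    channel: str = "",
    frame: int = 0,
) -> pd.DataFrame:
    """Detect diffraction-limited spots in a 2-D image.

    Local maxima of the difference-of-Gaussians bandpassed image above
    ``config.threshold`` are refined to subpixel accuracy by a fixed-sigma
    2-D Gaussian least-squares fit; duplicates within ``min_separation``
    are suppressed (brighter spot kept, enforced by peak_local_max).
    Returns a SpotTable; a degenerate image yields an empty table.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    empty = pd.DataFrame(columns=SPOT_COLUMNS)
    if image.size == 0 or np.ptp(image) == 0:
        return empty

    bp = gaussian_filter(image, config.bandpass_low) - gaussian_filter(
        image, config.bandpass_high
    )
    peaks = peak_local_max(
        bp, min_distance=config.min_separation, threshold_abs=config.threshold
    )
    if len(peaks) == 0:
        return empty

    x, y, amp, bg, kept = _gaussian_refine(
        image, peaks, config.psf_sigma, config.fit_window
    )
    integrated = 2 * np.pi * config.psf_sigma**2 * amp
    table = pd.DataFrame(
        {
            "frame": frame,
            "channel": channel,
            "x": x,
            "y": y,
            "intensity": np.maximum(integrated, 0.0),
            "background": bg,
        }
    )
    H, W = image.shape
    table = table[(table.x >= 0) & (table.x <= W - 1) & (table.y >= 0) & (table.y <= H - 1)]
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Channel registration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationMap:
    """2x3 affine mapping moving-channel coordinates into the reference frame."""

    coeffs: tuple  # ((a, b, tx), (c, d, ty))
    residual_rms: float
    n_fiducials: int

    def matrix(self) -> np.ndarray:
        return np.asarray(self.coeffs, dtype=float)

    def inverse(self) -> "RegistrationMap":
        A = self.matrix()
        M = A[:, :2]
        t = A[:, 2]
        Minv = np.linalg.inv(M)
        tinv = -Minv @ t
        coeffs = tuple(tuple(row) for row in np.column_stack([Minv, tinv]))
        return RegistrationMap(coeffs, self.residual_rms, self.n_fiducials)


def fit_registration(
    reference: np.ndarray, moving: np.ndarray
) -> RegistrationMap:
    """Least-squares affine from paired fiducial positions (moving -> reference).

    Requires >= 3 non-collinear pairs (else the 6-parameter map is
    unidentifiable and a ValueError is raised). Residual RMS is the root
    mean squared 2-D distance between mapped moving and reference points.
    """
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    mov = np.atleast_2d(np.asarray(moving, dtype=float))
    if ref.shape != mov.shape or ref.shape[0] < 3:
        raise ValueError("need >= 3 paired fiducials")
    X = np.column_stack([mov, np.ones(len(mov))])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("fiducials are collinear; affine map unidentifiable")
    sol, *_ = np.linalg.lstsq(X, ref, rcond=None)  # (3, 2): columns x', y'
    A = sol.T  # rows: x', y' in terms of [x, y, 1]
    pred = X @ sol
    rms = float(np.sqrt(np.mean(np.sum((pred - ref) ** 2, axis=1))))
    return RegistrationMap(tuple(tuple(row) for row in A), rms, len(ref))


def apply_registration(regmap: RegistrationMap, points: np.ndarray) -> np.ndarray:
    """Map points (N, 2) through the affine registration."""
    A = regmap.matrix()
    if np.linalg.det(A[:, :2]) == 0:
        raise ValueError("registration map is singular")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ A[:, :2].T + A[:, 2]


# ---------------------------------------------------------------------------
# Colocalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColocResult:
    """Per-field and aggregate colocalization fractions."""

    per_fov: pd.DataFrame  # fov, n_reference, n_colocalized, fraction, chance_fraction
    mean_fraction: float
    sem_fraction: float
    radius_px: float


def colocalization_fraction(
    reference: pd.DataFrame,
    target: pd.DataFrame,
    radius: float = 1.5,
    fov_column: str = "fov",
) -> ColocResult:
    """Fraction of reference sites with >= 1 target spot within ``radius``.

    Both tables must already be registered into the same coordinate
    frame. Fractions are computed per field of view and aggregated as an
    unweighted mean +/- SEM across fields. The expected chance fraction
    1 - exp(-rho * pi r^2), with rho the target spot density in that
    field, is reported alongside (not subtracted). Field area for rho is
    the bounding box of reference spots, a slight underestimate on
    sparse fields.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    rows = []
    fovs = sorted(reference[fov_column].unique()) if len(reference) else []
    for fov in fovs:
        ref = reference[reference[fov_column] == fov]
        tgt = target[target[fov_column] == fov] if len(target) else target
        n_ref = len(ref)
        if n_ref == 0:
            continue
        if len(tgt) == 0:
            n_hit, chance = 0, 0.0
        else:
            tree = cKDTree(tgt[["x", "y"]].to_numpy())
            d, _ = tree.query(ref[["x", "y"]].to_numpy(), k=1)
            n_hit = int(np.sum(d <= radius))
            span_x = np.ptp(ref.x.to_numpy()) or 1.0
            span_y = np.ptp(ref.y.to_numpy()) or 1.0
            rho = len(tgt) / (span_x * span_y)
            chance = 1.0 - np.exp(-rho * np.pi * radius**2)
        rows.append(
            {
                "fov": fov,
                "n_reference": n_ref,
                "n_colocalized": n_hit,
                "fraction": n_hit / n_ref,
                "chance_fraction": chance,
            }
        )
    per_fov = pd.DataFrame(rows)
    if len(per_fov):
        mean = float(per_fov.fraction.mean())
        sem = float(per_fov.fraction.std(ddof=1) / np.sqrt(len(per_fov))) if len(per_fov) > 1 else 0.0
    else:
        mean, sem = float("nan"), float("nan")
    return ColocResult(per_fov, mean, sem, radius)


# ---------------------------------------------------------------------------
# Polarity-marked capture calls
# ---------------------------------------------------------------------------

PLUS, MINUS, UNDETERMINED = "plus", "minus", "undetermined"


@dataclass(frozen=True)
class EndSegment:
    brightness: str  # "bright" | "dim"
    length: float  # um, terminal segment length


@dataclass(frozen=True)
class FilamentProfile:
    """Polarity-marked filament: bright seed, dim extensions.

    The plus-end extension is dim (and, without NEM-capping, longer than
    the minus-end extension).
    """

    end_a: EndSegment
    end_b: EndSegment
    attached_end: str  # "a" | "b"


def classify_capture_polarity(profile: FilamentProfile) -> str:
    """Label the attached end plus/minus from the brightness (or length) cue.

    Attached end is plus if its terminal segment is dim while the far
    end is bright; if both ends have the same brightness class the
    longer extension is taken as plus. Fully ambiguous profiles are
    labeled undetermined and excluded from fractions downstream.
    """
    att = profile.end_a if profile.attached_end == "a" else profile.end_b
    far = profile.end_b if profile.attached_end == "a" else profile.end_a
    if att.brightness != far.brightness:
        return PLUS if att.brightness == "dim" else MINUS
    if att.length != far.length:
        return PLUS if att.length > far.length else MINUS
    return UNDETERMINED


def summarize_capture(calls: pd.DataFrame) -> dict:
    """Aggregate polarity calls grouped by experiment.

    ``calls`` needs columns ``experiment`` and ``call``. Returns the
    unweighted mean and SD of per-experiment plus-end percentages plus
    pooled counts; undetermined calls are excluded.
    """
    det = calls[calls.call != UNDETERMINED]
    if len(det) == 0:
        raise ValueError("no determined polarity calls")
    per_exp = det.groupby("experiment").call.apply(
        lambda c: 100.0 * np.mean(c == PLUS)
    )
    n_plus = int((det.call == PLUS).sum())
    return {
        "per_experiment_pct_plus": per_exp,
        "mean_pct_plus": float(per_exp.mean()),
        "sd_pct_plus": float(per_exp.std(ddof=1)) if len(per_exp) > 1 else 0.0,
        "n_plus": n_plus,
        "n_total": int(len(det)),
        "pooled_pct_plus": 100.0 * n_plus / len(det),
    }
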