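"""Pupil-area extraction from tracked eye landmarks.

Per frame, an ellipse is fitted to the confident pupil-edge landmarks by
direct least squares (scikit-image's ``EllipseModel``) and the pupil size
is the ellipse area pi*a*b. Frames with fewer than five confident points
(blinks, tracking failures) are invalid; short invalid gaps are linearly
interpolated, long ones stay invalid and are excluded downstream. Areas
are standardized per session (z-score over valid frames, sample sd).
"""

from __future__ import annotations

import numpy as np
from skimage.measure import EllipseModel

from .types import EllipseParams, LandmarkSeries, PupilTrace


class DegenerateGeometryError(ValueError):
    """Point configuration does not determine an ellipse (e.g. collinear)."""


class InsufficientPointsError(ValueError):
    """Fewer than five usable points: an ellipse fit is underdetermined."""


#: Condition-number threshold on the scaled conic design matrix above which
#: the configuration is treated as degenerate.
DEFAULT_CONDITION_THRESHOLD = 1e8


def fit_ellipse(
    points: np.ndarray, condition_threshold: float = DEFAULT_CONDITION_THRESHOLD
) -> EllipseParams:
    """Least-squares ellipse fit to ``points`` (n >= 5, shape (n, 2)).

    Exact on noiseless conic samples. Raises
    :class:`InsufficientPointsError` for n < 5 and
    :class:`DegenerateGeometryError` for collinear or otherwise
    ellipse-degenerate configurations.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 5:
        raise InsufficientPointsError(
            f"need >= 5 points for an ellipse fit, got {pts.shape[0]}"
        )
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")

    # degeneracy screen: conic design matrix on centered/scaled coordinates
    c = pts - pts.mean(axis=0)
    scale = np.sqrt((c**2).sum(axis=1).mean())
    if scale == 0:
        raise DegenerateGeometryError("all points coincide")
    x, y = (c / scale).T
    design = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
    # points on an exact conic make `design` rank-5 (the conic is its null
    # vector); degeneracy means a *second* near-null direction, so screen on
    # the ratio of the largest to the fifth singular value
    s = np.linalg.svd(design, compute_uv=False)
    if s[4] == 0 or s[0] / s[4] > condition_threshold:
        raise DegenerateGeometryError(
            "near-degenerate point configuration (condition number above threshold)"
        )

    # fit in centered/scaled coordinates for numerical stability, map back
    try:
        # errstate: skimage's conic-to-parametric conversion divides by
        # (a - c), which is legitimately 0 for a perfect circle
        with np.errstate(divide="ignore", invalid="ignore"):
            model = EllipseModel.from_estimate(np.column_stack([x, y]))
    except TypeError as exc:  # complex conic roots on pathological input
        raise DegenerateGeometryError(f"ellipse estimation failed: {exc}") from exc
    if not model:
        raise DegenerateGeometryError("ellipse estimation failed")
    center = np.asarray(model.center, dtype=complex)
    axes = np.asarray(model.axis_lengths, dtype=complex)
    if np.any(np.abs(center.imag) > 1e-9) or np.any(np.abs(axes.imag) > 1e-9):
        raise DegenerateGeometryError("fit did not yield a real ellipse")
    xc, yc = center.real * scale + pts.mean(axis=0)
    a, b = axes.real * scale
    theta = float(np.real(model.theta))
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        raise DegenerateGeometryError("fit did not yield a valid ellipse")
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    theta = float(np.mod(theta, np.pi))
    params = EllipseParams(center=(float(xc), float(yc)), a=float(a), b=float(b), theta=theta)
    params.validate()
    return params


def ellipse_area(params: EllipseParams) -> float:
    """Area of the fitted ellipse, pi * a * b (px^2)."""
    params.validate()
    return float(np.pi * params.a * params.b)


def extract_pupil_trace(
    series: LandmarkSeries,
    min_confidence: float = 0.9,
    max_gap_s: float = 0.5,
    condition_threshold: float = DEFAULT_CONDITION_THRESHOLD,
) -> PupilTrace:
    """Convert a landmark series into a per-frame pupil-area trace.

    Frames with fewer than five points at confidence >= ``min_confidence``
    (or with a degenerate fit) are invalid. Invalid runs no longer than
    ``max_gap_s`` that are flanked by valid frames are filled by linear
    interpolation (and flagged in ``interpolated``); longer runs stay
    invalid and are excluded from downstream windows.
    """
    if len(series) == 0:
        raise ValueError("empty landmark series")
    n = len(series)
    area = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        good = series.likelihood[i] >= min_confidence
        if good.sum() < 5:
            continue
        try:
            params = fit_ellipse(series.xy[i, good], condition_threshold)
        except (DegenerateGeometryError, InsufficientPointsError):
            continue
        area[i] = ellipse_area(params)
        valid[i] = True
    if not valid.any():
        raise ValueError("no valid frames in landmark series")

    interpolated = np.zeros(n, dtype=bool)
    t = series.time_s
    invalid_idx = np.flatnonzero(~valid)
    if len(invalid_idx):
        # fill invalid runs short enough and flanked by valid frames
        runs = np.split(invalid_idx, np.flatnonzero(np.diff(invalid_idx) > 1) + 1)
        vt, va = t[valid], area[valid]
        for run in runs:
            lo, hi = run[0], run[-1]
            if lo == 0 or hi == n - 1:
                continue
            gap = t[hi + 1] - t[lo - 1]
            if gap <= max_gap_s:
                area[run] = np.interp(t[run], vt, va)
                valid[run] = True
                interpolated[run] = True
    return PupilTrace(time_s=t.copy(), area=area, valid=valid, interpolated=interpolated)


def zscore_session(trace: PupilTrace) -> PupilTrace:
    """Standardize the area over the session's valid frames.

    area_z = (area - mean) / sd with the sample (n-1) standard deviation,
    computed over valid frames only; invalid frames get NaN. Matches the
    conventional per-session standard-normal transform.
    """
    v = trace.valid
    if v.sum() < 2:
        raise ValueError("need >= 2 valid frames to standardize")
    mu = trace.area[v].mean()
    sd = trace.area[v].std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant trace")
    z = np.full(len(trace), np.nan)
    z[v] = (trace.area[v] - mu) / sd
    return trace.with_z(z)
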