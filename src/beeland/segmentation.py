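"""Landing-phase segmentation: hover-speed threshold and TL/LE windows.

The start of the total landing (TL) is the first hovering manoeuvre, found
as the first frame where the absolute speed towards the platform |U_P|
drops below a data-derived threshold, gated by two plausibility criteria:
total speed below 0.4 m/s and Euclidean distance below 0.15 m.

The threshold itself comes from the pooled approach-speed histogram of all
landings: a sum of five Gaussian components is fitted to the histogram, and
the threshold is the smallest speed to the right of the fitted curve's
global mode at which the fitted frequency falls back to the fitted
frequency at zero approach speed.

The leg-extension (LE) start frame is a manual annotation; this module only
validates it against the detected TL start and applies the study's
exclusion rules (recording too short, LE preceding TL, failed landing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, curve_fit

from .kinematics import KinematicSeries

#: hover threshold on |U_P| derived from the pooled speed histogram (m/s)
DEFAULT_SPEED_THRESHOLD = 0.066
#: total-speed plausibility cap for the TL-start frame (m/s)
DEFAULT_SPEED_CAP = 0.4
#: Euclidean-distance plausibility cap for the TL-start frame (m)
DEFAULT_DISTANCE_CAP = 0.15

REASON_CODES = ("ok", "no_hover_found", "recording_too_short", "le_precedes_tl", "failed_landing")


class ThresholdFitError(RuntimeError):
    """The five-Gaussian histogram fit failed to converge."""


class NoThresholdError(RuntimeError):
    """The fitted curve never returns to its zero-speed frequency right of the mode."""


class AnnotationError(ValueError):
    """Inconsistent manual annotations (e.g. leg extension after touchdown)."""


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x, dtype=float)
    for a, mu, sigma in zip(params[0::3], params[1::3], params[2::3]):
        y = y + a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))
    return y


@dataclass
class SpeedThresholdModel:
    """Fitted pooled-speed histogram model and the derived hover threshold.

    ``params`` holds the 15 fitted values (amplitude, mean, width per
    component); ``f_at_zero`` is the fitted frequency at U_P = 0 and
    ``threshold`` the first speed right of the global mode where the fitted
    curve crosses it.
    """

    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    params: np.ndarray = field(repr=False)
    f_at_zero: float = np.nan
    threshold: float = np.nan
    mode_speed: float = np.nan
    n_samples: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Fitted frequency curve at speeds ``x``."""
        return _gauss_sum(np.asarray(x, dtype=float), *self.params)

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "counts": self.counts.tolist(),
            "params": self.params.tolist(),
            "f_at_zero": self.f_at_zero,
            "threshold": self.threshold,
            "mode_speed": self.mode_speed,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeedThresholdModel":
        return cls(
            bin_edges=np.asarray(d["bin_edges"], dtype=float),
            counts=np.asarray(d["counts"], dtype=float),
            params=np.asarray(d["params"], dtype=float),
            f_at_zero=float(d["f_at_zero"]),
            threshold=float(d["threshold"]),
            mode_speed=float(d["mode_speed"]),
            n_samples=int(d["n_samples"]),
        )


def fit_speed_threshold(
    pooled_speeds: np.ndarray,
    n_components: int = 5,
    bins: str | int = "fd",
) -> SpeedThresholdModel:
    """Fit the five-Gaussian histogram model and derive the hover threshold.

    ``pooled_speeds`` are approach speeds U_P pooled over all frames of all
    landings (needs >= 1000 samples spanning negative and positive speeds).
    Histogram binning defaults to Freedman-Diaconis.
    """
    u = np.asarray(pooled_speeds, dtype=float)
    u = u[np.isfinite(u)]
    if u.size < 1000:
        raise ValueError("need at least 1000 pooled speed samples")
    if u.min() >= 0 or u.max() <= 0:
        raise ValueError("pooled speeds must span negative and positive values")

    counts, edges = np.histogram(u, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # initial guesses: component means spread over the central mass of the
    # sample, amplitudes read off the histogram, widths at a fraction of range
    qs = np.linspace(0.05, 0.95, n_components)
    mu0 = np.quantile(u, qs)
    span = edges[-1] - edges[0]
    p0 = []
    lb, ub = [], []
    for mu in mu0:
        amp = max(float(np.interp(mu, centers, counts)), 1.0)
        p0 += [amp, float(mu), span / 12.0]
        lb += [0.0, edges[0] - span, span / 1000.0]
        ub += [counts.max() * 10.0, edges[-1] + span, span * 2.0]
    try:
        params, _ = curve_fit(
            _gauss_sum, centers, counts, p0=p0, bounds=(lb, ub), maxfev=50000
        )
    except (RuntimeError, ValueError) as exc:
        raise ThresholdFitError(
            f"five-Gaussian histogram fit failed: {exc}; "
            f"{len(counts)} bins over [{edges[0]:.3g}, {edges[-1]:.3g}]"
        ) from exc

    grid = np.linspace(edges[0], edges[-1], 4001)
    curve = _gauss_sum(grid, *params)
    mode_speed = float(grid[np.argmax(curve)])
    f0 = float(_gauss_sum(np.array([0.0]), *params)[0])

    right = grid[grid > mode_speed]
    vals = _gauss_sum(right, *params) - f0
    sign_change = np.where((vals[:-1] > 0) & (vals[1:] <= 0))[0]
    if sign_change.size == 0:
        raise NoThresholdError(
            "fitted curve never crosses its zero-speed frequency right of the mode"
        )
    i = int(sign_change[0])
    threshold = float(
        brentq(lambda x: _gauss_sum(np.array([x]), *params)[0] - f0, right[i], right[i + 1])
    )
    # a crossing at (numerically) zero speed means the curve only returns to
    # its zero-speed frequency at zero itself: no usable threshold
    if threshold <= 1e-3 * (edges[-1] - edges[0]):
        raise NoThresholdError("derived threshold is not positive")
    return SpeedThresholdModel(
        bin_edges=edges,
        counts=counts.astype(float),
        params=np.asarray(params),
        f_at_zero=f0,
        threshold=threshold,
        mode_speed=mode_speed,
        n_samples=int(u.size),
    )


# ---------------------------------------------------------------------------
# per-landing segmentation


@dataclass(frozen=True)
class LandingAnnotation:
    """Manual per-landing annotations and design labels."""

    landing_id: int
    le_frame: int
    td_frame: int
    condition: str = ""
    day: int = 0
    part_of_day: str = ""
    failed_landing: bool = False


@dataclass
class PhaseWindows:
    """Frame indices and validity of the TL and LE phase windows."""

    tl_start_frame: int | None
    le_start_frame: int | None
    touchdown_frame: int
    tl_valid: bool
    le_valid: bool
    tl_reason: str = "ok"
    le_reason: str = "ok"

    def __post_init__(self) -> None:
        if self.tl_reason not in REASON_CODES or self.le_reason not in REASON_CODES:
            raise ValueError(f"reason codes must be in {REASON_CODES}")
        if (
            self.tl_valid
            and self.le_valid
            and self.tl_start_frame is not None
            and not (self.tl_start_frame <= self.le_start_frame <= self.touchdown_frame)
        ):
            raise ValueError("valid windows must satisfy tl <= le <= touchdown")


def detect_tl_start(
    kin: KinematicSeries,
    threshold: float = DEFAULT_SPEED_THRESHOLD,
    speed_cap: float = DEFAULT_SPEED_CAP,
    distance_cap: float = DEFAULT_DISTANCE_CAP,
) -> int | None:
    """First frame of the first hovering manoeuvre, or None.

    The earliest frame where |U_P| < threshold, |U| < speed_cap and
    d_E < distance_cap all hold; None when no frame qualifies.
    """
    ok = (
        (np.abs(kin.U_P) < threshold)
        & (kin.speed < speed_cap)
        & (kin.d_E < distance_cap)
    )
    idx = np.flatnonzero(ok)
    return int(idx[0]) if idx.size else None


def segment_landing(
    kin: KinematicSeries,
    annotation: LandingAnnotation,
    threshold: float = DEFAULT_SPEED_THRESHOLD,
    speed_cap: float = DEFAULT_SPEED_CAP,
    distance_cap: float = DEFAULT_DISTANCE_CAP,
) -> PhaseWindows:
    """Segment one landing into TL and LE windows with exclusion codes.

    Exclusion rules: a failed landing invalidates both phases; a missing
    hover invalidates TL only — as ``recording_too_short`` when the bee does
    get slow and close within the recording (the first hover then predates
    it), otherwise ``no_hover_found``; an annotated leg extension earlier
    than the detected TL start invalidates TL but keeps LE.
    """
    td = annotation.td_frame
    if not 0 <= annotation.le_frame <= td:
        raise AnnotationError(
            f"landing {annotation.landing_id}: le_frame {annotation.le_frame} "
            f"outside [0, td_frame {td}]"
        )
    if td >= kin.n_frames:
        raise AnnotationError(
            f"landing {annotation.landing_id}: td_frame {td} outside track"
        )

    if annotation.failed_landing:
        return PhaseWindows(
            tl_start_frame=None,
            le_start_frame=None,
            touchdown_frame=td,
            tl_valid=False,
            le_valid=False,
            tl_reason="failed_landing",
            le_reason="failed_landing",
        )

    tl = detect_tl_start(kin, threshold, speed_cap, distance_cap)
    if tl is None:
        near = (kin.speed < speed_cap) & (kin.d_E < distance_cap)
        reason = "recording_too_short" if near.any() else "no_hover_found"
        return PhaseWindows(
            tl_start_frame=None,
            le_start_frame=annotation.le_frame,
            touchdown_frame=td,
            tl_valid=False,
            le_valid=True,
            tl_reason=reason,
            le_reason="ok",
        )
    if annotation.le_frame < tl:
        return PhaseWindows(
            tl_start_frame=tl,
            le_start_frame=annotation.le_frame,
            touchdown_frame=td,
            tl_valid=False,
            le_valid=True,
            tl_reason="le_precedes_tl",
            le_reason="ok",
        )
    return PhaseWindows(
        tl_start_frame=tl,
        le_start_frame=annotation.le_frame,
        touchdown_frame=td,
        tl_valid=True,
        le_valid=True,
    )


def segment_batch(
    kins: list[KinematicSeries],
    annotations: list[LandingAnnotation],
    threshold: float = DEFAULT_SPEED_THRESHOLD,
) -> tuple[list[PhaseWindows], dict]:
    """Segment a batch and tally validity/exclusion counts."""
    windows = [segment_landing(k, a, threshold) for k, a in zip(kins, annotations)]
    summary = {
        "n": len(windows),
        "n_tl_valid": sum(w.tl_valid for w in windows),
        "n_le_valid": sum(w.le_valid for w in windows),
    }
    for code in REASON_CODES[1:]:
        summary[code] = sum(w.tl_reason == code for w in windows)
    return windows, summary
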