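"""Temperature-scan characterisation: transition dip and monotone trend.

Lipid vesicle suspensions show a characteristic dip in the sound-velocity
concentration increment [u](T) at the gel/fluid transition temperature Tm;
cholesterol broadens and mutes it.  ``detect_dip`` makes the visual call
quantitative: local quadratic smoothing, interior-minimum search, a depth
threshold in units of the measurement noise, and parabolic vertex
interpolation of the minimum temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ThermalSeries", "DipReport", "TrendReport", "detect_dip", "monotone_trend"]


@dataclass
class ThermalSeries:
    """A derived quantity sampled on a strictly monotone temperature grid."""

    temperatures: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sigmas is None:
            self.sigmas = np.zeros_like(self.values)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (self.temperatures.size == self.values.size == self.sigmas.size):
            raise ValueError("temperatures, values and sigmas must have equal length")
        d = np.diff(self.temperatures)
        if self.temperatures.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("temperatures must be strictly monotone")
        if np.all(d < 0):  # store in increasing order
            self.temperatures = self.temperatures[::-1]
            self.values = self.values[::-1]
            self.sigmas = self.sigmas[::-1]


@dataclass
class DipReport:
    dip_found: bool
    T_min: float | None = None
    depth: float | None = None
    depth_over_noise: float | None = None
    candidates: list[dict] = field(default_factory=list)


@dataclass
class TrendReport:
    direction: str            # "increasing" | "decreasing" | "flat"
    concordance: float        # fraction of consecutive pairs agreeing with direction
    n_pairs: int


def _local_quadratic_smooth(t: np.ndarray, v: np.ndarray, window: int) -> np.ndarray:
    """Least-squares quadratic fit in a sliding point window, evaluated at the centre.

    Equivalent to Savitzky–Golay on a uniform grid but valid for any strictly
    monotone temperature spacing.  Windows are shrunk symmetrically-truncated
    at the edges.
    """
    n = t.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        tt, vv = t[lo:hi], v[lo:hi]
        deg = min(2, tt.size - 1)
        coef = np.polyfit(tt - t[i], vv, deg)
        out[i] = coef[-1]
    return out


def detect_dip(
    series: ThermalSeries,
    window: int = 5,
    min_depth_sigma: float = 3.0,
) -> DipReport:
    """Locate a transition dip in a thermal series.

    A dip is an interior local minimum of the smoothed series whose depth —
    measured against the straight line joining the flanking smoothed maxima
    (or the series endpoints) — exceeds ``min_depth_sigma`` times the median
    point sigma.  When the sigmas are all zero any positive depth qualifies.
    The reported minimum temperature is the vertex of the parabola through
    the three smoothed points around the minimum, so a locally quadratic dip
    is localised exactly.  If several minima qualify the deepest is reported
    and all candidates are recorded.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    t, v, s = series.temperatures, series.values, series.sigmas
    if t.size < max(3, window):
        raise ValueError(f"need at least {max(3, window)} points for dip detection")

    sm = _local_quadratic_smooth(t, v, window)
    noise = float(np.median(s))
    threshold = min_depth_sigma * noise

    candidates: list[dict] = []
    for i in range(1, t.size - 1):
        if not (sm[i] <= sm[i - 1] and sm[i] < sm[i + 1]):
            continue
        # flanking maxima: walk outwards while the smoothed series keeps rising
        j = i - 1
        while j > 0 and sm[j - 1] >= sm[j]:
            j -= 1
        k = i + 1
        while k < t.size - 1 and sm[k + 1] >= sm[k]:
            k += 1
        # baseline through the flanks at the minimum's temperature
        if t[k] == t[j]:
            continue
        base = sm[j] + (sm[k] - sm[j]) * (t[i] - t[j]) / (t[k] - t[j])
        depth = base - sm[i]
        if depth <= 0 or depth < threshold:
            continue
        # parabolic vertex: least-squares quadratic over the smoothing window
        # centred on the minimum (exact for a locally quadratic dip)
        half = window // 2
        lo_i = max(0, i - half)
        hi_i = min(t.size, i + half + 1)
        coef = np.polyfit(t[lo_i:hi_i], sm[lo_i:hi_i], 2)
        if coef[0] > 0:
            T_min = float(np.clip(-coef[1] / (2 * coef[0]), t[max(0, i - 1)], t[i + 1]))
        else:
            T_min = float(t[i])
        candidates.append(
            {
                "T_min": T_min,
                "depth": float(depth),
                "depth_over_noise": float(depth / noise) if noise > 0 else np.inf,
                "index": i,
            }
        )

    if not candidates:
        return DipReport(dip_found=False, candidates=[])
    best = max(candidates, key=lambda c: c["depth"])
    return DipReport(
        dip_found=True,
        T_min=best["T_min"],
        depth=best["depth"],
        depth_over_noise=best["depth_over_noise"],
        candidates=candidates,
    )


def monotone_trend(series: ThermalSeries) -> TrendReport:
    """Direction and consecutive-pair concordance of a thermal series.

    Concordance is the fraction of consecutive pairs moving in the reported
    (majority) direction, so it is invariant under reversing the series; no
    p-value is attached.
    """
    v = series.values
    if v.size < 2:
        raise ValueError("need at least 2 points for a trend")
    d = np.diff(v)
    up = int(np.sum(d > 0))
    down = int(np.sum(d < 0))
    n_pairs = d.size
    if up > down:
        direction = "increasing"
    elif down > up:
        direction = "decreasing"
    else:
        direction = "flat"
    concordance = max(up, down) / n_pairs
    return TrendReport(direction=direction, concordance=float(concordance), n_pairs=n_pairs)
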