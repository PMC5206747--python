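"""Core drop-freezing assay analysis.

Turns per-droplet freezing temperatures from a cold-stage immersion-freezing
assay into frozen-fraction curves, cumulative ice-nucleus (IN) concentration
spectra, and onset / median freezing temperatures.

The central quantity is the cumulative IN concentration

    K(T) = (1/V) * ln(N0 / N(T))        [IN per mL of suspension]

where ``N0`` is the number of droplets tested, ``N(T)`` the cumulative number
of droplets still unfrozen at temperature ``T`` and ``V`` the droplet volume.
Under the singular (time-independent) nucleation hypothesis with Poisson IN
loading, ``K(T)`` estimates the concentration of nuclei with characteristic
freezing temperature at or above ``T``.

All temperatures are signed degrees Celsius (negative below zero); there is no
internal Kelvin conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DropletRecord",
    "DropletAssay",
    "FreezingCurve",
    "Spectrum",
    "AssaySummary",
    "TREATMENTS",
    "DEFAULT_GRID_STEP",
    "build_curve",
    "cumulative_spectrum",
    "confidence_interval",
    "onset_temperature",
    "median_freezing_temperature",
    "summarize_assay",
    "assay_spectrum",
    "spectrum_at",
]

#: Recognised treatment labels. ``crude`` is the untreated sample, ``heat`` is
#: 100 degC / 10 min, ``filtrate`` is a 0.22 um filtration, ``heat_filtrate``
#: both, and ``control`` a reference suspension (e.g. an INA-bacteria culture).
TREATMENTS = ("crude", "heat", "filtrate", "heat_filtrate", "control")

#: Reporting grid resolution in degC. Published onsets and T50s for this kind
#: of assay are given to 0.1-0.2 degC.
DEFAULT_GRID_STEP = 0.2

_TOL = 1e-9  # temperature comparison tolerance on the grid


@dataclass(frozen=True)
class DropletRecord:
    """One droplet of an assay.

    ``freeze_temp`` is the observed freezing temperature in degC, or — when
    ``censored`` is true — the coldest temperature at which the droplet was
    observed still liquid.
    """

    plate_id: str
    droplet_id: str
    freeze_temp: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and self.freeze_temp > 0.0:
            raise ValueError(
                f"droplet {self.plate_id}/{self.droplet_id}: freezing "
                f"temperature {self.freeze_temp} degC is above 0"
            )


@dataclass
class DropletAssay:
    """A drop-freezing assay: droplet records plus assay geometry.

    Parameters
    ----------
    sample_id : str
        Sample identifier (e.g. a collection month).
    treatment : str
        One of :data:`TREATMENTS`.
    records : list of DropletRecord
        One entry per droplet, across all plates.
    droplet_volume : float
        Droplet volume in mL (default 0.01 mL = 10 uL).
    cooling_rate : float
        Cooling rate in degC per minute; metadata only, the singular analysis
        does not use it.
    """

    sample_id: str
    treatment: str
    records: list[DropletRecord] = field(default_factory=list)
    droplet_volume: float = 0.01
    cooling_rate: float = 2.0

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive")
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}"
            )
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.plate_id, rec.droplet_id)
            if key in seen:
                raise ValueError(f"duplicate droplet id {key} within plate")
            seen.add(key)

    @property
    def n_droplets(self) -> int:
        return len(self.records)

    @property
    def plate_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.plate_id not in out:
                out.append(rec.plate_id)
        return out

    def event_temperatures(self, censored_as: float | None = None) -> np.ndarray:
        """Freezing temperatures as an array.

        Censored droplets are dropped when ``censored_as`` is None, otherwise
        replaced by that value (``-inf`` makes them never count as frozen).
        """
        if censored_as is None:
            return np.array(
                [r.freeze_temp for r in self.records if not r.censored], dtype=float
            )
        return np.array(
            [censored_as if r.censored else r.freeze_temp for r in self.records],
            dtype=float,
        )

    def subset_plate(self, plate_id: str) -> "DropletAssay":
        recs = [r for r in self.records if r.plate_id == plate_id]
        return DropletAssay(
            sample_id=self.sample_id,
            treatment=self.treatment,
            records=recs,
            droplet_volume=self.droplet_volume,
            cooling_rate=self.cooling_rate,
        )


@dataclass
class FreezingCurve:
    """Cumulative unfrozen counts on a descending temperature grid.

    ``n_unfrozen[j]`` counts droplets with freezing temperature strictly below
    ``grid[j]``; a droplet observed frozen exactly at a grid temperature counts
    as frozen there (closed-above convention). Censored droplets count as
    unfrozen at every grid point.
    """

    grid: np.ndarray
    n_total: int
    n_unfrozen: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.n_unfrozen = np.asarray(self.n_unfrozen, dtype=int)
        if self.grid.ndim != 1 or self.grid.shape != self.n_unfrozen.shape:
            raise ValueError("grid and n_unfrozen must be 1-D and equally long")
        if np.any(np.diff(self.grid) >= 0):
            raise ValueError("grid must be strictly decreasing")
        if np.any(np.diff(self.n_unfrozen) > 0):
            raise ValueError("n_unfrozen must be non-increasing with cooling")
        if np.any(self.n_unfrozen < 0) or np.any(self.n_unfrozen > self.n_total):
            raise ValueError("n_unfrozen out of [0, n_total]")

    @property
    def n_frozen(self) -> np.ndarray:
        return self.n_total - self.n_unfrozen

    @property
    def frozen_fraction(self) -> np.ndarray:
        """f(T) = 1 - N(T)/N0."""
        return 1.0 - self.n_unfrozen / self.n_total


@dataclass
class Spectrum:
    """Cumulative IN concentration K(T) with confidence bounds.

    ``K`` is NaN wherever N(T) = 0 (the estimator is undefined once every
    droplet froze); ``censored_below`` is the warmest such grid temperature, or
    None if N(T) > 0 everywhere.
    """

    grid: np.ndarray
    K: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_unfrozen: np.ndarray
    n_total: int
    volume: float
    ci_level: float
    censored_below: float | None = None

    def defined(self) -> np.ndarray:
        """Boolean mask of grid points where K is defined."""
        return ~np.isnan(self.K)


@dataclass
class AssaySummary:
    """Headline numbers of one assay."""

    sample_id: str
    treatment: str
    onset_temp: float | None
    t50: float | None
    n_total: int
    n_frozen: int
    plate_onsets: dict[str, float | None] = field(default_factory=dict)
    plate_t50s: dict[str, float | None] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _make_grid(coldest: float, grid_step: float) -> np.ndarray:
    """Descending grid of multiples of ``grid_step`` from 0 down to ``coldest``."""
    n_steps = int(math.ceil(round(-coldest / grid_step, 9)))
    return -grid_step * np.arange(n_steps + 1)


def build_curve(assay: DropletAssay, grid_step: float = DEFAULT_GRID_STEP) -> FreezingCurve:
    """Discretise droplet freezing events onto a reporting grid.

    The grid spans 0 degC down to the coldest observed event (freezing or last
    liquid observation), in steps of ``grid_step``.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if not assay.records:
        raise ValueError("no droplets")
    coldest = min(r.freeze_temp for r in assay.records)
    grid = _make_grid(coldest, grid_step)
    temps = assay.event_temperatures(censored_as=-np.inf)
    # frozen at grid point g  <=>  freeze_temp >= g (within tolerance)
    n_frozen = (temps[None, :] >= grid[:, None] - _TOL).sum(axis=1)
    return FreezingCurve(grid=grid, n_total=len(temps), n_unfrozen=len(temps) - n_frozen)


def confidence_interval(
    n_unfrozen: int | np.ndarray,
    n_total: int,
    volume: float,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (Clopper-Pearson) confidence bounds on K.

    The binomial interval is computed on the unfrozen proportion
    ``p = N(T)/N0`` and pushed through the monotone transform
    ``K = -ln(p)/V``. For ``n_unfrozen = 0`` the upper bound is +inf (the
    spectrum is censored there); for ``n_unfrozen = n_total`` the lower bound
    is exactly 0.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if volume <= 0:
        raise ValueError("volume must be positive")
    n = np.atleast_1d(np.asarray(n_unfrozen, dtype=float))
    if np.any(n < 0) or np.any(n > n_total):
        raise ValueError("n_unfrozen must lie in [0, n_total]")
    alpha = 1.0 - level
    with np.errstate(divide="ignore"):
        p_low = np.where(n > 0, stats.beta.ppf(alpha / 2, n, n_total - n + 1), 0.0)
        p_high = np.where(
            n < n_total, stats.beta.ppf(1 - alpha / 2, n + 1, n_total - n), 1.0
        )
        k_low = -np.log(p_high) / volume  # p upper bound -> K lower bound
        k_high = np.where(p_low > 0, -np.log(p_low) / volume, np.inf)
    k_low = np.maximum(k_low, 0.0)
    if np.isscalar(n_unfrozen):
        return float(k_low[0]), float(k_high[0])
    return k_low, k_high


def cumulative_spectrum(
    curve: FreezingCurve, volume: float, ci_level: float = 0.95
) -> Spectrum:
    """Cumulative IN concentration spectrum K(T) = ln(N0/N(T)) / V.

    K is left undefined (NaN) at grid points where N(T) = 0; the warmest such
    temperature is recorded as ``censored_below``.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if curve.n_total == 0:
        raise ValueError("curve has no droplets")
    n = curve.n_unfrozen.astype(float)
    with np.errstate(divide="ignore"):
        K = np.where(n > 0, np.log(curve.n_total / np.where(n > 0, n, 1.0)) / volume, np.nan)
    ci_low, ci_high = confidence_interval(curve.n_unfrozen, curve.n_total, volume, ci_level)
    ci_low = np.where(n > 0, ci_low, np.nan)
    ci_high = np.where(n > 0, ci_high, np.nan)
    exhausted = np.nonzero(curve.n_unfrozen == 0)[0]
    censored_below = float(curve.grid[exhausted[0]]) if exhausted.size else None
    return Spectrum(
        grid=curve.grid,
        K=K,
        ci_low=ci_low,
        ci_high=ci_high,
        n_unfrozen=curve.n_unfrozen,
        n_total=curve.n_total,
        volume=volume,
        ci_level=ci_level,
        censored_below=censored_below,
    )


def onset_temperature(curve: FreezingCurve) -> float | None:
    """Warmest grid temperature with at least one frozen droplet.

    Returns None when no droplet froze (fully censored assay).
    """
    frozen = np.nonzero(curve.n_frozen >= 1)[0]
    if frozen.size == 0:
        return None
    return float(curve.grid[frozen[0]])


def median_freezing_temperature(curve: FreezingCurve) -> float | None:
    """Median freezing temperature T50: where the frozen fraction crosses 1/2.

    Linear interpolation in temperature between the two grid points bracketing
    f = 0.5; if f = 0.5 exactly at a grid point, that temperature is returned.
    Returns None when fewer than half the droplets froze.
    """
    f = curve.frozen_fraction
    idx = np.nonzero(f >= 0.5)[0]
    if idx.size == 0:
        return None
    j = idx[0]
    if j == 0 or math.isclose(f[j], 0.5, abs_tol=1e-12):
        return float(curve.grid[j])
    f0, f1 = f[j - 1], f[j]
    t0, t1 = curve.grid[j - 1], curve.grid[j]
    return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))


def summarize_assay(
    assay: DropletAssay, grid_step: float = DEFAULT_GRID_STEP
) -> AssaySummary:
    """Pooled and per-plate onset and T50 for one assay."""
    curve = build_curve(assay, grid_step)
    plate_onsets: dict[str, float | None] = {}
    plate_t50s: dict[str, float | None] = {}
    for pid in assay.plate_ids:
        pc = build_curve(assay.subset_plate(pid), grid_step)
        plate_onsets[pid] = onset_temperature(pc)
        plate_t50s[pid] = median_freezing_temperature(pc)
    return AssaySummary(
        sample_id=assay.sample_id,
        treatment=assay.treatment,
        onset_temp=onset_temperature(curve),
        t50=median_freezing_temperature(curve),
        n_total=curve.n_total,
        n_frozen=int(curve.n_frozen[-1]),
        plate_onsets=plate_onsets,
        plate_t50s=plate_t50s,
    )


def assay_spectrum(
    assay: DropletAssay,
    grid_step: float = DEFAULT_GRID_STEP,
    ci_level: float = 0.95,
) -> Spectrum:
    """Convenience: curve + spectrum in one call, using the assay's volume."""
    return cumulative_spectrum(build_curve(assay, grid_step), assay.droplet_volume, ci_level)


def spectrum_at(spectrum: Spectrum, temp: float) -> float:
    """K at one temperature, linearly interpolated on the defined grid range.

    Returns NaN outside the grid or below the censoring temperature.
    """
    mask = spectrum.defined()
    if not mask.any():
        return float("nan")
    g = spectrum.grid[mask]
    k = spectrum.K[mask]
    hit = np.nonzero(np.abs(spectrum.grid - temp) < _TOL)[0]
    if hit.size:
        return float(spectrum.K[hit[0]])
    if temp > g[0] or temp < g[-1]:
        return float("nan")
    # np.interp needs ascending x: negate the temperature axis
    return float(np.interp(-temp, -g, k))
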