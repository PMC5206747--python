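"""Synthetic drop-freezing assays under the singular nucleation model.

Each ice-nucleus (IN) population ("class") has a concentration ``c`` (IN per
mL of suspension) and a Gaussian distribution of characteristic freezing
temperatures, truncated at 0 degC. A droplet of volume ``V`` receives
``Poisson(c * V)`` nuclei from each class; every nucleus draws a
characteristic temperature; the droplet additionally draws one intrinsic
background freezing temperature (impurity / container nucleation, the only
freezing pathway of particle-free water). Under the singular hypothesis the
droplet freezes at the warmest of all these temperatures, and is recorded as
censored if that is below the coldest temperature reached by the cold stage.

The closed-form cumulative active-nucleus spectrum of a scenario is

    Lambda(T) = sum_i c_i * S_i(T)

with ``S_i`` the upper-tail probability of class i's characteristic-
temperature distribution. The expected unfrozen fraction at T is
``exp(-V * Lambda(T)) * P(background < T)``, so the quantity the K(T)
estimator converges to is ``Lambda(T) - ln P(background < T) / V``.

Treatments act on scenarios: heating to 100 degC for 10 min removes
heat-labile (proteinaceous) classes outright; 0.22-um filtration removes
classes whose particle size exceeds the pore cutoff.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy import stats

from .assay import DropletAssay, DropletRecord

__all__ = [
    "INClass",
    "Scenario",
    "PRESET_NAMES",
    "expected_spectrum",
    "background_cdf",
    "expected_frozen_fraction",
    "expected_cumulative_concentration",
    "simulate_assay",
    "apply_heat",
    "apply_filtration",
    "apply_treatment",
    "simulate_treatment_set",
    "preset",
    "scenario_from_dict",
    "scenario_to_dict",
]

FILTER_CUTOFF_NM = 220.0  # 0.22-um membrane pore size


@dataclass(frozen=True)
class INClass:
    """One IN population.

    Parameters
    ----------
    label : str
        Free-text name.
    concentration : float
        IN per mL of suspension.
    temp_mean, temp_sd : float
        Mean and sd (degC) of the characteristic-temperature Gaussian,
        truncated above at 0 degC.
    heat_sensitive : bool
        Destroyed by 100 degC / 10 min (proteinaceous nucleators).
    size_nm : float
        Particle size, decides retention on a 0.22-um filter.
    """

    label: str
    concentration: float
    temp_mean: float
    temp_sd: float
    heat_sensitive: bool = False
    size_nm: float = 1000.0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"class {self.label!r}: concentration must be >= 0")
        if self.temp_sd < 0:
            raise ValueError(f"class {self.label!r}: temp_sd must be >= 0")
        if self.size_nm <= 0:
            raise ValueError(f"class {self.label!r}: size_nm must be > 0")

    def survival(self, temps: np.ndarray | float) -> np.ndarray | float:
        """Upper-tail probability of the truncated characteristic-T law."""
        if self.temp_sd == 0:
            return np.where(np.asarray(temps) <= min(self.temp_mean, 0.0), 1.0, 0.0)
        b = (0.0 - self.temp_mean) / self.temp_sd
        return stats.truncnorm.sf(temps, -np.inf, b, loc=self.temp_mean, scale=self.temp_sd)


@dataclass
class Scenario:
    """Full description of one simulated drop-freezing experiment."""

    classes: list[INClass] = field(default_factory=list)
    droplet_volume: float = 0.01  # mL (10 uL)
    n_droplets: int = 235  # 5 plates x 47 droplets
    n_plates: int = 5
    cooling_rate: float = 2.0  # degC / min, metadata only
    background_mean: float = -16.0  # degC, droplet-intrinsic freezing
    background_sd: float = 0.8
    background_max: float = -10.0  # background draws truncated at/below this
    min_temp: float = -20.0  # cold-stage floor; colder events are censored
    sample_id: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive")
        if self.n_droplets <= 0 or self.n_plates <= 0:
            raise ValueError("droplet and plate counts must be positive")
        if self.n_droplets % self.n_plates != 0:
            raise ValueError("n_droplets must be divisible by n_plates")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")

    @property
    def droplets_per_plate(self) -> int:
        return self.n_droplets // self.n_plates

    def _background_dist(self):
        b = (self.background_max - self.background_mean) / self.background_sd
        return stats.truncnorm(-np.inf, b, loc=self.background_mean, scale=self.background_sd)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def expected_spectrum(scenario: Scenario, temps) -> np.ndarray:
    """Cumulative active-nucleus concentration Lambda(T), IN per mL.

    Sums class contributions only; the droplet-intrinsic background is not an
    IN population in suspension and is excluded (see
    :func:`expected_cumulative_concentration` for the estimator's full
    target).
    """
    t = np.asarray(temps, dtype=float)
    lam = np.zeros_like(t, dtype=float)
    for cls in scenario.classes:
        lam += cls.concentration * cls.survival(t)
    return lam


def background_cdf(scenario: Scenario, temps) -> np.ndarray:
    """P(background freezing temperature < T)."""
    return scenario._background_dist().cdf(np.asarray(temps, dtype=float))


def expected_frozen_fraction(scenario: Scenario, temps) -> np.ndarray:
    """Expected frozen fraction 1 - exp(-V * Lambda(T)) * P(background < T)."""
    lam = expected_spectrum(scenario, temps)
    return 1.0 - np.exp(-scenario.droplet_volume * lam) * background_cdf(scenario, temps)


def expected_cumulative_concentration(scenario: Scenario, temps) -> np.ndarray:
    """Exact target of the K(T) estimator: -ln(E[unfrozen fraction]) / V.

    Equals ``Lambda(T)`` wherever the background cannot yet freeze droplets,
    and picks up the background hazard below that.
    """
    unfrozen = 1.0 - expected_frozen_fraction(scenario, temps)
    with np.errstate(divide="ignore"):
        return -np.log(unfrozen) / scenario.droplet_volume


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_assay(
    scenario: Scenario,
    seed: int | np.random.SeedSequence | None = None,
    treatment: str = "crude",
) -> DropletAssay:
    """Draw one assay from a scenario.

    Deterministic given (scenario, seed). ``seed`` falls back to
    ``scenario.seed``; one of the two must be set.
    """
    if seed is None:
        seed = scenario.seed
    if seed is None:
        raise ValueError("a seed is required (argument or scenario.seed)")
    rng = np.random.default_rng(seed)
    n = scenario.n_droplets
    warmest = np.full(n, -np.inf)
    for cls in scenario.classes:
        counts = rng.poisson(cls.concentration * scenario.droplet_volume, size=n)
        total = int(counts.sum())
        if total == 0:
            continue
        if cls.temp_sd == 0:
            draws = np.full(total, min(cls.temp_mean, 0.0))
        else:
            b = (0.0 - cls.temp_mean) / cls.temp_sd
            draws = stats.truncnorm.rvs(
                -np.inf, b, loc=cls.temp_mean, scale=cls.temp_sd,
                size=total, random_state=rng,
            )
        owner = np.repeat(np.arange(n), counts)
        np.maximum.at(warmest, owner, draws)
    bg = scenario._background_dist().rvs(size=n, random_state=rng)
    freeze = np.maximum(warmest, bg)
    censored = freeze < scenario.min_temp

    per_plate = scenario.droplets_per_plate
    records = []
    for i in range(n):
        records.append(
            DropletRecord(
                plate_id=f"plate{i // per_plate + 1}",
                droplet_id=f"d{i % per_plate + 1:03d}",
                freeze_temp=float(scenario.min_temp if censored[i] else freeze[i]),
                censored=bool(censored[i]),
            )
        )
    return DropletAssay(
        sample_id=scenario.sample_id,
        treatment=treatment,
        records=records,
        droplet_volume=scenario.droplet_volume,
        cooling_rate=scenario.cooling_rate,
    )


# ---------------------------------------------------------------------------
# treatment operators
# ---------------------------------------------------------------------------


def apply_heat(scenario: Scenario) -> Scenario:
    """100 degC / 10 min: remove heat-labile classes, keep everything else."""
    return dataclasses.replace(
        scenario, classes=[c for c in scenario.classes if not c.heat_sensitive]
    )


def apply_filtration(scenario: Scenario, cutoff_nm: float = FILTER_CUTOFF_NM) -> Scenario:
    """0.22-um (default) filtration: remove classes larger than the pore size."""
    if cutoff_nm <= 0:
        raise ValueError("cutoff_nm must be positive")
    return dataclasses.replace(
        scenario, classes=[c for c in scenario.classes if c.size_nm <= cutoff_nm]
    )


def apply_treatment(scenario: Scenario, treatment: str) -> Scenario:
    """Map a treatment label onto the scenario operators."""
    if treatment in ("crude", "control"):
        return scenario
    if treatment == "heat":
        return apply_heat(scenario)
    if treatment == "filtrate":
        return apply_filtration(scenario)
    if treatment == "heat_filtrate":
        return apply_heat(apply_filtration(scenario))
    raise ValueError(f"unknown treatment {treatment!r}")


def simulate_treatment_set(
    scenario: Scenario,
    treatments: tuple[str, ...] = ("crude", "heat", "filtrate", "heat_filtrate"),
    seed: int | None = None,
) -> dict[str, DropletAssay]:
    """Simulate independent aliquots of one sample under several treatments.

    Each treatment gets its own child seed (aliquots are physically distinct
    droplet sets), derived deterministically from ``seed``.
    """
    if seed is None:
        seed = scenario.seed
    if seed is None:
        raise ValueError("a seed is required (argument or scenario.seed)")
    children = np.random.SeedSequence(seed).spawn(len(treatments))
    out: dict[str, DropletAssay] = {}
    for trt, child in zip(treatments, children):
        out[trt] = simulate_assay(apply_treatment(scenario, trt), seed=child, treatment=trt)
    return out


# ---------------------------------------------------------------------------
# presets (packaged YAML scenario configs)
# ---------------------------------------------------------------------------

PRESET_NAMES = ("ps_control", "pure_water", "paper_like_rain")


def scenario_from_dict(d: dict) -> Scenario:
    """Build a Scenario from a plain mapping (YAML/JSON scenario config)."""
    d = dict(d)
    classes = [INClass(**c) for c in d.pop("classes", [])]
    bg = d.pop("background", {})
    kwargs = dict(
        classes=classes,
        droplet_volume=d.pop("droplet_volume", 0.01),
        n_droplets=d.pop("n_droplets", 235),
        n_plates=d.pop("n_plates", 5),
        cooling_rate=d.pop("cooling_rate", 2.0),
        background_mean=bg.get("temp_mean", -16.0),
        background_sd=bg.get("temp_sd", 0.8),
        background_max=bg.get("max_temp", -10.0),
        min_temp=d.pop("min_temp", -20.0),
        sample_id=d.pop("sample_id", "synthetic"),
        seed=d.pop("seed", None),
    )
    if d:
        raise ValueError(f"unknown scenario keys: {sorted(d)}")
    return Scenario(**kwargs)


def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "sample_id": scenario.sample_id,
        "droplet_volume": scenario.droplet_volume,
        "n_droplets": scenario.n_droplets,
        "n_plates": scenario.n_plates,
        "cooling_rate": scenario.cooling_rate,
        "min_temp": scenario.min_temp,
        "seed": scenario.seed,
        "background": {
            "temp_mean": scenario.background_mean,
            "temp_sd": scenario.background_sd,
            "max_temp": scenario.background_max,
        },
        "classes": [dataclasses.asdict(c) for c in scenario.classes],
    }


def preset(name: str) -> Scenario:
    """Load a packaged scenario preset.

    Available presets:

    - ``ps_control``: a dense INA-bacteria suspension — a single
      heat-sensitive proteinaceous class active near -4 degC.
    - ``pure_water``: particle-free water, background freezing only.
    - ``paper_like_rain``: a rainwater-like mixture of a heat-sensitive
      bacterial class and two heat-resistant submicron classes.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}")
    text = resources.files("dropfreeze.presets").joinpath(f"{name}.yaml").read_text()
    return scenario_from_dict(yaml.safe_load(text))
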