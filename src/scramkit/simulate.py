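"""Seeded synthetic-data generators for every assay the package analyses.

Each generator emulates the shape of one experimental readout with known
ground truth, so every analysis stage can be tested end to end without any
measured data:

* dithionite traces — pre-addition plateau at 1, post-addition exponential
  decay to a population-determined plateau, additive Gaussian noise;
* capture assays — Poisson protein incorporation per vesicle, binomial
  count statistics;
* glycoform band tables — a true glycoform distribution with multiplicative
  lognormal densitometry noise;
* growth curves — logistic growth sampled every 15 min with additive noise;
* calibration series — a linear standard curve with multiplicative noise
  and a sample lane synthesized from a true copies-per-cell value.

Noise models follow each measurement's physics: additive Gaussian for
fluorescence and optical density, multiplicative lognormal for band
densitometry, binomial for radioactive counts.  Every generator call
derives its random stream from ``(seed, replicate index)`` via NumPy seed
sequences, so outputs are bit-reproducible and adding replicates never
perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Any, Mapping

import numpy as np
from scipy.constants import Avogadro

from .cells import BandTable, CalibrationSeries, GrowthCurve, glycoscore
from .errors import ConfigurationError
from .occupancy import fraction_from_poisson_mean, predicted_capture_fraction
from .traces import CaptureAssayData, FluorescenceTrace


def _rng(seed: int, index: int = 0) -> np.random.Generator:
    """Deterministic per-replicate stream: child ``index`` of ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


@dataclass(frozen=True)
class TraceSimConfig:
    """Dithionite-trace generator settings.

    ``plateau_negative`` is the protected fraction of scramblase-free
    vesicles (the protein-free control level; the ideal symmetric value is
    0.5, the typical measured one ~0.43, i.e. a 57% drop).
    ``scramblase_fraction`` is the fraction of vesicles carrying at least
    one scramblase; those vesicles bleach completely.
    """

    plateau_negative: float = 0.43
    scramblase_fraction: float = 0.55
    rate_k_per_s: float = 0.05
    duration_s: float = 600.0
    sampling_dt_s: float = 1.0
    pre_addition_s: float = 60.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0 <= self.plateau_negative <= 1:
            raise ConfigurationError("plateau_negative must lie in [0, 1]")
        if not 0 <= self.scramblase_fraction <= 1:
            raise ConfigurationError("scramblase_fraction must lie in [0, 1]")
        if self.rate_k_per_s <= 0 or self.duration_s <= 0 or self.sampling_dt_s <= 0:
            raise ConfigurationError("rate, duration and dt must be > 0")
        if self.pre_addition_s <= 0:
            raise ConfigurationError("pre_addition_s must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CaptureSimConfig:
    """Capture-assay generator settings.

    ``m_mean`` is the Poisson mean of scramblase copies per vesicle;
    ``counts_total`` is the radiolabel per tube in cpm (default one third of
    a ~40,000 cpm three-sample prep).
    """

    m_mean: float = 0.3567
    n_vesicles: int = 10_000
    counts_total: int = 13_000

    def __post_init__(self) -> None:
        if self.m_mean < 0:
            raise ConfigurationError("m_mean must be >= 0")
        if self.n_vesicles < 1 or self.counts_total < 1:
            raise ConfigurationError("n_vesicles and counts_total must be >= 1")


@dataclass(frozen=True)
class BandSimConfig:
    """Glycoform band-table generator settings.

    ``proportions`` are the true glycoform fractions for bands carrying
    (4, 3, 2, 1, 0) glycans; the default corresponds to a Glycoscore of 85.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    lognormal densitometry noise.
    """

    proportions: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05, 0.0)
    noise_cv: float = 0.03
    lane_total: float = 1000.0

    def __post_init__(self) -> None:
        if len(self.proportions) != 5 or any(p < 0 for p in self.proportions):
            raise ConfigurationError("proportions must be 5 non-negative values")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ConfigurationError("proportions must sum to 1")
        if self.noise_cv < 0 or self.lane_total <= 0:
            raise ConfigurationError("noise_cv must be >= 0 and lane_total > 0")


@dataclass(frozen=True)
class GrowthSimConfig:
    """Logistic growth-curve generator settings.

    Defaults emulate a plate-reader run: inoculation at A600 = 0.01,
    readings every 15 min for 36 h, and a realistic stationary plateau of
    A600 ~ 2.  ``rate_per_min`` is the exponential-phase rate; the true
    doubling time is ln 2 / rate.
    """

    a0: float = 0.01
    carrying_capacity: float = 2.0
    rate_per_min: float = math.log(2.0) / 90.0
    sampling_dt_min: float = 15.0
    duration_min: float = 36 * 60.0
    noise_sd: float = 0.005

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.carrying_capacity <= 0:
            raise ConfigurationError("a0 and carrying_capacity must be > 0")
        if self.a0 > self.carrying_capacity:
            raise ConfigurationError("a0 cannot exceed carrying_capacity")
        if self.rate_per_min <= 0 or self.sampling_dt_min <= 0 or self.duration_min <= 0:
            raise ConfigurationError("rate, dt and duration must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CalibrationSimConfig:
    """Quantitative-blot calibration generator settings.

    The standard curve is ``intensity = slope * amount_ng + intercept``
    with multiplicative lognormal noise; the sample lane intensity is
    generated from ``true_copies_per_cell`` via the protein molar mass and
    cells loaded.
    """

    true_copies_per_cell: float = 800.0
    standard_amounts_ng: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    slope: float = 1.0
    intercept: float = 0.1
    noise_cv: float = 0.05
    lane_cells: float = 1.0e7
    protein_molar_mass_g_mol: float = 60_000.0

    def __post_init__(self) -> None:
        if self.true_copies_per_cell < 0:
            raise ConfigurationError("true_copies_per_cell must be >= 0")
        if len(self.standard_amounts_ng) < 3 or any(a <= 0 for a in self.standard_amounts_ng):
            raise ConfigurationError("need >= 3 positive standard amounts")
        if self.slope <= 0:
            raise ConfigurationError("slope must be > 0")
        if self.noise_cv < 0 or self.lane_cells <= 0 or self.protein_molar_mass_g_mol <= 0:
            raise ConfigurationError("invalid noise/lane parameters")


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of all generator settings plus the master seed."""

    seed: int = 0
    n_replicates: int = 3
    trace: TraceSimConfig = field(default_factory=TraceSimConfig)
    capture: CaptureSimConfig = field(default_factory=CaptureSimConfig)
    bands: BandSimConfig = field(default_factory=BandSimConfig)
    growth: GrowthSimConfig = field(default_factory=GrowthSimConfig)
    calibration: CalibrationSimConfig = field(default_factory=CalibrationSimConfig)


_SUBCONFIGS = {
    "trace": TraceSimConfig,
    "capture": CaptureSimConfig,
    "bands": BandSimConfig,
    "growth": GrowthSimConfig,
    "calibration": CalibrationSimConfig,
}


def config_from_mapping(mapping: Mapping[str, Any]) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a (YAML-loaded) mapping,
    overriding only the keys present."""
    kwargs: dict[str, Any] = {}
    for key, value in mapping.items():
        if key in _SUBCONFIGS:
            sub_cls = _SUBCONFIGS[key]
            known = {f.name for f in fields(sub_cls)}
            unknown = set(value) - known
            if unknown:
                raise ConfigurationError(f"unknown {key} config keys: {sorted(unknown)}")
            value = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[key] = sub_cls(**value)
        elif key in ("seed", "n_replicates"):
            kwargs[key] = int(value)
        else:
            raise ConfigurationError(f"unknown config section {key!r}")
    return SimulationConfig(**kwargs)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def simulate_dithionite_trace(
    config: TraceSimConfig,
    population: str,
    seed: int,
    replicate: int = 0,
    label: str | None = None,
) -> tuple[FluorescenceTrace, dict[str, Any]]:
    """Simulate one dithionite trace for a ``"liposome"`` or
    ``"proteoliposome"`` population.

    The population plateau is ``p_L`` for protein-free liposomes and
    ``(1 - f) * p_L`` for proteoliposomes, since scramblase-positive
    vesicles are fully bleachable.  Returns the trace and a ground-truth
    record.
    """
    if population not in ("liposome", "proteoliposome"):
        raise ConfigurationError(f"unknown population {population!r}")
    f = config.scramblase_fraction if population == "proteoliposome" else 0.0
    plateau = (1.0 - f) * config.plateau_negative
    t_pre = np.arange(-config.pre_addition_s, 0.0, config.sampling_dt_s)
    t_post = np.arange(0.0, config.duration_s + config.sampling_dt_s / 2, config.sampling_dt_s)
    t = np.concatenate([t_pre, t_post])
    signal = np.where(
        t < 0, 1.0, plateau + (1.0 - plateau) * np.exp(-config.rate_k_per_s * np.maximum(t, 0.0))
    )
    rng = _rng(seed, replicate)
    signal = signal + rng.normal(0.0, config.noise_sd, size=t.size)
    trace = FluorescenceTrace(
        time_s=t,
        fluorescence=signal,
        label=label or f"{population}-r{replicate}",
    )
    truth = {
        "population": population,
        "plateau": plateau,
        "delta_f": 1.0 - plateau,
        "rate_k_per_s": config.rate_k_per_s,
        "scramblase_fraction": f,
        "noise_sd": config.noise_sd,
    }
    return trace, truth


def simulate_trace_pair(
    config: TraceSimConfig, seed: int, replicate: int = 0
) -> tuple[FluorescenceTrace, FluorescenceTrace, dict[str, Any]]:
    """Paired protein-free and proteoliposome traces with shared settings.

    The two traces use distinct sub-streams of the same seed so the pair is
    reproducible as a unit.
    """
    lipo, truth_l = simulate_dithionite_trace(
        config, "liposome", seed, replicate=2 * replicate
    )
    proteo, truth_p = simulate_dithionite_trace(
        config, "proteoliposome", seed, replicate=2 * replicate + 1
    )
    truth = {
        "scramblase_fraction": config.scramblase_fraction,
        "liposome": truth_l,
        "proteoliposome": truth_p,
    }
    return lipo, proteo, truth


def expected_capture_fraction(m_mean: float) -> float:
    """Closed-form expected capture fraction of the simulator:
    ``0.5 + 0.5 * (1 - exp(-m))``."""
    return predicted_capture_fraction(fraction_from_poisson_mean(m_mean))


def simulate_capture_assay(
    config: CaptureSimConfig, seed: int, n_replicates: int = 3
) -> tuple[list[CaptureAssayData], dict[str, Any]]:
    """Simulate lectin-capture replicates under Poisson vesicle occupancy.

    Per replicate: draw per-vesicle copy numbers ~ Poisson(m); vesicles
    with >= 1 scramblase contribute their whole glycolipid pool to capture,
    the rest contribute half (outer leaflet only); captured counts are
    binomial at ``counts_total``.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    reps: list[CaptureAssayData] = []
    for i in range(n_replicates):
        rng = _rng(seed, i)
        occupancies = rng.poisson(config.m_mean, size=config.n_vesicles)
        frac_positive = float(np.mean(occupancies > 0))
        p_capture = 0.5 + 0.5 * frac_positive
        captured = int(rng.binomial(config.counts_total, p_capture))
        reps.append(
            CaptureAssayData(
                captured_signal=captured,
                total_signal=config.counts_total,
                replicate_id=f"rep{i + 1}",
            )
        )
    truth = {
        "m_mean": config.m_mean,
        "f_positive": fraction_from_poisson_mean(config.m_mean),
        "expected_capture": expected_capture_fraction(config.m_mean),
    }
    return reps, truth


def simulate_band_table(
    config: BandSimConfig, seed: int, n_lanes: int = 3, sample_prefix: str = "rep"
) -> tuple[BandTable, dict[str, Any]]:
    """Simulate a glycoform band table over a true glycoform distribution.

    Lane intensities are ``lane_total * proportion`` times unit-mean
    lognormal noise, so the noiseless Glycoscore equals the closed form of
    the true proportions.
    """
    lanes = []
    props = np.asarray(config.proportions, dtype=float)
    for i in range(n_lanes):
        rng = _rng(seed, i)
        intensities = config.lane_total * props * _lognormal_factors(rng, config.noise_cv, 5)
        lanes.append((f"{sample_prefix}{i + 1}", intensities.tolist()))
    table = BandTable.from_records(lanes)
    truth = {
        "proportions": tuple(props.tolist()),
        "glycoscore": glycoscore(props),
        "noise_cv": config.noise_cv,
    }
    return table, truth


def simulate_growth_curve(
    config: GrowthSimConfig, seed: int, replicate: int = 0, label: str = "sim"
) -> tuple[GrowthCurve, dict[str, Any]]:
    """Simulate a logistic growth curve,
    ``A(t) = K / (1 + ((K - A0)/A0) exp(-r t))`` plus Gaussian noise
    (clipped at 0).  Ground truth records the exponential-phase doubling
    time ln 2 / r.
    """
    t = np.arange(0.0, config.duration_min + config.sampling_dt_min / 2, config.sampling_dt_min)
    b = (config.carrying_capacity - config.a0) / config.a0
    a = config.carrying_capacity / (1.0 + b * np.exp(-config.rate_per_min * t))
    rng = _rng(seed, replicate)
    a = np.clip(a + rng.normal(0.0, config.noise_sd, size=t.size), 0.0, None)
    curve = GrowthCurve(time_min=t, a600=a, label=label)
    truth = {
        "doubling_time_min": math.log(2.0) / config.rate_per_min,
        "rate_per_min": config.rate_per_min,
        "carrying_capacity": config.carrying_capacity,
        "a0": config.a0,
    }
    return curve, truth


def simulate_calibration_series(
    config: CalibrationSimConfig, seed: int
) -> tuple[CalibrationSeries, float, dict[str, Any]]:
    """Simulate a quantitative-blot standard series plus one sample lane.

    Returns ``(series, sample_lane_intensity, ground_truth)``.  In the
    noiseless limit the downstream calibration recovers the true copies per
    cell exactly; a zero-copy sample lane reads the blot background
    (intercept).
    """
    amounts = np.asarray(config.standard_amounts_ng, dtype=float)
    rng = _rng(seed, 0)
    intensities = (config.slope * amounts + config.intercept) * _lognormal_factors(
        rng, config.noise_cv, amounts.size
    )
    sample_amount_ng = (
        config.true_copies_per_cell
        * config.lane_cells
        / Avogadro
        * config.protein_molar_mass_g_mol
        * 1e9
    )
    sample_intensity = float(
        (config.slope * sample_amount_ng + config.intercept)
        * _lognormal_factors(_rng(seed, 1), config.noise_cv, 1)[0]
    )
    series = CalibrationSeries(
        standard_amounts_ng=amounts,
        intensities=intensities,
        lane_cells=config.lane_cells,
        protein_molar_mass_g_mol=config.protein_molar_mass_g_mol,
    )
    truth = {
        "true_copies_per_cell": config.true_copies_per_cell,
        "sample_amount_ng": sample_amount_ng,
        "slope": config.slope,
        "intercept": config.intercept,
    }
    return series, sample_intensity, truth
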