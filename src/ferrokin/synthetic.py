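"""Synthetic batch experiments and cascade steady-state tables.

The generators emulate the monitoring data the kinetics analysis consumes:
batch Fe(II)-production trajectories at several planktonic biomass levels
(daily Eh and cell counts over a 12-day bioreduction of 4.5 g·L⁻¹
Fe(III)), and steady-state nutrient tables of the two-stage continuous
pilot. All randomness derives from an explicit integer seed; every
generator is a pure function of (parameters, seed).

Noise model (assumptions — the underlying experiments report no
measurement error model): Gaussian noise on the redox potential
(instrument-like, default sd 5 mV) and multiplicative lognormal noise on
cell counts (counting-chamber error, default sigma 0.15). The measured
Fe(II) channel is *derived from the noisy Eh* through the Nernst
speciation, mirroring the monitoring route in which Fe(II) is inferred
from the redox potential rather than assayed directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nutrients import NutrientRecord
from .rates import BioreductionSeries, PUBLISHED_RATE_LAW, RateLaw, mean_rate
from .reactor import (
    BatchConfig,
    GrowthReactorConfig,
    ReductionReactorConfig,
    simulate_batch,
    simulate_growth_reactor,
    steady_state,
)
from .speciation import DEFAULT_CALIBRATION, RedoxCalibration, eh_from_ratio, fe3_fraction_from_eh
from .constants import MOLAR_MASS

__all__ = [
    "SyntheticBatchParams",
    "generate_batch_experiment",
    "generate_rate_law_dataset",
    "generate_cascade_tables",
]


@dataclass(frozen=True)
class SyntheticBatchParams:
    """Conditions of the emulated batch bioreduction experiments.

    Defaults follow the 35 °C batch campaign: 4.5 g·L⁻¹ initial Fe(III),
    daily sampling for 12 days, biomass levels spanning the batch
    (3e8–2e9 cells·mL⁻¹) and richest continuous (5e9 cells·mL⁻¹)
    conditions, and the published biomass–rate law as ground truth.
    `fe2_0` is a small ferrous carry-over from the inoculum and medium,
    which also keeps the initial redox potential finite.
    """

    rate_law: RateLaw = PUBLISHED_RATE_LAW
    biomass_levels: tuple[float, ...] = (3e8, 2e9, 5e9)
    fe3_0: float = 4500.0            # mg·L⁻¹
    fe2_0: float = 50.0              # mg·L⁻¹
    sampling_interval: float = 24.0  # h
    duration: float = 288.0          # h (12 days)
    eh_noise_sd: float = 5.0         # mV
    cell_noise_sigma: float = 0.15   # lognormal sigma
    k_precip: float = 0.0            # h⁻¹
    seed: int = 0
    calibration: RedoxCalibration = DEFAULT_CALIBRATION

    def __post_init__(self) -> None:
        if self.eh_noise_sd < 0 or self.cell_noise_sigma < 0 or self.k_precip < 0:
            raise ValueError("noise parameters and k_precip must be nonnegative")
        if len(self.biomass_levels) < 1 or min(self.biomass_levels) <= 0:
            raise ValueError("biomass levels must be positive")


def _rng(params: SyntheticBatchParams, biomass_level: float, replicate: int):
    return np.random.default_rng(
        [params.seed & 0x7FFFFFFF, replicate, int(biomass_level) & 0x7FFFFFFF]
    )


def _simulate_level(params: SyntheticBatchParams, biomass_level: float):
    cfg = BatchConfig(
        fe3_0=params.fe3_0,
        fe2_0=params.fe2_0,
        biomass=biomass_level,
        rate_law=params.rate_law,
        k_precip=params.k_precip,
        duration=params.duration,
        step=params.sampling_interval,
    )
    return simulate_batch(cfg)


def generate_batch_experiment(params: SyntheticBatchParams, biomass_level: float,
                              replicate: int = 0) -> BioreductionSeries:
    """One synthetic batch run sampled at the monitoring cadence.

    The true trajectory comes from the batch simulator; the Eh channel is
    the Nernst potential of the true speciation plus Gaussian noise, the
    cell channel is the level times lognormal noise, and the Fe(II)
    channel is re-derived from the noisy Eh (the measurement route). With
    all noise at zero the series equals the simulator output exactly.
    `replicate` selects an independent noise stream under the same seed.
    """
    sim = _simulate_level(params, biomass_level)
    rng = _rng(params, biomass_level, replicate)
    fe3, fe2 = sim["fe3"], sim["fe2"]
    fe_total = fe3 + fe2
    # guard against an exactly ferric or ferrous state (potential undefined)
    ratio = np.clip(fe3, 1e-12, None) / np.clip(fe2, 1e-12, None)
    eh_true = np.asarray(eh_from_ratio(ratio, params.calibration))
    eh = eh_true + rng.normal(0.0, params.eh_noise_sd, size=eh_true.shape) \
        if params.eh_noise_sd > 0 else eh_true
    cells = biomass_level * rng.lognormal(0.0, params.cell_noise_sigma, size=eh.shape) \
        if params.cell_noise_sigma > 0 else np.full_like(eh, biomass_level)
    if params.eh_noise_sd > 0:
        fe2_meas = fe_total * (1.0 - fe3_fraction_from_eh(eh, params.calibration))
    else:
        fe2_meas = fe2
    return BioreductionSeries(times=sim.times, fe2=fe2_meas, eh=eh,
                              fe_total=fe_total, cells=cells)


def _active_phase_end(params: SyntheticBatchParams, biomass_level: float) -> int:
    """Last sample index of the active bioreduction phase.

    The phase ends when the true Fe(III) pool is effectively exhausted
    (below 1 % of the initial charge); afterwards the Fe(II) trace is a
    plateau that would dilute the mean-rate estimate.
    """
    sim = _simulate_level(params, biomass_level)
    active = np.nonzero(sim["fe3"] > 0.01 * params.fe3_0)[0]
    return max(int(active[-1]) if active.size else 1, 1)


def generate_rate_law_dataset(params: SyntheticBatchParams, replicates: int = 1,
                              n_experiments: int | None = None
                              ) -> list[tuple[float, float]]:
    """(biomass, mean rate) pairs from synthetic batch experiments.

    Applies the mean-rate estimator over the active bioreduction phase of
    each generated series. With `n_experiments` the biomass levels are
    cycled until that many experiments exist (replicate index advancing
    each cycle); otherwise each level is run `replicates` times.
    """
    if len(params.biomass_levels) < 2:
        raise ValueError("need at least two biomass levels to span a rate law")
    if n_experiments is None:
        runs = [(lvl, rep) for rep in range(replicates) for lvl in params.biomass_levels]
    else:
        runs = [(params.biomass_levels[i % len(params.biomass_levels)],
                 i // len(params.biomass_levels)) for i in range(n_experiments)]
    pairs = []
    end_cache: dict[float, int] = {}
    for level, rep in runs:
        if level not in end_cache:
            end_cache[level] = _active_phase_end(params, level)
        series = generate_batch_experiment(params, level, replicate=rep)
        biomass = float(np.mean(series.cells))
        pairs.append((biomass, mean_rate(series, 0, end_cache[level])))
    return pairs


def generate_cascade_tables(growth: GrowthReactorConfig,
                            reduction: ReductionReactorConfig,
                            noise: float = 0.0, seed: int = 0,
                            fe2_in_pulp: float = 0.0,
                            calibration: RedoxCalibration = DEFAULT_CALIBRATION):
    """Steady-state pilot tables: nutrient records plus reactor snapshots.

    Returns ``(nutrient_records, summary)`` where `nutrient_records` maps
    the growth-reactor outlet measurements to NutrientRecord objects
    (inlet from the feed medium, outlet from the chemostat steady state
    times multiplicative lognormal noise of the given sigma) and `summary`
    is a monitoring-style snapshot of both reactors (HRTs, biomass, Fe
    speciation and redox potential of the bioreduction stage). With zero
    noise the records round-trip exactly through the nutrient-flux
    analysis to the configured per-cell uptakes.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    r1 = simulate_growth_reactor(growth, duration=3000.0, step=50.0)
    x_star = r1.steady_state["biomass"]
    inlet = {"fe3": 0.0, "fe2": fe2_in_pulp, "biomass": x_star}
    r2 = steady_state(reduction, inlet)

    def noisy(x: float) -> float:
        return x * rng.lognormal(0.0, noise) if noise > 0 else x

    records = []
    for sp, c_in in growth.inlet.items():
        outlet = noisy(r1.steady_state[sp])
        records.append(NutrientRecord(sp, c_in, outlet, MOLAR_MASS.get(sp, 1.0)))

    fe3_frac = r2["fe3_fraction"]
    eh = float(eh_from_ratio(max(fe3_frac, 1e-12) / max(1.0 - fe3_frac, 1e-12),
                             calibration)) if 0 < fe3_frac < 1 else float("nan")
    summary = {
        "R1": {"hrt_h": growth.hrt, "biomass_cells_mL": noisy(x_star)},
        "R2": {
            "hrt_h": reduction.hrt,
            "biomass_cells_mL": noisy(r2["biomass"]),
            "fe_total_mg_L": noisy(r2["fe_total"]),
            "fe3_fraction": fe3_frac,
            "eh_mV": eh,
            "reduction_rate_mg_L_h": r2["rate"],
        },
    }
    return records, summary
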