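"""Synthetic cohorts with known ground truth.

Everything downstream — growth-curve scoring, ELISA aggregation, the
population mixed model — is exercised on data from this module, so each
generated quantity carries its latent truth.

The generative model, per animal:

* a latent log nAb level = population mean + a shared random intercept for
  the animal's sex + individual noise (lognormal signal: ELISA ODs are
  positive and right-skewed);
* a killing strength that increases linearly with latent log nAb plus
  independent noise; positive killing strength delays the bacterial growth
  lag by that many hours. Complete suppression ("absolute killing") is
  emergent — a delay long enough that no growth is observable within the
  incubation horizon — not assigned directly;
* growth curves follow the plate-reader phenomenology: flat lag, linear
  rise, plateau at carrying capacity, with truncated Gaussian read noise;
* ELISA replicate wells scatter around the latent signal with a fixed
  coefficient of variation; competition wells lose a Beta-distributed
  fraction of signal (parameterised by mean and sd); total IgM is
  constructed to realise a chosen squared correlation with the measured
  nAb signal.

Plasma-free control curves (four per run) and heat-inactivated aliquots,
whose killing effect is removed, are included so control-relative scoring
can run end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bka import CurveRole, GrowthCurve
from .config import DEFAULT_TIME_GRID
from .elisa import ElisaPlate, WellInfo, WellRole

_SEED_CAP = 2**31 - 1


@dataclass(frozen=True)
class GrowthModelParams:
    """Parameters of one simulated growth curve.

    The noiseless model is piecewise linear: OD stays at ``baseline_od``
    until ``lag_h``, rises at ``rate`` OD/h, and plateaus at
    ``carrying_capacity``. With ``killed`` set, growth is fully suppressed
    and OD stays at baseline throughout. ``shape='logistic'`` swaps in a
    logistic curve with matched midpoint and maximal slope, for robustness
    checks of the linear-phase estimator.
    """

    baseline_od: float = 0.05
    carrying_capacity: float = 0.9
    lag_h: float = 3.0
    rate: float = 0.1
    noise_sd: float = 0.0
    killed: bool = False
    shape: str = "piecewise"

    def __post_init__(self) -> None:
        if self.baseline_od < 0:
            raise ValueError("baseline_od must be >= 0")
        if not self.killed and self.carrying_capacity <= self.baseline_od:
            raise ValueError("carrying_capacity must exceed baseline_od")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        if self.shape not in ("piecewise", "logistic"):
            raise ValueError(f"unknown shape {self.shape!r}")


def model_od(params: GrowthModelParams, times: np.ndarray) -> np.ndarray:
    """Noiseless model OD at ``times`` (hours)."""
    t = np.asarray(times, dtype=float)
    if params.killed:
        return np.full_like(t, params.baseline_od)
    if params.shape == "piecewise":
        od = params.baseline_od + params.rate * np.clip(t - params.lag_h, 0.0, None)
        return np.minimum(od, params.carrying_capacity)
    # logistic with the same midpoint and max slope as the piecewise ramp
    b, k = params.baseline_od, params.carrying_capacity
    t_mid = params.lag_h + (k - b) / (2.0 * params.rate)
    growth_rate = 4.0 * params.rate / (k - b)
    return b + (k - b) / (1.0 + np.exp(-growth_rate * (t - t_mid)))


def true_crossing_time(params: GrowthModelParams, threshold: float) -> float | None:
    """Analytic time at which the noiseless model crosses ``threshold``.

    ``None`` when the curve never reaches the threshold (suppressed, or
    carrying capacity below it, or baseline already above it).
    """
    if params.killed or params.carrying_capacity < threshold:
        return None
    if params.baseline_od >= threshold:
        return None
    if params.shape == "piecewise":
        return params.lag_h + (threshold - params.baseline_od) / params.rate
    b, k = params.baseline_od, params.carrying_capacity
    t_mid = params.lag_h + (k - b) / (2.0 * params.rate)
    growth_rate = 4.0 * params.rate / (k - b)
    frac = (threshold - b) / (k - b)
    return t_mid - math.log(1.0 / frac - 1.0) / growth_rate if frac < 1 else None


def simulate_growth_curve(
    params: GrowthModelParams,
    times: Sequence[float] = DEFAULT_TIME_GRID,
    seed: int = 0,
    sample_id: str = "sim",
    role: CurveRole = CurveRole.PLASMA,
) -> GrowthCurve:
    """One growth curve on a read schedule, with truncated Gaussian noise.

    Reads are the noiseless model OD plus N(0, ``noise_sd``) noise,
    truncated at zero (a plate reader cannot report negative absorbance).
    The same parameters, times and seed always give identical output.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ValueError("need at least 3 read times")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed)
    od = model_od(params, t)
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, size=t.size)
    od = np.clip(od, 0.0, None)
    return GrowthCurve(sample_id=sample_id, role=role, times=tuple(t), od=tuple(od))


@dataclass(frozen=True)
class CohortSimConfig:
    """Knobs of the cohort generator.

    Defaults reproduce the structure of the field study being emulated:
    two desert bighorn sheep populations of 43 and 50 animals, the second
    with higher mean nAb; a sex random intercept; a killing strength that
    rises with latent nAb steeply enough that roughly half the low-nAb
    population shows no killing while a fifth of the high-nAb population
    suppresses growth completely; six antigen-competition pairs losing on
    average 93% of signal (sd 12%); duplicate ELISA wells at 10% CV; and a
    total-IgM variable sharing 25% of its variance with the reactive-nAb
    signal.
    """

    n_per_population: tuple[int, int] = (43, 50)
    population_labels: tuple[str, str] = ("Mojave", "Peninsular")
    population_nab_means: tuple[float, float] = (-0.8, -0.2)  # latent ln A450
    individual_sd: float = 0.5
    sex_effect_sd: float = 0.3
    nab_killing_slope: float = 7.0  # hours of growth delay per ln-unit nAb
    killing_pivot: float = -0.75  # latent ln nAb at which delay crosses zero
    killing_noise_sd: float = 2.8  # hours
    target_igm_r2: float = 0.25
    competition_reduction_mean: float = 0.93
    competition_reduction_sd: float = 0.12
    n_competition_pairs: int = 6
    replicate_cv: float = 0.10
    n_replicates: int = 2  # wells per sample; 3 mirrors the validation assay
    n_controls: int = 4
    n_heat_inactivated: int = 6
    hi_lag_advantage_h: float = 0.3  # heat-inactivated plasma enriches the medium
    od_noise_sd: float = 0.01
    total_igm_mean: float = 2.0  # mg/ml
    total_igm_sd: float = 0.5
    plate_effect_sd: float = 0.0  # optional per-plate intercept, off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_population) < 2:
            raise ValueError("need at least 2 animals per population")
        for name in ("individual_sd", "sex_effect_sd", "killing_noise_sd",
                     "competition_reduction_sd", "replicate_cv", "od_noise_sd",
                     "plate_effect_sd", "total_igm_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.target_igm_r2 <= 1.0:
            raise ValueError("target_igm_r2 must be in [0, 1]")
        if not 0.0 <= self.competition_reduction_mean <= 1.0:
            raise ValueError("competition_reduction_mean must be in [0, 1]")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass(frozen=True)
class SimulatedCohort:
    """Everything one simulated study run produces."""

    curves: list[GrowthCurve]
    plates: list[ElisaPlate]
    cohort: pd.DataFrame  # sample_id, population, sex, nab_a450, total_igm
    truth: dict  # per-animal latents, true crossing times and classes


def _beta_from_moments(mean: float, sd: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Beta draws with the requested mean and sd (degenerate when sd = 0)."""
    if sd == 0:
        return np.full(size, mean)
    var = sd**2
    max_var = mean * (1.0 - mean)
    if var >= max_var:
        raise ValueError("competition sd too large for a fraction with that mean")
    nu = max_var / var - 1.0
    return rng.beta(mean * nu, (1.0 - mean) * nu, size=size)


class _PlateBuilder:
    """Fills 8x12 plates well by well, seeding backgrounds on each new plate."""

    def __init__(self, rng: np.random.Generator, plate_effect_sd: float):
        self.rng = rng
        self.plate_effect_sd = plate_effect_sd
        self.plates: list[tuple[np.ndarray, dict[str, WellInfo]]] = []
        self._cursor = 96  # force a new plate on first write

    def _new_plate(self) -> None:
        grid = np.zeros((8, 12))
        layout: dict[str, WellInfo] = {}
        self.plates.append((grid, layout))
        self._cursor = 0
        self._offset = (
            self.rng.normal(0.0, self.plate_effect_sd) if self.plate_effect_sd > 0 else 0.0
        )
        for i, role in enumerate(
            [WellRole.BSA_BLANK] * 3 + [WellRole.SECONDARY_ONLY] * 3
        ):
            base = 0.05 if role is WellRole.BSA_BLANK else 0.08
            self._put(role, max(base + self.rng.normal(0, 0.01), 0.0))

    def _put(self, role: WellRole, value: float, **info) -> None:
        if self._cursor >= 96:
            self._new_plate()
        grid, layout = self.plates[-1]
        r, c = divmod(self._cursor, 12)
        well = f"{'ABCDEFGH'[r]}{c + 1}"
        grid[r, c] = max(value + getattr(self, "_offset", 0.0), 0.0)
        layout[well] = WellInfo(role=role, **info)
        self._cursor += 1

    def add_sample(self, sample_id: str, values: Sequence[float]) -> None:
        for i, v in enumerate(values):
            self._put(WellRole.SAMPLE, v, sample_id=sample_id, replicate=i)

    def add_competition(self, sample_id: str, values: Sequence[float], paired: str) -> None:
        for i, v in enumerate(values):
            self._put(
                WellRole.COMPETITION, v, sample_id=sample_id, replicate=i,
                paired_sample_id=paired,
            )

    def add_standards(self, concs: Sequence[float], ods: Sequence[float]) -> None:
        for conc, od in zip(concs, ods):
            self._put(WellRole.STANDARD, od, concentration=conc)

    def build(self) -> list[ElisaPlate]:
        return [ElisaPlate(wells=grid, layout=layout) for grid, layout in self.plates]


def simulate_cohort(config: CohortSimConfig = CohortSimConfig()) -> SimulatedCohort:
    """Draw one full study: growth curves, ELISA plates, cohort table, truth.

    Identical configs (including seed) give byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    base = GrowthModelParams(noise_sd=config.od_noise_sd)
    horizon = float(DEFAULT_TIME_GRID[-1])

    # --- animals -----------------------------------------------------------
    pops, ns = config.population_labels, config.n_per_population
    populations = [pops[0]] * ns[0] + [pops[1]] * ns[1]
    n = len(populations)
    ids = [f"BHS{i + 1:03d}" for i in range(n)]
    sexes = list(rng.choice(["F", "M"], size=n))
    if len(set(sexes)) == 1:  # degenerate tiny cohorts: force both sexes
        sexes[0] = "M" if sexes[0] == "F" else "F"
    sex_u = {"F": rng.normal(0, config.sex_effect_sd), "M": rng.normal(0, config.sex_effect_sd)}
    pop_mean = dict(zip(pops, config.population_nab_means))
    latent = np.array(
        [
            pop_mean[p] + sex_u[s] + rng.normal(0, config.individual_sd)
            for p, s in zip(populations, sexes)
        ]
    )
    signal = np.exp(latent)

    # killing strength -> growth-lag delay; suppression is emergent
    strength = (
        config.nab_killing_slope * (latent - config.killing_pivot)
        + rng.normal(0, config.killing_noise_sd, size=n)
    )
    # plasma without net killing behaves like heat-inactivated plasma: a
    # small nutrient boost, so non-killers cross slightly before controls
    delay = np.clip(strength, -config.hi_lag_advantage_h, None)

    # --- growth curves -----------------------------------------------------
    curves: list[GrowthCurve] = []
    true_cross: dict[str, float | None] = {}
    control_cross = true_crossing_time(base, 0.3)
    for j in range(config.n_controls):
        curves.append(
            simulate_growth_curve(
                base, DEFAULT_TIME_GRID, seed=int(rng.integers(_SEED_CAP)),
                sample_id=f"CTRL{j + 1}", role=CurveRole.CONTROL,
            )
        )
    for aid, d in zip(ids, delay):
        lag = base.lag_h + float(d)
        params = replace(base, lag_h=min(lag, horizon), killed=lag >= horizon)
        curves.append(
            simulate_growth_curve(
                params, DEFAULT_TIME_GRID, seed=int(rng.integers(_SEED_CAP)),
                sample_id=aid, role=CurveRole.PLASMA,
            )
        )
        true_cross[aid] = true_crossing_time(params, 0.3)
    hi_ids = ids[: config.n_heat_inactivated]
    hi_params = replace(base, lag_h=max(base.lag_h - config.hi_lag_advantage_h, 0.0))
    for aid in hi_ids:
        curves.append(
            simulate_growth_curve(
                hi_params, DEFAULT_TIME_GRID, seed=int(rng.integers(_SEED_CAP)),
                sample_id=aid, role=CurveRole.HEAT_INACTIVATED,
            )
        )

    def true_class(t: float | None) -> str:
        if t is None or t > horizon:
            return "absolute_killing"
        return "no_killing" if t <= control_cross else "intermediate_killing"

    # --- ELISA plates ------------------------------------------------------
    builder = _PlateBuilder(rng, config.plate_effect_sd)
    std_concs = [25.0 * 2**i for i in range(8)]  # ng/ml, 2-fold kit series
    std_truth = (0.05, 1.0, 400.0, 3.0)  # 4PL a, b, c, d
    std_ods = [
        max(std_truth[3] + (std_truth[0] - std_truth[3]) / (1 + (c / std_truth[2]) ** std_truth[1])
            + rng.normal(0, 0.01), 0.0)
        for c in std_concs for _ in (0, 1)
    ]
    builder.add_standards([c for c in std_concs for _ in (0, 1)], std_ods)

    def noisy_wells(mean: float, k: int | None = None) -> list[float]:
        k = config.n_replicates if k is None else k
        return [max(mean * (1.0 + rng.normal(0, config.replicate_cv)), 1e-3) for _ in range(k)]

    measured = np.empty(n)
    for i, (aid, s) in enumerate(zip(ids, signal)):
        wells = noisy_wells(float(s))
        builder.add_sample(aid, wells)
        measured[i] = float(np.mean(wells))

    comp_idx = rng.choice(n, size=min(config.n_competition_pairs, n), replace=False)
    reductions = _beta_from_moments(
        config.competition_reduction_mean, config.competition_reduction_sd, rng, comp_idx.size
    )
    comp_truth = {}
    for i, r in zip(comp_idx, reductions):
        aid = ids[int(i)]
        builder.add_competition(aid, noisy_wells(float(signal[i] * (1.0 - r))), paired=aid)
        comp_truth[aid] = float(r)
    plates = builder.build()

    # --- total IgM with the target squared correlation ---------------------
    z = (measured - measured.mean()) / measured.std()
    e = rng.normal(size=n)
    e -= z * (e @ z) / (z @ z)  # orthogonalise so the realised r2 is exact
    e /= e.std()
    r2 = config.target_igm_r2
    igm_z = math.sqrt(r2) * z + math.sqrt(1.0 - r2) * e
    total_igm = np.clip(config.total_igm_mean + config.total_igm_sd * igm_z, 1e-3, None)

    cohort = pd.DataFrame(
        {
            "sample_id": ids,
            "population": populations,
            "sex": sexes,
            "nab_a450": measured,
            "total_igm": total_igm,
        }
    )
    truth = {
        "control_crossing_h": control_cross,
        "sex_intercepts": sex_u,
        "animals": {
            aid: {
                "latent_log_nab": float(l),
                "killing_delay_h": float(d),
                "true_crossing_h": true_cross[aid],
                "true_class": true_class(true_cross[aid]),
            }
            for aid, l, d in zip(ids, latent, delay)
        },
        "competition_reductions": comp_truth,
        "heat_inactivated_ids": hi_ids,
        "standard_curve_params": std_truth,
    }
    return SimulatedCohort(curves=curves, plates=plates, cohort=cohort, truth=truth)
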