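"""Synthetic factorial fermentation experiments.

Generates complete strain x must x micro-oxygenation designs with the
statistical structure the downstream analysis assumes: every generative
kinetic parameter and every end-point metabolite is built additively from
grand mean, strain, must and micro-oxygenation main effects plus
strain x must and strain x micro-oxygenation interactions, with i.i.d.
Gaussian residuals (the same linear model the ANOVA stage fits).  Each
vial's CO2 trajectory is a delayed logistic sampled at realistic manual
weighing times (2-3 weighings/day) with additive balance noise, so the
kinetic extraction stage can be benchmarked against closed-form truth.

The reference design is 4 strains x 2 musts x 2 oxygenation levels x 10
replicates = 160 vials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import FermentationRecord, KineticParams, LAG_CO2_THRESHOLD
from .must import CO2_YIELD, MustComposition, REFERENCE_MUSTS

__all__ = [
    "CurveParams",
    "SimulationDesign",
    "TraitEffects",
    "EffectModel",
    "simulate_curve",
    "simulate_experiment",
    "ExperimentData",
]

#: Names of the generative kinetic parameters handled by the effect model.
#: ``lp`` is the fermentation onset (h), ``t50`` the onset-to-inflection time
#: (h), ``slope`` the logistic rate (1/h), ``co2max`` the plateau (g/L).
KINETIC_GENERATIVE = ("lp", "t50", "slope", "co2max")


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one vial's true (noise-free) CO2 trajectory.

    The trajectory is a delayed logistic: zero up to ``onset`` hours, then
    ``co2max * (f(t - onset) - f(0)) / (1 - f(0))`` with
    ``f(u) = 1 / (1 + exp(-rate * (u - inflection)))`` — continuous at the
    onset and saturating at ``co2max``.
    """

    onset: float
    inflection: float
    rate: float
    co2max: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.co2max <= 0:
            raise ValueError(f"co2max must be > 0, got {self.co2max}")
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")

    def _f0(self) -> float:
        return 1.0 / (1.0 + math.exp(self.rate * self.inflection))

    def co2(self, t: np.ndarray) -> np.ndarray:
        """True cumulative CO2 release (g/L) at times ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        f0 = self._f0()
        u = t - self.onset
        f = 1.0 / (1.0 + np.exp(-self.rate * (u - self.inflection)))
        c = self.co2max * (f - f0) / (1.0 - f0)
        return np.where(t <= self.onset, 0.0, c)

    def time_to_release(self, level: float) -> float:
        """Closed-form time (h) at which the trajectory reaches ``level`` g/L."""
        if level <= 0:
            return self.onset
        if level >= self.co2max:
            return float("nan")
        f0 = self._f0()
        nu = f0 + (level / self.co2max) * (1.0 - f0)
        return self.onset + self.inflection - math.log(1.0 / nu - 1.0) / self.rate

    def true_kinetics(self, tco2max: float) -> KineticParams:
        """Analytic kinetic traits of the noise-free trajectory.

        The same definitions the extraction stage applies to smoothed data,
        evaluated exactly — the oracle for parameter-recovery benchmarks.
        """
        lp = self.time_to_release(LAG_CO2_THRESHOLD)
        t35 = self.time_to_release(0.35 * tco2max)
        t50 = self.time_to_release(0.50 * tco2max)
        t80 = self.time_to_release(0.80 * tco2max)
        flags: set[str] = set()
        if math.isnan(lp):
            flags.add("NO_LAG_REACHED")
        if math.isnan(t80):
            flags.add("STUCK")
        if not math.isnan(lp):
            t35, t50, t80 = t35 - lp, t50 - lp, t80 - lp
        if not (math.isnan(t50) or math.isnan(t80)) and t80 > t50:
            v = (0.30 * tco2max / CO2_YIELD) / (t80 - t50)
        else:
            v = float("nan")
        return KineticParams(
            lp=lp, t35=t35, t50=t50, t80=t80, v50_80=v,
            co2max=self.co2max, tco2max=tco2max, flags=frozenset(flags),
        )


@dataclass(frozen=True)
class SimulationDesign:
    """Factorial layout and measurement-process settings of an experiment."""

    strains: tuple[str, ...] = ("M2", "GN", "F15", "SB")
    musts: tuple[MustComposition, ...] = tuple(m for m in REFERENCE_MUSTS if m.code in ("SB14", "M15"))
    shaking_levels: tuple[bool, ...] = (False, True)
    replicates: int = 10
    volume_ml: float = 5.0
    weighing_frequency: float = 2.5  # mean weighings per day
    balance_noise_sd: float = 0.002  # g, precision-balance repeatability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.strains or not self.musts or not self.shaking_levels:
            raise ValueError("strains, musts and shaking_levels must be non-empty")
        if self.weighing_frequency <= 0 or self.volume_ml <= 0:
            raise ValueError("weighing_frequency and volume_ml must be > 0")
        if self.balance_noise_sd < 0:
            raise ValueError("balance_noise_sd must be >= 0")

    @property
    def n_vials(self) -> int:
        return len(self.strains) * len(self.musts) * len(self.shaking_levels) * self.replicates

    def cells(self) -> Iterable[tuple[str, MustComposition, bool, int]]:
        for strain in self.strains:
            for must in self.musts:
                for shaking in self.shaking_levels:
                    for rep in range(1, self.replicates + 1):
                        yield strain, must, shaking, rep


def _center_main(effects: Mapping[str, float], levels: Sequence) -> dict:
    vals = {lv: float(effects.get(lv, 0.0)) for lv in levels}
    mean = sum(vals.values()) / len(vals)
    return {lv: v - mean for lv, v in vals.items()}


def _center_interaction(
    effects: Mapping[tuple, float], rows: Sequence, cols: Sequence
) -> dict:
    a = np.array([[float(effects.get((r, c), 0.0)) for c in cols] for r in rows])
    a = a - a.mean(axis=1, keepdims=True)
    a = a - a.mean(axis=0, keepdims=True)
    return {(r, c): a[i, j] for i, r in enumerate(rows) for j, c in enumerate(cols)}


@dataclass(frozen=True)
class TraitEffects:
    """Additive effect decomposition for one trait (sum-to-zero coded)."""

    mean: float
    strain: Mapping[str, float] = field(default_factory=dict)
    must: Mapping[str, float] = field(default_factory=dict)
    mox: Mapping[bool, float] = field(default_factory=dict)
    strain_x_must: Mapping[tuple, float] = field(default_factory=dict)
    strain_x_mox: Mapping[tuple, float] = field(default_factory=dict)
    resid_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be >= 0")

    def value(self, strain: str, must_code: str, shaking: bool) -> float:
        """Deterministic (noise-free) trait value for one design cell."""
        return (
            self.mean
            + self.strain.get(strain, 0.0)
            + self.must.get(must_code, 0.0)
            + self.mox.get(shaking, 0.0)
            + self.strain_x_must.get((strain, must_code), 0.0)
            + self.strain_x_mox.get((strain, shaking), 0.0)
        )


class EffectModel:
    """Per-trait additive effect models driving the generator.

    ``kinetic`` maps the four generative curve parameters (``lp``, ``t50``,
    ``slope``, ``co2max``) to :class:`TraitEffects`; ``metabolites`` maps
    end-point trait names (e.g. ``Glycerol``) to theirs.  Effects are
    validated to sum to zero within each factor (and across each margin of
    the interactions), the identifiable parameterization.
    """

    def __init__(
        self,
        kinetic: Mapping[str, TraitEffects],
        metabolites: Mapping[str, TraitEffects],
        *,
        check: bool = True,
    ):
        missing = set(KINETIC_GENERATIVE) - set(kinetic)
        if missing:
            raise ValueError(f"kinetic effects missing traits: {sorted(missing)}")
        self.kinetic = dict(kinetic)
        self.metabolites = dict(metabolites)
        if check:
            for name, te in {**self.kinetic, **self.metabolites}.items():
                self._check_trait(name, te)

    @staticmethod
    def _check_trait(name: str, te: TraitEffects, tol: float = 1e-8) -> None:
        for factor in ("strain", "must", "mox"):
            vals = list(getattr(te, factor).values())
            if vals and abs(sum(vals)) > tol * max(1.0, max(abs(v) for v in vals)):
                raise ValueError(f"trait {name!r}: {factor} effects do not sum to zero")
        for factor in ("strain_x_must", "strain_x_mox"):
            eff = getattr(te, factor)
            if not eff:
                continue
            rows = sorted({k[0] for k in eff}, key=str)
            cols = sorted({k[1] for k in eff}, key=str)
            a = np.array([[eff.get((r, c), 0.0) for c in cols] for r in rows])
            scale = max(1.0, np.abs(a).max())
            if np.abs(a.sum(axis=0)).max() > tol * scale or np.abs(a.sum(axis=1)).max() > tol * scale:
                raise ValueError(f"trait {name!r}: {factor} margins do not sum to zero")

    def check_design(self, design: SimulationDesign) -> None:
        """Raise if any effect refers to a factor level absent from the design."""
        strains = set(design.strains)
        musts = {m.code for m in design.musts}
        for name, te in {**self.kinetic, **self.metabolites}.items():
            bad = (set(te.strain) - strains) | (set(te.must) - musts)
            bad |= {k for k in te.strain_x_must if k[0] not in strains or k[1] not in musts}
            bad |= {k for k in te.strain_x_mox if k[0] not in strains}
            if bad:
                raise ValueError(f"trait {name!r}: effects reference unknown levels {sorted(map(str, bad))}")

    @classmethod
    def reference(cls, design: SimulationDesign | None = None) -> "EffectModel":
        """Default effect model for the reference 4 x 2 x 2 x 10 design.

        Magnitudes emulate the field's typical findings for these traits:
        strain dominates the lag phase, must and micro-oxygenation dominate
        mid-fermentation speed, shaking raises glycerol production by about
        15 % and lowers acetic acid, and residual malic acid is almost
        entirely a must effect.
        """
        if design is None:
            design = SimulationDesign()
        strains = list(design.strains)
        musts = [m.code for m in design.musts]
        shakes = list(design.shaking_levels)

        def spread(levels, half_range):
            n = len(levels)
            if n == 1:
                return {levels[0]: 0.0}
            vals = np.linspace(-half_range, half_range, n)
            return _center_main(dict(zip(levels, vals)), levels)

        def mox_eff(delta):
            # delta = effect of shaking relative to still, split sum-to-zero
            return _center_main({True: delta / 2, False: -delta / 2}, shakes) if len(shakes) > 1 else {shakes[0]: 0.0}

        # co2max plateau tracks each must's sugar (≈97 % of tCO2max: completed
        # fermentations finish near the stoichiometric maximum)
        tco2 = {m.code: m.tco2max for m in design.musts}
        co2max_mean = 0.97 * float(np.mean(list(tco2.values())))
        co2max_must = _center_main({c: 0.97 * t - co2max_mean for c, t in tco2.items()}, musts)

        sxm_lp = _center_interaction(
            {(strains[0], musts[0]): 2.5} if len(strains) > 1 and len(musts) > 1 else {},
            strains, musts,
        )
        sxo_lp = _center_interaction(
            {(strains[0], True): -1.2} if len(strains) > 1 and len(shakes) > 1 else {},
            strains, shakes,
        )

        kinetic = {
            "lp": TraitEffects(6.0, spread(strains, 3.0), spread(musts, 1.0), mox_eff(-1.0),
                               sxm_lp, sxo_lp, resid_sd=0.8),
            "t50": TraitEffects(45.0, spread(strains, 5.0), spread(musts, 8.0), mox_eff(-12.0),
                                resid_sd=2.0),
            "slope": TraitEffects(0.080, spread(strains, 0.015), spread(musts, 0.008),
                                  mox_eff(0.012), resid_sd=0.003),
            "co2max": TraitEffects(co2max_mean, spread(strains, 1.0), co2max_must,
                                   mox_eff(1.5), resid_sd=0.8),
        }
        metabolites = {
            "Glycerol": TraitEffects(5.2, spread(strains, 0.6), spread(musts, 0.15),
                                     mox_eff(0.78), resid_sd=0.25),
            "Acetic acid": TraitEffects(0.42, spread(strains, 0.06), spread(musts, 0.07),
                                        mox_eff(-0.08),
                                        strain_x_mox=_center_interaction(
                                            {(strains[-1], True): 0.05} if len(strains) > 1 and len(shakes) > 1 else {},
                                            strains, shakes),
                                        resid_sd=0.05),
            "Malic acid": TraitEffects(1.6, spread(strains, 0.25), spread(musts, 1.0),
                                       resid_sd=0.15),
            "SO2": TraitEffects(32.0, spread(strains, 3.0), spread(musts, 5.0), mox_eff(9.0),
                                resid_sd=4.0),
            "Pyruvate": TraitEffects(150.0, spread(strains, 18.0), spread(musts, 10.0),
                                     mox_eff(12.0), resid_sd=40.0),
        }
        return cls(kinetic, metabolites)


def _weighing_times(rng: np.random.Generator, horizon: float, frequency: float) -> np.ndarray:
    """Jittered manual weighing schedule over [0, horizon] hours.

    Gaps between weighings are gamma-distributed with mean 24/frequency and
    ~30 % coefficient of variation, starting from a weighing at inoculation.
    """
    mean_gap = 24.0 / frequency
    shape = 1.0 / 0.3**2
    times = [0.0]
    t = 0.0
    while t < horizon:
        t += rng.gamma(shape, mean_gap / shape)
        times.append(t)
    return np.asarray(times)


def simulate_curve(
    true_params: CurveParams,
    *,
    vial_id: str,
    strain: str,
    must: MustComposition,
    shaking: bool,
    replicate: int,
    volume_ml: float = 5.0,
    weighing_frequency: float = 2.5,
    balance_noise_sd: float = 0.002,
    initial_weight: float = 20.0,
    rng: np.random.Generator | int | None = None,
) -> FermentationRecord:
    """Simulate one vial's weighing log from a true CO2 trajectory.

    Monitoring emulates a fermentation followed to completion: the weighing
    horizon extends one day past the time the trajectory reaches 99.5 % of
    its plateau, so the plateau itself is observed.  Each reading carries
    additive Gaussian balance noise.  Raises if the trajectory's plateau
    exceeds the must's stoichiometric CO2 maximum.
    """
    if true_params.co2max > must.tco2max * (1 + 1e-9):
        raise ValueError(
            f"vial {vial_id}: plateau {true_params.co2max:.2f} g/L exceeds the "
            f"must's tCO2max {must.tco2max:.2f} g/L"
        )
    rng = np.random.default_rng(rng)
    horizon = true_params.time_to_release(0.995 * true_params.co2max) + 24.0
    times = _weighing_times(rng, horizon, weighing_frequency)
    co2 = true_params.co2(times)
    weights = initial_weight - co2 * (volume_ml / 1000.0)
    if balance_noise_sd > 0:
        weights = weights + rng.normal(0.0, balance_noise_sd, size=weights.shape)
    return FermentationRecord(
        vial_id=vial_id, strain=strain, must_code=must.code, shaking=shaking,
        volume=volume_ml, replicate=replicate, times=times, weights=weights,
    )


@dataclass(frozen=True)
class ExperimentData:
    """Output bundle of :func:`simulate_experiment`.

    ``records`` are the weighing logs; ``traits`` the end-point trait table
    (one row per vial: design labels + metabolite columns); ``truth`` the
    per-vial generative curve parameters and their analytic kinetic traits,
    for recovery benchmarks.
    """

    records: list[FermentationRecord]
    traits: pd.DataFrame
    truth: pd.DataFrame


def simulate_experiment(
    design: SimulationDesign,
    effects: EffectModel | None = None,
    *,
    simulate_weighings: bool = True,
) -> ExperimentData:
    """Generate a full factorial experiment under an additive effect model.

    Every generative kinetic parameter and metabolite value is
    ``mean + strain + must + mox + strain x must + strain x mox + noise``;
    the per-vial random streams are derived from ``design.seed`` with a
    counter so any subset of vials is reproducible in isolation.  Set
    ``simulate_weighings=False`` to skip the (comparatively costly) weighing
    logs when only end-point tables are needed.
    """
    if effects is None:
        effects = EffectModel.reference(design)
    effects.check_design(design)

    seed_seq = np.random.SeedSequence(design.seed)
    records: list[FermentationRecord] = []
    trait_rows, truth_rows = [], []
    for i, (strain, must, shaking, rep) in enumerate(design.cells()):
        child = np.random.SeedSequence(entropy=seed_seq.entropy, spawn_key=(i,))
        rng = np.random.default_rng(child)
        vial_id = f"V{i + 1:04d}"

        gen = {}
        for name in KINETIC_GENERATIVE:
            te = effects.kinetic[name]
            gen[name] = te.value(strain, must.code, shaking) + rng.normal(0.0, te.resid_sd)
        cp = CurveParams(
            onset=max(gen["lp"], 0.0),
            inflection=max(gen["t50"], 1.0),
            rate=max(gen["slope"], 1e-3),
            co2max=float(np.clip(gen["co2max"], 1.0, must.tco2max)),
        )
        if simulate_weighings:
            records.append(
                simulate_curve(
                    cp, vial_id=vial_id, strain=strain, must=must, shaking=shaking,
                    replicate=rep, volume_ml=design.volume_ml,
                    weighing_frequency=design.weighing_frequency,
                    balance_noise_sd=design.balance_noise_sd, rng=rng,
                )
            )

        base = {
            "vial_id": vial_id, "strain": strain, "must": must.code,
            "shaking": shaking, "replicate": rep,
        }
        row = dict(base)
        for name, te in effects.metabolites.items():
            row[name] = te.value(strain, must.code, shaking) + rng.normal(0.0, te.resid_sd)
        trait_rows.append(row)

        tk = cp.true_kinetics(must.tco2max)
        truth_rows.append({
            **base,
            "onset": cp.onset, "inflection": cp.inflection,
            "rate": cp.rate, "plateau": cp.co2max,
            **{k: v for k, v in tk.to_dict().items() if k != "flags"},
        })

    return ExperimentData(
        records=records,
        traits=pd.DataFrame(trait_rows),
        truth=pd.DataFrame(truth_rows),
    )
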