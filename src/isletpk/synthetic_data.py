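"""Synthetic-data generators.

Every input the pipeline consumes can be generated here with a declared noise
model and a mandatory seed, so the whole analysis is testable offline. All
generators are pure functions of (truth, schedule, noise.seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .blood_kinetics import BiexpDisposition, TimeActivityCurve, biexp_predict
from .plasma_model import InfusionProtocol, TwoCompParams, infusion_concentration
from .radiometrics import Isotope
from .tissue_model import PancreasModel, simulate_tissue_uptake

__all__ = [
    "NoiseSpec",
    "DEFAULT_BLEED_SCHEDULE_MIN",
    "gen_blood_samples",
    "gen_infusion_samples",
    "gen_pancreas_dataset",
]

#: Serial retro-orbital bleed schedule emulated by default (minutes).
DEFAULT_BLEED_SCHEDULE_MIN = (0.5, 1, 2, 4, 8, 15, 30, 60, 90, 120, 180)


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic contract of a generator.

    Gaussian proportional (CV) plus additive noise by default; ``lognormal``
    switches to multiplicative lognormal noise with the same CV, which keeps
    strictly positive data positive. The seed is mandatory.
    """

    seed: int
    proportional_cv: float = 0.0
    additive_sd: float = 0.0
    lognormal: bool = False

    def __post_init__(self) -> None:
        if self.proportional_cv < 0:
            raise ValueError("proportional_cv must be nonnegative")
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be nonnegative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")


def _apply_noise(mean: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    rng = np.random.default_rng(noise.seed)
    if noise.lognormal:
        sigma = np.sqrt(np.log1p(noise.proportional_cv**2))
        out = mean * rng.lognormal(-0.5 * sigma**2, sigma, size=mean.shape)
    else:
        out = mean * (1.0 + rng.normal(0.0, noise.proportional_cv, size=mean.shape))
    if noise.additive_sd > 0:
        out = out + rng.normal(0.0, noise.additive_sd, size=mean.shape)
    return np.clip(out, 0.0, None)


def _check_schedule(schedule: Sequence[float]) -> np.ndarray:
    t = np.asarray(schedule, dtype=float)
    if t.size == 0:
        raise ValueError("schedule must not be empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("schedule must be strictly increasing")
    return t


def gen_blood_samples(
    truth: BiexpDisposition,
    schedule: Sequence[float] = DEFAULT_BLEED_SCHEDULE_MIN,
    noise: NoiseSpec = NoiseSpec(seed=0),
    unit: str = "frac_c0",
    subject: str = "sim-mouse",
) -> TimeActivityCurve:
    """Serial blood samples drawn from a biexponential truth curve."""
    t = _check_schedule(schedule)
    mean = np.asarray(biexp_predict(truth, t), dtype=float)
    return TimeActivityCurve(
        times_min=t,
        values=_apply_noise(mean, noise),
        unit=unit,
        tissue="blood",
        subject=subject,
    )


def gen_infusion_samples(
    truth: TwoCompParams,
    proto: InfusionProtocol,
    schedule: Sequence[float],
    noise: NoiseSpec = NoiseSpec(seed=0),
    unit: str = "frac_c0",
    subject: str = "sim-patient",
) -> TimeActivityCurve:
    """Plasma samples under a constant-rate infusion of the truth model."""
    t = _check_schedule(schedule)
    mean = np.asarray(infusion_concentration(truth, proto, t), dtype=float)
    return TimeActivityCurve(
        times_min=t,
        values=_apply_noise(mean, noise),
        unit=unit,
        tissue="plasma",
        subject=subject,
    )


def gen_pancreas_dataset(
    model: PancreasModel,
    plasma: Union[BiexpDisposition, TwoCompParams],
    schedule: Sequence[float],
    noise: NoiseSpec = NoiseSpec(seed=0),
    isotope: Optional[Isotope] = None,
    unit: str = "%ID/g",
    snapshot_min: float = 180.0,
) -> dict:
    """Islet and exocrine TACs plus a biodistribution-style endpoint row.

    The schedule must include 0; the 3 h (configurable) snapshot reports the
    noise-free model value per tissue in the output unit. Returns a dict with
    keys ``islet``, ``exocrine`` (noisy TACs) and ``snapshot`` (per-tissue
    endpoint values).
    """
    t = _check_schedule(schedule)
    if t[0] != 0.0:
        raise ValueError("schedule must start at 0 for the uptake simulation")
    t_sim = t if snapshot_min <= t[-1] else np.append(t, snapshot_min)
    sim = simulate_tissue_uptake(model, plasma, t_sim, isotope=isotope, unit=unit)

    rng_seeds = np.random.SeedSequence(noise.seed).spawn(2)
    out: dict = {"snapshot": {}, "snapshot_min": snapshot_min}
    for sub_seed, name in zip(rng_seeds, ("islet", "exocrine")):
        clean = sim.tacs[name].values[: len(t)]
        sub_noise = NoiseSpec(
            seed=int(sub_seed.generate_state(1)[0]),
            proportional_cv=noise.proportional_cv,
            additive_sd=noise.additive_sd,
            lognormal=noise.lognormal,
        )
        out[name] = TimeActivityCurve(
            times_min=t,
            values=_apply_noise(clean, sub_noise),
            unit=unit,
            tissue=name,
            subject="sim-mouse",
        )
        snap_idx = int(np.argmin(np.abs(t_sim - snapshot_min)))
        out["snapshot"][name] = float(sim.tacs[name].values[snap_idx])
    return out
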