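"""Forward hemodynamic simulator and synthetic cohort generator.

The forward model runs the estimation chain in reverse: starting from a
ground-truth hemodynamic state (Ees, Ea, EDV, V0, Pad, PEP) it derives the
noninvasive observables that are exactly consistent with every model
equation simultaneously —

    r    = Ees/Ea
    SV   = EDV·r/(1+r)              (elastance definitions, V0 = 0)
    Pes  = Ea·SV
    Pmax = Pes·(1 + r)
    k    = 0.53·r^0.51
    ET   = PEP·(Pmax/Pad − 1)/k     (bilinear Pmax relation, inverted)
    DBP  = Pad
    SBP  = (Pes − 0.898·Pad − 0.4214)/0.205   (Pes regression, inverted)

so a noise-free observation, pushed back through the estimator, recovers
the ground-truth EDV to numerical precision.  The cohort generator samples
ground truths from configurable distributions, applies the forward model,
and adds independent Gaussian measurement noise to each observable.

The generator emulates a healthy young-adult cohort: defaults are chosen so
the emitted observables land near SBP 117±13 / DBP 73±9 mmHg, PEP 96±13 /
ET 286±77 ms, SV 61±13 ml, EDV ~95±15 ml.  SBP and DBP are tied through a
sampled pulse pressure; all other ground-truth draws are independent, so
further covariance structure of real cohorts is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import (
    K_COEF,
    K_EXP,
    PES_DBP_COEF,
    PES_INTERCEPT,
    PES_SBP_COEF,
    BeatObservation,
    InvalidInputError,
)

__all__ = [
    "GroundTruth",
    "Dist",
    "NoiseConfig",
    "CohortConfig",
    "InfeasibleGroundTruth",
    "simulate_forward",
    "generate_cohort",
]


class InfeasibleGroundTruth(ValueError):
    """The ground-truth state cannot produce a physiological observation."""


@dataclass(frozen=True)
class GroundTruth:
    """A simulated subject's true hemodynamic state.

    ``ees``/``ea`` in mmHg/ml, volumes in ml, ``pad`` in mmHg, ``pep`` in
    ms.  The exact forward–inverse round trip requires ``v0 = 0``.
    """

    ees: float
    ea: float
    edv: float
    pad: float
    pep: float
    v0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ees", "ea", "edv", "pad", "pep"):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.v0 < 0:
            raise InvalidInputError("v0 must be >= 0")

    @property
    def ratio(self) -> float:
        return self.ees / self.ea

    @property
    def sv(self) -> float:
        """Stroke volume implied by the elastance definitions."""
        r = self.ratio
        return (self.edv - self.v0) * r / (1.0 + r)


def simulate_forward(gt: GroundTruth, subject_id: str = "sim") -> BeatObservation:
    """Noise-free observables exactly consistent with the model equations.

    Raises :class:`InfeasibleGroundTruth` if the state would require a
    non-positive ejection time (Pmax <= Pad) or an inverted cuff pair
    (back-solved SBP <= DBP).
    """
    r = gt.ratio
    sv = gt.sv
    pes = gt.ea * sv
    pmax = pes * (1.0 + r)
    k = K_COEF * r**K_EXP
    if pmax <= gt.pad:
        raise InfeasibleGroundTruth(
            f"pmax ({pmax:.3g} mmHg) <= pad ({gt.pad:.3g} mmHg): "
            "would need negative ejection time"
        )
    et = gt.pep * (pmax / gt.pad - 1.0) / k
    dbp = gt.pad
    sbp = (pes - PES_DBP_COEF * dbp - PES_INTERCEPT) / PES_SBP_COEF
    if sbp <= dbp:
        raise InfeasibleGroundTruth(
            f"back-solved sbp ({sbp:.3g}) <= dbp ({dbp:.3g}) for pes={pes:.3g}: "
            "end-systolic pressure too low relative to pad"
        )
    return BeatObservation(
        subject_id=subject_id,
        sbp=sbp,
        dbp=dbp,
        pep=gt.pep,
        et=et,
        sv=sv,
        edv_ref=gt.edv,
    )


@dataclass(frozen=True)
class Dist:
    """A named 1-D sampling distribution with optional truncation bounds.

    ``family`` is "normal" (loc=mean, scale=sd), "uniform" (loc=low,
    scale=high−low) or "constant" (loc).  Truncation resamples, it does not
    clip, so no probability mass piles up at the bounds.
    """

    family: str
    loc: float
    scale: float = 0.0
    low: Optional[float] = None
    high: Optional[float] = None

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(1000):
            if self.family == "normal":
                x = rng.normal(self.loc, self.scale)
            elif self.family == "uniform":
                x = rng.uniform(self.loc, self.loc + self.scale)
            elif self.family == "constant":
                x = self.loc
            else:
                raise ValueError(f"unknown distribution family {self.family!r}")
            if (self.low is None or x >= self.low) and (
                self.high is None or x <= self.high
            ):
                return x
        raise RuntimeError(f"truncation bounds of {self} reject too many draws")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive zero-mean Gaussian measurement noise, one SD per observable.

    Pressures in mmHg, timings in ms, stroke volume in ml.  Defaults are
    typical cuff/Doppler repeatability magnitudes.
    """

    sbp_sd: float = 3.0
    dbp_sd: float = 3.0
    pep_sd: float = 5.0
    et_sd: float = 5.0
    sv_sd: float = 4.0

    def __post_init__(self) -> None:
        for f in ("sbp_sd", "dbp_sd", "pep_sd", "et_sd", "sv_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    def scaled(self, factor: float) -> "NoiseConfig":
        return NoiseConfig(
            *(getattr(self, f) * factor for f in ("sbp_sd", "dbp_sd", "pep_sd", "et_sd", "sv_sd"))
        )


@dataclass(frozen=True)
class CohortConfig:
    """Sampling laws, noise model, and seed for a synthetic cohort.

    Ground-truth laws: the coupling ratio, EDV, Pad, PEP and the pulse
    pressure (SBP − DBP) are sampled directly; SBP = Pad + pulse pressure,
    the true Pes follows from the cuff-pressure regression, and the
    elastance scale is then fixed by Ea = Pes/SV, Ees = ratio·Ea.  Sampling
    the pulse pressure rather than Pes itself keeps the systolic and
    diastolic pressures correlated the way cuff readings are, so the
    back-solved SBP has a realistic spread.  Draws whose forward model is
    infeasible (or whose noisy observation violates sbp > dbp, positive
    timings/volumes) are resampled up to ``max_resamples`` per subject.
    """

    n: int = 48
    seed: int = 0
    ratio: Dist = field(default_factory=lambda: Dist("uniform", 0.8, 1.7))  # 0.8–2.5
    edv: Dist = field(default_factory=lambda: Dist("normal", 95.0, 15.0, low=60.0, high=139.0))
    pad: Dist = field(default_factory=lambda: Dist("normal", 73.0, 9.0, low=45.0))
    pep: Dist = field(default_factory=lambda: Dist("normal", 96.0, 13.0, low=50.0))
    pulse_pressure: Dist = field(default_factory=lambda: Dist("normal", 44.0, 10.0, low=15.0))
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    v0: float = 0.0
    max_resamples: int = 1000

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


def _draw_ground_truth(cfg: CohortConfig, rng: np.random.Generator) -> GroundTruth:
    r = cfg.ratio.sample(rng)
    edv = cfg.edv.sample(rng)
    pad = cfg.pad.sample(rng)
    pep = cfg.pep.sample(rng)
    sbp = pad + cfg.pulse_pressure.sample(rng)
    pes = PES_SBP_COEF * sbp + PES_DBP_COEF * pad + PES_INTERCEPT
    sv = (edv - cfg.v0) * r / (1.0 + r)
    ea = pes / sv
    return GroundTruth(ees=r * ea, ea=ea, edv=edv, pad=pad, pep=pep, v0=cfg.v0)


def _add_noise(
    obs: BeatObservation, noise: NoiseConfig, rng: np.random.Generator
) -> BeatObservation:
    return replace(
        obs,
        sbp=obs.sbp + rng.normal(0.0, noise.sbp_sd) if noise.sbp_sd else obs.sbp,
        dbp=obs.dbp + rng.normal(0.0, noise.dbp_sd) if noise.dbp_sd else obs.dbp,
        pep=obs.pep + rng.normal(0.0, noise.pep_sd) if noise.pep_sd else obs.pep,
        et=obs.et + rng.normal(0.0, noise.et_sd) if noise.et_sd else obs.et,
        sv=obs.sv + rng.normal(0.0, noise.sv_sd) if noise.sv_sd else obs.sv,
    )


def _observation_feasible(obs: BeatObservation) -> bool:
    return (
        obs.sbp > obs.dbp > 0
        and obs.pep > 0
        and obs.et > 0
        and obs.sv > 0
        and (obs.edv_ref is None or obs.edv_ref > obs.sv)
    )


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[GroundTruth, BeatObservation]]:
    """Sample ``config.n`` (ground truth, noisy observation) pairs.

    Fully reproducible for a fixed seed.  Infeasible draws — ground truths
    the forward model rejects, or noisy observations violating basic
    ordering/positivity — are resampled; exceeding ``max_resamples`` for a
    subject raises a configuration error naming the margin.
    """
    rng = np.random.default_rng(config.seed)
    out: list[tuple[GroundTruth, BeatObservation]] = []
    resamples = 0
    for i in range(config.n):
        last_error = ""
        for _ in range(config.max_resamples):
            try:
                gt = _draw_ground_truth(config, rng)
                clean = simulate_forward(gt, subject_id=f"sim{i:04d}")
            except InfeasibleGroundTruth as exc:
                last_error = str(exc)
                resamples += 1
                continue
            noisy = _add_noise(clean, config.noise, rng)
            if not _observation_feasible(noisy):
                last_error = "noisy observation violated ordering/positivity"
                resamples += 1
                continue
            out.append((gt, noisy))
            break
        else:
            raise RuntimeError(
                f"subject {i}: resample cap {config.max_resamples} exceeded; "
                f"last infeasibility: {last_error}"
            )
    if resamples:
        import logging

        logging.getLogger(__name__).info(
            "cohort generation resampled %d infeasible draw(s)", resamples
        )
    return out
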