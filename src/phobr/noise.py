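"""Stationary noise statistics: coefficient of variation and Fano factor.

CV = sigma/mu measures overall relative variability; FF = sigma^2/mu
measures dispersion against the Poisson baseline (FF = CV^2 / CV_Poisson^2
with CV_Poisson^2 = 1/mu), so FF = 1 is constitutive-expression-like noise,
FF < 1 under-dispersed, FF > 1 over-dispersed.  Samples are copy numbers
read off the uniform recording grid of stationary SSA runs and pooled
across replicates before the moments are taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crn import ScalingFactors
from .simulate import Trajectory

__all__ = [
    "NoiseSummary",
    "stationary_samples",
    "coefficient_of_variation",
    "fano_factor",
    "summarize_condition",
    "effective_sample_size",
    "summaries_to_frame",
]


class UndefinedMetricError(ValueError):
    """Raised when CV/FF are requested for a zero-mean sample."""


@dataclass(frozen=True)
class NoiseSummary:
    """Stationary moments of one species under one (fc, bf, uf) condition."""

    species: str
    condition: ScalingFactors
    mean: float
    sd: float
    cv: float
    ff: float
    n_samples: int
    n_replicates: int

    def __post_init__(self):
        if self.mean <= 0:
            raise UndefinedMetricError(
                f"{self.species}: CV/FF undefined for mean {self.mean}"
            )


def stationary_samples(
    traj: Trajectory, species: str, t_start: float = 0.0
) -> np.ndarray:
    """Copy-number samples at grid times >= ``t_start``, order preserved."""
    if t_start > traj.times[-1]:
        raise ValueError(
            f"t_start={t_start} beyond trajectory end {traj.times[-1]}"
        )
    mask = traj.times >= t_start
    return traj.get(species)[mask]


def _moments(samples: np.ndarray):
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    mu = samples.mean()
    if mu <= 0:
        raise UndefinedMetricError("zero mean: CV/FF undefined")
    sd = samples.std(ddof=1)
    return mu, sd


def coefficient_of_variation(samples) -> float:
    """Sample CV = sd/mean with the unbiased (n-1) variance."""
    mu, sd = _moments(samples)
    return sd / mu


def fano_factor(samples) -> float:
    """Sample FF = variance/mean with the unbiased (n-1) variance."""
    mu, sd = _moments(samples)
    return sd * sd / mu


def effective_sample_size(samples) -> float:
    """ESS from the lag-1 autocorrelation (AR(1) approximation).

    Grid samples of a jump process are serially correlated; this is a
    diagnostic only -- pooled moments are reported on the raw sample count.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 3 or x.std() == 0:
        return float(n)
    x = x - x.mean()
    rho = float(np.dot(x[:-1], x[1:]) / np.dot(x, x))
    rho = min(max(rho, 0.0), 1 - 1e-12)
    return n * (1 - rho) / (1 + rho)


def summarize_condition(
    trajectories,
    species: str,
    condition: ScalingFactors | None = None,
    t_start: float = 0.0,
) -> NoiseSummary:
    """Pool grid samples across replicate runs, then compute CV and FF.

    All replicates must record the same species set; the condition defaults
    to the one stamped on the first trajectory.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one replicate")
    roster = trajectories[0].species
    for t in trajectories[1:]:
        if t.species != roster:
            raise ValueError("replicates record different species sets")
    if condition is None:
        condition = trajectories[0].condition or ScalingFactors()
    pool = np.concatenate(
        [stationary_samples(t, species, t_start) for t in trajectories]
    )
    mu, sd = _moments(pool)
    return NoiseSummary(
        species=species,
        condition=condition,
        mean=float(mu),
        sd=float(sd),
        cv=float(sd / mu),
        ff=float(sd * sd / mu),
        n_samples=int(pool.size),
        n_replicates=len(trajectories),
    )


def summaries_to_frame(summaries):
    """Tidy table: species,fc,bf,uf,mean,sd,cv,ff,n_samples,n_replicates."""
    import pandas as pd

    rows = [
        {
            "species": s.species,
            "fc": s.condition.fc,
            "bf": s.condition.bf,
            "uf": s.condition.uf,
            "mean": s.mean,
            "sd": s.sd,
            "cv": s.cv,
            "ff": s.ff,
            "n_samples": s.n_samples,
            "n_replicates": s.n_replicates,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
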