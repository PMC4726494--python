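"""Conversion of relative time estimates into absolute years / MYA.

Two conversions close the dating chain:

* Clone age.  A TMRCA in coalescent units (N_f generations) becomes years
  via t = TMRCA · N_f · g, where N_f = θ / (2 μ_gen) and the per-locus,
  per-generation mutation rate μ_gen = rate[/site/MYA] · 10⁻⁶ · L · g
  follows from the lineage-averaged substitution rate of the calibrated
  chronogram, the locus length L and the generation time g.

* Speciation times.  MSC divergence times τ (expected substitutions/site)
  scale linearly through the shared outgroup calibration:
  τ_abs = τ / τ_outgroup_split × outgroup_age (MYA), applied per posterior
  sample.

Rates are carried per MYA throughout and converted to per-year only here
(the 10⁶ factor lives in one constant), to keep unit errors loud.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coalescent import TmrcaEstimate
from .msc import PosteriorSummary, summarize_posterior

YEARS_PER_MY = 1_000_000.0


@dataclass(frozen=True)
class CalibrationParams:
    """Units: g in years, L in sites, rate in substitutions/site/MYA."""

    g: float = 2.0
    L: int = 1140
    rate: float = 0.0065
    outgroup_age: Optional[float] = None   # MYA

    def __post_init__(self) -> None:
        if self.g <= 0 or self.L <= 0 or self.rate <= 0:
            raise ValueError("g, L and rate must all be > 0")
        if self.outgroup_age is not None and self.outgroup_age <= 0:
            raise ValueError("outgroup_age must be > 0")

    @property
    def mu_per_generation(self) -> float:
        """Per-locus, per-generation mutation rate."""
        return self.rate / YEARS_PER_MY * self.L * self.g

    def n_f(self, theta: float) -> float:
        """Haploid female effective size from θ = 2·N_f·μ."""
        if theta <= 0:
            raise ValueError("theta must be > 0")
        return theta / (2.0 * self.mu_per_generation)


@dataclass(frozen=True)
class CloneAge:
    """Clone age in years with the CI mapped from the TMRCA interval."""

    age_years: float
    ci_low: float
    ci_high: float
    n_f: float
    mu_per_generation: float
    params: CalibrationParams
    theta: float

    @property
    def age_mya(self) -> float:
        return self.age_years / YEARS_PER_MY

    def as_dict(self) -> dict:
        return {
            "age_years": self.age_years, "ci_low_years": self.ci_low,
            "ci_high_years": self.ci_high, "age_mya": self.age_mya,
            "N_f": self.n_f, "mu_per_generation": self.mu_per_generation,
            "theta": self.theta,
            "params": {"g": self.params.g, "L": self.params.L,
                       "rate_per_site_per_mya": self.params.rate},
        }


def clone_age_years(tmrca: TmrcaEstimate, theta: float,
                    params: CalibrationParams) -> CloneAge:
    """Translate a coalescent-unit TMRCA into years: t = TMRCA · N_f · g.

    The 95% interval endpoints map through the same monotone transform; θ
    uncertainty is not propagated (use :func:`clone_age_years_joint` to
    fold in a θ profile).
    """
    n_f = params.n_f(theta)
    scale = n_f * params.g
    return CloneAge(
        age_years=tmrca.mean * scale,
        ci_low=tmrca.ci_low * scale,
        ci_high=tmrca.ci_high * scale,
        n_f=n_f,
        mu_per_generation=params.mu_per_generation,
        params=params,
        theta=theta,
    )


def clone_age_years_joint(joint, params: CalibrationParams) -> CloneAge:
    """Clone age with θ uncertainty propagated (the joint-propagation flag).

    ``joint`` is a :class:`cobitis.coalescent.JointTmrcaSamples`: each
    pooled TMRCA draw maps to years with the N_f implied by its own θ draw,
    so the θ-TMRCA coupling in the data is respected.
    """
    from .coalescent import weighted_quantile

    years = np.array([t * params.n_f(th) * params.g
                      for t, th in zip(joint.heights, joint.thetas)])
    w = joint.weights / joint.weights.sum()
    mean_theta = float(np.sum(w * joint.thetas))
    return CloneAge(
        age_years=float(np.sum(w * years)),
        ci_low=weighted_quantile(years, joint.weights, 0.025),
        ci_high=weighted_quantile(years, joint.weights, 0.975),
        n_f=params.n_f(mean_theta),
        mu_per_generation=params.mu_per_generation,
        params=params,
        theta=mean_theta,
    )


def absolute_speciation_times(
    tau_samples: Sequence[float] | np.ndarray,
    tau_outgroup_split: float,
    outgroup_age: float,
) -> tuple[np.ndarray, PosteriorSummary]:
    """Rescale MSC divergence-time samples to MYA via the outgroup split.

    τ_abs = τ / τ_outgroup_split × outgroup_age per posterior sample; the
    summary carries the posterior mean and 95% interval in MYA.
    """
    if tau_outgroup_split <= 0:
        raise ValueError("tau_outgroup_split must be > 0")
    if outgroup_age <= 0:
        raise ValueError("outgroup_age must be > 0")
    tau = np.asarray(tau_samples, dtype=float)
    mya = tau / tau_outgroup_split * outgroup_age
    summary = summarize_posterior({"age_mya": mya},
                                  {"tau_outgroup_split": tau_outgroup_split,
                                   "outgroup_age": outgroup_age})
    return mya, summary
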