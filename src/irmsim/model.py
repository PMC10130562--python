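"""Core quantitative-genetics kernel for polygenic insecticide resistance.

Resistance to each insecticide is tracked as the population-mean Polygenic
Resistance Score (PRS, ``z``), a latent additive trait on a scale anchored so
that ``z = 100`` corresponds to 10% survival in a diagnostic-dose bioassay
(WHO cylinder / CDC bottle).  A Hill function maps mean PRS to bioassay
survival, a linear regression maps bioassay survival to field (experimental
hut) survival, and the breeder's equation gives the per-generation response
to insecticide selection.  Two patches are modelled: an intervention site
where insecticides are deployed, and an untreated refugia coupled to it by
female dispersal after mating.

All operations here are pure functions of the state; the deployment policies
and the generation loop live in :mod:`irmsim.strategies` and
:mod:`irmsim.engine`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "ScaleConstants",
    "InsecticideProfile",
    "Scenario",
    "CrossResistance",
    "ResistanceState",
    "MIXTURE",
    "bioassay_survival",
    "field_survival",
    "potential_response",
    "intervention_update",
    "refugia_update",
    "dispersal_update",
    "population_averaged_survival",
]

#: Sentinel deployment value meaning "both insecticides in one formulation".
MIXTURE = "mixture"


@dataclass(frozen=True)
class ScaleConstants:
    """Constants of the PRS -> survival mappings.

    ``k_max``, ``z50`` and ``hill_n`` parameterize the Hill curve from mean
    PRS to bioassay survival; ``phi1``/``phi2`` are the regression slope and
    intercept converting bioassay survival to field (hut-trial) survival.
    The defaults anchor the scale so z = 100 gives 10% bioassay survival.
    """

    k_max: float = 1.0
    z50: float = 900.0
    hill_n: float = 1.0
    phi1: float = 0.48
    phi2: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.k_max <= 1.0:
            raise ValueError(f"k_max must be in (0, 1], got {self.k_max}")
        if self.z50 <= 0.0:
            raise ValueError(f"z50 must be positive, got {self.z50}")
        if self.hill_n < 1.0:
            raise ValueError(f"hill_n must be >= 1, got {self.hill_n}")
        if self.phi1 * self.k_max + self.phi2 > 1.0:
            raise ValueError("phi1 * k_max + phi2 exceeds 1: field survival "
                             "would leave the unit interval")


@dataclass(frozen=True)
class InsecticideProfile:
    """Genetics and exposure parameters of one insecticide / resistance trait.

    Parameters
    ----------
    h2
        Narrow-sense heritability of the resistance trait (0-1).
    psi
        Fitness cost per generation, expressed as a proportion of the
        potential selection response (0-1).
    x
        Proportion of females exposed to the deployed insecticide (0-1).
    m
        Male exposure as a proportion of female exposure (0-1).
    z0
        Starting mean PRS (same value in both patches); must lie below the
        z = 100 withdrawal anchor.
    """

    h2: float
    psi: float
    x: float
    m: float
    z0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("h2", "psi", "x", "m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.z0 < 100.0:
            raise ValueError(f"z0 must be in [0, 100), got {self.z0}")


@dataclass(frozen=True)
class Scenario:
    """Landscape and schedule constants shared by a whole simulation."""

    coverage: float = 0.8
    dispersal: float = 0.5
    beta: float = 10.0
    deploy_interval: int = 10
    withdrawal_threshold: float = 0.10
    return_threshold: float = 0.08
    max_generations: int = 500
    generations_per_year: int = 10
    #: grouped reading of the mixture update, scaling the cost term by the
    #: partner's field survival (off by default; see methods note).
    mixture_cost_scaled: bool = False
    scale: ScaleConstants = field(default_factory=ScaleConstants)

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage must be in [0, 1], got {self.coverage}")
        if not 0.0 <= self.dispersal <= 1.0:
            raise ValueError(f"dispersal must be in [0, 1], got {self.dispersal}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")
        if self.deploy_interval < 1:
            raise ValueError("deploy_interval must be a positive integer")
        if self.max_generations < 1:
            raise ValueError("max_generations must be a positive integer")
        if not self.return_threshold < self.withdrawal_threshold:
            raise ValueError("return_threshold must be strictly below the "
                             "withdrawal_threshold")

    @property
    def r_into_site(self) -> float:
        """Immigrant fraction into the intervention site, (1 - C) * theta."""
        return (1.0 - self.coverage) * self.dispersal

    @property
    def r_into_refugia(self) -> float:
        """Immigrant fraction into the refugia, C * theta."""
        return self.coverage * self.dispersal


@dataclass(frozen=True)
class CrossResistance:
    """Genetic correlations producing correlated responses between traits.

    ``alpha_ji`` scales trait 1's correlated response to selection on
    insecticide 2; ``alpha_ij`` is the reciprocal.  Symmetric cross
    resistance uses :meth:`symmetric`.
    """

    alpha_ji: float = 0.0
    alpha_ij: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha_ji", "alpha_ij"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1], got {v}")

    @classmethod
    def symmetric(cls, alpha: float) -> "CrossResistance":
        return cls(alpha_ji=alpha, alpha_ij=alpha)

    def onto(self, trait: int) -> float:
        """Correlation scaling the correlated response *onto* ``trait``."""
        return self.alpha_ji if trait == 0 else self.alpha_ij


@dataclass
class ResistanceState:
    """Mean PRS per trait in each patch at one generation."""

    z_site: np.ndarray
    z_refugia: np.ndarray

    def __post_init__(self) -> None:
        self.z_site = np.asarray(self.z_site, dtype=float)
        self.z_refugia = np.asarray(self.z_refugia, dtype=float)
        if np.any(self.z_site < 0) or np.any(self.z_refugia < 0):
            raise ValueError("mean PRS values must be non-negative")

    def copy(self) -> "ResistanceState":
        return ResistanceState(self.z_site.copy(), self.z_refugia.copy())


def bioassay_survival(z, scale: ScaleConstants = ScaleConstants()):
    """Proportion surviving a diagnostic-dose bioassay at mean PRS ``z``.

    Hill curve ``k_max * z**n / (z50 + z**n)``; with the default anchoring
    (k_max = 1, z50 = 900, n = 1) z = 100 gives 0.10 and z = 900 gives 0.50.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("mean PRS must be non-negative")
    zn = z ** scale.hill_n
    out = scale.k_max * zn / (scale.z50 + zn)
    return float(out) if out.ndim == 0 else out


def field_survival(kb, scale: ScaleConstants = ScaleConstants()):
    """Field (hut-trial) survival from bioassay survival: phi1*kb + phi2."""
    kb = np.asarray(kb, dtype=float)
    if np.any((kb < 0) | (kb > 1)):
        raise ValueError("bioassay survival must be a proportion in [0, 1]")
    out = np.clip(scale.phi1 * kb + scale.phi2, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def potential_response(profile: InsecticideProfile, beta: float) -> float:
    """Sex-averaged breeder's-equation response ``beta * h2 * x * (1+m)/2``.

    This is the per-generation gain in mean PRS under full solo deployment,
    i.e. the response to the female and male selection differentials
    S_f = x*beta and S_m = x*m*beta averaged across the sexes.
    """
    return beta * profile.h2 * profile.x * (1.0 + profile.m) / 2.0


def _responses(profiles: Sequence[InsecticideProfile], beta: float) -> np.ndarray:
    return np.array([potential_response(p, beta) for p in profiles])


def intervention_update(
    state: ResistanceState,
    deployment,
    profiles: Sequence[InsecticideProfile],
    alpha: CrossResistance,
    scenario: Scenario,
) -> np.ndarray:
    """One generation of selection + fitness costs in the intervention site.

    ``deployment`` is ``None`` (nothing relevant deployed), an insecticide
    index, or :data:`MIXTURE`.  Returns the primed (pre-dispersal) site
    means; the input state is not modified.

    Per trait I the applied change is:

    * solo i deployed:   ``R_i * (1 - psi_i)``
    * solo j deployed:   ``-psi_i R_i + alpha_JI (R_j - psi_j R_j)``
    * nothing deployed:  ``-psi_i R_i``
    * mixture:           ``K_jF R_i - psi_i R_i + K_iF alpha_JI (R_j - psi_j R_j)``

    with field survivals evaluated at the pre-update site means, and the
    result clamped at zero.
    """
    z = np.asarray(state.z_site, dtype=float)
    R = _responses(profiles, scenario.beta)
    psi = np.array([p.psi for p in profiles])
    n = len(profiles)
    delta = np.empty(n)

    if deployment == MIXTURE:
        if n != 2:
            raise ValueError("mixtures require exactly two insecticides")
        kf = field_survival(bioassay_survival(z, scenario.scale), scenario.scale)
        for i in range(n):
            j = 1 - i
            if scenario.mixture_cost_scaled:
                direct = kf[j] * (R[i] - psi[i] * R[i])
            else:
                direct = kf[j] * R[i] - psi[i] * R[i]
            indirect = kf[i] * alpha.onto(i) * (R[j] - psi[j] * R[j])
            delta[i] = direct + indirect
    elif deployment is None:
        delta = -psi * R
    elif isinstance(deployment, (int, np.integer)) and 0 <= deployment < n:
        for i in range(n):
            if i == deployment:
                delta[i] = R[i] * (1.0 - psi[i])
            else:
                delta[i] = -psi[i] * R[i] + alpha.onto(i) * (
                    R[deployment] - psi[deployment] * R[deployment]
                )
    else:
        raise ValueError(f"unknown deployment mode: {deployment!r}")

    return np.maximum(z + delta, 0.0)


def refugia_update(
    state: ResistanceState,
    profiles: Sequence[InsecticideProfile],
    scenario: Scenario,
) -> np.ndarray:
    """One generation of fitness-cost decay in the untreated refugia.

    No insecticide is ever deployed there, so each trait loses ``psi * R``
    per generation, clamped at zero.
    """
    z = np.asarray(state.z_refugia, dtype=float)
    R = _responses(profiles, scenario.beta)
    psi = np.array([p.psi for p in profiles])
    return np.maximum(z - psi * R, 0.0)


def dispersal_update(
    z_site_primed: np.ndarray,
    z_refugia_primed: np.ndarray,
    scenario: Scenario,
) -> tuple[np.ndarray, np.ndarray]:
    """Mix the post-selection means of the two patches by female dispersal.

    Both double-primed values are convex combinations computed
    simultaneously from the same primed inputs, with immigrant fractions
    ``(1 - C) * theta`` into the site and ``C * theta`` into the refugia.
    """
    rt = scenario.r_into_site
    ru = scenario.r_into_refugia
    if not (0.0 <= rt <= 1.0 and 0.0 <= ru <= 1.0):
        raise ValueError("immigrant fractions must lie in [0, 1]")
    zt = np.asarray(z_site_primed, dtype=float)
    zu = np.asarray(z_refugia_primed, dtype=float)
    return zt * (1.0 - rt) + zu * rt, zu * (1.0 - ru) + zt * ru


def population_averaged_survival(
    z_mean: float,
    sigma: float,
    scale: ScaleConstants = ScaleConstants(),
) -> float:
    """Expected bioassay survival averaged over a Normal PRS distribution.

    Individuals vary around the population mean; survival is the Hill curve
    integrated against Normal(z_mean, sigma), with the (biologically
    impossible) negative-PRS mass contributing zero survival.  At sigma = 0
    this reduces to :func:`bioassay_survival` of the mean.  The scale
    anchoring is insensitive to this averaging for sigma up to about 25.
    """
    if not (np.isfinite(z_mean) and np.isfinite(sigma)):
        raise ValueError("inputs must be finite")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return float(bioassay_survival(z_mean, scale))

    def integrand(z):
        return bioassay_survival(z, scale) * stats.norm.pdf(z, z_mean, sigma)

    upper = z_mean + 12.0 * sigma
    value, _ = integrate.quad(integrand, 0.0, upper, limit=200)
    return float(value)
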