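"""Generation loop: decisions, state updates, termination, outcomes.

Each generation ``g = 0, 1, ...``:

1. if ``g`` is a decision epoch (a multiple of the deployment interval),
   compute per-insecticide bioassay survival from the intervention-site
   means, update the armory, then ask the policy what to deploy — if it
   terminates, the run ends with lifespan ``g``;
2. apply selection + fitness costs in the intervention site for the chosen
   deployment;
3. apply fitness-cost decay in the refugia;
4. mix both patches by dispersal.

The engine is fully deterministic; identical inputs give bit-identical
trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    MIXTURE,
    CrossResistance,
    InsecticideProfile,
    ResistanceState,
    Scenario,
    bioassay_survival,
    dispersal_update,
    intervention_update,
    refugia_update,
)
from .strategies import (
    ArmoryStatus,
    DeploymentAction,
    armory_update,
    mixture_policy,
    rotation_policy,
    sequence_policy,
)

__all__ = ["SimulationResult", "run_simulation", "extract_outcomes"]


@dataclass
class SimulationResult:
    """Trajectories and outcomes of one simulated deployment programme."""

    lifespan: int
    trajectories: pd.DataFrame
    deployed_series: list
    mean_deployed_survival: float
    peak_survival: float
    terminated_by: str  # "armory-exhausted" | "cap"
    #: first decision epoch at which each insecticide, previously withdrawn,
    #: re-entered the armory (None if it never did)
    return_epochs: tuple[Optional[int], ...] = (None, None)


def _decide(strategy: str, status: ArmoryStatus, kb, scenario: Scenario) -> DeploymentAction:
    if strategy == "sequence":
        return sequence_policy(status)
    if strategy == "rotation":
        return rotation_policy(status, adaptive=False)
    if strategy == "adaptive_rotation":
        return rotation_policy(status, adaptive=True)
    if strategy == "mixture":
        return mixture_policy(kb, scenario)
    raise ValueError(f"unknown strategy: {strategy!r}")


def run_simulation(
    profiles: Sequence[InsecticideProfile],
    alpha: CrossResistance,
    scenario: Scenario,
    strategy: str,
) -> SimulationResult:
    """Run one strategy to armory exhaustion or the generation cap."""
    n = len(profiles)
    state = ResistanceState(
        z_site=np.array([p.z0 for p in profiles], dtype=float),
        z_refugia=np.array([p.z0 for p in profiles], dtype=float),
    )
    status = ArmoryStatus(available=(True,) * n, current=None)
    return_epochs: list[Optional[int]] = [None] * n
    rows = []
    deployed_series: list = []
    deployment = None
    lifespan = scenario.max_generations
    terminated_by = "cap"

    for g in range(scenario.max_generations):
        kb = bioassay_survival(state.z_site, scenario.scale)
        if g % scenario.deploy_interval == 0:
            before = status.available
            status = armory_update(status, kb, scenario)
            for i in range(n):
                if status.available[i] and not before[i] and return_epochs[i] is None:
                    return_epochs[i] = g
            action = _decide(strategy, status, kb, scenario)
            if action.kind == "terminate":
                lifespan = g
                terminated_by = "armory-exhausted"
                break
            deployment = action.deployment
            status = replace(status, current=deployment if deployment == MIXTURE
                             else int(deployment))

        rows.append(
            (g, _label(deployment), *state.z_site, *state.z_refugia, *np.atleast_1d(kb))
        )
        deployed_series.append(deployment)

        z_site_p = intervention_update(state, deployment, profiles, alpha, scenario)
        z_ref_p = refugia_update(state, profiles, scenario)
        state = ResistanceState(*dispersal_update(z_site_p, z_ref_p, scenario))

    columns = (
        ["generation", "deployed"]
        + [f"z_t_{i + 1}" for i in range(n)]
        + [f"z_u_{i + 1}" for i in range(n)]
        + [f"kb_{i + 1}" for i in range(n)]
    )
    traj = pd.DataFrame(rows, columns=columns)
    mean_dep, peak = extract_outcomes(traj, deployed_series)
    return SimulationResult(
        lifespan=lifespan,
        trajectories=traj,
        deployed_series=deployed_series,
        mean_deployed_survival=mean_dep,
        peak_survival=peak,
        terminated_by=terminated_by,
        return_epochs=tuple(return_epochs),
    )


def _label(deployment) -> str:
    if deployment is None:
        return "none"
    if deployment == MIXTURE:
        return "mixture"
    return str(int(deployment) + 1)


def extract_outcomes(trajectories: pd.DataFrame, deployed_series: Sequence) -> tuple[float, float]:
    """Secondary outcomes of a run.

    ``mean_deployed_survival`` averages, over all simulated generations, the
    bioassay survival of the insecticide deployed that generation (for a
    mixture, the mean of the two components).  ``peak_survival`` is the
    maximum bioassay survival of any trait at any generation in the
    intervention site.
    """
    if len(trajectories) == 0:
        raise ValueError("empty run")
    kb_cols = [c for c in trajectories.columns if c.startswith("kb_")]
    kb = trajectories[kb_cols].to_numpy()
    per_gen = np.empty(len(kb))
    for g, dep in enumerate(deployed_series):
        if dep == MIXTURE:
            per_gen[g] = kb[g].mean()
        elif dep is None:
            per_gen[g] = np.nan
        else:
            per_gen[g] = kb[g, int(dep)]
    mean_dep = float(np.nanmean(per_gen))
    peak = float(kb.max())
    return mean_dep, peak
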