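"""Armory bookkeeping and deployment policies.

An insecticide is *withdrawn* from the armory when its bioassay survival at
a decision epoch reaches the withdrawal threshold (default 10%), and becomes
available again once survival has decayed below the stricter return
threshold (default 8%) — a hysteresis band that stops a just-failed product
from being redeployed immediately.  Four policies decide what to deploy at
each epoch: sequence (deploy-until-failure), rotation (switch every epoch),
adaptive rotation (rotation with a sequence fallback when only one product
is available), and full-dose mixture (both products in one formulation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .model import MIXTURE, Scenario

__all__ = [
    "ArmoryStatus",
    "DeploymentAction",
    "armory_update",
    "sequence_policy",
    "rotation_policy",
    "mixture_policy",
    "POLICY_NAMES",
]

POLICY_NAMES = ("sequence", "rotation", "adaptive_rotation", "mixture")


@dataclass(frozen=True)
class ArmoryStatus:
    """Per-insecticide availability plus the currently deployed product."""

    available: tuple[bool, ...]
    current: Optional[object] = None  # index, MIXTURE, or None before start


@dataclass(frozen=True)
class DeploymentAction:
    """Outcome of a policy decision: deploy something, or terminate."""

    kind: str  # "solo" | "mixture" | "terminate"
    index: Optional[int] = None

    @property
    def deployment(self):
        """The deployment value consumed by the model update."""
        if self.kind == "solo":
            return self.index
        if self.kind == "mixture":
            return MIXTURE
        raise ValueError("a terminate action carries no deployment")


def armory_update(
    status: ArmoryStatus,
    kb: Sequence[float],
    scenario: Scenario,
) -> ArmoryStatus:
    """Apply withdrawal/return thresholds to each insecticide's availability.

    Withdrawal is ``kb >= withdrawal_threshold``; return is the strict
    ``kb < return_threshold`` (so survival of exactly 9.9% with a 10%
    threshold leaves the product deployable).
    """
    kb = np.asarray(kb, dtype=float)
    new = []
    for avail, k in zip(status.available, kb):
        if avail and k >= scenario.withdrawal_threshold:
            new.append(False)
        elif not avail and k < scenario.return_threshold:
            new.append(True)
        else:
            new.append(avail)
    return replace(status, available=tuple(new))


def sequence_policy(status: ArmoryStatus) -> DeploymentAction:
    """Keep the current product while it lasts; else the lowest-numbered
    available one; terminate when the armory is empty."""
    if isinstance(status.current, int) and status.available[status.current]:
        return DeploymentAction("solo", status.current)
    for i, avail in enumerate(status.available):
        if avail:
            return DeploymentAction("solo", i)
    return DeploymentAction("terminate")


def rotation_policy(status: ArmoryStatus, adaptive: bool = False) -> DeploymentAction:
    """Switch to the other product each epoch.

    Strict rotation terminates when the switch is impossible (the other
    product is withdrawn) — redeploying the incumbent would be a de facto
    sequence.  Adaptive rotation relaxes exactly that rule: the incumbent
    continues while it is the only product available, and rotation resumes
    as soon as the other returns.  The first epoch deploys insecticide 1.
    """
    if len(status.available) == 1:
        # degenerate one-product armory: nothing to rotate to, so rotation
        # coincides with a sequence
        return sequence_policy(status)
    if len(status.available) != 2:
        raise ValueError("rotation needs a one- or two-insecticide armory")
    if status.current is None:
        return sequence_policy(status)
    other = 1 - status.current
    if status.available[other]:
        return DeploymentAction("solo", other)
    if adaptive and status.available[status.current]:
        return DeploymentAction("solo", status.current)
    return DeploymentAction("terminate")


def mixture_policy(kb: Sequence[float], scenario: Scenario) -> DeploymentAction:
    """Deploy both products in one formulation until either component's
    bioassay survival reaches the withdrawal threshold; termination is
    final (no return pathway for a failed mixture)."""
    kb = np.asarray(kb, dtype=float)
    if kb.shape != (2,):
        raise ValueError("mixtures require exactly two insecticides")
    if np.any(kb >= scenario.withdrawal_threshold):
        return DeploymentAction("terminate")
    return DeploymentAction("mixture")
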