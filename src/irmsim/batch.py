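"""Vectorized batch engine: many parameter rows, one strategy, numpy arrays.

The experiment designs run tens of thousands of simulations per strategy;
looping the scalar engine over rows would dominate runtime, so this module
advances all rows of a parameter table through the generation loop
simultaneously.  It implements exactly the same decision and update rules
as :mod:`irmsim.engine` (asserted against it in the test suite) but records
only the outcome summaries, not full trajectories.

A parameter table has one row per simulation with columns::

    h2_1 h2_2 psi_1 psi_2 x m C theta alpha z0_1 z0_2 d

``x, m, C, theta`` and the deployment interval ``d`` are shared between the
two insecticides; ``alpha`` is the symmetric genetic correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import Scenario

__all__ = ["run_batch", "PARAM_COLUMNS"]

PARAM_COLUMNS = [
    "h2_1", "h2_2", "psi_1", "psi_2", "x", "m", "C", "theta",
    "alpha", "z0_1", "z0_2", "d",
]

_NONE, _MIX = -1, 2  # codes in the per-row `current` array


def run_batch(
    params: pd.DataFrame,
    strategy: str,
    scenario: Scenario = Scenario(),
) -> pd.DataFrame:
    """Run one strategy over every row of ``params``.

    ``scenario`` supplies the constants not present in the table (beta,
    thresholds, cap, scale); per-row ``C``, ``theta`` and ``d`` override the
    scenario's landscape and schedule.  Returns a DataFrame aligned with
    ``params`` holding ``lifespan``, ``mean_deployed_survival``,
    ``peak_survival`` and ``terminated_by``.
    """
    if strategy not in ("sequence", "rotation", "adaptive_rotation", "mixture"):
        raise ValueError(f"unknown strategy: {strategy!r}")
    adaptive = strategy == "adaptive_rotation"

    n = len(params)
    g_get = lambda c: params[c].to_numpy(dtype=float)
    h2 = np.column_stack([g_get("h2_1"), g_get("h2_2")])
    psi = np.column_stack([g_get("psi_1"), g_get("psi_2")])
    x = g_get("x")[:, None]
    m = g_get("m")[:, None]
    alpha = g_get("alpha")[:, None]
    d = params["d"].to_numpy(dtype=int)
    C = g_get("C")
    theta = g_get("theta")

    sc = scenario.scale
    beta = scenario.beta
    wd = scenario.withdrawal_threshold
    rtn = scenario.return_threshold
    cap = scenario.max_generations

    R = beta * h2 * x * (1.0 + m) / 2.0          # (n, 2) potential responses
    cost = psi * R                                # per-generation cost decrement
    rr = R - cost                                 # net response R(1 - psi)
    rt = ((1.0 - C) * theta)[:, None]             # immigrant fraction into site
    ru = (C * theta)[:, None]                     # immigrant fraction into refugia

    zt = np.column_stack([g_get("z0_1"), g_get("z0_2")])
    zu = zt.copy()
    avail = np.ones((n, 2), dtype=bool)
    cur = np.full(n, _NONE, dtype=int)
    active = np.ones(n, dtype=bool)
    lifespan = np.full(n, cap, dtype=int)

    kb_sum = np.zeros(n)
    gens = np.zeros(n, dtype=int)
    peak = np.zeros(n)

    rows = np.arange(n)
    for g in range(cap):
        if not active.any():
            break
        kb = sc.k_max * zt ** sc.hill_n / (sc.z50 + zt ** sc.hill_n)

        epoch = active & (g % d == 0)
        if epoch.any():
            e = epoch[:, None]
            avail = np.where(e & avail & (kb >= wd), False, avail)
            avail = np.where(e & ~avail & (kb < rtn), True, avail)

            if strategy == "mixture":
                stop = epoch & (kb >= wd).any(axis=1)
                cur = np.where(epoch & ~stop, _MIX, cur)
            else:
                started = cur >= 0
                cur_ok = np.zeros(n, dtype=bool)
                cur_ok[started] = avail[rows[started], cur[started]]
                # first-available fallback used by sequence and by the
                # initial deployment of every solo strategy
                first = np.where(avail[:, 0], 0, np.where(avail[:, 1], 1, _NONE))
                if strategy == "sequence":
                    newcur = np.where(cur_ok, cur, first)
                else:
                    other = 1 - cur
                    other_ok = np.zeros(n, dtype=bool)
                    other_ok[started] = avail[rows[started], other[started]]
                    rot = np.where(other_ok, other,
                                   np.where(adaptive & cur_ok, cur, _NONE))
                    newcur = np.where(started, rot, first)
                stop = epoch & (newcur == _NONE)
                cur = np.where(epoch & ~stop, newcur, cur)

            lifespan = np.where(stop, g, lifespan)
            active = active & ~stop

        if not active.any():
            break

        # record pre-update survival of this generation's deployment
        solo = active & (cur >= 0) & (cur < 2)
        kb_dep = np.zeros(n)
        kb_dep[solo] = kb[rows[solo], cur[solo]]
        mix = active & (cur == _MIX)
        kb_dep[mix] = kb[mix].mean(axis=1)
        kb_sum += np.where(active, kb_dep, 0.0)
        gens += active
        peak = np.where(active, np.maximum(peak, kb.max(axis=1)), peak)

        # selection + fitness costs in the intervention site
        delta = -cost  # default: idle with no relevant deployment
        if strategy == "mixture":
            kf = np.clip(sc.phi1 * kb + sc.phi2, 0.0, 1.0)
            kf_other = kf[:, ::-1]
            if scenario.mixture_cost_scaled:
                direct = kf_other * rr
            else:
                direct = kf_other * R - cost
            mdelta = direct + kf * alpha * rr[:, ::-1]
            delta = np.where(mix[:, None], mdelta, delta)
        else:
            for i in (0, 1):
                dep_i = solo & (cur == i)
                j = 1 - i
                sdelta = np.empty((n, 2))
                sdelta[:, i] = rr[:, i]
                sdelta[:, j] = -cost[:, j] + alpha[:, 0] * rr[:, i]
                delta = np.where(dep_i[:, None], sdelta, delta)

        ztp = np.maximum(zt + delta, 0.0)
        zup = np.maximum(zu - cost, 0.0)
        ztn = ztp * (1.0 - rt) + zup * rt
        zun = zup * (1.0 - ru) + ztp * ru
        zt = np.where(active[:, None], ztn, zt)
        zu = np.where(active[:, None], zun, zu)

    return pd.DataFrame(
        {
            "lifespan": lifespan,
            "mean_deployed_survival": np.divide(
                kb_sum, gens, out=np.zeros(n), where=gens > 0
            ),
            "peak_survival": peak,
            "terminated_by": np.where(lifespan < cap, "armory-exhausted", "cap"),
        },
        index=params.index,
    )
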