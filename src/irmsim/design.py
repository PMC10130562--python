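"""Latin-hypercube experiment designs and strategy head-to-head comparisons.

Two designs are used.  In the *equal-properties* design both insecticides
share heritability, fitness cost and starting resistance, so differences
between strategies are not confounded by one product being intrinsically
better; the continuous parameters are Latin-hypercube sampled and crossed
with a grid of cross-resistance values, two starting-resistance levels and
two deployment intervals.  In the *unique-properties* design each
insecticide draws its own heritability, fitness cost and starting
resistance, and cross resistance is sampled continuously.

Comparisons are paired: every strategy runs on identical parameter rows.
A strategy *wins* a pairing when its lifespan is strictly longer, and wins
*operationally* when it is at least 10% longer (an
operationally-relevant-win threshold below which logistics would dominate
the choice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .batch import PARAM_COLUMNS, run_batch
from .model import Scenario

__all__ = [
    "TABLE_RANGES",
    "ALPHA_GRID",
    "ComparisonOutcome",
    "lhs_design",
    "build_equal_design",
    "build_unique_design",
    "run_design",
    "classify_pair",
    "classify_pairs",
    "classify_triple",
    "classify_triples",
    "pair_summary",
    "triple_summary",
    "OPERATIONAL_RATIO",
]

#: Marginal ranges of the varied model parameters.
TABLE_RANGES: Mapping[str, tuple[float, float]] = {
    "h2": (0.05, 0.30),
    "x": (0.4, 0.9),
    "m": (0.0, 1.0),
    "psi": (0.01, 0.2),
    "C": (0.1, 0.9),
    "theta": (0.1, 0.9),
}

#: Cross-resistance grid of the equal-properties design.
ALPHA_GRID = tuple(np.round(np.arange(-0.5, 0.51, 0.1), 1))

OPERATIONAL_RATIO = 1.1


def lhs_design(
    n: int,
    ranges: Mapping[str, tuple[float, float]],
    seed: int,
) -> pd.DataFrame:
    """Stratified Latin-hypercube sample of ``n`` rows over ``ranges``.

    Each marginal places exactly one value in each of ``n`` equal-probability
    strata; reproducible under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    names = list(ranges)
    lows = np.array([ranges[k][0] for k in names], dtype=float)
    highs = np.array([ranges[k][1] for k in names], dtype=float)
    if np.any(highs <= lows):
        raise ValueError("each range must have low < high")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    unit = sampler.random(n)
    return pd.DataFrame(qmc.scale(unit, lows, highs), columns=names)


def build_equal_design(
    n_lhs: int,
    seed: int,
    alphas: Sequence[float] = ALPHA_GRID,
    z0s: Sequence[float] = (0.0, 50.0),
    intervals: Sequence[int] = (10, 30),
) -> pd.DataFrame:
    """Equal-properties design: LHS rows crossed with the design factors.

    Returns ``n_lhs * len(alphas) * len(z0s) * len(intervals)`` simulation
    rows in batch-engine column layout, plus bookkeeping columns
    ``lhs_row``, ``alpha``, ``z0`` and ``d``.
    """
    base = lhs_design(n_lhs, TABLE_RANGES, seed)
    base["lhs_row"] = np.arange(n_lhs)
    grid = pd.MultiIndex.from_product(
        [alphas, z0s, intervals], names=["alpha", "z0", "d"]
    ).to_frame(index=False)
    design = base.merge(grid, how="cross")
    design["h2_1"] = design["h2"]
    design["h2_2"] = design["h2"]
    design["psi_1"] = design["psi"]
    design["psi_2"] = design["psi"]
    design["z0_1"] = design["z0"]
    design["z0_2"] = design["z0"]
    return design[
        ["lhs_row", "h2", "psi", "z0"] + PARAM_COLUMNS
    ].reset_index(drop=True)


def build_unique_design(
    n: int,
    seed: int,
    deploy_interval: int = 10,
) -> pd.DataFrame:
    """Unique-properties design: per-insecticide genetics, shared landscape.

    Heritability, fitness cost and starting PRS are sampled independently
    for each insecticide (starting PRS uniform on 0-80, keeping every
    product below the z = 100 withdrawal anchor); cross resistance is a
    single symmetric draw on (-0.5, 0.5).  Exposure and landscape
    parameters are shared, and the deployment interval is fixed.
    """
    ranges = {
        "h2_1": TABLE_RANGES["h2"],
        "h2_2": TABLE_RANGES["h2"],
        "psi_1": TABLE_RANGES["psi"],
        "psi_2": TABLE_RANGES["psi"],
        "z0_1": (0.0, 80.0),
        "z0_2": (0.0, 80.0),
        "alpha": (-0.5, 0.5),
        "x": TABLE_RANGES["x"],
        "m": TABLE_RANGES["m"],
        "C": TABLE_RANGES["C"],
        "theta": TABLE_RANGES["theta"],
    }
    design = lhs_design(n, ranges, seed)
    design["d"] = deploy_interval
    return design[PARAM_COLUMNS].reset_index(drop=True)


def run_design(
    design: pd.DataFrame,
    strategies: Sequence[str],
    scenario: Scenario = Scenario(),
) -> pd.DataFrame:
    """Run every strategy on every (identical) design row.

    Returns the design columns plus, per strategy, ``lifespan_<s>``,
    ``mean_survival_<s>`` and ``peak_survival_<s>``.
    """
    out = design.copy()
    for s in strategies:
        res = run_batch(design, s, scenario)
        out[f"lifespan_{s}"] = res["lifespan"]
        out[f"mean_survival_{s}"] = res["mean_deployed_survival"]
        out[f"peak_survival_{s}"] = res["peak_survival"]
    return out


@dataclass(frozen=True)
class ComparisonOutcome:
    """Win/loss/draw plus operational classification for one pairing."""

    winner: str       # "a" | "b" | "draw"
    operational: str  # "a" | "b" | "draw"
    ratio: float      # longer / shorter lifespan


def classify_pair(lifespan_a: float, lifespan_b: float) -> ComparisonOutcome:
    """Classify one paired comparison of two strategies."""
    if lifespan_a <= 0 or lifespan_b <= 0:
        raise ValueError("lifespans must be positive")
    longer, shorter = max(lifespan_a, lifespan_b), min(lifespan_a, lifespan_b)
    ratio = longer / shorter
    if lifespan_a == lifespan_b:
        return ComparisonOutcome("draw", "draw", 1.0)
    winner = "a" if lifespan_a > lifespan_b else "b"
    operational = winner if ratio >= OPERATIONAL_RATIO else "draw"
    return ComparisonOutcome(winner, operational, ratio)


def classify_pairs(a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
    """Vectorized :func:`classify_pair` over aligned lifespan arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    winner = np.where(a == b, "draw", np.where(a > b, "a", "b"))
    ratio = np.maximum(a, b) / np.minimum(a, b)
    operational = np.where(ratio >= OPERATIONAL_RATIO, winner, "draw")
    return pd.DataFrame({"winner": winner, "operational": operational, "ratio": ratio})


def classify_triple(
    lifespan_seq: float, lifespan_rot: float, lifespan_mix: float
) -> tuple[str, str]:
    """Three-way class of a mixture-vs-solo comparison.

    Absolute classes: ``draw`` (mixture equals both), ``mixtures-win``
    (strictly exceeds both), ``sequences-lose`` / ``rotations-lose``
    (exceeds only that strategy), and ``mixtures-lose`` (strictly shorter
    than both — counted separately, not expected under the model).  The
    operational analogue applies the 1.1 lifespan-ratio threshold.
    """
    df = classify_triples(
        np.array([lifespan_seq]), np.array([lifespan_rot]), np.array([lifespan_mix])
    )
    return df["outcome"].iloc[0], df["operational"].iloc[0]


def classify_triples(seq: np.ndarray, rot: np.ndarray, mix: np.ndarray) -> pd.DataFrame:
    """Vectorized :func:`classify_triple`."""
    seq = np.asarray(seq, dtype=float)
    rot = np.asarray(rot, dtype=float)
    mix = np.asarray(mix, dtype=float)
    if np.any(seq <= 0) or np.any(rot <= 0) or np.any(mix <= 0):
        raise ValueError("lifespans must be positive")

    beats_s, beats_r = mix > seq, mix > rot
    outcome = np.select(
        [
            beats_s & beats_r,
            (mix == seq) & (mix == rot),
            beats_s & ~beats_r,
            beats_r & ~beats_s,
        ],
        ["mixtures-win", "draw", "sequences-lose", "rotations-lose"],
        default="mixtures-lose",
    )
    ow_s, ow_r = mix / seq >= OPERATIONAL_RATIO, mix / rot >= OPERATIONAL_RATIO
    operational = np.select(
        [ow_s & ow_r, ow_s & ~ow_r, ow_r & ~ow_s],
        ["mixture-operational-win", "sequence-operational-loss",
         "rotation-operational-loss"],
        default="no-operational-win",
    )
    return pd.DataFrame({"outcome": outcome, "operational": operational})


def _percent(counts: pd.Series, total: int) -> pd.DataFrame:
    return pd.DataFrame(
        {"count": counts, "percent": 100.0 * counts / total}
    )


def pair_summary(outcomes: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Win/draw counts and percentages for a paired strategy comparison."""
    cls = classify_pairs(
        outcomes[f"lifespan_{a}"].to_numpy(), outcomes[f"lifespan_{b}"].to_numpy()
    )
    total = len(cls)
    rows = {}
    for label, col in (("outcome", "winner"), ("operational", "operational")):
        counts = cls[col].value_counts()
        for key, name in (("a", a), ("b", b), ("draw", "draw")):
            rows[f"{label}:{name}"] = counts.get(key, 0)
    return _percent(pd.Series(rows), total)


def triple_summary(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Mixture-vs-both counts and percentages (three-way comparison)."""
    cls = classify_triples(
        outcomes["lifespan_sequence"].to_numpy(),
        outcomes["lifespan_rotation"].to_numpy(),
        outcomes["lifespan_mixture"].to_numpy(),
    )
    total = len(cls)
    rows = {}
    for col in ("outcome", "operational"):
        counts = cls[col].value_counts()
        for key, cnt in counts.items():
            rows[f"{col}:{key}"] = cnt
    return _percent(pd.Series(rows), total)
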