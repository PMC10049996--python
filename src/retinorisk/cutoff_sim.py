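"""Monte Carlo determination of the high/low-risk dividing node.

Random exposure profiles are drawn factor-by-factor from configurable
marginal level probabilities, scored with the model, and the resulting
probabilities sorted ascending.  The rank at which the sorted curve first
crosses P = 0.5 is the dividing node between low- and high-risk patients;
its LP equivalent is 0.5 / prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import CoefficientSet
from .scoring import PatientProfile, probability_from_logit, compute_logit

__all__ = [
    "SimulationConfig",
    "CutoffNode",
    "default_marginals",
    "simulate_profiles",
    "sorted_probability_curve",
    "find_cutoff_node",
    "run_cutoff_simulation",
    "curve_to_csv",
    "plot_curve",
]


class SimulationError(ValueError):
    """Raised for invalid simulation configuration."""


def default_marginals(coeffs: CoefficientSet) -> dict[str, dict[str, float]]:
    """Uninformative marginals: 0.5/0.5 for binary factors, uniform over
    the three lipid-lowering duration levels.  The original study does not
    report the marginals behind its 1000 draws."""
    marginals: dict[str, dict[str, float]] = {}
    for fid in coeffs.factor_ids:
        levels = coeffs.levels_for(fid)
        marginals[fid] = {lvl: 1.0 / len(levels) for lvl in levels}
    return marginals


@dataclass
class SimulationConfig:
    """Configuration of the Monte Carlo cutoff run."""

    coeffs: CoefficientSet
    n_profiles: int = 1000
    marginals: dict[str, dict[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_profiles < 1:
            raise SimulationError(f"n_profiles must be >= 1, got {self.n_profiles}")
        if self.marginals is None:
            self.marginals = default_marginals(self.coeffs)
        for fid in self.coeffs.factor_ids:
            if fid not in self.marginals:
                raise SimulationError(f"no marginal for factor {fid!r}")
            vec = self.marginals[fid]
            levels = self.coeffs.levels_for(fid)
            if set(vec) != set(levels):
                raise SimulationError(
                    f"marginal for {fid!r} must cover levels {levels}, got {sorted(vec)}"
                )
            probs = np.asarray(list(vec.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise SimulationError(
                    f"marginal for {fid!r} must be non-negative and sum to 1"
                )


@dataclass(frozen=True)
class CutoffNode:
    """Location of the dividing node on the sorted probability curve.

    ``status`` is "crossed" when some probability reaches p_star,
    "all-below" or "all-above" otherwise (rank is then None or 1).
    """

    status: str
    rank: int | None
    probability: float | None
    lp_equivalent: float


def simulate_profiles(config: SimulationConfig) -> list[PatientProfile]:
    """Draw ``n_profiles`` independent profiles from the factor marginals."""
    rng = np.random.default_rng(config.seed)
    fids = config.coeffs.factor_ids
    # Draw per factor in a fixed order so results are seed-reproducible.
    draws: dict[str, np.ndarray] = {}
    for fid in fids:
        vec = config.marginals[fid]
        levels = list(vec.keys())
        draws[fid] = rng.choice(levels, size=config.n_profiles, p=list(vec.values()))
    return [
        PatientProfile(
            exposures={fid: str(draws[fid][i]) for fid in fids},
            patient_id=f"sim-{i + 1}",
        )
        for i in range(config.n_profiles)
    ]


def sorted_probability_curve(
    profiles: Sequence[PatientProfile], coeffs: CoefficientSet
) -> pd.DataFrame:
    """Score profiles and sort probabilities ascending.

    Returns a DataFrame with columns ``rank`` (1..n) and ``probability``
    (non-decreasing), ready for plotting or CSV export.
    """
    if not profiles:
        raise SimulationError("no profiles to score")
    probs = np.array(
        [probability_from_logit(compute_logit(p, coeffs)[0]) for p in profiles]
    )
    probs.sort()
    return pd.DataFrame(
        {"rank": np.arange(1, len(probs) + 1), "probability": probs}
    )


def find_cutoff_node(
    curve: pd.DataFrame,
    prevalence: float,
    p_star: float = 0.5,
) -> CutoffNode:
    """First rank whose probability reaches ``p_star`` on the sorted curve.

    The LP equivalent of the node is ``p_star / prevalence`` regardless of
    whether the curve crosses it.
    """
    if not (0.0 < p_star < 1.0):
        raise SimulationError(f"p_star must lie in (0, 1), got {p_star}")
    if curve.empty:
        raise SimulationError("empty curve")
    lp_eq = p_star / prevalence
    probs = curve["probability"].to_numpy()
    idx = np.searchsorted(probs, p_star, side="left")
    if idx >= len(probs):
        return CutoffNode("all-below", None, None, lp_eq)
    if idx == 0:
        # every simulated patient is already at or above the node
        return CutoffNode("all-above", 1, float(probs[0]), lp_eq)
    rank = int(curve["rank"].iloc[idx])
    return CutoffNode("crossed", rank, float(probs[idx]), lp_eq)


def run_cutoff_simulation(config: SimulationConfig, p_star: float = 0.5):
    """Convenience wrapper: simulate, sort, locate the node.

    Returns ``(curve, node)``.
    """
    profiles = simulate_profiles(config)
    curve = sorted_probability_curve(profiles, config.coeffs)
    node = find_cutoff_node(curve, config.coeffs.prevalence, p_star=p_star)
    return curve, node


def curve_to_csv(curve: pd.DataFrame, path: str | Path) -> None:
    curve.to_csv(path, index=False, columns=["rank", "probability"])


def plot_curve(
    curve: pd.DataFrame,
    path: str | Path,
    node: CutoffNode | None = None,
    p_star: float = 0.5,
) -> None:
    """Joint-distribution plot of the sorted probabilities (rank vs P)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(curve["rank"], curve["probability"], s=4)
    ax.axhline(p_star, color="red", lw=0.8, ls="--", label=f"P = {p_star}")
    if node is not None and node.rank is not None:
        ax.axvline(node.rank, color="gray", lw=0.8, ls=":")
    ax.set_xlabel("sorted sample rank")
    ax.set_ylabel("predicted probability of DR")
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
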