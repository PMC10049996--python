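"""Synthetic two-group (DR / non-DR) cohort generator.

The original model was validated on a 60-patient questionnaire cohort that
is not publicly available.  This module generates labelled stand-in
cohorts whose per-factor odds ratios match a target evidence table: given
a control exposure probability q0 and a target odds ratio OR, cases are
drawn with the OR-tilted probability

    q1 = OR^lambda * odds0 / (1 + OR^lambda * odds0),   odds0 = q0/(1-q0),

so that the case-vs-control exposure odds ratio equals OR^lambda exactly
in expectation.  ``effect_scale`` (lambda) interpolates between a null
cohort (lambda = 0, identical groups) and full published effects
(lambda = 1).  Factors are drawn independently within each group; no
exposure correlation is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import BASELINE_LEVELS, CoefficientSet, RiskFactorSpec
from .scoring import PatientProfile

__all__ = [
    "CohortConfig",
    "tilted_probability",
    "generate_cohort",
    "empirical_or",
    "cohort_to_csv",
    "DEFAULT_CONTROL_MARGINAL",
]

#: Default control-group exposure probability per factor level.
DEFAULT_CONTROL_MARGINAL = 0.3


class CohortError(ValueError):
    """Raised for degenerate or inconsistent cohort configuration."""


def tilted_probability(q0: float, target_or: float, effect_scale: float = 1.0) -> float:
    """Case exposure probability giving odds ratio ``target_or**effect_scale``
    against a control exposure probability ``q0``."""
    if not (0.0 < q0 < 1.0):
        if target_or != 1.0 or effect_scale != 0.0:
            raise CohortError(
                f"degenerate control marginal q0={q0} with a non-null odds ratio"
            )
        return q0
    if not target_or > 0:
        raise CohortError(f"odds ratio must be > 0, got {target_or}")
    if effect_scale < 0:
        raise CohortError(f"effect_scale must be >= 0, got {effect_scale}")
    odds = (target_or ** effect_scale) * q0 / (1.0 - q0)
    return odds / (1.0 + odds)


@dataclass
class CohortConfig:
    """Configuration of one synthetic case/control cohort.

    ``target_ors`` maps ``(factor_id, level)`` to the odds ratio of that
    level vs the factor's baseline; by default it is taken from an
    evidence table.  ``control_marginals`` gives the control-group
    probability of each non-baseline level (default 0.3 each).
    """

    target_ors: dict[tuple[str, str], float]
    n_case: int = 30
    n_control: int = 30
    control_marginals: dict[tuple[str, str], float] | None = None
    effect_scale: float = 1.0
    seed: int = 0
    baseline_levels: dict[str, str] = field(default_factory=lambda: dict(BASELINE_LEVELS))

    @classmethod
    def from_evidence(
        cls,
        evidence: Iterable[RiskFactorSpec],
        **kwargs,
    ) -> "CohortConfig":
        target_ors = {(s.factor_id, s.level): s.pooled_or for s in evidence}
        return cls(target_ors=target_ors, **kwargs)

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise CohortError("n_case and n_control must be >= 1")
        if self.effect_scale < 0:
            raise CohortError("effect_scale must be >= 0")
        if self.control_marginals is None:
            self.control_marginals = {
                key: DEFAULT_CONTROL_MARGINAL for key in self.target_ors
            }
        missing = set(self.target_ors) - set(self.control_marginals)
        if missing:
            raise CohortError(f"no control marginal for {sorted(missing)}")
        # Multi-level factors: levels of one factor must not exceed unit mass.
        by_factor: dict[str, float] = {}
        for (fid, _), q in self.control_marginals.items():
            by_factor[fid] = by_factor.get(fid, 0.0) + q
        for fid, total in by_factor.items():
            if total >= 1.0:
                raise CohortError(
                    f"factor {fid!r}: non-baseline level probabilities sum to {total} >= 1"
                )


def _case_marginals(config: CohortConfig) -> dict[tuple[str, str], float]:
    tilted = {
        key: tilted_probability(q0, config.target_ors[key], config.effect_scale)
        for key, q0 in config.control_marginals.items()
    }
    by_factor: dict[str, float] = {}
    for (fid, _), q in tilted.items():
        by_factor[fid] = by_factor.get(fid, 0.0) + q
    for fid, total in by_factor.items():
        if total >= 1.0:
            raise CohortError(
                f"factor {fid!r}: tilted case-level probabilities sum to {total} >= 1"
            )
    return tilted


def _draw_group(
    rng: np.random.Generator,
    n: int,
    marginals: Mapping[tuple[str, str], float],
    baseline_levels: Mapping[str, str],
    id_prefix: str,
) -> list[PatientProfile]:
    # group level keys by factor: each factor is one categorical draw
    factors: dict[str, list[tuple[str, float]]] = {}
    for (fid, level), q in marginals.items():
        factors.setdefault(fid, []).append((level, q))
    profiles = [
        PatientProfile(exposures={}, patient_id=f"{id_prefix}-{i + 1}") for i in range(n)
    ]
    for fid, levels in factors.items():
        names = [baseline_levels[fid]] + [lvl for lvl, _ in levels]
        probs = [1.0 - sum(q for _, q in levels)] + [q for _, q in levels]
        drawn = rng.choice(names, size=n, p=probs)
        for prof, lvl in zip(profiles, drawn):
            prof.exposures[fid] = str(lvl)
    return profiles


def generate_cohort(config: CohortConfig) -> tuple[list[PatientProfile], np.ndarray]:
    """Draw a labelled case/control cohort.

    Returns ``(profiles, labels)`` with cases first; labels are 1 for DR
    cases and 0 for controls.  Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cases = _draw_group(
        rng, config.n_case, _case_marginals(config), config.baseline_levels, "case"
    )
    controls = _draw_group(
        rng, config.n_control, config.control_marginals, config.baseline_levels, "control"
    )
    labels = np.concatenate(
        [np.ones(config.n_case, dtype=int), np.zeros(config.n_control, dtype=int)]
    )
    return cases + controls, labels


def empirical_or(
    profiles: Sequence[PatientProfile],
    labels: Sequence[int],
    factor_id: str,
    level: str = "present",
    baseline_levels: Mapping[str, str] | None = None,
) -> float:
    """Sample odds ratio of a factor level from the 2x2 exposure-by-label
    table, (a*d)/(b*c), with a 0.5 Haldane–Anscombe correction applied to
    every cell when any cell is zero."""
    baseline_levels = baseline_levels or BASELINE_LEVELS
    if len(profiles) != len(labels):
        raise CohortError("profiles and labels differ in length")
    a = b = c = d = 0  # a: exposed case, b: unexposed case, c: exposed ctrl, d: unexposed ctrl
    for prof, lab in zip(profiles, labels):
        if factor_id not in prof.exposures:
            raise CohortError(f"factor {factor_id!r} absent from profiles")
        exposed = prof.exposures[factor_id] == level
        if lab:
            a += exposed
            b += not exposed
        else:
            c += exposed
            d += not exposed
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def cohort_to_csv(
    profiles: Sequence[PatientProfile],
    labels: Sequence[int],
    path: str | Path,
) -> None:
    """Write a cohort as CSV: one factor column per factor plus ``label``."""
    rows = []
    for prof, lab in zip(profiles, labels):
        row = {"patient_id": prof.patient_id, **prof.exposures, "label": int(lab)}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
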