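"""Evidence table and logistic coefficients for the DR risk model.

The model is a literature-coefficient ("Rothman–Keller") logistic score:
each risk factor's coefficient is the natural log of a pooled odds ratio
taken from published meta-analyses, and the intercept is anchored to the
local prevalence of diabetic retinopathy, alpha = ln(p / (1 - p)).

Two coefficient sets are available.  The "printed" set reproduces the
publication's canonical numbers exactly (including an intercept of -0.949
and a smoking coefficient of -0.083 that do not follow from the shipped
odds ratios); the "derived" set recomputes everything from the evidence
table.  A reconciliation report records every discrepancy between the two.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "RiskFactorSpec",
    "CoefficientSet",
    "ReconciliationEntry",
    "beta_from_or",
    "alpha_from_prevalence",
    "build_coefficient_set",
    "load_evidence_table",
    "default_evidence_table",
    "reconcile",
    "DEFAULT_PREVALENCE",
    "PRINTED_BETAS",
    "PRINTED_ALPHA",
    "BASELINE_LEVELS",
]

#: Local DR prevalence used throughout the publication's worked example (27.8%).
DEFAULT_PREVALENCE = 0.278

#: Canonical coefficient set exactly as printed (abstract values).  Keys are
#: (factor_id, level); baseline levels ("absent", "none") carry 0 and are
#: not listed here.
PRINTED_BETAS: dict[tuple[str, str], float] = {
    ("male", "present"): 0.548,
    ("bariatric_surgery", "present"): -0.942,
    ("myopia", "present"): -0.357,
    ("lipid_lowering", "lt3y"): -0.994,
    ("lipid_lowering", "gt3y"): -0.223,
    ("fpg", "present"): 0.223,
    ("duration", "present"): 0.174,
    ("hba1c", "present"): 0.372,
    ("intensive_control", "present"): -0.400,
    ("hypertension", "present"): 0.405,
    ("insulin", "present"): 0.688,
    ("rural", "present"): 0.199,
    ("smoking", "present"): -0.083,
}

#: Printed intercept; stated to correspond to a local prevalence of 27.8%,
#: although ln(0.278/0.722) = -0.954 (the source may have used ~27.9%).
PRINTED_ALPHA = -0.949

#: Baseline (zero-coefficient) level per factor.
BASELINE_LEVELS: dict[str, str] = {
    "male": "absent",
    "bariatric_surgery": "absent",
    "myopia": "absent",
    "lipid_lowering": "none",
    "fpg": "absent",
    "duration": "absent",
    "hba1c": "absent",
    "intensive_control": "absent",
    "hypertension": "absent",
    "insulin": "absent",
    "rural": "absent",
    "smoking": "absent",
}

#: The source's Results section prints the myopia coefficient as -0.375,
#: while the abstract and ln(0.70) give -0.357; the latter is canonical.
KNOWN_ERRATA = {
    ("myopia", "present"): "results section prints -0.375; ln(0.70) = -0.357 is canonical"
}


class EvidenceError(ValueError):
    """Raised for invalid evidence-table content or lookups."""


@dataclass(frozen=True)
class RiskFactorSpec:
    """One evidence-table row: a factor level with its pooled odds ratio.

    Parameters
    ----------
    factor_id : str
        Short identifier, e.g. ``"insulin"``.
    label : str
        Human-readable name.
    level : str
        Category label within the factor ("present" for binary factors;
        "lt3y"/"gt3y" for lipid-lowering duration).
    pooled_or : float
        Pooled odds ratio from meta-analysis, > 0.
    ci_low, ci_high : float
        95% confidence-interval bounds, > 0 with ``ci_high >= ci_low``.
    direction_note : str
        Free-text note (protective vs hazardous).
    """

    factor_id: str
    label: str
    level: str
    pooled_or: float
    ci_low: float
    ci_high: float
    direction_note: str = ""

    def __post_init__(self) -> None:
        if not self.pooled_or > 0:
            raise EvidenceError(
                f"factor {self.factor_id!r}: pooled OR must be > 0, got {self.pooled_or}"
            )
        if not (self.ci_low > 0 and self.ci_high >= self.ci_low):
            raise EvidenceError(
                f"factor {self.factor_id!r}: invalid CI ({self.ci_low}, {self.ci_high})"
            )

    @property
    def or_outside_ci(self) -> bool:
        """True when the pooled OR lies outside its own 95% CI.

        This occurs for the shipped smoking row (OR 0.68, CI 0.86-0.98),
        transcribed as printed.
        """
        return not (self.ci_low <= self.pooled_or <= self.ci_high)


@dataclass
class CoefficientSet:
    """The beta vector plus the prevalence-anchored intercept alpha.

    ``betas`` maps ``(factor_id, level)`` to a log-odds-ratio coefficient;
    baseline levels are implicit zeros (see :data:`BASELINE_LEVELS`).
    """

    betas: dict[tuple[str, str], float]
    alpha: float
    prevalence: float
    source: str  # "printed" | "derived"
    baseline_levels: dict[str, str] = field(default_factory=lambda: dict(BASELINE_LEVELS))

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise EvidenceError(f"prevalence must lie in (0, 1), got {self.prevalence}")
        if not math.isfinite(self.alpha):
            raise EvidenceError("alpha must be finite")

    @property
    def factor_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for fid, _ in self.betas:
            seen.setdefault(fid)
        return list(seen)

    def levels_for(self, factor_id: str) -> list[str]:
        """All declared levels of a factor, baseline first."""
        levels = [self.baseline_levels[factor_id]]
        levels += [lvl for fid, lvl in self.betas if fid == factor_id]
        return levels

    def beta(self, factor_id: str, level: str) -> float:
        """Coefficient for one factor level (0 for the baseline level)."""
        if self.baseline_levels.get(factor_id) == level:
            return 0.0
        try:
            return self.betas[(factor_id, level)]
        except KeyError:
            raise EvidenceError(
                f"unknown factor/level {factor_id!r}={level!r}"
            ) from None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "alpha": self.alpha,
            "prevalence": self.prevalence,
            "source": self.source,
            "betas": {f"{fid}:{lvl}": b for (fid, lvl), b in self.betas.items()},
            "baseline_levels": self.baseline_levels,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CoefficientSet":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        payload = json.loads(text)
        betas = {
            tuple(key.split(":", 1)): float(b) for key, b in payload["betas"].items()
        }
        return cls(
            betas=betas,  # type: ignore[arg-type]
            alpha=float(payload["alpha"]),
            prevalence=float(payload["prevalence"]),
            source=payload.get("source", "derived"),
            baseline_levels=dict(payload.get("baseline_levels", BASELINE_LEVELS)),
        )


@dataclass(frozen=True)
class ReconciliationEntry:
    """One printed-vs-derived coefficient discrepancy."""

    name: str  # factor_id:level, or "alpha"
    printed: float
    derived: float

    @property
    def delta(self) -> float:
        return self.printed - self.derived


def beta_from_or(pooled_or: float, factor: str | None = None) -> float:
    """Convert a pooled odds ratio to a logistic coefficient, ln(OR).

    Rounded half-to-even to 3 decimals, matching the published precision.

    >>> beta_from_or(1.99)
    0.688
    >>> beta_from_or(0.39)
    -0.942
    """
    if not pooled_or > 0:
        who = f" for factor {factor!r}" if factor else ""
        raise EvidenceError(f"odds ratio must be > 0{who}, got {pooled_or}")
    return round(math.log(pooled_or), 3)


def alpha_from_prevalence(p: float) -> float:
    """Prevalence-anchored intercept: ln(p / (1 - p)).

    >>> alpha_from_prevalence(0.5)
    0.0
    """
    if not (0.0 < p < 1.0):
        raise EvidenceError(f"prevalence must lie strictly in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def _evidence_dataframe_to_specs(df: pd.DataFrame) -> list[RiskFactorSpec]:
    required = {"factor_id", "label", "level", "pooled_or", "ci_low", "ci_high"}
    missing = required - set(df.columns)
    if missing:
        raise EvidenceError(f"evidence table missing columns: {sorted(missing)}")
    specs = [
        RiskFactorSpec(
            factor_id=str(row.factor_id),
            label=str(row.label),
            level=str(row.level),
            pooled_or=float(row.pooled_or),
            ci_low=float(row.ci_low),
            ci_high=float(row.ci_high),
        )
        for row in df.itertuples(index=False)
    ]
    seen: set[tuple[str, str]] = set()
    for s in specs:
        key = (s.factor_id, s.level)
        if key in seen:
            raise EvidenceError(f"duplicate evidence row for {key}")
        seen.add(key)
    return specs


def load_evidence_table(path: str | Path) -> list[RiskFactorSpec]:
    """Read an evidence table from CSV or JSON.

    CSV header: ``factor_id,label,level,pooled_or,ci_low,ci_high``.
    JSON: a list of objects with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path)
    return _evidence_dataframe_to_specs(df)


def default_evidence_table() -> list[RiskFactorSpec]:
    """The shipped evidence table (thirteen factor levels, twelve factors)."""
    with resources.as_file(
        resources.files("retinorisk.data") / "dr_evidence_table.csv"
    ) as p:
        return load_evidence_table(p)


def build_coefficient_set(
    evidence: Iterable[RiskFactorSpec],
    prevalence: float = DEFAULT_PREVALENCE,
    mode: str = "printed",
) -> CoefficientSet:
    """Build the model's coefficients from an evidence table.

    ``mode="printed"`` loads the canonical published set (alpha = -0.949 at
    p = 0.278); ``mode="derived"`` computes each beta as ln(OR) and alpha as
    ln(p/(1-p)).  The printed set is the default because the publication's
    worked example is only reproducible with those exact numbers.
    """
    specs = list(evidence)
    if not specs:
        raise EvidenceError("evidence table is empty")
    if mode not in ("printed", "derived"):
        raise EvidenceError(f"unknown mode {mode!r}")

    derived = {
        (s.factor_id, s.level): beta_from_or(s.pooled_or, s.factor_id) for s in specs
    }
    if mode == "derived":
        return CoefficientSet(
            betas=derived,
            alpha=alpha_from_prevalence(prevalence),
            prevalence=prevalence,
            source="derived",
        )

    missing = [k for k in derived if k not in PRINTED_BETAS]
    if missing:
        raise EvidenceError(f"no printed coefficient for factor levels: {missing}")
    betas = {k: PRINTED_BETAS[k] for k in derived}
    return CoefficientSet(
        betas=betas, alpha=PRINTED_ALPHA, prevalence=prevalence, source="printed"
    )


def reconcile(
    evidence: Iterable[RiskFactorSpec],
    prevalence: float = DEFAULT_PREVALENCE,
    tolerance: float = 0.001,
) -> list[ReconciliationEntry]:
    """Compare printed coefficients against ln(OR)-derived ones.

    Returns one entry per coefficient (and the intercept) where
    ``|printed - derived| > tolerance``.  With the shipped table at
    p = 0.278 this flags exactly the smoking coefficient and alpha.
    """
    specs = list(evidence)
    printed = build_coefficient_set(specs, prevalence, mode="printed")
    derived = build_coefficient_set(specs, prevalence, mode="derived")
    out: list[ReconciliationEntry] = []
    for key, b_printed in printed.betas.items():
        b_derived = derived.betas[key]
        if abs(b_printed - b_derived) > tolerance:
            out.append(
                ReconciliationEntry(
                    name=f"{key[0]}:{key[1]}", printed=b_printed, derived=b_derived
                )
            )
    if abs(printed.alpha - derived.alpha) > tolerance:
        out.append(
            ReconciliationEntry(
                name="alpha", printed=printed.alpha, derived=derived.alpha
            )
        )
    return out
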