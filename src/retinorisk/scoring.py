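"""Per-patient scoring: exposures -> logit -> probability -> LP -> risk class.

The score is Logit(P) = alpha + sum_i beta_i X_i over the patient's active
factor levels.  P is the inverse logit, and the relative-risk score
LP = P / p expresses the patient's risk as a multiple of the local DR
prevalence p (LP = 2.75 means "2.75 times the risk of the local diabetic
population").
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from .evidence import CoefficientSet, EvidenceError

__all__ = [
    "PatientProfile",
    "RiskResult",
    "compute_logit",
    "probability_from_logit",
    "relative_risk",
    "classify",
    "score_patient",
    "score_cohort",
    "load_patients_csv",
    "worked_example_profile",
    "FPG_THRESHOLD_MMOL_L",
    "HBA1C_THRESHOLD_PCT",
    "DEFAULT_LP_CUTOFF",
]

#: Binarization default for fasting plasma glucose: "elevated" above the
#: upper normal fasting limit of 6.1 mmol/L.
FPG_THRESHOLD_MMOL_L = 6.1
#: Binarization default for HbA1c: "elevated" at or above the 6.5%
#: diabetes-diagnostic threshold.
HBA1C_THRESHOLD_PCT = 6.5
#: Published LP dividing node: LP > 2.24 marks a high-risk patient.
DEFAULT_LP_CUTOFF = 2.24


class ProfileError(ValueError):
    """Raised when a patient profile does not validate against the model."""


@dataclass
class PatientProfile:
    """One subject's exposure vector.

    ``exposures`` maps factor_id to a level string; binary factors use
    "present"/"absent", lipid-lowering duration uses "none"/"lt3y"/"gt3y".
    Demographics (age, height, weight, ...) are carried but never scored.
    """

    exposures: dict[str, str]
    demographics: dict[str, Any] = field(default_factory=dict)
    patient_id: str | None = None

    def validate(self, coeffs: CoefficientSet) -> None:
        """Check that every model factor has a declared, known level."""
        problems: list[str] = []
        for fid in coeffs.factor_ids:
            level = self.exposures.get(fid)
            if level is None:
                problems.append(f"missing factor {fid!r}")
            elif level not in coeffs.levels_for(fid):
                problems.append(
                    f"factor {fid!r}: unknown level {level!r} "
                    f"(expected one of {coeffs.levels_for(fid)})"
                )
        extra = set(self.exposures) - set(coeffs.factor_ids)
        if extra:
            problems.append(f"unknown factors {sorted(extra)}")
        if problems:
            raise ProfileError("; ".join(problems))


@dataclass
class RiskResult:
    """Scored output for one patient."""

    logit: float
    probability: float
    lp: float
    risk_class: str
    contributions: dict[str, float]
    patient_id: str | None = None

    def to_dict(self) -> dict[str, Any]:
        d = {
            "logit": self.logit,
            "probability": self.probability,
            "lp": self.lp,
            "lp_2dp": round(self.lp, 2),
            "risk_class": self.risk_class,
            "contributions": dict(self.contributions),
        }
        if self.patient_id is not None:
            d["patient_id"] = self.patient_id
        return d


def compute_logit(
    profile: PatientProfile, coeffs: CoefficientSet
) -> tuple[float, dict[str, float]]:
    """Linear predictor alpha + sum of active betas, with per-factor terms.

    Returns ``(logit, contributions)`` where contributions maps each
    factor_id to its additive term (0 for baseline levels).
    """
    profile.validate(coeffs)
    contributions = {
        fid: coeffs.beta(fid, profile.exposures[fid]) for fid in coeffs.factor_ids
    }
    return coeffs.alpha + sum(contributions.values()), contributions


def probability_from_logit(logit: float) -> float:
    """Numerically stable inverse logit, saturating at the float limits."""
    if not math.isfinite(logit):
        raise ProfileError(f"logit must be finite, got {logit}")
    if logit >= 0:
        return 1.0 / (1.0 + math.exp(-logit))
    e = math.exp(logit)
    return e / (1.0 + e)


def relative_risk(probability: float, prevalence: float) -> float:
    """LP score: patient probability as a multiple of local prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise EvidenceError(f"prevalence must lie in (0, 1), got {prevalence}")
    if not (0.0 < probability < 1.0):
        raise ProfileError(f"probability must lie in (0, 1), got {probability}")
    return probability / prevalence


def classify(
    result: "RiskResult | float",
    rule: str = "lp_cutoff",
    lp_cutoff: float = DEFAULT_LP_CUTOFF,
    probability: float | None = None,
) -> str:
    """Assign "high" or "low" risk.

    rule "p_half": high iff probability >= 0.5 (equivalently logit >= 0);
    the boundary belongs to "high".
    rule "lp_cutoff": high iff LP > lp_cutoff (strictly greater, per the
    published wording "greater than 2.24").
    """
    if isinstance(result, RiskResult):
        lp, probability = result.lp, result.probability
    else:
        lp = float(result)
    if rule == "p_half":
        if probability is None:
            raise ProfileError("p_half rule needs a probability")
        return "high" if probability >= 0.5 else "low"
    if rule == "lp_cutoff":
        if not lp_cutoff > 0:
            raise ProfileError(f"lp_cutoff must be > 0, got {lp_cutoff}")
        return "high" if lp > lp_cutoff else "low"
    raise ProfileError(f"unknown classification rule {rule!r}")


def score_patient(
    profile: PatientProfile,
    coeffs: CoefficientSet,
    rule: str = "lp_cutoff",
    lp_cutoff: float = DEFAULT_LP_CUTOFF,
) -> RiskResult:
    """Full scoring pipeline for one patient."""
    logit, contributions = compute_logit(profile, coeffs)
    probability = probability_from_logit(logit)
    lp = relative_risk(probability, coeffs.prevalence)
    result = RiskResult(
        logit=logit,
        probability=probability,
        lp=lp,
        risk_class="",
        contributions=contributions,
        patient_id=profile.patient_id,
    )
    result.risk_class = classify(result, rule=rule, lp_cutoff=lp_cutoff)
    return result


def score_cohort(
    profiles: Iterable[PatientProfile],
    coeffs: CoefficientSet,
    rule: str = "lp_cutoff",
    lp_cutoff: float = DEFAULT_LP_CUTOFF,
) -> list[RiskResult]:
    return [score_patient(p, coeffs, rule=rule, lp_cutoff=lp_cutoff) for p in profiles]


def _binarize(value: float, threshold: float, ge: bool) -> str:
    hit = value >= threshold if ge else value > threshold
    return "present" if hit else "absent"


def load_patients_csv(
    path: str | Path,
    coeffs: CoefficientSet,
    fpg_threshold: float = FPG_THRESHOLD_MMOL_L,
    hba1c_threshold: float = HBA1C_THRESHOLD_PCT,
) -> list[PatientProfile]:
    """Read questionnaire-style patient rows.

    Columns named after factor_ids carry level strings.  Optional
    continuous columns ``fpg_mmol_l`` and ``hba1c_pct`` are auto-binarized
    (FPG elevated when > ``fpg_threshold``; HbA1c elevated when
    >= ``hba1c_threshold``) and take precedence over level columns for the
    corresponding factors.  Other columns (patient_id, age, height_cm,
    weight_kg, label, ...) are carried as demographics.
    """
    df = pd.read_csv(path)
    factor_ids = set(coeffs.factor_ids)
    profiles: list[PatientProfile] = []
    for i, row in df.iterrows():
        exposures: dict[str, str] = {}
        demographics: dict[str, Any] = {}
        for col, value in row.items():
            if col in factor_ids:
                exposures[col] = str(value)
            elif col == "fpg_mmol_l":
                exposures["fpg"] = _binarize(float(value), fpg_threshold, ge=False)
                demographics[col] = float(value)
            elif col == "hba1c_pct":
                exposures["hba1c"] = _binarize(float(value), hba1c_threshold, ge=True)
                demographics[col] = float(value)
            else:
                demographics[col] = value
        pid = str(demographics.get("patient_id", i))
        profiles.append(
            PatientProfile(exposures=exposures, demographics=demographics, patient_id=pid)
        )
    return profiles


def worked_example_profile() -> PatientProfile:
    """The published use-case patient.

    A 60-year-old rural male, 10 years of diabetes, FPG 6.5 mmol/L,
    HbA1c 7%, hypertensive, on insulin with intensive glycemic control,
    a smoker, with no bariatric surgery, myopia or lipid-lowering drugs.
    Scores to logit 1.177 and LP 2.75 at 27.8% prevalence under the
    printed coefficient set.
    """
    return PatientProfile(
        exposures={
            "male": "present",
            "bariatric_surgery": "absent",
            "myopia": "absent",
            "lipid_lowering": "none",
            "fpg": _binarize(6.5, FPG_THRESHOLD_MMOL_L, ge=False),
            "duration": "present",
            "hba1c": _binarize(7.0, HBA1C_THRESHOLD_PCT, ge=True),
            "intensive_control": "present",
            "hypertension": "present",
            "insulin": "present",
            "rural": "present",
            "smoking": "present",
        },
        demographics={"age": 60, "height_cm": 170, "weight_kg": 60,
                      "fpg_mmol_l": 6.5, "hba1c_pct": 7.0, "duration_years": 10},
        patient_id="worked-example",
    )


def results_to_json(results: Iterable[RiskResult], path: str | Path | None = None) -> str:
    """Serialize scored results as a JSON report (one object per patient)."""
    text = json.dumps([r.to_dict() for r in results], indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
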