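"""Design constants of the reference pregnancy cohort.

The synthetic generator emulates a Spanish mother-infant cohort in which
maternal urine was collected at gestational week 12 and children were
assessed at age 4 with the WPPSI-IV (composite indices, mean 100 / SD 15)
and three NEPSY-II subtests (scaled scores, mean 10 / SD 3).  This module
records the recruitment accounting that fixes the analytic sample size,
the covariate marginals used to simulate maternal/child characteristics,
and the outcome-column contract shared by the writer and reader.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Attrition",
    "ATTRITION",
    "analytic_sample_size",
    "WPPSI_OUTCOMES",
    "NEPSY_OUTCOMES",
    "OUTCOME_COLUMNS",
    "COVARIATE_COLUMNS",
    "CovariateMarginals",
    "DEFAULT_COVARIATE_MARGINALS",
]


@dataclass(frozen=True)
class Attrition:
    """Recruitment-to-analysis accounting of the reference cohort."""

    recruited: int = 791
    voluntary_withdrawal: int = 180
    miscarriage: int = 13
    exclusion_criteria: int = 46
    unknown: int = 18
    psych_assessed_at_4y: int = 231
    missing_urine_or_metals: int = 30

    @property
    def lost_to_followup(self) -> int:
        return (
            self.voluntary_withdrawal
            + self.miscarriage
            + self.exclusion_criteria
            + self.unknown
        )

    @property
    def completed_third_trimester(self) -> int:
        return self.recruited - self.lost_to_followup

    @property
    def analytic_n(self) -> int:
        """Mother-infant pairs with both urinary metals and psych data."""
        return self.psych_assessed_at_4y - self.missing_urine_or_metals


ATTRITION = Attrition()


def analytic_sample_size() -> int:
    """Recompute the analytic sample size from the recruitment counts."""
    return ATTRITION.analytic_n


# WPPSI-IV composite indices (mean 100, SD 15) followed by NEPSY-II
# subtests (mean 10, SD 3); column names form the cohort file contract.
WPPSI_OUTCOMES: tuple[str, ...] = (
    "VCI", "FRI", "WMI", "PSI", "FSIQ", "VAI", "NVI", "GAI",
)
NEPSY_OUTCOMES: tuple[str, ...] = (
    "verbal_fluency", "visuomotor_precision", "emotion_recognition",
)
OUTCOME_COLUMNS: tuple[str, ...] = WPPSI_OUTCOMES + NEPSY_OUTCOMES

COVARIATE_COLUMNS: tuple[str, ...] = (
    "age", "bmi", "social_class", "smoking", "meddiet", "child_sex", "feeding",
)


@dataclass(frozen=True)
class CovariateMarginals:
    """Marginal distributions used to simulate the seven model covariates.

    Continuous covariates are normal (age and BMI truncated to plausible
    ranges); binary covariates are Bernoulli with the cohort's observed
    proportions.  Indicator coding: social_class 1 = high; smoking
    1 = ever-smoker; child_sex 1 = female; feeding 1 = mixed/formula
    (non-exclusive breastfeeding).
    """

    age_mean: float = 31.58
    age_sd: float = 4.72
    age_bounds: tuple[float, float] = (18.0, 45.0)
    bmi_mean: float = 24.68
    bmi_sd: float = 4.27
    p_social_class_high: float = 0.254
    p_smoking_ever: float = 0.323
    meddiet_mean: float = 9.65
    meddiet_sd: float = 2.44
    p_child_female: float = 0.468
    p_feeding_nonexclusive: float = 0.229


DEFAULT_COVARIATE_MARGINALS = CovariateMarginals()
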