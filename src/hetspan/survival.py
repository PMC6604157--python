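"""Charlson 10-year survival probability and its regression on heterozygosity.

The Charlson index summarises a patient's mortality risk from age and
comorbid conditions.  Age contributes 0-4 points in decade bands (41-50 -> 1,
..., 71-80 -> 4; the score is not defined above 80).  Each comorbid condition
contributes a fixed weight; three condition families carry a severity variant
with a higher weight.  The estimated 10-year survival probability is

    Z = 0.983 ** exp(0.9 * (A + C))

with A the age points and C the summed condition points, so Z is at most
0.983 (a healthy patient under 41) and decreases strictly with A + C.

``regress_survival`` fits the ordinary least-squares model

    10ySP ~ HetRate + age + comorbidity + gender + PC1..PC5

pooled and per gender (the gender indicator is dropped from single-gender
fits), mirroring how EHR-derived survival is related to an individual's
genome-wide heterozygosity rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

#: Condition weights.  Severity variants (diabetes with end-organ damage,
#: metastatic solid tumor, moderate/severe liver disease) are distinct ids;
#: at most one variant of a family may be present on a record.
CONDITION_POINTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "copd": 1,
    "connective_tissue_disease": 1,
    "peptic_ulcer_disease": 1,
    "diabetes_uncomplicated": 1,
    "diabetes_end_organ_damage": 2,
    "moderate_severe_chronic_kidney_disease": 2,
    "hemiplegia": 2,
    "leukemia": 2,
    "malignant_lymphoma": 2,
    "solid_tumor": 2,
    "solid_tumor_metastatic": 6,
    "liver_disease_mild": 1,
    "liver_disease_moderate_severe": 3,
    "aids": 6,
}

#: Families whose severity variants are mutually exclusive on one record.
SEVERITY_FAMILIES: dict[str, tuple[str, ...]] = {
    "diabetes": ("diabetes_uncomplicated", "diabetes_end_organ_damage"),
    "solid_tumor": ("solid_tumor", "solid_tumor_metastatic"),
    "liver_disease": ("liver_disease_mild", "liver_disease_moderate_severe"),
}

#: One representative (base-severity) id per condition family.
CONDITION_FAMILIES: tuple[str, ...] = (
    "myocardial_infarction", "congestive_heart_failure",
    "peripheral_vascular_disease", "cerebrovascular_disease", "dementia",
    "copd", "connective_tissue_disease", "peptic_ulcer_disease",
    "diabetes_uncomplicated", "moderate_severe_chronic_kidney_disease",
    "hemiplegia", "leukemia", "malignant_lymphoma", "solid_tumor",
    "liver_disease_mild", "aids",
)


class ScoringIneligibleError(ValueError):
    """Raised for records outside the Charlson eligibility window."""


def age_points(age: float) -> int:
    """Age score A: <=40 -> 0, then one point per decade band up to 80.

    Fractional ages are floored to whole years before banding.
    """
    age = int(np.floor(age))
    if age > 80:
        raise ScoringIneligibleError(f"age {age} exceeds 80; score undefined")
    if age < 0:
        raise ValueError("negative age")
    if age <= 40:
        return 0
    return min((age - 41) // 10 + 1, 4)


def comorbidity_points(conditions) -> int:
    """Summed condition score C over a set of catalogue condition ids."""
    conditions = set(conditions)
    unknown = conditions - set(CONDITION_POINTS)
    if unknown:
        raise KeyError(f"unknown condition ids: {sorted(unknown)}")
    for family, variants in SEVERITY_FAMILIES.items():
        if len(conditions & set(variants)) > 1:
            raise ValueError(f"conflicting severity variants for {family}")
    return sum(CONDITION_POINTS[c] for c in conditions)


def charlson_probability(a: int, c: int) -> float:
    """10-year survival probability Z = 0.983^exp(0.9 (A + C))."""
    if a < 0 or c < 0:
        raise ValueError("scores must be non-negative")
    return float(0.983 ** np.exp((a + c) * 0.9))


def charlson_log_probability(a: int, c: int) -> float:
    """ln Z = exp(0.9 (A + C)) ln 0.983.

    Z itself underflows double precision beyond A + C ~ 12; the log form
    stays representable across the whole score grid and preserves the strict
    decrease in A + C.
    """
    if a < 0 or c < 0:
        raise ValueError("scores must be non-negative")
    return float(np.exp((a + c) * 0.9) * np.log(0.983))


def score_ehr(ehr: pd.DataFrame) -> pd.DataFrame:
    """Add age points, comorbidity points and Z to an EHR table.

    Expects columns ``sample_id``, ``age``, ``gender`` and ``conditions``
    (semicolon-separated catalogue ids, empty for none).
    """
    out = ehr.copy()
    out["age_points"] = [age_points(a) for a in out["age"]]
    out["comorbidity_points"] = [
        comorbidity_points([c for c in str(s).split(";") if c])
        for s in out["conditions"].fillna("")
    ]
    out["charlson_z"] = [
        charlson_probability(a, c)
        for a, c in zip(out["age_points"], out["comorbidity_points"])
    ]
    return out


_PREDICTORS = ["het_rate", "age", "comorbidity_points", "gender_female",
               "PC1", "PC2", "PC3", "PC4", "PC5"]


@dataclass
class RegressionReport:
    subset: str
    n: int
    coefficients: pd.DataFrame  # index predictor; columns coef, se, p
    degenerate: bool
    dropped_columns: list[str]

    def coef(self, predictor: str) -> float:
        return float(self.coefficients.loc[predictor, "coef"])

    def pvalue(self, predictor: str) -> float:
        return float(self.coefficients.loc[predictor, "p"])

    def conf_int(self, predictor: str, alpha: float = 0.05):
        row = self.coefficients.loc[predictor]
        t = stats.t.ppf(1 - alpha / 2, self.n - len(self.coefficients) - 1)
        return float(row["coef"] - t * row["se"]), float(row["coef"] + t * row["se"])


def regress_survival(ehr: pd.DataFrame, het_rates: pd.Series,
                     pc_scores: pd.DataFrame | None = None,
                     subset: str = "all",
                     response: str | None = None) -> RegressionReport:
    """OLS fit of 10-year survival probability on heterozygosity rate.

    Parameters
    ----------
    ehr
        Scored EHR table (see :func:`score_ehr`); rows outside (40, 80] are
        excluded before fitting.  If ``response`` is None the observed
        ``ten_year_survival`` column is used when present, else ``charlson_z``.
    het_rates
        Per-sample heterozygosity rate indexed by sample id.
    pc_scores
        Optional per-sample PC1..PC5 frame indexed by sample id; zero-filled
        when absent.
    subset
        ``"all"``, ``"male"`` or ``"female"``; single-gender fits drop the
        gender indicator (it is constant there).
    """
    eligible = ehr[(ehr["age"] > 40) & (ehr["age"] <= 80)]
    scored = eligible if "charlson_z" in eligible else score_ehr(eligible)
    scored = scored.copy()
    if subset != "all":
        scored = scored[scored["gender"] == subset]
    if response is None:
        response = ("ten_year_survival" if "ten_year_survival" in scored
                    else "charlson_z")
    frame = scored.set_index("sample_id")
    frame["het_rate"] = het_rates.reindex(frame.index)
    if frame["het_rate"].isna().any():
        raise ValueError("missing heterozygosity rate for some EHR samples")
    frame["gender_female"] = (frame["gender"] == "female").astype(float)
    for j in range(1, 6):
        col = f"PC{j}"
        if pc_scores is not None and col in pc_scores:
            frame[col] = pc_scores[col].reindex(frame.index).fillna(0.0)
        else:
            frame[col] = 0.0

    predictors = [p for p in _PREDICTORS if not (subset != "all" and p == "gender_female")]
    x = frame[predictors].astype(float)
    # constant columns other than the intercept make the design rank deficient
    dropped = [c for c in predictors if x[c].nunique() <= 1]
    kept = [c for c in predictors if c not in dropped]
    if len(frame) < len(kept) + 2:
        raise ValueError(f"too few samples ({len(frame)}) for {len(kept)} predictors")
    design = sm.add_constant(x[kept])
    fit = sm.OLS(frame[response].astype(float), design).fit()
    coefs = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    for c in dropped:
        coefs.loc[c] = [np.nan, np.nan, np.nan]
    return RegressionReport(subset=subset, n=len(frame),
                            coefficients=coefs.drop(index="const"),
                            degenerate=bool(dropped), dropped_columns=dropped)


def extreme_group_comparison(ehr: pd.DataFrame, het_rates: pd.Series,
                             age_band: tuple[int, int] = (51, 60),
                             z_low: float = 0.10, z_high: float = 0.90,
                             subset: str = "all"):
    """Mann-Whitney U of het rates between low- and high-survival extremes.

    Compares individuals with Z below ``z_low`` against those above
    ``z_high`` within the (inclusive) age band, optionally per gender.
    Returns a :class:`hetspan.het_stats.TestResult`; a ``none`` direction with
    p = NaN and ``statistic`` = NaN flags an empty extreme group (skipped).
    """
    from .het_stats import TestResult

    in_band = ehr[(ehr["age"] >= age_band[0]) & (ehr["age"] <= age_band[1])]
    scored = in_band if "charlson_z" in in_band else score_ehr(in_band)
    if subset != "all":
        scored = scored[scored["gender"] == subset]
    rates = het_rates.reindex(scored["sample_id"]).to_numpy(dtype=float)
    z = scored["charlson_z"].to_numpy()
    low, high = rates[z < z_low], rates[z > z_high]
    if len(low) == 0 or len(high) == 0:
        return TestResult("mannwhitney_extreme_groups", np.nan, np.nan, "none",
                          note="empty extreme group; test skipped")
    stat, p = stats.mannwhitneyu(high, low, alternative="two-sided")
    direction = ("high-survival-higher" if np.median(high) > np.median(low)
                 else "low-survival-higher" if np.median(high) < np.median(low)
                 else "none")
    return TestResult("mannwhitney_extreme_groups", float(stat), float(p), direction)
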