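"""SEDAN and HAT prognostic scores, adapted variants, and univariate odds
ratios.

SEDAN (0-6): blood Sugar 8.1-12.0 mmol/L = 1 point, > 12.0 = 2; Early
infarct signs on CT = 1; Dense cerebral artery (hyperdense MCA) = 1;
Age > 75 years = 1; NIHSS >= 10 = 1.

HAT (0-5): history of diabetes or glucose > 11.1 mmol/L (200 mg/dL) = 1;
baseline NIHSS 15-20 = 1, > 20 = 2; easily visible hypodensity on CT
covering < 1/3 MCA territory = 1, >= 1/3 = 2.

The "adapted" variants keep only the radiological and NIHSS components with
unchanged weights, i.e. adapted SEDAN drops glucose and age (range 0-3) and
adapted HAT drops the glucose/diabetes point (range 0-4; the arithmetic of
the remaining components caps at 4 even though the parent range is printed
out of 5).

Scores take the binary consensus radiology flags; the real-valued mean
Fazekas consensus never enters a score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from sichml.cohort import ClinicalRecord, ConsensusReading


@dataclass(frozen=True)
class ScorePanel:
    sedan: int
    hat: int
    adapted_sedan: int
    adapted_hat: int
    component_breakdown: dict

    def __post_init__(self) -> None:
        b = self.component_breakdown
        assert self.sedan == sum(v for k, v in b.items() if k.startswith("sedan_"))
        assert self.hat == sum(v for k, v in b.items() if k.startswith("hat_"))


def _sedan_components(record: ClinicalRecord, consensus: ConsensusReading) -> dict:
    glucose = 2 if record.glucose > 12.0 else (1 if record.glucose >= 8.1 else 0)
    return {
        "sedan_glucose": glucose,
        "sedan_age": 1 if record.age > 75 else 0,
        "sedan_nihss": 1 if record.nihss >= 10 else 0,
        "sedan_early_infarct": 1 if consensus.acute_ischemia else 0,
        "sedan_dense_artery": 1 if consensus.hyperdense_mca else 0,
    }


def _hat_components(record: ClinicalRecord, consensus: ConsensusReading,
                    diabetes: bool = False) -> dict:
    if record.nihss > 20:
        nihss = 2
    elif record.nihss >= 15:
        nihss = 1
    else:
        nihss = 0
    if consensus.acute_ischemia:
        hypodensity = 2 if consensus.gt_third_mca else 1
    else:
        hypodensity = 0
    return {
        "hat_glucose": 1 if (diabetes or record.glucose > 11.1) else 0,
        "hat_nihss": nihss,
        "hat_hypodensity": hypodensity,
    }


def sedan_score(record: ClinicalRecord, consensus: ConsensusReading) -> int:
    """SEDAN score, 0-6."""
    return sum(_sedan_components(record, consensus).values())


def hat_score(record: ClinicalRecord, consensus: ConsensusReading,
              diabetes: bool = False) -> int:
    """HAT score, 0-5."""
    return sum(_hat_components(record, consensus, diabetes).values())


def adapted_scores(record: ClinicalRecord,
                   consensus: ConsensusReading) -> tuple[int, int]:
    """Radiology + NIHSS components only, parent weights unchanged:
    (adapted SEDAN 0-3, adapted HAT 0-4)."""
    s = _sedan_components(record, consensus)
    h = _hat_components(record, consensus)
    return (s["sedan_nihss"] + s["sedan_early_infarct"] + s["sedan_dense_artery"],
            h["hat_nihss"] + h["hat_hypodensity"])


def score_panel(record: ClinicalRecord, consensus: ConsensusReading,
                diabetes: bool = False) -> ScorePanel:
    s = _sedan_components(record, consensus)
    h = _hat_components(record, consensus, diabetes)
    a_sedan, a_hat = adapted_scores(record, consensus)
    return ScorePanel(sedan=sum(s.values()), hat=sum(h.values()),
                      adapted_sedan=a_sedan, adapted_hat=a_hat,
                      component_breakdown={**s, **h})


# ---------------------------------------------------------------------------
# univariate logistic odds ratios

@dataclass(frozen=True)
class OrResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separated: bool = False


class SeparationError(RuntimeError):
    """Complete separation: no finite maximum-likelihood odds ratio."""


def univariate_or(exposure: Sequence[float], outcome: Sequence[bool],
                  raise_on_separation: bool = False) -> OrResult:
    """Single-predictor logistic regression odds ratio with Wald 95% CI.

    For a binary exposure with all four 2x2 cells non-empty the fitted OR
    equals the cross-product ratio.  Complete (or quasi-complete)
    separation is flagged rather than reported as a finite OR.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one subject in each outcome class")
    X = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            if raise_on_separation:
                raise SeparationError("logistic fit failed to converge")
            return OrResult(np.nan, np.nan, np.nan, np.nan, separated=True)
    coef = fit.params[1]
    se = np.sqrt(fit.cov_params()[1, 1])
    if not np.isfinite(coef) or not np.isfinite(se) or abs(coef) > 30:
        if raise_on_separation:
            raise SeparationError("complete separation: odds ratio diverges")
        return OrResult(np.nan, np.nan, np.nan, np.nan, separated=True)
    with np.errstate(over="ignore"):
        # a huge Wald SE can overflow the upper CI; report inf in that case
        return OrResult(
            odds_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.959963984540054 * se)),
            ci_high=float(np.exp(coef + 1.959963984540054 * se)),
            p_value=float(fit.pvalues[1]),
        )


def or_from_cells(exposed_cases: int, unexposed_cases: int,
                  exposed_controls: int, unexposed_controls: int) -> OrResult:
    """Odds ratio for a 2x2 table via the same logistic path, by expanding
    the table into per-subject exposure/outcome vectors."""
    exposure = ([1.0] * exposed_cases + [0.0] * unexposed_cases
                + [1.0] * exposed_controls + [0.0] * unexposed_controls)
    outcome = ([True] * (exposed_cases + unexposed_cases)
               + [False] * (exposed_controls + unexposed_controls))
    return univariate_or(exposure, outcome)


def cohort_or_table(records: Sequence[ClinicalRecord],
                    consensuses: Sequence[ConsensusReading]):
    """Per-variable univariate odds ratios for a cohort, as a DataFrame with
    group means / percentages — the shape of a baseline-characteristics
    table."""
    import pandas as pd
    from sichml.cohort import Outcome

    y = np.array([r.outcome == Outcome.SICH for r in records])
    variables: dict[str, np.ndarray] = {
        "gender_male": np.array([r.gender_male for r in records], dtype=float),
        "age": np.array([r.age for r in records]),
        "treatment_delay": np.array([r.treatment_delay for r in records]),
        "nihss": np.array([r.nihss for r in records], dtype=float),
        "sbp": np.array([r.sbp for r in records]),
        "glucose": np.array([r.glucose for r in records]),
        "inr": np.array([r.inr for r in records]),
        "platelets": np.array([r.platelets for r in records]),
        "antithrombotic": np.array([r.antithrombotic for r in records], dtype=float),
        "ct_acute_ischemia": np.array([c.acute_ischemia for c in consensuses], dtype=float),
        "ct_gt_third_mca": np.array([c.gt_third_mca for c in consensuses], dtype=float),
        "ct_hyperdense_mca": np.array([c.hyperdense_mca for c in consensuses], dtype=float),
        "fazekas": np.array([c.fazekas for c in consensuses]),
    }
    panels = [score_panel(r, c) for r, c in zip(records, consensuses)]
    variables["sedan"] = np.array([p.sedan for p in panels], dtype=float)
    variables["hat"] = np.array([p.hat for p in panels], dtype=float)
    variables["adapted_sedan"] = np.array([p.adapted_sedan for p in panels], dtype=float)
    variables["adapted_hat"] = np.array([p.adapted_hat for p in panels], dtype=float)

    rows = []
    for name, values in variables.items():
        res = univariate_or(values, y)
        rows.append({
            "variable": name,
            "sich_mean": float(values[y].mean()),
            "no_sich_mean": float(values[~y].mean()),
            "odds_ratio": res.odds_ratio,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "p_value": res.p_value,
            "separated": res.separated,
        })
    return pd.DataFrame(rows)
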