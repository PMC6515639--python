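"""Cohort ingestion, exposure categorization and design-matrix construction.

The study design combines cumulative corticosteroid (CS) dose, dichotomized
at its third quartile (13,414 mg/m^2 prednisone-equivalent), with cranial
radiotherapy (CRT, yes/no) into a three-level exposure: LD/No CRT (baseline),
LD/CRT, HD/CRT.  No survivor received high-dose CS without CRT, so that
combination is rejected rather than silently categorized.  Adjustment
covariates are sex, age at diagnosis, WBC count at diagnosis (functional form
selected by AIC among 1-df transforms) and time since diagnosis.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError, UnsupportedExposureError, ValidationError

logger = logging.getLogger(__name__)

#: Third quartile of the cumulative prednisone-equivalent CS dose (mg/m^2).
CS_DOSE_THRESHOLD = 13414.0

OUTCOME_COLUMNS = ("obesity", "insulin_resistance", "pre_hypertension", "dyslipidemia")
COVARIATE_COLUMNS = ("sex", "age_dx", "wbc_dx", "time_dx")

WBC_FORMS = {
    "identity": lambda w: w,
    "log": np.log,
    "sqrt": np.sqrt,
}

COVARIATE_SETS = ("crude", "full", "full_no_wbc")


class Exposure(enum.IntEnum):
    """Three-level combined CS/CRT exposure; T0 is the reference."""

    LD_NO_CRT = 0  # T0: low-dose CS, no CRT
    LD_CRT = 1     # T1: low-dose CS, CRT
    HD_CRT = 2     # T2: high-dose CS, CRT

    @property
    def label(self) -> str:
        return ("LD/No CRT", "LD/CRT", "HD/CRT")[int(self)]


def categorize_exposure(cs_dose: float, crt: int,
                        threshold: float = CS_DOSE_THRESHOLD) -> Exposure:
    """Map (CS dose, CRT) to the three-level exposure.

    Doses exactly at the threshold count as low dose (the split is "at the
    third quartile" with ties assigned to the lower category).  High-dose
    without CRT does not exist in the design and raises.
    """
    if cs_dose < 0:
        raise ValidationError(f"cs_dose must be nonnegative, got {cs_dose}")
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    crt = int(crt)
    if crt not in (0, 1):
        raise ValidationError(f"crt must be 0/1, got {crt}")
    high = cs_dose > threshold
    if high and crt == 0:
        raise UnsupportedExposureError(
            "high-dose corticosteroids without cranial radiotherapy is not a "
            "category of the study design")
    if not high:
        return Exposure.LD_CRT if crt else Exposure.LD_NO_CRT
    return Exposure.HD_CRT


@dataclass(frozen=True)
class SurvivorRecord:
    """One survivor: four binary outcomes, exposure, adjustment covariates."""

    id: str
    y: tuple[int, int, int, int]
    exposure: Exposure
    sex: int
    age_dx: float
    wbc_dx: float
    time_dx: float
    cs_dose: float | None = None
    crt: int | None = None

    def __post_init__(self):
        if any(v not in (0, 1) for v in self.y):
            raise ValidationError(f"record {self.id}: outcomes must be 0/1, got {self.y}")
        if self.sex not in (0, 1):
            raise ValidationError(f"record {self.id}: sex must be 0/1")
        if not (self.age_dx >= 0 and self.wbc_dx > 0 and self.time_dx >= 0):
            raise ValidationError(f"record {self.id}: covariates out of range")
        if self.crt is not None and self.crt == 0 and self.exposure is Exposure.HD_CRT:
            raise UnsupportedExposureError(
                f"record {self.id}: HD exposure recorded without CRT")


@dataclass(frozen=True)
class CohortData:
    """An ordered collection of survivor records with a fixed covariate order."""

    records: tuple[SurvivorRecord, ...]
    covariate_names: tuple[str, ...] = COVARIATE_COLUMNS

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def outcomes(self) -> np.ndarray:
        """(n, 4) binary outcome matrix in (O, I, H, D) order."""
        return np.array([r.y for r in self.records], dtype=float).reshape(self.n, 4)

    @property
    def exposures(self) -> np.ndarray:
        return np.array([int(r.exposure) for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"id": r.id}
            row.update(dict(zip(OUTCOME_COLUMNS, r.y)))
            row.update(exposure=int(r.exposure), sex=r.sex, age_dx=r.age_dx,
                       wbc_dx=r.wbc_dx, time_dx=r.time_dx)
            if r.cs_dose is not None:
                row["cs_dose"] = r.cs_dose
            if r.crt is not None:
                row["crt"] = r.crt
            rows.append(row)
        return pd.DataFrame(rows)


DEFAULT_SCHEMA = {name: name for name in
                  ("id",) + OUTCOME_COLUMNS + COVARIATE_COLUMNS + ("cs_dose", "crt", "exposure")}


def load_cohort(path, schema: dict[str, str] | None = None,
                threshold: float = CS_DOSE_THRESHOLD) -> CohortData:
    """Read a delimited cohort table (CSV, header row) into a CohortData.

    ``schema`` maps canonical field names to file column names; unmapped
    fields default to their canonical names.  The exposure category is taken
    from an ``exposure`` column when present, otherwise derived from CS dose
    and CRT; rows missing those ingredients are dropped with a logged count.
    Record order equals file order.
    """
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: empty cohort file")

    required = list(OUTCOME_COLUMNS + COVARIATE_COLUMNS)
    has_exposure = mapping["exposure"] in df.columns
    if not has_exposure:
        required += ["cs_dose", "crt"]
    missing = [mapping[f] for f in required if mapping[f] not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mapped column(s) {missing}")

    records = []
    n_dropped = 0
    for pos, (_, row) in enumerate(df.iterrows()):
        rid = str(row[mapping["id"]]) if mapping["id"] in df.columns else str(pos)
        y = []
        for oc in OUTCOME_COLUMNS:
            v = row[mapping[oc]]
            if pd.isna(v) or float(v) not in (0.0, 1.0):
                raise ValidationError(
                    f"{path}: non-binary value {v!r} for outcome {oc} in row {pos} (id={rid})")
            y.append(int(v))
        cs_dose = row[mapping["cs_dose"]] if mapping["cs_dose"] in df.columns else None
        crt = row[mapping["crt"]] if mapping["crt"] in df.columns else None
        if has_exposure and not pd.isna(row[mapping["exposure"]]):
            exposure = Exposure(int(row[mapping["exposure"]]))
        else:
            if pd.isna(cs_dose) or pd.isna(crt):
                n_dropped += 1
                continue
            exposure = categorize_exposure(float(cs_dose), int(crt), threshold)
        records.append(SurvivorRecord(
            id=rid, y=tuple(y), exposure=exposure,
            sex=int(row[mapping["sex"]]), age_dx=float(row[mapping["age_dx"]]),
            wbc_dx=float(row[mapping["wbc_dx"]]), time_dx=float(row[mapping["time_dx"]]),
            cs_dose=None if cs_dose is None or pd.isna(cs_dose) else float(cs_dose),
            crt=None if crt is None or pd.isna(crt) else int(crt)))
    if n_dropped:
        logger.info("load_cohort: dropped %d row(s) with missing exposure ingredients "
                    "(complete-case analysis)", n_dropped)
    if not records:
        raise ValidationError(f"{path}: no usable records after exclusions")
    return CohortData(records=tuple(records))


def write_cohort(cohort: CohortData, path) -> None:
    """Write a cohort back to CSV in the same layout load_cohort reads."""
    cohort.to_frame().to_csv(path, index=False)


def design_terms(covariate_set: str = "full") -> tuple[str, ...]:
    """Ordered design column names for one outcome's linear predictor."""
    if covariate_set not in COVARIATE_SETS:
        raise ConfigurationError(f"unknown covariate set {covariate_set!r}")
    terms = ["intercept", "t1", "t2"]
    if covariate_set == "full":
        terms += ["sex", "age_dx", "wbc_dx", "time_dx"]
    elif covariate_set == "full_no_wbc":
        terms += ["sex", "age_dx", "time_dx"]
    return tuple(terms)


def build_design(record: SurvivorRecord, covariate_set: str = "full",
                 wbc_form: str = "identity") -> np.ndarray:
    """One survivor's design row: intercept, treatment dummies, covariates.

    Covariates enter on their natural scale (per-10-unit WBC odds ratios are
    produced at reporting time by rescaling the coefficient, not here).
    """
    if wbc_form not in WBC_FORMS:
        raise ConfigurationError(f"unknown WBC transform {wbc_form!r}")
    t1 = 1.0 if record.exposure is Exposure.LD_CRT else 0.0
    t2 = 1.0 if record.exposure is Exposure.HD_CRT else 0.0
    row = [1.0, t1, t2]
    for term in design_terms(covariate_set)[3:]:
        if term == "wbc_dx":
            row.append(float(WBC_FORMS[wbc_form](record.wbc_dx)))
        else:
            row.append(float(getattr(record, term)))
    return np.array(row)


def design_matrix(cohort: CohortData, covariate_set: str = "full",
                  wbc_form: str = "identity") -> tuple[np.ndarray, tuple[str, ...]]:
    """(n, q) design matrix and its term names."""
    X = np.vstack([build_design(r, covariate_set, wbc_form) for r in cohort.records])
    return X, design_terms(covariate_set)


def descriptive_summary(cohort: CohortData) -> pd.DataFrame:
    """Cohort descriptives overall and by exposure group.

    Binary variables as count and percent (one decimal); continuous variables
    as mean and sample SD (SD absent for groups of size 1).  Returned tidy:
    one row per (variable, statistic), one column per group.
    """
    if cohort.n < 1:
        raise ValidationError("empty cohort")
    df = cohort.to_frame()
    groups = {"overall": df}
    for exp in Exposure:
        groups[exp.label] = df[df["exposure"] == int(exp)]

    binary_vars = list(OUTCOME_COLUMNS) + ["sex"]
    continuous_vars = [c for c in ("cs_dose", "age_dx", "time_dx", "wbc_dx")
                       if c in df.columns]
    rows = []
    rows.append({"variable": "n", "statistic": "count",
                 **{g: float(len(sub)) for g, sub in groups.items()}})
    rows.append({"variable": "n", "statistic": "percent",
                 **{g: round(100.0 * len(sub) / cohort.n, 1) for g, sub in groups.items()}})
    for var in binary_vars:
        counts = {g: float(sub[var].sum()) for g, sub in groups.items()}
        pcts = {g: (round(100.0 * sub[var].sum() / len(sub), 1) if len(sub) else np.nan)
                for g, sub in groups.items()}
        rows.append({"variable": var, "statistic": "count", **counts})
        rows.append({"variable": var, "statistic": "percent", **pcts})
    for var in continuous_vars:
        means = {g: (float(sub[var].mean()) if len(sub) else np.nan)
                 for g, sub in groups.items()}
        sds = {g: (float(sub[var].std(ddof=1)) if len(sub) > 1 else np.nan)
               for g, sub in groups.items()}
        rows.append({"variable": var, "statistic": "mean", **means})
        rows.append({"variable": var, "statistic": "sd", **sds})
    return pd.DataFrame(rows).set_index(["variable", "statistic"])


def format_descriptive(summary: pd.DataFrame) -> str:
    """Human-readable text rendering of descriptive_summary output."""
    lines = []
    header = ["variable".ljust(20)] + [c.rjust(14) for c in summary.columns]
    lines.append(" ".join(header))
    for var in summary.index.get_level_values(0).unique():
        block = summary.loc[var]
        stats_here = list(block.index)
        if "count" in stats_here and "percent" in stats_here:
            cells = [f"{block.loc['count', c]:.0f} ({block.loc['percent', c]:.1f}%)"
                     for c in summary.columns]
        elif "mean" in stats_here:
            cells = []
            for c in summary.columns:
                sd = block.loc["sd", c]
                sd_txt = f"{sd:.3g}" if np.isfinite(sd) else "--"
                cells.append(f"{block.loc['mean', c]:.3g} ({sd_txt})")
        else:
            cells = [f"{block.loc['count', c]:.0f}" for c in summary.columns]
        lines.append(" ".join([str(var).ljust(20)] + [t.rjust(14) for t in cells]))
    return "\n".join(lines)


def select_covariate_form(cohort: CohortData, outcome: int | str,
                          candidate_forms: tuple[str, ...] = ("identity", "log", "sqrt"),
                          covariate_set: str = "full") -> str:
    """AIC selection of the 1-df WBC functional form.

    Fits one maximum-likelihood univariate logistic regression of the chosen
    outcome on the fully adjusted design per candidate transform and returns
    the form with smallest AIC = 2k - 2 loglik.  Ties break by candidate
    order; candidates whose fit fails (e.g., perfect separation) are excluded
    with a warning.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if isinstance(outcome, str):
        outcome = OUTCOME_COLUMNS.index(outcome)
    for form in candidate_forms:
        if form not in WBC_FORMS:
            raise ConfigurationError(f"unknown WBC transform {form!r}")
    if len(candidate_forms) == 1:
        return candidate_forms[0]
    y = cohort.outcomes[:, outcome]
    if y.min() == y.max():
        raise ValidationError("outcome has a single class; AIC comparison undefined")
    best_form, best_aic = None, np.inf
    for form in candidate_forms:
        X, _ = design_matrix(cohort, covariate_set, wbc_form=form)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.params)):
                raise PerfectSeparationError("non-finite estimates")
            aic = float(fit.aic)
        except Exception as exc:  # separation / convergence failure
            warnings.warn(f"WBC form {form!r} excluded from AIC comparison: {exc}")
            continue
        if aic < best_aic - 1e-12:
            best_form, best_aic = form, aic
    if best_form is None:
        raise ValidationError("no WBC candidate form could be fitted")
    return best_form
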