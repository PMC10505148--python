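"""Group-difference, validity, modality, confound and power analyses.

The inference layer mirrors a standard clinical-comparison protocol for a
two-group (clinical high-risk, CHR, vs. healthy control, HC) speech study:

* ordinary least squares of each log-transformed speech measure on group
  status, controlling for the participant's mean speech rate when the
  measure is duration-derived;
* Pearson validity correlations, within the CHR group only, between each
  measure that shows a significant group difference and clinical (SIPS
  symptom totals, item G3), motor (finger-tapping CoV per hand) and risk
  (SIPS-RC score) variables;
* post-hoc stratification by testing modality (in-person vs. remote) with a
  group x modality interaction model;
* demographic-confound regressions and a leave-one-out univariate logistic
  classification;
* Fisher-z power calculations for a two-sided test of a Pearson r.

Alpha is 0.05 throughout, uncorrected, matching the protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from math import atanh, ceil, sqrt, tanh
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import InferenceError, SchemaError, ValidationError
from .measures import (
    DURATIONAL_MEASURES,
    MEASURE_TASKS,
    Measure,
    MeasureTable,
    log_value,
)
from .segments import Task

ALPHA = 0.05

#: Table-2-style validation variables (columns of the participant table)
VALIDATION_FIELDS = [
    "sips_positive_total",
    "sips_negative_total",
    "sips_disorganized_total",
    "sips_g3",
    "tap_cov_dominant",
    "tap_cov_nondominant",
    "sips_rc_risk",
]

PARTICIPANT_COLUMNS = [
    "participant_id", "group", "modality", "age", "sex", "race", "ethnicity",
    "first_language", "sips_positive_total", "sips_negative_total",
    "sips_disorganized_total", "sips_g3",
    "tap_dom_1", "tap_dom_2", "tap_dom_3",
    "tap_nondom_1", "tap_nondom_2", "tap_nondom_3",
    "sips_rc_risk",
]


@dataclass(slots=True)
class ParticipantRecord:
    """Group membership plus clinical / motor / risk / demographic covariates."""

    participant_id: str
    group: str  # "CHR" or "HC"
    modality: str = "in_person"
    age: Optional[float] = None
    sex: Optional[str] = None
    race: Optional[str] = None
    ethnicity: Optional[str] = None
    first_language: Optional[str] = None
    sips_positive_total: Optional[float] = None
    sips_negative_total: Optional[float] = None
    sips_disorganized_total: Optional[float] = None
    sips_g3: Optional[float] = None
    tap_counts_dominant: tuple[int, ...] = ()
    tap_counts_nondominant: tuple[int, ...] = ()
    sips_rc_risk: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("CHR", "HC"):
            raise ValidationError(f"group must be CHR or HC, got {self.group!r}")
        for hand in (self.tap_counts_dominant, self.tap_counts_nondominant):
            if any((c != int(c) or c <= 0) for c in hand):
                raise ValidationError("tap counts must be positive integers")


@dataclass(slots=True)
class RegressionResult:
    """Coefficient of interest from one OLS / logistic fit."""

    beta: float
    se: float
    t: float
    p: float
    n: int
    covariates: list[str] = dc_field(default_factory=list)
    term: str = "group"


@dataclass(slots=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(slots=True)
class PowerSpec:
    """Inputs of a Fisher-z power calculation (two-sided test of Pearson r)."""

    r: float = 0.37
    alpha: float = 0.05
    power: float = 0.80
    n: int = 0


# --------------------------------------------------------------------------- #
# participant table I/O
# --------------------------------------------------------------------------- #
def read_participants_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing participant columns {missing}")
    return df


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        taps_d = tuple(r.tap_counts_dominant) + (np.nan,) * 3
        taps_n = tuple(r.tap_counts_nondominant) + (np.nan,) * 3
        rows.append(
            [
                r.participant_id, r.group, r.modality, r.age, r.sex, r.race,
                r.ethnicity, r.first_language, r.sips_positive_total,
                r.sips_negative_total, r.sips_disorganized_total, r.sips_g3,
                taps_d[0], taps_d[1], taps_d[2], taps_n[0], taps_n[1], taps_n[2],
                r.sips_rc_risk,
            ]
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


# --------------------------------------------------------------------------- #
# elementary operations
# --------------------------------------------------------------------------- #
def finger_tapping_cov(record, hand: str = "dominant") -> Optional[float]:
    """CoV of the number of taps across the first three trials of one hand.

    Only the first three trials enter, so in-person sessions (which ran five
    trials) are scored on the same footing as remote ones.  Returns None
    (missing) when fewer than three trials are available.
    """
    if hand not in ("dominant", "nondominant"):
        raise ValueError(f"unknown hand {hand!r}")
    if isinstance(record, ParticipantRecord):
        counts = (
            record.tap_counts_dominant if hand == "dominant"
            else record.tap_counts_nondominant
        )
        counts = list(counts)
    else:  # mapping / pandas row with tap_{dom,nondom}_{1..3} fields
        key = "dom" if hand == "dominant" else "nondom"
        counts = [record[f"tap_{key}_{i}"] for i in (1, 2, 3)]
    counts = [c for c in counts if c is not None and np.isfinite(c)]
    if len(counts) < 3:
        return None
    x = np.asarray(counts[:3], dtype=float)
    return float(np.std(x, ddof=1) / np.mean(x))


def attach_tapping_covs(participants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with tap_cov_dominant / tap_cov_nondominant columns."""
    out = participants.copy()
    for hand, col in (("dominant", "tap_cov_dominant"), ("nondominant", "tap_cov_nondominant")):
        out[col] = [
            v if (v := finger_tapping_cov(row, hand)) is not None else np.nan
            for row in out.to_dict("records")
        ]
    return out


def log_transform_measures(table: MeasureTable, epsilon: float = 1e-3) -> MeasureTable:
    """Re-populate the log column from raw values (log(x), zeros -> log(eps))."""
    data = table.data.copy()
    raw = data["raw"]
    if ((raw < 0) & (data["measure"] != Measure.FORMANT_DISPERSION_CHANGE.value)).any():
        raise ValidationError("negative raw value in a non-signed measure")
    data["log"] = [np.nan if pd.isna(v) else log_value(float(v), epsilon) for v in raw]
    return MeasureTable(data)


# --------------------------------------------------------------------------- #
# group differences
# --------------------------------------------------------------------------- #
def _measure_design(
    table: MeasureTable,
    participants: pd.DataFrame,
    measure: Measure | str,
    task: Task | str,
) -> pd.DataFrame:
    """Per-participant frame of log measure, group indicator and rate covariate."""
    measure = Measure(measure)
    y = table.series(measure, task, scale="log").rename("y")
    df = participants.set_index("participant_id").join(y, how="inner")
    if measure in DURATIONAL_MEASURES:
        rate = table.series(Measure.SPEECH_RATE_MEAN, task, scale="raw")
        df = df.join(rate.rename(Measure.SPEECH_RATE_MEAN.value), how="left")
    df["group_chr"] = (df["group"] == "CHR").astype(float)
    return df


def fit_group_difference(
    table: MeasureTable,
    participants: pd.DataFrame,
    measure: Measure | str,
    task: Task | str,
    min_per_group: int = 3,
) -> RegressionResult:
    """OLS of the log measure on group status (CHR = 1, HC = 0).

    Duration-derived measures additionally control for the participant's
    mean speech rate in the same task.  Missing covariates trigger listwise
    deletion; a collinear covariate is dropped with a warning.
    """
    measure = Measure(measure)
    df = _measure_design(table, participants, measure, task)
    covariates = [Measure.SPEECH_RATE_MEAN.value] if measure in DURATIONAL_MEASURES else []
    cols = ["y", "group_chr"] + covariates
    df = df[cols + ["group"]].dropna(subset=cols)

    counts = df["group"].value_counts()
    for g in ("CHR", "HC"):
        if counts.get(g, 0) == 0:
            raise InferenceError(f"no usable {g} participants for {measure.value}/{task}")
        if counts.get(g, 0) < min_per_group:
            raise InferenceError(
                f"fewer than {min_per_group} {g} participants with "
                f"{measure.value}/{task} present"
            )

    X = df[["group_chr"] + covariates].to_numpy(float)
    kept = covariates
    design = np.column_stack([np.ones(len(df)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            f"{measure.value}/{task}: collinear covariate dropped", stacklevel=2
        )
        kept = []
        design = np.column_stack([np.ones(len(df)), df[["group_chr"]].to_numpy(float)])
    fit = sm.OLS(df["y"].to_numpy(float), design).fit()
    return RegressionResult(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        t=float(fit.tvalues[1]),
        p=float(fit.pvalues[1]),
        n=int(fit.nobs),
        covariates=kept,
    )


# --------------------------------------------------------------------------- #
# validity correlations (CHR only, gated on significant group differences)
# --------------------------------------------------------------------------- #
def fit_validity_correlation(
    table: MeasureTable,
    participants: pd.DataFrame,
    measure: Measure | str,
    task: Task | str,
    validation_field: str,
    min_pairs: int = 4,
) -> CorrelationResult:
    """Pearson r between a log speech measure and one validation variable.

    Computed within the CHR group only.  Raises on fewer than ``min_pairs``
    complete pairs or zero variance in either variable.
    """
    if validation_field in ("tap_cov_dominant", "tap_cov_nondominant") and \
            validation_field not in participants.columns:
        participants = attach_tapping_covs(participants)
    if validation_field not in participants.columns:
        raise SchemaError(f"unknown validation field {validation_field!r}")
    chr_only = participants[participants["group"] == "CHR"]
    y = table.series(measure, task, scale="log")
    df = chr_only.set_index("participant_id")[[validation_field]].join(y.rename("y"), how="inner")
    df = df.dropna()
    if len(df) < min_pairs:
        raise InferenceError(
            f"only {len(df)} complete CHR pairs for {validation_field} "
            f"(need >= {min_pairs})"
        )
    a = df["y"].to_numpy(float)
    b = df[validation_field].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InferenceError("correlation undefined: zero variance")
    r, p = st.pearsonr(a, b)
    return CorrelationResult(r=float(r), p=float(p), n=len(df))


def validity_grid(
    table: MeasureTable,
    participants: pd.DataFrame,
    tasks: Sequence[Task | str],
    measures: Sequence[Measure | str],
    validation_fields: Sequence[str] = tuple(VALIDATION_FIELDS),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Table-2-style grid: validity correlations for significant measures only.

    For each task x measure, the group model is fit first; validity
    correlations are computed only when its p-value is below ``alpha``
    (the gating rule of the protocol).
    """
    participants = attach_tapping_covs(participants)
    rows = []
    for task in tasks:
        for measure in measures:
            measure = Measure(measure)
            if Task(task) not in MEASURE_TASKS[measure]:
                continue
            try:
                group_fit = fit_group_difference(table, participants, measure, task)
            except InferenceError:
                continue
            if group_fit.p >= alpha:
                continue
            for field in validation_fields:
                try:
                    c = fit_validity_correlation(table, participants, measure, task, field)
                    rows.append((Task(task).value, measure.value, field, c.r, c.p, c.n))
                except InferenceError:
                    rows.append((Task(task).value, measure.value, field, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["task", "measure", "validation_field", "r", "p", "n"])


# --------------------------------------------------------------------------- #
# modality stratification
# --------------------------------------------------------------------------- #
@dataclass
class ModalityAnalysis:
    per_modality: dict[str, RegressionResult]
    interaction: Optional[RegressionResult]


def modality_stratified_analysis(
    table: MeasureTable,
    participants: pd.DataFrame,
    measure: Measure | str,
    task: Task | str,
) -> ModalityAnalysis:
    """Group models per testing modality plus a group x modality interaction.

    Strata with an empty group x modality cell are skipped with a warning.
    The interaction model is fit on the full sample (group, modality and
    their product, plus the rate covariate where applicable) and reports
    the interaction coefficient; it requires both modalities.
    """
    measure = Measure(measure)
    per_modality: dict[str, RegressionResult] = {}
    for modality in ("in_person", "remote"):
        sub = participants[participants["modality"] == modality]
        try:
            per_modality[modality] = fit_group_difference(table, sub, measure, task)
        except InferenceError as exc:
            warnings.warn(f"stratum {modality} skipped: {exc}", stacklevel=2)

    interaction = None
    if len(per_modality) == 2:
        df = _measure_design(table, participants, measure, task)
        covariates = (
            [Measure.SPEECH_RATE_MEAN.value] if measure in DURATIONAL_MEASURES else []
        )
        df["remote"] = (df["modality"] == "remote").astype(float)
        df["group_x_remote"] = df["group_chr"] * df["remote"]
        cols = ["y", "group_chr", "remote", "group_x_remote"] + covariates
        df = df.dropna(subset=cols)
        design = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(float) for c in cols[1:]]
        )
        fit = sm.OLS(df["y"].to_numpy(float), design).fit()
        interaction = RegressionResult(
            beta=float(fit.params[3]),
            se=float(fit.bse[3]),
            t=float(fit.tvalues[3]),
            p=float(fit.pvalues[3]),
            n=int(fit.nobs),
            covariates=covariates,
            term="group_x_remote",
        )
    return ModalityAnalysis(per_modality=per_modality, interaction=interaction)


# --------------------------------------------------------------------------- #
# confounds and classification
# --------------------------------------------------------------------------- #
@dataclass
class ConfoundAnalysis:
    demographic_results: dict[str, RegressionResult]
    loo_accuracy: float
    n: int


def confound_and_classification(
    table: MeasureTable,
    participants: pd.DataFrame,
    measure: Measure | str,
    task: Task | str,
    demographics: Sequence[str] = ("age", "sex", "race", "first_language"),
) -> ConfoundAnalysis:
    """Demographic-confound regressions plus leave-one-out classification.

    Continuous demographics are regressed on the log measure with OLS;
    categorical ones are binarised (most frequent level vs. rest) and fit
    with logistic regression.  Constant demographics are skipped.
    Classification is a univariate logistic regression of group on the log
    measure, scored by leave-one-out accuracy.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import LeaveOneOut, cross_val_score

    measure = Measure(measure)
    df = _measure_design(table, participants, measure, task).dropna(subset=["y"])

    results: dict[str, RegressionResult] = {}
    X = np.column_stack([np.ones(len(df)), df["y"].to_numpy(float)])
    for dem in demographics:
        if dem not in df.columns:
            continue
        col = df[dem]
        usable = col.notna().to_numpy()
        if usable.sum() < 4 or col[usable].nunique() < 2:
            continue  # constant or near-empty demographic
        Xd = X[usable]
        if pd.api.types.is_numeric_dtype(col):
            fit = sm.OLS(col[usable].to_numpy(float), Xd).fit()
        else:
            top = col[usable].mode().iloc[0]
            yb = (col[usable] == top).to_numpy(float)
            if yb.std() == 0:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(yb, Xd).fit(disp=0)
            except Exception:
                continue  # separation or non-convergence: skipped
        results[dem] = RegressionResult(
            beta=float(fit.params[1]),
            se=float(fit.bse[1]),
            t=float(fit.tvalues[1]),
            p=float(fit.pvalues[1]),
            n=int(usable.sum()),
            term=str(dem),
        )

    y = (df["group"] == "CHR").to_numpy(int)
    x = df["y"].to_numpy(float).reshape(-1, 1)
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    scores = cross_val_score(clf, x, y, cv=LeaveOneOut())
    return ConfoundAnalysis(
        demographic_results=results,
        loo_accuracy=float(scores.mean()),
        n=len(df),
    )


# --------------------------------------------------------------------------- #
# power
# --------------------------------------------------------------------------- #
def power_analysis(spec: PowerSpec, mode: str = "required_n") -> float:
    """Fisher-z power calculation for a two-sided test of a Pearson r.

    ``required_n``: smallest N detecting ``spec.r`` at the given alpha and
    power, using the small-sample correction
    ``N = ceil(((z_{1-alpha/2} + z_power) / atanh(r))^2 + 3)``.
    ``minimal_r``: smallest detectable correlation at ``spec.n``:
    ``r = tanh((z_{1-alpha/2} + z_power) / sqrt(n - 3))``.
    """
    if not 0 < spec.alpha < 1 or not 0 < spec.power < 1:
        raise ValidationError("alpha and power must lie in (0, 1)")
    z = st.norm.ppf(1 - spec.alpha / 2) + st.norm.ppf(spec.power)
    if mode == "required_n":
        if spec.r == 0:
            raise InferenceError("required_n diverges as r -> 0")
        return int(ceil((z / atanh(abs(spec.r))) ** 2 + 3))
    if mode == "minimal_r":
        if spec.n < 4:
            raise ValidationError("minimal_r requires n >= 4")
        return float(tanh(z / sqrt(spec.n - 3)))
    raise ValueError(f"unknown mode {mode!r}")
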