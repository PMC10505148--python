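"""The speech-variability measure battery.

For each participant x task the battery quantifies how variable speech
production is, using coefficients of variation (CoV = sample SD / mean) of
voice-onset-times, vowel durations, speech rates and syllable timing, plus
vowel-space dispersion in (F1, F2) space, vowel-category overlap and pause
rate.  Task applicability follows the protocol: diadochokinetic (AMR/SMR)
tasks carry the syllable-timing measures, read/spontaneous speech carries
voiced-stop, overlap and pausing measures, and the remaining measures apply
everywhere.

Speech rate is syllables per second: per trial for diadochokinetic speech,
per phrase for read/spontaneous speech, where a phrase is a maximal spoken
interval between silences of at least 150 ms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, UnsupportedCombinationError, ValidationError
from .segments import SpeechSample, Task, TokenSet
from .segments_io import ADJACENCY_TOL_S, select_stop_tokens, select_stressed_vowel_tokens


class Measure(str, Enum):
    """The measure battery (plus one auxiliary covariate row)."""

    VOT_COV_VOICELESS = "vot_cov_voiceless"
    VOT_COV_VOICED = "vot_cov_voiced"
    SPEECH_RATE_COV = "speech_rate_cov"
    VOWEL_DURATION_COV = "vowel_duration_cov"
    FORMANT_DISPERSION_20 = "formant_dispersion_20"
    FORMANT_DISPERSION_CHANGE = "formant_dispersion_change"
    VOWEL_OVERLAP = "vowel_overlap"
    SYLLABLE_COV = "syllable_cov"
    INTERSYLLABLE_COV = "intersyllable_cov"
    PAUSE_RATE = "pause_rate"
    #: participant's mean speech rate for the task; covariate, not an outcome
    SPEECH_RATE_MEAN = "speech_rate_mean"


#: measure -> tasks it is defined for (blank elsewhere)
MEASURE_TASKS: dict[Measure, tuple[Task, ...]] = {
    Measure.VOT_COV_VOICELESS: (Task.AMR, Task.SMR, Task.READ, Task.SPONT),
    Measure.VOT_COV_VOICED: (Task.READ, Task.SPONT),
    Measure.SPEECH_RATE_COV: (Task.AMR, Task.SMR, Task.READ, Task.SPONT),
    Measure.VOWEL_DURATION_COV: (Task.AMR, Task.SMR, Task.READ, Task.SPONT),
    Measure.FORMANT_DISPERSION_20: (Task.AMR, Task.SMR, Task.READ, Task.SPONT),
    Measure.FORMANT_DISPERSION_CHANGE: (Task.AMR, Task.SMR, Task.READ, Task.SPONT),
    Measure.VOWEL_OVERLAP: (Task.READ, Task.SPONT),
    Measure.SYLLABLE_COV: (Task.AMR, Task.SMR),
    Measure.INTERSYLLABLE_COV: (Task.AMR, Task.SMR),
    Measure.PAUSE_RATE: (Task.READ, Task.SPONT),
    Measure.SPEECH_RATE_MEAN: (Task.AMR, Task.SMR, Task.READ, Task.SPONT),
}

#: the ten analysis outcomes (excludes the covariate row)
ANALYSIS_MEASURES = [m for m in Measure if m is not Measure.SPEECH_RATE_MEAN]

#: measures whose value is a duration-derived CoV; group models for these
#: control for the participant's mean speech rate
DURATIONAL_MEASURES = frozenset(
    {
        Measure.VOT_COV_VOICELESS,
        Measure.VOT_COV_VOICED,
        Measure.VOWEL_DURATION_COV,
        Measure.SYLLABLE_COV,
        Measure.INTERSYLLABLE_COV,
    }
)


@dataclass(frozen=True)
class MeasureConfig:
    """Tunable measure parameters.

    min_silence_s
        Silence duration (inclusive) that delimits phrases and counts as a
        pause; 0.150 s by protocol.
    min_n
        Minimum token count for CoV / dispersion / overlap measures.
    epsilon
        Offset used when log-transforming exact zeros (overlap and pause
        rate can legitimately be 0).
    """

    min_silence_s: float = 0.150
    min_n: int = 5
    epsilon: float = 1e-3


# --------------------------------------------------------------------------- #
# elementary statistics
# --------------------------------------------------------------------------- #
def coefficient_of_variation(
    values: Sequence[float] | np.ndarray, min_n: int = 2
) -> Optional[float]:
    """Sample SD (n-1 denominator) divided by the mean.

    Returns ``None`` when fewer than ``min_n`` values are supplied
    (insufficient tokens).  Values must be finite and strictly positive:
    the durations and rates this statistic is applied to are positive by
    construction, and CoV is not meaningful otherwise.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    bad = ~np.isfinite(x) | (x <= 0)
    if bad.any():
        raise ValidationError(
            f"coefficient_of_variation: non-positive or non-finite value at "
            f"index {int(np.flatnonzero(bad)[0])}"
        )
    if x.size < max(min_n, 2):
        return None
    return float(np.std(x, ddof=1) / np.mean(x))


def log_value(raw: float, epsilon: float = 1e-3) -> float:
    """Natural log of a measure value; zeros are mapped to log(epsilon).

    Negative values (possible for the signed dispersion-change measure)
    have no defined log and yield NaN.
    """
    if raw > 0:
        return math.log(raw)
    if raw == 0:
        return math.log(epsilon)
    return math.nan


# --------------------------------------------------------------------------- #
# diadochokinetic timing
# --------------------------------------------------------------------------- #
@dataclass
class DDKTiming:
    """Per-trial rates and token-level timing of a diadochokinetic sample."""

    trial_rates: np.ndarray  # syllables / second, one per non-empty trial
    syllable_durations_s: np.ndarray
    intersyllable_gaps_s: np.ndarray
    syllables_per_trial: list[int]


def ddk_timing(sample: SpeechSample) -> DDKTiming:
    """Trial rates, syllable durations and intersyllable gaps of a DDK sample.

    A syllable is anchored on a vowel nucleus; its span runs from the
    immediately preceding adjacent consonant (when present) to the vowel's
    end.  Intersyllable gaps are the silent intervals between consecutive
    syllables *within* a trial; between-trial gaps are excluded.  Empty
    trial windows are skipped with a warning.
    """
    if not sample.task.is_ddk:
        raise UnsupportedCombinationError(
            f"ddk_timing is defined for AMR/SMR, not {sample.task.value}"
        )
    p = sample.phone_arrays()
    start, end, is_vowel = p["start"], p["end"], p["is_vowel"]

    rates: list[float] = []
    syll_durs: list[np.ndarray] = []
    gaps: list[np.ndarray] = []
    per_trial: list[int] = []
    for a, b in sample.trial_windows:
        inside = (start >= a - 1e-9) & (end <= b + 1e-9)
        vi = np.flatnonzero(inside & is_vowel)
        if vi.size == 0:
            warnings.warn(
                f"sample {sample.participant_id}/{sample.task.value}: "
                f"empty trial window ({a:.3f}, {b:.3f}) skipped",
                stacklevel=2,
            )
            continue
        rates.append(vi.size / (b - a))
        per_trial.append(int(vi.size))
        prev = vi - 1
        has_onset = (
            (prev >= 0)
            & inside[np.clip(prev, 0, None)]
            & ~is_vowel[np.clip(prev, 0, None)]
            & (start[vi] - end[np.clip(prev, 0, None)] <= ADJACENCY_TOL_S)
        )
        s_start = np.where(has_onset, start[np.clip(prev, 0, None)], start[vi])
        s_end = end[vi]
        syll_durs.append(s_end - s_start)
        g = s_start[1:] - s_end[:-1]
        gaps.append(g[g > 1e-9])

    return DDKTiming(
        trial_rates=np.asarray(rates, dtype=float),
        syllable_durations_s=(
            np.concatenate(syll_durs) if syll_durs else np.empty(0)
        ),
        intersyllable_gaps_s=np.concatenate(gaps) if gaps else np.empty(0),
        syllables_per_trial=per_trial,
    )


# --------------------------------------------------------------------------- #
# phrases and pausing
# --------------------------------------------------------------------------- #
@dataclass
class PhrasePartition:
    """Phrases and the supra-threshold silences that separate them.

    Phrases and separating silences interleave and tile the spoken span
    (first to last phone); every separating silence is at least
    ``min_silence_s`` long and no phrase contains an internal silence that
    long.
    """

    phrases: list[tuple[float, float]] = field(default_factory=list)
    separating_silences: list[tuple[float, float]] = field(default_factory=list)
    min_silence_s: float = 0.150


def segment_phrases(sample: SpeechSample, min_silence_s: float = 0.150) -> PhrasePartition:
    """Split a read/spontaneous sample into phrases at silences >= threshold.

    The threshold is inclusive: a silence of exactly ``min_silence_s``
    delimits.  Leading and trailing silence is excluded from the partition.
    """
    if sample.task.is_ddk:
        raise UnsupportedCombinationError("phrase segmentation applies to READ/SPONT tasks")
    p = sample.phone_arrays()
    if len(p["start"]) == 0:
        return PhrasePartition(min_silence_s=min_silence_s)
    span_start = float(p["start"].min())
    span_end = float(p["end"].max())

    s = sample.silence_arrays()
    dur = s["end"] - s["start"]
    sep = (
        (dur >= min_silence_s - 1e-9)
        & (s["start"] >= span_start - 1e-9)
        & (s["end"] <= span_end + 1e-9)
    )
    order = np.argsort(s["start"][sep])
    sep_ivs = list(zip(s["start"][sep][order], s["end"][sep][order]))

    phrases: list[tuple[float, float]] = []
    cursor = span_start
    for a, b in sep_ivs:
        if a - cursor > 1e-9:
            phrases.append((cursor, a))
        cursor = b
    if span_end - cursor > 1e-9:
        phrases.append((cursor, span_end))
    return PhrasePartition(phrases=phrases, separating_silences=sep_ivs,
                           min_silence_s=min_silence_s)


def phrase_rates(partition: PhrasePartition, sample: SpeechSample) -> np.ndarray:
    """Speech rate of each phrase, as vowel nuclei per second of phrase time.

    Sub-threshold internal silences stay in the denominator.  Phrases with
    no countable syllable nucleus are dropped with a warning.
    """
    p = sample.phone_arrays()
    nuclei = p["start"][p["is_vowel"]]
    rates = []
    for a, b in partition.phrases:
        n = int(np.count_nonzero((nuclei >= a - 1e-9) & (nuclei < b - 1e-9)))
        if n == 0:
            warnings.warn(
                f"sample {sample.participant_id}/{sample.task.value}: phrase "
                f"({a:.3f}, {b:.3f}) has no syllable nucleus; dropped",
                stacklevel=2,
            )
            continue
        rates.append(n / (b - a))
    return np.asarray(rates, dtype=float)


def pause_rate(sample: SpeechSample, min_silence_s: float = 0.150) -> float:
    """Internal pauses (silences >= threshold) per second of sample duration."""
    if sample.task.is_ddk:
        raise UnsupportedCombinationError("pause rate applies to READ/SPONT tasks")
    if sample.total_duration_s <= 0:
        return 0.0
    partition = segment_phrases(sample, min_silence_s)
    return len(partition.separating_silences) / sample.total_duration_s


# --------------------------------------------------------------------------- #
# formant-space measures
# --------------------------------------------------------------------------- #
def formant_dispersion(tokens: TokenSet, timepoint: int = 20) -> Optional[float]:
    """Mean Euclidean distance (Hz) of (F1, F2) points from their centroid.

    Tokens with missing formants at the requested timepoint are dropped;
    returns None when no token has usable formants.
    """
    xy = tokens.formants(timepoint)
    xy = xy[np.isfinite(xy).all(axis=1)]
    if len(xy) == 0:
        return None
    centroid = xy.mean(axis=0)
    return float(np.linalg.norm(xy - centroid, axis=1).mean())


def dispersion_change(tokens: TokenSet) -> Optional[float]:
    """Dispersion at 50% of vowel duration minus dispersion at 20% (signed Hz).

    Only tokens with formants at both timepoints enter either dispersion,
    so the difference reflects cloud-shape change, not token composition.
    """
    xy20 = tokens.formants(20)
    xy50 = tokens.formants(50)
    ok = np.isfinite(xy20).all(axis=1) & np.isfinite(xy50).all(axis=1)
    if not ok.any():
        return None
    d20 = np.linalg.norm(xy20[ok] - xy20[ok].mean(axis=0), axis=1).mean()
    d50 = np.linalg.norm(xy50[ok] - xy50[ok].mean(axis=0), axis=1).mean()
    return float(d50 - d20)


def vowel_category_overlap(
    tokens: TokenSet,
    category_labels: Sequence[str] | None = None,
    min_n: int = 2,
) -> Optional[float]:
    """Percent of tokens closer to another vowel category's centroid than their own.

    Categories default to the token's base vowel label.  Distances are
    Euclidean in (F1, F2) at the 20% timepoint; ties resolve to the token's
    own category (not counted).  Returns None when fewer than two categories
    have at least ``min_n`` usable tokens.
    """
    xy = tokens.formants(20)
    if category_labels is None:
        from .phones import base_label

        category_labels = [base_label(str(l).upper()) for l in tokens.labels]
    cats = np.asarray(category_labels, dtype=object)
    ok = np.isfinite(xy).all(axis=1)
    xy, cats = xy[ok], cats[ok]

    names = [c for c in pd.unique(cats) if np.count_nonzero(cats == c) >= min_n]
    if len(names) < 2:
        return None
    keep = np.isin(cats, names)
    xy, cats = xy[keep], cats[keep]
    centroids = np.stack([xy[cats == c].mean(axis=0) for c in names])
    dists = np.linalg.norm(xy[:, None, :] - centroids[None, :, :], axis=2)
    own = np.array([names.index(c) for c in cats])
    own_dist = dists[np.arange(len(xy)), own]
    other = dists.copy()
    other[np.arange(len(xy)), own] = np.inf
    misassigned = other.min(axis=1) < own_dist - 1e-12
    return float(100.0 * np.count_nonzero(misassigned) / len(xy))


# --------------------------------------------------------------------------- #
# the measure table
# --------------------------------------------------------------------------- #
MEASURE_TABLE_COLUMNS = [
    "participant_id", "task", "modality", "measure", "raw", "log",
    "n_tokens", "missing_reason",
]


class MeasureTable:
    """Tidy participant x task x measure table (raw + log values)."""

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in MEASURE_TABLE_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"measure table lacks columns {missing}")
        self.data = data[MEASURE_TABLE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def series(self, measure: Measure | str, task: Task | str, scale: str = "log") -> pd.Series:
        """Per-participant values of one measure for one task (missing dropped)."""
        measure = Measure(measure).value
        task = Task(task).value
        sub = self.data[
            (self.data["measure"] == measure)
            & (self.data["task"] == task)
            & self.data["missing_reason"].isna()
        ]
        col = "log" if scale == "log" else "raw"
        return pd.Series(sub[col].to_numpy(float), index=sub["participant_id"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with shortest round-tripping decimals (byte-stable)."""
        df = self.data
        lines = [",".join(MEASURE_TABLE_COLUMNS)]
        for r in df.itertuples(index=False):
            lines.append(
                ",".join(
                    [
                        str(r.participant_id), r.task, r.modality, r.measure,
                        "" if pd.isna(r.raw) else repr(float(r.raw)),
                        "" if pd.isna(r.log) else repr(float(r.log)),
                        "" if pd.isna(r.n_tokens) else str(int(r.n_tokens)),
                        "" if pd.isna(r.missing_reason) else str(r.missing_reason),
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeasureTable":
        df = pd.read_csv(
            path, dtype={"participant_id": str, "missing_reason": object}
        )
        return cls(df)

    def concat(self, other: "MeasureTable") -> "MeasureTable":
        return MeasureTable(pd.concat([self.data, other.data], ignore_index=True))


def _cov_row(values: np.ndarray | Sequence[float], min_n: int) -> tuple:
    """(raw, n, reason) for a CoV-type measure."""
    n = len(values)
    cov = coefficient_of_variation(values, min_n=min_n) if n else None
    if cov is None:
        return (np.nan, n, "insufficient_tokens")
    return (cov, n, None)


def compute_measure_table(
    samples: Iterable[SpeechSample],
    config: MeasureConfig = MeasureConfig(),
    measures: Sequence[Measure] | None = None,
) -> MeasureTable:
    """Compute every applicable measure for each sample.

    Only measure x task combinations the protocol defines are emitted.
    Per-measure failures are recorded via ``missing_reason`` and never abort
    the table.  ``measures`` restricts computation to a subset (the mean
    speech rate is always included, as group models need it as a covariate).
    """
    wanted = set(Measure(m) for m in measures) if measures is not None else set(Measure)
    wanted.add(Measure.SPEECH_RATE_MEAN)
    rows: list[tuple] = []

    for sample in samples:
        task = sample.task
        meta = (sample.participant_id, task.value, sample.modality.value)

        def emit(measure: Measure, raw, n, reason) -> None:
            logv = np.nan if (reason is not None or pd.isna(raw)) else log_value(raw, config.epsilon)
            rows.append(meta + (measure.value, raw, logv, n, reason))

        def want(measure: Measure) -> bool:
            return measure in wanted and task in MEASURE_TASKS[measure]

        # --- stop consonants -------------------------------------------- #
        for measure, voicing in (
            (Measure.VOT_COV_VOICELESS, "voiceless"),
            (Measure.VOT_COV_VOICED, "voiced"),
        ):
            if not want(measure):
                continue
            try:
                tokens = select_stop_tokens(sample, voicing)
                emit(measure, *_cov_row(tokens.values, config.min_n))
            except ValidationError as exc:
                emit(measure, np.nan, 0, f"error:{exc}")

        # --- vowels ------------------------------------------------------ #
        vowel_tokens = None
        need_vowels = [
            m
            for m in (
                Measure.VOWEL_DURATION_COV,
                Measure.FORMANT_DISPERSION_20,
                Measure.FORMANT_DISPERSION_CHANGE,
                Measure.VOWEL_OVERLAP,
            )
            if want(m)
        ]
        if need_vowels:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vowel_tokens = select_stressed_vowel_tokens(sample)
        if want(Measure.VOWEL_DURATION_COV):
            emit(Measure.VOWEL_DURATION_COV, *_cov_row(vowel_tokens.values, config.min_n))
        if want(Measure.FORMANT_DISPERSION_20):
            d = formant_dispersion(vowel_tokens, 20)
            n = int(np.isfinite(vowel_tokens.formants(20)).all(axis=1).sum())
            if d is None:
                emit(Measure.FORMANT_DISPERSION_20, np.nan, 0, "no_formants")
            elif n < config.min_n:
                emit(Measure.FORMANT_DISPERSION_20, np.nan, n, "insufficient_tokens")
            else:
                emit(Measure.FORMANT_DISPERSION_20, d, n, None)
        if want(Measure.FORMANT_DISPERSION_CHANGE):
            d = dispersion_change(vowel_tokens)
            ok = (
                np.isfinite(vowel_tokens.formants(20)).all(axis=1)
                & np.isfinite(vowel_tokens.formants(50)).all(axis=1)
            )
            n = int(ok.sum())
            if d is None:
                emit(Measure.FORMANT_DISPERSION_CHANGE, np.nan, 0, "no_formants")
            elif n < config.min_n:
                emit(Measure.FORMANT_DISPERSION_CHANGE, np.nan, n, "insufficient_tokens")
            else:
                emit(Measure.FORMANT_DISPERSION_CHANGE, d, n, None)
        if want(Measure.VOWEL_OVERLAP):
            cats = [c for c in pd.unique(vowel_tokens.labels)]
            ov = vowel_category_overlap(vowel_tokens, min_n=config.min_n)
            if ov is None:
                reason = "one_category" if len(cats) < 2 else "insufficient_tokens"
                emit(Measure.VOWEL_OVERLAP, np.nan, vowel_tokens.n, reason)
            else:
                emit(Measure.VOWEL_OVERLAP, ov, vowel_tokens.n, None)

        # --- rate and timing --------------------------------------------- #
        if task.is_ddk:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                timing = ddk_timing(sample)
            if want(Measure.SPEECH_RATE_COV):
                emit(Measure.SPEECH_RATE_COV, *_cov_row(timing.trial_rates, config.min_n))
            if timing.trial_rates.size:
                emit(Measure.SPEECH_RATE_MEAN, float(timing.trial_rates.mean()),
                     timing.trial_rates.size, None)
            else:
                emit(Measure.SPEECH_RATE_MEAN, np.nan, 0, "insufficient_tokens")
            if want(Measure.SYLLABLE_COV):
                emit(Measure.SYLLABLE_COV,
                     *_cov_row(timing.syllable_durations_s, config.min_n))
            if want(Measure.INTERSYLLABLE_COV):
                emit(Measure.INTERSYLLABLE_COV,
                     *_cov_row(timing.intersyllable_gaps_s, config.min_n))
        else:
            partition = segment_phrases(sample, config.min_silence_s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rates = phrase_rates(partition, sample)
            if want(Measure.SPEECH_RATE_COV):
                emit(Measure.SPEECH_RATE_COV, *_cov_row(rates, config.min_n))
            if rates.size:
                emit(Measure.SPEECH_RATE_MEAN, float(rates.mean()), rates.size, None)
            else:
                emit(Measure.SPEECH_RATE_MEAN, np.nan, 0, "insufficient_tokens")
            if want(Measure.PAUSE_RATE):
                emit(Measure.PAUSE_RATE,
                     pause_rate(sample, config.min_silence_s),
                     len(partition.separating_silences), None)

    df = pd.DataFrame(rows, columns=MEASURE_TABLE_COLUMNS)
    return MeasureTable(df)
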