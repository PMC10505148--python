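"""Core containers for time-aligned segment data.

A :class:`SpeechSample` holds every labeled interval of one participant
performing one speech task: phones (with optional voice-onset-time and
formant attributes), words, trial windows and silences.  Segments are kept
internally as numpy column arrays so that measure computation is vectorised
and cheap at Monte-Carlo scale; a :class:`pandas.DataFrame` view and
:class:`AlignedSegment` objects are materialised on demand.

Conventions: times are seconds from recording onset, intervals are half-open
``[start_s, end_s)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phones import base_label, is_vowel, stress_digit


class SegmentKind(str, Enum):
    PHONE = "phone"
    WORD = "word"
    TRIAL = "trial"
    SILENCE = "silence"


class Task(str, Enum):
    AMR = "AMR"
    SMR = "SMR"
    READ = "READ"
    SPONT = "SPONT"

    @property
    def is_ddk(self) -> bool:
        """Diadochokinetic tasks: trial-structured rapid syllable repetition."""
        return self in (Task.AMR, Task.SMR)


class Modality(str, Enum):
    IN_PERSON = "in_person"
    REMOTE = "remote"


class Stress(str, Enum):
    PRIMARY = "primary"
    NONPRIMARY = "nonprimary"
    NONE = "none"


#: canonical column order of the segment frame / segment CSV
SEGMENT_COLUMNS = [
    "kind",
    "label",
    "start_s",
    "end_s",
    "vot_s",
    "f1_20",
    "f2_20",
    "f1_50",
    "f2_50",
    "stress",
]

_FLOAT_COLS = ("start_s", "end_s", "vot_s", "f1_20", "f2_20", "f1_50", "f2_50")
_OBJECT_COLS = ("kind", "label", "stress")

#: number of trial windows in a complete diadochokinetic sample
EXPECTED_TRIALS = {Task.AMR: 12, Task.SMR: 20}


@dataclass(slots=True)
class AlignedSegment:
    """One labeled time interval, with optional acoustic attributes.

    ``vot_s`` is the voice-onset-time of a stop token (time between the
    consonant release and the onset of voicing of the following vowel);
    ``f1_20 ... f2_50`` are the first/second formant (Hz) measured at 20%
    and 50% of a vowel's duration.
    """

    label: str
    kind: SegmentKind
    start_s: float
    end_s: float
    vot_s: Optional[float] = None
    f1_20: Optional[float] = None
    f2_20: Optional[float] = None
    f1_50: Optional[float] = None
    f2_50: Optional[float] = None
    stress: Optional[Stress] = None

    def __post_init__(self) -> None:
        self.kind = SegmentKind(self.kind)
        if self.stress is not None:
            self.stress = Stress(self.stress)
        for name in ("start_s", "end_s", "vot_s", "f1_20", "f2_20", "f1_50", "f2_50"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"segment {self.label!r}: {name} is not finite")
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"segment {self.label!r}: end_s ({self.end_s}) must exceed "
                f"start_s ({self.start_s})"
            )
        if self.vot_s is not None and self.vot_s > self.duration_s + 1e-9:
            raise ValidationError(
                f"segment {self.label!r}: vot_s ({self.vot_s}) exceeds the "
                f"interval duration ({self.duration_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _cols_from_segments(segments: Iterable[AlignedSegment]) -> dict[str, np.ndarray]:
    segments = list(segments)
    n = len(segments)
    cols: dict[str, np.ndarray] = {
        "kind": np.array([s.kind.value for s in segments], dtype=object),
        "label": np.array([s.label for s in segments], dtype=object),
        "stress": np.array(
            [None if s.stress is None else s.stress.value for s in segments], dtype=object
        ),
    }
    if n == 0:
        cols["kind"] = np.empty(0, dtype=object)
        cols["label"] = np.empty(0, dtype=object)
        cols["stress"] = np.empty(0, dtype=object)
    for name in _FLOAT_COLS:
        cols[name] = np.array(
            [np.nan if getattr(s, name) is None else float(getattr(s, name)) for s in segments],
            dtype=float,
        )
    return cols


def _cols_from_frame(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    missing = [c for c in SEGMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"segment frame lacks columns {missing}")
    cols: dict[str, np.ndarray] = {}
    for name in _OBJECT_COLS:
        arr = frame[name].to_numpy(object).copy()
        if name == "stress":
            arr = np.array([None if (v is None or (isinstance(v, float) and math.isnan(v))) else v for v in arr], dtype=object)
        cols[name] = arr
    for name in _FLOAT_COLS:
        cols[name] = frame[name].to_numpy(float).copy()
    return cols


class SpeechSample:
    """All segments of one participant x task x modality.

    Parameters
    ----------
    segments
        A sequence of :class:`AlignedSegment`, a DataFrame with
        :data:`SEGMENT_COLUMNS`, or a dict of numpy column arrays with the
        same keys (the cheap path used by the synthetic generator).
    trial_windows
        ``(start_s, end_s)`` pairs delimiting diadochokinetic trials;
        required for AMR/SMR, empty otherwise.
    total_duration_s
        Recording length; defaults to the latest segment end.
    """

    def __init__(
        self,
        participant_id: str,
        task: Task | str,
        modality: Modality | str = Modality.IN_PERSON,
        segments: Sequence[AlignedSegment] | pd.DataFrame | dict = (),
        trial_windows: Sequence[tuple[float, float]] = (),
        total_duration_s: Optional[float] = None,
        validate: bool = True,
    ) -> None:
        self.participant_id = str(participant_id)
        self.task = Task(task)
        self.modality = Modality(modality)
        if isinstance(segments, dict):
            missing = [c for c in SEGMENT_COLUMNS if c not in segments]
            if missing:
                raise ValidationError(f"segment columns missing {missing}")
            self._cols = segments
        elif isinstance(segments, pd.DataFrame):
            self._cols = _cols_from_frame(segments)
        else:
            self._cols = _cols_from_segments(segments)
        self.trial_windows = [(float(a), float(b)) for a, b in trial_windows]
        if total_duration_s is None:
            ends = self._cols["end_s"]
            total_duration_s = float(ends.max()) if len(ends) else 0.0
        self.total_duration_s = float(total_duration_s)
        self._cache: dict[str, object] = {}
        if validate:
            self.validate()

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self._cols["start_s"])

    def validate(self) -> None:
        """Check ordering/overlap invariants; raise ValidationError on failure."""
        kinds = self._cols["kind"]
        start_all = self._cols["start_s"]
        end_all = self._cols["end_s"]
        for kind in pd.unique(kinds):
            m = kinds == kind
            start, end = start_all[m], end_all[m]
            if np.any(end <= start):
                bad = np.flatnonzero(m)[end <= start].tolist()
                raise ValidationError(f"{kind} segments with end<=start at rows {bad}")
            if np.any(np.diff(start) < 0):
                raise ValidationError(f"{kind} segments not sorted by start_s")
            if np.any(start[1:] < end[:-1] - 1e-9):
                bad = np.flatnonzero(m)[1:][start[1:] < end[:-1] - 1e-9].tolist()
                raise ValidationError(f"overlapping {kind} segments at rows {bad}")
        if self.task.is_ddk and not self.trial_windows:
            raise ValidationError(f"{self.task.value} sample requires trial windows")

    @property
    def complete(self) -> bool:
        """True when a DDK sample has its full trial count (always for READ/SPONT)."""
        expected = EXPECTED_TRIALS.get(self.task)
        return expected is None or len(self.trial_windows) == expected

    @property
    def frame(self) -> pd.DataFrame:
        """DataFrame view of the segments (materialised lazily, then cached)."""
        if "frame" not in self._cache:
            self._cache["frame"] = pd.DataFrame(
                {c: self._cols[c] for c in SEGMENT_COLUMNS}
            )
        return self._cache["frame"]  # type: ignore[return-value]

    @property
    def segments(self) -> list[AlignedSegment]:
        c = self._cols
        out = []

        def opt(x: float) -> Optional[float]:
            return None if math.isnan(x) else float(x)

        for i in range(len(self)):
            out.append(
                AlignedSegment(
                    label=c["label"][i],
                    kind=SegmentKind(c["kind"][i]),
                    start_s=float(c["start_s"][i]),
                    end_s=float(c["end_s"][i]),
                    vot_s=opt(c["vot_s"][i]),
                    f1_20=opt(c["f1_20"][i]),
                    f2_20=opt(c["f2_20"][i]),
                    f1_50=opt(c["f1_50"][i]),
                    f2_50=opt(c["f2_50"][i]),
                    stress=None if c["stress"][i] is None else Stress(c["stress"][i]),
                )
            )
        return out

    # -- cached vectorised views --------------------------------------- #
    def kind_arrays(self, kind: SegmentKind) -> dict[str, np.ndarray]:
        """Column arrays restricted to one segment kind (sorted by start)."""
        key = f"kind_{kind.value}"
        if key not in self._cache:
            m = self._cols["kind"] == kind.value
            self._cache[key] = {c: self._cols[c][m] for c in SEGMENT_COLUMNS if c != "kind"}
        return self._cache[key]  # type: ignore[return-value]

    def phone_arrays(self) -> dict[str, np.ndarray]:
        """Numpy views of the phone tier, sorted by start time.

        Keys: label, base, start, end, vot, is_vowel, stress (digit, -1 when
        unmarked), f1_20, f2_20, f1_50, f2_50.
        """
        if "phones" not in self._cache:
            sub = self.kind_arrays(SegmentKind.PHONE)
            labels = sub["label"]
            base = np.array([base_label(str(l).upper()) for l in labels], dtype=object)
            digits = np.empty(len(labels), dtype=np.int8)
            for i, (lab, sa) in enumerate(zip(labels, sub["stress"])):
                if sa is not None:
                    digits[i] = {"primary": 1, "nonprimary": 2, "none": 0}[str(sa)]
                else:
                    d = stress_digit(str(lab))
                    digits[i] = -1 if d is None else (2 if d == 2 else d)
            self._cache["phones"] = {
                "label": labels,
                "base": base,
                "start": sub["start_s"],
                "end": sub["end_s"],
                "vot": sub["vot_s"],
                "is_vowel": np.array([is_vowel(str(l)) for l in labels], dtype=bool),
                "stress": digits,
                "f1_20": sub["f1_20"],
                "f2_20": sub["f2_20"],
                "f1_50": sub["f1_50"],
                "f2_50": sub["f2_50"],
            }
        return self._cache["phones"]  # type: ignore[return-value]

    def silence_arrays(self) -> dict[str, np.ndarray]:
        if "silences" not in self._cache:
            sub = self.kind_arrays(SegmentKind.SILENCE)
            self._cache["silences"] = {"start": sub["start_s"], "end": sub["end_s"]}
        return self._cache["silences"]  # type: ignore[return-value]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"SpeechSample({self.participant_id!r}, {self.task.value}, "
            f"{self.modality.value}, {len(self)} segments, "
            f"{len(self.trial_windows)} trials, {self.total_duration_s:.2f}s)"
        )


@dataclass
class TokenSet:
    """Phone tokens of one sample passing a selection rule.

    ``data`` holds one numpy array per segment column (a subset of the
    sample's phone tier) plus ``value_s``: the scalar the rule extracts
    (VOT for stop tokens, interval duration for vowel tokens).
    """

    sample_ref: tuple[str, str, str]
    rule_name: str
    data: dict[str, np.ndarray]
    n_excluded: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.data["value_s"])

    def __len__(self) -> int:
        return self.n

    @property
    def values(self) -> np.ndarray:
        """The per-token scalar (seconds) the selection rule defines."""
        return self.data["value_s"]

    @property
    def labels(self) -> np.ndarray:
        return self.data["label"]

    def formants(self, timepoint: int) -> np.ndarray:
        """(n, 2) array of (F1, F2) at the 20% or 50% timepoint."""
        if timepoint not in (20, 50):
            raise ValueError("timepoint must be 20 or 50")
        return np.column_stack(
            [self.data[f"f1_{timepoint}"], self.data[f"f2_{timepoint}"]]
        )

    @property
    def frame(self) -> pd.DataFrame:
        cols = [c for c in SEGMENT_COLUMNS if c in self.data] + ["value_s"]
        return pd.DataFrame({c: self.data[c] for c in cols})

    @property
    def tokens(self) -> list[AlignedSegment]:
        d = self.data

        def opt(x: float) -> Optional[float]:
            return None if math.isnan(x) else float(x)

        return [
            AlignedSegment(
                label=d["label"][i],
                kind=SegmentKind.PHONE,
                start_s=float(d["start_s"][i]),
                end_s=float(d["end_s"][i]),
                vot_s=opt(d["vot_s"][i]) if "vot_s" in d else None,
                f1_20=opt(d["f1_20"][i]),
                f2_20=opt(d["f2_20"][i]),
                f1_50=opt(d["f1_50"][i]),
                f2_50=opt(d["f2_50"][i]),
            )
            for i in range(self.n)
        ]
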