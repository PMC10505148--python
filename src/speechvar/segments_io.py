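"""Segment-level I/O and token selection.

Reads the interval output of a forced-alignment stack (Praat TextGrid long
format, or an equivalent flat CSV) into :class:`~speechvar.segments.SpeechSample`
objects, writes them back losslessly, and applies the token-selection rules
the variability measures are defined over:

* syllable-initial, pre-vocalic stop consonants (voiceless p/t/k or voiced
  b/d/g), each carrying a voice-onset-time, and
* vowels bearing primary stress.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError, UnsupportedCombinationError, ValidationError
from .phones import VOICED_STOPS, VOICELESS_STOPS
from .segments import (
    SEGMENT_COLUMNS,
    Modality,
    SegmentKind,
    SpeechSample,
    Task,
    TokenSet,
)
from .textgrid import Interval, TextGrid, Tier, read_textgrid_file, write_textgrid_file

#: two phones whose boundary is closer than this are treated as adjacent
ADJACENCY_TOL_S = 1e-3

#: tier-tier labels conventionally used for silence by aligners
DEFAULT_SILENCE_LABELS = frozenset({"", "sp", "sil", "spn", "<sil>"})

CSV_COLUMNS = ["participant_id", "task", "modality"] + SEGMENT_COLUMNS
_FLOAT_COLUMNS = ("start_s", "end_s", "vot_s", "f1_20", "f2_20", "f1_50", "f2_50")


# --------------------------------------------------------------------------- #
# TextGrid ingestion
# --------------------------------------------------------------------------- #
def read_textgrid(
    path: str | Path,
    tier_map: Mapping[str, str],
    participant_id: str,
    task: Task | str,
    modality: Modality | str = Modality.IN_PERSON,
    silence_labels: frozenset[str] = DEFAULT_SILENCE_LABELS,
) -> SpeechSample:
    """Read a long-format TextGrid into a SpeechSample.

    ``tier_map`` maps roles (``"phone"`` required; ``"word"``, ``"trial"``
    optional) to tier names in the file.  Empty-label or conventional
    silence-label intervals on the phone tier, and any un-tiered gaps, become
    silence segments so that phone + silence time tiles the recording.
    """
    if "phone" not in tier_map:
        raise ConfigError("tier_map must map the 'phone' role to a tier name")
    grid = read_textgrid_file(path)

    rows: list[tuple] = []
    trial_windows: list[tuple[float, float]] = []
    for role in ("phone", "word", "trial"):
        name = tier_map.get(role)
        if name is None:
            continue
        tier = grid.tier(name)
        if tier is None:
            raise ConfigError(
                f"{Path(path).name}: no tier named {name!r} (for role {role!r}); "
                f"available: {[t.name for t in grid.tiers]}"
            )
        kind = {"phone": SegmentKind.PHONE, "word": SegmentKind.WORD,
                "trial": SegmentKind.TRIAL}[role]
        cursor = grid.xmin
        for iv in tier.intervals:
            label = iv.text.strip()
            silent = label.lower() in silence_labels
            if role == "phone" and iv.xmin > cursor + 1e-9:
                rows.append(_row(SegmentKind.SILENCE, "", cursor, iv.xmin))
            if role == "trial":
                if not silent:
                    trial_windows.append((iv.xmin, iv.xmax))
            elif silent:
                if role == "phone":
                    rows.append(_row(SegmentKind.SILENCE, "", iv.xmin, iv.xmax))
            else:
                rows.append(_row(kind, label, iv.xmin, iv.xmax))
            cursor = max(cursor, iv.xmax)
        if role == "phone" and grid.xmax > cursor + 1e-9:
            rows.append(_row(SegmentKind.SILENCE, "", cursor, grid.xmax))

    frame = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    frame = frame.sort_values(["kind", "start_s"], kind="stable").reset_index(drop=True)
    return SpeechSample(
        participant_id, task, modality, frame,
        trial_windows=trial_windows, total_duration_s=grid.xmax - grid.xmin,
    )


def _row(kind: SegmentKind, label: str, start: float, end: float) -> tuple:
    return (kind.value, label, start, end, np.nan, np.nan, np.nan, np.nan, np.nan, None)


def write_textgrid(
    sample: SpeechSample,
    path: str | Path,
    tier_map: Mapping[str, str] | None = None,
) -> None:
    """Write a SpeechSample back to a long-format TextGrid.

    Phones and silences share one tier (silences as empty-label intervals);
    words and trial windows get their own tiers when present.  Inverse of
    :func:`read_textgrid` up to float round-trip.
    """
    tier_map = dict(tier_map or {"phone": "phones", "word": "words", "trial": "trials"})
    xmax = sample.total_duration_s
    grid = TextGrid(0.0, xmax)

    f = sample.frame
    phone_like = f[f["kind"].isin([SegmentKind.PHONE.value, SegmentKind.SILENCE.value])]
    phone_like = phone_like.sort_values("start_s", kind="stable")
    tier = Tier(tier_map["phone"], 0.0, xmax)
    for r in phone_like.itertuples(index=False):
        tier.intervals.append(Interval(r.start_s, r.end_s, "" if r.kind == "silence" else r.label))
    grid.tiers.append(tier)

    words = f[f["kind"] == SegmentKind.WORD.value]
    if len(words) and "word" in tier_map:
        tier = Tier(tier_map["word"], 0.0, xmax)
        for r in words.itertuples(index=False):
            tier.intervals.append(Interval(r.start_s, r.end_s, r.label))
        grid.tiers.append(tier)

    if sample.trial_windows and "trial" in tier_map:
        tier = Tier(tier_map["trial"], 0.0, xmax)
        for i, (a, b) in enumerate(sample.trial_windows, start=1):
            tier.intervals.append(Interval(a, b, f"trial{i}"))
        grid.tiers.append(tier)

    write_textgrid_file(grid, path)


# --------------------------------------------------------------------------- #
# Segment CSV
# --------------------------------------------------------------------------- #
def write_segments_csv(samples: SpeechSample | Iterable[SpeechSample], path: str | Path) -> None:
    """Write one row per segment; trial windows become ``kind=trial`` rows.

    Floats are written as shortest round-tripping decimals, so
    ``write -> read`` is identity on every field.
    """
    if isinstance(samples, SpeechSample):
        samples = [samples]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for sample in samples:
            meta = [sample.participant_id, sample.task.value, sample.modality.value]
            for i, (a, b) in enumerate(sample.trial_windows, start=1):
                writer.writerow(meta + ["trial", f"trial{i}", repr(a), repr(b)] + [""] * 6)
            for r in sample.frame.itertuples(index=False):
                if r.kind == SegmentKind.TRIAL.value:
                    continue  # trial windows already emitted
                row = meta + [
                    r.kind, r.label, repr(float(r.start_s)), repr(float(r.end_s)),
                    *("" if pd.isna(v) else repr(float(v))
                      for v in (r.vot_s, r.f1_20, r.f2_20, r.f1_50, r.f2_50)),
                    "" if r.stress is None or pd.isna(r.stress) else str(r.stress),
                ]
                writer.writerow(row)


def read_segments_csv(path: str | Path) -> list[SpeechSample]:
    """Read a segment CSV into SpeechSamples grouped by (participant, task, modality)."""
    dtypes: dict[str, object] = {"participant_id": str, "stress": object}
    dtypes.update({c: str for c in _FLOAT_COLUMNS})
    df = pd.read_csv(path, dtype=dtypes, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing required columns {missing}")
    df = df[CSV_COLUMNS]  # extra columns ignored
    for col in _FLOAT_COLUMNS:
        raw = df[col].astype(str).str.strip()
        values = np.empty(len(raw), dtype=float)
        # Python's float() is correctly rounded, so shortest-repr decimals
        # written by write_segments_csv round-trip bit-exactly.
        for i, text in enumerate(raw):
            if text == "":
                values[i] = np.nan
                continue
            try:
                values[i] = float(text)
            except ValueError:
                raise ValidationError(
                    f"{Path(path).name}: non-numeric {col} at data row {i}: {text!r}"
                ) from None
        df[col] = values
    df["stress"] = df["stress"].where(df["stress"].astype(str) != "", None)

    bad = df["end_s"] <= df["start_s"]
    if bad.any():
        raise ValidationError(
            f"{Path(path).name}: end_s <= start_s at data rows "
            f"{np.flatnonzero(bad.to_numpy()).tolist()}"
        )

    samples = []
    for (pid, task, modality), group in df.groupby(
        ["participant_id", "task", "modality"], sort=False
    ):
        trials = group[group["kind"] == "trial"].sort_values("start_s")
        windows = list(zip(trials["start_s"], trials["end_s"]))
        seg = group[group["kind"] != "trial"][SEGMENT_COLUMNS]
        seg = seg.sort_values(["kind", "start_s"], kind="stable").reset_index(drop=True)
        samples.append(
            SpeechSample(pid, Task(task), Modality(modality), seg, trial_windows=windows)
        )
    return samples


# --------------------------------------------------------------------------- #
# Token selection
# --------------------------------------------------------------------------- #
def _syllable_initial_mask(sample: SpeechSample) -> np.ndarray:
    """Onset positions under the word-initial / post-vowel / post-silence proxy."""
    p = sample.phone_arrays()
    n = len(p["start"])
    if n == 0:
        return np.zeros(0, dtype=bool)
    prev_is_vowel = np.concatenate(([False], p["is_vowel"][:-1]))
    prev_end = np.concatenate(([-np.inf], p["end"][:-1]))
    after_gap = p["start"] > prev_end + ADJACENCY_TOL_S
    first = np.zeros(n, dtype=bool)
    first[0] = True
    mask = first | prev_is_vowel | after_gap

    words = sample.kind_arrays(SegmentKind.WORD)
    if len(words["start_s"]):
        word_starts = words["start_s"]
        idx = np.searchsorted(word_starts, p["start"])
        near = np.zeros(n, dtype=bool)
        for shift in (0, 1):
            j = np.clip(idx - shift, 0, len(word_starts) - 1)
            near |= np.abs(word_starts[j] - p["start"]) <= ADJACENCY_TOL_S
        mask |= near
    return mask


def select_stop_tokens(sample: SpeechSample, voicing: str = "voiceless") -> TokenSet:
    """Select syllable-initial stop consonants that immediately precede a vowel.

    Each token's ``value_s`` is its voice-onset-time: the ``vot_s`` attribute
    when present (detector-style input), otherwise the stop interval's own
    duration (segmenter-style input, where the consonant interval spans the
    VOT).  Tokens with non-positive VOT (e.g. prevoiced voiced stops) are
    excluded and counted, since a coefficient of variation over signed values
    is not meaningful.
    """
    if voicing not in ("voiceless", "voiced"):
        raise ValueError(f"unknown voicing class {voicing!r}")
    if voicing == "voiced" and sample.task.is_ddk:
        raise UnsupportedCombinationError(
            "voiced-stop analysis is not defined for diadochokinetic tasks "
            "(only voiceless stops are analysed there)"
        )
    p = sample.phone_arrays()
    n = len(p["start"])
    if n == 0:
        raise ValidationError(
            f"sample {sample.participant_id}/{sample.task.value} has no phone segments"
        )
    inventory = VOICELESS_STOPS if voicing == "voiceless" else VOICED_STOPS
    is_stop = np.isin(p["base"], sorted(inventory))
    next_is_vowel = np.concatenate((p["is_vowel"][1:], [False]))
    next_start = np.concatenate((p["start"][1:], [np.inf]))
    adjacent = next_start <= p["end"] + ADJACENCY_TOL_S
    mask = is_stop & next_is_vowel & adjacent & _syllable_initial_mask(sample)

    vot = p["vot"][mask]
    duration = (p["end"] - p["start"])[mask]
    value = np.where(np.isfinite(vot), vot, duration)
    positive = value > 0
    keep = np.flatnonzero(mask)[positive]
    data = _token_data(p, keep)
    data["value_s"] = value[positive]
    return TokenSet(
        sample_ref=(sample.participant_id, sample.task.value, sample.modality.value),
        rule_name=f"stop_{voicing}",
        data=data,
        n_excluded=int(np.sum(~positive)),
    )


def _token_data(p: Mapping[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "label": p["label"][idx],
        "start_s": p["start"][idx],
        "end_s": p["end"][idx],
        "vot_s": p["vot"][idx],
        "f1_20": p["f1_20"][idx],
        "f2_20": p["f2_20"][idx],
        "f1_50": p["f1_50"][idx],
        "f2_50": p["f2_50"][idx],
    }


def select_stressed_vowel_tokens(sample: SpeechSample) -> TokenSet:
    """Select primary-stressed vowel tokens (all vowels for DDK tasks).

    Diadochokinetic syllables are single repeated CV syllables, so every DDK
    vowel counts as stressed.  Elsewhere a vowel qualifies when its label
    carries the primary-stress digit 1 or its stress attribute is primary.
    ``value_s`` is the vowel's interval duration.
    """
    p = sample.phone_arrays()
    if sample.task.is_ddk:
        mask = p["is_vowel"].copy()
    else:
        mask = p["is_vowel"] & (p["stress"] == 1)
    if not mask.any():
        warnings.warn(
            f"sample {sample.participant_id}/{sample.task.value}: "
            "no primary-stressed vowels found",
            stacklevel=2,
        )
    idx = np.flatnonzero(mask)
    data = _token_data(p, idx)
    data["value_s"] = (p["end"] - p["start"])[idx]
    return TokenSet(
        sample_ref=(sample.participant_id, sample.task.value, sample.modality.value),
        rule_name="stressed_vowel",
        data=data,
    )
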