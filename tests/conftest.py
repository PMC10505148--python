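from pathlib import Path

import pytest

import speechvar as sv

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA


@pytest.fixture(scope="session")
def small_cohort() -> sv.Cohort:
    """A small but complete four-task cohort used across test modules."""
    return sv.generate_cohort(sv.SyntheticConfig(n_chr=4, n_hc=4), seed=123)


@pytest.fixture(scope="session")
def amr_sample(small_cohort) -> sv.SpeechSample:
    return next(s for s in small_cohort.samples if s.task == sv.Task.AMR)


@pytest.fixture(scope="session")
def read_sample(small_cohort) -> sv.SpeechSample:
    return next(s for s in small_cohort.samples if s.task == sv.Task.READ)


def make_sample(segments, task=sv.Task.READ, trial_windows=(), **kwargs) -> sv.SpeechSample:
    """Convenience constructor for hand-built samples."""
    return sv.SpeechSample(
        "p1", task, sv.Modality.IN_PERSON, segments,
        trial_windows=trial_windows, **kwargs,
    )


def phone(label, start, end, **kw) -> sv.AlignedSegment:
    return sv.AlignedSegment(label=label, kind=sv.SegmentKind.PHONE,
                             start_s=start, end_s=end, **kw)


def silence(start, end) -> sv.AlignedSegment:
    return sv.AlignedSegment(label="", kind=sv.SegmentKind.SILENCE,
                             start_s=start, end_s=end)
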