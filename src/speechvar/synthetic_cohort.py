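"""Synthetic cohort generator.

Generates segment-level speech samples and clinical profiles with the
statistical structure the analysis pipeline assumes, so every stage can be
exercised and calibrated without access to clinical recordings:

* task structure — AMR: 12 trials x 15 CV syllables (two trials each of
  pa/ta/ka/ba/da/ga); SMR: 20 trials x 30 syllables (three-syllable
  sequences repeated 10 times); a read-passage-like sample built from
  phrases; a ~2-minute spontaneous-style sample;
* per-participant variability targets — each controlled measure (voiceless
  and voiced VOT CoV, speech-rate CoV, vowel-duration CoV, intersyllable
  CoV, DDK formant dispersion) gets a per-participant target drawn from
  group-level mean/SD anchors, and token durations are drawn log-normal
  with the sigma that realises that coefficient of variation
  (``CoV = sqrt(exp(sigma^2) - 1)``);
* a latent motor factor — one standard-normal factor per participant is
  expressed exactly in the participant's voiceless-VOT CoV and, with
  configurable correlation ``rho``, in finger-tapping CoV and (weakly) in
  SIPS scores;
* modality structure — participants are split in-person/remote; an optional
  inflation factor increases remote healthy controls' variability targets.

Every draw derives from a per-participant :class:`numpy.random.SeedSequence`
substream, so cohorts are fully deterministic given (config, seed) and
removing one participant leaves all others' data unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .measures import Measure
from .segments import Modality, SpeechSample, Task

_KIND_PHONE = "phone"
_KIND_SILENCE = "silence"

#: vowel categories used for read/spontaneous samples: (F1, F2) means in Hz
PASSAGE_VOWELS = {
    "IY": (300.0, 2300.0),
    "EH": (550.0, 1850.0),
    "AE": (700.0, 1700.0),
    "AA": (750.0, 1200.0),
    "UW": (350.0, 900.0),
}

#: mean distance of an isotropic bivariate normal point from its centre is
#: sigma * sqrt(pi/2); used to convert a dispersion target to a scatter SD
_RAYLEIGH_MEAN = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class GroupParams:
    """Group-level anchor for one measure x task: mean and between-participant SD."""

    chr_mean: float
    chr_sd: float
    hc_mean: float
    hc_sd: float

    def mean(self, group: str) -> float:
        return self.chr_mean if group == "CHR" else self.hc_mean

    def sd(self, group: str) -> float:
        return self.chr_sd if group == "CHR" else self.hc_sd


def _gp(cm, cs, hm, hs) -> GroupParams:
    return GroupParams(cm, cs, hm, hs)


#: Default measure anchors, keyed "measure:task".  CoV anchors are the study
#: conditions the pipeline is validated against; dispersion anchors (Hz)
#: apply to the single-vowel DDK tasks where within-category scatter is the
#: whole measure.
DEFAULT_GROUP_PARAMS: dict[str, GroupParams] = {
    "vot_cov_voiceless:AMR": _gp(0.31, 0.09, 0.27, 0.10),
    "vot_cov_voiceless:SMR": _gp(0.39, 0.10, 0.35, 0.09),
    "vot_cov_voiceless:READ": _gp(0.43, 0.10, 0.39, 0.07),
    "vot_cov_voiceless:SPONT": _gp(0.40, 0.09, 0.40, 0.07),
    "vot_cov_voiced:READ": _gp(0.70, 0.26, 0.71, 0.26),
    "vot_cov_voiced:SPONT": _gp(0.66, 0.26, 0.58, 0.31),
    "speech_rate_cov:AMR": _gp(0.07, 0.04, 0.05, 0.04),
    "speech_rate_cov:SMR": _gp(0.10, 0.05, 0.08, 0.04),
    "speech_rate_cov:READ": _gp(0.20, 0.05, 0.18, 0.06),
    "speech_rate_cov:SPONT": _gp(0.43, 0.45, 0.37, 0.32),
    "vowel_duration_cov:AMR": _gp(0.20, 0.09, 0.17, 0.09),
    "vowel_duration_cov:SMR": _gp(0.43, 0.12, 0.40, 0.15),
    "vowel_duration_cov:READ": _gp(0.56, 0.05, 0.56, 0.06),
    "vowel_duration_cov:SPONT": _gp(0.74, 0.11, 0.73, 0.09),
    "intersyllable_cov:AMR": _gp(0.42, 0.25, 0.34, 0.18),
    "intersyllable_cov:SMR": _gp(0.90, 0.27, 0.82, 0.23),
    "formant_dispersion_20:AMR": _gp(158.63, 86.4, 128.85, 64.57),
    "formant_dispersion_20:SMR": _gp(211.7, 85.72, 185.02, 75.8),
}

#: the measure whose per-participant target expresses the latent motor
#: factor exactly (z-score equal to the factor)
ANCHOR_MEASURE = Measure.VOT_COV_VOICELESS.value


@dataclass(frozen=True)
class DDKTaskSpec:
    """Structure of a diadochokinetic task."""

    task: str
    n_trials: int
    syllables_per_trial: int
    onsets: tuple[str, ...]  # per-trial onset for AMR; per-syllable cycle for SMR
    cycle_onsets: bool  # False: onsets[i] repeats within trial i; True: cycle within trial
    mean_rate: float = 6.0  # syllables / s
    vot_mean_voiceless_s: float = 0.030
    vot_mean_voiced_s: float = 0.015
    vot_cov_voiced: float = 0.30  # voiced DDK stops are not analysed; fixed spread
    vowel_mean_s: float = 0.085
    gap_mean_s: float = 0.040
    min_gap_s: float = 0.004
    intertrial_gap_s: float = 1.0
    lead_silence_s: float = 0.5
    vowel: str = "AA1"
    formant_scale_50: float = 1.10
    formant_noise_hz: float = 5.0


@dataclass(frozen=True)
class PassageTaskSpec:
    """Structure of a read-passage-like or spontaneous-style sample."""

    task: str
    n_phrases: int
    syllables_per_phrase: float  # Poisson mean
    mean_rate: float  # syllables / s
    frac_stressed: float = 0.35
    p_voiceless_stop: float = 0.18
    p_voiced_stop: float = 0.08
    vot_mean_voiceless_s: float = 0.055
    vot_mean_voiced_s: float = 0.018
    stressed_vowel_mean_s: float = 0.16
    unstressed_vowel_mean_s: float = 0.10
    unstressed_vowel_cov: float = 0.30
    pause_floor_s: float = 0.155  # inter-phrase pauses exceed the 150 ms threshold
    pause_extra_mean_s: float = 0.30
    pause_extra_cov: float = 0.35
    min_slack_s: float = 0.004
    max_slack_s: float = 0.120  # per-syllable slack stays sub-threshold
    lead_silence_s: float = 0.5
    formant_within_sd_hz: float = 60.0
    formant_scale_50: float = 0.70
    formant_noise_hz: float = 5.0


@dataclass(frozen=True)
class LatentModel:
    """Latent motor factor loadings and tapping/SIPS generation parameters."""

    rho: float = 0.37  # corr(latent-expressed speech CoV, tapping CoV)
    sips_loading: float = 0.20
    tap_cov_mean: float = 0.07
    tap_cov_sd: float = 0.035
    tap_base_mean: float = 65.0
    tap_base_sd: float = 8.0
    risk_min: float = 0.8
    risk_max: float = 10.1


def default_task_specs() -> dict[str, object]:
    return {
        "AMR": DDKTaskSpec(
            task="AMR", n_trials=12, syllables_per_trial=15,
            onsets=("P", "T", "K", "B", "D", "G") * 2, cycle_onsets=False,
            mean_rate=6.0,
        ),
        "SMR": DDKTaskSpec(
            task="SMR", n_trials=20, syllables_per_trial=30,
            onsets=("P", "T", "K"), cycle_onsets=True, mean_rate=6.5,
        ),
        "READ": PassageTaskSpec(
            task="READ", n_phrases=9, syllables_per_phrase=36.0, mean_rate=4.5,
        ),
        "SPONT": PassageTaskSpec(
            task="SPONT", n_phrases=19, syllables_per_phrase=24.0, mean_rate=4.0,
        ),
    }


@dataclass
class SyntheticConfig:
    """Full generative specification of a synthetic cohort."""

    n_chr: int = 51
    n_hc: int = 53
    tasks: tuple[str, ...] = ("AMR", "SMR", "READ", "SPONT")
    group_params: dict[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PARAMS)
    )
    task_specs: dict[str, object] = field(default_factory=default_task_specs)
    latent: LatentModel = field(default_factory=LatentModel)
    remote_frac_chr: float = 30 / 56
    remote_frac_hc: float = 22 / 66
    hc_remote_inflation: float = 1.0  # multiplies remote-HC variability targets
    rate_between_cov: float = 0.08  # between-participant spread of mean rate
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chr < 0 or self.n_hc < 0 or self.n_chr + self.n_hc == 0:
            raise ConfigError("cohort sizes must be non-negative and not both zero")
        for key, gp in self.group_params.items():
            if gp.chr_sd <= 0 or gp.hc_sd <= 0:
                raise ConfigError(f"group_params[{key}]: SDs must be positive")
        if not -1 < self.latent.rho < 1:
            raise ConfigError("latent rho must lie in (-1, 1)")
        for t in self.tasks:
            if t not in self.task_specs:
                raise ConfigError(f"no task spec for task {t!r}")
            spec = self.task_specs[t]
            if isinstance(spec, DDKTaskSpec) and spec.syllables_per_trial < 2:
                raise ConfigError("DDK trials need at least 2 syllables for a CoV")

    # -- serialisation --------------------------------------------------- #
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task_specs"] = {
            k: {"_kind": type(v).__name__, **dataclasses.asdict(v)}
            for k, v in self.task_specs.items()
        }
        d["group_params"] = {k: dataclasses.asdict(v) for k, v in self.group_params.items()}
        d["tasks"] = list(self.tasks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        kinds = {"DDKTaskSpec": DDKTaskSpec, "PassageTaskSpec": PassageTaskSpec}
        if "task_specs" in d:
            specs = {}
            for k, v in d["task_specs"].items():
                v = dict(v)
                kind = kinds[v.pop("_kind")]
                v["onsets"] = tuple(v["onsets"]) if "onsets" in v else None
                v = {kk: vv for kk, vv in v.items() if vv is not None or kk != "onsets"}
                specs[k] = kind(**v)
            d["task_specs"] = specs
        if "group_params" in d:
            d["group_params"] = {k: GroupParams(**v) for k, v in d["group_params"].items()}
        if "latent" in d and isinstance(d["latent"], dict):
            d["latent"] = LatentModel(**d["latent"])
        if "tasks" in d:
            d["tasks"] = tuple(d["tasks"])
        return cls(**d)


def null_config(config: Optional[SyntheticConfig] = None) -> SyntheticConfig:
    """Copy of a config with no group effect (CHR anchors set to HC values)."""
    config = config or SyntheticConfig()
    params = {
        k: GroupParams(v.hc_mean, v.hc_sd, v.hc_mean, v.hc_sd)
        for k, v in config.group_params.items()
    }
    return dataclasses.replace(config, group_params=params)


# --------------------------------------------------------------------------- #
# low-level draws
# --------------------------------------------------------------------------- #
def _lognormal(rng: np.random.Generator, mean: float, cov: float, size) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CoV."""
    cov = max(cov, 1e-9)
    sigma2 = np.log1p(cov * cov)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


@dataclass
class ParticipantProfile:
    """Internal bundle of one participant's latent state and targets."""

    participant_id: str
    group: str
    modality: str
    latent: float
    targets: dict[str, float]  # "measure:task" -> per-participant target
    mean_rates: dict[str, float]  # task -> participant mean speech rate


def _expected_token_count(config: SyntheticConfig, measure: str, task: str):
    """Expected number of tokens a measured CoV will average over."""
    spec = config.task_specs[task]
    if isinstance(spec, DDKTaskSpec):
        n_syll = spec.n_trials * spec.syllables_per_trial
        if measure == "speech_rate_cov":
            return spec.n_trials
        if measure == "vowel_duration_cov":
            return n_syll
        if measure == "intersyllable_cov":
            return spec.n_trials * (spec.syllables_per_trial - 1)
        if measure == "vot_cov_voiceless":
            onsets = np.array(spec.onsets, dtype=object)
            frac = float(np.isin(onsets, ["P", "T", "K"]).mean())
            return n_syll * frac
        return None
    if isinstance(spec, PassageTaskSpec):
        n_syll = spec.n_phrases * spec.syllables_per_phrase
        return {
            "speech_rate_cov": spec.n_phrases,
            "vowel_duration_cov": n_syll * spec.frac_stressed,
            "vot_cov_voiceless": n_syll * spec.p_voiceless_stop,
            "vot_cov_voiced": n_syll * spec.p_voiced_stop,
        }.get(measure)
    return None


def _between_sd(config: SyntheticConfig, measure: str, task: str,
                mean: float, sd: float) -> float:
    """Deflate an anchor SD by the expected CoV-estimator noise.

    The anchors describe the spread of *measured* per-participant CoVs;
    a sample CoV over n tokens carries sampling variance of roughly
    ``c^2 (1/(2(n-1)) + c^2/n)``, which adds to the target spread.
    Drawing targets with the deflated SD makes the realised
    between-participant SD match the anchor.  Floored at 20% of the
    anchor when the estimator noise alone exceeds it.
    """
    n = _expected_token_count(config, measure, task)
    if n is None or n < 3:
        return sd
    noise_var = mean * mean * (0.5 / (n - 1) + mean * mean / n)
    return float(np.sqrt(max(sd * sd - noise_var, (0.2 * sd) ** 2)))


def _draw_targets(
    config: SyntheticConfig, group: str, modality: str, latent: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    targets: dict[str, float] = {}
    inflate = (
        config.hc_remote_inflation
        if (group == "HC" and modality == Modality.REMOTE.value)
        else 1.0
    )
    for key in sorted(config.group_params):
        measure, task = key.split(":")
        if task not in config.tasks:
            continue
        gp = config.group_params[key]
        z = latent if measure == ANCHOR_MEASURE else rng.standard_normal()
        sd = _between_sd(config, measure, task, gp.mean(group), gp.sd(group))
        value = (gp.mean(group) + sd * z) * inflate
        floor = 20.0 if measure == "formant_dispersion_20" else 0.02
        targets[key] = max(value, floor)
    return targets


def generate_clinical_profile(
    participant_id: str,
    group: str,
    latent: float,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict:
    """Demographics, SIPS scores, tapping trials and risk score for one participant.

    Tapping CoV is generated with correlation ``rho`` to the latent factor
    by constructing three integer tap counts whose sample CoV equals the
    drawn target (up to rounding).  SIPS symptom totals load weakly on the
    latent factor for CHR participants; healthy controls get near-zero
    scores.  Risk scores exist for CHR participants only.
    """
    lm = config.latent
    chr_ = group == "CHR"

    age = rng.normal(21.8 if chr_ else 21.7, 2.8 if chr_ else 3.2)
    sex = "F" if rng.random() < (0.607 if chr_ else 0.621) else "M"
    if chr_:
        race = rng.choice(
            ["White", "Black", "Asian", "CentralSouthAmerican", "NHPI", "Multiracial"],
            p=[0.446, 0.196, 0.179, 0.089, 0.018, 0.072],
        )
        ethnicity = "Hispanic" if rng.random() < 0.268 else "NotHispanic"
        first_language = rng.choice(
            ["English", "Other", "NotReported"], p=[0.625, 0.179, 0.196]
        )
    else:
        race = rng.choice(
            ["White", "Black", "Asian", "FirstNations", "Multiracial"],
            p=[0.455, 0.091, 0.288, 0.030, 0.136],
        )
        ethnicity = "Hispanic" if rng.random() < 0.106 else "NotHispanic"
        first_language = rng.choice(
            ["English", "Other", "NotReported"], p=[0.803, 0.182, 0.015]
        )

    taps = {}
    rho = lm.rho
    for hand in ("dom", "nondom"):
        noise = rng.standard_normal()
        target = lm.tap_cov_mean + lm.tap_cov_sd * (
            rho * latent + np.sqrt(1.0 - rho * rho) * noise
        )
        target = max(target, 0.001)
        base = max(10.0, rng.normal(lm.tap_base_mean, lm.tap_base_sd))
        counts = np.rint([base, base * (1 - target), base * (1 + target)])
        counts = np.maximum(counts, 1.0)
        order = rng.permutation(3)
        for i, j in enumerate(order):
            taps[f"tap_{hand}_{i + 1}"] = int(counts[j])

    if chr_:
        s = lm.sips_loading
        mix = lambda sd, mean: mean + sd * (s * latent + np.sqrt(1 - s * s) * rng.standard_normal())  # noqa: E731
        sips_pos = float(np.clip(np.rint(mix(4.0, 12.0)), 1, 30))
        sips_neg = float(np.clip(np.rint(mix(5.0, 10.0)), 0, 36))
        sips_dis = float(np.clip(np.rint(mix(3.0, 5.0)), 0, 24))
        sips_g3 = float(np.clip(np.rint(mix(1.3, 1.8)), 0, 6))
        risk = float(
            np.clip(
                np.exp(np.log(2.5) + 0.55 * (s * latent + np.sqrt(1 - s * s) * rng.standard_normal())),
                lm.risk_min, lm.risk_max,
            )
        )
    else:
        sips_pos = float(np.clip(np.rint(np.abs(rng.normal(0, 1.2))), 0, 6))
        sips_neg = float(np.clip(np.rint(np.abs(rng.normal(0, 1.2))), 0, 6))
        sips_dis = float(np.clip(np.rint(np.abs(rng.normal(0, 1.0))), 0, 6))
        sips_g3 = float(np.clip(np.rint(np.abs(rng.normal(0, 0.7))), 0, 2))
        risk = np.nan

    return {
        "participant_id": participant_id,
        "group": group,
        "age": float(age),
        "sex": sex,
        "race": str(race),
        "ethnicity": ethnicity,
        "first_language": str(first_language),
        "sips_positive_total": sips_pos,
        "sips_negative_total": sips_neg,
        "sips_disorganized_total": sips_dis,
        "sips_g3": sips_g3,
        **taps,
        "sips_rc_risk": risk,
    }


# --------------------------------------------------------------------------- #
# speech-sample synthesis
# --------------------------------------------------------------------------- #
def _assemble_sample(
    participant_id: str,
    task: str,
    modality: str,
    phone_rows: dict[str, np.ndarray],
    silences: list[tuple[float, float]],
    trial_windows: list[tuple[float, float]],
    total_duration_s: float,
) -> SpeechSample:
    """Build a SpeechSample from pre-sorted phone arrays plus silence spans."""
    n_p = len(phone_rows["start"])
    sil = np.asarray(silences, dtype=float).reshape(-1, 2)
    n_s = len(sil)
    nan_p = np.full(n_p, np.nan)
    nan_s = np.full(n_s, np.nan)
    cols = {
        "kind": np.concatenate(
            [np.full(n_p, _KIND_PHONE, dtype=object), np.full(n_s, _KIND_SILENCE, dtype=object)]
        ),
        "label": np.concatenate([phone_rows["label"], np.full(n_s, "", dtype=object)]),
        "start_s": np.concatenate([phone_rows["start"], sil[:, 0]]),
        "end_s": np.concatenate([phone_rows["end"], sil[:, 1]]),
        "vot_s": np.concatenate([nan_p, nan_s]),
        "f1_20": np.concatenate([phone_rows["f1_20"], nan_s]),
        "f2_20": np.concatenate([phone_rows["f2_20"], nan_s]),
        "f1_50": np.concatenate([phone_rows["f1_50"], nan_s]),
        "f2_50": np.concatenate([phone_rows["f2_50"], nan_s]),
        "stress": np.concatenate(
            [phone_rows["stress"], np.full(n_s, None, dtype=object)]
        ),
    }
    sample = SpeechSample(
        participant_id, Task(task), Modality(modality), cols,
        trial_windows=trial_windows, total_duration_s=total_duration_s,
        validate=False,
    )
    # pre-populate the phone-array cache with generator-known attributes
    sample._cache["phones"] = {
        "label": phone_rows["label"],
        "base": phone_rows["base"],
        "start": phone_rows["start"],
        "end": phone_rows["end"],
        "vot": nan_p,
        "is_vowel": phone_rows["is_vowel"],
        "stress": phone_rows["stress_digit"],
        "f1_20": phone_rows["f1_20"],
        "f2_20": phone_rows["f2_20"],
        "f1_50": phone_rows["f1_50"],
        "f2_50": phone_rows["f2_50"],
    }
    return sample


def _formants(
    rng: np.random.Generator,
    centres: np.ndarray,
    scatter_sd: float | np.ndarray,
    scale_50: float,
    noise_hz: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = len(centres)
    dev = rng.standard_normal((n, 2)) * scatter_sd
    f20 = centres + dev
    f50 = centres + scale_50 * dev + rng.standard_normal((n, 2)) * noise_hz
    return f20[:, 0], f20[:, 1], f50[:, 0], f50[:, 1]


def generate_ddk_sample(
    profile: ParticipantProfile,
    spec: DDKTaskSpec,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> SpeechSample:
    """Synthesize one diadochokinetic sample (AMR or SMR).

    Each trial's window duration is set by a drawn per-trial rate; VOTs and
    vowel durations are drawn i.i.d. log-normal at the participant's CoV
    targets, and intersyllable gaps absorb the remaining window time with
    the participant's gap-CoV spread, so trial windows tile exactly.
    """
    task = spec.task
    t = profile.targets
    c_vl = t[f"vot_cov_voiceless:{task}"]
    c_rate = t[f"speech_rate_cov:{task}"]
    c_vow = t[f"vowel_duration_cov:{task}"]
    c_gap = t[f"intersyllable_cov:{task}"]
    disp = t[f"formant_dispersion_20:{task}"]

    n_t, n_s = spec.n_trials, spec.syllables_per_trial
    if spec.cycle_onsets:
        onsets = np.tile(np.array(spec.onsets, dtype=object), (n_t, (n_s + len(spec.onsets) - 1) // len(spec.onsets)))[:, :n_s]
    else:
        onsets = np.tile(np.array(spec.onsets, dtype=object)[:n_t, None], (1, n_s))
    voiceless = np.isin(onsets, ["P", "T", "K"])

    rates = _lognormal(rng, profile.mean_rates[task], c_rate, n_t)
    windows = n_s / rates

    vot = np.where(
        voiceless,
        _lognormal(rng, spec.vot_mean_voiceless_s, c_vl, (n_t, n_s)),
        _lognormal(rng, spec.vot_mean_voiced_s, spec.vot_cov_voiced, (n_t, n_s)),
    )
    vow = _lognormal(rng, spec.vowel_mean_s, c_vow, (n_t, n_s))
    content = vot + vow
    content_sum = content.sum(axis=1)

    # rescale vowels in (rare) trials whose drawn content exceeds the window
    budget = windows - (n_s - 1) * spec.min_gap_s
    over = content_sum > budget
    if over.any():
        scale = (budget[over] - vot[over].sum(axis=1)) / vow[over].sum(axis=1)
        vow[over] *= np.maximum(scale, 0.05)[:, None]
        content = vot + vow
        content_sum = content.sum(axis=1)

    gaps = _lognormal(rng, spec.gap_mean_s, c_gap, (n_t, n_s - 1))
    gaps *= ((windows - content_sum) / gaps.sum(axis=1))[:, None]

    # timeline: [lead][trial 1][intertrial gap][trial 2]...
    trial_starts = spec.lead_silence_s + np.concatenate(
        ([0.0], np.cumsum(windows[:-1] + spec.intertrial_gap_s))
    )
    step = content.copy()
    step[:, :-1] += gaps
    onset_start = trial_starts[:, None] + np.concatenate(
        [np.zeros((n_t, 1)), np.cumsum(step[:, :-1], axis=1)], axis=1
    )
    vowel_start = onset_start + vot
    vowel_end = vowel_start + vow

    # interleave: onset, vowel, onset, vowel, ... per trial, trials in order
    n_phones = 2 * n_t * n_s
    start = np.empty((n_t, 2 * n_s))
    end = np.empty((n_t, 2 * n_s))
    start[:, 0::2], start[:, 1::2] = onset_start, vowel_start
    end[:, 0::2], end[:, 1::2] = vowel_start, vowel_end
    label = np.empty((n_t, 2 * n_s), dtype=object)
    label[:, 0::2] = onsets
    label[:, 1::2] = spec.vowel
    is_vowel = np.zeros((n_t, 2 * n_s), dtype=bool)
    is_vowel[:, 1::2] = True

    # formants on vowels only
    centre = np.array(PASSAGE_VOWELS["AA"])
    sd = disp / _RAYLEIGH_MEAN / np.sqrt(2.0)
    f1_20 = np.full(n_phones, np.nan)
    f2_20 = np.full(n_phones, np.nan)
    f1_50 = np.full(n_phones, np.nan)
    f2_50 = np.full(n_phones, np.nan)
    vmask = is_vowel.ravel()
    a, b, c, d = _formants(
        rng, np.tile(centre, (n_t * n_s, 1)), sd * np.sqrt(2.0),
        spec.formant_scale_50, spec.formant_noise_hz,
    )
    f1_20[vmask], f2_20[vmask], f1_50[vmask], f2_50[vmask] = a, b, c, d

    stress_digit = np.where(vmask, np.int8(1), np.int8(-1)).astype(np.int8)
    base = np.array([str(l).rstrip("0123456789") for l in label.ravel()], dtype=object)

    silences: list[tuple[float, float]] = [(0.0, float(trial_starts[0]))]
    gap_start = vowel_end[:, :-1]
    gap_end = onset_start[:, 1:]
    for ti in range(n_t):
        silences.extend(zip(gap_start[ti], gap_end[ti]))
        t_end = trial_starts[ti] + windows[ti]
        nxt = trial_starts[ti + 1] if ti + 1 < n_t else t_end + spec.lead_silence_s
        silences.append((float(t_end), float(nxt)))

    total = trial_starts[-1] + windows[-1] + spec.lead_silence_s
    trial_windows = [(float(a_), float(a_ + w)) for a_, w in zip(trial_starts, windows)]
    phone_rows = {
        "label": label.ravel(),
        "base": base,
        "start": start.ravel(),
        "end": end.ravel(),
        "is_vowel": vmask,
        "stress_digit": stress_digit,
        "stress": np.full(n_phones, None, dtype=object),
        "f1_20": f1_20, "f2_20": f2_20, "f1_50": f1_50, "f2_50": f2_50,
    }
    return _assemble_sample(
        profile.participant_id, task, profile.modality,
        phone_rows, silences, trial_windows, float(total),
    )


def generate_passage_sample(
    profile: ParticipantProfile,
    spec: PassageTaskSpec,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> SpeechSample:
    """Synthesize a read-passage-like or spontaneous-style sample.

    The sample is a sequence of phrases separated by supra-threshold pauses.
    Within a phrase, syllables are [stop?][vowel] units separated by small
    sub-threshold slack silences; the phrase's duration is set by a drawn
    per-phrase speech rate, clamped so slack never reaches the phrase
    threshold.
    """
    task = spec.task
    t = profile.targets
    c_vl = t[f"vot_cov_voiceless:{task}"]
    c_vd = t[f"vot_cov_voiced:{task}"]
    c_rate = t[f"speech_rate_cov:{task}"]
    c_vow = t[f"vowel_duration_cov:{task}"]

    cats = list(PASSAGE_VOWELS)
    centres_lut = np.array([PASSAGE_VOWELS[c] for c in cats])

    labels: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    vmasks: list[np.ndarray] = []
    sdigits: list[np.ndarray] = []
    centres: list[np.ndarray] = []
    silences: list[tuple[float, float]] = []

    cursor = spec.lead_silence_s
    silences.append((0.0, cursor))
    for pi in range(spec.n_phrases):
        n = max(3, int(rng.poisson(spec.syllables_per_phrase)))
        rate = float(_lognormal(rng, profile.mean_rates[task], c_rate, ()))
        stop_kind = rng.random(n)
        has_vl = stop_kind < spec.p_voiceless_stop
        has_vd = (~has_vl) & (stop_kind < spec.p_voiceless_stop + spec.p_voiced_stop)
        vot = np.zeros(n)
        vot[has_vl] = _lognormal(rng, spec.vot_mean_voiceless_s, c_vl, int(has_vl.sum()))
        vot[has_vd] = _lognormal(rng, spec.vot_mean_voiced_s, c_vd, int(has_vd.sum()))
        stressed = rng.random(n) < spec.frac_stressed
        vow = np.where(
            stressed,
            _lognormal(rng, spec.stressed_vowel_mean_s, c_vow, n),
            _lognormal(rng, spec.unstressed_vowel_mean_s, spec.unstressed_vowel_cov, n),
        )
        content = vot + vow
        slack = (n / rate - content.sum()) / max(n - 1, 1)
        slack = float(np.clip(slack, spec.min_slack_s, spec.max_slack_s))
        # slack between syllables stays sub-threshold; when the drawn rate
        # calls for more time than capped slack provides, slow speech shows
        # up as longer segments instead, keeping the realised rate on target
        deficit = n / rate - content.sum() - (n - 1) * slack
        if deficit > 0:
            vow *= 1.0 + deficit / vow.sum()
            content = vot + vow

        onset = cursor + np.concatenate(([0.0], np.cumsum(content[:-1] + slack)))
        v_start = onset + vot
        v_end = v_start + vow
        silences.extend(zip(v_end[:-1], onset[1:]))

        cat_idx = rng.integers(0, len(cats), n)
        vlab = np.array(
            [cats[k] + ("1" if s else "0") for k, s in zip(cat_idx, stressed)],
            dtype=object,
        )
        olab = np.where(
            has_vl,
            rng.choice(["P", "T", "K"], n),
            np.where(has_vd, rng.choice(["B", "D", "G"], n), ""),
        ).astype(object)

        has_stop = has_vl | has_vd
        n_ph = int(has_stop.sum()) + n
        ph_start = np.empty(n_ph)
        ph_end = np.empty(n_ph)
        ph_lab = np.empty(n_ph, dtype=object)
        ph_vow = np.zeros(n_ph, dtype=bool)
        ph_sd = np.full(n_ph, -1, dtype=np.int8)
        ph_cat = np.zeros(n_ph, dtype=int)
        j = 0
        for k in range(n):
            if has_stop[k]:
                ph_start[j], ph_end[j], ph_lab[j] = onset[k], v_start[k], olab[k]
                j += 1
            ph_start[j], ph_end[j], ph_lab[j] = v_start[k], v_end[k], vlab[k]
            ph_vow[j] = True
            ph_sd[j] = 1 if stressed[k] else 0
            ph_cat[j] = cat_idx[k]
            j += 1

        labels.append(ph_lab)
        starts.append(ph_start)
        ends.append(ph_end)
        vmasks.append(ph_vow)
        sdigits.append(ph_sd)
        centres.append(centres_lut[ph_cat] * ph_vow[:, None])

        cursor = float(v_end[-1])
        if pi + 1 < spec.n_phrases:
            pause = spec.pause_floor_s + float(
                _lognormal(rng, spec.pause_extra_mean_s, spec.pause_extra_cov, ())
            )
            silences.append((cursor, cursor + pause))
            cursor += pause

    total = cursor + spec.lead_silence_s
    silences.append((cursor, total))

    label = np.concatenate(labels)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    vmask = np.concatenate(vmasks)
    sdig = np.concatenate(sdigits)
    centre = np.concatenate(centres)

    n_phones = len(label)
    f1_20 = np.full(n_phones, np.nan)
    f2_20 = np.full(n_phones, np.nan)
    f1_50 = np.full(n_phones, np.nan)
    f2_50 = np.full(n_phones, np.nan)
    a, b, c, d = _formants(
        rng, centre[vmask], spec.formant_within_sd_hz,
        spec.formant_scale_50, spec.formant_noise_hz,
    )
    f1_20[vmask], f2_20[vmask], f1_50[vmask], f2_50[vmask] = a, b, c, d

    base = np.array([str(l).rstrip("0123456789") for l in label], dtype=object)
    phone_rows = {
        "label": label, "base": base, "start": start, "end": end,
        "is_vowel": vmask, "stress_digit": sdig,
        "stress": np.full(n_phones, None, dtype=object),
        "f1_20": f1_20, "f2_20": f2_20, "f1_50": f1_50, "f2_50": f2_50,
    }
    return _assemble_sample(
        profile.participant_id, task, profile.modality,
        phone_rows, silences, [], float(total),
    )


def generate_speech_sample(
    profile: ParticipantProfile,
    task_spec: DDKTaskSpec | PassageTaskSpec,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> SpeechSample:
    """Dispatch to the DDK or passage synthesiser for one task."""
    if isinstance(task_spec, DDKTaskSpec):
        return generate_ddk_sample(profile, task_spec, config, rng)
    return generate_passage_sample(profile, task_spec, config, rng)


# --------------------------------------------------------------------------- #
# cohort assembly
# --------------------------------------------------------------------------- #
@dataclass
class Cohort:
    """A generated cohort: participant table, speech samples and targets.

    ``participants`` has the participant-table schema plus ``latent_motor``;
    ``targets`` records each participant's generating per-measure targets
    ("measure:task" keys), which convergence and latent-recovery checks
    compare against realised values.
    """

    participants: pd.DataFrame
    samples: list[SpeechSample]
    targets: pd.DataFrame
    config: SyntheticConfig
    seed: int


def generate_cohort(
    config: SyntheticConfig | None = None,
    seed: Optional[int] = None,
    with_samples: bool = True,
    tasks: Optional[Sequence[str]] = None,
) -> Cohort:
    """Generate a full synthetic cohort, deterministically from (config, seed).

    Each participant consumes an independent seed substream keyed by their
    index, so participants are order-independent.  ``tasks`` restricts
    sample synthesis to a subset of the configured tasks; ``with_samples=False``
    generates clinical profiles and targets only.
    """
    config = config or SyntheticConfig()
    if seed is None:
        seed = config.master_seed
    task_list = list(config.tasks if tasks is None else tasks)
    for t in task_list:
        if t not in config.tasks:
            raise ConfigError(f"task {t!r} not in config.tasks")

    groups = ["CHR"] * config.n_chr + ["HC"] * config.n_hc
    ids = [f"CHR{i + 1:03d}" for i in range(config.n_chr)] + [
        f"HC{i + 1:03d}" for i in range(config.n_hc)
    ]

    rows: list[dict] = []
    target_rows: list[dict] = []
    samples: list[SpeechSample] = []
    for idx, (pid, group) in enumerate(zip(ids, groups)):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(idx,))
        rng = np.random.default_rng(ss)

        remote_frac = config.remote_frac_chr if group == "CHR" else config.remote_frac_hc
        modality = (
            Modality.REMOTE.value if rng.random() < remote_frac
            else Modality.IN_PERSON.value
        )
        latent = float(rng.standard_normal())
        targets = _draw_targets(config, group, modality, latent, rng)
        mean_rates = {
            t: float(_lognormal(rng, _spec_rate(config, t), config.rate_between_cov, ()))
            for t in config.tasks
        }
        profile = ParticipantProfile(pid, group, modality, latent, targets, mean_rates)

        record = generate_clinical_profile(pid, group, latent, config, rng)
        record["modality"] = modality
        record["latent_motor"] = latent
        rows.append(record)
        target_rows.append({"participant_id": pid, "group": group, **targets})

        if with_samples:
            for t in task_list:
                samples.append(
                    generate_speech_sample(profile, config.task_specs[t], config, rng)
                )

    participants = pd.DataFrame(rows)
    from .stats_inference import PARTICIPANT_COLUMNS

    participants = participants[PARTICIPANT_COLUMNS + ["latent_motor"]]
    return Cohort(
        participants=participants,
        samples=samples,
        targets=pd.DataFrame(target_rows),
        config=config,
        seed=int(seed),
    )


def _spec_rate(config: SyntheticConfig, task: str) -> float:
    return config.task_specs[task].mean_rate
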