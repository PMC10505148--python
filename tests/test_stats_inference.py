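"""Group models, validity correlations, power analytics, confounds."""

import numpy as np
import pandas as pd
import pytest

import speechvar as sv
from speechvar.measures import MEASURE_TABLE_COLUMNS, Measure, MeasureTable
from speechvar.stats_inference import (
    PARTICIPANT_COLUMNS,
    attach_tapping_covs,
    confound_and_classification,
    records_to_frame,
)


def make_table(values_by_measure, task="AMR"):
    """Tidy MeasureTable from {measure: {pid: raw}} dicts."""
    rows = []
    for measure, values in values_by_measure.items():
        for pid, raw in values.items():
            rows.append(
                (pid, task, "in_person", Measure(measure).value, raw,
                 np.log(raw) if raw > 0 else np.log(1e-3), 30, None)
            )
    return MeasureTable(pd.DataFrame(rows, columns=MEASURE_TABLE_COLUMNS))


def make_participants(n_chr, n_hc, rng=None, modality=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for i in range(n_chr + n_hc):
        group = "CHR" if i < n_chr else "HC"
        pid = f"{group}{i:03d}"
        taps = rng.integers(55, 75, 6)
        rows.append(
            dict(
                participant_id=pid, group=group,
                modality=modality or ("remote" if i % 2 else "in_person"),
                age=float(rng.normal(22, 3)), sex="F" if i % 2 else "M",
                race="White" if i % 3 else "Asian", ethnicity="NotHispanic",
                first_language="English" if i % 4 else "Other",
                sips_positive_total=float(rng.integers(0, 20)),
                sips_negative_total=float(rng.integers(0, 20)),
                sips_disorganized_total=float(rng.integers(0, 10)),
                sips_g3=float(rng.integers(0, 6)),
                tap_dom_1=int(taps[0]), tap_dom_2=int(taps[1]), tap_dom_3=int(taps[2]),
                tap_nondom_1=int(taps[3]), tap_nondom_2=int(taps[4]),
                tap_nondom_3=int(taps[5]),
                sips_rc_risk=float(rng.uniform(0.8, 10.1)) if group == "CHR" else np.nan,
            )
        )
    return pd.DataFrame(rows)[PARTICIPANT_COLUMNS]


class TestFingerTappingCov:
    def test_hand_computed(self):
        rec = sv.ParticipantRecord("p", "CHR", tap_counts_dominant=(60, 62, 58))
        assert sv.finger_tapping_cov(rec, "dominant") == pytest.approx(2 / 60)

    def test_constant_counts_zero(self):
        rec = sv.ParticipantRecord("p", "CHR", tap_counts_dominant=(50, 50, 50))
        assert sv.finger_tapping_cov(rec, "dominant") == 0.0

    def test_only_first_three_of_five_trials_used(self):
        rec = sv.ParticipantRecord("p", "CHR", tap_counts_dominant=(60, 62, 58, 10, 90))
        assert sv.finger_tapping_cov(rec, "dominant") == pytest.approx(2 / 60)

    def test_fewer_than_three_trials_missing(self):
        rec = sv.ParticipantRecord("p", "CHR", tap_counts_dominant=(60, 62))
        assert sv.finger_tapping_cov(rec, "dominant") is None

    def test_non_integer_counts_rejected(self):
        with pytest.raises(sv.ValidationError):
            sv.ParticipantRecord("p", "CHR", tap_counts_dominant=(60.5, 62, 58))

    def test_records_frame_round_trip(self):
        rec = sv.ParticipantRecord(
            "p", "CHR", tap_counts_dominant=(60, 62, 58),
            tap_counts_nondominant=(55, 57, 53),
        )
        frame = records_to_frame([rec])
        assert sv.finger_tapping_cov(frame.iloc[0], "nondominant") == pytest.approx(2 / 55)


class TestGroupDifference:
    def test_identical_groups_beta_zero(self):
        values = {f"CHR{i:03d}": 0.3 for i in range(5)}
        values.update({f"HC{i:03d}": 0.3 for i in range(5, 10)})
        table = make_table({"speech_rate_cov": values})
        participants = make_participants(5, 5)
        fit = sv.fit_group_difference(table, participants, "speech_rate_cov", "AMR")
        assert fit.beta == pytest.approx(0.0, abs=1e-12)

    def test_recovers_injected_log_shift(self):
        rng = np.random.default_rng(1)
        delta = 0.25
        participants = make_participants(300, 300, rng)
        base = rng.normal(-1.2, 0.3, 600)
        raw = {}
        for i, pid in enumerate(participants["participant_id"]):
            shift = delta if pid.startswith("CHR") else 0.0
            raw[pid] = float(np.exp(base[i] + shift))
        table = make_table({"speech_rate_cov": raw})
        fit = sv.fit_group_difference(table, participants, "speech_rate_cov", "AMR")
        assert fit.beta == pytest.approx(delta, abs=3 * fit.se)
        assert fit.t == pytest.approx(fit.beta / fit.se, abs=1e-9)

    def test_durational_measure_gets_rate_covariate(self, small_cohort):
        table = sv.compute_measure_table(small_cohort.samples)
        fit = sv.fit_group_difference(
            table, small_cohort.participants, "vot_cov_voiceless", "AMR",
            min_per_group=3,
        )
        assert fit.covariates == ["speech_rate_mean"]
        fit2 = sv.fit_group_difference(
            table, small_cohort.participants, "speech_rate_cov", "AMR",
            min_per_group=3,
        )
        assert fit2.covariates == []

    def test_missing_group_raises(self):
        values = {f"CHR{i:03d}": 0.3 + 0.01 * i for i in range(5)}
        table = make_table({"speech_rate_cov": values})
        participants = make_participants(5, 5)
        with pytest.raises(sv.InferenceError):
            sv.fit_group_difference(table, participants, "speech_rate_cov", "AMR")

    def test_participant_order_invariance(self, small_cohort):
        table = sv.compute_measure_table(small_cohort.samples)
        participants = small_cohort.participants
        shuffled = participants.sample(frac=1.0, random_state=7).reset_index(drop=True)
        f1 = sv.fit_group_difference(table, participants, "speech_rate_cov", "AMR", 3)
        f2 = sv.fit_group_difference(table, shuffled, "speech_rate_cov", "AMR", 3)
        assert f1.beta == pytest.approx(f2.beta, abs=1e-12)
        assert f1.p == pytest.approx(f2.p, abs=1e-12)


class TestValidityCorrelation:
    def test_affine_copy_gives_r_one(self):
        rng = np.random.default_rng(2)
        participants = make_participants(10, 5, rng)
        raw = {pid: float(v) for pid, v in zip(
            participants["participant_id"], rng.lognormal(-1, 0.3, 15))}
        table = make_table({"speech_rate_cov": raw})
        participants["sips_g3"] = [
            2.0 + 3.0 * np.log(raw[p]) for p in participants["participant_id"]
        ]
        c = sv.fit_validity_correlation(
            table, participants, "speech_rate_cov", "AMR", "sips_g3"
        )
        assert c.r == pytest.approx(1.0, abs=1e-9)
        assert c.n == 10  # CHR participants only

    def test_zero_variance_rejected(self):
        participants = make_participants(6, 4)
        raw = {pid: 0.3 for pid in participants["participant_id"]}
        table = make_table({"speech_rate_cov": raw})
        with pytest.raises(sv.InferenceError, match="zero variance"):
            sv.fit_validity_correlation(
                table, participants, "speech_rate_cov", "AMR", "sips_g3"
            )

    def test_too_few_pairs_rejected(self):
        participants = make_participants(3, 4)
        raw = {pid: 0.3 + 0.01 * i for i, pid in
               enumerate(participants["participant_id"])}
        table = make_table({"speech_rate_cov": raw})
        with pytest.raises(sv.InferenceError):
            sv.fit_validity_correlation(
                table, participants, "speech_rate_cov", "AMR", "sips_g3"
            )

    def test_gating_excludes_nonsignificant_measures(self):
        rng = np.random.default_rng(3)
        participants = make_participants(12, 12, rng)
        null_raw = {pid: float(v) for pid, v in zip(
            participants["participant_id"], rng.lognormal(-1, 0.3, 24))}
        table = make_table({"speech_rate_cov": null_raw})
        grid = sv.validity_grid(
            table, participants, tasks=["AMR"], measures=["speech_rate_cov"]
        )
        fit = sv.fit_group_difference(
            table, participants, "speech_rate_cov", "AMR"
        )
        if fit.p >= 0.05:
            assert grid.empty
        else:  # unlucky draw: grid must then cover every validation field
            assert len(grid) == 7


class TestModalityAnalysis:
    def test_single_modality_skips_stratum_and_interaction(self):
        rng = np.random.default_rng(4)
        participants = make_participants(8, 8, rng, modality="in_person")
        raw = {pid: float(v) for pid, v in zip(
            participants["participant_id"], rng.lognormal(-1, 0.3, 16))}
        table = make_table({"speech_rate_cov": raw})
        with pytest.warns(UserWarning, match="remote"):
            res = sv.modality_stratified_analysis(
                table, participants, "speech_rate_cov", "AMR"
            )
        assert set(res.per_modality) == {"in_person"}
        assert res.interaction is None

    def test_balanced_null_interaction_near_zero(self):
        rng = np.random.default_rng(5)
        betas = []
        for rep in range(50):
            participants = make_participants(20, 20, rng)
            raw = {pid: float(v) for pid, v in zip(
                participants["participant_id"], rng.lognormal(-1, 0.3, 40))}
            table = make_table({"speech_rate_cov": raw})
            res = sv.modality_stratified_analysis(
                table, participants, "speech_rate_cov", "AMR"
            )
            betas.append(res.interaction.beta)
        assert np.mean(betas) == pytest.approx(0.0, abs=0.05)

    def test_hc_remote_inflation_shrinks_remote_contrast(self):
        cfg = sv.SyntheticConfig(
            n_chr=60, n_hc=60, tasks=("AMR",), hc_remote_inflation=1.25,
            remote_frac_chr=0.5, remote_frac_hc=0.5,
        )
        diffs = {"in_person": [], "remote": []}
        for s in range(10):
            cohort = sv.generate_cohort(cfg, seed=900 + s)
            table = sv.compute_measure_table(
                cohort.samples, measures=[Measure.VOT_COV_VOICELESS]
            )
            res = sv.modality_stratified_analysis(
                table, cohort.participants, "vot_cov_voiceless", "AMR"
            )
            for m in diffs:
                diffs[m].append(res.per_modality[m].beta)
        assert np.mean(diffs["remote"]) < np.mean(diffs["in_person"])


class TestConfoundAndClassification:
    def test_separated_groups_loo_accuracy_100(self):
        participants = make_participants(10, 10)
        raw = {}
        for i, pid in enumerate(participants["participant_id"]):
            raw[pid] = 0.9 if pid.startswith("CHR") else 0.1
        # add tiny jitter so the logistic design is not degenerate
        rng = np.random.default_rng(6)
        raw = {pid: v * float(np.exp(rng.normal(0, 0.01))) for pid, v in raw.items()}
        table = make_table({"speech_rate_cov": raw})
        res = confound_and_classification(table, participants, "speech_rate_cov", "AMR")
        assert res.loo_accuracy == 1.0

    def test_identical_distributions_no_better_than_chance(self):
        # Leave-one-out logistic under the null is at (or pessimistically
        # below) chance: holding one sample out makes its class the training
        # minority, so a signal-free model votes against it.
        rng = np.random.default_rng(7)
        accs = []
        for rep in range(20):
            participants = make_participants(25, 25, rng)
            raw = {pid: float(v) for pid, v in zip(
                participants["participant_id"], rng.lognormal(-1, 0.3, 50))}
            table = make_table({"speech_rate_cov": raw})
            res = confound_and_classification(
                table, participants, "speech_rate_cov", "AMR"
            )
            accs.append(res.loo_accuracy)
        assert np.mean(accs) <= 0.55

    def test_moderate_separation_above_chance_but_imperfect(self):
        rng = np.random.default_rng(9)
        accs = []
        for rep in range(20):
            participants = make_participants(30, 30, rng)
            raw = {}
            for pid in participants["participant_id"]:
                shift = 0.35 if pid.startswith("CHR") else 0.0
                raw[pid] = float(np.exp(rng.normal(-1.2 + shift, 0.3)))
            table = make_table({"speech_rate_cov": raw})
            res = confound_and_classification(
                table, participants, "speech_rate_cov", "AMR"
            )
            accs.append(res.loo_accuracy)
        assert 0.55 < np.mean(accs) < 0.85

    def test_null_demographic_p_values_roughly_uniform(self):
        rng = np.random.default_rng(8)
        ps = []
        for rep in range(60):
            participants = make_participants(20, 20, rng)
            raw = {pid: float(v) for pid, v in zip(
                participants["participant_id"], rng.lognormal(-1, 0.3, 40))}
            table = make_table({"speech_rate_cov": raw})
            res = confound_and_classification(
                table, participants, "speech_rate_cov", "AMR"
            )
            ps.append(res.demographic_results["age"].p)
        # under the null, p-values are Uniform(0,1)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.11)
        assert (np.asarray(ps) < 0.05).mean() < 0.2


class TestPowerAnalysis:
    def test_required_n_at_anchor_effect_size(self):
        n = sv.power_analysis(sv.PowerSpec(r=0.37, alpha=0.05, power=0.80), "required_n")
        assert n == 56

    def test_minimal_r_at_fifty(self):
        r = sv.power_analysis(sv.PowerSpec(alpha=0.05, power=0.80, n=50), "minimal_r")
        assert r == pytest.approx(0.387, abs=0.001)

    def test_required_n_half(self):
        assert sv.power_analysis(sv.PowerSpec(r=0.5), "required_n") == 30

    def test_zero_r_diverges(self):
        with pytest.raises(sv.InferenceError):
            sv.power_analysis(sv.PowerSpec(r=0.0), "required_n")

    def test_monotonicity(self):
        ns = [sv.power_analysis(sv.PowerSpec(r=r), "required_n")
              for r in (0.2, 0.3, 0.4, 0.6)]
        assert ns == sorted(ns, reverse=True) and len(set(ns)) == 4
        rs = [sv.power_analysis(sv.PowerSpec(n=n), "minimal_r")
              for n in (10, 50, 200, 5000)]
        assert rs == sorted(rs, reverse=True)
        assert rs[-1] < 0.05  # minimal detectable r vanishes as n grows

    def test_power_increases_required_n(self):
        n80 = sv.power_analysis(sv.PowerSpec(r=0.3, power=0.80), "required_n")
        n90 = sv.power_analysis(sv.PowerSpec(r=0.3, power=0.90), "required_n")
        assert n90 > n80


class TestLogTransformTable:
    def test_log_recomputed_with_epsilon(self):
        table = make_table({"vowel_overlap": {"CHR000": 0.0}}, task="READ")
        out = sv.log_transform_measures(table, epsilon=1e-3)
        assert out.data["log"].iloc[0] == pytest.approx(np.log(1e-3))

    def test_negative_non_signed_measure_rejected(self):
        df = make_table({"speech_rate_cov": {"CHR000": 0.3}}).data.copy()
        df.loc[0, "raw"] = -0.5
        with pytest.raises(sv.ValidationError):
            sv.log_transform_measures(MeasureTable(df))


class TestTappingAttachment:
    def test_attach_tapping_covs_columns(self):
        participants = make_participants(3, 3)
        out = attach_tapping_covs(participants)
        assert {"tap_cov_dominant", "tap_cov_nondominant"} <= set(out.columns)
        assert out["tap_cov_dominant"].notna().all()
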