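import numpy as np
import pandas as pd
import pytest

from recmem.pdp import PairCounts, pdp_indices
from recmem.rkg import RKGCounts, rkg_indices
from recmem.sdt import CountPair
from recmem.simulate import (
    DEFAULT_GROUPS,
    GroupParams,
    SimConfig,
    SubjectLatents,
    TaskDesign,
    draw_subject,
    simulate_cohort,
    simulate_pdp_trials,
    simulate_rkg_trials,
    simulate_roc_trials,
)

LATENTS = SubjectLatents(
    rho=0.4,
    delta=1.2,
    criteria_roc=np.array([-1.0, -0.2, 0.6, 1.4, 2.2]),
    yes_criterion=0.6,
    guess_rate=0.1,
)


class TestDrawSubject:
    def test_zero_spread_returns_group_means(self):
        cfg = SimConfig(
            groups={"control": GroupParams(0.5, 0.0, 1.3, 0.0, criterion_sd=0.0, yes_criterion_sd=0.0)}
        )
        lat = draw_subject("control", cfg, np.random.default_rng(0))
        assert lat.rho == pytest.approx(0.5)
        assert lat.delta == pytest.approx(1.3)

    def test_same_seed_same_latents(self):
        cfg = SimConfig()
        a = draw_subject("patient", cfg, np.random.default_rng(9))
        b = draw_subject("patient", cfg, np.random.default_rng(9))
        assert a.rho == b.rho and a.delta == b.delta
        assert np.array_equal(a.criteria_roc, b.criteria_roc)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            draw_subject("alien", SimConfig(), np.random.default_rng(0))

    def test_law_of_large_numbers_on_rho(self):
        cfg = SimConfig()
        rng = np.random.default_rng(1)
        draws = [draw_subject("control", cfg, rng).rho for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(DEFAULT_GROUPS["control"].rho_mean, abs=0.01)

    def test_criteria_strictly_ordered(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        for _ in range(200):
            lat = draw_subject("control", cfg, rng)
            assert np.all(np.diff(lat.criteria_roc) > 0)


class TestTaskSimulators:
    def test_roc_item_counts_and_columns(self):
        df = simulate_roc_trials(LATENTS, SimConfig(), np.random.default_rng(0))
        assert len(df) == 180
        assert (df["item_class"] == "target").sum() == 120
        assert set(df.loc[df["item_class"] == "target", "encoding_depth"]) == {"deep", "shallow"}

    def test_roc_pure_recollection_all_top_confidence(self):
        lat = SubjectLatents(1.0, 1.2, LATENTS.criteria_roc, 0.6, 0.1)
        df = simulate_roc_trials(lat, SimConfig(), np.random.default_rng(0))
        assert (df.loc[df["item_class"] == "target", "confidence"] == 6).all()

    def test_roc_null_model_indistinguishable(self):
        from recmem.stats import chi_square

        lat = SubjectLatents(0.0, 0.0, np.array([-1.0, -0.5, 0.0, 0.5, 1.0]), 0.0, 0.1)
        cfg = SimConfig().scaled(100)  # 12,000 targets, 6,000 distractors
        df = simulate_roc_trials(lat, cfg, np.random.default_rng(3))
        table = pd.crosstab(df["item_class"], df["confidence"]).to_numpy()
        _, p = chi_square(table)
        assert p > 0.01

    def test_pdp_counts_and_veto(self):
        cfg = SimConfig()
        lat = SubjectLatents(1.0, 1.2, LATENTS.criteria_roc, 0.6, 0.1)
        df = simulate_pdp_trials(lat, cfg, np.random.default_rng(0))
        assert len(df) == 120
        by_class = df.groupby("item_class")["response"].apply(lambda s: (s == "yes").mean())
        assert by_class["intact"] == 1.0
        assert by_class["recombined"] == 0.0  # recollection vetoes recombined pairs

    def test_pdp_null_inclusion_equals_exclusion(self):
        lat = SubjectLatents(0.0, 1.2, LATENTS.criteria_roc, 0.6, 0.1)
        cfg = SimConfig().scaled(250)  # 10,000 pairs per class
        df = simulate_pdp_trials(lat, cfg, np.random.default_rng(4))
        yes = df.groupby("item_class")["response"].apply(lambda s: (s == "yes").mean())
        assert yes["intact"] == pytest.approx(yes["recombined"], abs=0.03)

    def test_rkg_attribution_structure(self):
        df = simulate_rkg_trials(LATENTS, SimConfig(), np.random.default_rng(0))
        assert len(df) == 120
        yes = df[df["response"] == "yes"]
        assert set(yes["attribution"]) <= {"R", "K", "G"}
        assert (df.loc[df["response"] == "no", "attribution"] == "").all()

    def test_rkg_zero_guess_rate_yields_no_guesses(self):
        lat = SubjectLatents(0.4, 1.2, LATENTS.criteria_roc, 0.6, 0.0)
        df = simulate_rkg_trials(lat, SimConfig(), np.random.default_rng(1))
        assert (df["attribution"] != "G").all()

    def test_rkg_pure_recollection(self):
        lat = SubjectLatents(1.0, 1.2, LATENTS.criteria_roc, 0.6, 0.1)
        df = simulate_rkg_trials(lat, SimConfig(), np.random.default_rng(2))
        targets = df[df["item_class"] == "target"]
        assert (targets["response"] == "yes").all()
        assert (targets["attribution"] == "R").all()


class TestEstimatorConsistency:
    """Matched estimators recover the generating latents at large n."""

    def test_pdp_estimator_recovers_latents(self):
        from scipy.special import ndtr

        cfg = SimConfig().scaled(250)
        df = simulate_pdp_trials(LATENTS, cfg, np.random.default_rng(5))
        yes = df.groupby("item_class")["response"].apply(lambda s: int((s == "yes").sum()))
        n = cfg.design.pdp_intact
        idx = pdp_indices(
            PairCounts(CountPair(yes["intact"], n), CountPair(yes["recombined"], n), CountPair(yes["new"], n))
        )
        assert idx.R_pdp == pytest.approx(LATENTS.rho, abs=0.05)
        assert idx.F_pdp == pytest.approx(float(ndtr(LATENTS.delta - LATENTS.yes_criterion)), abs=0.05)

    def test_rkg_estimator_recovers_latents(self):
        cfg = SimConfig().scaled(170)  # ~10,000 items per row
        df = simulate_rkg_trials(LATENTS, cfg, np.random.default_rng(6))

        def row(klass):
            sub = df[df["item_class"] == klass]
            return (
                int((sub["attribution"] == "R").sum()),
                int((sub["attribution"] == "K").sum()),
                int((sub["attribution"] == "G").sum()),
                int((sub["response"] == "no").sum()),
            )

        idx = rkg_indices(RKGCounts(*row("target"), *row("distractor")))
        assert idx.R_rkg == pytest.approx(LATENTS.rho, abs=0.05)
        assert idx.F_rkg == pytest.approx(LATENTS.delta, abs=0.1)

    def test_roc_estimator_recovers_latents(self):
        from recmem.dpsd import ConfusionTable, fit_dpsd

        cfg = SimConfig().scaled(84)  # ~10,000 targets
        df = simulate_roc_trials(LATENTS, cfg, np.random.default_rng(7))
        conf = df.groupby("item_class")["confidence"].apply(
            lambda s: np.bincount(s.astype(int), minlength=7)[1:7]
        )
        fit = fit_dpsd(ConfusionTable(conf["target"], conf["distractor"]), seed=0)
        assert fit.R == pytest.approx(LATENTS.rho, abs=0.05)
        assert fit.d_f == pytest.approx(LATENTS.delta, abs=0.05)

    def test_monotone_in_latents(self):
        # raising rho raises every R index; raising delta raises every F index
        from recmem.pipeline import score_subjects

        cfg = SimConfig().scaled(25)
        out = {}
        for name, (rho, delta) in {
            "low": (0.2, 0.8),
            "high_rho": (0.6, 0.8),
            "high_delta": (0.2, 1.8),
        }.items():
            lat = SubjectLatents(rho, delta, delta / 2 + np.array([-1.6, -0.8, 0, 0.8, 1.6]), delta / 2, 0.1)
            rng = np.random.default_rng(8)
            frames = [
                simulate_roc_trials(lat, cfg, rng),
                simulate_pdp_trials(lat, cfg, rng),
                simulate_rkg_trials(lat, cfg, rng),
            ]
            out[name] = score_subjects(pd.concat(frames, ignore_index=True)).set_index("task")
        for task in ("ROC", "PDP", "RKG"):
            assert out["high_rho"].loc[task, "R_index"] > out["low"].loc[task, "R_index"]
            assert out["high_delta"].loc[task, "F_index"] > out["low"].loc[task, "F_index"]


class TestCohort:
    def test_default_cohort_shape(self, default_cohort):
        trials, groups = default_cohort
        assert len(groups) == 37
        assert len(trials) == 37 * (180 + 120 + 120)
        counts = trials.groupby(["subject_id", "task"]).size().unstack()
        assert (counts["ROC"] == 180).all()
        assert (counts["PDP"] == 120).all()
        assert (counts["RKG"] == 120).all()

    def test_subgroup_labels(self, default_cohort):
        _, groups = default_cohort
        assert (groups.loc[groups["group"] == "patient", "subgroup"].value_counts() == pd.Series({"dMTT": 7, "iMTT": 5})).all()
        assert (groups.loc[groups["group"] == "control", "subgroup"] == "").all()

    def test_same_seed_byte_identical_csv(self, tmp_path):
        cfg = SimConfig(seed=123)
        paths = []
        for tag in ("a", "b"):
            trials, groups = simulate_cohort(cfg)
            p = tmp_path / f"trials_{tag}.csv"
            trials.to_csv(p, index=False)
            groups.to_csv(tmp_path / f"groups_{tag}.csv", index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert (tmp_path / "groups_a.csv").read_bytes() == (tmp_path / "groups_b.csv").read_bytes()

    def test_subgroup_effects_lower_dmtt_latents(self):
        cfg = SimConfig(seed=3, subgroup_effects=True)
        trials, groups = simulate_cohort(cfg)
        from recmem.pipeline import score_subjects

        idx = score_subjects(trials).merge(groups, on="subject_id")
        by = idx[idx["group"] == "patient"].groupby("subgroup")[["R_index", "F_index"]].mean()
        assert by.loc["dMTT", "F_index"] < by.loc["iMTT", "F_index"]
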