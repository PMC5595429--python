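"""Trial-level simulator for the three recognition tasks.

Each subject carries two latent memory parameters: a recollection
probability ``rho`` (all-or-none threshold retrieval of the study context)
and a familiarity strength ``delta`` (mean of an equal-variance Gaussian
strength distribution for studied items, unstudied items at mean 0). These
are exactly the assumptions under which the three estimators are unbiased,
so large-sample parameter recovery is a fair consistency check.

The default cohort reproduces the study conditions: 12 patients and 25
controls; a confidence-ROC task with 120 targets and 60 distractors on a
6-point scale; an associative task with 40 intact, 40 recombined and 40
new pairs; and a Remember/Know/Guess task with 60 targets and 60
distractors. The default patient configuration lowers recollection only,
leaving familiarity matched to controls; the damaged-MTT subgroup
configuration (used when subgroup effects are switched on) lowers both.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SubjectLatents",
    "GroupParams",
    "TaskDesign",
    "SimConfig",
    "draw_subject",
    "simulate_roc_trials",
    "simulate_pdp_trials",
    "simulate_rkg_trials",
    "simulate_cohort",
]

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "task",
    "item_class",
    "response",
    "confidence",
    "attribution",
    "encoding_depth",
]

# confidence-criteria offsets around the midpoint between the old and new
# strength distributions; chosen to spread responses over the 6-point scale
_CRITERIA_OFFSETS = np.array([-1.6, -0.8, 0.0, 0.8, 1.6])


@dataclass(frozen=True)
class SubjectLatents:
    rho: float  # recollection probability
    delta: float  # familiarity strength (z units)
    criteria_roc: np.ndarray  # 5 ordered confidence criteria
    yes_criterion: float  # yes/no decision criterion (PDP, RKG)
    guess_rate: float  # P(G | familiarity-driven yes) in the RKG task


@dataclass(frozen=True)
class GroupParams:
    """Location and spread of the latent distributions for one group."""

    rho_mean: float
    rho_sd: float
    delta_mean: float
    delta_sd: float
    criterion_sd: float = 0.10
    yes_criterion_sd: float = 0.15
    guess_rate_mean: float = 0.10
    guess_rate_sd: float = 0.05


DEFAULT_GROUPS: dict[str, GroupParams] = {
    "control": GroupParams(rho_mean=0.55, rho_sd=0.12, delta_mean=1.30, delta_sd=0.25),
    "patient": GroupParams(rho_mean=0.15, rho_sd=0.08, delta_mean=1.30, delta_sd=0.25),
    "patient_dMTT": GroupParams(rho_mean=0.12, rho_sd=0.06, delta_mean=0.95, delta_sd=0.25),
    "patient_iMTT": GroupParams(rho_mean=0.25, rho_sd=0.10, delta_mean=1.30, delta_sd=0.25),
}


@dataclass(frozen=True)
class TaskDesign:
    roc_targets: int = 120
    roc_distractors: int = 60
    pdp_intact: int = 40
    pdp_recombined: int = 40
    pdp_new: int = 40
    rkg_targets: int = 60
    rkg_distractors: int = 60


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 12
    n_controls: int = 25
    n_dmtt: int = 7  # of the patients, how many carry the dMTT label
    groups: dict[str, GroupParams] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    design: TaskDesign = field(default_factory=TaskDesign)
    delta_assoc_frac: float = 1.0  # recombined-pair familiarity as a fraction of delta
    subgroup_effects: bool = False  # draw dMTT/iMTT patients from their own distributions
    seed: int = 0

    def scaled(self, factor: int) -> "SimConfig":
        """Same config with every item count multiplied by ``factor``."""
        d = self.design
        return replace(
            self,
            design=TaskDesign(
                roc_targets=d.roc_targets * factor,
                roc_distractors=d.roc_distractors * factor,
                pdp_intact=d.pdp_intact * factor,
                pdp_recombined=d.pdp_recombined * factor,
                pdp_new=d.pdp_new * factor,
                rkg_targets=d.rkg_targets * factor,
                rkg_distractors=d.rkg_distractors * factor,
            ),
        )


def draw_subject(group: str, config: SimConfig, rng: np.random.Generator) -> SubjectLatents:
    """Sample one subject's latent parameters from the group distribution."""
    try:
        params = config.groups[group]
    except KeyError:
        raise ValueError(f"unknown group label {group!r}") from None
    rho = float(np.clip(rng.normal(params.rho_mean, params.rho_sd), 0.01, 0.99))
    delta = float(np.clip(rng.normal(params.delta_mean, params.delta_sd), 0.05, None))
    criteria = delta / 2 + _CRITERIA_OFFSETS + rng.normal(0.0, params.criterion_sd, size=5)
    criteria = np.sort(criteria)
    criteria = np.maximum.accumulate(criteria + np.arange(5) * 1e-3)  # strict order
    yes_criterion = float(delta / 2 + rng.normal(0.0, params.yes_criterion_sd))
    guess_rate = float(np.clip(rng.normal(params.guess_rate_mean, params.guess_rate_sd), 0.0, 0.4))
    return SubjectLatents(rho, delta, criteria, yes_criterion, guess_rate)


def _bin_confidence(strength: np.ndarray, criteria: np.ndarray) -> np.ndarray:
    return np.searchsorted(criteria, strength) + 1  # categories 1..6


def _frame(rows: dict, subject_id: str, group: str, task: str) -> pd.DataFrame:
    n = len(rows["item_class"])
    data = {
        "subject_id": [subject_id] * n,
        "group": [group] * n,
        "task": [task] * n,
        "item_class": rows["item_class"],
        "response": rows["response"],
        "confidence": rows.get("confidence", [""] * n),
        "attribution": rows.get("attribution", [""] * n),
        "encoding_depth": rows.get("encoding_depth", [""] * n),
    }
    return pd.DataFrame(data, columns=TRIAL_COLUMNS)


def simulate_roc_trials(
    latents: SubjectLatents,
    config: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "S1",
    group: str = "control",
) -> pd.DataFrame:
    """Confidence-ROC task: recollected targets answer 6, the rest bin a
    Gaussian strength draw by the subject's criteria."""
    d = config.design
    recollected = rng.random(d.roc_targets) < latents.rho
    strength = rng.normal(latents.delta, 1.0, size=d.roc_targets)
    conf_old = np.where(recollected, 6, _bin_confidence(strength, latents.criteria_roc))
    conf_new = _bin_confidence(rng.normal(0.0, 1.0, size=d.roc_distractors), latents.criteria_roc)

    half = d.roc_targets // 2
    depth = np.array(["deep"] * half + ["shallow"] * (d.roc_targets - half))
    conf = np.concatenate([conf_old, conf_new])
    rows = {
        "item_class": ["target"] * d.roc_targets + ["distractor"] * d.roc_distractors,
        "response": np.where(conf >= 4, "yes", "no"),
        "confidence": conf,
        "encoding_depth": np.concatenate([depth, [""] * d.roc_distractors]),
    }
    return _frame(rows, subject_id, group, "ROC")


def simulate_pdp_trials(
    latents: SubjectLatents,
    config: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "S1",
    group: str = "control",
) -> pd.DataFrame:
    """Associative task under the independence model.

    Intact pairs are accepted on recollection or on familiarity above the
    yes criterion; recollection of the original pairing vetoes recombined
    pairs, which are accepted only on (attenuated) familiarity; new pairs
    only through false alarms.
    """
    from scipy.special import ndtr

    d = config.design
    delta_assoc = config.delta_assoc_frac * latents.delta
    p_fam = float(ndtr(latents.delta - latents.yes_criterion))
    p_fam_assoc = float(ndtr(delta_assoc - latents.yes_criterion))
    p_fa = float(ndtr(-latents.yes_criterion))

    p_intact = latents.rho + (1 - latents.rho) * p_fam
    p_recomb = (1 - latents.rho) * p_fam_assoc
    yes_int = rng.random(d.pdp_intact) < p_intact
    yes_rec = rng.random(d.pdp_recombined) < p_recomb
    yes_new = rng.random(d.pdp_new) < p_fa
    rows = {
        "item_class": ["intact"] * d.pdp_intact
        + ["recombined"] * d.pdp_recombined
        + ["new"] * d.pdp_new,
        "response": np.where(np.concatenate([yes_int, yes_rec, yes_new]), "yes", "no"),
    }
    return _frame(rows, subject_id, group, "PDP")


def simulate_rkg_trials(
    latents: SubjectLatents,
    config: SimConfig,
    rng: np.random.Generator,
    subject_id: str = "S1",
    group: str = "control",
) -> pd.DataFrame:
    """Remember/Know/Guess task: recollection yields 'yes'+R; otherwise a
    familiarity draw above the yes criterion yields 'yes' attributed K, or
    G with the subject's guess rate."""
    d = config.design

    def one_class(n: int, mean: float, can_recollect: bool):
        rec = (rng.random(n) < latents.rho) if can_recollect else np.zeros(n, bool)
        fam_yes = rng.normal(mean, 1.0, size=n) > latents.yes_criterion
        yes = rec | fam_yes
        attr = np.full(n, "", dtype=object)
        attr[rec] = "R"
        fam_only = fam_yes & ~rec
        guesses = rng.random(n) < latents.guess_rate
        attr[fam_only & guesses] = "G"
        attr[fam_only & ~guesses] = "K"
        return yes, attr

    yes_old, attr_old = one_class(d.rkg_targets, latents.delta, True)
    yes_new, attr_new = one_class(d.rkg_distractors, 0.0, False)
    rows = {
        "item_class": ["target"] * d.rkg_targets + ["distractor"] * d.rkg_distractors,
        "response": np.where(np.concatenate([yes_old, yes_new]), "yes", "no"),
        "attribution": np.concatenate([attr_old, attr_new]),
    }
    return _frame(rows, subject_id, group, "RKG")


def simulate_cohort(config: SimConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trials, groups) data frames.

    Deterministic given ``config.seed``: each subject gets an independent
    child seed, so adding subjects never perturbs existing ones.
    """
    config = config or SimConfig()
    roster = []
    for i in range(config.n_patients):
        subgroup = "dMTT" if i < config.n_dmtt else "iMTT"
        roster.append((f"P{i + 1:02d}", "patient", subgroup))
    for i in range(config.n_controls):
        roster.append((f"C{i + 1:02d}", "control", ""))

    seeds = np.random.SeedSequence(config.seed).spawn(len(roster))
    trial_frames = []
    for (sid, group, subgroup), ss in zip(roster, seeds):
        rng = np.random.default_rng(ss)
        draw_group = group
        if config.subgroup_effects and group == "patient":
            draw_group = f"patient_{subgroup}"
        latents = draw_subject(draw_group, config, rng)
        trial_frames.append(simulate_roc_trials(latents, config, rng, sid, group))
        trial_frames.append(simulate_pdp_trials(latents, config, rng, sid, group))
        trial_frames.append(simulate_rkg_trials(latents, config, rng, sid, group))

    trials = pd.concat(trial_frames, ignore_index=True)
    groups = pd.DataFrame(roster, columns=["subject_id", "group", "subgroup"])
    return trials, groups
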