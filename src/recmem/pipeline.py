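"""End-to-end orchestration: trial-level data -> per-subject indices ->
z-summaries, group comparisons, correlations, and parameter-recovery
experiments.

Scoring dispatches each subject x task cell to the matching estimator
(confidence-ROC model fit, process-dissociation algebra, Remember/Know/
Guess algebra) and always attaches the task's d' and criterion c. The
group analysis mirrors a fixed comparison battery: patient-vs-control
Mann-Whitney tests per index and task with the stochastic-superiority
effect size A, the same tests on the cross-task z averages, Spearman
correlation of the averaged recollection and familiarity z-scores within
each group, and exhaustive permutation contrasts between the lesion
subgroups. Holm adjustment is applied within each index's family of three
per-task comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dpsd, stats
from .pdp import PairCounts, pdp_indices
from .rkg import RKGCounts, rkg_indices
from .sdt import CountPair, dprime_c
from .simulate import SimConfig, draw_subject, simulate_cohort

logger = logging.getLogger("recmem")

__all__ = ["ScoreOptions", "ResultsBundle", "score_subjects", "run_group_analysis", "recover_parameters"]

INDEX_COLS = ("d_prime", "R_index", "F_index")
TASKS = ("ROC", "PDP", "RKG")


@dataclass(frozen=True)
class ScoreOptions:
    roc_method: str = "ml"  # ml | sse
    roc_restarts: int = 10
    pdp_correct_rates: bool = True
    pdp_fa_class: str = "new"  # new | pooled
    rkg_variant: str = "irk"  # irk | literal
    rkg_drop_guesses: bool = False
    seed: int = 0


@dataclass
class ResultsBundle:
    indices: pd.DataFrame
    z_scores: pd.DataFrame
    comparisons: list[dict] = field(default_factory=list)
    correlations: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "comparisons": self.comparisons,
            "correlations": self.correlations,
            "n_subjects": int(self.indices["subject_id"].nunique()),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_table(self) -> str:
        """Markdown summary of the comparison battery, rounded to 2 decimals."""
        lines = [
            "| comparison | index | task | stat | p | p (Holm) | A | n1 | n2 |",
            "|---|---|---|---|---|---|---|---|---|",
        ]
        for c in self.comparisons:
            a = "" if c.get("effect_A") is None else f"{c['effect_A']:.2f}"
            holm = c.get("p_holm")
            lines.append(
                f"| {c['contrast']} | {c['index']} | {c.get('task') or 'z-avg'} | "
                f"{c['statistic']:.2f} | {c['p_value']:.3f} | "
                f"{'' if holm is None else format(holm, '.3f')} | {a} | {c['n1']} | {c['n2']} |"
            )
        for c in self.correlations:
            lines.append(
                f"| spearman ({c['group']}) | {c['pair']} |  | {c['rho']:.2f} | "
                f"{c['p_value']:.3f} |  |  | {c['n']} |  |"
            )
        return "\n".join(lines)


def _roc_cell(cell: pd.DataFrame, opts: ScoreOptions) -> dict | None:
    old = cell[cell["item_class"] == "target"]
    new = cell[cell["item_class"] == "distractor"]
    if old.empty or new.empty:
        return None
    conf_old = old["confidence"].astype(int).to_numpy()
    conf_new = new["confidence"].astype(int).to_numpy()
    table = dpsd.ConfusionTable(
        old_counts=np.bincount(conf_old, minlength=7)[1:7],
        new_counts=np.bincount(conf_new, minlength=7)[1:7],
    )
    fit = dpsd.fit_dpsd(table, method=opts.roc_method, n_restarts=opts.roc_restarts, seed=opts.seed)
    sdt = dprime_c(
        CountPair(int((old["response"] == "yes").sum()), len(old)),
        CountPair(int((new["response"] == "yes").sum()), len(new)),
    )
    return {
        "d_prime": sdt.d_prime,
        "criterion_c": sdt.criterion_c,
        "R_index": fit.R,
        "F_index": fit.d_f,
        "hit_rate": sdt.hit_rate,
        "fa_rate": sdt.fa_rate,
        "converged": fit.converged and fit.identifiable,
    }


def _pdp_cell(cell: pd.DataFrame, opts: ScoreOptions) -> dict | None:
    def yes_pair(klass: str) -> CountPair | None:
        sub = cell[cell["item_class"] == klass]
        if sub.empty:
            return None
        return CountPair(int((sub["response"] == "yes").sum()), len(sub))

    pairs = [yes_pair(k) for k in ("intact", "recombined", "new")]
    if any(p is None for p in pairs):
        return None
    idx = pdp_indices(
        PairCounts(*pairs),
        correct_rates=opts.pdp_correct_rates,
        fa_class=opts.pdp_fa_class,
    )
    return {
        "d_prime": idx.d_prime,
        "criterion_c": idx.criterion_c,
        "R_index": idx.R_pdp,
        "F_index": idx.F_pdp,
        "hit_rate": idx.p_included,
        "fa_rate": idx.p_excluded,
        "converged": True,
    }


def _rkg_cell(cell: pd.DataFrame, opts: ScoreOptions) -> dict | None:
    old = cell[cell["item_class"] == "target"]
    new = cell[cell["item_class"] == "distractor"]
    if old.empty or new.empty:
        return None

    def attr_counts(sub: pd.DataFrame) -> tuple[int, int, int, int]:
        yes = sub[sub["response"] == "yes"]
        r = int((yes["attribution"] == "R").sum())
        k = int((yes["attribution"] == "K").sum())
        g = int((yes["attribution"] == "G").sum())
        return r, k, g, len(sub) - len(yes)

    counts = RKGCounts(*attr_counts(old), *attr_counts(new))
    idx = rkg_indices(counts, variant=opts.rkg_variant, drop_guesses=opts.rkg_drop_guesses)
    return {
        "d_prime": idx.d_prime,
        "criterion_c": idx.criterion_c,
        "R_index": idx.R_rkg,
        "F_index": idx.F_rkg,
        "hit_rate": idx.yes_rate_old,
        "fa_rate": idx.yes_rate_new,
        "converged": True,
    }


_SCORERS = {"ROC": _roc_cell, "PDP": _pdp_cell, "RKG": _rkg_cell}


def score_subjects(trials: pd.DataFrame, options: ScoreOptions | None = None) -> pd.DataFrame:
    """Per-subject, per-task indices (d', c, R, F plus raw rates).

    A subject x task cell missing a whole item class is dropped with a log
    message; an unknown task label is a hard error.
    """
    opts = options or ScoreOptions()
    unknown = set(trials["task"].unique()) - set(TASKS)
    if unknown:
        raise ValueError(f"unknown task label(s): {sorted(unknown)}")
    rows = []
    for (sid, task), cell in trials.groupby(["subject_id", "task"], sort=True):
        scored = _SCORERS[task](cell, opts)
        if scored is None:
            logger.warning("dropping %s/%s: empty item class", sid, task)
            continue
        rows.append({"subject_id": sid, "task": task, **scored})
    return pd.DataFrame(rows)


def _comparison_dict(contrast: str, index: str, task: str | None, gc: stats.GroupComparison) -> dict:
    d = gc.to_dict()
    d.update({"contrast": contrast, "index": index, "task": task})
    return d


def run_group_analysis(
    indices: pd.DataFrame,
    groups: pd.DataFrame,
    seed: int = 0,
    n_perm: int = 10_000,
    alpha: float = 0.05,
) -> ResultsBundle:
    """Full comparison battery on a scored cohort.

    ``groups`` must label every subject present in ``indices`` (columns
    subject_id, group, optional subgroup); an unlabeled subject is a hard
    error. Subgroup permutation contrasts are only run for subgroups with
    at least 2 members.
    """
    labels = groups.set_index("subject_id")
    missing = set(indices["subject_id"]) - set(labels.index)
    if missing:
        raise ValueError(f"subject(s) missing from groups sheet: {sorted(missing)}")

    control_ids = labels.index[labels["group"] == "control"]
    patient_ids = labels.index[labels["group"] == "patient"]
    z = stats.z_summary(indices, control_ids)
    z = z.merge(groups, on="subject_id", how="left")

    comparisons: list[dict] = []
    # per-index, per-task patient vs control Mann-Whitney (Holm family = the
    # three tasks of one index)
    for index in INDEX_COLS:
        fam = []
        for task in TASKS:
            sub = indices[indices["task"] == task].set_index("subject_id")[index].dropna()
            a = sub[sub.index.isin(patient_ids)].to_numpy()
            b = sub[sub.index.isin(control_ids)].to_numpy()
            if a.size < 2 or b.size < 2:
                logger.warning("skipping %s/%s: group too small", index, task)
                continue
            fam.append(_comparison_dict("patient_vs_control", index, task, stats.mann_whitney(a, b)))
        if fam:
            adj = stats.holm_correct([c["p_value"] for c in fam])
            for c, p in zip(fam, adj):
                c["p_holm"] = float(p)
            comparisons.extend(fam)

    # averaged-z comparisons
    zp = z[z["group"] == "patient"]
    zc = z[z["group"] == "control"]
    zfam = []
    for index in INDEX_COLS:
        col = f"z_{index}"
        zfam.append(
            _comparison_dict(
                "patient_vs_control", col, None,
                stats.mann_whitney(zp[col].to_numpy(), zc[col].to_numpy()),
            )
        )
    adj = stats.holm_correct([c["p_value"] for c in zfam])
    for c, p in zip(zfam, adj):
        c["p_holm"] = float(p)
    comparisons.extend(zfam)

    # subgroup permutation contrasts on averaged z
    zd = z[(z["group"] == "patient") & (z["subgroup"] == "dMTT")]
    zi = z[(z["group"] == "patient") & (z["subgroup"] == "iMTT")]
    pairs = [("dMTT_vs_iMTT", zd, zi), ("dMTT_vs_control", zd, zc), ("iMTT_vs_control", zi, zc)]
    for name, a_df, b_df in pairs:
        if len(a_df) < 2 or len(b_df) < 2:
            logger.warning("skipping subgroup contrast %s: group too small", name)
            continue
        for index in INDEX_COLS:
            col = f"z_{index}"
            gc = stats.permutation_test(
                a_df[col].to_numpy(), b_df[col].to_numpy(),
                statistic="mean_diff", n_perm=n_perm, seed=seed,
            )
            comparisons.append(_comparison_dict(name, col, None, gc))

    # zR - zF correlation within each group
    correlations: list[dict] = []
    for gname, gdf in (("patient", zp), ("control", zc)):
        if len(gdf) >= 3:
            res = stats.spearman_rho(gdf["z_R_index"].to_numpy(), gdf["z_F_index"].to_numpy())
            correlations.append(
                {
                    "group": gname,
                    "pair": "z_R~z_F",
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "n": res.n,
                    "undefined": res.undefined,
                }
            )

    return ResultsBundle(indices=indices, z_scores=z, comparisons=comparisons, correlations=correlations)


def recover_parameters(
    config: SimConfig | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    scale_factors: tuple[int, ...] = (1, 10),
    options: ScoreOptions | None = None,
) -> pd.DataFrame:
    """Simulate -> score -> compare latents with estimates.

    For each scale factor the study design's item counts are multiplied up
    and ``n_replicates`` subjects per group are simulated; reports bias and
    RMSE of each estimator's R and F indices against the generating
    latents. For familiarity, the ROC and RKG estimates target delta
    itself; the associative-task familiarity is compared on the acceptance
    probability scale Phi(delta - yes criterion).
    """
    from scipy.special import ndtr
    from .simulate import simulate_pdp_trials, simulate_rkg_trials, simulate_roc_trials

    config = config or SimConfig()
    opts = options or ScoreOptions()
    rows = []
    sims = {"ROC": simulate_roc_trials, "PDP": simulate_pdp_trials, "RKG": simulate_rkg_trials}
    for factor in scale_factors:
        cfg = config.scaled(factor)
        seeds = np.random.SeedSequence((seed, factor)).spawn(n_replicates)
        errs: dict[tuple[str, str], list[float]] = {}
        for ss in seeds:
            rng = np.random.default_rng(ss)
            group = "control" if rng.random() < 0.5 else "patient"
            lat = draw_subject(group, cfg, rng)
            frames = [sims[t](lat, cfg, rng, "S1", group) for t in TASKS]
            scored = score_subjects(pd.concat(frames, ignore_index=True), opts).set_index("task")
            f_pdp_true = float(ndtr(lat.delta - lat.yes_criterion))
            truth = {
                ("ROC", "R"): lat.rho, ("ROC", "F"): lat.delta,
                ("PDP", "R"): lat.rho, ("PDP", "F"): f_pdp_true,
                ("RKG", "R"): lat.rho, ("RKG", "F"): lat.delta,
            }
            for task in TASKS:
                for which, col in (("R", "R_index"), ("F", "F_index")):
                    err = float(scored.loc[task, col]) - truth[(task, which)]
                    errs.setdefault((task, which), []).append(err)
        for (task, which), es in errs.items():
            arr = np.asarray(es)
            rows.append(
                {
                    "scale": factor,
                    "task": task,
                    "index": which,
                    "bias": float(arr.mean()),
                    "rmse": float(np.sqrt(np.mean(arr**2))),
                    "n_replicates": n_replicates,
                }
            )
    return pd.DataFrame(rows)
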