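"""Process-dissociation estimates from the associative word-pair task.

Intact (target) pairs can be accepted through recollection of the studied
pairing or through familiarity of the components ("included"); recombined
pairs can only be accepted through familiarity, because recollecting the
original pairing vetoes them ("excluded"). Subtracting the two acceptance
rates isolates recollection, and the excluded rate rescaled by the
recollection failure probability estimates familiarity:

    R = p(included) - p(excluded)
    F = p(excluded) / (1 - R)
"""

from __future__ import annotations

from dataclasses import dataclass

from .sdt import CountPair, corrected_rate, dprime_c

__all__ = ["PairCounts", "PDPIndices", "pdp_indices"]


@dataclass(frozen=True)
class PairCounts:
    """'Yes' counts for the three pair classes of the associative task."""

    intact_yes: CountPair
    recombined_yes: CountPair
    new_yes: CountPair


@dataclass(frozen=True)
class PDPIndices:
    p_included: float
    p_excluded: float
    R_pdp: float
    F_pdp: float  # nan when R_pdp == 1 (only reachable with correction off)
    d_prime: float
    criterion_c: float


def pdp_indices(
    counts: PairCounts,
    correct_rates: bool = True,
    fa_class: str = "new",
) -> PDPIndices:
    """Recollection and familiarity via the process-dissociation equations.

    With ``correct_rates`` on (default) every rate passes through the
    Snodgrass-Corwin correction, which keeps R strictly below 1 and F inside
    (0, 1). ``fa_class`` selects the false-alarm class for the task's d'/c:
    ``"new"`` (pure old/new discrimination, default) or ``"pooled"``
    (new + recombined pairs).
    """
    if fa_class not in ("new", "pooled"):
        raise ValueError("fa_class must be 'new' or 'pooled'")

    def rate(pair: CountPair) -> float:
        return corrected_rate(pair) if correct_rates else pair.successes / pair.trials

    p_inc = rate(counts.intact_yes)
    p_exc = rate(counts.recombined_yes)
    R = p_inc - p_exc
    F = p_exc / (1.0 - R) if R < 1.0 else float("nan")

    if fa_class == "new":
        fas = counts.new_yes
    else:
        fas = CountPair(
            counts.new_yes.successes + counts.recombined_yes.successes,
            counts.new_yes.trials + counts.recombined_yes.trials,
        )
    sdt = dprime_c(counts.intact_yes, fas)
    return PDPIndices(
        p_included=p_inc,
        p_excluded=p_exc,
        R_pdp=R,
        F_pdp=F,
        d_prime=sdt.d_prime,
        criterion_c=sdt.criterion_c,
    )
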