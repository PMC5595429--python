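"""Recollection and familiarity from Remember/Know/Guess attributions.

Remember (R) responses index recollection; Know (K) and Guess (G)
responses are old decisions without retrieved context and are treated as
familiarity-driven. The default estimator follows the independence
Remember-Know logic: recollection is the corrected Remember-rate
difference between targets and distractors, and familiarity is estimated
from non-Remember yes rates conditioned on recollection failure,

    R_rkg = P*(R | old) - P*(R | new)
    F_old = P*(K or G yes | old) / (1 - P*(R | old))      (same for new)
    F_rkg = z(F_old) - z(F_new)

where P* is the Snodgrass-Corwin corrected rate over the item-class total.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .sdt import CountPair, corrected_rate, dprime_c

__all__ = ["RKGCounts", "RKGIndices", "rkg_indices"]


@dataclass(frozen=True)
class RKGCounts:
    """Attribution counts for targets (old_*) and distractors (new_*)."""

    old_R: int
    old_K: int
    old_G: int
    old_no: int
    new_R: int
    new_K: int
    new_G: int
    new_no: int

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_old == 0 or self.n_new == 0:
            raise ValueError("each item class needs at least one trial")

    @property
    def n_old(self) -> int:
        return self.old_R + self.old_K + self.old_G + self.old_no

    @property
    def n_new(self) -> int:
        return self.new_R + self.new_K + self.new_G + self.new_no


@dataclass(frozen=True)
class RKGIndices:
    R_rkg: float
    F_rkg: float
    d_prime: float
    criterion_c: float
    yes_rate_old: float
    yes_rate_new: float
    r_rate_old: float
    r_rate_new: float


def rkg_indices(
    counts: RKGCounts,
    variant: str = "irk",
    drop_guesses: bool = False,
) -> RKGIndices:
    """Compute R and F indices from Remember/Know/Guess counts.

    ``variant="irk"`` (default) is the independence estimator described in
    the module docstring. ``variant="literal"`` instead multiplies the
    corrected yes-rate difference by the proportion of target yes responses
    attributed to Remember. ``drop_guesses`` removes G trials from the
    denominators entirely rather than counting them as familiarity yeses.
    """
    if variant not in ("irk", "literal"):
        raise ValueError("variant must be 'irk' or 'literal'")

    old_g, new_g = counts.old_G, counts.new_G
    n_old, n_new = counts.n_old, counts.n_new
    if drop_guesses:
        n_old -= old_g
        n_new -= new_g
        old_g = new_g = 0
        if n_old == 0 or n_new == 0:
            raise ValueError("dropping guesses emptied an item class")

    yes_old = CountPair(counts.old_R + counts.old_K + old_g, n_old)
    yes_new = CountPair(counts.new_R + counts.new_K + new_g, n_new)
    sdt = dprime_c(yes_old, yes_new)

    p_r_old = corrected_rate(CountPair(counts.old_R, n_old))
    p_r_new = corrected_rate(CountPair(counts.new_R, n_new))

    if variant == "irk":
        R = p_r_old - p_r_new
    else:
        p_r_given_yes = counts.old_R / max(yes_old.successes, 1)
        R = (sdt.hit_rate - sdt.fa_rate) * p_r_given_yes

    # familiarity operates on trials where recollection failed
    f_old = corrected_rate(CountPair(counts.old_K + old_g, n_old)) / (1.0 - p_r_old)
    f_new = corrected_rate(CountPair(counts.new_K + new_g, n_new)) / (1.0 - p_r_new)
    # the ratio can touch 1 when every non-Remember trial is a familiarity
    # yes; clamp back into the open interval the correction guarantees
    lo_old, lo_new = 0.5 / (n_old + 1), 0.5 / (n_new + 1)
    f_old = min(max(f_old, lo_old), 1.0 - lo_old)
    f_new = min(max(f_new, lo_new), 1.0 - lo_new)
    F = float(norm.ppf(f_old) - norm.ppf(f_new))

    return RKGIndices(
        R_rkg=R,
        F_rkg=F,
        d_prime=sdt.d_prime,
        criterion_c=sdt.criterion_c,
        yes_rate_old=sdt.hit_rate,
        yes_rate_new=sdt.fa_rate,
        r_rate_old=p_r_old,
        r_rate_new=p_r_new,
    )
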