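"""Equal-variance signal-detection primitives shared by all three tasks.

Hit and false-alarm proportions are corrected with the Snodgrass-Corwin
rule (x + 0.5) / (n + 1) before any quantile transform, which keeps every
rate strictly inside (0, 1) and the z-transforms finite even for empty or
perfect response counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["CountPair", "SDTIndices", "corrected_rate", "dprime_c", "indices_from_rates"]


@dataclass(frozen=True)
class CountPair:
    """A success count out of a fixed number of trials."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials <= 0:
            raise ValueError(f"trials must be positive, got {self.trials}")
        if not 0 <= self.successes <= self.trials:
            raise ValueError(
                f"successes must lie in [0, trials], got {self.successes}/{self.trials}"
            )


@dataclass(frozen=True)
class SDTIndices:
    """Corrected rates plus discrimination d' and response criterion c.

    d' = z(H) - z(F);  c = -(z(H) + z(F)) / 2, with z the standard-normal
    quantile function. Negative c is a liberal bias, positive conservative.
    """

    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion_c: float


def _as_pair(counts: CountPair | tuple[int, int]) -> CountPair:
    if isinstance(counts, CountPair):
        return counts
    return CountPair(*counts)


def corrected_rate(counts: CountPair | tuple[int, int]) -> float:
    """Snodgrass-Corwin corrected proportion (x + 0.5) / (n + 1).

    Strictly increasing in the success count and bounded away from 0 and 1.
    """
    pair = _as_pair(counts)
    return (pair.successes + 0.5) / (pair.trials + 1)


def indices_from_rates(hit_rate: float, fa_rate: float) -> SDTIndices:
    """d' and c from already-corrected rates strictly inside (0, 1)."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must lie strictly inside (0, 1); correct counts first")
    zh = norm.ppf(hit_rate)
    zf = norm.ppf(fa_rate)
    return SDTIndices(
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        d_prime=zh - zf,
        criterion_c=-0.5 * (zh + zf),
    )


def dprime_c(
    hits: CountPair | tuple[int, int], fas: CountPair | tuple[int, int]
) -> SDTIndices:
    """Discrimination d' and criterion c from hit and false-alarm counts.

    Both counts pass through :func:`corrected_rate` first, so the result is
    defined for floor (0/n) and ceiling (n/n) performance.
    """
    return indices_from_rates(corrected_rate(hits), corrected_rate(fas))
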