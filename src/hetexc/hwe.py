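"""Exact Hardy-Weinberg test with mid-P correction.

The test is conditional on the observed allele counts: given ``n`` diploid
individuals carrying ``m`` copies of the minor allele, the number of
heterozygotes under Hardy-Weinberg equilibrium (random union of alleles)
follows the exact distribution

    P(n_het | n, m)  ∝  n! / (n_hom_ref! n_het! n_hom_alt!) · 2**n_het

over the feasible heterozygote counts (same parity as ``m``).  The
two-sided P value sums the probabilities of all outcomes no more probable
than the observed one; the mid-P variant counts only half of the observed
outcome's probability, which makes the discrete test less conservative and
better calibrated for rare variants.

The distribution is evaluated with a ratio recurrence anchored at the mode,
so every intermediate value lies in (0, 1] and the computation is stable up
to population-scale samples (n of several million).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, UndefinedRatioError, UntestableSiteError

__all__ = [
    "GenotypeCounts",
    "HWETestResult",
    "HetDistribution",
    "DetectabilityResult",
    "conditional_het_distribution",
    "hwe_exact_midp",
    "expected_het_given_hom",
    "het_fold_excess",
    "min_detectable_het_af",
]

#: Relative tolerance used when deciding whether an outcome is "no more
#: probable" than the observed one (two-sided tail construction).
_TAIL_RTOL = 1e-12


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts of one biallelic variant in one population."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    def __post_init__(self) -> None:
        for name in ("n_hom_ref", "n_het", "n_hom_alt"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidInputError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise InvalidInputError("at least one genotyped individual is required")

    @property
    def n(self) -> int:
        """Number of genotyped individuals."""
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def alt_allele_count(self) -> int:
        return 2 * self.n_hom_alt + self.n_het

    @property
    def minor_allele_count(self) -> int:
        return min(self.alt_allele_count, 2 * self.n_hom_ref + self.n_het)

    @property
    def alt_af(self) -> float:
        """Alternate allele frequency q = (2·hom_alt + het) / (2n)."""
        return self.alt_allele_count / (2 * self.n)

    def expected_het(self) -> float:
        """Expected heterozygotes 2·p·q·n at the sample allele frequencies."""
        q = self.alt_af
        return 2.0 * q * (1.0 - q) * self.n


@dataclass(frozen=True)
class HWETestResult:
    """Outcome of the exact HWE test on one genotype sample."""

    mid_p: float
    p_two_sided: float
    observed_het: int
    expected_het_uncond: float
    direction: str  # "excess" | "deficit" | "none"
    significant: bool
    alpha: float


@dataclass(frozen=True)
class HetDistribution:
    """Exact conditional null distribution of the heterozygote count.

    ``log_probabilities`` carry the same distribution in natural-log space;
    they stay finite far into the tails where the linear probabilities
    underflow to zero.
    """

    n: int
    m: int
    support: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)
    log_probabilities: np.ndarray = field(repr=False)

    def _index(self, n_het: int) -> int | None:
        if n_het < self.support[0] or n_het > self.support[-1] or (n_het - self.m) % 2 != 0:
            return None
        return (n_het - int(self.support[0])) // 2

    def pmf(self, n_het: int) -> float:
        """Probability of observing exactly ``n_het`` heterozygotes."""
        i = self._index(n_het)
        return 0.0 if i is None else float(self.probabilities[i])

    def log_pmf(self, n_het: int) -> float:
        i = self._index(n_het)
        return -math.inf if i is None else float(self.log_probabilities[i])

    @property
    def mode(self) -> int:
        return int(self.support[int(np.argmax(self.probabilities))])


@dataclass(frozen=True)
class DetectabilityResult:
    """Smallest all-heterozygote carrier count (and allele frequency) at
    which heterozygote excess reaches significance in a sample of ``n``."""

    n: int
    alpha: float
    min_het_count: int | None
    min_af: float

    @property
    def detectable(self) -> bool:
        return self.min_het_count is not None


def conditional_het_distribution(n: int, m: int) -> HetDistribution:
    """Exact distribution of the heterozygote count given ``n`` individuals
    and ``m`` minor alleles under Hardy-Weinberg equilibrium.

    Parameters
    ----------
    n
        Number of diploid individuals (> 0).
    m
        Minor allele count; must satisfy ``0 <= m <= n`` (i.e. the caller
        passes the *minor* allele, so ``m <= 2n - m``).

    Returns
    -------
    HetDistribution
        Support (heterozygote counts with the parity of ``m``) and their
        probabilities, normalised to sum to one.
    """
    if n <= 0:
        raise InvalidInputError("n must be a positive number of individuals")
    if m < 0 or m > n:
        raise InvalidInputError(
            f"m={m} is not a minor allele count for n={n} (need 0 <= m <= n)"
        )
    het_min = m % 2
    support = np.arange(het_min, m + 1, 2, dtype=np.int64)
    if len(support) == 1:
        return HetDistribution(
            n=n, m=m, support=support,
            probabilities=np.array([1.0]), log_probabilities=np.array([0.0]),
        )

    # Ratio between adjacent support points:
    #   P(h+2)/P(h) = 4 * hom_ref(h) * hom_alt(h) / ((h+1)(h+2))
    # with hom_alt(h) = (m-h)/2 and hom_ref(h) = n - h - hom_alt(h).
    def _step_up(h: int) -> float:
        hom_alt = (m - h) // 2
        hom_ref = n - h - hom_alt
        return 4.0 * hom_ref * hom_alt / ((h + 1.0) * (h + 2.0))

    # Walk up from the smallest support point to locate the mode (ratios
    # are monotone decreasing, so the mode is where the ratio crosses 1).
    mode_idx = 0
    for i, h in enumerate(support[:-1]):
        if _step_up(int(h)) < 1.0:
            break
        mode_idx = i + 1

    # Log-ratio sweep anchored at the mode: every relative value lies in
    # (0, 1], so nothing can overflow, and the log form stays finite even
    # where the linear probabilities underflow deep in the tails.
    log_ratio = np.array([math.log(_step_up(int(h))) for h in support[:-1]])
    log_rel = np.zeros(len(support))
    log_rel[mode_idx + 1:] = np.cumsum(log_ratio[mode_idx:])
    log_rel[:mode_idx] = -np.cumsum(log_ratio[:mode_idx][::-1])[::-1]
    log_norm = float(np.log(np.exp(log_rel - log_rel.max()).sum()) + log_rel.max())
    log_probs = log_rel - log_norm
    probs = np.exp(log_probs)
    return HetDistribution(
        n=n, m=m, support=support, probabilities=probs, log_probabilities=log_probs,
    )


def hwe_exact_midp(counts: GenotypeCounts, alpha: float = 0.05) -> HWETestResult:
    """Exact HWE test with the mid-P modification.

    The two-sided P value sums P(h) over every heterozygote count ``h``
    whose null probability does not exceed that of the observed count
    (within relative tolerance 1e-12); ``mid_p`` subtracts half of the
    observed outcome's probability from that sum.

    Raises
    ------
    UntestableSiteError
        If the site is monomorphic (zero minor alleles).
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")
    m = counts.minor_allele_count
    if m == 0:
        raise UntestableSiteError(
            "monomorphic site: the exact HWE test is undefined without minor alleles"
        )
    dist = conditional_het_distribution(counts.n, m)
    if dist._index(counts.n_het) is None:
        raise InvalidInputError(
            f"observed het count {counts.n_het} is outside the feasible support for "
            f"n={counts.n}, m={m}"
        )
    # Tail construction in log space: an outcome belongs to the two-sided
    # tail iff its null probability is <= the observed one (relative
    # tolerance 1e-12, i.e. additive ~1e-12 in log space).
    log_p_obs = dist.log_pmf(counts.n_het)
    in_tail = dist.log_probabilities <= log_p_obs + _TAIL_RTOL
    tail_logs = dist.log_probabilities[in_tail]
    shift = tail_logs.max()
    log_p_two = float(np.log(np.exp(tail_logs - shift).sum()) + shift)
    p_obs = math.exp(log_p_obs)
    p_two = min(math.exp(log_p_two), 1.0)
    mid_p = p_two - 0.5 * p_obs
    # Guard representability at the floating-point floor: the true mid-P is
    # strictly positive and strictly below the two-sided P, so keep both
    # properties when exp() underflows or the subtraction rounds away.
    if p_two <= 0.0:
        p_two = 5e-324 * 4
    if mid_p >= p_two:
        mid_p = math.nextafter(p_two, 0.0)
    if mid_p <= 0.0:
        mid_p = math.nextafter(0.0, 1.0)

    expected = counts.expected_het()
    if counts.n_het > expected:
        direction = "excess"
    elif counts.n_het < expected:
        direction = "deficit"
    else:
        direction = "none"
    return HWETestResult(
        mid_p=mid_p,
        p_two_sided=p_two,
        observed_het=counts.n_het,
        expected_het_uncond=expected,
        direction=direction,
        significant=mid_p <= alpha,
        alpha=alpha,
    )


def expected_het_given_hom(n: int, n_hom_alt: int) -> float:
    """Expected heterozygote count implied by the homozygote count alone.

    The homozygote frequency estimates q̂ = sqrt(n_hom_alt / n); under HWE
    the heterozygote count is then 2·q̂·(1−q̂)·n.  This is the comparison
    used to quantify how many more carriers a variant has than its
    homozygote count would predict.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if not 0 <= n_hom_alt <= n:
        raise InvalidInputError(f"n_hom_alt={n_hom_alt} must lie in [0, n={n}]")
    q_hat = math.sqrt(n_hom_alt / n)
    return 2.0 * q_hat * (1.0 - q_hat) * n


def het_fold_excess(observed_het: int, expected_het: float) -> float:
    """Ratio of observed to expected heterozygote counts."""
    if expected_het < 0:
        raise InvalidInputError("expected_het must be non-negative")
    if expected_het == 0:
        if observed_het == 0:
            raise UndefinedRatioError("0 observed / 0 expected heterozygotes")
        return math.inf
    return observed_het / expected_het


def _all_het_midp(n: int, h: int, alpha: float) -> float:
    return hwe_exact_midp(GenotypeCounts(n - h, h, 0), alpha=alpha).mid_p


def min_detectable_het_af(n: int, alpha: float = 0.05) -> DetectabilityResult:
    """Minimum allele frequency at which heterozygote excess is detectable.

    Finds the smallest carrier count ``h`` such that a sample of ``n``
    individuals with ``h`` heterozygotes and zero homozygotes yields
    mid-P <= ``alpha`` — i.e. every minor allele is assumed to be carried
    heterozygously.  The allele frequency is ``h / (2n)``.

    The search bisects on ``h`` and then confirms the bracket by stepping
    ±1, since mid-P is not guaranteed to be globally monotone in ``h``.
    """
    if n < 2:
        raise InvalidInputError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha}")

    if _all_het_midp(n, n, alpha) > alpha:
        return DetectabilityResult(n=n, alpha=alpha, min_het_count=None, min_af=math.nan)
    if _all_het_midp(n, 1, alpha) <= alpha:
        return DetectabilityResult(n=n, alpha=alpha, min_het_count=1, min_af=1.0 / (2 * n))

    lo, hi = 1, n  # midp(lo) > alpha, midp(hi) <= alpha
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _all_het_midp(n, mid, alpha) <= alpha:
            hi = mid
        else:
            lo = mid
    # Local verification of the bracket.  Mid-P is not exactly monotone in
    # h: with zero homozygotes the support parity follows h, so adjacent
    # odd/even counts live on different lattices and the P value can dip
    # below alpha two steps before the bisection bracket.  Scan a ±2
    # window until neither neighbour below is significant.
    while hi < n and _all_het_midp(n, hi, alpha) > alpha:
        hi += 1
    moved = True
    while moved and hi > 1:
        moved = False
        for step in (1, 2):
            if hi - step >= 1 and _all_het_midp(n, hi - step, alpha) <= alpha:
                hi -= step
                moved = True
                break
    return DetectabilityResult(n=n, alpha=alpha, min_het_count=hi, min_af=hi / (2 * n))
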