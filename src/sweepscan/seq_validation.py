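"""Allele-frequency estimates with finite-sample confidence intervals.

The readout for a handful of re-sequenced individuals: estimate the
frequency of one allele from diploid genotype counts at a biallelic locus
and attach a binomial sampling interval over the 2n sampled chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts at one biallelic locus (alleles A and B)."""

    n_AA: int
    n_AB: int
    n_BB: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_AB, self.n_BB) < 0:
            raise ValueError("negative genotype count")
        if self.n == 0:
            raise ValueError("need at least one genotyped individual")

    @property
    def n(self) -> int:
        return self.n_AA + self.n_AB + self.n_BB


def allele_frequency(counts: GenotypeCounts, allele: str = "B") -> float:
    """Sample frequency of one allele: (2 * homozygotes + heterozygotes) / 2n."""
    if allele == "B":
        return (2 * counts.n_BB + counts.n_AB) / (2 * counts.n)
    if allele == "A":
        return (2 * counts.n_AA + counts.n_AB) / (2 * counts.n)
    raise ValueError(f"allele must be 'A' or 'B', got {allele!r}")


def binomial_ci(
    p: float, n_chromosomes: int, level: float = 0.68
) -> tuple[float, float, float]:
    """Normal-approximation binomial interval p +/- z * sqrt(p(1-p)/2n).

    For the conventional 68% level z = 1 exactly (one standard error).
    Returns (half_width, lower, upper) with bounds clipped to [0, 1].
    """
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    z = 1.0 if level == 0.68 else float(stats.norm.ppf((1 + level) / 2))
    half = z * (p * (1 - p) / n_chromosomes) ** 0.5
    return half, max(0.0, p - half), min(1.0, p + half)
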