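"""Corrected somatic-hypermutation rates and simulation rate tiers.

Mutations can only be counted on positions covered by a germline V/J
reference; the CDR3/junction interval has no aligned reference, so the
denominator excludes it. Without this correction the per-nucleotide
mutation rate would be systematically underestimated.

The corrected-rate distribution over a curated antibody set is reduced
to a low and a high rate tier plus mixture proportions, which
parameterize the repertoire simulator: the bundled defaults are a low
rate of 5.1% and a high rate of 11.9%, mixed as 50% unmutated / 36% low
/ 14% high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .backtranslation import BacktranslationResult

__all__ = ["ShmProfile", "RateTiers", "corrected_shm_rate", "profile_from_backtranslation", "derive_rate_tiers"]

DEFAULT_LOW_RATE = 0.051
DEFAULT_HIGH_RATE = 0.119
DEFAULT_MIXTURE = (0.50, 0.36, 0.14)  # (no SHM, low, high)


@dataclass(frozen=True)
class ShmProfile:
    """Per-antibody mutation count over reference-covered nucleotides."""

    antibody_id: str
    n_mutations: int
    covered_len: int
    total_len: int

    def __post_init__(self):
        if not (0 <= self.n_mutations <= self.covered_len <= self.total_len):
            raise ValueError(
                f"{self.antibody_id}: need 0 <= n_mutations <= covered_len <= total_len, "
                f"got {self.n_mutations}/{self.covered_len}/{self.total_len}"
            )

    @property
    def corrected_rate(self) -> float:
        return corrected_shm_rate(self.n_mutations, self.covered_len)


@dataclass(frozen=True)
class RateTiers:
    """Low/high SHM rates and the mixture over (none, low, high)."""

    low_rate: float = DEFAULT_LOW_RATE
    high_rate: float = DEFAULT_HIGH_RATE
    mixture: tuple[float, float, float] = DEFAULT_MIXTURE

    def __post_init__(self):
        if not (0.0 <= self.low_rate < self.high_rate < 1.0):
            raise ValueError(f"need 0 <= low < high < 1, got {self.low_rate}, {self.high_rate}")
        if abs(sum(self.mixture) - 1.0) > 1e-9 or any(p < 0 for p in self.mixture):
            raise ValueError(f"mixture {self.mixture} must be non-negative and sum to 1")

    @property
    def rates(self) -> tuple[float, float, float]:
        return (0.0, self.low_rate, self.high_rate)


def corrected_shm_rate(n_mutations: int, covered_len: int) -> float:
    """Mutations per reference-covered nucleotide (junction excluded)."""
    if covered_len <= 0:
        raise ValueError("covered_len must be positive")
    if not (0 <= n_mutations <= covered_len):
        raise ValueError(f"n_mutations {n_mutations} outside [0, {covered_len}]")
    return n_mutations / covered_len


def profile_from_backtranslation(result: BacktranslationResult) -> ShmProfile:
    """Mutation profile implied by a backtranslation: substitutions vs
    the chosen references over the covered positions."""
    return ShmProfile(
        antibody_id=result.record.antibody_id,
        n_mutations=result.n_substitutions,
        covered_len=result.covered_nt,
        total_len=3 * len(result.record.heavy_aa),
    )


def derive_rate_tiers(
    profiles: Sequence[ShmProfile],
    mixture: tuple[float, float, float] | None = None,
    method: str = "median",
) -> RateTiers:
    """Reduce observed corrected rates to (low, high) tiers.

    method="median": split the nonzero rates at their median; the low
    tier is the mean of rates at/below the split, the high tier the
    mean above. method="variance": place the split between consecutive
    sorted rates so total within-group variance is minimal (robust when
    the low/high groups are unbalanced). With no profiles (or no
    nonzero rates) the bundled default tiers are returned with a
    warning.
    """
    if method not in ("median", "variance"):
        raise ValueError("method must be 'median' or 'variance'")
    mixture = mixture or DEFAULT_MIXTURE
    rates = np.array([p.corrected_rate for p in profiles], dtype=float)
    nonzero = np.sort(rates[rates > 0])
    if nonzero.size < 2:
        if profiles:
            warnings.warn("fewer than 2 nonzero SHM rates; falling back to default tiers")
        return RateTiers(mixture=mixture)
    if method == "median":
        split = float(np.median(nonzero))
        low_vals = nonzero[nonzero <= split]
        high_vals = nonzero[nonzero > split]
    else:
        best = None
        for k in range(1, nonzero.size):
            lo, hi = nonzero[:k], nonzero[k:]
            ssw = float(((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum())
            if best is None or ssw < best[0]:
                best = (ssw, k)
        low_vals, high_vals = nonzero[: best[1]], nonzero[best[1] :]
    if high_vals.size == 0:  # all nonzero rates identical
        warnings.warn("degenerate SHM rate distribution; falling back to default tiers")
        return RateTiers(mixture=mixture)
    low, high = float(low_vals.mean()), float(high_vals.mean())
    if not low < high:
        warnings.warn("degenerate SHM rate distribution; falling back to default tiers")
        return RateTiers(mixture=mixture)
    return RateTiers(low_rate=low, high_rate=high, mixture=mixture)
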