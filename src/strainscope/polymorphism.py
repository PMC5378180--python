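"""Secondary-strain detection via a per-site binomial test.

Under the single-strain null, every read covering a site carries the
dominant allele except for sequencing error at rate E.  With N_s reads at
the site and T_s of them supporting the dominant (most abundant) allele,
the p-value is P(X <= T_s) for X ~ Binomial(N_s, 1 - E): a surprisingly
low dominant-allele count is evidence for a second allele, i.e. a second
strain.  Sites with p < alpha are polymorphic; the species-level summary
reports the fraction of tested sites flagged and the median
dominant-allele frequency over flagged sites (the median guards against
alleles shared by several nondominant strains inflating single-site
frequencies).

No multiple-testing correction is applied across sites by default, which
mirrors how the per-site test is meant to be read (a per-site error rate,
not a family-wise one); Benjamini-Hochberg is available via ``site_fdr``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .ingest import Pileup

__all__ = [
    "SiteTest",
    "SpeciesPolymorphism",
    "site_pvalues",
    "test_site",
    "species_polymorphism",
    "flag_polymorphic_species",
]


@dataclass
class SiteTest:
    """Binomial test result for one covered site."""

    n_total: int  # N_s: quality-passing reads covering the site
    t_dominant: int  # T_s: reads supporting the dominant allele
    p_value: float
    polymorphic: bool
    marker_id: Optional[str] = None
    position: Optional[int] = None

    @property
    def dominant_allele_freq(self) -> float:
        return self.t_dominant / self.n_total


@dataclass
class SpeciesPolymorphism:
    """Species-level polymorphism summary for one sample."""

    sample_id: str
    species: str
    n_sites_tested: int
    polymorphic_rate: float
    dominant_strain_freq: float  # 1.0 when no site is polymorphic


def site_pvalues(
    n_total: np.ndarray, t_dominant: np.ndarray, error_rate: float = 0.01
) -> np.ndarray:
    """Vectorized binomial CDF p-values P(X <= T_s), X ~ B(N_s, 1 - E)."""
    if not 0 < error_rate < 1:
        raise ValueError("error_rate must be in (0, 1)")
    n = np.asarray(n_total)
    t = np.asarray(t_dominant)
    if np.any(t > n) or np.any(t < 0):
        raise ValueError("require 0 <= T_s <= N_s")
    return stats.binom.cdf(t, n, 1.0 - error_rate)


def test_site(
    n_total: int,
    t_dominant: int,
    error_rate: float = 0.01,
    alpha: float = 0.05,
    marker_id: Optional[str] = None,
    position: Optional[int] = None,
) -> SiteTest:
    """Test one site for polymorphism; N_s = 0 is untestable."""
    if n_total <= 0:
        raise ValueError("site with N_s = 0 is untestable")
    p = float(site_pvalues(np.array([n_total]), np.array([t_dominant]), error_rate)[0])
    return SiteTest(
        n_total=n_total,
        t_dominant=t_dominant,
        p_value=p,
        polymorphic=p < alpha,
        marker_id=marker_id,
        position=position,
    )


def species_polymorphism(
    pileups: Iterable[Pileup],
    sample_id: str = "",
    species: str = "",
    error_rate: float = 0.01,
    alpha: float = 0.05,
    site_fdr: bool = False,
) -> SpeciesPolymorphism:
    """Pool every covered site across the species' markers and test each.

    Sites with no quality-passing coverage are excluded from both the
    numerator and the denominator of the polymorphic rate.
    """
    n_parts: list[np.ndarray] = []
    t_parts: list[np.ndarray] = []
    for pileup in pileups:
        depth = pileup.depth
        covered = depth >= 1
        if not covered.any():
            continue
        n_parts.append(depth[covered])
        t_parts.append(pileup.counts.max(axis=0)[covered])
    if not n_parts:
        raise ValueError(f"species {species!r} not testable: no covered sites")
    n = np.concatenate(n_parts)
    t = np.concatenate(t_parts)
    p = site_pvalues(n, t, error_rate)
    if site_fdr:
        flagged = _benjamini_hochberg(p, alpha)
    else:
        flagged = p < alpha
    n_tested = int(n.size)
    rate = float(flagged.sum()) / n_tested
    if flagged.any():
        freq = float(np.median(t[flagged] / n[flagged]))
    else:
        freq = 1.0
    return SpeciesPolymorphism(
        sample_id=sample_id,
        species=species,
        n_sites_tested=n_tested,
        polymorphic_rate=rate,
        dominant_strain_freq=freq,
    )


def _benjamini_hochberg(p: np.ndarray, alpha: float) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    below = ranked <= alpha * (np.arange(1, m + 1) / m)
    flagged = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.nonzero(below)[0].max())
        flagged[order[: k + 1]] = True
    return flagged


def flag_polymorphic_species(
    rates: Mapping[str, float] | Sequence[float],
) -> set:
    """Flag samples whose polymorphic rate exceeds median + sample SD.

    Accepts a mapping sample -> rate (returns flagged sample ids) or a bare
    sequence of rates (returns flagged indices).  Fewer than two samples
    cannot define a spread: empty set with a warning.
    """
    if isinstance(rates, Mapping):
        keys = list(rates.keys())
        values = np.asarray([rates[k] for k in keys], dtype=float)
    else:
        keys = list(range(len(rates)))
        values = np.asarray(rates, dtype=float)
    if values.size < 2:
        warnings.warn("need >= 2 samples to flag polymorphic species", stacklevel=2)
        return set()
    threshold = float(np.median(values)) + float(np.std(values, ddof=1))
    return {k for k, v in zip(keys, values) if v > threshold}
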