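"""Benchmark routines that measure the pipeline's accuracy on synthetic data.

These reproduce the method's validation design at desk scale: reconstruct a
known strain from simulated reads and count per-nucleotide consensus
errors, with and without an unrelated background community, and measure the
empirical type-I error of the polymorphic-site test when the assumed
sequencing error rate matches the truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .consensus import StrainProfile, qc_cascade
from .ingest import build_pileups, naive_map
from .markerdb import MarkerDB
from .polymorphism import site_pvalues
from .simulate import SimConfig, make_marker_db, mutate_strain, simulate_reads, spike_background

__all__ = [
    "consensus_error_pct",
    "synthetic_benchmark",
    "semisynthetic_benchmark",
    "polymorphism_calibration",
]

#: validation conditions: 100 markers of ~1 kb, mean 5x coverage, 150 nt
#: reads, 1% substitution error with two-point qualities (38 correct / 15
#: erroneous), strain divergence 0.45% from the database markers
BENCHMARK_CONFIG = SimConfig(
    n_markers=100,
    marker_length_range=(900, 1100),
    coverage=5.0,
    read_length=150,
    error_rate=0.01,
    q_correct=38,
    q_error=15,
    strain_snv_rate=0.0045,
)


def consensus_error_pct(
    profile: StrainProfile, truth: dict[str, str], strip: int = 50
) -> tuple[float, int]:
    """Percent mismatching nucleotides over all reconstructed (non-N)
    positions, against the true strain sequences."""
    errors = compared = 0
    for mid, cm in profile.markers.items():
        ref = truth[mid][strip:-strip] if strip else truth[mid]
        for a, b in zip(cm.sequence, ref):
            if a != "N":
                compared += 1
                errors += a != b
    if compared == 0:
        raise ValueError("no reconstructed positions to compare")
    return 100.0 * errors / compared, compared


def _simulate_target(seed: int, cfg: SimConfig):
    cfg = replace(cfg, seed=seed)
    db, truth = make_marker_db(cfg)
    strain, _ = mutate_strain(truth.strains["base"], cfg.strain_snv_rate, seed + 1)
    reads, _ = simulate_reads(strain, cfg, seed + 2, strain_name="target")
    return db, strain, reads, cfg


def _profile_reads(reads, db: MarkerDB, cfg: SimConfig) -> StrainProfile:
    piles = build_pileups(naive_map(reads, db), db, min_base_quality=30)
    species = next(iter(db)).species
    profile = qc_cascade(piles, species, "benchmark", markers_in_db=len(db))
    if profile is None:
        raise RuntimeError("benchmark strain failed the species gate")
    return profile


def synthetic_benchmark(
    seed: int, cfg: SimConfig = BENCHMARK_CONFIG
) -> tuple[float, int]:
    """Per-nucleotide consensus error (%) on a fully synthetic sample."""
    db, strain, reads, cfg = _simulate_target(seed, cfg)
    profile = _profile_reads(reads, db, cfg)
    return consensus_error_pct(profile, strain)


def semisynthetic_benchmark(
    seed: int,
    cfg: SimConfig = BENCHMARK_CONFIG,
    background_ratio: float = 10.0,
) -> tuple[float, int]:
    """Consensus error (%) when target reads are spiked into a background
    community with ``background_ratio`` background reads per target read."""
    db, strain, reads, cfg = _simulate_target(seed, cfg)
    combined = spike_background(
        reads, db, cfg, seed + 3, background_ratio=background_ratio
    )
    profile = _profile_reads(combined, db, cfg)
    return consensus_error_pct(profile, strain)


def polymorphism_calibration(
    seed: int,
    depths: tuple[int, ...] = (10, 20, 50, 100, 200),
    sites_per_depth: int = 100_000,
    error_rate: float = 0.01,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Empirical per-site rejection rate on single-strain data whose true
    error rate equals the test's assumed one.  Returns (fraction, n_sites).
    """
    rng = np.random.default_rng(seed)
    rejected = total = 0
    for depth in depths:
        errors = rng.binomial(depth, error_rate, size=sites_per_depth)
        # at these depths errors can never out-count the true allele, so the
        # dominant-allele support is exactly depth - errors
        t_dom = depth - errors
        p = site_pvalues(np.full(sites_per_depth, depth), t_dom, error_rate)
        rejected += int((p < alpha).sum())
        total += sites_per_depth
    return rejected / total, total
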