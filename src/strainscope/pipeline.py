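"""End-to-end orchestration: reads/alignments -> profiles -> trees -> reports.

Species are processed independently; a run is fully determined by its
:class:`RunConfig` (thresholds + seed), which is serialized verbatim into
the run manifest so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .consensus import StrainProfile, qc_cascade
from .ingest import Read, build_pileups, naive_map, parse_sam
from .io import (
    write_polymorphism_report,
    write_profile,
    write_retention_report,
    write_subclade_report,
)
from .markerdb import MarkerDB
from .msa import build_species_alignment
from .phylogeny import build_tree, export_alignment, snv_distance
from .polymorphism import SpeciesPolymorphism, species_polymorphism
from .popstructure import (
    call_retention,
    country_subtrees,
    detect_subclades,
    normalize_distances,
    ordination,
)

logger = logging.getLogger("strainscope")

__all__ = ["RunConfig", "SampleResult", "profile_sample_reads", "profile_sample_sam", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds, with their standard defaults."""

    min_base_quality: int = 30
    min_depth: int = 1
    marker_strip_length: int = 50
    max_ambiguous_fraction: float = 0.20
    min_marker_fraction: float = 0.80
    gap_in_trailing_col: float = 0.20
    gap_in_internal_col: float = 0.30
    n_col: float = 0.80
    long_gap_percentage: float = 0.80
    gap_in_sample: float = 0.20
    error_rate: float = 0.01
    alpha: float = 0.05
    max_intra_snv: float = 0.001
    country_min_fraction: float = 0.80
    country_min_size: int = 5
    min_strains_per_species: int = 4
    seed_k: int = 15
    seed: int = 42

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SampleResult:
    """Per-sample outcome: QC-passed profiles and polymorphism summaries."""

    sample_id: str
    profiles: dict[str, StrainProfile]  # species -> profile
    polymorphism: dict[str, SpeciesPolymorphism]


def _profile_from_pileups(
    pileups, db: MarkerDB, sample_id: str, cfg: RunConfig
) -> SampleResult:
    by_species: dict[str, dict] = {}
    for mid, pile in pileups.items():
        by_species.setdefault(db[mid].species, {})[mid] = pile
    profiles: dict[str, StrainProfile] = {}
    polymorphism: dict[str, SpeciesPolymorphism] = {}
    for species, sp_piles in sorted(by_species.items()):
        profile = qc_cascade(
            sp_piles,
            species=species,
            sample_id=sample_id,
            markers_in_db=db.n_markers(species),
            min_depth=cfg.min_depth,
            strip_length=cfg.marker_strip_length,
            max_ambiguous_fraction=cfg.max_ambiguous_fraction,
            min_marker_fraction=cfg.min_marker_fraction,
        )
        if profile is None:
            logger.info("sample %s: species %s below marker gate", sample_id, species)
            continue
        profiles[species] = profile
        polymorphism[species] = species_polymorphism(
            sp_piles.values(),
            sample_id=sample_id,
            species=species,
            error_rate=cfg.error_rate,
            alpha=cfg.alpha,
        )
    return SampleResult(sample_id=sample_id, profiles=profiles, polymorphism=polymorphism)


def profile_sample_reads(
    reads: Sequence[Read], db: MarkerDB, sample_id: str, cfg: RunConfig = RunConfig()
) -> SampleResult:
    """Profile a sample from raw reads using the built-in mapper."""
    aligned = naive_map(reads, db, seed_k=cfg.seed_k)
    pileups = build_pileups(aligned, db, min_base_quality=cfg.min_base_quality)
    return _profile_from_pileups(pileups, db, sample_id, cfg)


def profile_sample_sam(
    sam_path: str | Path, db: MarkerDB, sample_id: str, cfg: RunConfig = RunConfig()
) -> SampleResult:
    """Profile a sample from an existing SAM/BAM alignment."""
    pileups = build_pileups(
        parse_sam(sam_path, db), db, min_base_quality=cfg.min_base_quality
    )
    return _profile_from_pileups(pileups, db, sample_id, cfg)


def run_pipeline(
    cfg: RunConfig,
    samples: dict[str, Sequence[Read] | str | Path],
    db: MarkerDB,
    metadata: Optional[pd.DataFrame] = None,
    reference_profiles: Sequence[StrainProfile] = (),
    outdir: str | Path = "strainscope_out",
) -> dict:
    """Run the full pipeline and write per-species artifacts + a manifest.

    ``samples`` maps sample_id to either an in-memory read list or a
    SAM/BAM path.  Species with fewer retained profiles than
    ``cfg.min_strains_per_species`` are skipped for the comparative steps.
    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, SampleResult] = {}
    for sid, src in sorted(samples.items()):
        if isinstance(src, (str, Path)):
            res = profile_sample_sam(src, db, sid, cfg)
        else:
            res = profile_sample_reads(src, db, sid, cfg)
        results[sid] = res
        for species, profile in res.profiles.items():
            sp_dir = outdir / species
            sp_dir.mkdir(exist_ok=True)
            write_profile(profile, sp_dir / f"{sid}.fasta")

    poly_reports = [
        p for res in results.values() for p in res.polymorphism.values()
    ]
    if poly_reports:
        write_polymorphism_report(poly_reports, outdir / "polymorphism.tsv")

    by_species: dict[str, dict[str, StrainProfile]] = {}
    for res in results.values():
        for species, profile in res.profiles.items():
            by_species.setdefault(species, {})[res.sample_id] = profile
    for ref in reference_profiles:
        by_species.setdefault(ref.species, {})[ref.sample_id] = ref

    manifest: dict = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "n_samples": len(samples),
        "species": {},
    }
    for species, profiles in sorted(by_species.items()):
        if len(profiles) < cfg.min_strains_per_species:
            logger.info(
                "species %s: %d profiles < %d required, skipping comparative analysis",
                species,
                len(profiles),
                cfg.min_strains_per_species,
            )
            continue
        sp_dir = outdir / species
        sp_dir.mkdir(exist_ok=True)
        marker_sequences: dict[str, dict[str, str]] = {}
        for sid, profile in profiles.items():
            for mid, cm in profile.markers.items():
                marker_sequences.setdefault(mid, {})[sid] = cm.sequence
        aln = build_species_alignment(
            marker_sequences,
            species=species,
            gap_trailing=cfg.gap_in_trailing_col,
            gap_internal=cfg.gap_in_internal_col,
            n_col=cfg.n_col,
            long_gap=cfg.long_gap_percentage,
            gap_sample=cfg.gap_in_sample,
        )
        export_alignment(aln, sp_dir / "alignment")
        dist = snv_distance(aln)
        dist.to_tsv(sp_dir / "distances.tsv")
        entry: dict = {
            "n_strains": len(profiles),
            "alignment_columns": aln.n_columns,
        }
        if len(dist.sample_ids) >= 3:
            tree = build_tree(dist, metadata)
            tree.to_newick(sp_dir / "tree.nwk")
            subclades = detect_subclades(
                tree, dist, max_intra_snv=cfg.max_intra_snv, metadata=metadata
            )
            write_subclade_report(subclades, sp_dir / "subclades.tsv")
            entry["n_subclades"] = len(subclades)
            coords = ordination(dist, k_components=2)
            coords.to_csv(sp_dir / "ordination.tsv", sep="\t")
            if metadata is not None and "country" in metadata.columns:
                cs = country_subtrees(
                    tree,
                    metadata,
                    min_fraction=cfg.country_min_fraction,
                    min_size=cfg.country_min_size,
                )
                entry["n_country_subtrees"] = len(cs)
        if metadata is not None and "subject" in metadata.columns:
            try:
                nd = normalize_distances(dist, metadata)
                calls = call_retention(nd, seed=cfg.seed)
                write_retention_report(calls, sp_dir / "retention.tsv")
                entry["n_retention_calls"] = len(calls)
            except (ValueError, RuntimeError) as exc:
                logger.info("species %s: retention analysis skipped (%s)", species, exc)
        else:
            logger.info(
                "species %s: no subject metadata, retention analysis skipped", species
            )
        manifest["species"][species] = entry

    if not manifest["species"]:
        warnings.warn("no species passed the species gate in any sample", stacklevel=2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
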