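"""Serialization of profiles, reports and metadata."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .consensus import ConsensusMarker, StrainProfile
from .polymorphism import SpeciesPolymorphism

__all__ = [
    "write_profile",
    "read_profile",
    "load_metadata",
    "write_polymorphism_report",
    "write_retention_report",
    "write_subclade_report",
]


def write_profile(profile: StrainProfile, fasta_path: str | Path) -> None:
    """One FASTA per sample (``>species|marker_id`` records) plus a JSON
    sidecar with QC statistics."""
    records = [
        SeqRecord(Seq(cm.sequence), id=f"{profile.species}|{mid}", description="")
        for mid, cm in sorted(profile.markers.items())
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    sidecar = {
        "sample_id": profile.sample_id,
        "species": profile.species,
        "source": profile.source,
        "markers_in_db": profile.markers_in_db,
        "n_markers": profile.n_markers,
        "markers": {
            mid: {
                "length": cm.length,
                "ambiguous_fraction": cm.ambiguous_fraction,
                "mean_depth": None if cm.mean_depth != cm.mean_depth else cm.mean_depth,
            }
            for mid, cm in sorted(profile.markers.items())
        },
    }
    Path(fasta_path).with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_profile(fasta_path: str | Path) -> StrainProfile:
    sidecar = json.loads(Path(fasta_path).with_suffix(".json").read_text())
    markers: dict[str, ConsensusMarker] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        species, mid = rec.id.split("|", 1)
        info = sidecar["markers"][mid]
        markers[mid] = ConsensusMarker(
            marker_id=mid,
            species=species,
            sequence=str(rec.seq),
            mean_depth=info["mean_depth"] if info["mean_depth"] is not None else float("nan"),
        )
    return StrainProfile(
        sample_id=sidecar["sample_id"],
        species=sidecar["species"],
        markers=markers,
        markers_in_db=sidecar["markers_in_db"],
        source=sidecar["source"],
    )


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample, subject, country, timepoint
    (extra columns pass through); indexed by sample id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ValueError("metadata must have a 'sample' column")
    return df.set_index("sample")


def write_polymorphism_report(
    reports: Iterable[SpeciesPolymorphism], path: str | Path
) -> None:
    rows = [
        {
            "sample": r.sample_id,
            "species": r.species,
            "n_sites_tested": r.n_sites_tested,
            "polymorphic_rate": r.polymorphic_rate,
            "dominant_strain_freq": r.dominant_strain_freq,
        }
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_retention_report(calls, path: str | Path) -> None:
    rows = [
        {
            "species": c.species,
            "subject": c.subject,
            "sample_i": c.pair[0],
            "sample_j": c.pair[1],
            "normalized_distance": c.normalized,
            "verdict": c.verdict,
            "reliable": c.reliable,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_subclade_report(subclades, path: str | Path) -> None:
    rows = []
    for sc in subclades:
        top_country, top_frac = "", 0.0
        total = sum(sc.country_counts.values())
        if total:
            top_country = max(sorted(sc.country_counts), key=lambda c: sc.country_counts[c])
            top_frac = sc.country_counts[top_country] / total
        rows.append(
            {
                "species": sc.species,
                "subclade_id": sc.id,
                "size": sc.size,
                "n_subjects": sc.n_subjects,
                "intra_snv_median": sc.intra_snv_median,
                "top_country": top_country,
                "top_country_frac": top_frac,
                "contains_reference": sc.contains_reference,
                "members": ",".join(sorted(sc.leaf_set)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
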