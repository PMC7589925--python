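"""Readers and writers for the pipeline's on-disk formats.

FASTA via Bio.SeqIO (T accepted and preserved as written; the analysis code
converts to the RNA alphabet on use); tab-separated tables for counts,
library metadata and degradome tags; JSON for the simulation truth table.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GroundTruth
from .types import AbundanceMatrix, DegradomeProfile, LibraryMeta, design_frame


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_counts_tsv(matrix: AbundanceMatrix, path) -> None:
    matrix.values.rename_axis("feature_id").to_csv(path, sep="\t")


def read_counts_tsv(path, meta: pd.DataFrame, unit: str = "raw_count") -> AbundanceMatrix:
    values = pd.read_csv(path, sep="\t", index_col="feature_id")
    return AbundanceMatrix(values=values[list(meta.index)], meta=meta, unit=unit)


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("library_id").to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t").set_index("library_id")
    # validate through the dataclass
    design_frame(
        [
            LibraryMeta(
                library_id=str(lib),
                genotype=row["genotype"],
                treatment=row["treatment"],
                timepoint_dpa=int(row["timepoint_dpa"]),
                replicate=int(row["replicate"]),
            )
            for lib, row in meta.iterrows()
        ]
    )
    return meta


def write_degradome_tsv(profiles: Iterable[DegradomeProfile], path) -> None:
    """Sparse degradome table: transcript_id, position, count, library_id."""
    rows = []
    for prof in profiles:
        for pos in (prof.counts.nonzero()[0] + 1):
            rows.append(
                {
                    "transcript_id": prof.transcript_id,
                    "position": int(pos),
                    "count": int(prof.counts[pos - 1]),
                    "library_id": prof.library_id,
                }
            )
    pd.DataFrame(
        rows, columns=["transcript_id", "position", "count", "library_id"]
    ).to_csv(path, sep="\t", index=False)


def read_degradome_tsv(path, transcript_lengths: dict[str, int]) -> list[DegradomeProfile]:
    """Rebuild dense profiles; transcripts with no tags get all-zero profiles."""
    from .degradome import build_tplot

    table = pd.read_csv(path, sep="\t")
    profiles = []
    seen = set()
    for (tid, lib), grp in table.groupby(["transcript_id", "library_id"]):
        if tid not in transcript_lengths:
            raise ValueError(f"unknown transcript {tid} in degradome table")
        profiles.append(
            build_tplot(
                list(zip(grp["position"], grp["count"])),
                transcript_id=tid,
                length=transcript_lengths[tid],
                library_id=lib,
            )
        )
        seen.add((tid, lib))
    for lib in table["library_id"].unique():
        for tid, length in transcript_lengths.items():
            if (tid, lib) not in seen:
                profiles.append(build_tplot([], tid, length, library_id=lib))
    return profiles


def write_truth_json(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "planted_sites": truth.planted_sites,
                "planted_antagonistic_pairs": truth.planted_antagonistic_pairs,
                "planted_null_features": truth.planted_null_features,
            },
            fh,
            indent=1,
        )


def read_truth_json(path) -> GroundTruth:
    with open(path) as fh:
        data = json.load(fh)
    return GroundTruth(
        planted_sites=[tuple(x) for x in data["planted_sites"]],
        planted_antagonistic_pairs=[
            tuple(x) for x in data["planted_antagonistic_pairs"]
        ],
        planted_null_features=list(data["planted_null_features"]),
    )


def write_simulation(sim: dict, outdir) -> dict[str, Path]:
    """Write every artifact of ``simulate.simulate_all`` to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_fasta": outdir / "mirnas.fa",
        "transcript_fasta": outdir / "transcripts.fa",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "metadata": outdir / "library_metadata.tsv",
        "degradome": outdir / "degradome_tags.tsv",
        "degradome_metadata": outdir / "degradome_metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(sim["mirnas"], paths["mirna_fasta"])
    write_fasta(sim["transcripts"], paths["transcript_fasta"])
    write_counts_tsv(sim["mirna_matrix"], paths["mirna_counts"])
    write_counts_tsv(sim["mrna_matrix"], paths["mrna_counts"])
    write_metadata_tsv(sim["mirna_matrix"].meta, paths["metadata"])
    write_degradome_tsv(sim["degradome_profiles"], paths["degradome"])
    write_metadata_tsv(sim["degradome_meta"], paths["degradome_metadata"])
    write_truth_json(sim["truth"], paths["truth"])
    return paths
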