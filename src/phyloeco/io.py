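"""File input/output: proteome FASTA, manifests, matrices, phenotypes."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cluster import DistanceMatrix
from .features import ProteomeRecord


def read_fasta_proteome(path: str | Path, species_id: str | None = None) -> ProteomeRecord:
    """Read one species' proteome from a multi-FASTA file.

    The filename stem is the species id unless one is supplied.
    """
    path = Path(path)
    seqs = tuple(str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta"))
    return ProteomeRecord(species_id or path.stem, seqs)


def read_proteome_manifest(path: str | Path) -> list[ProteomeRecord]:
    """Read a manifest TSV (columns ``species_id``, ``path``); relative
    paths resolve against the manifest's directory."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    records = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = path.parent / p
        records.append(read_fasta_proteome(p, species_id=str(row.species_id)))
    return records


def write_proteome_fasta(record: ProteomeRecord, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=f"{record.species_id}_{i + 1:05d}", description="")
        for i, seq in enumerate(record.protein_sequences)
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_dataset(
    proteomes: list[ProteomeRecord],
    out_dir: str | Path,
    phenotypes: pd.DataFrame | None = None,
    truth=None,
) -> Path:
    """Write simulated proteomes as FASTA + manifest (+ phenotypes, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in proteomes:
        fasta = out / f"{p.species_id}.fasta"
        write_proteome_fasta(p, fasta)
        rows.append({"species_id": p.species_id, "path": fasta.name})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    if phenotypes is not None:
        phenotypes.to_csv(out / "phenotypes.tsv", sep="\t")
    if truth is not None:
        (out / "truth.json").write_text(
            json.dumps(
                {"seed": truth.seed, "archetype_of": truth.archetype_of}, indent=2
            )
        )
    return out


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_feature_matrix(m: pd.DataFrame, path: str | Path) -> None:
    m.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    D.to_frame().to_csv(path, sep="\t", float_format="%.17g")


def read_distance_matrix(path: str | Path, metric: str = "") -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(tuple(frame.index), frame.to_numpy(), metric)
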