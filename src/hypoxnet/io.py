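"""Readers and writers for the pipeline's plain-text interchange formats.

Counts and metadata travel as TSV, ground truth as JSON, sequences as
60-column wrapped FASTA, gene annotation as GFF3.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GroundTruth


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "gene_class": truth.gene_class,
        "planted_edges": sorted(list(e) for e in truth.planted_edges),
        "motif_genes": sorted(truth.motif_genes),
        "degron_tfs": sorted(truth.degron_tfs),
        "tf_ids": list(truth.tf_ids),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth_json(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        gene_class=payload["gene_class"],
        planted_edges={tuple(e) for e in payload["planted_edges"]},
        motif_genes=set(payload["motif_genes"]),
        degron_tfs=set(payload["degron_tfs"]),
        tf_ids=list(payload["tf_ids"]),
    )


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene spans from a GFF3 file: gene_id, seqid, start, end, strand."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for gene in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": gene.id,
                "seqid": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "seqid", "start", "end", "strand"])


def write_tf_list(tfs, path) -> None:
    Path(path).write_text("\n".join(sorted(tfs)) + "\n")


def read_tf_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
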