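"""File input/output: FASTA with metadata sidecars, and the pipeline TSVs.

Every writer can stamp a provenance comment (``# key=value``) in the first
lines; readers skip ``#`` comments.
"""

from __future__ import annotations

from pathlib import Path
from collections.abc import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from clockmine.datatypes import ProteinSeq, RBHPair, TaxonGroup


def read_fasta(
    path,
    organism: str = "",
    metadata: Mapping[str, tuple[str, TaxonGroup | str]] | None = None,
) -> list[ProteinSeq]:
    """Read a protein multi-FASTA into :class:`ProteinSeq` records.

    ``metadata`` (organism -> (genus, taxon_group)), typically from
    :func:`read_metadata_sidecar`, supplies taxonomy; otherwise the genus is
    derived from the organism name.
    """
    genus, group = "", TaxonGroup.OTHER
    if metadata and organism in metadata:
        genus, group = metadata[organism]
    return [
        ProteinSeq(
            id=rec.id,
            sequence=str(rec.seq),
            organism=organism,
            genus=genus,
            taxon_group=TaxonGroup.coerce(group),
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path, proteins: Sequence[ProteinSeq]) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description=p.organism) for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_metadata_sidecar(path) -> dict[str, tuple[str, TaxonGroup]]:
    """Read an (organism, genus, taxon_group) TSV sidecar."""
    table = pd.read_csv(path, sep="\t", comment="#")
    return {
        row.organism: (row.genus, TaxonGroup.coerce(row.taxon_group))
        for row in table.itertuples(index=False)
    }


def write_metadata_sidecar(path, metadata: Mapping[str, tuple[str, TaxonGroup]]) -> None:
    rows = [
        {"organism": org, "genus": genus, "taxon_group": TaxonGroup.coerce(group).value}
        for org, (genus, group) in metadata.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_tsv(path, frame: pd.DataFrame, header_comments: Mapping[str, str] | None = None,
              index: bool = True) -> None:
    """Write a TSV with optional ``# key=value`` provenance comment lines."""
    path = Path(path)
    with open(path, "w") as handle:
        for key, value in (header_comments or {}).items():
            handle.write(f"# {key}={value}\n")
        frame.to_csv(handle, sep="\t", index=index)


def read_matrix_tsv(path, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV matrix (first column = row labels), skipping comments."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_presence_tsv(path) -> pd.DataFrame:
    """Read a 0/1 systems x factors presence matrix."""
    return read_matrix_tsv(path).astype(bool)


def read_homolog_map(path) -> pd.DataFrame:
    """Read a cross-dataset homolog map TSV (group_id, dataset, gene_id)."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"group_id", "dataset", "gene_id"}
    if not required <= set(table.columns):
        raise ValueError(f"homolog map must have columns {sorted(required)}")
    return table


def rbh_pairs_table(pairs: Sequence[RBHPair]) -> pd.DataFrame:
    """Flatten accepted RBH pairs into a tidy table."""
    return pd.DataFrame(
        [
            {
                "query_id": p.query_id,
                "subject_id": p.subject_id,
                "subject_organism": p.subject_organism,
                "subtype": p.subtype,
                "score": p.forward_hit.score,
                "bitscore": p.forward_hit.bitscore,
                "evalue": p.forward_hit.evalue,
                "percent_similarity": p.forward_hit.percent_similarity,
                "aln_length": p.forward_hit.aln_length,
            }
            for p in pairs
        ]
    )
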