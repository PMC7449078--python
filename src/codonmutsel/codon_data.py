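"""Reading coding sequences, codon counting, and genome partitioning.

Input is a CDS FASTA (one coding sequence per record, sense strand, in frame
from the first base) plus a gene-location annotation: either GFF3 or a
3-column TSV ``gene_id  chromosome  start``. Codon counting keeps only codons
belonging to a synonymous family (start/stop and the single-codon amino
acids Met and Trp are excluded); codons containing ambiguous bases and any
trailing partial codon are skipped with a warning rather than failing the
record, since real assemblies contain Ns.

Genes are split into *endogenous* and *exogenous* sets by a genomic window
(chromosome, 1-based inclusive start/end); a gene is exogenous iff its start
coordinate falls inside the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .families import CodonFamilyTable

logger = logging.getLogger(__name__)

ENDOGENOUS = "endogenous"
EXOGENOUS = "exogenous"

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Region:
    """Genomic window, 1-based inclusive coordinates (GFF3 convention)."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region {self}")

    def contains(self, chromosome: str, position: int) -> bool:
        return chromosome == self.chromosome and self.start <= position <= self.end


@dataclass
class GeneCodonCounts:
    """Codon-usage counts for one gene: the sufficient statistics of the model."""

    gene_id: str
    length: int  # codons in the CDS (including start/stop/excluded codons)
    counts: np.ndarray  # per-codon counts aligned with table.codons
    table: CodonFamilyTable

    def family_counts(self) -> dict[str, int]:
        """Amino-acid (family) usage m: sum of codon counts within each family."""
        return {
            fam.label: int(self.counts[self.table.slice(fam.label)].sum())
            for fam in self.table.families
        }

    def as_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(self.table.codons, self.counts)}


class GenomeCounts:
    """Per-gene codon counts for a genome, matrix-backed.

    Attributes
    ----------
    counts : pandas.DataFrame
        Genes × codons count matrix (columns ordered as ``table.codons``).
    annotation : pandas.DataFrame
        Indexed by gene id with columns ``chromosome`` and ``start``.
    lengths : pandas.Series
        CDS length in codons per gene.
    """

    def __init__(
        self,
        table: CodonFamilyTable,
        counts: pd.DataFrame,
        annotation: pd.DataFrame,
        lengths: pd.Series | None = None,
    ):
        if list(counts.columns) != list(table.codons):
            counts = counts.reindex(columns=list(table.codons), fill_value=0)
        missing = set(counts.index) - set(annotation.index)
        if missing:
            raise ValueError(
                "annotation missing for records: " + ", ".join(sorted(missing)[:10])
            )
        self.table = table
        self.counts = counts
        self.annotation = annotation.loc[counts.index]
        if lengths is None:
            lengths = counts.sum(axis=1)
        self.lengths = lengths.loc[counts.index]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def family_matrix(self) -> np.ndarray:
        """Genes × families matrix of amino-acid usage counts m."""
        n = self.matrix()
        return np.column_stack(
            [n[:, self.table.slice(f.label)].sum(axis=1) for f in self.table.families]
        )

    def gene(self, gene_id: str) -> GeneCodonCounts:
        row = self.counts.loc[gene_id].to_numpy()
        return GeneCodonCounts(gene_id, int(self.lengths.loc[gene_id]), row, self.table)

    def subset(self, gene_ids) -> "GenomeCounts":
        ids = list(gene_ids)
        return GenomeCounts(
            self.table, self.counts.loc[ids], self.annotation.loc[ids], self.lengths.loc[ids]
        )

    # -- io ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.annotation.join(self.counts)
        out.insert(2, "length_codons", self.lengths)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, table: CodonFamilyTable) -> "GenomeCounts":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        ann = frame[["chromosome", "start"]]
        lengths = frame["length_codons"]
        counts = frame[list(table.codons)]
        return cls(table, counts, ann, lengths)


@dataclass
class GenomePartition:
    """Exhaustive endogenous/exogenous gene assignment for one genome."""

    assignment: pd.Series  # gene id -> ENDOGENOUS | EXOGENOUS
    region: Region

    @property
    def exogenous(self) -> list[str]:
        return list(self.assignment.index[self.assignment == EXOGENOUS])

    @property
    def endogenous(self) -> list[str]:
        return list(self.assignment.index[self.assignment == ENDOGENOUS])

    def to_tsv(self, path) -> None:
        self.assignment.rename("environment").to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, region: Region) -> "GenomePartition":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return cls(frame["environment"], region)


# ---------------------------------------------------------------------------
# counting


def count_codons(sequence: str, table: CodonFamilyTable, gene_id: str = "?") -> np.ndarray:
    """Count family codons of an in-frame CDS; returns a vector over table.codons.

    Trailing partial codons and codons with ambiguous bases are skipped with a
    warning; stop codons and excluded codons (ATG, TGG) are not counted.
    """
    seq = str(sequence).upper().replace("U", "T")
    counts = np.zeros(table.n_codons, dtype=np.int64)
    n_full = len(seq) // 3
    if len(seq) % 3:
        logger.warning(
            "record %s: length %d not a multiple of 3; final partial codon skipped",
            gene_id,
            len(seq),
        )
    pos = {c: i for i, c in enumerate(table.codons)}
    n_ambiguous = 0
    for k in range(n_full):
        codon = seq[3 * k : 3 * k + 3]
        i = pos.get(codon)
        if i is not None:
            counts[i] += 1
        elif codon in _STOPS or codon in ("ATG", "TGG"):
            continue
        else:
            n_ambiguous += 1
    if n_ambiguous:
        logger.warning(
            "record %s: %d codon(s) with ambiguous bases skipped", gene_id, n_ambiguous
        )
    return counts


def _read_annotation(path) -> pd.DataFrame:
    """Gene → (chromosome, start) map from GFF3 or a 3-column TSV."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] not in ("gene", "CDS", "mRNA"):
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID") or attrs.get("Name")
                if gid and gid not in rows:  # first feature wins (gene before CDS)
                    rows[gid] = (parts[0], int(parts[3]))
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=["chromosome", "start"])
        frame.index.name = "gene_id"
        return frame
    frame = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=["gene_id", "chromosome", "start"]
    )
    if frame.iloc[0]["gene_id"] == "gene_id":  # optional header row
        frame = frame.iloc[1:]
    frame["start"] = frame["start"].astype(int)
    return frame.set_index("gene_id")


def load_genome(
    cds_fasta, annotation, table: CodonFamilyTable | None = None
) -> GenomeCounts:
    """Read a CDS FASTA and annotation into per-gene codon counts.

    Raises if the FASTA is empty or any record lacks an annotation entry.
    """
    if table is None:
        table = CodonFamilyTable.standard()
    ann = _read_annotation(annotation)
    ids, rows, lengths = [], [], []
    for record in SeqIO.parse(str(cds_fasta), "fasta"):
        ids.append(record.id)
        rows.append(count_codons(str(record.seq), table, record.id))
        lengths.append(len(record.seq) // 3)
    if not ids:
        raise ValueError(f"no FASTA records in {cds_fasta}")
    missing = [i for i in ids if i not in ann.index]
    if missing:
        raise ValueError("annotation missing for records: " + ", ".join(missing[:10]))
    counts = pd.DataFrame(np.array(rows), index=ids, columns=list(table.codons))
    counts.index.name = "gene_id"
    return GenomeCounts(table, counts, ann, pd.Series(lengths, index=ids))


def partition_genes(genome: GenomeCounts | pd.DataFrame, region: Region) -> GenomePartition:
    """Assign every gene to endogenous/exogenous by the genomic window.

    A gene is exogenous iff its chromosome matches the region and its start
    coordinate lies within [start, end]; all other genes are endogenous.
    """
    ann = genome.annotation if isinstance(genome, GenomeCounts) else genome
    if region.chromosome not in set(ann["chromosome"]):
        raise ValueError(
            f"region chromosome {region.chromosome!r} absent from annotation"
        )
    exo = (ann["chromosome"] == region.chromosome) & ann["start"].between(
        region.start, region.end
    )
    labels = pd.Series(np.where(exo, EXOGENOUS, ENDOGENOUS), index=ann.index)
    return GenomePartition(labels, region)
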