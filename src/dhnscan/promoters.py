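"""Strand-aware extraction of upstream promoter sequences.

Promoters are up to 1000 bp immediately upstream of a gene's transcription
start (the translation start when no transcript annotation exists), taken
5'->3' relative to the gene and truncated where the contig ends.  Internal
coordinates are 0-based half-open; the GFF3 1-based inclusive convention is
converted at the parsing boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .simulate import reverse_complement  # canonical complement lives there

logger = logging.getLogger(__name__)

#: anchor precedence: transcript start beats gene start beats CDS start
_ANCHOR_PRECEDENCE = {"mRNA": 0, "gene": 1, "CDS": 2}


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    tss: int  # 0-based position of the transcription/translation start
    source_field: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class PromoterSeq:
    gene_id: str
    sequence: str
    contig_id: str
    start: int  # forward-strand coordinates, 0-based half-open
    end: int
    strand: str
    truncated: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length must equal end - start")

    @property
    def header(self) -> str:
        return f"{self.gene_id}|{self.contig_id}:{self.start}-{self.end}({self.strand})"

    @property
    def n_fraction(self) -> float:
        seq = self.sequence.upper()
        return seq.count("N") / len(seq) if seq else 0.0


def _parse_attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if "=" in item:
            key, _, value = item.partition("=")
            out[key.strip()] = value.strip()
    return out


def parse_gene_models(gff3: str | Path) -> list[GeneModel]:
    """One :class:`GeneModel` per gene from a GFF3 file or text.

    The anchor is the 5' end of the mRNA feature when present, else the gene
    feature, else the CDS start.  Malformed lines are skipped with a logged
    warning.
    """
    text = gff3 if isinstance(gff3, str) and "\t" in gff3 else Path(gff3).read_text()
    # best (precedence, model) seen per gene id
    best: dict[str, tuple[int, GeneModel]] = {}
    order: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            logger.warning("skipping malformed GFF3 line %d", lineno)
            continue
        contig, _, ftype, start_s, end_s, _, strand, _, attrs_col = cols
        if ftype not in _ANCHOR_PRECEDENCE:
            continue
        if strand not in "+-":
            logger.warning("skipping GFF3 line %d: missing strand", lineno)
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError:
            logger.warning("skipping malformed GFF3 line %d", lineno)
            continue
        attrs = _parse_attributes(attrs_col)
        if ftype == "gene":
            gene_id = attrs.get("ID", f"gene_at_{contig}_{start1}")
        else:
            gene_id = attrs.get("Parent") or attrs.get("ID", "")
            gene_id = gene_id.split(".")[0] if "." in gene_id else gene_id
        if not gene_id:
            logger.warning("skipping GFF3 line %d: no gene id", lineno)
            continue
        # GFF3 is 1-based inclusive; the 5' end on '+' is start-1 in 0-based
        # coordinates, on '-' it is end-1
        tss = start1 - 1 if strand == "+" else end1 - 1
        model = GeneModel(gene_id, contig, strand, tss, source_field=ftype)
        rank = _ANCHOR_PRECEDENCE[ftype]
        if gene_id not in best:
            order.append(gene_id)
            best[gene_id] = (rank, model)
        elif rank < best[gene_id][0]:
            best[gene_id] = (rank, model)
    return [best[g][1] for g in order]


def extract_promoter(
    genome: Mapping[str, str],
    gene: GeneModel,
    length: int = 1000,
) -> PromoterSeq | None:
    """The up-to-``length`` bp upstream sequence of one gene, 5'->3' relative
    to the gene; ``None`` (with a logged report) when no upstream sequence
    exists at all."""
    if gene.contig_id not in genome:
        raise KeyError(f"contig {gene.contig_id!r} not in genome")
    contig = genome[gene.contig_id]
    if gene.strand == "+":
        start, end = max(0, gene.tss - length), gene.tss
        seq = contig[start:end]
    else:
        start, end = gene.tss + 1, min(len(contig), gene.tss + 1 + length)
        seq = reverse_complement(contig[start:end])
    if end <= start:
        logger.warning("gene %s has no upstream sequence; excluded", gene.gene_id)
        return None
    return PromoterSeq(
        gene_id=gene.gene_id,
        sequence=seq,
        contig_id=gene.contig_id,
        start=start,
        end=end,
        strand=gene.strand,
        truncated=(end - start) < length,
    )


def extract_promoters(
    genome: Mapping[str, str],
    genes: Iterable[GeneModel],
    length: int = 1000,
    max_n_fraction: float = 0.5,
) -> list[PromoterSeq]:
    """Promoters for every gene; zero-length results and promoters that are
    mostly N are excluded (reported via logging)."""
    out = []
    for gene in genes:
        prom = extract_promoter(genome, gene, length)
        if prom is None:
            continue
        if prom.n_fraction > max_n_fraction:
            logger.warning(
                "promoter of %s is %.0f%% N; excluded from discovery",
                gene.gene_id,
                100 * prom.n_fraction,
            )
            continue
        out.append(prom)
    return out


def load_genome(fasta: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}


def promoters_to_fasta(promoters: Iterable[PromoterSeq]) -> str:
    lines = []
    for p in promoters:
        lines.append(f">{p.header}")
        for i in range(0, len(p.sequence), 60):
            lines.append(p.sequence[i : i + 60])
    return "\n".join(lines) + "\n"


def promoters_to_bed(promoters: Iterable[PromoterSeq]) -> str:
    """BED6 intervals of the extracted promoters (forward-strand coords)."""
    lines = []
    for p in promoters:
        lines.append(
            f"{p.contig_id}\t{p.start}\t{p.end}\t{p.gene_id}\t0\t{p.strand}"
        )
    return "\n".join(lines) + "\n"
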