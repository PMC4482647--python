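"""Extract strand-aware upstream promoters from an annotated genome.

Generates 40 gene-bearing contigs (20% of genes placed with less than
1000 bp of upstream sequence), parses the GFF3 gene models and extracts
up-to-1000 bp promoters, truncating at contig boundaries.
"""

from dhnscan import extract_promoters, make_genome_with_genes, parse_gene_models

records, gff, truth = make_genome_with_genes(40, near_edge_fraction=0.2, seed=29)
genome = {r.id: str(r.seq) for r in records}

genes = parse_gene_models(gff)
promoters = extract_promoters(genome, genes, length=1000)

full = [p for p in promoters if not p.truncated]
short = [p for p in promoters if p.truncated]
print(f"{len(promoters)} promoters extracted: "
      f"{len(full)} of 1000 bp, {len(short)} shorter (near a contig edge)")
for p in short[:3]:
    print(f"  {p.header} -> {len(p.sequence)} bp")
# A promoter header records the gene, the forward-strand genome interval and
# the strand; minus-strand promoters are reverse-complemented so the
# sequence always reads 5'->3' toward the gene start.
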