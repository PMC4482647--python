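"""Discover an overrepresented promoter word against a background pool.

Plants the LTRE-like word ACCGACA in 90% of 100 foreground promoters and
10% of 1000 background promoters, then ranks canonical k-mers (k = 6..10)
by binomial enrichment with Benjamini-Hochberg control.
"""

from dhnscan import discover_motifs, make_promoter_sets

fg, bg, truth = make_promoter_sets(
    n_fg=100, n_bg=1000, word="ACCGACA", p_fg=0.9, p_bg=0.1, seed=42
)
print(f"planted {len(truth.planted_motifs)} copies of ACCGACA")

motifs = discover_motifs(
    [str(r.seq) for r in fg], [str(r.seq) for r in bg], q_max=0.01
)
print(f"{len(motifs)} motif(s) at q <= 0.01")
for m in motifs[:3]:
    print(f"  seed {m.seed_word:>10}  consensus {m.consensus_iupac:<14} "
          f"occurrence {m.occurrence}  q = {m.q_value:.2e}")
# Occurrence n/N is the number of foreground promoters containing the motif
# on either strand over the foreground size; the consensus extends the seed
# word by two flanking columns tallied from its occurrences.
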