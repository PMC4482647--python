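"""Contrast dehydrin hydropathy and disorder with background proteins.

Dehydrins are hydrophilic (strongly negative GRAVY) and intrinsically
disordered; this script reproduces that contrast on synthetic sets with
Welch's t-test.
"""

from dhnscan import compare_sets, gravy, make_proteome

print(f"GRAVY of the canonical K-segment: {gravy('EKKGIMDKIKEKLPG'):.2f}")

records, truth = make_proteome(
    50, {"K_n": 10, "KS": 10, "SK_n": 10, "Y_nK_n": 10, "Y_nSK_n": 10}, 0.1, seed=17
)
planted = {t.sequence_id for t in truth.planted_dehydrins}
dehydrins = [(r.id, str(r.seq)) for r in records if r.id in planted]
background = [(r.id, str(r.seq)) for r in records if r.id not in planted]

summary = compare_sets(dehydrins, background)
print(f"mean GRAVY: dehydrins {summary.gravy_mean_a:.4f} "
      f"vs background {summary.gravy_mean_b:.4f} "
      f"(Welch p = {summary.gravy_test[2]:.2e})")
print(f"mean disorder proportion: dehydrins {summary.disorder_mean_a:.2%} "
      f"vs background {summary.disorder_mean_b:.2%} "
      f"(Welch p = {summary.disorder_test[2]:.2e})")
# Lower GRAVY = more hydrophilic; disorder proportion is the fraction of
# residues whose windowed fold-index score exceeds 0.5.
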