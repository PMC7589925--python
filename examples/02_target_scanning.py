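"""Score a miRNA/target duplex and scan a transcript for candidate sites.

Plant-style target prediction: match 0, G:U wobble 0.5, mismatch 1.0, with
penalties doubled across miRNA positions 2-13; sites scoring <= 4.5 pass.
The reported cleavage position lies opposite miRNA position 10.
"""

from trio_mirnet import scan_transcript, score_duplex
from trio_mirnet.targets import reverse_complement

mirna = "UGGACGAGGAUCUCGGCAAGU"  # 21 nt
perfect_site = reverse_complement(mirna)

# weaken the site: one G:U wobble at miRNA position 15 (outside the 2-13 core)
weak_site = list(perfect_site)
weak_site[len(mirna) - 15] = "U"
weak_site = "".join(weak_site)

for label, site in [("perfect", perfect_site), ("one wobble", weak_site)]:
    duplex = score_duplex(mirna, site)
    print(f"{label:>11}: score {duplex.score:.1f}  "
          f"states {''.join(s[0] for s in duplex.per_position_state)}")
# score 0.0 = perfect complementarity; 0.5 = one wobble outside the core.

transcript = "GAUACCGUAA" * 20 + weak_site + "CCAUGGAUCC" * 20
hits = scan_transcript(mirna, transcript, max_score=4.5)
for h in hits:
    print(f"site at {h.site_start}-{h.site_end}, score {h.score}, "
          f"cleavage position {h.cleavage_pos}")
# the single planted site is recovered; its cleavage position is where
# degradome 5'-end tags would accumulate if the site were used in vivo.
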