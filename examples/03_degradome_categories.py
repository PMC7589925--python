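"""Build degradome t-plots and classify cleavage sites into categories 0-4.

A t-plot is the per-position degradome 5'-end tag profile of a transcript.
A predicted cleavage site is classified by where its tag count sits in the
profile: unique maximum (0), tied maximum (1), above the median (2), at or
below the median (3), single read (4) -- category 0 is the strongest
evidence of miRNA-guided cleavage.
"""

from trio_mirnet import assign_category, build_tplot

# tag records: (position, count); duplicate positions aggregate
profiles = {
    "dominant peak": [(120, 18), (33, 2), (310, 1)],
    "tied maximum": [(120, 9), (200, 9), (33, 2)],
    "above median": [(120, 5), (200, 12), (33, 2), (87, 3)],
    "single read": [(120, 1), (200, 9)],
    "no signal": [(200, 9)],
}

for label, tags in profiles.items():
    tplot = build_tplot(tags, transcript_id="tx1", length=400)
    category = assign_category(tplot, cleavage_pos=120)
    print(f"{label:>14}: tags at site = {tplot.count_at(120):>2}, "
          f"category {category}")
# Prints categories 0, 1, 2, 4 and None: only tag-supported sites receive a
# category, and None (no tag at the predicted position) fails validation.
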