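"""Hypergeometric term enrichment with rich factors.

Builds a toy annotation of three terms over 200 genes, plants a study set
concentrated in one term, and reports the upper-tail hypergeometric p-value
and the rich factor (fraction of the term's genes present in the study set)
for each term.
"""

import numpy as np
import pandas as pd

from trio_mirnet import enrich_terms

rng = np.random.default_rng(11)
genes = [f"gene{i:03d}" for i in range(200)]
annotation = pd.DataFrame(
    [{"gene_id": g, "term_id": "GO:stress", "term_label": "response to stress"}
     for g in genes[:25]]
    + [{"gene_id": g, "term_id": "GO:starch", "term_label": "starch biosynthesis"}
       for g in genes[25:45]]
    + [{"gene_id": g, "term_id": "GO:house", "term_label": "housekeeping"}
       for g in genes]
)

# study set: 12 of the 25 stress genes plus 8 random others
study = genes[:12] + list(rng.choice(genes[45:], size=8, replace=False))

result = enrich_terms(study, annotation)
for _, row in result.iterrows():
    print(f"{row['term_id']:>10}  k={row['k']:>3}/{row['n_term']:<3} "
          f"rich factor {row['rich_factor']:.2f}  "
          f"p {row['p_value']:.2e}  q {row['q_value']:.2e}")
# GO:stress shows a high rich factor and a tiny p-value (12 of its 25 genes
# are in a 20-gene study set drawn from 200); the catch-all term is flat.
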