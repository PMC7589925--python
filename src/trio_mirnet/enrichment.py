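"""Hypergeometric term enrichment with rich-factor reporting.

For a study gene set against a user-supplied annotation (GO terms, KEGG
pathways, or any gene -> term table), each term is tested with the
upper-tail hypergeometric probability P(X >= k) of drawing k or more term
members in a study of size n_study from a population of N genes of which
n_term carry the term (one-sided Fisher). The rich factor k / n_term — the
proportion of the term's genes recovered in the study set — is reported as
the effect size, with Benjamini-Hochberg q-values over the tested terms.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ANNOTATION_COLUMNS = ["gene_id", "term_id", "term_label", "namespace"]
RESULT_COLUMNS = [
    "term_id",
    "term_label",
    "namespace",
    "k",
    "n_term",
    "n_study",
    "N",
    "rich_factor",
    "p_value",
    "q_value",
]


def enrich_terms(
    study_set: Iterable[str],
    annotation: pd.DataFrame,
    population: Optional[Iterable[str]] = None,
    min_term_size: int = 3,
    report_all: bool = False,
) -> pd.DataFrame:
    """Term enrichment of a study gene set.

    ``annotation`` needs columns gene_id and term_id (term_label/namespace
    optional). The population universe defaults to all genes in the
    annotation; when supplied explicitly it must contain the study set.
    Terms with fewer than ``min_term_size`` members in the universe are
    skipped, and terms with no study hit are omitted unless ``report_all``.
    Results are sorted by p-value, then rich factor descending.
    """
    ann = annotation.copy()
    for col in ("term_label", "namespace"):
        if col not in ann.columns:
            ann[col] = ""
    study = set(study_set)
    universe = set(population) if population is not None else set(ann["gene_id"])
    offenders = sorted(study - universe)
    if offenders:
        raise ValueError(f"study genes absent from population: {offenders[:10]}")
    ann = ann[ann["gene_id"].isin(universe)].drop_duplicates(["gene_id", "term_id"])

    N = len(universe)
    n_study = len(study)
    rows = []
    for term_id, members in ann.groupby("term_id"):
        genes = set(members["gene_id"])
        n_term = len(genes)
        if n_term < min_term_size:
            continue
        k = len(genes & study)
        if k == 0 and not report_all:
            continue
        p = float(hypergeom.sf(k - 1, N, n_term, n_study))
        rows.append(
            {
                "term_id": term_id,
                "term_label": members["term_label"].iloc[0],
                "namespace": members["namespace"].iloc[0],
                "k": k,
                "n_term": n_term,
                "n_study": n_study,
                "N": N,
                "rich_factor": k / n_term,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "q_value"])
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values(
            ["p_value", "rich_factor"], ascending=[True, False]
        ).reset_index(drop=True)
    else:
        result["q_value"] = pd.Series(dtype=float)
    return result[RESULT_COLUMNS]
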