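"""Three-step integration into antagonistic miRNA-mRNA modules.

Because a miRNA silences its target, a functional miRNA-mRNA pair is
expected to move antagonistically (miRNA up, mRNA down, or the reverse).
The integration proceeds in three steps:

1. **Validated pair universe** — a (miRNA, gene) pair exists only when the
   miRNA is expressed in the small-RNA data, the mRNA is expressed in the
   transcriptome data, and at least one degradome-validated cleavage site
   links them (the best, i.e. lowest, category across sites and libraries is
   recorded).
2. **Joint significance** — for a given contrast, both members must be
   differentially expressed at raw p < alpha (default 0.05).
3. **Antagonism** — the two log2 fold-changes must have opposite signs; the
   direction (mirna_up_mrna_down / mirna_down_mrna_up) is annotated.

Contrasts come in two flavours mirroring the study design: stress response
(one treatment vs control within a genotype) and genotype (stress-tolerant
vs stress-sensitive under one treatment), where "up" means higher in the
tolerant genotype. The resulting modules are exported as edge lists, a node
table and a node-link network JSON, with a per-condition direction glyph
table for multi-contrast figures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .degradome import CategorizedSite
from .types import AbundanceMatrix

PAIR_COLUMNS = [
    "mirna_id",
    "gene_id",
    "transcript_id",
    "best_category",
    "best_library",
    "n_sites",
]
MODULE_COLUMNS = PAIR_COLUMNS + [
    "contrast",
    "contrast_type",
    "mirna_log2fc",
    "mirna_p",
    "mrna_log2fc",
    "mrna_p",
    "direction",
]


def build_validated_pairs(
    mirna_matrix: AbundanceMatrix,
    mrna_matrix: AbundanceMatrix,
    categorized_sites: Sequence[CategorizedSite],
    tx2gene: Optional[Mapping[str, str]] = None,
    presence_threshold: float = 0.0,
) -> pd.DataFrame:
    """Step 1: the universe of expressed, degradome-validated pairs.

    One row per (miRNA, gene); multiple validated sites collapse to the best
    (lowest) category. A pair is kept only when the miRNA's maximum
    abundance and the mRNA's maximum abundance both exceed
    ``presence_threshold`` somewhere in their matrices. Transcripts missing
    from ``tx2gene`` (when supplied) are skipped.
    """
    mirna_max = mirna_matrix.values.max(axis=1)
    mrna_max = mrna_matrix.values.max(axis=1)

    best: dict[tuple[str, str], dict] = {}
    for cs in categorized_sites:
        mid = cs.site.mirna_id
        tid = cs.site.transcript_id
        if tx2gene is not None:
            if tid not in tx2gene:
                continue
            gene = tx2gene[tid]
        else:
            gene = tid
        if mid not in mirna_max.index or not mirna_max[mid] > presence_threshold:
            continue
        expr_id = tid if tid in mrna_max.index else gene
        if expr_id not in mrna_max.index or not mrna_max[expr_id] > presence_threshold:
            continue
        key = (mid, gene)
        row = best.get(key)
        if row is None:
            best[key] = {
                "mirna_id": mid,
                "gene_id": gene,
                "transcript_id": tid,
                "best_category": cs.category,
                "best_library": cs.library_id,
                "n_sites": 1,
            }
        else:
            row["n_sites"] += 1
            if cs.category < row["best_category"]:
                row["best_category"] = cs.category
                row["best_library"] = cs.library_id
                row["transcript_id"] = tid
    return pd.DataFrame(list(best.values()), columns=PAIR_COLUMNS)


def select_significant_pairs(
    pair_universe: pd.DataFrame,
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Step 2: pairs whose both members are significant in the same contrast.

    The two DE tables must carry a single, identical contrast label. The
    mRNA table may be keyed by transcript or by gene id.
    """
    contrasts = set(mirna_de["contrast"]) | set(mrna_de["contrast"])
    if len(contrasts) != 1:
        raise ValueError(f"DE tables carry mismatched contrasts: {sorted(contrasts)}")
    contrast = contrasts.pop()

    m = mirna_de.set_index("feature_id")
    g = mrna_de.set_index("feature_id")
    rows = []
    for _, pair in pair_universe.iterrows():
        if pair["mirna_id"] not in m.index:
            continue
        gid = (
            pair["gene_id"]
            if pair["gene_id"] in g.index
            else pair["transcript_id"]
        )
        if gid not in g.index:
            continue
        mr = m.loc[pair["mirna_id"]]
        gr = g.loc[gid]
        if mr["p_value"] < alpha and gr["p_value"] < alpha:
            rec = dict(pair)
            rec.update(
                contrast=contrast,
                mirna_log2fc=float(mr["log2fc"]),
                mirna_p=float(mr["p_value"]),
                mrna_log2fc=float(gr["log2fc"]),
                mrna_p=float(gr["p_value"]),
            )
            rows.append(rec)
    return pd.DataFrame(rows, columns=[c for c in MODULE_COLUMNS if c != "direction"
                                       and c != "contrast_type"])


def filter_antagonistic(
    significant_pairs: pd.DataFrame, contrast_type: str = "stress_response"
) -> pd.DataFrame:
    """Step 3: keep opposite-sign pairs and annotate the direction.

    Pairs where either log2fc is exactly zero (possible under an omnibus
    test, where direction is undefined) are excluded.
    """
    if contrast_type not in ("stress_response", "genotype"):
        raise ValueError(f"unknown contrast type {contrast_type!r}")
    if significant_pairs.empty:
        return pd.DataFrame(columns=MODULE_COLUMNS)
    df = significant_pairs.copy()
    opposite = np.sign(df["mirna_log2fc"]) * np.sign(df["mrna_log2fc"]) < 0
    df = df[opposite].copy()
    df["contrast_type"] = contrast_type
    df["direction"] = np.where(
        df["mirna_log2fc"] > 0, "mirna_up_mrna_down", "mirna_down_mrna_up"
    )
    return df[MODULE_COLUMNS].reset_index(drop=True)


def is_antagonistic_module(row: Mapping, alpha: float = 0.05) -> bool:
    """Independent re-check of the three step predicates for one module row.

    Used as a soundness audit over exported modules: degradome-validated
    category, joint significance at alpha, and strictly opposite signs.
    """
    return (
        row["best_category"] in (0, 1, 2, 3, 4)
        and row["mirna_p"] < alpha
        and row["mrna_p"] < alpha
        and row["mirna_log2fc"] * row["mrna_log2fc"] < 0
    )


def integrate(
    pair_universe: pd.DataFrame,
    de_tables: Mapping[str, tuple[pd.DataFrame, pd.DataFrame]],
    alpha: float = 0.05,
    contrast_types: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Run steps 2-3 for several contrasts and concatenate the modules.

    ``de_tables`` maps contrast label -> (miRNA DE table, mRNA DE table);
    ``contrast_types`` optionally maps labels to "stress_response" or
    "genotype" (default stress_response).
    """
    frames = []
    for contrast, (mirna_de, mrna_de) in de_tables.items():
        sig = select_significant_pairs(pair_universe, mirna_de, mrna_de, alpha=alpha)
        ctype = (contrast_types or {}).get(contrast, "stress_response")
        frames.append(filter_antagonistic(sig, contrast_type=ctype))
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=MODULE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def direction_glyphs(modules: pd.DataFrame) -> pd.DataFrame:
    """Per-condition direction table for each pair across contrasts.

    Rows are (miRNA, gene); one column per contrast holding "up"/"down" for
    the miRNA side ("-" where the pair was not called in that contrast) —
    the tabular equivalent of per-treatment arrow annotations in network
    figures.
    """
    if modules.empty:
        return pd.DataFrame(columns=["mirna_id", "gene_id"])
    glyph = modules.assign(
        glyph=np.where(modules["mirna_log2fc"] > 0, "up", "down")
    )
    table = glyph.pivot_table(
        index=["mirna_id", "gene_id"],
        columns="contrast",
        values="glyph",
        aggfunc="first",
    )
    return table.fillna("-").reset_index()


def export_network(modules: pd.DataFrame, outdir) -> dict[str, Path]:
    """Write module edge lists, node table, glyph table and network JSON.

    One ``modules_<contrast>.tsv`` per contrast, a combined ``nodes.tsv``
    with role labels, ``direction_glyphs.tsv`` and a node-link
    ``network.json``. Empty inputs produce valid empty files with headers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    contrasts = sorted(set(modules["contrast"])) if len(modules) else []
    if not contrasts:
        path = outdir / "modules_none.tsv"
        modules.head(0).to_csv(path, sep="\t", index=False)
        written["modules_none"] = path
    for contrast in contrasts:
        safe = contrast.replace(":", "_").replace("@", "_dpa")
        path = outdir / f"modules_{safe}.tsv"
        modules[modules["contrast"] == contrast].to_csv(path, sep="\t", index=False)
        written[f"modules_{safe}"] = path

    nodes = pd.DataFrame(
        [
            {"node_id": n, "role": "miRNA"}
            for n in sorted(set(modules["mirna_id"])) if len(modules)
        ]
        + [
            {"node_id": n, "role": "gene"}
            for n in sorted(set(modules["gene_id"])) if len(modules)
        ],
        columns=["node_id", "role"],
    )
    nodes_path = outdir / "nodes.tsv"
    nodes.to_csv(nodes_path, sep="\t", index=False)
    written["nodes"] = nodes_path

    glyph_path = outdir / "direction_glyphs.tsv"
    direction_glyphs(modules).to_csv(glyph_path, sep="\t", index=False)
    written["direction_glyphs"] = glyph_path

    graph = nx.MultiDiGraph()
    for _, row in nodes.iterrows():
        graph.add_node(row["node_id"], role=row["role"])
    for _, row in modules.iterrows():
        graph.add_edge(
            row["mirna_id"],
            row["gene_id"],
            contrast=row["contrast"],
            contrast_type=row["contrast_type"],
            direction=row["direction"],
            category=int(row["best_category"]),
            mirna_log2fc=float(row["mirna_log2fc"]),
            mrna_log2fc=float(row["mrna_log2fc"]),
            mirna_p=float(row["mirna_p"]),
            mrna_p=float(row["mrna_p"]),
        )
    net_path = outdir / "network.json"
    with open(net_path, "w") as fh:
        json.dump(nx.node_link_data(graph, edges="edges"), fh, indent=1)
    written["network"] = net_path
    return written


def read_modules(path) -> pd.DataFrame:
    """Round-trip reader for an exported module edge list."""
    return pd.read_csv(path, sep="\t", dtype={"best_category": "Int64"})
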