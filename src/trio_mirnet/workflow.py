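"""End-to-end pipeline on synthetic data, plus evaluation against the truth.

``run_scenario`` executes simulate -> normalize -> target scan -> degradome
validation -> per-contrast differential expression -> three-step integration
on one :class:`~trio_mirnet.simulate.SimulationPlan`, and
``evaluate_recovery`` scores the recovered antagonistic modules against the
planted truth. ``null_calibration`` measures empirical type-I error rates of
the differential tests and of step-2 joint retention under a global null.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from . import degradome as deg
from . import expression as expr
from . import integration as integ
from . import simulate as sim
from . import targets as tgt
from .simulate import STRESS_TREATMENTS, SimulationPlan
from .types import AbundanceMatrix


def stress_contrast_label(genotype: str, treatment: str, dpa: int) -> str:
    return f"{genotype}:{treatment}_vs_CG@{dpa}"


def stress_de_tables(
    mirna_rpm: AbundanceMatrix,
    mrna_rpm: AbundanceMatrix,
    dpa: int,
    alpha_pseudocount: float = 1.0,
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Welch-t DE tables for every (genotype, stress treatment) vs CG at one DPA."""
    tables = {}
    genotypes = sorted(set(mirna_rpm.meta["genotype"]))
    for g in genotypes:
        control = mirna_rpm.libraries_where(genotype=g, treatment="CG", timepoint_dpa=dpa)
        for t in STRESS_TREATMENTS:
            stress = mirna_rpm.libraries_where(
                genotype=g, treatment=t, timepoint_dpa=dpa
            )
            if not stress or not control:
                continue
            label = stress_contrast_label(g, t, dpa)
            groups = {t: stress, "CG": control}
            m_de = expr.test_differential(
                mirna_rpm, groups, pseudocount=alpha_pseudocount, contrast=label
            )
            g_de = expr.test_differential(
                mrna_rpm, groups, pseudocount=alpha_pseudocount, contrast=label
            )
            tables[label] = (m_de, g_de)
    return tables


def run_scenario(
    plan: SimulationPlan,
    max_score: float = tgt.DEFAULT_MAX_SCORE,
    max_category: int = 4,
    alpha: float = 0.05,
    presence_threshold: float = 0.0,
) -> dict:
    """Full pipeline on one synthetic scenario; returns all intermediates."""
    data = sim.simulate_all(plan)

    mirna_rpm = expr.normalize_rpm(data["mirna_matrix"])
    mrna_rpm = expr.normalize_rpm(data["mrna_matrix"])

    candidate_sites = tgt.scan_many(
        data["mirnas"], data["transcripts"], max_score=max_score
    )
    validated = deg.validate_sites(
        candidate_sites, data["degradome_profiles"], max_category=max_category
    )
    pair_universe = integ.build_validated_pairs(
        mirna_rpm, mrna_rpm, validated, presence_threshold=presence_threshold
    )

    de_tables = stress_de_tables(mirna_rpm, mrna_rpm, dpa=plan.effect_timepoint)
    modules = integ.integrate(pair_universe, de_tables, alpha=alpha)

    return {
        **data,
        "mirna_rpm": mirna_rpm,
        "mrna_rpm": mrna_rpm,
        "candidate_sites": candidate_sites,
        "validated_sites": validated,
        "pair_universe": pair_universe,
        "de_tables": de_tables,
        "modules": modules,
    }


def evaluate_recovery(modules: pd.DataFrame, truth: sim.GroundTruth) -> dict:
    """Recall/precision of recovered modules against the planted truth.

    A recovered (miRNA, gene, contrast) triple is a true positive iff the
    pair was planted antagonistically in that very contrast.
    """
    planted = {
        (m, t, c) for m, t, c, _ in truth.planted_antagonistic_pairs
    }
    found = {
        (row["mirna_id"], row["gene_id"], row["contrast"])
        for _, row in modules.iterrows()
    }
    tp = len(found & planted)
    recall = tp / len(planted) if planted else float("nan")
    precision = tp / len(found) if found else float("nan")
    return {
        "n_planted": len(planted),
        "n_found": len(found),
        "n_true_positive": tp,
        "recall": recall,
        "precision": precision,
    }


def null_calibration(
    n_features: int = 2000,
    n_replicates: int = 3,
    mean: float = 100.0,
    dispersion: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical type-I error of the Welch test and of step-2 joint retention.

    Simulates ``n_features`` null features (identical negative-binomial mean
    in both groups) for a miRNA-like and an mRNA-like assay, tests each at
    ``alpha``, and treats feature i of the two assays as a candidate pair to
    measure the joint-retention rate, which should sit near alpha^2 when the
    two sides are independent.
    """
    plan = SimulationPlan(
        n_mirna=n_features,
        n_transcript=n_features,
        n_planted_pairs=0,
        n_antagonistic=0,
        n_replicates=n_replicates,
        effect_log2fc=0.0,
        dispersion=dispersion,
        base_mean_log2_mu=float(np.log2(mean)),
        base_mean_log2_sigma=0.0,
        seed=seed,
    )
    truth = sim.GroundTruth()
    mirna_matrix, mrna_matrix = sim.simulate_expression(plan, truth)
    group_a = {"genotype": "TG", "treatment": "WS", "timepoint_dpa": 5}
    group_b = {"genotype": "TG", "treatment": "CG", "timepoint_dpa": 5}
    groups = {
        "WS": mirna_matrix.libraries_where(**group_a),
        "CG": mirna_matrix.libraries_where(**group_b),
    }
    mirna_de = expr.test_differential(expr.normalize_rpm(mirna_matrix), groups)
    mrna_de = expr.test_differential(expr.normalize_rpm(mrna_matrix), groups)

    mirna_sig = (mirna_de["p_value"] < alpha).to_numpy()
    mrna_sig = (mrna_de["p_value"] < alpha).to_numpy()
    fpr = float(np.concatenate([mirna_sig, mrna_sig]).mean())
    joint = float((mirna_sig & mrna_sig).mean())
    return {
        "n_features": n_features,
        "alpha": alpha,
        "false_positive_rate": fpr,
        "joint_retention": joint,
        "expected_joint": alpha**2,
    }


def power_scenario(
    plan: Optional[SimulationPlan] = None, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Fraction of planted differential miRNAs detected at ``alpha``.

    Uses the planted antagonistic pairs of a scenario: every planted miRNA
    is tested in its own contrast cell with the Welch test on RPM values.
    """
    if plan is None:
        plan = replace(SimulationPlan(), seed=seed)
    data = sim.simulate_all(plan)
    mirna_rpm = expr.normalize_rpm(data["mirna_matrix"])
    de_tables = stress_de_tables(mirna_rpm, expr.normalize_rpm(data["mrna_matrix"]),
                                 dpa=plan.effect_timepoint)
    detected = 0
    pairs = data["truth"].planted_antagonistic_pairs
    for mid, _, contrast, _ in pairs:
        m_de = de_tables[contrast][0].set_index("feature_id")
        if m_de.loc[mid, "p_value"] < alpha:
            detected += 1
    return {
        "n_planted_mirnas": len(pairs),
        "n_detected": detected,
        "power": detected / len(pairs) if pairs else float("nan"),
    }
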