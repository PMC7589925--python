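"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator plants known regulatory structure so every downstream stage —
target scanning, degradome validation, differential expression and the
three-step antagonistic integration — can be tested against a truth table:

* 21-24 nt miRNAs over {A,C,G,U};
* transcripts carrying embedded target sites that are reverse complements of
  their miRNA (optionally weakened by planned mismatch/G:U edits), with the
  cleavage position recorded opposite miRNA position 10;
* overdispersed negative-binomial count matrices over the full genotype x
  treatment x time-point design, where a subset of planted (miRNA, mRNA)
  pairs receive an antagonistic differential effect (+effect on one side,
  -effect on the other) in one stress-vs-control cell;
* degradome tag profiles with a peak at each planted cleavage position whose
  expectation scales linearly with the miRNA's abundance in that condition,
  over uniform Poisson background noise.

Everything is deterministic under the plan's seed: each stage draws from an
independent stream spawned from it, so regenerating any one output is
byte-identical regardless of which other stages run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .targets import reverse_complement
from .types import (
    GENOTYPES,
    TIMEPOINTS_DPA,
    TREATMENTS,
    AbundanceMatrix,
    DegradomeProfile,
    LibraryMeta,
    design_frame,
)

_RNA = np.array(list("ACGU"))
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
#: target-side wobble partner: the transcript base pairing the miRNA base as G:U
_WOBBLE_TARGET = {"G": "U", "U": "G"}

STRESS_TREATMENTS = ("WS", "HS", "WH")


@dataclass
class SiteEdit:
    """One planned weakening of a planted site, at a 1-based miRNA position."""

    position: int
    kind: str  # "mismatch" | "GU"

    def __post_init__(self) -> None:
        if self.kind not in ("mismatch", "GU"):
            raise ValueError(f"unknown edit kind {self.kind!r}")


@dataclass
class SimulationPlan:
    """All knobs of the synthetic scenario.

    Defaults define the reference scenario used throughout the test suite:
    400 miRNAs x 400 transcripts hosting 500 planted target sites, of which
    50 pairs (on distinct miRNAs and distinct transcripts) carry an
    antagonistic log2FC of 2.0 in one random stress-vs-control cell at
    5 DPA, negative-binomial counts with dispersion 0.1 and 3 replicates per
    design cell, and degradome peaks over sparse Poisson background. The
    catalogue sizes keep per-million totals insensitive to the planted
    effects, as they are in real libraries with hundreds to thousands of
    features.
    """

    n_mirna: int = 400
    n_transcript: int = 400
    mirna_length_range: tuple[int, int] = (21, 24)
    transcript_length: int = 600
    n_planted_pairs: int = 500
    n_antagonistic: int = 50
    site_edit_plan: dict[int, list[SiteEdit]] = field(default_factory=dict)
    min_site_spacing: int = 30
    genotypes: tuple[str, ...] = GENOTYPES
    treatments: tuple[str, ...] = TREATMENTS
    timepoints: tuple[int, ...] = TIMEPOINTS_DPA
    n_replicates: int = 3
    effect_log2fc: float = 2.0
    effect_timepoint: int = 5
    dispersion: float = 0.1
    base_mean_log2_mu: float = np.log2(100.0)
    base_mean_log2_sigma: float = 0.7
    degradome_peak_fraction: float = 0.5
    degradome_peak_scale: float = 10.0
    background_tag_rate: float = 0.05
    degradome_n_replicates: int = 3
    degradome_timepoint: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mirna_length_range
        if not (18 <= lo <= hi <= 26):
            raise ValueError("miRNA length range must lie within [18, 26]")
        if self.n_mirna < 0 or self.n_transcript < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_planted_pairs > self.n_mirna * self.n_transcript:
            raise ValueError("more planted pairs than (miRNA, transcript) combinations")
        if self.n_antagonistic > self.n_planted_pairs:
            raise ValueError("antagonistic pairs must be a subset of planted pairs")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 < self.degradome_peak_fraction <= 1):
            raise ValueError("degradome_peak_fraction must lie in (0, 1]")
        if self.background_tag_rate < 0:
            raise ValueError("background_tag_rate must be non-negative")
        if self.effect_timepoint not in self.timepoints:
            raise ValueError("effect_timepoint not in the design time-points")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream for one generation stage."""
        return np.random.default_rng([int(self.seed) % (2**31), stage])

    def design(self) -> list[LibraryMeta]:
        """Full-factorial expression design with the plan's replicate count."""
        libs = []
        for g in self.genotypes:
            for t in self.treatments:
                for dpa in self.timepoints:
                    for r in range(1, self.n_replicates + 1):
                        libs.append(
                            LibraryMeta(
                                library_id=f"{g}{dpa}_{t}_r{r}",
                                genotype=g,
                                treatment=t,
                                timepoint_dpa=dpa,
                                replicate=r,
                            )
                        )
        return libs

    def degradome_design(self) -> list[LibraryMeta]:
        """Degradome libraries: genotype x treatment x replicate at one DPA."""
        dpa = self.degradome_timepoint
        return [
            LibraryMeta(
                library_id=f"D_{g}{dpa}_{t}_r{r}",
                genotype=g,
                treatment=t,
                timepoint_dpa=dpa,
                replicate=r,
            )
            for g in self.genotypes
            for t in self.treatments
            for r in range(1, self.degradome_n_replicates + 1)
        ]


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests.

    ``planted_sites`` rows: (mirna_id, transcript_id, site_start,
    cleavage_pos), 1-based. ``planted_antagonistic_pairs`` rows: (mirna_id,
    transcript_id, contrast, mirna_direction) where contrast is
    "GENOTYPE:TREATMENT_vs_CG@DPA" and mirna_direction in {"up", "down"}
    (the mRNA moves the opposite way). ``planted_null_features`` lists ids
    with no differential effect anywhere.
    """

    planted_sites: list[tuple[str, str, int, int]] = field(default_factory=list)
    planted_antagonistic_pairs: list[tuple[str, str, str, str]] = field(
        default_factory=list
    )
    planted_null_features: list[str] = field(default_factory=list)

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted_sites,
            columns=["mirna_id", "transcript_id", "site_start", "cleavage_pos"],
        )

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.planted_antagonistic_pairs,
            columns=["mirna_id", "transcript_id", "contrast", "mirna_direction"],
        )


def simulate_mirnome(plan: SimulationPlan) -> dict[str, str]:
    """Random mature miRNA sequences, ids "mir-0001"... Deterministic."""
    rng = plan.rng(stage=1)
    lo, hi = plan.mirna_length_range
    out: dict[str, str] = {}
    for i in range(plan.n_mirna):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_RNA, size=length))
        out[f"mir-{i + 1:04d}"] = seq
    return out


def _apply_edits(site: str, mirna: str, edits: Sequence[SiteEdit], rng) -> str:
    """Weaken a perfect site by the planned edits (positions index the miRNA)."""
    length = len(mirna)
    chars = list(site)
    for edit in edits:
        p = edit.position
        if not (1 <= p <= length):
            raise ValueError(f"edit position {p} outside miRNA 1..{length}")
        m_base = mirna[p - 1]
        idx = length - p  # site is read 5'->3'; miRNA pos 1 pairs its 3' end
        if edit.kind == "GU":
            if m_base not in _WOBBLE_TARGET:
                raise ValueError(
                    f"G:U edit at miRNA position {p} needs G or U, found {m_base}"
                )
            chars[idx] = _WOBBLE_TARGET[m_base]
        else:
            forbidden = {_COMPLEMENT[m_base], _WOBBLE_TARGET.get(m_base, "")}
            options = [b for b in "ACGU" if b not in forbidden]
            chars[idx] = str(rng.choice(options))
    return "".join(chars)


def simulate_transcriptome_with_sites(
    mirnas: dict[str, str], plan: SimulationPlan
) -> tuple[dict[str, str], GroundTruth]:
    """Random transcripts with planted, non-overlapping miRNA target sites.

    Planted pairs are dealt round-robin over transcripts (so site capacity is
    never exceeded) with the targeting miRNA drawn at random; each site is
    the reverse complement of its miRNA with the plan's edits applied, and
    sites on one transcript keep at least ``min_site_spacing`` nt apart.
    """
    rng = plan.rng(stage=2)
    mirna_ids = list(mirnas)
    tx_ids = [f"tx-{i + 1:04d}" for i in range(plan.n_transcript)]
    truth = GroundTruth()

    if plan.n_planted_pairs and not mirna_ids:
        raise ValueError("cannot plant sites without miRNAs")

    # choose (transcript, miRNA) combos without repeating a pair
    assignments: dict[str, list[str]] = {t: [] for t in tx_ids}
    for k in range(plan.n_planted_pairs):
        tid = tx_ids[k % len(tx_ids)]
        available = [m for m in mirna_ids if m not in assignments[tid]]
        if not available:
            raise ValueError("transcript cannot host more distinct miRNAs")
        assignments[tid].append(str(rng.choice(available)))

    transcripts: dict[str, str] = {}
    pair_index = 0
    for tid in tx_ids:
        seq = list(rng.choice(_RNA, size=plan.transcript_length))
        cursor = int(rng.integers(0, plan.min_site_spacing + 1))
        for mid in assignments[tid]:
            mseq = mirnas[mid]
            length = len(mseq)
            if cursor + length > plan.transcript_length:
                raise ValueError(
                    f"transcript length {plan.transcript_length} too short for "
                    f"{len(assignments[tid])} spaced sites"
                )
            site = reverse_complement(mseq)
            edits = plan.site_edit_plan.get(pair_index, [])
            site = _apply_edits(site, mseq, edits, rng)
            start = cursor + 1  # 1-based
            seq[cursor : cursor + length] = list(site)
            cleavage = start + length - 10
            truth.planted_sites.append((mid, tid, start, cleavage))
            cursor += length + plan.min_site_spacing
            cursor += int(rng.integers(0, max(plan.min_site_spacing // 2, 1)))
            pair_index += 1
        transcripts[tid] = "".join(seq)

    # pick which planted pairs are antagonistically coupled; pairs use
    # distinct miRNAs and distinct transcripts so planted effects cannot
    # cancel through shared features in one contrast
    if plan.n_antagonistic:
        order = rng.permutation(len(truth.planted_sites))
        used_mirnas: set[str] = set()
        used_tx: set[str] = set()
        chosen: list[int] = []
        for idx in order:
            mid, tid, _, _ = truth.planted_sites[int(idx)]
            if mid in used_mirnas or tid in used_tx:
                continue
            chosen.append(int(idx))
            used_mirnas.add(mid)
            used_tx.add(tid)
            if len(chosen) == plan.n_antagonistic:
                break
        if len(chosen) < plan.n_antagonistic:
            raise ValueError(
                "not enough disjoint planted pairs for the antagonistic set"
            )
        contrast_cells = [
            (g, t) for g in plan.genotypes for t in STRESS_TREATMENTS
            if t in plan.treatments
        ]
        for idx in sorted(chosen):
            mid, tid, _, _ = truth.planted_sites[idx]
            g, t = contrast_cells[int(rng.integers(len(contrast_cells)))]
            contrast = f"{g}:{t}_vs_CG@{plan.effect_timepoint}"
            direction = "up" if rng.random() < 0.5 else "down"
            truth.planted_antagonistic_pairs.append((mid, tid, contrast, direction))

    antagonistic_features = {
        m for m, *_ in truth.planted_antagonistic_pairs
    } | {t for _, t, *_ in truth.planted_antagonistic_pairs}
    truth.planted_null_features = [
        f for f in (*mirna_ids, *tx_ids) if f not in antagonistic_features
    ]
    return transcripts, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """Negative binomial with mean ``mean`` and Var = mean + dispersion*mean^2."""
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite negative-binomial means")
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mean, dtype=float))
    return rng.negative_binomial(size, p)


def simulate_expression(
    plan: SimulationPlan, truth: GroundTruth
) -> tuple[AbundanceMatrix, AbundanceMatrix]:
    """Raw-count matrices for the miRNA and mRNA assays over the full design.

    Each feature gets a log-normal baseline mean shared by every design
    cell; features on an antagonistic pair have the mean multiplied by
    2^(+-effect_log2fc) in the pair's planted (genotype, treatment,
    time-point) cell — plus sign on the miRNA for an "up" pair and the
    opposite sign on the target mRNA. Counts are negative binomial with the
    plan's dispersion.
    """
    rng = plan.rng(stage=3)
    design = plan.design()
    meta = design_frame(design)

    mirna_ids = [f"mir-{i + 1:04d}" for i in range(plan.n_mirna)]
    tx_ids = [f"tx-{i + 1:04d}" for i in range(plan.n_transcript)]

    def base_means(n: int) -> np.ndarray:
        return 2.0 ** rng.normal(plan.base_mean_log2_mu, plan.base_mean_log2_sigma, n)

    mirna_base = base_means(plan.n_mirna)
    tx_base = base_means(plan.n_transcript)

    # per-feature log2 multiplier in each library
    mirna_shift = pd.DataFrame(0.0, index=mirna_ids, columns=meta.index)
    tx_shift = pd.DataFrame(0.0, index=tx_ids, columns=meta.index)
    for mid, tid, contrast, direction in truth.planted_antagonistic_pairs:
        cell, _, rest = contrast.partition(":")
        treatment = rest.split("_vs_")[0]
        dpa = int(contrast.split("@")[1])
        libs = meta.index[
            (meta["genotype"] == cell)
            & (meta["treatment"] == treatment)
            & (meta["timepoint_dpa"] == dpa)
        ]
        sign = 1.0 if direction == "up" else -1.0
        mirna_shift.loc[mid, libs] += sign * plan.effect_log2fc
        tx_shift.loc[tid, libs] -= sign * plan.effect_log2fc

    def draw(base: np.ndarray, shift: pd.DataFrame, ids: list[str]) -> pd.DataFrame:
        means = base[:, None] * 2.0 ** shift.to_numpy()
        counts = _nb_draw(rng, means, plan.dispersion)
        return pd.DataFrame(counts, index=ids, columns=meta.index)

    mirna_matrix = AbundanceMatrix(
        values=draw(mirna_base, mirna_shift, mirna_ids), meta=meta, unit="raw_count"
    )
    tx_lengths = pd.Series(plan.transcript_length, index=tx_ids, dtype=float)
    mrna_matrix = AbundanceMatrix(
        values=draw(tx_base, tx_shift, tx_ids),
        meta=meta,
        unit="raw_count",
        feature_lengths=tx_lengths,
    )
    return mirna_matrix, mrna_matrix


def simulate_degradome(
    transcripts: dict[str, str],
    truth: GroundTruth,
    mirna_matrix: AbundanceMatrix,
    plan: SimulationPlan,
) -> tuple[list[DegradomeProfile], pd.DataFrame]:
    """Degradome tag profiles for every transcript in every degradome library.

    Background tags are Poisson(``background_tag_rate``) per position. At
    each planted cleavage position an extra Poisson peak is added with mean
    ``degradome_peak_fraction`` x (mean miRNA count in the matching design
    cell) / ``degradome_peak_scale`` — a linear abundance-to-cleavage
    coupling, so cleavage evidence tracks the guide miRNA's expression.
    Returns the profiles and the degradome library metadata table.
    """
    rng = plan.rng(stage=4)
    design = plan.degradome_design()
    meta = design_frame(design)

    for mid, tid, start, cleavage in truth.planted_sites:
        if tid in transcripts and not (1 <= cleavage <= len(transcripts[tid])):
            raise ValueError(f"cleavage position {cleavage} outside {tid}")

    sites_by_tx: dict[str, list[tuple[str, int]]] = {}
    for mid, tid, _, cleavage in truth.planted_sites:
        sites_by_tx.setdefault(tid, []).append((mid, cleavage))

    profiles: list[DegradomeProfile] = []
    for lib in design:
        cell_libs = mirna_matrix.libraries_where(
            genotype=lib.genotype,
            treatment=lib.treatment,
            timepoint_dpa=lib.timepoint_dpa,
        )
        cell_means = (
            mirna_matrix.values[cell_libs].mean(axis=1)
            if cell_libs
            else pd.Series(0.0, index=mirna_matrix.values.index)
        )
        for tid, seq in transcripts.items():
            length = len(seq)
            counts = rng.poisson(plan.background_tag_rate, size=length)
            for mid, cleavage in sites_by_tx.get(tid, []):
                peak_mean = (
                    plan.degradome_peak_fraction
                    * float(cell_means.get(mid, 0.0))
                    / plan.degradome_peak_scale
                )
                counts[cleavage - 1] += rng.poisson(peak_mean)
            profiles.append(
                DegradomeProfile(
                    transcript_id=tid,
                    length=length,
                    counts=counts.astype(np.int64),
                    library_id=lib.library_id,
                )
            )
    return profiles, meta


def simulate_all(plan: SimulationPlan) -> dict:
    """Run every generation stage; returns a dict of all artifacts."""
    mirnas = simulate_mirnome(plan)
    transcripts, truth = simulate_transcriptome_with_sites(mirnas, plan)
    mirna_matrix, mrna_matrix = simulate_expression(plan, truth)
    degradome_profiles, degradome_meta = simulate_degradome(
        transcripts, truth, mirna_matrix, plan
    )
    return {
        "plan": plan,
        "mirnas": mirnas,
        "transcripts": transcripts,
        "truth": truth,
        "mirna_matrix": mirna_matrix,
        "mrna_matrix": mrna_matrix,
        "degradome_profiles": degradome_profiles,
        "degradome_meta": degradome_meta,
    }
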