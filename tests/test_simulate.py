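"""The synthetic generator: determinism, planted structure, calibration."""

import io as _io

import numpy as np
import pytest

from trio_mirnet import io as tio
from trio_mirnet.simulate import (
    GroundTruth,
    SimulationPlan,
    SiteEdit,
    simulate_degradome,
    simulate_expression,
    simulate_mirnome,
    simulate_transcriptome_with_sites,
)
from trio_mirnet.targets import scan_transcript, score_duplex
from trio_mirnet.degradome import assign_category


def fasta_bytes(seqs: dict[str, str]) -> bytes:
    buf = _io.StringIO()
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()],
        buf,
        "fasta",
    )
    return buf.getvalue().encode()


class TestMirnome:
    def test_identical_seed_gives_identical_fasta_bytes(self):
        plan = SimulationPlan(n_mirna=5, n_planted_pairs=0, n_antagonistic=0, seed=1)
        assert fasta_bytes(simulate_mirnome(plan)) == fasta_bytes(
            simulate_mirnome(plan)
        )

    def test_zero_mirnas_is_an_empty_set(self):
        plan = SimulationPlan(n_mirna=0, n_planted_pairs=0, n_antagonistic=0, seed=1)
        assert simulate_mirnome(plan) == {}

    def test_lengths_respect_the_range(self):
        plan = SimulationPlan(
            n_mirna=100, n_planted_pairs=0, n_antagonistic=0,
            mirna_length_range=(21, 24), seed=3,
        )
        lengths = {len(s) for s in simulate_mirnome(plan).values()}
        assert lengths <= {21, 22, 23, 24}
        assert {21, 24} <= lengths  # both ends reached at n=100

    def test_alphabet_is_rna(self):
        plan = SimulationPlan(n_mirna=20, n_planted_pairs=0, n_antagonistic=0, seed=4)
        assert set("".join(simulate_mirnome(plan).values())) <= set("ACGU")

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ValueError, match="length range"):
            SimulationPlan(mirna_length_range=(10, 24))


class TestTranscriptome:
    def test_planted_perfect_site_rediscovered_at_score_zero(self, small_sim):
        truth = small_sim["truth"]
        assert truth.planted_sites
        for mid, tid, start, cleavage in truth.planted_sites:
            mirna = small_sim["mirnas"][mid]
            hits = scan_transcript(mirna, small_sim["transcripts"][tid], max_score=0.0)
            assert any(h.site_start == start for h in hits)
            [hit] = [h for h in hits if h.site_start == start]
            assert hit.cleavage_pos == cleavage

    def test_cleavage_position_lies_within_the_site(self, small_sim):
        for mid, tid, start, cleavage in small_sim["truth"].planted_sites:
            length = len(small_sim["mirnas"][mid])
            assert start <= cleavage < start + length

    def test_planted_mismatch_edit_scores_two_under_default_scheme(self):
        plan = SimulationPlan(
            n_mirna=1,
            n_transcript=1,
            n_planted_pairs=1,
            n_antagonistic=0,
            site_edit_plan={0: [SiteEdit(5, "mismatch")]},
            seed=11,
        )
        mirnas = simulate_mirnome(plan)
        transcripts, truth = simulate_transcriptome_with_sites(mirnas, plan)
        [(mid, tid, start, _)] = truth.planted_sites
        mirna = mirnas[mid]
        site = transcripts[tid][start - 1 : start - 1 + len(mirna)]
        assert score_duplex(mirna, site).score == 2.0

    def test_no_planted_pairs_leaves_truth_empty(self):
        plan = SimulationPlan(
            n_mirna=3, n_transcript=3, n_planted_pairs=0, n_antagonistic=0, seed=5
        )
        _, truth = simulate_transcriptome_with_sites(simulate_mirnome(plan), plan)
        assert truth.planted_sites == []
        assert truth.planted_antagonistic_pairs == []

    def test_sites_on_one_transcript_keep_minimum_spacing(self, small_plan, small_sim):
        by_tx: dict[str, list[tuple[int, int]]] = {}
        for mid, tid, start, _ in small_sim["truth"].planted_sites:
            by_tx.setdefault(tid, []).append(
                (start, start + len(small_sim["mirnas"][mid]) - 1)
            )
        for spans in by_tx.values():
            spans.sort()
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                assert s2 - e1 - 1 >= small_plan.min_site_spacing

    def test_antagonistic_pairs_use_disjoint_features(self, small_sim):
        pairs = small_sim["truth"].planted_antagonistic_pairs
        mirnas = [p[0] for p in pairs]
        txs = [p[1] for p in pairs]
        assert len(set(mirnas)) == len(mirnas)
        assert len(set(txs)) == len(txs)

    def test_more_pairs_than_combinations_rejected(self):
        with pytest.raises(ValueError, match="planted pairs"):
            SimulationPlan(n_mirna=2, n_transcript=2, n_planted_pairs=5)


class TestExpression:
    def test_identical_seed_gives_identical_matrices(self, small_plan):
        truth = GroundTruth()
        a1, b1 = simulate_expression(small_plan, truth)
        a2, b2 = simulate_expression(small_plan, truth)
        assert a1.values.equals(a2.values)
        assert b1.values.equals(b2.values)

    def test_design_covers_the_full_factorial_layout(self, small_plan):
        meta = small_plan.design()
        cells = {(m.genotype, m.treatment, m.timepoint_dpa) for m in meta}
        assert len(cells) == 2 * 4 * 5
        assert len(meta) == 2 * 4 * 5 * small_plan.n_replicates

    def test_planted_pair_shifts_means_antagonistically(self, small_sim, small_plan):
        mirna_matrix = small_sim["mirna_matrix"]
        mrna_matrix = small_sim["mrna_matrix"]
        for mid, tid, contrast, direction in small_sim["truth"].planted_antagonistic_pairs:
            genotype, rest = contrast.split(":")
            treatment = rest.split("_vs_")[0]
            stress = mirna_matrix.libraries_where(
                genotype=genotype, treatment=treatment, timepoint_dpa=5
            )
            control = mirna_matrix.libraries_where(
                genotype=genotype, treatment="CG", timepoint_dpa=5
            )
            m_ratio = (
                mirna_matrix.values.loc[mid, stress].mean()
                / mirna_matrix.values.loc[mid, control].mean()
            )
            g_ratio = (
                mrna_matrix.values.loc[tid, stress].mean()
                / mrna_matrix.values.loc[tid, control].mean()
            )
            if direction == "up":
                assert m_ratio > 1.5 and g_ratio < 0.67
            else:
                assert m_ratio < 0.67 and g_ratio > 1.5

    def test_dispersion_must_be_positive(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationPlan(dispersion=0.0)


class TestDegradome:
    def test_identical_seed_gives_identical_profiles(self, small_plan, small_sim):
        profiles_again, _ = simulate_degradome(
            small_sim["transcripts"],
            small_sim["truth"],
            small_sim["mirna_matrix"],
            small_plan,
        )
        for p1, p2 in zip(small_sim["degradome_profiles"], profiles_again):
            assert p1.library_id == p2.library_id
            assert p1.transcript_id == p2.transcript_id
            np.testing.assert_array_equal(p1.counts, p2.counts)

    def test_zero_background_supported_sites_are_category_zero(self):
        plan = SimulationPlan(
            n_mirna=6,
            n_transcript=6,
            n_planted_pairs=6,
            n_antagonistic=0,
            background_tag_rate=0.0,
            degradome_peak_fraction=1.0,
            degradome_peak_scale=5.0,  # strong peaks (mean counts / 5)
            seed=8,
        )
        mirnas = simulate_mirnome(plan)
        transcripts, truth = simulate_transcriptome_with_sites(mirnas, plan)
        mirna_matrix, _ = simulate_expression(plan, truth)
        profiles, _ = simulate_degradome(transcripts, truth, mirna_matrix, plan)
        by_key = {(p.transcript_id, p.library_id): p for p in profiles}
        checked = 0
        for _, tid, _, cleavage in truth.planted_sites:
            for (ptid, _), prof in by_key.items():
                if ptid != tid:
                    continue
                if prof.count_at(cleavage) > 1:
                    assert assign_category(prof, cleavage) == 0
                    checked += 1
        assert checked > 0

    def test_peak_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="peak_fraction"):
            SimulationPlan(degradome_peak_fraction=1.5)

    def test_non_cleavage_positions_carry_only_background_noise(self, small_sim):
        cleavage_by_tx: dict[str, set[int]] = {}
        for _, tid, _, cleavage in small_sim["truth"].planted_sites:
            cleavage_by_tx.setdefault(tid, set()).add(cleavage)
        for prof in small_sim["degradome_profiles"]:
            counts = prof.counts.copy()
            for pos in cleavage_by_tx.get(prof.transcript_id, ()):
                counts[pos - 1] = 0
            assert counts.max() <= 5  # Poisson(0.05) background only


class TestRoundTrip:
    def test_simulation_artifacts_round_trip_through_disk(self, small_sim, tmp_path):
        paths = tio.write_simulation(small_sim, tmp_path)
        mirnas = tio.read_fasta(paths["mirna_fasta"])
        assert mirnas == small_sim["mirnas"]
        meta = tio.read_metadata_tsv(paths["metadata"])
        matrix = tio.read_counts_tsv(paths["mirna_counts"], meta)
        assert matrix.values.astype(int).equals(
            small_sim["mirna_matrix"].values.astype(int)
        )
        truth = tio.read_truth_json(paths["truth"])
        assert truth.planted_sites == [
            tuple(s) for s in small_sim["truth"].planted_sites
        ]
        lengths = {t: len(s) for t, s in small_sim["transcripts"].items()}
        profiles = tio.read_degradome_tsv(paths["degradome"], lengths)
        total_written = sum(p.total for p in profiles)
        total_original = sum(p.total for p in small_sim["degradome_profiles"])
        assert total_written == total_original
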