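"""Synthetic pangenome and MITE generators: determinism, calibration, truth."""

from __future__ import annotations

import itertools

import pytest

from pandorapan import align_protein, generate_pangenome, plant_mites
from pandorapan.synthetic import (
    MAX_LENGTH,
    MIN_LENGTH,
    _mutation_rate,
    write_synthetic_dataset,
)
from pandorapan.utils import reverse_complement


class TestGeneratePangenome:
    def test_deterministic_for_a_seed(self):
        g1, t1 = generate_pangenome(4, 8, 4, 0.5, 3, 0.8, 0.1, seed=5)
        g2, t2 = generate_pangenome(4, 8, 4, 0.5, 3, 0.8, 0.1, seed=5)
        assert {k: [x.sequence for x in v] for k, v in g1.items()} == {
            k: [x.sequence for x in v] for k, v in g2.items()
        }
        assert t1.gene_to_family == t2.gene_to_family
        g3, _ = generate_pangenome(4, 8, 4, 0.5, 3, 0.8, 0.1, seed=6)
        assert {k: [x.sequence for x in v] for k, v in g1.items()} != {
            k: [x.sequence for x in v] for k, v in g3.items()
        }

    def test_written_dataset_is_byte_identical(self, tmp_path):
        genomes, truth = generate_pangenome(3, 5, 2, 0.5, 2, 0.8, 0.0, seed=1)
        write_synthetic_dataset(tmp_path / "a", genomes, truth, params={"seed": 1})
        write_synthetic_dataset(tmp_path / "b", genomes, truth, params={"seed": 1})
        for name in ("G1.faa", "G2.faa", "G3.faa", "truth_families.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_planted_core_count_matches_truth_exactly(self):
        _, truth = generate_pangenome(6, 12, 8, 0.5, 5, 0.8, 0.0, seed=3)
        assert truth.planted_core == 12
        # core families occupy every genome by construction; shell families
        # only reach full occupancy by chance, never by design
        core_all = sum(
            1
            for fam, gs in truth.family_genomes.items()
            if fam.startswith("core") and gs == set(truth.genome_ids)
        )
        assert core_all == 12
        assert truth.families_in_all_genomes() >= 12

    def test_lengths_respect_truncation_bounds(self):
        genomes, _ = generate_pangenome(3, 30, 0, 0.5, 30, 0.8, 0.0, seed=9)
        lengths = [g.length for gs in genomes.values() for g in gs]
        assert min(lengths) >= MIN_LENGTH
        assert max(lengths) <= MAX_LENGTH

    def test_pairwise_identity_matches_target(self):
        # 12 members per family -> 66 pairs per family, 3 families
        genomes, truth = generate_pangenome(12, 3, 0, 0.5, 0, 0.8, 0.0, seed=7)
        by_family: dict[str, list] = {}
        for gs in genomes.values():
            for g in gs:
                by_family.setdefault(truth.gene_to_family[g.gene_id], []).append(g)
        idents = []
        for members in by_family.values():
            for a, b in itertools.combinations(members, 2):
                idents.append(align_protein(a.sequence, b.sequence).identity_short)
        mean = sum(idents) / len(idents)
        assert abs(mean - 0.8) < 0.05

    def test_realized_identity_monotone_in_target(self):
        means = []
        for target in (0.5, 0.65, 0.8, 0.95):
            genomes, truth = generate_pangenome(6, 4, 0, 0.5, 0, target, 0.0, seed=21)
            by_family: dict[str, list] = {}
            for gs in genomes.values():
                for g in gs:
                    by_family.setdefault(truth.gene_to_family[g.gene_id], []).append(g)
            idents = [
                align_protein(a.sequence, b.sequence).identity_short
                for members in by_family.values()
                for a, b in itertools.combinations(members, 2)
            ]
            means.append(sum(idents) / len(idents))
        assert means == sorted(means)

    def test_mutation_rate_solves_identity_equation(self):
        for t in (0.3, 0.5, 0.8, 0.95, 1.0):
            mu = _mutation_rate(t)
            # two members agree if neither site mutated or both hit the same
            # of the 19 alternatives
            expected = (1 - mu) ** 2 + (mu**2) / 19
            assert expected == pytest.approx(t, abs=1e-12)
        with pytest.raises(ValueError):
            _mutation_rate(0.01)

    def test_paralogs_recorded_and_more_similar_than_orthologs(self):
        genomes, truth = generate_pangenome(4, 10, 0, 0.5, 0, 0.7, 1.0, seed=13)
        assert truth.paralog_genes  # paralog_prob=1 guarantees duplications
        by_gene = {g.gene_id: g for gs in genomes.values() for g in gs}
        paralog_idents, ortholog_idents = [], []
        by_family: dict[str, list] = {}
        for gid, fam in truth.gene_to_family.items():
            by_family.setdefault(fam, []).append(by_gene[gid])
        for members in by_family.values():
            for a, b in itertools.combinations(members, 2):
                ident = align_protein(a.sequence, b.sequence).identity_short
                if a.genome_id == b.genome_id:
                    paralog_idents.append(ident)
                else:
                    ortholog_idents.append(ident)
        mean_p = sum(paralog_idents) / len(paralog_idents)
        mean_o = sum(ortholog_idents) / len(ortholog_idents)
        assert mean_p > mean_o

    def test_single_genome_degenerate_case(self):
        genomes, truth = generate_pangenome(1, 5, 0, 0.5, 3, 0.8, 0.0, seed=2)
        assert list(genomes) == ["G1"]
        assert len(genomes["G1"]) == 8
        assert truth.families_in_all_genomes() == 8

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            generate_pangenome(0, 5)
        with pytest.raises(ValueError):
            generate_pangenome(3, -1)
        with pytest.raises(ValueError):
            generate_pangenome(3, 5, shell_p=1.5)
        with pytest.raises(ValueError):
            generate_pangenome(3, 5, identity=0.0)
        with pytest.raises(ValueError):
            generate_pangenome(3, 5, paralog_prob=-0.1)


class TestPlantMites:
    def test_planted_elements_have_exact_tirs_and_tsds(self):
        scaffold, truth = plant_mites(
            scaffold_length=8000,
            n_mites=3,
            mite_length=300,
            tir_length=20,
            tsd_length=4,
            seed=11,
        )
        assert len(truth.mites) == 3
        assert truth.mite_consensus is not None
        assert len(truth.mite_consensus) == 300
        for mp in truth.mites:
            element = scaffold[mp.start : mp.end]
            assert len(element) == 300
            # TIR: prefix is exact revcomp of suffix
            assert element[:20] == reverse_complement(element[-20:])
            # TSD: identical direct repeats immediately flanking
            assert scaffold[mp.start - 4 : mp.start] == mp.tsd
            assert scaffold[mp.end : mp.end + 4] == mp.tsd

    def test_elements_do_not_overlap_and_are_ordered(self):
        scaffold, truth = plant_mites(6000, 4, 150, 12, 3, seed=8)
        spans = sorted((m.start, m.end) for m in truth.mites)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 + 3 <= s2 - 3  # separated at least by the TSD copies
        # elements replace scaffold stretches, so total length is conserved
        assert len(scaffold) == 6000

    def test_zero_mites_returns_plain_scaffold(self):
        scaffold, truth = plant_mites(1000, 0, 200, 15, 4, seed=0)
        assert len(scaffold) == 1000
        assert truth.mites == []
        assert truth.mite_consensus is None

    def test_diverged_copies_keep_exact_tirs(self):
        scaffold, truth = plant_mites(
            9000, 3, 300, 20, 4, seed=4, copy_identity=0.85
        )
        diverged = 0
        for mp in truth.mites:
            element = scaffold[mp.start : mp.end]
            assert element[:20] == reverse_complement(element[-20:])
            if element != truth.mite_consensus:
                diverged += 1
        assert diverged >= 2  # at 85% identity, copies differ from consensus

    def test_deterministic_for_a_seed(self):
        s1, _ = plant_mites(3000, 2, 200, 15, 4, seed=6)
        s2, _ = plant_mites(3000, 2, 200, 15, 4, seed=6)
        assert s1 == s2

    def test_infeasible_or_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            plant_mites(500, 3, 200, 15, 4)  # cannot fit 3 x ~208 bp in 500 bp
        with pytest.raises(ValueError):
            plant_mites(5000, 1, 90, 10, 4)  # below the 100 bp floor
        with pytest.raises(ValueError):
            plant_mites(5000, 1, 700, 10, 4)  # above the 600 bp ceiling
        with pytest.raises(ValueError):
            plant_mites(5000, 1, 200, 100, 4)  # TIRs longer than the element
        with pytest.raises(ValueError):
            plant_mites(5000, 1, 200, 15, 4, copy_identity=0.0)
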