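"""Generator contracts: determinism, planted-arm recoverability,
avoidance omission, CDS profile convergence, and fixture round-trips."""

import dataclasses

import numpy as np
import pytest

from phagetrna.codon_usage import count_codons
from phagetrna.errors import ValidationError
from phagetrna.io_formats import parse_trnascan_table, read_fasta
from phagetrna.synthetic_data import (
    Scenario,
    ScenarioTarget,
    codon_profile,
    default_scenario,
    generate_cds_set,
    generate_host_trnas,
    generate_phage_collection,
    load_scenario,
    scenario_catalog,
    scenario_from_json,
    scenario_to_json,
    write_scenario_fixtures,
)
from phagetrna.trna_structure import (
    IsoacceptorKey,
    extract_loop,
    find_anticodon_arm,
    normalize_gene,
)


class TestHostGeneration:
    def test_one_gene_per_key_and_determinism(self):
        sc = default_scenario(seed=7)
        genes1 = generate_host_trnas(sc)
        genes2 = generate_host_trnas(sc)
        assert len(genes1) == len(sc.host_keys) == 12
        assert genes1 == genes2

    def test_different_seeds_change_flanks_not_keys(self):
        a = generate_host_trnas(default_scenario(seed=1))
        b = generate_host_trnas(default_scenario(seed=2))
        assert [g.key for g in a] == [g.key for g in b]
        assert [g.sequence for g in a] != [g.sequence for g in b]

    def test_every_gene_resolves_to_its_planted_arm(self):
        for seed in range(4):
            for gene in generate_host_trnas(default_scenario(seed=seed)):
                arm = find_anticodon_arm(gene.sequence, gene.anticodon)
                assert arm.pairing_count == 5
                assert arm.anticodon == gene.anticodon


class TestPhageGeneration:
    def test_planted_mutations_and_omissions(self, small_pipeline):
        sc = small_pipeline["scenario"]
        phage_sets = small_pipeline["phage_sets"]
        avoided = set(sc.avoided_keys)
        for genes in phage_sets.values():
            keys = {g.key for g in genes}
            assert not keys & avoided
            assert keys == set(sc.host_keys) - avoided
        # every targeted copy differs from its host gene at the plan index
        host_by_key = {g.key: g for g in small_pipeline["host"]}
        for genes in phage_sets.values():
            for g in genes:
                plan = sc.mutation_plan.get(g.key)
                host_loop = extract_loop(host_by_key[g.key])
                phage_loop = extract_loop(g)
                if plan is None:
                    assert phage_loop == host_loop
                else:
                    diff = [
                        i for i in range(7) if host_loop[i] != phage_loop[i]
                    ]
                    assert diff == [plan]

    def test_truth_has_one_row_per_generated_gene(self, small_pipeline):
        n_genes = sum(
            len(g) for g in small_pipeline["phage_sets"].values()
        )
        assert len(small_pipeline["truth"]) == n_genes

    def test_unplanned_targeted_key_expected_loop_identical(self):
        sc = default_scenario(seed=5)
        plan = dict(sc.mutation_plan)
        plan[IsoacceptorKey("Lys", "ttt")] = None
        sc = dataclasses.replace(sc, mutation_plan=plan, n_phages=2)
        host = generate_host_trnas(sc)
        _, truth = generate_phage_collection(sc, host)
        lys = [t for t in truth if (t.isotype, t.anticodon) == ("Lys", "ttt")]
        assert lys and all(t.expected_call == "loop_identical" for t in lys)

    def test_adding_a_phage_does_not_perturb_earlier_phages(self):
        sc = default_scenario(seed=9)
        small = dataclasses.replace(sc, n_phages=3)
        big = dataclasses.replace(sc, n_phages=6)
        host = generate_host_trnas(sc)
        sets_small, _ = generate_phage_collection(small, host)
        sets_big, _ = generate_phage_collection(big, host)
        for phage_id in sets_small:
            assert sets_small[phage_id] == sets_big[phage_id]


class TestScenarioValidation:
    def test_mutation_index_off_the_cleavage_site_names_the_key(self):
        sc = default_scenario(seed=1)
        plan = dict(sc.mutation_plan)
        plan[IsoacceptorKey("Thr", "tgt")] = 6  # spec bond 0 -> site {0,1}
        sc = dataclasses.replace(sc, mutation_plan=plan)
        with pytest.raises(ValidationError, match="Thr"):
            sc.validate()

    def test_avoided_must_be_targeted(self):
        sc = default_scenario(seed=1)
        bad = dataclasses.replace(
            sc, avoided_keys=(IsoacceptorKey("Pro", "tgg"),)
        )
        with pytest.raises(ValidationError, match="avoided"):
            bad.validate()

    def test_targeted_must_be_in_host_set(self):
        sc = default_scenario(seed=1)
        bad = dataclasses.replace(
            sc,
            targets=sc.targets
            + (ScenarioTarget("X", IsoacceptorKey("Trp", "cca"), 0),),
        )
        with pytest.raises(ValidationError, match="targeted"):
            bad.validate()

    def test_json_round_trip(self):
        sc = default_scenario(seed=3)
        assert scenario_from_json(scenario_to_json(sc)) == sc

    def test_shipped_scenario_file_loads(self):
        from importlib import resources

        ref = resources.files("phagetrna.data") / "scenario_default.json"
        with resources.as_file(ref) as path:
            sc = load_scenario(path)
        assert sc == default_scenario()


class TestCdsGeneration:
    def test_degenerate_profile_fills_with_single_codon(self):
        recs = generate_cds_set({"AAA": 1.0}, 2, 30, seed=0)
        for rec in recs:
            assert rec.residues.startswith("ATG")
            assert rec.residues.endswith("TAA")
            internal = rec.residues[3:-3]
            assert internal == "AAA" * (len(internal) // 3)

    def test_zero_records(self):
        assert generate_cds_set("uniform", 0, 30, seed=0) == []

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValidationError):
            codon_profile({"AAA": -1.0})
        with pytest.raises(ValidationError):
            codon_profile({"AAA": 0.0})

    def test_deterministic_under_seed(self):
        a = generate_cds_set("gc_rich", 5, 90, seed=11)
        b = generate_cds_set("gc_rich", 5, 90, seed=11)
        assert a == b

    def test_empirical_frequencies_converge_to_weights(self):
        # multinomial oracle: observed count of codon c over N internal
        # draws is within 3 standard errors of N*p_c for most codons
        profile = codon_profile("gc_rich")
        sense_total = sum(profile.values())
        recs = generate_cds_set("gc_rich", 100, 300, seed=21)
        table = count_codons(recs)
        n_internal = 100 * (300 // 3 - 2)
        outside = 0
        for codon, weight in profile.items():
            p = weight / sense_total
            expected = n_internal * p
            se = np.sqrt(n_internal * p * (1 - p))
            observed = table.counts[codon]
            if codon == "ATG":
                observed -= 100  # forced start codons
            if abs(observed - expected) > 3 * se:
                outside += 1
        # 3 sigma ≈ 99.7%; allow a couple of excursions among 61 codons
        assert outside <= 2


class TestFixtureFiles:
    def test_round_trip_through_annotation_tables(self, tmp_path):
        sc = dataclasses.replace(default_scenario(seed=13), n_phages=2)
        paths = write_scenario_fixtures(sc, tmp_path)
        host_genes = generate_host_trnas(sc)
        (genome,) = read_fasta(paths["host_fasta"])
        rows = parse_trnascan_table(paths["host_annot"])
        recovered = [normalize_gene(r, genome) for r in rows]
        assert [g.sequence for g in recovered] == [
            g.sequence for g in host_genes
        ]
        assert [g.anticodon for g in recovered] == [
            g.anticodon for g in host_genes
        ]

    def test_fixture_generation_is_byte_identical(self, tmp_path):
        sc = dataclasses.replace(default_scenario(seed=17), n_phages=2)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_scenario_fixtures(sc, d1)
        write_scenario_fixtures(sc, d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_scenario_catalog_matches_written_catalog(self, tmp_path):
        from phagetrna.io_formats import load_catalog

        sc = dataclasses.replace(default_scenario(seed=19), n_phages=1)
        paths = write_scenario_fixtures(sc, tmp_path)

        def essence(catalog):
            return {
                e.name: [
                    (s.key, s.cleavage_bond, s.motif) for s in e.targets
                ]
                for e in catalog
            }

        assert essence(load_catalog(paths["catalog"])) == essence(
            scenario_catalog(sc)
        )


class TestFullRecoveryAcrossSeeds:
    @pytest.mark.parametrize("seed", range(20))
    def test_pipeline_recovers_ground_truth(self, seed):
        from phagetrna.sensitivity_analysis import analyze_collection, prevalence

        sc = dataclasses.replace(default_scenario(seed=seed), n_phages=3)
        host = generate_host_trnas(sc)
        phage_sets, truth = generate_phage_collection(sc, host)
        calls, _, skips = analyze_collection(
            phage_sets, host, scenario_catalog(sc)
        )
        assert skips == []
        expected = {
            (t.phage_id, t.gene_id): t.expected_call
            for t in truth
            if t.expected_call
        }
        got = {}
        for c in calls:
            got.setdefault((c.phage_id, c.phage_gene_id), set()).add(
                c.call.value
            )
        assert got == {k: {v} for k, v in expected.items()}
        prev = {
            (r.isotype, r.anticodon): r.fraction
            for r in prevalence(phage_sets)
        }
        for key in sc.avoided_keys:
            assert prev.get((key.isotype, key.anticodon), 0.0) == 0.0
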