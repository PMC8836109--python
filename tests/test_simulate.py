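"""Synthetic data generator: Mendelian gene dropping, determinism, planted
variant handling, and invariants of the emitted records."""

import dataclasses

import numpy as np
import pytest

from famprio import (
    FilterConfig,
    Genotype,
    PedigreeError,
    PedigreeMember,
    PlantedVariant,
    SimulationParams,
    gene_drop,
    generate_dataset,
    run_funnel,
)
from famprio.datasets import crc_candidate_variants, crc_family_pedigree
from famprio.io import read_annotated_table, write_annotated_table
from famprio.simulate import _gene_drop_matrix


def _planted_example():
    rec = next(r for r in crc_candidate_variants().records if r.gene == "PTK7")
    return PlantedVariant(rec, frozenset({"I-2", "II-1", "II-2", "II-4"}))


class TestGeneDrop:
    def test_zero_frequency_all_hom_ref(self):
        gts = gene_drop(crc_family_pedigree(), 0.0, seed=1)
        assert set(gts.values()) == {Genotype.HOM_REF}

    def test_unit_frequency_all_hom_alt(self):
        gts = gene_drop(crc_family_pedigree(), 1.0, seed=1)
        assert set(gts.values()) == {Genotype.HOM_ALT}

    def test_trio_carrier_rate_matches_closed_form(self):
        """With founder allele frequency q, a child of two founders carries
        an alternate allele with probability 1 - (1-q)^2; check the
        gene-drop estimate over 10^4 replicates against the closed form
        within 3 standard errors."""
        q = 0.5
        trio = [
            PedigreeMember("dad"), PedigreeMember("mom"),
            PedigreeMember("kid", father_id="dad", mother_id="mom"),
        ]
        n = 10_000
        rng = np.random.default_rng(42)
        counts = _gene_drop_matrix(trio, np.full(n, q), rng)
        carrier_rate = float((counts["kid"] > 0).mean())
        expected = 1 - (1 - q) ** 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(carrier_rate - expected) < 3 * se

    def test_scalar_and_matrix_geneflow_share_model(self):
        """The per-variant helper and the vectorized matrix drop give the
        same marginal carrier rate for a founder."""
        ped = crc_family_pedigree()
        q, n = 0.3, 4000
        rng = np.random.default_rng(3)
        matrix = _gene_drop_matrix(ped, np.full(n, q), rng)
        founder_rate = float((matrix["I-2"] > 0).mean())
        expected = 1 - (1 - q) ** 2
        assert abs(founder_rate - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_cyclic_pedigree_rejected(self):
        loop = [
            PedigreeMember("a", father_id="b"),
            PedigreeMember("b", father_id="a"),
        ]
        with pytest.raises(PedigreeError):
            gene_drop(loop, 0.1, seed=0)


class TestGenerateDataset:
    def test_fixed_seed_byte_identical(self, tmp_path):
        params = SimulationParams(seed=11, n_background=300)
        out = []
        for name in ("a.tsv", "b.tsv"):
            table, ped, _ = generate_dataset(params)
            write_annotated_table(table, tmp_path / name, ped)
            out.append((tmp_path / name).read_bytes())
        assert out[0] == out[1]

    def test_different_seeds_differ(self):
        t1, _, _ = generate_dataset(SimulationParams(seed=1, n_background=100))
        t2, _, _ = generate_dataset(SimulationParams(seed=2, n_background=100))
        assert [r.variant_id for r in t1.records] != [r.variant_id for r in t2.records]

    def test_forced_recovery_with_no_background(self, family):
        """A planted variant meeting every threshold is the entire final list
        when there is no background."""
        params = SimulationParams(seed=0, n_background=0, planted=[_planted_example()])
        table, ped, truth = generate_dataset(params)
        report, final = run_funnel(table, ped)
        assert [v.variant_id for v in final] == truth.planted_ids

    def test_planted_carrier_set_is_exact(self):
        params = SimulationParams(seed=5, n_background=0, planted=[_planted_example()])
        table, _, _ = generate_dataset(params)
        rec = table.records[-1]
        carriers = {m for m, g in rec.genotypes.items() if g is Genotype.HET}
        assert carriers == {"I-2", "II-1", "II-2", "II-4"}
        assert all(g is Genotype.HOM_REF for m, g in rec.genotypes.items()
                   if m not in carriers)

    def test_planted_unknown_carrier_rejected(self):
        bad = PlantedVariant(_planted_example().record, frozenset({"IV-9"}))
        with pytest.raises(ValueError, match="IV-9"):
            generate_dataset(SimulationParams(seed=0, n_background=0, planted=[bad]))

    def test_emitted_records_satisfy_invariants_and_round_trip(self, tmp_path):
        params = SimulationParams(seed=9, n_background=500,
                                  planted=[_planted_example()])
        table, ped, _ = generate_dataset(params)
        for r in table.records:
            r.validate()
        write_annotated_table(table, tmp_path / "t.tsv", ped)
        again = read_annotated_table(tmp_path / "t.tsv", ped)
        assert [r.variant_id for r in again.records] == [
            r.variant_id for r in table.records
        ]
        assert all(set(r.genotypes) == {m.member_id for m in ped}
                   for r in again.records)

    def test_every_background_variant_seen_in_family(self):
        """Ascertainment conditioning: every generated background row carries
        at least one alternate allele among the sequenced members."""
        table, _, _ = generate_dataset(SimulationParams(seed=13, n_background=400))
        for r in table.records:
            assert any(g is not Genotype.HOM_REF for g in r.genotypes.values())

    def test_benign_only_background_rarely_survives(self):
        """With no deleterious fraction the benign regime sits below the
        score thresholds and the funnel output is (near) empty."""
        params = SimulationParams(
            seed=21, n_background=5000, fraction_deleterious_background=0.0
        )
        table, ped, _ = generate_dataset(params)
        report, final = run_funnel(table, ped)
        assert len(final) <= 2

    def test_background_survival_monotone_in_cadd_threshold(self):
        table, ped, _ = generate_dataset(SimulationParams(seed=8, n_background=2000))
        finals = []
        for cadd_min in (5.0, 10.0, 20.0, 30.0):
            _, final = run_funnel(table, ped, FilterConfig(cadd_min=cadd_min))
            finals.append({v.variant_id for v in final})
        for bigger, smaller in zip(finals, finals[1:]):
            assert smaller <= bigger
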