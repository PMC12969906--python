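"""Generator statistics, determinism and the bundled end-to-end scenario."""

import collections
import filecmp

import numpy as np
import pytest

from acescan import cnv, genotyping, popgen, qpcr, simulate as sim
from acescan.activity import activity_table, population_comparison_table


class TestGenotypeGenerator:
    def test_ps_zero_all_gg(self):
        pairs = sim.gen_genotypes(sim.PopulationSpec("x", 30, 0.0), seed=1)
        assert all(p == ("GGC", "GGC") for p in pairs)

    def test_f_minus_one_all_heterozygous(self):
        pairs = sim.gen_genotypes(sim.PopulationSpec("x", 30, 0.5, f=-1.0), seed=1)
        assert all(genotyping.genotype_class(p) == "GS" for p in pairs)

    def test_het_fraction_matches_binomial_expectation(self):
        n = 10_000
        pairs = sim.gen_genotypes(sim.PopulationSpec("x", n, 0.5, f=0.0), seed=2)
        het = sum(genotyping.genotype_class(p) == "GS" for p in pairs)
        se = np.sqrt(0.5 * 0.5 / n)
        assert abs(het / n - 0.5) <= 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sim.PopulationSpec("x", 10, 1.5).genotype_probs()
        with pytest.raises(ValueError):
            sim.PopulationSpec("x", 10, 0.5, f=2.0).genotype_probs()


class TestAmpliconGenerator:
    def test_heterozygote_emitted_as_iupac(self, ref):
        recs = sim.gen_amplicons([("AGC", "GGC")], "p", ref)
        codon = str(recs[0].seq)[ref.codon119_offset : ref.codon119_offset + 3]
        assert codon == "RGC"
        recs = sim.gen_amplicons([("GGC", "GGT")], "p", ref)
        codon = str(recs[0].seq)[ref.codon119_offset : ref.codon119_offset + 3]
        assert codon == "GGY"

    def test_ggt_restricted_to_homozygotes(self):
        # p_ggt never lands on a GS individual, whose consensus would be
        # unphaseable (RGY)
        pairs = sim.gen_genotypes(sim.PopulationSpec("x", 2000, 0.5, p_ggt=0.5), seed=3)
        assert not any("GGT" in p and "AGC" in p for p in pairs)


class TestDepthGenerator:
    def test_copy1_mean_near_lambda(self):
        cov = sim.CoverageSpec()
        df = sim.gen_depth(cov, seed=4, resistant=False, omit_zeros=False)
        target = df[df["contig"] == cov.target_contig]["depth"]
        assert abs(target.mean() / cov.mean_depth - 1) < 0.02

    def test_copy2_span_doubles(self):
        cov = sim.CoverageSpec()
        df = sim.gen_depth(cov, seed=5, resistant=True, omit_zeros=False)
        t = df[df["contig"] == cov.target_contig]
        inside = t[(t["pos"] > cov.dup_start) & (t["pos"] <= cov.dup_end)]["depth"]
        assert inside.mean() == pytest.approx(2 * cov.mean_depth, rel=0.05)

    def test_negative_binomial_overdisperses(self):
        cov = sim.CoverageSpec(dispersion=3.0)
        df = sim.gen_depth(cov, seed=6, resistant=False, omit_zeros=False)
        d = df[df["contig"] == cov.target_contig]["depth"]
        assert d.var() > 1.5 * d.mean()  # Poisson would give var == mean

    def test_span_outside_contig_rejected(self):
        with pytest.raises(ValueError):
            sim.gen_depth(sim.CoverageSpec(dup_end=50_000), seed=0, resistant=True)


class TestQpcrGenerator:
    def test_reference_gene_is_single_copy(self):
        spec = sim.QpcrSpec(cq_sigma=0.0)
        plate = sim.gen_qpcr(spec, {"a": 3.0}, seed=0)
        unk = plate[(plate["role"] == "unknown") & (plate["gene"] == "rps7")]
        expected = spec.intercept["rps7"] + spec.slope("rps7") * np.log10(spec.base_concentration)
        assert np.allclose(unk["cq"], expected)

    def test_efficiency_bounds(self):
        with pytest.raises(ValueError):
            sim.gen_qpcr(sim.QpcrSpec(efficiency={"ace1": 0.5, "rps7": 1.0}), {"a": 1.0})


class TestDeterminism:
    def test_scenario_byte_identical_under_fixed_seed(self, tmp_path):
        m1 = sim.generate_scenario(tmp_path / "a", seed=123)
        m2 = sim.generate_scenario(tmp_path / "b", seed=123)
        for key, p1 in m1["files"].items():
            assert filecmp.cmp(p1, m2["files"][key], shallow=False), key

    def test_different_seed_differs(self, tmp_path):
        sim.generate_scenario(tmp_path / "a", seed=1)
        sim.generate_scenario(tmp_path / "b", seed=2)
        assert not filecmp.cmp(
            tmp_path / "a" / "amplicons.fasta", tmp_path / "b" / "amplicons.fasta", shallow=False
        )


@pytest.fixture(scope="module")
def scenario(tmp_path_factory):
    out = tmp_path_factory.mktemp("scenario")
    return sim.generate_scenario(out, seed=20_240_101)


class TestEndToEndScenario:
    """The bundled survey-like scenario reproduces the qualitative findings:
    heterozygote-excess flags, an activity gap vs the sensitive reference,
    a duplication call at the target locus and ~2x qPCR copy number."""

    def test_popgen_flags_heterozygote_excess(self, scenario):
        calls = genotyping.read_amplicon_fasta(scenario["files"]["amplicons"])
        by_pop = collections.defaultdict(list)
        for c in calls:
            by_pop[c.population].append(c)
        tables = [genotyping.tally_population(v) for v in by_pop.values()]
        summary = popgen.summarize(tables)
        assert summary["n_total"] == 551
        assert summary["n_hwe_deviant"] >= 1
        flagged = summary["per_population"]
        excess = flagged[(flagged["hwe_p"] < 0.05)]["hwe_direction"]
        assert (excess == "excess").all() and len(excess) >= 1

    def test_cnv_duplication_called(self, scenario):
        cov = sim.GUIZHOU_SCENARIO["coverage"]
        lengths = {cov.target_contig: cov.target_length, cov.control_contig: cov.control_length}
        res = cnv.read_depth_tsv(scenario["files"]["depth_resistant"])
        sen = cnv.read_depth_tsv(scenario["files"]["depth_sensitive"])
        spans = cnv.read_bed_spans(scenario["files"]["loci_bed"])
        track = cnv.doc_ratio(
            cnv.profile_from_depth(res, cov.target_contig, contig_lengths=lengths),
            cnv.profile_from_depth(sen, cov.target_contig, contig_lengths=lengths),
        )
        control = cnv.doc_ratio(
            cnv.profile_from_depth(res, cov.control_contig, contig_lengths=lengths),
            cnv.profile_from_depth(sen, cov.control_contig, contig_lengths=lengths),
        )
        call = cnv.call_duplication(track, spans["ace1"], control, spans["vgsc"], locus_name="ace1")
        assert call.is_duplicated
        assert call.copy_estimate == pytest.approx(2.0, abs=0.2)

    def test_qpcr_and_activity_separate_resistant_from_sensitive(self, scenario):
        import pandas as pd

        plate = pd.read_csv(scenario["files"]["qpcr_plate"])
        estimates, _ = qpcr.estimates_from_plate(plate)
        pops = qpcr.population_copy_number(estimates, reference_population="LP")
        assert pops.set_index("population").loc["LP", "mean_copy"] == pytest.approx(1.0, abs=0.2)
        assert pops.set_index("population").loc["CH", "mean_copy"] == pytest.approx(2.0, abs=0.3)

        table = activity_table(scenario["files"]["od_plate"])
        comp = population_comparison_table(table, reference="LP").set_index("population")
        assert comp.loc["CH", "p_vs_reference"] < 0.05
        assert comp.loc["HX", "p_vs_reference"] > 0.05
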