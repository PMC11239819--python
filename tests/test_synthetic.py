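"""Generator determinism, class structure, and round-trips through the readers."""

import numpy as np
import pandas as pd
import pytest

from cellsafety import offtarget as ot
from cellsafety import synthetic
from cellsafety.variants import merge_cell_types, read_caller_vcf, read_depth_track


class TestCohort:
    def test_empty_config(self):
        config = synthetic.CohortConfig(
            n_variants_per_class={c: 0 for c in synthetic.CLASSES})
        sim = synthetic.simulate_cohort(config)
        assert len(sim.truth) == 0
        assert all(not calls for calls in sim.calls.values())

    def test_noiseless_afs_are_exact(self):
        config = synthetic.CohortConfig(
            n_variants_per_class={"germline_het": 20}, noiseless=True)
        sim = synthetic.simulate_cohort(config)
        assert (sim.truth[["obs_af_fibro", "obs_af_ipsc", "obs_af_isc"]] == 0.5).all().all()

    def test_true_af_structure_per_class(self, cohort_sim):
        t = cohort_sim.truth
        het = t[t["class"] == "germline_het"]
        assert (het[["true_af_fibro", "true_af_ipsc", "true_af_isc"]] == 0.5).all().all()
        hom = t[t["class"] == "germline_hom"]
        assert (hom[["true_af_fibro", "true_af_ipsc", "true_af_isc"]] == 1.0).all().all()
        clonal = t[t["class"] == "clonally_amplified"]
        assert clonal["true_af_fibro"].between(0.01, 0.20).all()
        assert (clonal[["true_af_ipsc", "true_af_isc"]] == 0.5).all().all()
        denovo = t[t["class"] == "de_novo_isc"]
        assert (denovo[["true_af_fibro", "true_af_ipsc"]] == 0.0).all().all()
        assert (denovo["true_af_isc"] == 0.5).all()
        somatic = t[t["class"] == "preexisting_somatic"]
        assert somatic["true_af_fibro"].between(0.01, 0.30).all()
        assert (somatic["true_af_fibro"] == somatic["true_af_isc"]).all()

    def test_same_seed_byte_identical_outputs(self, tmp_path):
        config = synthetic.CohortConfig(
            n_variants_per_class={"germline_het": 50, "clonally_amplified": 20}, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthetic.simulate_cohort(config, out_dir=str(d1))
        synthetic.simulate_cohort(config, out_dir=str(d2))
        for name in ("fibro.vcf", "ipsc.vcf", "isc.vcf", "truth.tsv", "fibro.depth.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_vcf_and_depth_round_trip_through_readers(self, tmp_path):
        config = synthetic.CohortConfig(
            n_variants_per_class={"germline_het": 30, "de_novo_isc": 10}, seed=4)
        sim = synthetic.simulate_cohort(config, out_dir=str(tmp_path))
        back = read_caller_vcf(str(tmp_path / "isc.vcf"), "sim", "SNV")
        assert back.calls.keys() == sim.calls["isc"].keys()
        for key, (af, depth) in sim.calls["isc"].items():
            assert back.calls[key][0] == pytest.approx(af, abs=1e-6)
            assert back.calls[key][1] == depth
        depths = read_depth_track(str(tmp_path / "isc.depth.tsv"))
        assert depths == sim.depth_lookup["isc"]

    def test_observed_af_converges_with_depth(self):
        counts = {"clonally_amplified": 1000}
        shallow = synthetic.simulate_cohort(
            synthetic.CohortConfig(n_variants_per_class=counts, depth_mean=40, seed=11))
        deep = synthetic.simulate_cohort(
            synthetic.CohortConfig(n_variants_per_class=counts, depth_mean=4000, seed=11))
        for sim, tol in ((shallow, 0.01), (deep, 0.002)):
            err = (sim.truth["obs_af_ipsc"] - sim.truth["true_af_ipsc"]).abs().mean()
            assert err < 0.08
        err40 = (shallow.truth["obs_af_ipsc"] - 0.5).abs().mean()
        err4000 = (deep.truth["obs_af_ipsc"] - 0.5).abs().mean()
        assert err4000 < err40 / 5

    def test_merged_table_complete_af_triples(self, cohort_sim):
        table = merge_cell_types(cohort_sim.calls["fibro"], cohort_sim.calls["ipsc"],
                                 cohort_sim.calls["isc"], depth_lookup=cohort_sim.depth_lookup)
        afs = table[["af_fibro", "af_ipsc", "af_isc"]]
        assert afs.notna().all().all()
        assert ((afs >= 0) & (afs <= 1)).all().all()


class TestPlantedSites:
    def test_rejects_overlap_and_out_of_bounds(self):
        with pytest.raises(ValueError):
            synthetic.plant_offtarget_sites(200, [(10, 0, "AGG"), (20, 0, "AGG")])
        with pytest.raises(ValueError):
            synthetic.plant_offtarget_sites(30, [(20, 0, "AGG")])

    def test_planted_distance_is_exact(self):
        guide = ot.GuideSpec()
        for mm in range(7):
            seq, truth = synthetic.plant_offtarget_sites(300, [(100, mm, "AGG")],
                                                         guide, seed=mm)
            planted = truth[0]["matched_20mer"]
            assert sum(a != b for a, b in zip(planted, guide.protospacer)) == mm
            assert seq[100:120] == planted and seq[120:123] == "AGG"

    def test_random_background_rarely_resembles_guide(self):
        # with no plants, a 1 kb background should not contain a sub-6-mismatch
        # NRG-adjacent 20-mer (checked over several seeds)
        guide = ot.GuideSpec()
        for seed in range(5):
            seq, _ = synthetic.plant_offtarget_sites(1000, [], guide, seed=seed)
            _, mm = ot.scan_guide_homology(seq, guide)
            assert mm is None or mm >= 6


class TestCoverageSim:
    def test_flat_and_planted(self):
        track, truth = synthetic.simulate_coverage(500, 40)
        assert (track.depth == 40).all() and truth == []
        track, truth = synthetic.simulate_coverage(2000, 40, [(700, 654, "het")])
        assert (track.depth[700:1354] == 20).all()
        assert truth[0] == {"start": 700, "end": 1354, "zygosity": "het"}

    def test_determinism_and_overlap_rejection(self):
        a, _ = synthetic.simulate_coverage(1000, 40, [(100, 50, "het")], "binomial", seed=5)
        b, _ = synthetic.simulate_coverage(1000, 40, [(100, 50, "het")], "binomial", seed=5)
        assert np.array_equal(a.depth, b.depth)
        with pytest.raises(ValueError):
            synthetic.simulate_coverage(1000, 40, [(100, 50, "het"), (120, 10, "hom")])


class TestAmpliconSim:
    def test_degenerate_mixture_and_empty(self, amplicon_spec):
        reads, labels = synthetic.simulate_amplicon_reads(
            amplicon_spec, {"unmodified": 1.0}, 10, seed=0)
        assert all(seq == amplicon_spec.ref_amplicon for _, seq in reads)
        assert labels == ["unmodified"] * 10
        reads, labels = synthetic.simulate_amplicon_reads(amplicon_spec, {"unmodified": 1.0}, 0)
        assert reads == [] and labels == []

    def test_rejects_bad_proportions(self, amplicon_spec):
        with pytest.raises(ValueError):
            synthetic.simulate_amplicon_reads(amplicon_spec, {"unmodified": 0.5}, 10)
        with pytest.raises(ValueError):
            synthetic.simulate_amplicon_reads(amplicon_spec, {"nonsense": 1.0}, 10)

    def test_deterministic_for_seed(self, amplicon_spec):
        props = {"unmodified": 0.5, "indel": 0.5}
        r1, _ = synthetic.simulate_amplicon_reads(amplicon_spec, props, 50, 0.01, seed=3)
        r2, _ = synthetic.simulate_amplicon_reads(amplicon_spec, props, 50, 0.01, seed=3)
        assert r1 == r2
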