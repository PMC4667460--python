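"""Generator contracts: heritability bookkeeping, masking, trials, reads."""

import numpy as np
import pytest

from polygs.simdata import (
    MISSING,
    PopulationSpec,
    SimulationError,
    make_tag_panel,
    mask_missing,
    simulate_population,
    simulate_progeny_trial,
    simulate_tag_reads,
    simulate_two_populations,
)


class TestPopulationSpec:
    def test_qtl_exceeding_markers_rejected(self):
        with pytest.raises(SimulationError):
            simulate_population(PopulationSpec(10, 5, n_qtl=6))

    @pytest.mark.parametrize("h2", [-0.1, 1.2])
    def test_h2_out_of_range_rejected(self, h2):
        with pytest.raises(SimulationError):
            simulate_population(PopulationSpec(10, 5, n_qtl=2, h2=h2))


class TestSimulatePopulation:
    def test_noiseless_limit_phenotype_equals_breeding_value(self):
        G, truth, y = simulate_population(PopulationSpec(100, 50, n_qtl=10, h2=1.0, seed=1))
        assert truth.residual_sd == 0.0
        np.testing.assert_allclose(y, truth.breeding_values)

    def test_pure_noise_limit_uncorrelated(self):
        G, truth, y = simulate_population(PopulationSpec(1000, 50, n_qtl=10, h2=0.0, seed=2))
        r = np.corrcoef(y, G.codes[:, truth.qtl_indices] @ truth.qtl_effects)[0, 1]
        assert abs(r) < 0.1

    def test_variance_bookkeeping_at_h2_half(self):
        G, truth, y = simulate_population(PopulationSpec(500, 200, n_qtl=50, h2=0.5, seed=3))
        ratio = np.var(truth.breeding_values) / np.var(y)
        assert 0.40 <= ratio <= 0.60

    def test_realized_heritability_converges(self):
        # squared correlation of phenotype with breeding value -> h2 at n=2000
        G, truth, y = simulate_population(PopulationSpec(2000, 100, n_qtl=50, h2=0.3, seed=4))
        r2 = np.corrcoef(y, truth.breeding_values)[0, 1] ** 2
        assert abs(r2 - 0.3) < 0.05

    def test_seed_determinism_bit_exact(self):
        spec = PopulationSpec(50, 40, n_qtl=5, h2=0.4, seed=9)
        a = simulate_population(spec)
        b = simulate_population(spec)
        np.testing.assert_array_equal(a[0].codes, b[0].codes)
        np.testing.assert_array_equal(a[2], b[2])

    def test_tetraploid_collapse_codes(self):
        G, _, _ = simulate_population(PopulationSpec(200, 50, n_qtl=5, seed=5))
        assert set(np.unique(G.codes)) <= {0, 1, 2}
        het = G.codes == 1
        assert np.isin(G.dosages[het], [1, 2, 3]).all()
        assert (G.dosages[G.codes == 0] == 0).all()
        assert (G.dosages[G.codes == 2] == 4).all()


class TestProgenyTrial:
    def test_zero_replication_rejected(self):
        with pytest.raises(SimulationError):
            simulate_progeny_trial(np.zeros(5), r=0)

    def test_zero_plot_error_gives_identical_replicates(self):
        bv = np.random.default_rng(0).normal(size=30)
        trial = simulate_progeny_trial(bv, r=3, s2_hs=1.0, s2_e=0.0, seed=1)
        wide = trial.pivot(index="progeny_id", columns="replication_id", values="plot_value")
        centered = wide - wide.mean(axis=0)  # block effects differ; remove them
        assert np.allclose(centered.var(axis=1, ddof=0), 0.0, atol=1e-20)

    def test_zero_progeny_variance_leaves_error_only(self):
        trial = simulate_progeny_trial(np.zeros(2000), r=2, s2_hs=0.0, s2_e=3.0, seed=2)
        means = trial.groupby("progeny_id")["plot_value"].mean()
        expected = 3.0 / 2  # s2_e / r
        assert abs(means.var(ddof=1) - expected) / expected < 0.15


class TestMaskMissing:
    def test_point_mass_zero_identity(self, small_population):
        G, _, _ = small_population
        out = mask_missing(G, 0.0, seed=1)
        np.testing.assert_array_equal(out.codes, G.codes)

    def test_point_mass_one_all_missing(self, small_population):
        G, _, _ = small_population
        out = mask_missing(G, 1.0, seed=1)
        assert (out.codes == MISSING).all()

    def test_point_mass_rate_within_binomial_interval(self):
        G, _, _ = simulate_population(PopulationSpec(100, 100, n_qtl=5, seed=6))
        out = mask_missing(G, 0.3, seed=7)
        frac = (out.codes == MISSING).mean()
        half = 2.576 * np.sqrt(0.3 * 0.7 / 10000)
        assert 0.3 - half <= frac <= 0.3 + half

    def test_observed_entries_unchanged(self, small_population):
        G, _, _ = small_population
        out = mask_missing(G, seed=8)
        obs = out.codes != MISSING
        np.testing.assert_array_equal(out.codes[obs], G.codes[obs])

    def test_rate_out_of_range_rejected(self, small_population):
        G, _, _ = small_population
        with pytest.raises(SimulationError):
            mask_missing(G, 1.5, seed=1)


class TestTwoPopulations:
    def test_shared_panel_and_architecture(self):
        sa = PopulationSpec(50, 200, n_qtl=20, h2=0.5)
        (Ga, ma, _), (Gb, mb, _) = simulate_two_populations(sa, sa, 1.0, 0.0, seed=3)
        assert Ga.marker_names == Gb.marker_names
        np.testing.assert_array_equal(np.sort(ma.qtl_indices), np.sort(mb.qtl_indices))
        np.testing.assert_allclose(ma.qtl_effects, mb.qtl_effects)

    def test_disjoint_architecture_when_unshared(self):
        sa = PopulationSpec(50, 400, n_qtl=20, h2=0.5)
        (_, ma, _), (_, mb, _) = simulate_two_populations(sa, sa, 0.0, 0.1, seed=4)
        assert not set(ma.qtl_indices) & set(mb.qtl_indices)

    def test_invalid_shared_fraction(self):
        sa = PopulationSpec(10, 50, n_qtl=5)
        with pytest.raises(SimulationError):
            simulate_two_populations(sa, sa, 1.5, 0.0)


class TestTagReads:
    def test_zero_depth_gives_empty_fastq(self, tmp_path):
        G, _, _ = simulate_population(PopulationSpec(5, 10, n_qtl=2, seed=1))
        panel = make_tag_panel(10, seed=1)
        simulate_tag_reads(G, panel, tmp_path / "r.fastq", tmp_path / "k.tsv", mean_depth=0)
        assert (tmp_path / "r.fastq").read_text() == ""

    def test_homozygous_ref_emits_only_reference_tag(self, tmp_path):
        G, _, _ = simulate_population(PopulationSpec(8, 6, n_qtl=2, seed=2))
        panel = make_tag_panel(6, seed=2)
        simulate_tag_reads(G, panel, tmp_path / "r.fastq", tmp_path / "k.tsv",
                           mean_depth=30, error_rate=0.0, seed=3)
        alt_tags = set(panel["tag_alt"])
        import pandas as pd
        from Bio import SeqIO

        key = pd.read_csv(tmp_path / "k.tsv", sep="\t")
        bc_of = dict(zip(key["sample_id"], key["barcode"]))
        hom_ref = {(i, j) for i in range(8) for j in range(6) if G.codes[i, j] == 0}
        for rec in SeqIO.parse(str(tmp_path / "r.fastq"), "fastq"):
            seq = str(rec.seq)
            for i, s in enumerate(G.sample_ids):
                bc = bc_of[s]
                if seq.startswith(bc):
                    tag = seq[len(bc):]
                    for j, (tr, ta) in enumerate(zip(panel["tag_ref"], panel["tag_alt"])):
                        if tag in (tr, ta) and (i, j) in hom_ref:
                            assert tag == tr
                    break

    def test_heterozygote_minor_fraction_matches_dosage_mixture(self, tmp_path):
        # pooled over het individuals, alt-read fraction ~ Binomial(D, mean d/4)
        G, _, _ = simulate_population(PopulationSpec(30, 10, n_qtl=2, seed=4))
        panel = make_tag_panel(10, seed=4)
        simulate_tag_reads(G, panel, tmp_path / "r.fastq", tmp_path / "k.tsv",
                           mean_depth=100, depth_dispersion=None, error_rate=0.0, seed=5)
        from polygs.calling import demultiplex_trim

        table = demultiplex_trim(tmp_path / "r.fastq", tmp_path / "k.tsv", "CWGC")
        het = G.codes == 1
        n_alt = n_tot = exp_alt = 0
        for j, mk in enumerate(panel.index):
            ca = table.counts.get(panel.loc[mk, "tag_ref"], 0)
            cb = table.counts.get(panel.loc[mk, "tag_alt"], 0)
            for i in range(30):
                if het[i, j]:
                    a, b = int(np.asarray(ca)[i]), int(np.asarray(cb)[i])
                    n_alt += b
                    n_tot += a + b
                    exp_alt += (a + b) * int(G.dosages[i, j]) / 4.0
        p_exp = exp_alt / n_tot
        half = 2.576 * np.sqrt(p_exp * (1 - p_exp) / n_tot)
        assert abs(n_alt / n_tot - p_exp) <= half

    def test_bad_panel_rejected(self, tmp_path):
        import pandas as pd

        G, _, _ = simulate_population(PopulationSpec(3, 1, n_qtl=1, seed=1))
        bad = pd.DataFrame({"tag_ref": ["ACGT" * 16], "tag_alt": ["ACGT" * 16]},
                           index=["M00000"])
        with pytest.raises(SimulationError):
            simulate_tag_reads(G, bad, tmp_path / "r.fastq", tmp_path / "k.tsv")
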