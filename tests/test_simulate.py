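"""The synthetic plate and promoter generators."""

import numpy as np
import pytest

import taqase as tq


class TestReaction:
    def test_deterministic_given_seed(self):
        cfg = tq.ReactionSimConfig(true_x=0.3, noise_sd=0.01, seed=99)
        f1, v1 = tq.simulate_reaction(cfg)
        f2, v2 = tq.simulate_reaction(cfg)
        assert np.array_equal(f1.fluorescence, f2.fluorescence)
        assert np.array_equal(v1.fluorescence, v2.fluorescence)

    def test_balanced_noiseless_channels_identical(self):
        fam, vic = tq.simulate_reaction(tq.ReactionSimConfig(true_x=0.5, noise_sd=0.0))
        assert np.allclose(fam.fluorescence, vic.fluorescence)

    def test_more_template_amplifies_earlier(self):
        """The VIC inflection cycle moves earlier as its template fraction grows."""
        b_vic = {}
        for x in (0.5, 0.8):
            _, vic = tq.simulate_reaction(tq.ReactionSimConfig(true_x=x, noise_sd=0.0))
            b_vic[x] = tq.fit_sigmoid_two_step(vic).b
        assert b_vic[0.8] < b_vic[0.5]

    def test_logistic_recursion_well_fit_by_sigmoid(self):
        """The discrete recursion is close to a 4PL (rms misfit < ~2% of plateau)."""
        cfg = tq.ReactionSimConfig(true_x=0.5, noise_sd=0.0)
        fam, _ = tq.simulate_reaction(cfg)
        fit = tq.fit_sigmoid_two_step(fam)
        assert fit.converged
        assert fit.rss < 5e-3 * fit.a ** 2

    def test_reagent_conservation(self):
        """Amplicon totals never exceed the shared carrying capacity."""
        cfg = tq.ReactionSimConfig(true_x=0.3, noise_sd=0.0, probe_gain=1.0,
                                   baseline=0.0, carrying_capacity=1.0)
        fam, vic = tq.simulate_reaction(cfg)
        totals = fam.fluorescence + vic.fluorescence
        assert np.all(totals <= 1.0 + 1e-12)
        assert np.all(np.diff(totals) >= -1e-12)

    def test_pure_reaction_leaves_null_channel_flat(self):
        fam, vic = tq.simulate_reaction(tq.ReactionSimConfig(true_x=1.0, noise_sd=0.0))
        with pytest.raises(tq.NoAmplificationError):
            tq.initial_guess(fam)
        assert tq.fit_sigmoid_two_step(vic).converged

    @pytest.mark.parametrize("bad", [
        dict(true_x=1.5), dict(true_x=0.5, efficiency=1.5),
        dict(true_x=0.5, noise_sd=-1.0), dict(true_x=0.5, total_template=0.0),
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ValueError):
            tq.ReactionSimConfig(**bad)


def test_k_prime_strictly_monotone_in_true_fraction():
    """Noiseless k' is strictly monotone over the mixture grid (invertibility)."""
    ks = []
    for x in np.arange(0.05, 0.96, 0.09):
        fam, vic = tq.simulate_reaction(tq.ReactionSimConfig(true_x=float(x), noise_sd=0.0))
        ks.append(tq.k_prime_for_reaction(fam, vic).k_prime)
    diffs = np.diff(ks)
    assert np.all(diffs < 0) or np.all(diffs > 0)


class TestPlate:
    def test_default_design_well_count(self):
        design = tq.PlateDesign(unknowns=[("s1", "ovary", 0.7), ("s2", "brain", 0.5)])
        plate = tq.simulate_plate(design, seed=1)
        assert len(plate.true_fractions) == 13 * 3 + 2 * 3
        assert set(plate.fluorescence.columns) == {"well", "cycle", "channel", "fluorescence"}
        assert len(plate.sample_sheet) == len(plate.true_fractions)

    def test_bit_identical_across_runs(self):
        design = tq.PlateDesign(standard_fractions=(0.2, 0.5, 0.8), replicates=2)
        p1 = tq.simulate_plate(design, seed=4)
        p2 = tq.simulate_plate(design, seed=4)
        assert p1.fluorescence.equals(p2.fluorescence)

    def test_roundtrip_through_readers(self, tmp_path):
        from taqase.io import read_fluorescence_csv, read_sample_sheet
        design = tq.PlateDesign(standard_fractions=(0.1, 0.5, 0.9),
                                replicates=2, unknowns=[("s1", "gill", 0.3)])
        plate = tq.simulate_plate(design, seed=2)
        fluor_path, sheet_path = plate.write_csvs(tmp_path)
        curves = read_fluorescence_csv(fluor_path)
        assert set(curves) == set(plate.curves)
        for key, curve in curves.items():
            assert np.allclose(curve.fluorescence, plate.curves[key].fluorescence)
            assert curve.n_cycles == 46
        entries = read_sample_sheet(sheet_path)
        assert len(entries) == len(plate.sample_sheet)

    def test_single_replicate_still_calibrates(self):
        from conftest import run_simulated_plate
        design = tq.PlateDesign(replicates=1, unknowns=[("s1", "ovary", 0.6)])
        _, result = run_simulated_plate(design, seed=5)
        assert result.standard_curve is not None
        assert result.standard_curve.r_squared > 0.99
        for p in result.standard_points:
            assert p.cv_percent is None  # undefined with one replicate


class TestStudyDesigns:
    def test_ase_design_draws_per_fish_fractions(self):
        design = tq.ase_study_design(seed=1)
        assert len(design.unknowns) == 12
        by_tissue = {}
        for _, tissue, x in design.unknowns:
            by_tissue.setdefault(tissue, []).append(x)
        assert np.mean(by_tissue["ovary"]) > np.mean(by_tissue["brain"])
        assert len(set(by_tissue["ovary"])) > 1  # biological variation present

    def test_gdna_design_is_exactly_heterozygous(self):
        design = tq.gdna_study_design()
        assert len(design.unknowns) == 6
        assert all(x == 0.5 for _, _, x in design.unknowns)


class TestPromoterPair:
    def test_deterministic(self):
        a1, b1 = tq.simulate_promoter_pair(seed=5)
        a2, b2 = tq.simulate_promoter_pair(seed=5)
        assert a1.residues == a2.residues and b1.residues == b2.residues

    def test_planted_feature_structure(self):
        a, b = tq.simulate_promoter_pair(seed=7)
        assert len(a) == 670 and len(b) == 669
        assert a.residues[76] != b.residues[76]  # SNP at 1-based 77
        # deletion of base 231: suffixes realign after the indel
        assert b.residues[230:] == a.residues[231:]

    def test_deleted_base_differs_from_neighbours(self):
        for seed in range(5):
            a, _ = tq.simulate_promoter_pair(seed=seed)
            assert a.residues[230] != a.residues[229]
            assert a.residues[230] != a.residues[231]

    def test_position_validation(self):
        with pytest.raises(ValueError):
            tq.simulate_promoter_pair(snp_pos=100, indel_pos=100)
        with pytest.raises(ValueError):
            tq.simulate_promoter_pair(snp_pos=0)
        with pytest.raises(ValueError):
            tq.simulate_promoter_pair(island_span=(600, 700))
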