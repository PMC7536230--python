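import numpy as np
import pandas as pd
import pytest

from circuitflux.metrics import (
    DecayModel,
    GeneInterval,
    TranslationConstants,
    compute_rd,
    fit_decay_model,
    offtarget_screen,
    proteome_fraction,
    ribosome_usage,
    steady_state_mrna,
    translation_efficiency,
)
from circuitflux.profiles import (
    UNIT_ARB_FLUX,
    UNIT_RIBOSOMES,
    UNIT_RNAP_PER_S_TOTAL,
    StrandedProfile,
)

GAMMA = 0.0067


def occ_profile(values, strand="+", ref="ref"):
    return StrandedProfile(ref, strand, np.asarray(values, dtype=float), UNIT_RIBOSOMES)


def flux_profile(values, strand="+", ref="ref"):
    return StrandedProfile(
        ref, strand, np.asarray(values, dtype=float), UNIT_RNAP_PER_S_TOTAL
    )


def gene(start, end, strand="+", ref="ref"):
    return GeneInterval(ref, start, end, strand)


class TestComputeRd:
    def test_uniform_identity(self):
        prof = occ_profile(np.full(200, 0.37))
        assert compute_rd(prof, gene(50, 150)) == pytest.approx(0.37)

    def test_too_short_gene_raises(self):
        with pytest.raises(ValueError):
            compute_rd(occ_profile(np.ones(100)), gene(10, 40))

    def test_winsorized_outlier_percentile_oracle(self):
        v = np.full(300, 2.0)
        v[100] = 200.0  # single outlier; mean density > 1 triggers winsorization
        prof = occ_profile(v)
        g = gene(0, 300)
        rd = compute_rd(prof, g)
        # independent percentile-clip oracle over the trimmed gene
        trimmed = v[15:285]
        lo, hi = np.percentile(trimmed, [5, 95])
        expected = np.clip(trimmed, lo, hi).mean()
        assert rd == pytest.approx(expected)
        assert rd < trimmed.mean()

    def test_no_winsorization_below_density_threshold(self):
        v = np.full(300, 0.01)
        v[100] = 0.5
        prof = occ_profile(v)
        rd = compute_rd(prof, gene(0, 300))
        assert rd == pytest.approx(v[15:285].mean())

    def test_self_normalization_by_decay_model(self):
        model = DecayModel(a=2.0, lam=60.0)
        d = np.arange(300, dtype=float)
        prof = occ_profile(np.asarray(model(d)))
        rd = compute_rd(prof, gene(0, 300), decay_model=model, winsorize=False)
        assert rd == pytest.approx(1.0, rel=1e-12)

    def test_trimmed_mean_oracle_equivalence(self, rng):
        # identity decay model, no winsorization == plain trimmed mean
        for _ in range(100):
            start = int(rng.integers(0, 50))
            length = int(rng.integers(40, 200))
            values = rng.random(start + length + 50)
            prof = occ_profile(values)
            g = gene(start, start + length)
            rd = compute_rd(prof, g, winsorize=False)
            assert rd == pytest.approx(values[start + 15 : start + length - 15].mean())

    def test_antisense_distance_orientation(self):
        model = DecayModel(a=2.0, lam=60.0)
        d = np.arange(300, dtype=float)
        prof = occ_profile(np.asarray(model(d))[::-1], strand="-")
        rd = compute_rd(prof, gene(0, 300, strand="-"), decay_model=model, winsorize=False)
        assert rd == pytest.approx(1.0, rel=1e-12)


class TestFitDecayModel:
    def _genes_with_elevation(self, a, lam, n_genes=30, length=400):
        rng = np.random.default_rng(7)
        pitch = length + 100
        values = np.zeros(n_genes * pitch)
        genes = []
        model = DecayModel(a=a, lam=lam)
        for i in range(n_genes):
            start = i * pitch
            level = rng.uniform(0.5, 5.0)
            d = np.arange(length, dtype=float)
            values[start : start + length] = level * np.asarray(model(d))
            genes.append(gene(start, start + length))
        return [occ_profile(values)], genes

    def test_flat_metagene_identity(self):
        profs, genes = self._genes_with_elevation(a=0.0, lam=60.0)
        with pytest.warns(UserWarning):
            model = fit_decay_model(profs, genes)
        assert model.a == 0.0

    def test_parameter_recovery(self):
        profs, genes = self._genes_with_elevation(a=2.0, lam=60.0)
        model = fit_decay_model(profs, genes)
        assert model.a == pytest.approx(2.0, rel=0.1)
        assert model.lam == pytest.approx(60.0, rel=0.1)

    def test_correction_at_zero_is_one_plus_a(self):
        model = DecayModel(a=2.0, lam=60.0)
        assert float(model(0.0)) == pytest.approx(3.0)

    def test_too_few_genes_raises(self):
        profs, genes = self._genes_with_elevation(a=1.0, lam=50.0, n_genes=5)
        with pytest.raises(ValueError):
            fit_decay_model(profs, genes)


class TestSteadyStateMrna:
    def test_unity(self):
        prof = flux_profile(np.full(200, GAMMA))
        assert steady_state_mrna(prof, gene(50, 150), GAMMA) == pytest.approx(1.0)

    def test_zero_flux(self):
        prof = flux_profile(np.zeros(200))
        assert steady_state_mrna(prof, gene(50, 150), GAMMA) == 0.0

    def test_ramp_window_oracle(self):
        v = np.arange(200, dtype=float)
        prof = flux_profile(v)
        expected = v[140:150].mean() / GAMMA
        assert steady_state_mrna(prof, gene(50, 150), GAMMA) == pytest.approx(expected)

    def test_window_shift(self):
        v = np.arange(400, dtype=float)
        prof = flux_profile(v)
        expected = v[200 - 160 : 200 - 150].mean() / GAMMA
        assert steady_state_mrna(
            prof, gene(0, 200), GAMMA, window_shift=150
        ) == pytest.approx(expected)

    def test_window_outside_gene_raises(self):
        prof = flux_profile(np.ones(100))
        with pytest.raises(ValueError):
            steady_state_mrna(prof, gene(50, 56), GAMMA)

    def test_arbitrary_units_rejected(self):
        prof = StrandedProfile("ref", "+", np.ones(100), UNIT_ARB_FLUX)
        with pytest.raises(ValueError):
            steady_state_mrna(prof, gene(0, 100), GAMMA)

    def test_antisense_window_at_gene_start(self):
        v = np.arange(200, dtype=float)
        prof = flux_profile(v, strand="-")
        expected = v[50:60].mean() / GAMMA
        assert steady_state_mrna(prof, gene(50, 150, strand="-"), GAMMA) == pytest.approx(
            expected
        )


class TestTranslationEfficiency:
    def test_unity(self):
        assert translation_efficiency(1.0, 15.0) == pytest.approx(1.0)

    def test_zero_rd(self):
        assert translation_efficiency(0.0, 3.0) == 0.0

    def test_h1_scale_value(self):
        # RD and m_ss back-solved from the TE formula; matches the strongest
        # RBS scale (14.5 proteins/s per mRNA)
        assert translation_efficiency(0.9667, 1.0) == pytest.approx(14.5, abs=0.01)

    def test_zero_mrna_is_nan(self):
        assert np.isnan(translation_efficiency(1.0, 0.0))

    def test_round_trip_identity(self, rng):
        consts = TranslationConstants()
        for _ in range(20):
            rd = float(rng.random() * 5)
            m_ss = float(rng.random() * 100 + 0.1)
            te = translation_efficiency(rd, m_ss, consts)
            assert te * m_ss / consts.omega == pytest.approx(rd)


class TestRibosomeUsage:
    def test_uniform(self):
        prof = occ_profile(np.full(400, 0.1))
        assert ribosome_usage(prof, gene(50, 350)) == pytest.approx(30.0)

    def test_zero(self):
        assert ribosome_usage(occ_profile(np.zeros(100)), gene(0, 100)) == 0.0

    def test_sum_oracle(self, rng):
        v = rng.random(300)
        prof = occ_profile(v)
        assert ribosome_usage(prof, gene(37, 203)) == pytest.approx(sum(v[37:203]))


class TestProteomeFraction:
    def test_single_gene(self):
        np.testing.assert_allclose(proteome_fraction([2.0], [50000.0]), [1.0])

    def test_two_equal(self):
        np.testing.assert_allclose(
            proteome_fraction([1.0, 2.0], [60000.0, 30000.0]), [0.5, 0.5]
        )

    def test_normalization_oracle(self, rng):
        rd = rng.random(100)
        mw = rng.uniform(2e4, 1.2e5, 100)
        phi = proteome_fraction(rd, mw)
        expected = np.array([r * m for r, m in zip(rd, mw)])
        expected /= expected.sum()
        np.testing.assert_allclose(phi, expected)
        assert abs(phi.sum() - 1.0) < 1e-12

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            proteome_fraction([0.0, 0.0], [1.0, 1.0])

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            proteome_fraction([-1.0], [1.0])


class TestOfftargetScreen:
    def states_frame(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2", "s3", "s4"]).rename_axis("gene")

    def test_tenfold_flagged(self):
        table = pd.DataFrame(
            {"s_on": [1.0], "s_off": [10.0]}, index=["geneA"]
        )
        out = offtarget_screen(table, ["s_on"])
        assert list(out.index) == ["geneA"]
        assert out.loc["geneA", "fold_repression"] == pytest.approx(10.0)

    def test_twofold_not_flagged(self):
        table = pd.DataFrame({"s_on": [1.0], "s_off": [2.0]}, index=["geneA"])
        assert offtarget_screen(table, ["s_on"]).empty

    def test_zero_on_mean_infinite_fold(self):
        table = pd.DataFrame({"s_on": [0.0], "s_off": [3.0]}, index=["geneA"])
        out = offtarget_screen(table, ["s_on"])
        assert np.isinf(out.loc["geneA", "fold_repression"])

    def test_empty_subgroup_raises(self):
        table = pd.DataFrame({"s_on": [1.0]}, index=["geneA"])
        with pytest.raises(ValueError):
            offtarget_screen(table, ["s_on"])

    def test_planted_responders_recovered(self, rng):
        n = 500
        states = [f"st{i}" for i in range(8)]
        on_states = states[:4]
        base = rng.lognormal(0.0, 0.3, size=(n, 8))
        table = pd.DataFrame(base, columns=states, index=[f"g{i}" for i in range(n)])
        planted = ["g10", "g200", "g499"]
        for name in planted:
            table.loc[name, on_states] /= 10.0
        out = offtarget_screen(table, on_states)
        assert sorted(out.index) == sorted(planted)


class TestSyntheticConsistency:
    def test_te_round_trip_noise_free(self):
        # occupancy planted as TE*m_ss/omega uniform over a gene
        consts = TranslationConstants()
        te_planted, m_ss = 14.5, 3.0
        density = te_planted * m_ss / consts.omega
        occ = occ_profile(np.full(600, density))
        g = gene(100, 500)
        rd = compute_rd(occ, g, winsorize=False)
        flux = flux_profile(np.full(600, m_ss * consts.gamma))
        m_hat = steady_state_mrna(flux, g, consts.gamma)
        te = translation_efficiency(rd, m_hat, consts)
        assert te == pytest.approx(te_planted, rel=0.01)
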