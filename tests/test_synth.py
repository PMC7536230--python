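import numpy as np
import pytest

from circuitflux import synth
from circuitflux.io import CircuitAnnotation, Part
from circuitflux.metrics import (
    DecayModel,
    GeneInterval,
    fit_decay_model,
    proteome_fraction,
)
from circuitflux.part_calling import ribozyme_ce
from circuitflux.profiles import SENSE, build_transcript_profile, map_psites_center_weighted
from circuitflux.synth import (
    forward_flux,
    forward_occupancy,
    generate_bundle,
    generate_genome_background,
    nominal_annotation,
    sample_fragments,
    transcript_classes,
)


def simple_annotation(T=None, eta=None, two_promoters=False):
    parts = [Part("P1", "promoter", "chr", 70, 100, "+")]
    if two_promoters:
        parts.append(Part("P2", "promoter", "chr", 130, 160, "+"))
    if eta is not None:
        site = (160 if two_promoters else 100) + 10
        parts.append(Part("rz", "ribozyme", "chr", site - 10, site, "+"))
    if T is not None:
        parts.append(Part("t1", "terminator", "chr", 600, 625, "+"))
    return CircuitAnnotation({"chr": 1000}, parts)


class TestForwardFlux:
    def test_single_promoter_step(self):
        ann = simple_annotation()
        classes = transcript_classes(ann, {"P1": 0.7}, {}, {})
        flux = forward_flux(classes, ann.reference_lengths)
        v = flux[("chr", "+")].values
        assert np.all(v[:100] == 0)
        np.testing.assert_allclose(v[100:], 0.7)

    def test_promoter_then_terminator(self):
        ann = simple_annotation(T=50.0)
        classes = transcript_classes(ann, {"P1": 0.7}, {}, {"t1": 50.0})
        flux = forward_flux(classes, ann.reference_lengths)
        v = flux[("chr", "+")].values
        np.testing.assert_allclose(v[100:600], 0.7)
        np.testing.assert_allclose(v[600:], 0.7 / 50.0)

    def test_ribozyme_loss_zone(self):
        ann = simple_annotation(eta=0.9)
        classes = transcript_classes(ann, {"P1": 1.0}, {"rz": 0.9}, {})
        flux = forward_flux(classes, ann.reference_lengths)
        v = flux[("chr", "+")].values
        # short 5' product lost: only uncleaved molecules seen before the site
        np.testing.assert_allclose(v[100:110], 0.1)
        np.testing.assert_allclose(v[110:], 1.0)

    def test_far_promoter_cleavage_product_retained(self):
        ann = simple_annotation(eta=0.9, two_promoters=True)
        classes = transcript_classes(
            ann, {"P1": 1.0, "P2": 2.0}, {"rz": 0.9}, {}
        )
        flux = forward_flux(classes, ann.reference_lengths)
        v = flux[("chr", "+")].values
        np.testing.assert_allclose(v[100:160], 1.0)  # P1 5' piece retained
        np.testing.assert_allclose(v[160:170], 1.0 + 0.1 * 2.0)  # P2 piece lost
        np.testing.assert_allclose(v[170:], 3.0)

    def test_nominal_gate_regions_equal_steady_state(self, nominal_model):
        state = (0, 0, 0)
        bundle = generate_bundle(
            nominal_model, state, seed=0, depth=1e3, sample_footprints=False
        )
        m, R, y = nominal_model.steady_state(state)
        J = nominal_model.fluxes(R, nominal_model.sensor_values(state))
        for i, gate in enumerate(nominal_model.gate_names):
            info = bundle.truth.genes[gate]
            prof = bundle.flux[(info["reference"], info["strand"])]
            assert prof.values[info["end"] - 1] == pytest.approx(J[i], rel=1e-9)


class TestSampleFragments:
    def test_determinism(self, nominal_model):
        b1 = generate_bundle(nominal_model, (1, 0, 0), seed=7, depth=1e4)
        b2 = generate_bundle(nominal_model, (1, 0, 0), seed=7, depth=1e4)
        for ref in b1.fragments:
            np.testing.assert_array_equal(
                b1.fragments[ref].starts, b2.fragments[ref].starts
            )
            np.testing.assert_array_equal(
                b1.fragments[ref].ends, b2.fragments[ref].ends
            )

    def test_eta_one_no_spanning(self, rng):
        ann = simple_annotation(eta=1.0)
        classes = transcript_classes(ann, {"P1": 1.0}, {"rz": 1.0}, {})
        frags = sample_fragments(classes, 5e4, rng)["chr"]
        ce = ribozyme_ce(frags, 110, "+")
        assert ce.f_uncut == 0
        assert ce.ce == pytest.approx(1.0)

    def test_eta_zero_near_zero_ce(self, rng):
        # only chance starts/ends at the site contribute to F_cut
        ann = simple_annotation(eta=0.0)
        classes = transcript_classes(ann, {"P1": 1.0}, {"rz": 0.0}, {})
        frags = sample_fragments(classes, 5e4, rng)["chr"]
        ce = ribozyme_ce(frags, 110, "+")
        assert ce.ce < 0.12

    def test_recovery_within_binomial_ci(self, rng):
        eta = 0.89
        ann = simple_annotation(eta=eta)
        classes = transcript_classes(ann, {"P1": 1.0}, {"rz": eta}, {})
        frags = sample_fragments(classes, 1e5, rng)["chr"]
        sense, _ = build_transcript_profile(frags, 1000)
        assert sense.values[500] > 0  # profile built from the same fragments
        ce = ribozyme_ce(frags, 110, "+")
        n = ce.f_cut + ce.f_uncut
        half = 2.576 * np.sqrt(eta * (1 - eta) / n)
        # allow for the known chance-abutter offset in the estimator
        chance = 2 * np.mean(1.0 / np.arange(10, 46))
        expected = (eta + (1 - eta) * chance) / (eta + (1 - eta) * (1 + chance / 2))
        assert abs(ce.ce - expected) < half

    def test_expectation_matches_forward_profile(self, rng):
        # averaged over seeds the sampled coverage converges to the
        # forward shape (relative L1 over covered positions < 2%)
        ann = simple_annotation(T=25.0)
        classes = transcript_classes(ann, {"P1": 1.0}, {}, {"t1": 25.0})
        flux = forward_flux(classes, ann.reference_lengths)[("chr", "+")].values
        acc = np.zeros(1000)
        n_seeds = 40
        for seed in range(n_seeds):
            frags = sample_fragments(
                classes, 1e6, np.random.default_rng(seed)
            )["chr"]
            sense, _ = build_transcript_profile(frags, 1000)
            acc += sense.values
        mean_profile = acc / n_seeds
        covered = flux > 0
        scale = flux[covered].sum() / mean_profile[covered].sum()
        l1 = np.abs(mean_profile[covered] * scale - flux[covered]).sum()
        assert l1 / flux[covered].sum() < 0.02


class TestForwardOccupancy:
    def test_zero_alpha_no_footprints(self, rng):
        genes = [(GeneInterval("chr", 100, 700, SENSE), 0.0, 5.0)]
        fps, occ = forward_occupancy(genes, {"chr": 1000}, rng)
        assert fps == {}
        assert occ[("chr", "+")].values.sum() == 0

    def test_planted_te_round_trip_exact_expectation(self):
        alpha, m_ss = 14.5, 3.0
        genes = [(GeneInterval("chr", 100, 700, SENSE), alpha, m_ss)]
        _, occ = forward_occupancy(genes, {"chr": 1000}, np.random.default_rng(0))
        density = occ[("chr", "+")].values[400]
        assert density == pytest.approx(alpha * m_ss / 15.0)

    def test_footprints_reconstruct_occupancy(self, rng):
        alpha, m_ss = 2.0, 50.0
        genes = [(GeneInterval("chr", 100, 700, SENSE), alpha, m_ss)]
        fps, occ = forward_occupancy(
            genes, {"chr": 1000}, rng, footprints_per_ribosome=200.0
        )
        mapped, _ = map_psites_center_weighted(fps["chr"], 1000)
        planted = occ[("chr", "+")].values
        # compare interior shape (edges are smoothed by the center window)
        interior = slice(150, 650)
        scale = planted[interior].sum() / mapped.values[interior].sum()
        rel = np.abs(
            mapped.values[interior] * scale - planted[interior]
        ).sum() / planted[interior].sum()
        assert rel < 0.05

    def test_decay_elevation_recovered_by_fit(self):
        rng = np.random.default_rng(3)
        elevation = DecayModel(a=2.0, lam=60.0)
        genes = []
        lengths = {"chr": 40000}
        for i in range(40):
            start = 100 + i * 900
            genes.append((GeneInterval("chr", start, start + 600, SENSE), 1.0, 30.0))
        fps, _ = forward_occupancy(
            genes, lengths, rng, footprints_per_ribosome=10.0, elevation=elevation
        )
        mapped, _ = map_psites_center_weighted(fps["chr"], 40000)
        intervals = [GeneInterval("chr", g.start, g.end, "+") for g, _, _ in genes]
        model = fit_decay_model([mapped], intervals)
        # center-weighted mapping smooths the 5' elevation over ~20 nt, so
        # raw (a, lam) are biased; the correction *function* is recovered
        d = np.arange(0, 300, dtype=float)
        fitted = np.asarray(model(d))
        planted = np.asarray(elevation(d))
        assert np.max(np.abs(fitted - planted) / planted) < 0.10


class TestGenomeBackground:
    def test_single_gene_full_proteome(self, rng):
        table, _, _ = generate_genome_background(1, rng)
        phi = proteome_fraction(table["rd"], table["mw"])
        assert phi[0] == pytest.approx(1.0)

    def test_planted_responder_flagged(self, rng):
        from circuitflux.metrics import offtarget_screen

        states = [f"s{i}" for i in range(8)]
        table, _, _ = generate_genome_background(
            200,
            rng,
            planted_responders=[("g0010", 10.0)],
            states=states,
            repressor_on_states=states[:4],
        )
        rd_table = table.set_index("name")[[f"rd_{s}" for s in states[:4]] + [f"rd_{s}" for s in states[4:]]]
        rd_table.columns = states
        flagged = offtarget_screen(rd_table, states[:4])
        assert list(flagged.index) == ["g0010"]

    def test_median_expression_ratio_configurable(self, rng, nominal_model):
        # circuit genes are generated far above the genome background
        bundle = generate_bundle(
            nominal_model, (1, 0, 0), seed=5, depth=1e5, sample_footprints=False
        )
        circuit_m = np.median(
            [info["m_ss"] for info in bundle.truth.genes.values()]
        )
        target_ratio = 220.0
        mu = float(np.log(circuit_m / target_ratio))
        table, _, _ = generate_genome_background(501, rng, fpkm_lognorm=(mu, 0.8))
        ratio = circuit_m / np.median(table["fpkm"])
        assert ratio == pytest.approx(target_ratio, rel=0.2)

    def test_invalid_n_genes(self, rng):
        with pytest.raises(ValueError):
            generate_genome_background(0, rng)


class TestBundle:
    def test_determinism_full_bundle(self, nominal_model):
        b1 = generate_bundle(nominal_model, (0, 1, 1), seed=11, depth=2e4)
        b2 = generate_bundle(nominal_model, (0, 1, 1), seed=11, depth=2e4)
        for key in b1.flux:
            np.testing.assert_array_equal(b1.flux[key].values, b2.flux[key].values)
        for ref in b1.footprints:
            np.testing.assert_array_equal(
                b1.footprints[ref].starts, b2.footprints[ref].starts
            )

    def test_annotation_part_counts(self):
        ann = nominal_annotation()
        assert len(ann.of_kind("promoter")) == 12
        assert len(ann.of_kind("terminator")) == 8
        assert len(ann.of_kind("ribozyme")) == 8
        assert len(ann.of_kind("CDS")) == 8

    def test_planted_occupancy_sums_to_ribosome_pool(self, nominal_model):
        bundle = generate_bundle(nominal_model, (1, 0, 0), seed=2, depth=1e4)
        total = sum(p.values.sum() for p in bundle.occupancy.values())
        assert total == pytest.approx(20000.0, rel=1e-9)
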