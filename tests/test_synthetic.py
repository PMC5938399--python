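"""Generator determinism, exactness of planted quantities, cohort statistics."""

import numpy as np
import pytest

from projquant import (
    SpecError,
    SyntheticCohortSpec,
    SyntheticNeuronSpec,
    cable_length,
    count_branch_points,
    count_stems,
    generate_bulk_density,
    generate_cohort,
    generate_neuron,
    quantify_projection,
    split_into_sections,
)
from projquant.synthetic import DEFAULT_CLASS_PARAMS


class TestGenerateNeuron:
    def test_same_seed_bit_identical(self, model):
        spec = SyntheticNeuronSpec(
            collaterals=[("wS2", 12.0, True), ("Striatum", 8.0, True)],
            rng_seed=7,
        )
        a, _ = generate_neuron(spec, model)
        b, _ = generate_neuron(spec, model)
        assert np.array_equal(a.xyz, b.xyz)
        assert np.array_equal(a.parent_index, b.parent_index)
        assert np.array_equal(a.types, b.types)

    @pytest.mark.parametrize(
        "stems,branches,length", [(8, 64, 8.1), (5, 30, 6.0), (12, 64, 9.5)]
    )
    def test_dendritic_targets_exact(self, model, stems, branches, length):
        spec = SyntheticNeuronSpec(
            n_stems=stems,
            n_dendrite_branch_points=branches,
            dendrite_length_mm=length,
            local_axon_mm=5.0,
            rng_seed=1,
        )
        n, _ = generate_neuron(spec, model)
        assert count_stems(n, "dendrite") == stems
        assert count_branch_points(n, "dendrite") == branches
        assert cable_length(n, "dendrite") == pytest.approx(length, rel=1e-9)

    def test_generator_and_quantifier_agree(self, model):
        """Central cross-validation: planted profile equals quantified profile."""
        spec = SyntheticNeuronSpec(
            collaterals=[
                ("wS2", 12.0, True),
                ("wM1/2", 20.8, True),
                ("TeA", 7.7, True),
                ("Striatum", 16.9, True),
                ("PL1", 1.5, True),
            ],
            passing_fibers=[("PP", 2.0)],
            rng_seed=13,
        )
        neuron, gt = generate_neuron(spec, model)
        got = quantify_projection(neuron, model)
        for r in model.names:
            assert got.region_lengths[r] == pytest.approx(
                gt.region_lengths[r], abs=1e-6
            )
            assert got.passing_lengths[r] == pytest.approx(
                gt.passing_lengths[r], abs=1e-6
            )
        assert got.elsewhere_length == pytest.approx(gt.elsewhere_length, abs=1e-6)
        assert got.total_axon_length == pytest.approx(
            gt.total_axon_length, abs=1e-6
        )
        assert got.total_axon_length == pytest.approx(
            cable_length(neuron, "axon"), abs=1e-9
        )

    def test_zero_collaterals_nothing_outside_ws1(self, model):
        n, gt = generate_neuron(SyntheticNeuronSpec(rng_seed=2), model)
        outside = {
            r: v for r, v in gt.region_lengths.items() if r != "wS1" and v > 0
        }
        assert outside == {}
        assert sum(gt.passing_lengths.values()) == 0.0

    def test_infeasible_dendrites_rejected(self, model):
        with pytest.raises(SpecError):
            generate_neuron(
                SyntheticNeuronSpec(
                    dendrite_length_mm=0.5, n_dendrite_branch_points=64,
                    rng_seed=0,
                ),
                model,
            )

    def test_unknown_region_rejected(self, model):
        with pytest.raises(SpecError, match="not in model"):
            generate_neuron(
                SyntheticNeuronSpec(collaterals=[("V1", 5.0, True)],
                                    rng_seed=0),
                model,
            )

    def test_soma_outside_ws1_rejected(self, model):
        with pytest.raises(SpecError, match="wS1"):
            generate_neuron(
                SyntheticNeuronSpec(soma=(0.0, 0.0, 0.2), rng_seed=0), model
            )


class TestGenerateCohort:
    def test_s2p_never_projects_to_wm12(self, cohort):
        for prof, label in zip(cohort.profiles, cohort.labels):
            if label == "S2p":
                assert prof.region_lengths["wM1/2"] == 0.0
                assert prof.region_lengths["wS2"] > 0.0

    def test_class_defining_inequality_holds(self, cohort):
        for prof, label in zip(cohort.profiles, cohort.labels):
            s2, m1 = prof.region_lengths["wS2"], prof.region_lengths["wM1/2"]
            assert (s2 > m1) == (label == "S2p")

    def test_core_fraction_floor_respected(self, cohort):
        from projquant import core_fraction

        for prof in cohort.profiles:
            assert core_fraction(prof) > 0.75

    def test_empty_cohort(self, model):
        c = generate_cohort(SyntheticCohortSpec(n_s2p=0, n_m1p=0), model)
        assert c.neurons == [] and c.labels == []

    def test_determinism(self, model):
        a = generate_cohort(SyntheticCohortSpec(n_s2p=1, n_m1p=1, rng_seed=5),
                            model)
        b = generate_cohort(SyntheticCohortSpec(n_s2p=1, n_m1p=1, rng_seed=5),
                            model)
        for na, nb in zip(a.neurons, b.neurons):
            assert np.array_equal(na.xyz, nb.xyz)

    def test_ws1_sampling_mean_within_two_se(self, model):
        """Empirical planted wS1 cable over a large cohort converges to the
        configured class mean (~1/sqrt(n))."""
        n = 200
        c = generate_cohort(SyntheticCohortSpec(n_s2p=n, n_m1p=0, rng_seed=3),
                            model)
        vals = np.array([p.region_lengths["wS1"] for p in c.profiles])
        mu, sd, _, _ = DEFAULT_CLASS_PARAMS["S2p"]["wS1"]
        assert abs(vals.mean() - mu) < 2 * sd / np.sqrt(n)


class TestSplitIntoSections:
    def test_cable_conserved_exactly(self, cohort):
        n = cohort.neurons[0]
        stack = split_into_sections(n, 0.08, jitter_mm=0.02, seed=4)
        frag = sum(s.fragment.edge_lengths().sum() for s in stack.sections)
        assert frag == pytest.approx(n.edge_lengths().sum(), rel=1e-9)

    def test_fragment_dv_within_section(self, cohort):
        stack = split_into_sections(cohort.neurons[0], 0.08)
        for s in stack.sections:
            dv = s.fragment.xyz[:, 2]
            assert dv.min() >= -1e-9
            assert dv.max() <= 0.08 + 1e-9


class TestBulkDensity:
    def test_determinism(self, model):
        a = generate_bulk_density(n_animals=1, model=model, seed=9)
        b = generate_bulk_density(n_animals=1, model=model, seed=9)
        assert np.array_equal(a.volumes[0].values, b.volumes[0].values)
        assert np.array_equal(
            a.planted_centers["wS2"], b.planted_centers["wS2"]
        )

    def test_mass_per_animal(self, model):
        res = generate_bulk_density(n_animals=2, model=model, seed=1,
                                    mass_mm=10.0)
        for vol in res.volumes:
            assert vol.total_mass() == pytest.approx(110.0, rel=1e-9)
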