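"""Projection profiles, thresholded matrix, classification, core fraction."""

import numpy as np
import pytest

from projquant import (
    MorphologyBuilder,
    ProjectionProfile,
    RegionDef,
    RegionModel,
    SyntheticNeuronSpec,
    classify_length,
    classify_projection_class,
    core_fraction,
    default_region_model,
    generate_neuron,
    group_summary,
    quantify_projection,
    threshold_matrix,
)
from projquant.morphology import ROOT_PARENT, SOMA, FrameError
from projquant.morphometry import MorphometrySummary
from projquant.projection import UndefinedResultError


def _profile(neuron_id="x", **lengths):
    regions = ["wS1", "wS2", "wM1/2", "Striatum", "TeA"]
    rl = {r: float(lengths.get(r, 0.0)) for r in regions}
    total = sum(rl.values())
    return ProjectionProfile(neuron_id, rl, {r: 0.0 for r in regions}, 0.0, total)


class TestQuantify:
    def test_planted_ws2_collateral_recovered(self, model):
        spec = SyntheticNeuronSpec(
            neuron_id="w", collaterals=[("wS2", 12.0, True)], rng_seed=2
        )
        neuron, gt = generate_neuron(spec, model)
        prof = quantify_projection(neuron, model)
        assert prof.region_lengths["wS2"] == pytest.approx(12.0, abs=1e-6)
        assert prof.region_lengths["wS1"] == pytest.approx(
            gt.region_lengths["wS1"], abs=1e-6
        )
        # nothing branching anywhere else
        others = [
            v for r, v in prof.region_lengths.items() if r not in ("wS1", "wS2")
        ]
        assert max(others) == 0.0

    def test_unbranched_crossing_fiber_is_passing(self):
        """A single unbranched fiber through a region (amygdala-like box)
        counts as passing cable, never as a projection target."""
        model = default_region_model()
        amygdala = RegionDef("Amygdala", "box", -2.6, 0.3, 0.4, 0.4, 2.0, 3.0, 20)
        model = RegionModel([*model.regions, amygdala], model.injection_site)
        spec = SyntheticNeuronSpec(
            neuron_id="ty310-like",
            passing_fibers=[("Amygdala", 5.0)],
            rng_seed=4,
        )
        neuron, gt = generate_neuron(spec, model)
        prof = quantify_projection(neuron, model)
        assert gt.passing_lengths["Amygdala"] == pytest.approx(5.0)
        assert prof.region_lengths["Amygdala"] == 0.0
        assert prof.passing_lengths["Amygdala"] == pytest.approx(5.0, abs=1e-6)

    def test_soma_only_neuron_all_zero(self, model):
        b = MorphologyBuilder("soma_only")
        b.add_node(ROOT_PARENT, SOMA, (-3.02, -1.65, 0.22))
        prof = quantify_projection(b.build(), model)
        assert prof.total_axon_length == 0.0
        assert max(prof.region_lengths.values()) == 0.0

    def test_requires_bregma_frame(self, model):
        b = MorphologyBuilder("f", frame="section-local")
        b.add_node(ROOT_PARENT, SOMA, (0, 0, 0))
        with pytest.raises(FrameError):
            quantify_projection(b.build(), model)

    def test_conservation_invariant(self, model, cohort):
        for n in cohort.neurons[:3]:
            p = quantify_projection(n, model)
            assigned = (
                sum(p.region_lengths.values())
                + sum(p.passing_lengths.values())
                + p.elsewhere_length
            )
            assert assigned == pytest.approx(p.total_axon_length, rel=1e-9)


class TestThresholds:
    def test_striatal_12_5_is_dark(self):
        assert classify_length(12.5) == "dark"

    def test_boundaries_fall_to_lower_class(self):
        assert classify_length(10.0) == "light"
        assert classify_length(1.0) == "none"
        assert classify_length(0.0) == "none"

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_length(5.0, light_mm=-1.0)
        with pytest.raises(ValueError):
            classify_length(5.0, light_mm=10.0, dark_mm=1.0)

    def test_monotone_in_length(self):
        rank = {"none": 0, "light": 1, "dark": 2}
        lengths = np.linspace(0, 20, 200)
        classes = [rank[classify_length(v)] for v in lengths]
        assert all(b >= a for a, b in zip(classes, classes[1:]))

    def test_matrix_layout(self):
        profiles = [_profile("a", wS2=12.0), _profile("b", wS2=3.0, wS1=40.0)]
        m = threshold_matrix(profiles)
        df = m.to_frame()
        assert df.loc["a", "wS2"] == "dark"
        assert df.loc["b", "wS2"] == "light"
        assert df.loc["b", "wS1"] == "dark"
        assert df.loc["a", "Striatum"] == "none"

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            threshold_matrix([])


class TestClassification:
    def test_dominant_ws2_is_s2p(self):
        assert classify_projection_class(_profile(wS2=12.2)) == "S2p"

    def test_dominant_wm12_is_m1p(self):
        assert classify_projection_class(_profile(**{"wS2": 1.6, "wM1/2": 20.8})) \
            == "M1p"

    def test_tie_and_empty_unclassified(self):
        assert classify_projection_class(_profile()) == "unclassified"
        assert classify_projection_class(
            _profile(**{"wS2": 2.0, "wM1/2": 2.0})
        ) == "unclassified"

    def test_missing_regions_rejected(self):
        p = ProjectionProfile("p", {"wS1": 1.0}, {"wS1": 0.0}, 0.0, 1.0)
        with pytest.raises(ValueError, match="lacks region"):
            classify_projection_class(p)

    def test_scale_invariance(self):
        base = _profile(**{"wS2": 3.0, "wM1/2": 1.0, "Striatum": 9.0})
        for c in (0.01, 1.0, 250.0):
            scaled = _profile(
                **{"wS2": 3.0 * c, "wM1/2": 1.0 * c, "Striatum": 9.0 * c}
            )
            assert classify_projection_class(scaled) == \
                classify_projection_class(base)


class TestCoreFraction:
    def test_all_cable_in_ws1(self):
        assert core_fraction(_profile(wS1=40.0)) == pytest.approx(1.0)

    def test_arithmetic(self):
        p = _profile(wS1=40.0, wS2=12.0, Striatum=8.0)
        assert core_fraction(p) == pytest.approx(52.0 / 60.0)

    def test_zero_denominator(self):
        with pytest.raises(UndefinedResultError):
            core_fraction(_profile())


class TestGroupSummary:
    @staticmethod
    def _summary(nid, dend=8.0):
        return MorphometrySummary(nid, dend, 8, 60, 70.0)

    def test_single_neuron_group_sd_flagged(self):
        profiles = [_profile("a", wS2=12.0), _profile("b", wS2=10.0),
                    _profile("c", **{"wM1/2": 20.0})]
        summaries = [self._summary(p.neuron_id) for p in profiles]
        g = group_summary(profiles, summaries, ["S2p", "S2p", "M1p"])
        assert g.loc["S2p", "branching_wS2_mm_mean"] == pytest.approx(11.0)
        assert g.loc["M1p", "branching_wS2_mm_n"] == 1
        assert np.isnan(g.loc["M1p", "branching_wS2_mm_sd"])

    def test_recovers_sampling_mean_within_two_se(self):
        rng = np.random.default_rng(0)
        mu, sd, n = 12.0, 7.0, 100
        vals = np.abs(rng.normal(mu, sd, n))
        profiles = [_profile(f"n{i}", wS2=v) for i, v in enumerate(vals)]
        summaries = [self._summary(p.neuron_id) for p in profiles]
        g = group_summary(profiles, summaries, ["S2p"] * n)
        se = sd / np.sqrt(n)
        assert abs(g.loc["S2p", "branching_wS2_mm_mean"] - vals.mean()) < 1e-12
        assert abs(vals.mean() - mu) < 2 * se + 0.2  # sanity on the construction

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            group_summary([_profile("a")], [], ["S2p"])
        with pytest.raises(ValueError):
            group_summary([], [], [])
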