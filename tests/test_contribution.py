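import numpy as np
import pytest

from widefield_mc.contribution import (
    DffScenario,
    apply_dff_scenario,
    cumulative_contour_volumes,
    fluorescence_by_depth,
)
from widefield_mc.expression import (
    DEFAULT_LAYER_BOUNDARIES,
    LAYER_NAMES,
    ExpressionProfile,
    synthetic_profile,
)

_GRID = np.arange(0.005, 1.0, 0.01)


def _flat_profile():
    return ExpressionProfile("flat", np.array([0.0, 1.0]), np.array([1.0, 1.0]))


def _unit_curve():
    return (_GRID, np.ones_like(_GRID))


class TestFluorescenceByDepth:
    def test_flat_inputs_reproduce_thickness_fractions(self):
        w = fluorescence_by_depth(_unit_curve(), _flat_profile(), _unit_curve())
        fractions = DEFAULT_LAYER_BOUNDARIES.thickness_fractions()
        for name in LAYER_NAMES:
            assert w.layer_percentages[name] == pytest.approx(
                100 * fractions[name], abs=0.5
            )

    def test_percentages_sum_exactly_to_100(self):
        expr = synthetic_profile("x", ("L2/3",), neuropil_baseline=0.1)
        w = fluorescence_by_depth(_unit_curve(), expr, _unit_curve())
        assert sum(w.layer_percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_single_layer_expression_gets_everything(self):
        lo, hi = DEFAULT_LAYER_BOUNDARIES.span("L4")
        values = ((_GRID >= lo) & (_GRID < hi)).astype(float)
        expr = ExpressionProfile("x", _GRID, values)
        w = fluorescence_by_depth(_unit_curve(), expr, _unit_curve())
        assert w.layer_percentages["L4"] == pytest.approx(100.0)

    def test_scale_invariance(self):
        expr = synthetic_profile("x", ("L5",))
        z, i = _unit_curve()
        w1 = fluorescence_by_depth((z, i), expr, (z, 0.005 * i))
        w2 = fluorescence_by_depth((z, 300 * i), expr, (z, i))
        for name in LAYER_NAMES:
            assert w1.layer_percentages[name] == pytest.approx(
                w2.layer_percentages[name], abs=1e-9
            )

    def test_superficial_line_outweighs_deep_line_in_upper_layers(self):
        """A layer-2/3-4 expression pattern puts most fluorescence in
        L2/3; a layer-6 pattern puts almost none in L1."""
        # weight shallow depths more, as illumination x collection does
        decay = (_GRID, np.exp(-_GRID))
        cux2 = fluorescence_by_depth(decay, synthetic_profile("Cux2", ("L2/3", "L4")),
                                     _unit_curve())
        ntsr1 = fluorescence_by_depth(decay, synthetic_profile("Ntsr1", ("L6",)),
                                      _unit_curve())
        assert max(cux2.layer_percentages, key=cux2.layer_percentages.get) == "L2/3"
        assert cux2.layer_percentages["L1"] > ntsr1.layer_percentages["L1"]


class TestDffScenario:
    @pytest.fixture()
    def weighting(self):
        expr = synthetic_profile("all", tuple(LAYER_NAMES))
        return fluorescence_by_depth(_unit_curve(), expr, _unit_curve())

    def test_identity_scenario_is_noop(self, weighting):
        out = apply_dff_scenario(weighting, DffScenario())
        for name in LAYER_NAMES:
            assert out[name] == pytest.approx(weighting.layer_percentages[name])

    def test_neuropil_ratio_raises_l1_share(self, weighting):
        shares = []
        for r in (1.0, 3.0, 10.0):
            out = apply_dff_scenario(
                weighting, DffScenario(dff_ratio_neuropil_over_soma=r)
            )
            shares.append(out["L1"])
        assert shares[0] < shares[1] < shares[2]
        # the L1 boost is modest: a few times larger neuropil signal only
        # nudges the percentage, since all layers are mostly neuropil
        assert shares[2] < 2 * shares[0]

    def test_layer1_multiplier_raises_share_severalfold(self, weighting):
        out = apply_dff_scenario(weighting, DffScenario(layer1_dff_multiplier=10.0))
        assert out["L1"] > 3 * weighting.layer_percentages["L1"]
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            DffScenario(neuropil_volume_fraction={"L1": 1.2})
        with pytest.raises(ValueError):
            DffScenario(dff_ratio_neuropil_over_soma=0.0)


class TestContourVolumes:
    def test_matches_flatten_sort_oracle_on_toy_grid(self):
        rng = np.random.default_rng(5)
        values = rng.random((10, 10, 10))
        volumes = np.full(values.shape, 1e-6)
        got = cumulative_contour_volumes(values, volumes, (0.25, 0.5, 0.75, 0.9, 0.95))
        flat = np.sort(values.ravel())[::-1]
        total = flat.sum()
        for f, v in got.items():
            k = int(np.searchsorted(np.cumsum(flat) / total, f)) + 1
            assert v == pytest.approx(k * 1e-6)

    def test_contours_non_decreasing(self):
        rng = np.random.default_rng(6)
        values = rng.random(500)
        volumes = rng.random(500) * 1e-3
        got = cumulative_contour_volumes(values, volumes)
        vols = [got[f] for f in sorted(got)]
        assert all(a <= b for a, b in zip(vols, vols[1:]))

    def test_single_hot_voxel_yields_its_volume_at_every_fraction(self):
        values = np.zeros(100)
        values[37] = 5.0
        volumes = np.full(100, 2e-6)
        got = cumulative_contour_volumes(values, volumes, (0.25, 0.5, 0.95))
        assert all(v == pytest.approx(2e-6) for v in got.values())

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            cumulative_contour_volumes(np.array([-1.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            cumulative_contour_volumes(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError):
            cumulative_contour_volumes(np.ones(3), np.ones(3), (1.5,))


class TestSourceVolumeMap:
    @staticmethod
    def _toy_kernel():
        """Analytic per-pixel collection kernel: Gaussian surface spread
        whose width grows with source depth, as scattering produces."""
        from widefield_mc.collection import CollectionKernel

        depths = np.arange(0.05, 1.0, 0.1)
        r_edges = np.arange(0.0, 2.001, 0.01)
        r_mid = r_edges[:-1] + 0.005
        mass = np.empty((depths.size, r_mid.size))
        for i, z in enumerate(depths):
            sigma = 0.05 + 0.8 * z
            dens = np.exp(-(r_mid**2) / (2 * sigma**2))
            annuli = np.pi * np.diff(r_edges**2)
            mass[i] = 0.005 * dens * annuli / (dens * annuli).sum()
        return CollectionKernel(depths=depths, r_edges=r_edges, mass=mass,
                                efficiency=mass.sum(axis=1))

    def test_deep_expression_needs_larger_volume(self):
        """Layer-6 expression collects from a larger 95% volume than
        layer-2/3-4 expression: deep sources spread more laterally."""
        from widefield_mc.contribution import source_volume_map

        kern = self._toy_kernel()
        illum = (np.arange(0.005, 1.0, 0.01),
                 np.exp(-np.arange(0.005, 1.0, 0.01)))
        deep = source_volume_map(illum, synthetic_profile("deep", ("L6",)), kern)
        shallow = source_volume_map(illum, synthetic_profile("shallow", ("L2/3", "L4")), kern)
        assert deep.contour_volumes[0.95] > shallow.contour_volumes[0.95]
        vols = [deep.contour_volumes[f] for f in sorted(deep.contour_volumes)]
        assert all(a <= b for a, b in zip(vols, vols[1:]))
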