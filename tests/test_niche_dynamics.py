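import numpy as np
import pandas as pd
import pytest

from nichedyn.niche_dynamics import (
    DensityGrid,
    EnvSpace,
    conservatism_verdict,
    density_grid,
    fit_env_pca,
    indices_from_sets,
    niche_indices,
    sorensen_from_triple,
    top_loadings,
)
from nichedyn.predictors import SampleMatrix

from conftest import make_matrix


def space_2d(lo=-3.0, hi=3.0, resolution=50):
    return EnvSpace(
        basis=np.eye(2),
        explained=np.array([0.6, 0.4]),
        center=np.zeros(2),
        scale=np.ones(2),
        columns=["a", "b"],
        bounds=np.array([[lo, hi], [lo, hi]]),
        resolution=resolution,
    )


def grid_from_mask(mask: np.ndarray) -> DensityGrid:
    d = mask.astype(float)
    return DensityGrid(d, np.ones_like(d), d, mask.astype(bool), np.array([0.1, 0.1]))


class TestPca:
    def test_two_uncorrelated_columns_split_variance(self):
        rng = np.random.default_rng(0)
        m = make_matrix({"a": rng.normal(size=4000), "b": rng.normal(size=4000)})
        space = fit_env_pca(m)
        assert space.explained[0] == pytest.approx(0.5, abs=0.05)
        assert space.explained[1] == pytest.approx(0.5, abs=0.05)

    def test_duplicated_columns_preserve_axes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = 0.5 * x + rng.normal(size=500)
        single = fit_env_pca(make_matrix({"a": x, "b": y}))
        doubled = fit_env_pca(make_matrix({"a": x, "a2": x, "b": y, "b2": y}))
        # duplicated predictors carry identical loadings on each axis
        lt = doubled.loadings_table
        assert lt.loc["a", "PC1"] == pytest.approx(lt.loc["a2", "PC1"], abs=1e-9)
        # and the score geometry matches the single fit up to scale
        s1 = single.project(make_matrix({"a": x, "b": y}))
        s2 = doubled.project(make_matrix({"a": x, "a2": x, "b": y, "b2": y}))
        corr = np.corrcoef(s1[:, 0], s2[:, 0])[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_background_rejected(self):
        m = make_matrix({"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            fit_env_pca(m)

    def test_dominant_loading_is_positive(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        m = make_matrix({"a": x, "b": -x + 0.01 * rng.normal(size=300)})
        space = fit_env_pca(m)
        for axis in range(2):
            j = np.argmax(np.abs(space.basis[axis]))
            assert space.basis[axis, j] > 0


class TestTopLoadings:
    def space_with(self, pc1, pc2):
        names = sorted(pc1)
        return EnvSpace(
            basis=np.array([[pc1[n] for n in names], [pc2[n] for n in names]]),
            explained=np.array([0.6, 0.3]),
            center=np.zeros(len(names)),
            scale=np.ones(len(names)),
            columns=names,
            bounds=np.array([[-1.0, 1.0], [-1.0, 1.0]]),
        )

    def test_dominant(self):
        sp = self.space_with({"a": 0.9, "b": 0.1}, {"a": 0.1, "b": 0.9})
        assert top_loadings(sp, 1, 1) == ["a"]

    def test_tie_alphabetical(self):
        sp = self.space_with({"a": 0.5, "b": -0.5}, {"a": 0.0, "b": 0.0})
        assert top_loadings(sp, 1, 2) == ["a", "b"]

    def test_k_clamped(self):
        sp = self.space_with({"a": 0.9, "b": 0.1}, {"a": 0.1, "b": 0.9})
        assert top_loadings(sp, 2, 10) == ["b", "a"]

    def test_bad_axis(self):
        sp = self.space_with({"a": 0.9, "b": 0.1}, {"a": 0.1, "b": 0.9})
        with pytest.raises(ValueError):
            top_loadings(sp, 3, 1)


class TestDensityGrid:
    def test_point_mass_occupies_single_cell(self):
        sp = space_2d()
        pt = np.array([[0.03, 0.03]])  # inside one grid cell
        scores = np.repeat(pt, 50, axis=0)
        rng = np.random.default_rng(0)
        bg = rng.uniform(-3, 3, size=(2000, 2))
        g = density_grid(scores, bg, sp, bandwidth=0.01)
        assert g.occupied.sum() == 1

    def test_uniform_background_cancels(self):
        sp = space_2d()
        rng = np.random.default_rng(1)
        scores = rng.normal(0.0, 0.5, size=(3000, 2))
        bg = rng.uniform(-3, 3, size=(20000, 2))
        g = density_grid(scores, bg, sp)
        # with near-uniform availability the corrected density is
        # proportional to the occurrence density over the occupied bulk
        core = g.occ_density > np.quantile(g.occ_density[g.occ_density > 0], 0.6)
        ratio = g.corrected[core] / g.occ_density[core]
        assert np.std(ratio) / np.mean(ratio) < 0.15

    def test_density_normalized(self):
        sp = space_2d()
        rng = np.random.default_rng(2)
        scores = rng.normal(size=(500, 2)).clip(-3, 3)
        bg = rng.uniform(-3, 3, size=(2000, 2))
        g = density_grid(scores, bg, sp)
        assert g.occ_density.sum() == pytest.approx(1.0, abs=1e-6)

    def test_too_few_scores(self):
        sp = space_2d()
        with pytest.raises(ValueError):
            density_grid(np.zeros((3, 2)), np.zeros((10, 2)), sp)

    def test_mass_mode_region_shrinks_with_quantile(self):
        sp = space_2d()
        rng = np.random.default_rng(3)
        scores = rng.normal(0.0, 0.7, size=(2000, 2)).clip(-3, 3)
        bg = rng.uniform(-3, 3, size=(5000, 2))
        sizes = [
            density_grid(scores, bg, sp, threshold_quantile=q, threshold_mode="mass").occupied.sum()
            for q in (0.0, 0.05, 0.25)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2] > 0


class TestNicheIndices:
    def test_worked_example(self):
        nat = {(0, i) for i in (1, 2, 3, 4)}
        intro = {(0, i) for i in (3, 4, 5, 6, 7, 8)}
        idx = indices_from_sets(nat, intro)
        assert (idx.S_cells, idx.U_cells, idx.E_cells) == (2, 2, 4)
        assert (idx.BN, idx.BI) == (4, 6)
        assert idx.BR == pytest.approx(1.5)
        assert idx.SI == pytest.approx(0.4)
        assert idx.E_frac == pytest.approx(2 / 3, abs=1e-3)
        assert idx.U_frac == pytest.approx(0.5)

    def test_identical_sets(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:5, 3:8] = True
        idx = niche_indices(grid_from_mask(mask), grid_from_mask(mask))
        assert idx.E_frac == 0.0 and idx.U_frac == 0.0
        assert idx.BR == 1.0 and idx.SI == 1.0

    def test_matches_brute_force_on_random_grids(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            a = rng.random((20, 20)) < 0.3
            b = rng.random((20, 20)) < 0.3
            if not a.any():
                a[0, 0] = True
            idx = niche_indices(grid_from_mask(a), grid_from_mask(b))
            cells_a = {tuple(c) for c in np.argwhere(a)}
            cells_b = {tuple(c) for c in np.argwhere(b)}
            oracle = indices_from_sets(cells_a, cells_b)
            assert idx == oracle

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.random((15, 15)) < 0.4
        b = rng.random((15, 15)) < 0.4
        a[0, 0] = b[0, 1] = True
        fwd = niche_indices(grid_from_mask(a), grid_from_mask(b))
        rev = niche_indices(grid_from_mask(b), grid_from_mask(a))
        assert fwd.SI == pytest.approx(rev.SI)
        assert fwd.BR == pytest.approx(1.0 / rev.BR)

    def test_empty_native_errors(self):
        empty = np.zeros((5, 5), dtype=bool)
        full = np.ones((5, 5), dtype=bool)
        with pytest.raises(ZeroDivisionError):
            niche_indices(grid_from_mask(empty), grid_from_mask(full))


class TestVerdict:
    @pytest.mark.parametrize(
        "br,si,expected",
        [
            (5.21, 0.32, "not_conserved"),
            (3.53, 0.44, "not_conserved"),
            (1.47, 0.81, "conserved"),
            (1.12, 0.94, "conserved"),
            (1.0, 0.49, "conserved"),   # BR must be strictly greater than 1
            (1.01, 0.5, "conserved"),   # SI must be strictly below 0.5
        ],
    )
    def test_rule(self, br, si, expected):
        idx = indices_from_sets({(0, 0)}, {(0, 0)})
        idx.BR, idx.SI = br, si
        assert conservatism_verdict(idx) == expected


class TestSorensenFromTriple:
    @pytest.mark.parametrize(
        "e,s,u,expected",
        [
            (0.81, 0.19, 0.00, 0.32),
            (0.72, 0.28, 0.00, 0.44),
            (0.32, 0.70, 0.00, 0.81),
        ],
    )
    def test_reported_triples(self, e, s, u, expected):
        assert round(sorensen_from_triple(e, s, u), 2) == expected
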