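"""Gower distances, PCoA, hulls and the FSpe/FIde/FOri indices."""

import numpy as np
import pandas as pd
import pytest

from phenobank import funcdiv as fd
from phenobank.descriptors import DescriptorMatrix, DescriptorMeta, infer_meta

from oracles import gower_cell, hull_vertices_bruteforce


def matrix_from_frame(df, species_map, ordinal_levels=None):
    meta = infer_meta(df, "classical", ordinal_levels=ordinal_levels or {})
    return DescriptorMatrix(
        data=df,
        meta=meta,
        accession=pd.Series(df.index, index=df.index),
        species=pd.Series([species_map[a] for a in df.index], index=df.index),
    )


def numeric_space(points, species_map):
    df = pd.DataFrame(
        np.asarray(points, dtype=float),
        index=list(species_map),
        columns=[f"x{i}" for i in range(np.asarray(points).shape[1])],
    )
    coords = df.copy()
    coords.columns = [f"PCo{i+1}" for i in range(df.shape[1])]
    return coords


class TestGower:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": ["x", "x", "y"]},
                          index=["A", "B", "C"])
        m = matrix_from_frame(df, {"A": "S", "B": "S", "C": "T"})
        d = fd.gower(m)
        assert d.loc["A", "B"] == 0.0
        assert d.loc["A", "A"] == 0.0

    def test_hand_computed_mixed_pair(self):
        df = pd.DataFrame(
            {"num": [0.0, 5.0], "cat": ["x", "y"]}, index=["A", "B"]
        )
        df_ref = pd.DataFrame(
            {"num": [0.0, 5.0, 10.0], "cat": ["x", "y", "x"]},
            index=["A", "B", "C"],
        )
        m = matrix_from_frame(df_ref, {"A": "S", "B": "S", "C": "T"})
        d = fd.gower(m)
        # numeric range 10, delta 5 -> 0.5; nominal mismatch -> 1; mean 0.75
        assert d.loc["A", "B"] == pytest.approx(0.75)

    def test_matches_per_cell_oracle(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(
            {
                "n1": rng.normal(0, 1, 5),
                "n2": rng.uniform(0, 10, 5),
                "cat": rng.choice(["u", "v", "w"], 5),
                "ord": rng.choice(["low", "mid", "high"], 5),
            },
            index=[f"A{i}" for i in range(5)],
        )
        smap = {f"A{i}": "S" for i in range(5)}
        m = matrix_from_frame(df, smap, ordinal_levels={"ord": ("low", "mid", "high")})
        d = fd.gower(m)

        ranks = {"ord": {}}
        levels = ("low", "mid", "high")
        raw = df["ord"].map({l: i + 1.0 for i, l in enumerate(levels)})
        avg = raw.rank(method="average")
        ranks["ord"] = dict(zip(df["ord"], avg))
        tie_counts = {"ord": avg.map(avg.value_counts()).groupby(avg).first().to_dict()}
        ranges = {"n1": np.ptp(df["n1"]), "n2": np.ptp(df["n2"])}
        for i in df.index:
            for j in df.index:
                ref = gower_cell(
                    df.loc[i], df.loc[j], m.meta,
                    ranks=ranks, tie_counts=tie_counts, ranges=ranges,
                )
                assert d.loc[i, j] == pytest.approx(ref, abs=1e-12)

    def test_zero_range_descriptor_dropped_with_warning(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [0.0, 1.0, 2.0]},
                          index=["A", "B", "C"])
        m = matrix_from_frame(df, {"A": "S", "B": "S", "C": "T"})
        with pytest.warns(UserWarning, match="zero-range"):
            d = fd.gower(m)
        assert d.loc["A", "C"] == pytest.approx(1.0)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"a": rng.normal(0, 1, 8), "b": rng.choice(list("xyz"), 8)},
            index=[f"A{i}" for i in range(8)],
        )
        m = matrix_from_frame(df, {f"A{i}": "S" for i in range(8)})
        d = fd.gower(m).to_numpy()
        assert d.min() >= 0 and d.max() <= 1 + 1e-12


class TestPCoA:
    def test_recovers_planar_configuration(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 2], [-1, 0.5]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dist = pd.DataFrame(d, index=list("abcde"), columns=list("abcde"))
        coords, vals = fd.pcoa(dist, n_axes=4)
        rec = np.linalg.norm(
            coords.to_numpy()[:, None] - coords.to_numpy()[None, :], axis=-1
        )
        assert np.allclose(rec, d, atol=1e-8)

    def test_three_equidistant_points_equilateral(self):
        dist = pd.DataFrame(
            1.0 - np.eye(3), index=list("abc"), columns=list("abc")
        )
        coords, vals = fd.pcoa(dist, n_axes=2)
        pos = vals[vals > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1], abs=1e-8)
        rec = np.linalg.norm(
            coords.to_numpy()[:, None] - coords.to_numpy()[None, :], axis=-1
        )
        assert np.allclose(rec[~np.eye(3, dtype=bool)], 1.0, atol=1e-8)

    def test_eigenvalues_nonincreasing(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1, (7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        _, vals = fd.pcoa(pd.DataFrame(d), n_axes=4)
        assert np.all(np.diff(vals) <= 1e-9)

    def test_rejects_single_axis_request(self):
        with pytest.raises(ValueError):
            fd.pcoa(pd.DataFrame(1.0 - np.eye(3)), n_axes=1)


class TestHull:
    def test_square_with_interior_point(self):
        coords = numeric_space(
            [[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]],
            {k: "S" for k in "abcde"},
        )
        area, verts = fd.hull(coords)
        assert area == pytest.approx(1.0)
        assert set(verts) == {"a", "b", "c", "d"}

    def test_triangle_area(self):
        coords = numeric_space([[0, 0], [2, 0], [0, 2]], {k: "S" for k in "abc"})
        area, verts = fd.hull(coords)
        assert area == pytest.approx(2.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(0, 1, (30, 2))
        coords = numeric_space(pts, {f"a{i}": "S" for i in range(30)})
        _, verts = fd.hull(coords)
        ref = hull_vertices_bruteforce(pts)
        assert {f"a{i}" for i in ref} == set(verts)

    def test_collinear_degenerates_with_warning(self):
        coords = numeric_space([[0, 0], [1, 1], [2, 2], [3, 3]],
                               {k: "S" for k in "abcd"})
        with pytest.warns(UserWarning, match="collinear"):
            area, verts = fd.hull(coords)
        assert area == 0.0
        assert set(verts) == {"a", "d"}


class TestIndices:
    def test_fspe_farthest_singleton_is_one(self):
        coords = numeric_space(
            [[0, 0], [0.1, 0], [-0.1, 0], [5, 0]],
            {"a": "S1", "b": "S1", "c": "S1", "d": "S2"},
        )
        fe = pd.Series({"a": "S1", "b": "S1", "c": "S1", "d": "S2"})
        s = fd.fspe(coords, fe)
        assert s["S2"] == pytest.approx(1.0, abs=1e-12)
        assert s.max() == 1.0

    def test_fspe_at_centroid_zero(self):
        coords = numeric_space(
            [[0, 0], [1, 0], [-1, 0]], {"a": "S1", "b": "S2", "c": "S2"}
        )
        fe = pd.Series({"a": "S1", "b": "S2", "c": "S2"})
        s = fd.fspe(coords, fe)
        assert s["S1"] == pytest.approx(0.0, abs=1e-12)

    def test_fspe_symmetric_singletons(self):
        coords = numeric_space([[1, 0], [-1, 0]], {"a": "S1", "b": "S2"})
        fe = pd.Series({"a": "S1", "b": "S2"})
        s = fd.fspe(coords, fe)
        assert s["S1"] == s["S2"] == pytest.approx(1.0)

    def test_fori_isolated_singleton_is_one(self):
        coords = numeric_space(
            [[0, 0], [0.2, 0], [0.1, 0.1], [6, 0]],
            {"a": "S1", "b": "S1", "c": "S2", "d": "S3"},
        )
        fe = pd.Series({"a": "S1", "b": "S1", "c": "S2", "d": "S3"})
        s = fd.fori(coords, fe)
        assert s["S3"] == pytest.approx(1.0, abs=1e-12)
        assert s.max() == 1.0

    def test_fori_identical_accessions_across_fes(self):
        coords = numeric_space(
            [[0, 0], [0, 0], [3, 0]], {"a": "S1", "b": "S2", "c": "S3"}
        )
        fe = pd.Series({"a": "S1", "b": "S2", "c": "S3"})
        s = fd.fori(coords, fe)
        assert s["S1"] == 0.0 and s["S2"] == 0.0

    def test_fori_intra_mean_singleton_missing(self):
        coords = numeric_space(
            [[0, 0], [1, 0], [5, 5]], {"a": "S1", "b": "S1", "c": "S2"}
        )
        fe = pd.Series({"a": "S1", "b": "S1", "c": "S2"})
        s = fd.fori(coords, fe, variant="intra_mean")
        assert np.isnan(s["S2"])
        assert s["S1"] == pytest.approx(1.0)

    def test_fide_centroids_and_linearity(self):
        coords = numeric_space(
            [[-1, 0], [1, 0], [0, 2]], {"a": "S1", "b": "S1", "c": "S2"}
        )
        fe = pd.Series({"a": "S1", "b": "S1", "c": "S2"})
        table = fd.fide(coords, fe)
        assert np.allclose(table.loc["S1"], [0, 0])
        assert np.allclose(table.loc["S2"], [0, 2])
        sizes = fe.value_counts()
        grand = (table.mul(sizes, axis=0)).sum() / sizes.sum()
        assert np.allclose(grand, coords.mean(), atol=1e-10)


class TestModelAndReport:
    @staticmethod
    def _matrices(seed=0, n_extra=5):
        rng = np.random.default_rng(seed)
        accs = [f"A{i}" for i in range(n_extra)] + ["OUT"]
        smap = {a: f"S{i % 2}" for i, a in enumerate(accs[:-1])}
        smap["OUT"] = "S_OUT"
        phe = pd.DataFrame(
            rng.normal(0, 1, (len(accs), 4)),
            index=accs, columns=[f"PC{i}" for i in range(4)],
        )
        cla = pd.DataFrame(
            rng.normal(0, 1, (len(accs), 3)),
            index=accs, columns=[f"t{i}" for i in range(3)],
        )
        phe.loc["OUT"] += 8.0
        cla.loc["OUT"] += 8.0
        return {
            "phenomic": matrix_from_frame(phe, smap),
            "classical": matrix_from_frame(cla, smap),
            "combined": matrix_from_frame(pd.concat([phe, cla], axis=1), smap),
        }

    def test_identical_matrices_identical_tables(self):
        mats = self._matrices()
        table, _ = fd.fd_report(
            {"phenomic": mats["phenomic"], "classical": mats["phenomic"]}
        )
        assert np.allclose(table[("FSpe", "Phe")], table[("FSpe", "Cla")])
        assert np.allclose(table[("FOri", "Phe")], table[("FOri", "Cla")])

    def test_outlier_fe_tops_fspe_in_every_type(self):
        table, results = fd.fd_report(self._matrices())
        for tag in ("Phe", "Cla", "Com"):
            assert table[("FSpe", tag)].idxmax() == "S_OUT"
            assert table[("FSpe", tag)].max() == pytest.approx(1.0)

    def test_vertices_subset_of_accessions(self):
        _, results = fd.fd_report(self._matrices())
        for res in results.values():
            accs = set(res.space.coordinates.index)
            assert set(res.space.hull_vertices) <= accs
            assert len(res.space.hull_vertices) <= len(accs)

    def test_summary_smoke(self):
        _, results = fd.fd_report(self._matrices())
        text = results["phenomic"].summary()
        assert "FSpe" in text and "hull area" in text

    def test_model_from_dataframe(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (6, 3)), index=list("abcdef"),
                          columns=["x", "y", "z"])
        smap = {a: ("S1" if a < "d" else "S2") for a in df.index}
        res = fd.FunctionalDiversityModel.from_dataframe(df, smap).fit()
        assert res.fspe.index.tolist() == ["S1", "S2"]
        assert res.space.coordinates.shape[0] == 6
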