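import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from succnet import io as sio
from succnet.containers import (ClrMatrix, CommunityTable, SampleMetadata,
                                ValidationError, concat_clr)
from succnet.network import build_network, network_stats


class TestCommunityTable:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValidationError):
            CommunityTable(["a"], ["t1", "t2"], np.array([[1, -1]]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValidationError):
            CommunityTable(["a", "a"], ["t"], np.array([[1], [2]]))
        with pytest.raises(ValidationError):
            CommunityTable(["a"], ["t", "t"], np.array([[1, 2]]))

    def test_default_annotations_unknown(self):
        t = CommunityTable(["a"], ["t1"], np.array([[3]]))
        assert t.group == ["unknown"] and t.trophic == ["unknown"]

    def test_select_taxa_keeps_annotations_aligned(self, tiny_table):
        sub = tiny_table.select_taxa(["eukC", "bacA"])
        assert sub.group == ["small_eukaryote", "bacteria"]
        assert sub.counts[:, 0].tolist() == [1, 0, 5, 2]


class TestClrMatrix:
    def test_rejects_nonzero_row_sums(self):
        with pytest.raises(ValidationError):
            ClrMatrix(["s"], ["a", "b"], np.array([[1.0, 1.0]]))

    def test_concat_preserves_zero_sum(self):
        a = ClrMatrix(["s1", "s2"], ["x", "y"], np.array([[1.0, -1.0], [2.0, -2.0]]))
        b = ClrMatrix(["s1", "s2"], ["u", "v"], np.array([[0.5, -0.5], [0.0, 0.0]]))
        c = concat_clr([a, b])
        assert c.taxon_ids == ["x", "y", "u", "v"]
        np.testing.assert_allclose(c.values.sum(axis=1), 0.0, atol=1e-12)

    def test_concat_rejects_misaligned_samples(self):
        a = ClrMatrix(["s1"], ["x", "y"], np.array([[1.0, -1.0]]))
        b = ClrMatrix(["s2"], ["u", "v"], np.array([[1.0, -1.0]]))
        with pytest.raises(ValidationError):
            concat_clr([a, b])


class TestCommunityTableIO:
    def test_round_trip(self, tiny_table, tmp_path):
        cpath, apath = tmp_path / "c.tsv", tmp_path / "a.tsv"
        sio.write_community_table(tiny_table, cpath, apath)
        back = sio.read_community_table(cpath, apath)
        assert back.sample_ids == tiny_table.sample_ids
        assert back.taxon_ids == tiny_table.taxon_ids
        np.testing.assert_array_equal(back.counts, tiny_table.counts)
        assert back.group == tiny_table.group
        assert back.trophic == tiny_table.trophic

    def test_duplicate_taxon_column_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("sample_id\tt1\tt1\ns1\t1\t2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            sio.read_community_table(p)

    def test_negative_and_nonnumeric_rejected(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("sample_id\tt1\ns1\t-3\n")
        with pytest.raises(ValidationError):
            sio.read_community_table(p)
        p.write_text("sample_id\tt1\ns1\tabc\n")
        with pytest.raises(ValidationError):
            sio.read_community_table(p)

    def test_missing_annotation_defaults_unknown(self, tmp_path, caplog):
        c, a = tmp_path / "c.tsv", tmp_path / "a.tsv"
        c.write_text("sample_id\tt1\tt2\tt3\ns1\t1\t2\t3\n")
        a.write_text("taxon_id\tgroup\ttrophic\n"
                     "t1\tbacteria\theterotrophic\nt2\tfungi\tunknown\n")
        with caplog.at_level("WARNING"):
            t = sio.read_community_table(c, a)
        assert t.group == ["bacteria", "fungi", "unknown"]
        assert "t3" in caplog.text


class TestMetadataIO:
    def _write(self, tmp_path, order=("s1", "s2", "s3", "s4")):
        p = tmp_path / "meta.tsv"
        lines = ["sample_id\tsnow\tpH\tmoisture\tx\ty"]
        vals = {"s1": "1.0\t6.5\t0.2\t0\t0", "s2": "0.5\t7.0\t0.3\t50\t0",
                "s3": "0.1\t7.5\t0.4\t0\t50", "s4": "0.9\t6.8\t0.25\t50\t50"}
        lines += [f"{s}\t{vals[s]}" for s in order]
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_shapes(self, tmp_path):
        meta = sio.read_metadata(self._write(tmp_path))
        assert meta.n_samples == 4
        assert list(meta.covariates.columns) == ["snow", "pH", "moisture"]
        assert meta.coords.shape == (4, 2)

    def test_missing_coordinate_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tsnow\tx\ns1\t1.0\t0\n")
        with pytest.raises(ValidationError, match="y"):
            sio.read_metadata(p)

    def test_na_covariate_named_in_error(self, tmp_path):
        p = tmp_path / "na.tsv"
        p.write_text("sample_id\tsnow\tx\ty\ns1\t\t0\t0\ns2\t1\t1\t1\n")
        meta = sio.read_metadata(p)
        with pytest.raises(ValidationError, match="snow"):
            meta.covariate_matrix(["snow"])

    def test_realigned_to_declared_order(self, tmp_path):
        path = self._write(tmp_path, order=("s3", "s1", "s4", "s2"))
        meta = sio.read_metadata(path, sample_order=["s1", "s2", "s3", "s4"])
        manual = sio.read_metadata(self._write(tmp_path))
        assert meta.sample_ids == manual.sample_ids
        np.testing.assert_array_equal(meta.coords, manual.coords)
        pd.testing.assert_frame_equal(meta.covariates, manual.covariates)


class TestNetworkOutputs:
    def _graph(self):
        edges = pd.DataFrame([("a", "b", 0.5, 0.2, 0.7, "positive"),
                              ("b", "c", -0.4, -0.6, -0.1, "negative")],
                             columns=["taxon_a", "taxon_b", "median_rho",
                                      "lower", "upper", "sign"])
        ann = pd.DataFrame({"group": ["bacteria", "fungi", "bacteria"],
                            "trophic": ["heterotrophic"] * 3},
                           index=["a", "b", "c"])
        return build_network(edges, ann)

    def test_edge_tsv_rows(self, tmp_path):
        g = self._graph()
        epath, gpath, spath = sio.write_network_outputs(
            g, network_stats(g), tmp_path)
        assert len(pd.read_csv(epath, sep="\t")) == 2

    def test_empty_network_valid_files(self, tmp_path):
        g = nx.Graph()
        epath, gpath, spath = sio.write_network_outputs(
            g, network_stats(g), tmp_path, prefix="empty")
        assert len(pd.read_csv(epath, sep="\t")) == 0
        stats = json.loads(spath.read_text())
        assert stats["nodes"] == 0

    def test_graphml_round_trip_isomorphic(self, tmp_path):
        g = self._graph()
        _, gpath, _ = sio.write_network_outputs(g, network_stats(g), tmp_path)
        back = nx.read_graphml(gpath)
        assert nx.is_isomorphic(g, back)
        assert back.nodes["a"]["group"] == "bacteria"


class TestRunConfig:
    def test_defaults_mirror_study_settings(self):
        cfg = sio.RunConfig()
        assert cfg.rarefaction_depths["bacteria"] == 7987
        assert cfg.rarefaction_depths["fungi"] == 1023
        assert cfg.frequency_cutoff == 12
        assert cfg.n_latent == 3
        assert (cfg.iterations, cfg.burn_in, cfg.thin) == (40000, 10000, 30)
        assert cfg.credible_level == 0.95

    def test_yaml_round_trip(self, tmp_path):
        cfg = sio.RunConfig(seed=7, n_latent=2)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert sio.RunConfig.from_yaml(path) == cfg

    @pytest.mark.parametrize("kw", [
        {"iterations": 100, "burn_in": 100},
        {"thin": 0},
        {"credible_level": 1.0},
        {"n_latent": -1},
        {"rarefaction_depths": {"bacteria": 0}},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValidationError):
            sio.RunConfig(**kw)


class TestPosteriorPersistence:
    def test_round_trip(self, tmp_path):
        from succnet.jsdm import JsdmModel, fit_jsdm
        rng = np.random.default_rng(0)
        m = JsdmModel(y=rng.normal(size=(10, 4)), x=rng.normal(size=(10, 1)),
                      coords=rng.uniform(0, 50, size=(10, 2)), d=2)
        post = fit_jsdm(m, 200, 100, 2, seed=1)
        sio.save_posterior(post, tmp_path / "post")
        back = sio.load_posterior(tmp_path / "post")
        np.testing.assert_allclose(back.loadings, post.loadings)
        np.testing.assert_allclose(back.phi, post.phi)
        assert back.taxon_ids == post.taxon_ids
        assert back.settings["thin"] == 2
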