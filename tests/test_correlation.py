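"""Pearson correlation (Eqs over 20 residues) and cluster summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idphydro.correlation import (
    ClusterSummary,
    ConstantVectorError,
    CorrelationRow,
    IndexEntry,
    cluster_summary,
    correlate_scale_vs_collection,
    pearson_r,
    read_index_collection_tsv,
)
from idphydro.scales import CANONICAL_RESIDUES, get_builtin_scale


def two_pass_pearson(x, y):
    """Textbook two-pass oracle: means first, then centered sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = sum((a - mx) ** 2 for a in x)
    dy = sum((b - my) ** 2 for b in y)
    return num / (dx * dy) ** 0.5


def make_index(values, cluster="H", idx="IDX1"):
    return IndexEntry(
        id=idx, cluster=cluster,
        values=dict(zip(CANONICAL_RESIDUES, values)),
    )


class TestPearson:
    def test_self_correlation(self, rng):
        x = rng.normal(size=20)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_table3_scales_match_oracle(self):
        kd = get_builtin_scale("kyte_doolittle").as_array()
        guy = get_builtin_scale("guy").as_array()
        r = pearson_r(kd, guy)
        assert r == pytest.approx(two_pass_pearson(kd, guy), abs=1e-12)
        assert r < -0.5  # Guy's inverted sign convention

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantVectorError):
            pearson_r(np.ones(20), np.arange(20.0))

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        alpha=st.floats(min_value=1e-3, max_value=1e3),
        beta=st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance(self, seed, alpha, beta):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=20), r.normal(size=20)
        base = pearson_r(x, y)
        assert pearson_r(alpha * x + beta, y) == pytest.approx(base, abs=1e-9)
        assert pearson_r(-alpha * x + beta, y) == pytest.approx(-base, abs=1e-9)

    def test_random_vectors_match_oracle(self, rng):
        for _ in range(200):
            x, y = rng.normal(size=20), rng.normal(size=20)
            assert pearson_r(x, y) == pytest.approx(
                two_pass_pearson(x, y), abs=1e-12)


class TestCollection:
    def test_self_in_collection(self):
        scale = get_builtin_scale("idp_hydropathy")
        rows = correlate_scale_vs_collection(
            scale, [make_index(scale.as_array())])
        assert len(rows) == 1
        assert rows[0].r == pytest.approx(1.0)

    def test_constant_index_skipped_with_warning(self, caplog, rng):
        scale = get_builtin_scale("guy")
        collection = [
            make_index(rng.normal(size=20), idx="OK"),
            make_index(np.zeros(20) + 3.0, idx="CONST"),
        ]
        with caplog.at_level("WARNING"):
            rows = correlate_scale_vs_collection(scale, collection)
        assert [r.index_id for r in rows] == ["OK"]
        assert "CONST" in caplog.text

    def test_rows_match_elementwise_calls(self, rng):
        scale = get_builtin_scale("kyte_doolittle")
        collection = [
            make_index(rng.normal(size=20), idx=f"I{i}") for i in range(5)
        ]
        rows = correlate_scale_vs_collection(scale, collection)
        for row, entry in zip(rows, collection):
            assert row.r == pearson_r(scale.as_array(), entry.as_array())

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            correlate_scale_vs_collection(get_builtin_scale("guy"), [])


def summary_oracle(rows):
    """Brute-force per-cluster five-number summary of |r|."""
    out = {}
    for row in rows:
        out.setdefault(row.cluster, []).append(abs(row.r))
    result = {}
    for cluster, vals in out.items():
        vals = sorted(vals)
        n = len(vals)
        mean = sum(vals) / n
        median = (vals[n // 2] if n % 2
                  else (vals[n // 2 - 1] + vals[n // 2]) / 2)
        std = (None if n < 2 else
               (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5)
        result[cluster] = (mean, median, std, vals[-1], vals[0])
    return result


class TestClusterSummary:
    def test_hand_computed(self):
        rows = [CorrelationRow("a", "H", 0.5),
                CorrelationRow("b", "H", -0.7),
                CorrelationRow("c", "H", 0.9)]
        (s,) = cluster_summary(rows)
        assert (s.mean, s.median, s.max, s.min) == pytest.approx(
            (0.7, 0.7, 0.9, 0.5))
        assert s.std == pytest.approx(0.2)

    def test_singleton_std_undefined(self):
        (s,) = cluster_summary([CorrelationRow("a", "B", -0.4)])
        assert s.mean == s.median == s.max == s.min == 0.4
        assert s.std is None

    def test_sorted_by_descending_mean(self, rng):
        rows = [
            CorrelationRow(f"i{k}", c, float(rng.uniform(-1, 1)))
            for c in "ABH" for k in range(4)
        ]
        summaries = cluster_summary(rows)
        means = [s.mean for s in summaries]
        assert means == sorted(means, reverse=True)

    def test_oracle_agreement(self, rng):
        for _ in range(100):
            clusters = rng.choice(list("ABCHPO"), size=12)
            rows = [
                CorrelationRow(f"i{k}", c, float(rng.uniform(-1, 1)))
                for k, c in enumerate(clusters)
            ]
            expect = summary_oracle(rows)
            for s in cluster_summary(rows):
                mean, median, std, mx, mn = expect[s.cluster]
                assert s.mean == pytest.approx(mean)
                assert s.median == pytest.approx(median)
                assert s.max == mx and s.min == mn
                if std is None:
                    assert s.std is None
                else:
                    assert s.std == pytest.approx(std)
                assert s.min <= s.mean <= s.max
                assert s.min <= s.median <= s.max

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_summary([])


class TestIndexCollectionTsv:
    def test_round_trip_read(self, tmp_path, rng):
        header = "id\tcluster\t" + "\t".join(CANONICAL_RESIDUES)
        vals = rng.normal(size=20)
        row = "IDX1\tH\t" + "\t".join(repr(float(v)) for v in vals)
        path = tmp_path / "collection.tsv"
        path.write_text(header + "\n" + row + "\n")
        (entry,) = read_index_collection_tsv(path)
        assert entry.cluster == "H"
        np.testing.assert_array_equal(entry.as_array(), vals)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tgroup\t" + "\t".join(CANONICAL_RESIDUES) + "\n")
        with pytest.raises(ValueError, match="header"):
            read_index_collection_tsv(path)
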