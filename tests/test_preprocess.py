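import numpy as np
import pytest

from hicenhance.io_formats import ContactMap
from hicenhance.preprocess import (
    CellRecord,
    build_pseudobulk,
    cell_qc,
    cell_similarity,
    chromosome_partition,
    downsample,
    from_synthetic,
)


def _cmap(m, chrom="chr1"):
    m = np.asarray(m, dtype=np.float64)
    return ContactMap(chrom, 1, m, state="raw_counts")


def _cell(cid, m, ctype="A", **qc):
    qc.setdefault("unique_reads", 5000)
    qc.setdefault("intra_inter_ratio", 2.0)
    qc.setdefault("uniq_map_frac", 0.99)
    return CellRecord(cell_id=cid, maps={"chr1": _cmap(m)}, cell_type=ctype, **qc)


class TestDownsample:
    def test_ratio_one_identity(self):
        c = _cmap(np.full((4, 4), 8.0))
        out = downsample(c, 1.0, seed=0)
        np.testing.assert_array_equal(out.matrix, c.matrix)

    def test_expectation(self):
        c = _cmap(np.full((2, 2), 1600.0))
        vals = [downsample(c, 1 / 16, seed=s).matrix[0, 1] for s in range(200)]
        # Binomial(1600, 1/16): mean 100, sd 9.68; mean of 200 draws
        assert abs(np.mean(vals) - 100.0) < 4 * 9.68 / np.sqrt(200)

    def test_symmetric_integer_output(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(20, (6, 6)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        out = downsample(_cmap(m), 0.25, seed=1).matrix
        np.testing.assert_array_equal(out, out.T)
        np.testing.assert_array_equal(out, np.round(out))
        assert np.all(out <= m)

    def test_rejects_non_integer(self):
        with pytest.raises(ValueError):
            downsample(_cmap(np.full((2, 2), 1.5)), 0.5)

    def test_rejects_bad_ratio(self):
        with pytest.raises(ValueError):
            downsample(_cmap(np.eye(2)), 0.0)
        with pytest.raises(ValueError):
            downsample(_cmap(np.eye(2)), 1.5)

    def test_seeded(self):
        c = _cmap(np.full((4, 4), 100.0))
        a = downsample(c, 0.5, seed=3).matrix
        b = downsample(c, 0.5, seed=3).matrix
        np.testing.assert_array_equal(a, b)


class TestCellQc:
    def test_all_pass(self):
        kept, dropped = cell_qc([_cell("a", np.eye(3)), _cell("b", np.eye(3))])
        assert len(kept) == 2 and not dropped

    def test_boundaries_inclusive(self):
        # exactly-at-threshold cells pass (strict < comparisons)
        c = _cell("edge", np.eye(3), unique_reads=1000,
                  intra_inter_ratio=1.0, uniq_map_frac=0.95)
        kept, dropped = cell_qc([c])
        assert kept and not dropped

    def test_each_filter(self):
        cells = [
            _cell("r", np.eye(3), unique_reads=999),
            _cell("i", np.eye(3), intra_inter_ratio=0.99),
            _cell("u", np.eye(3), uniq_map_frac=0.949),
        ]
        kept, dropped = cell_qc(cells)
        assert not kept
        reasons = dict(dropped)
        assert reasons["r"] == ["unique_reads"]
        assert reasons["i"] == ["intra_inter_ratio"]
        assert reasons["u"] == ["uniq_map_frac"]

    def test_missing_field_errors(self):
        c = _cell("x", np.eye(3))
        c.uniq_map_frac = None
        with pytest.raises(ValueError, match="uniq_map_frac"):
            cell_qc([c])


class TestSimilarity:
    def test_identical_cells(self):
        rng = np.random.default_rng(1)
        m = rng.poisson(4, (5, 5)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        assert cell_similarity(_cell("a", m), _cell("b", m)) == pytest.approx(1.0)

    def test_matches_numpy_pearson(self):
        rng = np.random.default_rng(2)
        ms = []
        for _ in range(2):
            m = rng.poisson(4, (6, 6)).astype(float)
            ms.append(np.triu(m) + np.triu(m, 1).T)
        got = cell_similarity(_cell("a", ms[0]), _cell("b", ms[1]))
        iu = np.triu_indices(6)
        want = np.corrcoef(ms[0][iu], ms[1][iu])[0, 1]
        assert got == pytest.approx(want)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            s = cell_similarity(_cell("a", np.zeros((3, 3))), _cell("b", np.eye(3)))
        assert s == 0.0


class TestPseudobulk:
    def _population(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        cells = []
        for i in range(n):
            m = rng.poisson(6, (5, 5)).astype(float)
            m = np.triu(m) + np.triu(m, 1).T
            cells.append(_cell(f"c{i}", m, ctype="A" if i < 5 else "B"))
        return cells

    def test_matches_bruteforce_oracle(self):
        cells = self._population()
        anchor = cells[0]
        pb = build_pseudobulk(anchor, cells, k=3)
        # oracle: rank same-type candidates by Pearson, sum top 3 + anchor
        sims = []
        for c in cells[1:5]:
            sims.append((-cell_similarity(anchor, c), c.cell_id, c))
        sims.sort(key=lambda t: (t[0], t[1]))
        expected_ids = [anchor.cell_id] + [t[2].cell_id for t in sims[:3]]
        assert pb.member_ids == expected_ids
        acc = sum(
            c.maps["chr1"].matrix for c in cells if c.cell_id in expected_ids
        )
        np.testing.assert_array_equal(pb.maps["chr1"].matrix, acc)

    def test_same_type_only(self):
        cells = self._population()
        pb = build_pseudobulk(cells[0], cells, k=4)
        members = {c.cell_id: c for c in cells}
        assert all(members[i].cell_type == "A" for i in pb.member_ids)

    def test_k_capped_with_warning(self):
        cells = self._population()
        with pytest.warns(UserWarning, match="candidates available"):
            pb = build_pseudobulk(cells[5], cells, k=10)  # only 2 other B cells
        assert pb.k == 2 and len(pb.member_ids) == 3

    def test_total_is_sum_of_members(self):
        cells = self._population()
        pb = build_pseudobulk(cells[1], cells, k=2)
        members = {c.cell_id: c for c in cells}
        want = sum(members[i].maps["chr1"].matrix.sum() for i in pb.member_ids)
        assert pb.maps["chr1"].matrix.sum() == pytest.approx(want)


class TestPartition:
    def test_default_layout(self):
        train, val, test = chromosome_partition()
        assert len(train) == 14 and len(val) == 4 and len(test) == 4
        assert set(test) == {"4", "14", "16", "20"}
        assert set(val) == {"2", "6", "10", "12"}
        assert not (set(train) & set(val)) and not (set(train) & set(test))

    def test_custom(self):
        train, val, test = chromosome_partition(["a", "b", "c"], test=["a"], val=["b"])
        assert train == ["c"] and val == ["b"] and test == ["a"]

    def test_overlap_errors(self):
        with pytest.raises(ValueError):
            chromosome_partition(["a", "b"], test=["a"], val=["a"])

    def test_unknown_chrom_errors(self):
        with pytest.raises(ValueError):
            chromosome_partition(["a"], test=["z"], val=[])


def test_from_synthetic_adapter():
    from hicenhance.synthetic import CellPopulationSpec, SyntheticSpec, sample_cells

    pop = CellPopulationSpec(
        type_specs=[SyntheticSpec(n_bins=20, depth=1e3, chrom="chrS")],
        cells_per_type=3,
        per_cell_depth=(100, 200),
        seed=0,
    )
    recs = from_synthetic(sample_cells(pop))
    assert len(recs) == 3
    r = recs[0]
    assert set(r.maps) == {"chrS"}
    assert r.unique_reads is not None and r.cell_type == "type0"
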