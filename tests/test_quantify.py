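import numpy as np
import pandas as pd
import pytest

from hybrid_ase import (
    AlignmentRecord,
    CountMatrix,
    GeneModel,
    PipelineConfig,
    count_fragments,
    estimate_size_factors,
    filter_allelic,
    filter_low_expression,
    marker_zscores,
    normalize_allelic_counts,
    read_gene_models,
    union_intervals,
)

CFG = PipelineConfig()


def cm(data, samples=None, chroms=None, layer="BULK"):
    df = pd.DataFrame(
        data,
        index=[f"g{i}" for i in range(len(data))],
        columns=samples or [f"s{j}" for j in range(len(data[0]))],
    )
    info = None
    if chroms is not None:
        info = pd.DataFrame({"chrom": chroms}, index=df.index)
    return CountMatrix(df, layer, info)


class TestGeneModels:
    def test_gtf_overlapping_exons_union(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tx\texon\t11\t50\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tx\texon\t41\t80\t.\t+\t.\tgene_id "gA";\n'
        )
        (model,) = read_gene_models(gtf)
        assert model.exons == [(10, 80)]

    def test_gtf_union_lengths(self, tmp_path):
        # 5 genes with hand-computed exon-union lengths
        rows = [
            ("gA", [(1, 100)]),                      # 100
            ("gB", [(1, 50), (61, 100)]),            # 90
            ("gC", [(1, 50), (41, 100)]),            # 100 (overlap merged)
            ("gD", [(1, 10), (11, 20), (21, 30)]),   # 30
            ("gE", [(5, 5)]),                        # 1
        ]
        expected = {"gA": 100, "gB": 90, "gC": 100, "gD": 30, "gE": 1}
        lines = []
        for gid, exons in rows:
            for s, e in exons:
                lines.append(f'chr1\tx\texon\t{s}\t{e}\t.\t+\t.\tgene_id "{gid}";\n')
        gtf = tmp_path / "five.gtf"
        gtf.write_text("".join(lines))
        models = read_gene_models(gtf)
        lengths = {
            m.gene_id: sum(e - s for s, e in m.exons) for m in models
        }
        assert lengths == expected

    def test_bed12_single_exon(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text(
            "chr1\t100\t200\tgX\t0\t+\t100\t200\t0\t1\t100,\t0,\n"
        )
        (model,) = read_gene_models(bed)
        assert model.exons == [(100, 200)]
        assert model.tss == 100

    def test_tss_respects_strand(self):
        g = GeneModel("g", "chr1", "-", [(100, 200)])
        assert g.tss == 199

    def test_union_intervals_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            union_intervals([(5, 5)])


def frag(chrom, start0, length, read_id="f", mate=None):
    r1 = AlignmentRecord(read_id, chrom, start0 + 1, [("M", length)], "A" * length)
    return (r1, mate)


class TestCountFragments:
    genes = [
        GeneModel("gA", "chr1", "+", [(100, 200)]),
        GeneModel("gB", "chr1", "+", [(300, 400)]),
    ]

    def test_fragment_inside_one_gene(self):
        out = count_fragments([frag("chr1", 120, 50)], self.genes)
        assert out.counts["sample"].to_dict() == {"gA": 1, "gB": 0}

    def test_fragment_spanning_two_genes_discarded(self):
        out = count_fragments([frag("chr1", 150, 200)], self.genes)
        assert out.counts["sample"].sum() == 0

    def test_intergenic_fragment_ignored(self):
        out = count_fragments([frag("chr1", 210, 50)], self.genes)
        assert out.counts["sample"].sum() == 0

    def test_mates_count_once(self):
        r1 = AlignmentRecord("p", "chr1", 101, [("M", 30)], "A" * 30, "+", 161, True)
        r2 = AlignmentRecord("p", "chr1", 161, [("M", 30)], "A" * 30, "-", 101, False)
        out = count_fragments([(r1, r2)], self.genes)
        assert out.counts.loc["gA", "sample"] == 1

    def test_intron_only_overlap_does_not_count(self):
        spliced_gene = [GeneModel("gS", "chr1", "+", [(100, 150), (500, 550)])]
        out = count_fragments([frag("chr1", 200, 50)], spliced_gene)
        assert out.counts["sample"].sum() == 0

    def test_recovers_simulated_truth(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", "+", [(i * 1000, i * 1000 + 500)])
            for i in range(10)
        ]
        truth = rng.integers(0, 40, size=10)
        frags = []
        k = 0
        for i, n in enumerate(truth):
            for _ in range(n):
                start = int(rng.integers(i * 1000, i * 1000 + 450))
                frags.append(frag("chr1", start, 50, read_id=f"f{k}"))
                k += 1
        out = count_fragments(frags, genes)
        assert (out.counts["sample"].to_numpy() == truth).all()


class TestFilterLowExpression:
    def test_strict_cutoff_over_grand_total(self):
        mat = cm([[5, 4], [4, 4], [0, 0]])  # totals 9, 8, 0
        kept = filter_low_expression(mat, CFG)
        assert kept.gene_ids == ["g0"]

    def test_x_chromosome_removed(self):
        mat = cm([[500, 500], [500, 500]], chroms=["chrX", "chr1"])
        kept = filter_low_expression(mat, CFG)
        assert kept.gene_ids == ["g1"]

    def test_empty_matrix(self):
        mat = CountMatrix(pd.DataFrame(columns=["s0"], dtype=float))
        assert filter_low_expression(mat, CFG).counts.empty


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        mat = cm([[10, 10], [20, 20], [5, 5]])
        np.testing.assert_allclose(estimate_size_factors(mat), [1.0, 1.0], atol=1e-14)

    def test_hand_computed_example(self):
        mat = cm([[2, 4], [3, 6], [4, 8]])
        np.testing.assert_allclose(
            estimate_size_factors(mat),
            [1 / np.sqrt(2), np.sqrt(2)],
            atol=1e-12,
        )

    def test_gene_permutation_invariance(self, rng):
        counts = rng.integers(1, 100, size=(20, 3))
        mat = cm(counts.tolist())
        perm = rng.permutation(20)
        mat_perm = CountMatrix(mat.counts.iloc[perm])
        np.testing.assert_allclose(
            estimate_size_factors(mat).to_numpy(),
            estimate_size_factors(mat_perm).to_numpy(),
        )

    def test_column_scaling_scales_relative_factor(self, rng):
        # scaling a column by c also scales the per-gene geometric means by
        # c^(1/n), so the absolute factor moves by c^((n-1)/n); the factor
        # *relative to any other sample* scales by exactly c
        counts = rng.integers(1, 100, size=(30, 3)).astype(float)
        base = estimate_size_factors(cm(counts.tolist())).to_numpy()
        scaled = counts.copy()
        scaled[:, 1] *= 5
        out = estimate_size_factors(cm(scaled.tolist())).to_numpy()
        np.testing.assert_allclose(out[1] / base[1], 5.0 ** (2 / 3), rtol=1e-12)
        np.testing.assert_allclose(
            (out[1] / out[0]) / (base[1] / base[0]), 5.0, rtol=1e-12
        )

    def test_no_reference_gene_raises(self):
        mat = cm([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="reference gene"):
            estimate_size_factors(mat)


class TestNormalizeAllelic:
    def test_unit_factors_identity(self):
        m = cm([[10, 20]], layer="MATERNAL")
        p = cm([[30, 40]], layer="PATERNAL")
        sf = pd.Series([1.0, 1.0], index=["s0", "s1"])
        nm, np_ = normalize_allelic_counts(m, p, sf)
        assert nm.counts.equals(m.counts.astype(float)) or np.allclose(nm.counts, m.counts)

    def test_shared_divisor_preserves_ratio(self, rng):
        m = cm(rng.integers(1, 100, size=(10, 4)).tolist(), layer="MATERNAL")
        p = cm(rng.integers(1, 100, size=(10, 4)).tolist(), layer="PATERNAL")
        sf = pd.Series(rng.uniform(0.5, 2.0, size=4), index=m.sample_ids)
        nm, np_ = normalize_allelic_counts(m, p, sf)
        before = m.counts / (m.counts + p.counts)
        after = nm.counts / (nm.counts + np_.counts)
        np.testing.assert_allclose(before, after)

    def test_nonpositive_factor_rejected(self):
        m = cm([[10, 20]], layer="MATERNAL")
        p = cm([[30, 40]], layer="PATERNAL")
        sf = pd.Series([1.0, 0.0], index=["s0", "s1"])
        with pytest.raises(ValueError, match="positive"):
            normalize_allelic_counts(m, p, sf)


class TestFilterAllelic:
    def _pair(self, wt_totals):
        # one gene, two WT replicates, maternal == paternal == total/2
        mdf = pd.DataFrame([[t / 2 for t in wt_totals]], index=["g0"], columns=["w1", "w2"])
        pdf = mdf.copy()
        return CountMatrix(mdf, "MATERNAL"), CountMatrix(pdf, "PATERNAL")

    @pytest.mark.parametrize(
        "wt_totals, kept",
        [((9, 9), False), ((9, 11), True), ((10, 0), True)],
    )
    def test_both_replicate_rule(self, wt_totals, kept):
        m, p = self._pair(wt_totals)
        result = filter_allelic(m, p, ["w1", "w2"], CFG)
        assert (result == ["g0"]) is kept

    def test_empty_wt_samples_rejected(self):
        m, p = self._pair((10, 10))
        with pytest.raises(ValueError, match="non-empty"):
            filter_allelic(m, p, [], CFG)


class TestMarkerZscores:
    def test_constant_gene_zero_row(self):
        mat = cm([[10, 10], [7, 7], [3, 3]])
        z = marker_zscores(mat, "g0")
        assert (z.loc["g1"] == 0).all()

    def test_two_sample_values(self):
        mat = cm([[10, 10], [4, 9], [3, 3]])
        z = marker_zscores(mat, "g0")
        np.testing.assert_allclose(
            np.abs(z.loc["g1"]).to_numpy(), [2**-0.5, 2**-0.5], atol=1e-12
        )

    def test_column_scaling_invariance(self, rng):
        counts = rng.integers(1, 200, size=(15, 3)).astype(float)
        mat = cm(counts.tolist())
        scaled = counts.copy()
        scaled[:, 2] *= 10
        z1 = marker_zscores(mat, "g0")
        z2 = marker_zscores(cm(scaled.tolist()), "g0")
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_missing_reference_rejected(self):
        mat = cm([[10, 10]])
        with pytest.raises(ValueError, match="reference gene"):
            marker_zscores(mat, "nope")
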