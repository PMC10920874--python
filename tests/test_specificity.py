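"""Expression z-scores, element-gene links, and the identity-gene screen."""

import numpy as np
import pandas as pd
import pytest

from regland.intervals import GeneModel, GenomicInterval, LoopRecord, Peak
from regland.specificity import (
    ElementLink,
    assign_elements_to_genes,
    expression_zscores,
    identity_gene_screen,
    tissue_specific_elements,
)


class TestExpressionZscores:
    def test_hand_computed_z(self):
        expr = pd.DataFrame(
            {"f": [10.0], "t1": [0.0], "t2": [0.0], "t3": [0.0], "t4": [0.0]},
            index=["g"],
        )
        res = expression_zscores(expr, "f")[0]
        # mean 2, sample SD sqrt(20): z = 8/sqrt(20)
        assert res.z == pytest.approx(8 / np.sqrt(20), abs=1e-9)

    def test_constant_expression_degenerate(self):
        expr = pd.DataFrame({"f": [5.0], "t1": [5.0], "t2": [5.0]}, index=["g"])
        res = expression_zscores(expr, "f")[0]
        assert res.z == 0.0 and not res.specific

    def test_threshold_conjunction(self):
        cols = {"f": [60.0, 40.0]}
        cols.update({f"t{i}": [0.0, 0.0] for i in range(60)})
        expr = pd.DataFrame(cols, index=["hi", "lo"])
        results = {r.gene_id: r for r in expression_zscores(expr, "f")}
        assert results["hi"].z > 7 and results["lo"].z > 7
        assert results["hi"].specific
        assert not results["lo"].specific  # TPM 40 < 50

    def test_tissue_order_invariance(self, rng):
        data = rng.gamma(2.0, 20.0, size=(20, 10))
        cols = [f"t{i}" for i in range(10)]
        expr = pd.DataFrame(data, index=[f"g{i}" for i in range(20)], columns=cols)
        shuffled = expr[list(reversed(cols))]
        a = {r.gene_id: r.z for r in expression_zscores(expr, "t3")}
        b = {r.gene_id: r.z for r in expression_zscores(shuffled, "t3")}
        for g in a:
            assert a[g] == pytest.approx(b[g], abs=1e-12)

    def test_focal_absent_and_too_few_tissues(self):
        expr = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [1.0]}, index=["g"])
        with pytest.raises(KeyError):
            expression_zscores(expr, "zzz")
        with pytest.raises(ValueError):
            expression_zscores(expr[["a", "b"]], "a")


class TestElementSharing:
    def test_no_more_than_one_additional_tissue(self):
        el = GenomicInterval("chr1", 0, 1000)
        other = GenomicInterval("chr1", 0, 1000)
        sets0 = {"f": [el], "t1": [], "t2": []}
        sets1 = {"f": [el], "t1": [other], "t2": []}
        sets2 = {"f": [el], "t1": [other], "t2": [other]}
        assert tissue_specific_elements(sets0, "f")[el] is True
        assert tissue_specific_elements(sets1, "f")[el] is True
        assert tissue_specific_elements(sets2, "f")[el] is False


class TestElementGeneAssignment:
    GENES = [
        GeneModel("A", GenomicInterval("chr1", 100_000, 102_000), "+"),
        GeneModel("B", GenomicInterval("chr1", 150_000, 152_000), "+"),
    ]

    def test_nearest_tss_rule(self):
        el = GenomicInterval("chr1", 109_000, 111_000)  # 10 kb from A, 40 kb from B
        links = assign_elements_to_genes([el], self.GENES)
        assert [(l.gene_id, l.evidence) for l in links] == [("A", "nearest")]

    def test_loop_evidence_beyond_nearest(self):
        el = GenomicInterval("chr1", 449_000, 450_000)
        far_gene = GeneModel("C", GenomicInterval("chr1", 750_000, 752_000), "+")
        loop = LoopRecord(
            GenomicInterval("chr1", 448_000, 451_000),
            GenomicInterval("chr1", 748_000, 752_000),
        )
        links = assign_elements_to_genes([el], self.GENES + [far_gene], loops=[loop])
        assert ("C", "loop") in {(l.gene_id, l.evidence) for l in links}

    def test_unassigned_when_too_far(self):
        el = GenomicInterval("chr2", 0, 1000)  # different chromosome, no loop
        assert assign_elements_to_genes([el], self.GENES) == []

    def test_max_distance_respected(self):
        el = GenomicInterval("chr1", 700_000, 700_500)
        links = assign_elements_to_genes([el], self.GENES, max_distance=100_000)
        assert links == []


class TestIdentityScreen:
    def _inputs(self):
        genes = [
            GeneModel("good", GenomicInterval("chr1", 10_000, 12_000), "+"),
            GeneModel("no_tf", GenomicInterval("chr1", 200_000, 202_000), "+"),
        ]
        from regland.specificity import SpecificityResult

        spec = [
            SpecificityResult("good", 500.0, 9.0, True),
            SpecificityResult("no_tf", 500.0, 8.0, True),
        ]
        el_good = GenomicInterval("chr1", 20_000, 30_000)
        el_no_tf = GenomicInterval("chr1", 210_000, 220_000)
        links = [
            ElementLink(el_good, "good", "nearest"),
            ElementLink(el_no_tf, "no_tf", "nearest"),
        ]
        tf_peaks = [Peak(GenomicInterval("chr1", 21_000, 21_400))]  # only in good's element
        return spec, links, tf_peaks, genes

    def test_pass_and_single_criterion_failure(self):
        spec, links, tf_peaks, genes = self._inputs()
        records = {r.gene_id: r for r in identity_gene_screen(spec, links, tf_peaks, genes)}
        assert records["good"].passes
        r = records["no_tf"]
        assert not r.passes
        assert r.has_specific_element and r.is_expression_specific and not r.is_tf_target

    def test_sorted_by_z_descending(self):
        spec, links, tf_peaks, genes = self._inputs()
        records = identity_gene_screen(spec, links, tf_peaks, genes)
        assert [r.gene_id for r in records] == ["good", "no_tf"]


class TestScreenOnBundle:
    def test_recovers_planted_identity_genes_exactly(self, bundle):
        """Precision = recall = 1 against the manifest on the default bundle."""
        from regland import io as rio
        from regland.pipeline import config_for_bundle, run_all

        outdir, manifest = bundle
        cfg = config_for_bundle(outdir, outdir.parent / "pipeline_out", n_perm=19)
        report = run_all(cfg)
        assert report["identity_genes"] == manifest.identity_genes

    def test_loosening_thresholds_never_shrinks_set(self, bundle):
        from regland import io as rio
        from regland.specificity import expression_zscores

        outdir, _m = bundle
        expr = rio.read_tsv_matrix(outdir / "expression_tpm.tsv")
        strict = {r.gene_id for r in expression_zscores(expr, "parathyroid", 7.0, 50.0) if r.specific}
        loose = {r.gene_id for r in expression_zscores(expr, "parathyroid", 5.0, 10.0) if r.specific}
        assert strict <= loose
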