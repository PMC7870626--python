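"""DEG-count response statistics, signatures, regulation matrix and PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from aopke import (
    CompoundSpec,
    CountSimConfig,
    DEGResponsePoint,
    bmc10_dgh,
    build_signature,
    deg_response,
    dgh,
    ec10_deg,
    generate_counts,
    pca_overview,
    prefilter,
    regulation_matrix,
)
from aopke.errors import FlatCurve


class TestDegResponse:
    @pytest.mark.parametrize(
        "n_deg,npos,expected",
        [(325, 325, 100.0), (0, 325, 0.0), (650, 325, 100.0), (65, 325, 20.0)],
    )
    def test_normalization_and_cap(self, n_deg, npos, expected):
        assert deg_response(n_deg, npos) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            deg_response(10, 0)
        with pytest.raises(ValueError):
            deg_response(-1, 325)

    def test_monotone_and_bounded(self):
        vals = [deg_response(n, 100) for n in range(0, 300, 7)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 100.0 for v in vals)


class TestDGH:
    @pytest.mark.parametrize("n_deg,expected", [(0, 100.0), (40, 60.0), (150, 0.0)])
    def test_formula_with_floor(self, n_deg, expected):
        assert dgh(n_deg) == expected

    def test_monotone_and_bounded(self):
        vals = [dgh(n) for n in range(0, 300, 7)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 100.0 for v in vals)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dgh(-5)


def _points_from_curve(ec50, h, concs, npos=325):
    """DEG-response points lying exactly on a rising Hill curve."""
    pts = []
    for c in concs:
        r = (c / ec50) ** h
        resp = 100.0 * r / (1.0 + r)
        n_deg = resp / 100.0 * npos  # float kept exact for analytic checks
        pts.append(
            DEGResponsePoint(concentration=c, n_deg=n_deg,
                             normalized_response=resp, dgh=max(0.0, 100.0 - n_deg))
        )
    return pts


class TestEC10DEG:
    def test_analytic_crossing(self):
        # rising Hill, EC50 = 2 uM, h = 1 -> 10% response at 2/9 uM
        concs = np.logspace(-8, -4, 8)
        est = ec10_deg(_points_from_curve(2e-6, 1.0, concs))
        assert est.concentration == pytest.approx(2e-6 / 9.0, rel=1e-5)

    def test_all_zero_is_flat(self):
        pts = [DEGResponsePoint(c, 0, 0.0, 100.0) for c in np.logspace(-8, -5, 5)]
        with pytest.raises(FlatCurve):
            ec10_deg(pts)

    def test_saturated_at_lowest_concentration_flags_extrapolated(self):
        pts = [DEGResponsePoint(c, 400, 100.0, 0.0) for c in np.logspace(-8, -5, 5)]
        pts[0] = DEGResponsePoint(pts[0].concentration, 390, 99.9, 0.0)
        est = ec10_deg(pts)
        assert est.extrapolated and est.concentration < pts[0].concentration

    def test_from_counts_constructor(self):
        p = DEGResponsePoint.from_counts(1e-6, 150, 325)
        assert p.normalized_response == pytest.approx(150 / 325 * 100)
        assert p.dgh == 0.0


class TestBMC10DGH:
    def test_analytic_inversion(self):
        # n_deg(c) = 100 * (c/m)/(1 + c/m) makes DGH an exact 100 -> 0 Hill
        # curve with midpoint m; n_deg crosses 10 (DGH = 90) at c* = m/9
        m = 1e-6
        concs = np.logspace(-8, -4, 8)
        pts = []
        for c in concs:
            nd = 100.0 * (c / m) / (1.0 + c / m)
            pts.append(DEGResponsePoint(c, nd, min(nd / 325, 1) * 100, 100.0 - nd))
        res = bmc10_dgh(pts, n_bootstrap=20, seed=0)
        assert res.bmc == pytest.approx(m / 9.0, rel=1e-4)

    def test_flat_when_no_genes_respond(self):
        pts = [DEGResponsePoint(c, 0, 0.0, 100.0) for c in np.logspace(-8, -5, 5)]
        with pytest.raises(FlatCurve):
            bmc10_dgh(pts, n_bootstrap=10, seed=0)

    def test_point_estimate_seed_free(self):
        concs = np.logspace(-8, -4, 8)
        pts = _points_from_curve(1e-6, 1.5, concs)
        r1 = bmc10_dgh(pts, n_bootstrap=20, seed=1)
        r2 = bmc10_dgh(pts, n_bootstrap=20, seed=99)
        assert r1.bmc == r2.bmc


class TestSignature:
    def test_disjoint_sets_flagged_empty(self):
        sig = build_signature({"a", "b"}, {"c"}, 13e-6)
        assert sig.empty and sig.gene_ids == frozenset()

    def test_subset_intersection(self):
        sig = build_signature({"a", "b", "c"}, {"a", "b"}, 13e-6)
        assert sig.gene_ids == frozenset({"a", "b"})

    def test_four_fold_dilution_from_anchor(self):
        sig = build_signature({"a"}, {"a"}, 13e-6, dilution=4.0)
        assert sig.low_concentration == pytest.approx(3.25e-6)

    def test_gene_order_invariance(self):
        s1 = build_signature(["a", "b", "c"], ["c", "a"], 1e-6)
        s2 = build_signature(["c", "b", "a"], ["a", "c"], 1e-6)
        assert s1.gene_ids == s2.gene_ids

    def test_dilution_must_exceed_one(self):
        with pytest.raises(ValueError):
            build_signature({"a"}, {"a"}, 1e-6, dilution=1.0)


class TestRegulationMatrix:
    def _table(self, entries):
        return pd.DataFrame(entries, columns=["log2fc", "padj"]).rename_axis("gene")

    def test_mask_absent_and_shown_states(self):
        sig = build_signature({"a", "b", "c"}, {"a", "b", "c"}, 1e-6)
        t1 = pd.DataFrame({"log2fc": [-1.0, 0.5], "padj": [0.05, 0.2]}, index=["a", "b"])
        mat = regulation_matrix(sig, {"cond1": t1}, mask_alpha=0.1)
        assert mat.state.at["a", "cond1"] == "shown"
        assert mat.values.at["a", "cond1"] == pytest.approx(-1.0)
        assert mat.state.at["b", "cond1"] == "masked"  # padj 0.2 > 0.1
        assert np.isnan(mat.values.at["b", "cond1"])
        assert mat.state.at["c", "cond1"] == "absent"


class TestPCAOverview:
    def _counts(self, seed=0, shift=None):
        cfg = CountSimConfig(n_genes=300, concentrations=(1e-6,),
                             de_fraction=0.2, min_log2fc=2.0, max_log2fc=3.0,
                             seed=seed, gene_ec50_spread_log10=0.0,
                             baseline_meanlog=6.0)
        spec = CompoundSpec("cmp", "cI", {"tx": 1e-8}, {"tx": 2.0}, 1e-4)
        cm, meta, _ = generate_counts(cfg, spec)
        return prefilter(cm, meta)[:2]

    def test_duplicated_samples_get_identical_coordinates(self):
        cm, meta = self._counts()
        dup = cm.counts.copy()
        dup["dup_of_s0"] = dup.iloc[:, 0]
        from aopke import CountMatrix

        coords, _ = pca_overview(CountMatrix(dup), n_top=100)
        c = coords.set_index("sample_id")
        first = cm.sample_ids[0]
        assert c.loc["dup_of_s0", ["pc1", "pc2"]].to_numpy() == pytest.approx(
            c.loc[first, ["pc1", "pc2"]].to_numpy()
        )

    def test_explained_variance_fractions(self):
        cm, meta = self._counts()
        _, explained = pca_overview(cm, meta, n_top=100)
        assert 0.0 < sum(explained) <= 1.0

    def test_planted_clusters_separate(self):
        cm, meta = self._counts(seed=31)
        coords, _ = pca_overview(cm, meta, n_top=100)
        labels = (coords["concentration_M"] > 0).astype(int)
        score = silhouette_score(coords[["pc1", "pc2"]], labels)
        assert score > 0.5

    def test_needs_enough_genes(self):
        cm, meta = self._counts()
        with pytest.raises(ValueError):
            pca_overview(cm, meta, n_top=10_000)
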