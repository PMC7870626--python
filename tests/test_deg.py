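"""Prefilter, normalization, NB Wald test and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aopke import (
    CompoundSpec,
    CountMatrix,
    CountSimConfig,
    SampleMeta,
    benjamini_hochberg,
    call_degs,
    generate_counts,
    prefilter,
    size_factors,
)
from aopke import deg as degmod
from aopke.errors import AllSamplesRemoved, InsufficientReplicates, NoReferenceGenes


def _tx_spec(tx=1e-6):
    return CompoundSpec("cmp", "cI", {"tx": tx}, {"tx": 1.5}, 1e-4)


class TestPrefilter:
    def test_sample_total_threshold(self):
        # three samples with totals 250k / 150k / 300k -> middle removed
        base = np.full((100, 3), 2500, dtype=int)
        base[:, 1] = 1500
        base[:, 2] = 3000
        cm = CountMatrix(pd.DataFrame(base, index=[f"g{i}" for i in range(100)],
                                      columns=["a", "b", "c"]))
        filtered, report = prefilter(cm)
        assert filtered.sample_ids == ["a", "c"]
        assert "b" in report["removed_samples"]

    def test_gene_mean_threshold(self):
        arr = np.full((3, 3), 100_000, dtype=int)
        arr[1] = [1, 1, 2]  # mean 1.33 < 1.5
        cm = CountMatrix(pd.DataFrame(arr, index=["g0", "g1", "g2"],
                                      columns=["a", "b", "c"]))
        filtered, report = prefilter(cm)
        assert filtered.gene_ids == ["g0", "g2"]
        assert "g1" in report["removed_genes"]

    def test_passthrough_when_all_pass(self):
        arr = np.full((4, 2), 100_000, dtype=int)
        cm = CountMatrix(pd.DataFrame(arr, index=list("wxyz"), columns=["a", "b"]))
        filtered, report = prefilter(cm)
        assert filtered.counts.equals(cm.counts)
        assert not report["removed_samples"] and not report["removed_genes"]

    def test_all_samples_removed(self):
        cm = CountMatrix(pd.DataFrame([[5, 5]], index=["g"], columns=["a", "b"]))
        with pytest.raises(AllSamplesRemoved):
            prefilter(cm)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = CountMatrix(pd.DataFrame([[10, 10], [7, 7]], index=["g0", "g1"],
                                      columns=["a", "b"]))
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_column(self):
        cm = CountMatrix(pd.DataFrame([[10, 20], [50, 100]], index=["g0", "g1"],
                                      columns=["a", "b"]))
        sf = size_factors(cm)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_hand_worked_matrix(self):
        # ratios to geometric means are 1/sqrt(2) and sqrt(2) for every gene
        cm = CountMatrix(pd.DataFrame([[10, 20], [100, 200], [4, 8]],
                                      index=["g0", "g1", "g2"], columns=["a", "b"]))
        sf = size_factors(cm)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_no_reference_genes(self):
        cm = CountMatrix(pd.DataFrame([[0, 5], [5, 0]], index=["g0", "g1"],
                                      columns=["a", "b"]))
        with pytest.raises(NoReferenceGenes):
            size_factors(cm)

    def test_idempotence_on_normalized_matrix(self):
        rng = np.random.default_rng(0)
        raw = rng.poisson(50.0, size=(200, 4)) + 1
        raw[:, 2] *= 3
        cm = CountMatrix(pd.DataFrame(raw, index=[f"g{i}" for i in range(200)],
                                      columns=list("abcd")))
        sf = size_factors(cm)
        normalized = CountMatrix(
            pd.DataFrame(np.round(raw / sf.to_numpy()[None, :]).astype(int),
                         index=cm.gene_ids, columns=cm.sample_ids)
        )
        assert np.allclose(size_factors(normalized), 1.0, atol=0.05)


def _bh_bruteforce(p):
    """Step-up BH by direct enumeration over all ranks."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_hand_examples(self, p, expected):
        assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(1, 13)
            p = rng.uniform(0, 1, size=n)
            assert benjamini_hochberg(p) == pytest.approx(_bh_bruteforce(p))

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestWaldTest:
    def test_identical_groups_give_null_results(self, toy_counts):
        rng = np.random.default_rng(3)
        block = rng.poisson(100.0, size=(50, 3))
        cm, meta = toy_counts(np.hstack([block, block]), n_control=3)
        table = degmod.test_differential_expression(cm, meta, ("cmp", 1e-6))
        assert np.allclose(table["log2fc"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_insufficient_replicates(self, toy_counts):
        cm, meta = toy_counts(np.full((5, 3), 100), n_control=2)
        with pytest.raises(InsufficientReplicates):
            degmod.test_differential_expression(cm, meta, ("cmp", 1e-6))

    def test_planted_strong_gene_detected(self, toy_counts):
        """A gene at baseline 500 with true log2FC = 2 is found near 2."""
        rng = np.random.default_rng(21)
        n_genes = 400
        base = rng.lognormal(4.0, 1.0, size=n_genes)
        base[0] = 500.0
        alpha = 0.05
        means = np.tile(base[:, None], (1, 6))
        means[0, 3:] = 500.0 * 4.0  # log2FC = 2 in the treated group
        lam = rng.gamma(1.0 / alpha, means * alpha)
        cm, meta = toy_counts(rng.poisson(lam), n_control=3)
        table = degmod.test_differential_expression(cm, meta, ("cmp", 1e-6))
        assert table.iloc[0]["log2fc"] == pytest.approx(2.0, abs=0.5)
        assert table.iloc[0]["padj"] < 0.05

    def test_null_pvalues_uniform_under_label_permutation(self):
        """Permuted labels on null data leave p-values ~ Uniform(0,1)."""
        cfg = CountSimConfig(n_genes=1500, concentrations=(1e-6,),
                             de_fraction=0.0, dispersion=0.05, seed=17,
                             baseline_meanlog=5.0)
        cm, meta, _ = generate_counts(cfg, _tx_spec())
        cm, report = prefilter(cm)
        # permute condition labels across the 6 samples
        t = meta.table.copy()
        t["concentration_M"] = [0.0, 1e-6, 0.0, 1e-6, 0.0, 1e-6]
        table = degmod.test_differential_expression(cm, SampleMeta(t), ("cmp", 1e-6))
        ks = stats.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_power_monotone_in_planted_effect_size(self):
        """DEG recall is non-decreasing in the planted |log2FC|."""
        recalls = []
        for lfc in (0.5, 1.0, 2.0):
            cfg = CountSimConfig(
                n_genes=1000, concentrations=(1e-9, 1e-3), de_fraction=0.05,
                min_log2fc=lfc, max_log2fc=lfc, dispersion=0.05, seed=23,
                gene_ec50_spread_log10=0.0, baseline_meanlog=5.0,
            )
            cm, meta, truth = generate_counts(cfg, _tx_spec())
            cm, _ = prefilter(cm)
            table = degmod.test_differential_expression(cm, meta, ("cmp", 1e-3))
            call = call_degs(table)
            de = set(truth["params"].index[truth["params"]["is_de"]]) & set(table.index)
            recalls.append(len(set(call.genes) & de) / len(de))
        assert recalls == sorted(recalls)
        assert recalls[-1] > 0.8


class TestCallDegs:
    def _table(self, rows):
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                            columns=["log2fc", "p", "padj"])

    def test_default_rule_requires_fold_change_and_fdr(self):
        table = self._table([[0.7, 0.001, 0.04], [0.30, 0.001, 0.04], [-0.9, 0.5, 0.6]])
        call = call_degs(table)
        assert call.genes == ("g0",)  # g1 below 0.59, g2 above alpha
        assert call.n_deg == 1 and call.n_up == 1 and call.n_down == 0

    def test_fdr_only_rule_is_inclusive_at_alpha(self):
        table = self._table([[0.1, 0.01, 0.05], [0.0, 0.9, 0.9]])
        call = call_degs(table, rule="fdr_only")
        assert call.genes == ("g0",)

    def test_empty_table(self):
        assert call_degs(self._table([])).n_deg == 0

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            call_degs(self._table([]), rule="bogus")
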