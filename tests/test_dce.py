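"""DCe: link classification, LFC outlier screen, binomial enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from dclink.corr import FilteredLinkSet
from dclink.dce import (
    DIFF_SIGNED,
    REVERSED,
    SAME_SIGNED,
    binomial_enrich,
    classify_links,
    dce_run,
    lfc_select,
    link_features,
)


def binom_upper_tail_naive(n, k, rate):
    """Brute-force pmf summation oracle."""
    return sum(
        math.comb(n, j) * rate**j * (1 - rate) ** (n - j)
        for j in range(k, n + 1)
    )


def _fls(rows):
    df = pd.DataFrame(rows, columns=["gene_i", "gene_j", "pcc_x", "pcc_y"])
    df["q_x"] = 0.01
    df["q_y"] = 0.01
    return FilteredLinkSet(df)


class TestClassify:
    def test_three_way_partition(self):
        fls = _fls([
            ("a", "b", 0.9, -0.9),   # reversed: both strong, opposite
            ("a", "c", 0.7, 0.9),    # same-signed
            ("b", "c", 0.9, -0.3),   # diff-signed: only one side strong
            ("c", "d", -0.2, 0.1),   # diff-signed, both weak
            ("d", "e", 0.0, -0.5),   # zero counts as same-signed
        ])
        out = classify_links(fls, rho=0.8)
        cls = dict(zip(zip(out.gene_i, out.gene_j), out.cls))
        assert cls[("a", "b")] == REVERSED
        assert cls[("a", "c")] == SAME_SIGNED
        assert cls[("b", "c")] == DIFF_SIGNED
        assert cls[("c", "d")] == DIFF_SIGNED
        assert cls[("d", "e")] == SAME_SIGNED
        # partition: every link in exactly one class
        assert out.cls.isin([REVERSED, SAME_SIGNED, DIFF_SIGNED]).all()
        # reversed links are DCLs immediately
        assert out.set_index(["gene_i", "gene_j"]).loc[("a", "b"), "is_dcl"]

    def test_qth_mode_reversal(self):
        fls = _fls([("a", "b", 0.5, -0.5)])
        out = classify_links(fls, rho=None, q_th=0.05)
        assert out.iloc[0].cls == REVERSED

    def test_raising_rho_shrinks_reversed_set(self):
        rows = [(f"g{k}", f"h{k}", 0.5 + 0.05 * k, -(0.5 + 0.05 * k))
                for k in range(10)]
        fls = _fls(rows)
        small = set(classify_links(fls, rho=0.9).query("cls == @REVERSED").gene_i)
        large = set(classify_links(fls, rho=0.6).query("cls == @REVERSED").gene_i)
        assert small < large

    def test_mode_exclusivity(self):
        with pytest.raises(ValueError):
            classify_links(_fls([("a", "b", 0.5, 0.5)]), rho=0.8, q_th=0.25)

    def test_log_ratio_feature_finite_at_zero_correlation(self):
        feats = link_features(
            _fls([("a", "b", 0.0, 0.9)]).links
        )
        assert np.isfinite(feats.lfc).all()
        assert feats.max_corr.iloc[0] == pytest.approx(0.9)


class TestLFCSelect:
    @staticmethod
    def _cloud(n=400, seed=5):
        gen = np.random.default_rng(seed)
        x = gen.uniform(0.3, 1.0, n)
        resp = gen.uniform(0.0, 0.2, n)
        df = pd.DataFrame({
            "gene_i": [f"a{k}" for k in range(n)],
            "gene_j": [f"b{k}" for k in range(n)],
            "pcc_x": x, "pcc_y": x,
            "max_corr": x, "lfc": resp,
        })
        return df

    def test_planted_outlier_is_flagged(self):
        df = self._cloud()
        df.loc[0, "lfc"] = 5.0  # far above the homogeneous cloud
        flags, fit = lfc_select(df, "max_corr", "lfc", delta=0.1)
        assert flags[0]
        assert not fit.fallback

    def test_flat_response_falls_back_to_per_bin_fraction(self):
        df = self._cloud()
        df["lfc"] = 0.07  # identical response everywhere
        flags, fit = lfc_select(df, "max_corr", "lfc", n_bins=10, delta=0.1)
        assert fit.fallback
        # exactly the per-bin ceil(0.1 * bin size) outliers are flagged
        bins = np.clip(
            np.searchsorted(fit.bin_edges, df.max_corr, side="right") - 1,
            0, len(fit.bin_edges) - 2,
        )
        for b in np.unique(bins):
            size = int((bins == b).sum())
            assert flags[bins == b].sum() == math.ceil(0.1 * size)

    def test_zero_lfc_link_not_flagged_with_positive_boundary(self):
        df = self._cloud()
        df.loc[1, "lfc"] = 0.0  # x == y: no coexpression change
        flags, fit = lfc_select(df, "max_corr", "lfc", delta=0.1)
        assert fit.curve(df.loc[1, "max_corr"]) > 0
        assert not flags[1]

    def test_lowering_delta_shrinks_outlier_sets(self):
        # the per-bin outlier logic is isolated via a flat response
        df_flat = self._cloud().assign(lfc=0.07)
        s_flags, _ = lfc_select(df_flat, "max_corr", "lfc", delta=0.05)
        l_flags, _ = lfc_select(df_flat, "max_corr", "lfc", delta=0.2)
        assert set(np.flatnonzero(s_flags)) <= set(np.flatnonzero(l_flags))

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            lfc_select(self._cloud(), "max_corr", "lfc", delta=0.0)


class TestBinomialEnrich:
    def test_zero_hits_give_p_one(self):
        assert binomial_enrich(5, 0, 10, 100) == pytest.approx(1.0)

    def test_two_of_two_at_half(self):
        assert binomial_enrich(2, 2, 50, 100) == pytest.approx(0.25)

    def test_known_value(self):
        assert binomial_enrich(10, 3, 10, 100) == pytest.approx(
            0.0701908264, abs=1e-9
        )

    def test_degenerate_rates(self):
        assert binomial_enrich(4, 0, 0, 100) == pytest.approx(1.0)
        assert binomial_enrich(4, 4, 100, 100) == pytest.approx(1.0)

    def test_monotone_nonincreasing_in_k(self):
        p = binomial_enrich([20] * 21, list(range(21)), 10, 100)
        assert (np.diff(p) <= 1e-15).all()

    def test_matches_bruteforce_on_small_grid(self):
        for rate_kn in [(1, 100), (10, 100), (50, 100)]:
            K, N = rate_kn
            for n in (1, 5, 17):
                for k in range(n + 1):
                    assert binomial_enrich(n, k, K, N) == pytest.approx(
                        binom_upper_tail_naive(n, k, K / N), abs=1e-12
                    )

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            binomial_enrich(3, 4, 10, 100)
        with pytest.raises(ValueError):
            binomial_enrich(3, 1, 101, 100)


class TestDceRun:
    def test_no_flagged_links_all_p_one(self):
        # identical, moderate, same-signed correlations: nothing to flag
        rows = [(f"g{k}", f"h{k}", 0.5, 0.5) for k in range(30)]
        dcl, dcg = dce_run(_fls(rows), rho=0.8)
        if int(dcl.is_dcl.sum()) == 0:
            assert np.allclose(dcg.p, 1.0)

    def test_all_reversed_is_degenerate_rate_one(self):
        rows = [(f"g{k}", f"h{k}", 0.9, -0.9) for k in range(10)]
        dcl, dcg = dce_run(_fls(rows), rho=0.8)
        assert dcl.is_dcl.all()
        assert np.allclose(dcg.p, 1.0)

    def test_hub_gene_with_all_dcls_ranks_first(self):
        gen = np.random.default_rng(4)
        rows = [("hub", f"n{k}", 0.9, -0.9) for k in range(6)]
        for k in range(60):
            r = gen.uniform(0.4, 0.7)
            rows.append((f"x{k}", f"y{k}", r, r + gen.uniform(-0.05, 0.05)))
        dcl, dcg = dce_run(_fls(rows), rho=0.8)
        assert dcg.iloc[0].gene == "hub"
        assert dcg.iloc[0].p == dcg.p.min()

    def test_restriction_drops_untouched_dcls(self):
        rows = [("a", "b", 0.9, -0.9), ("c", "d", 0.9, -0.9),
                ("e", "f", 0.5, 0.5)]
        dcl, _ = dce_run(_fls(rows), rho=0.8, restrict_to_genes=["a"])
        kept_dcls = set(zip(dcl[dcl.is_dcl].gene_i, dcl[dcl.is_dcl].gene_j))
        assert ("a", "b") in kept_dcls
        assert ("c", "d") not in kept_dcls

    def test_endpoint_count_bookkeeping(self):
        rows = [("a", "b", 0.9, -0.9), ("a", "c", 0.6, 0.5),
                ("b", "c", 0.4, 0.45)]
        dcl, dcg = dce_run(_fls(rows), rho=0.8)
        N, K = len(dcl), int(dcl.is_dcl.sum())
        assert dcg.n_links.sum() == 2 * N
        assert dcg.n_dcl.sum() == 2 * K
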