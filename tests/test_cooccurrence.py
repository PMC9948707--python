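"""Spearman screen, BH adjustment, transitive pruning, absolute abundance,
environmental correlations, network summary and rank-density binning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from seaphage.cooccurrence import (
    asv_asv_pairs,
    bh_adjust,
    env_correlations,
    prune_transitive,
    rank_vs_density,
    screen,
    spearman_matrix,
    summarize_network,
    to_absolute,
)


def _months(n=18):
    return [f"M{i:02d}" for i in range(n)]


def _pairs_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=["asv_id", "contig_id", "rho", "p", "q", "significant", "supported"],
    )
    df["cooccurring"] = df["significant"] & df["supported"]
    df["pruned"] = False
    return df


class TestSpearmanMatrix:
    def test_matches_scipy_pairwise(self, rng):
        a = pd.DataFrame(rng.random((4, 15)))
        b = pd.DataFrame(rng.random((3, 15)))
        rho, p = spearman_matrix(a, b)
        for i in range(4):
            for j in range(3):
                r_ref, p_ref = spearmanr(a.iloc[i], b.iloc[j])
                assert rho[i, j] == pytest.approx(r_ref, abs=1e-12)
                assert p[i, j] == pytest.approx(p_ref, rel=1e-9)


class TestScreen:
    def test_monotone_pair_significant_anticorrelated_not(self, rng):
        months = _months()
        base = np.linspace(1, 2, 18) + rng.normal(0, 1e-3, 18)
        asv = pd.DataFrame([base], index=["ASVx"], columns=months)
        viral = pd.DataFrame(
            [np.exp(base), -base + 4], index=["vUp", "vDown"], columns=months
        )
        out = screen(
            asv, viral,
            {"vUp": "TaxA", "vDown": "TaxA"}, {"ASVx": "TaxA"},
        ).set_index("contig_id")
        assert out.loc["vUp", "significant"] and out.loc["vUp", "cooccurring"]
        assert out.loc["vUp", "rho"] == pytest.approx(1.0)
        assert not out.loc["vDown", "significant"]  # rho = -1 fails one-sided gate

    def test_unsupported_pair_not_cooccurring(self, rng):
        months = _months()
        base = np.linspace(0.1, 1.0, 18)
        asv = pd.DataFrame([base], index=["ASVx"], columns=months)
        viral = pd.DataFrame([base * 2], index=["v"], columns=months)
        out = screen(asv, viral, {"v": "TaxB"}, {"ASVx": "TaxA"})
        assert bool(out.loc[0, "significant"])
        assert not bool(out.loc[0, "supported"])
        assert not bool(out.loc[0, "cooccurring"])

    def test_too_few_shared_samples_rejected(self):
        asv = pd.DataFrame(np.ones((1, 5)), columns=_months(5))
        viral = pd.DataFrame(np.ones((1, 5)), columns=_months(5))
        with pytest.raises(ValueError):
            screen(asv, viral, {}, {})


class TestBhAdjust:
    def test_monotone_and_dominates_p(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_permutation_invariance(self, rng):
        p = rng.random(30)
        perm = rng.permutation(30)
        q = bh_adjust(p)
        assert np.allclose(bh_adjust(p[perm]), q[perm])


class TestPruneTransitive:
    def asv_edges(self, pairs):
        df = pd.DataFrame(pairs, columns=["asv_a", "asv_b"])
        df["rho"], df["p"], df["q"], df["significant"] = 0.9, 1e-4, 1e-3, True
        return df

    def test_worked_example_pruned(self):
        pairs = _pairs_frame([
            ("X", "A", 0.8, 1e-3, 1e-2, True, False),   # unsupported
            ("Y", "A", 0.9, 1e-4, 1e-3, True, True),    # supported partner
        ])
        out = prune_transitive(pairs, self.asv_edges([("X", "Y")]))
        res = out.set_index("asv_id")
        assert bool(res.loc["X", "pruned"])
        assert not bool(res.loc["Y", "pruned"])

    def test_no_supported_partner_retained(self):
        pairs = _pairs_frame([("X", "A", 0.8, 1e-3, 1e-2, True, False)])
        out = prune_transitive(pairs, self.asv_edges([("X", "Y")]))
        assert not out["pruned"].any()

    def test_supported_pairs_never_pruned(self):
        pairs = _pairs_frame([
            ("X", "A", 0.8, 1e-3, 1e-2, True, True),
            ("Y", "A", 0.9, 1e-4, 1e-3, True, True),
        ])
        out = prune_transitive(pairs, self.asv_edges([("X", "Y")]))
        assert not out["pruned"].any()

    def test_pruning_monotone_in_asv_edges(self):
        pairs = _pairs_frame([
            ("X", "A", 0.8, 1e-3, 1e-2, True, False),
            ("Y", "A", 0.9, 1e-4, 1e-3, True, True),
            ("Z", "B", 0.8, 1e-3, 1e-2, True, False),
            ("W", "B", 0.9, 1e-4, 1e-3, True, True),
        ])
        few = prune_transitive(pairs, self.asv_edges([("X", "Y")]))
        more = prune_transitive(pairs, self.asv_edges([("X", "Y"), ("Z", "W")]))
        assert more["pruned"].sum() >= few["pruned"].sum()


class TestToAbsolute:
    def test_multiplication_and_missing_months(self):
        rel = pd.DataFrame({"m1": [0.01], "m2": [0.5]}, index=["a"])
        counts = pd.Series({"m1": 1e6, "m2": np.nan})
        out = to_absolute(rel, counts)
        assert list(out.columns) == ["m1"]
        assert out.loc["a", "m1"] == pytest.approx(1e4)

    def test_negative_counts_rejected(self):
        rel = pd.DataFrame({"m1": [0.1]})
        with pytest.raises(ValueError):
            to_absolute(rel, pd.Series({"m1": -5.0}))

    def test_zero_relative_zero_absolute(self):
        rel = pd.DataFrame({"m1": [0.0]}, index=["a"])
        out = to_absolute(rel, pd.Series({"m1": 1e6}))
        assert out.loc["a", "m1"] == 0.0


class TestEnvCorrelations:
    def test_signs_and_constant_variable(self, rng):
        months = _months()
        temp = np.linspace(10, 28, 18) + rng.normal(0, 0.01, 18)
        asv = pd.DataFrame(
            [temp, -temp + 40], index=["warm", "cold"], columns=months
        )
        variables = pd.DataFrame({"temp": temp, "flat": np.ones(18)}, index=months)
        with pytest.warns(UserWarning, match="flat"):
            out = env_correlations(asv, variables)
        out = out.set_index("asv_id")
        assert set(out["variable"]) == {"temp"}
        assert out.loc["warm", "sign"] == 1 and bool(out.loc["warm", "significant"])
        assert out.loc["cold", "sign"] == -1 and bool(out.loc["cold", "significant"])


class TestNetworkSummary:
    def test_degrees_and_median(self):
        pairs = _pairs_frame([
            ("A", "v1", 0.9, 1e-3, 1e-2, True, True),
            ("A", "v2", 0.9, 1e-3, 1e-2, True, True),
            ("A", "v3", 0.9, 1e-3, 1e-2, True, True),
            ("B", "v4", 0.9, 1e-3, 1e-2, True, True),
        ])
        s = summarize_network(pairs, ["A", "B", "C"], {"A": "t1", "B": "t2", "C": "t2"})
        assert s["degree"]["A"] == 3 and s["degree"]["C"] == 0
        assert s["median_viruses_per_asv"] == 1.0
        assert s["pairs_by_taxon"] == {"t1": 3, "t2": 1}

    def test_no_pairs_all_zero(self):
        pairs = _pairs_frame([])
        s = summarize_network(pairs, ["A", "B"])
        assert s["n_pairs"] == 0 and set(s["degree"].index) == {"A", "B"}


class TestRankVsDensity:
    def test_bin_edges(self):
        months = ["M00", "M01", "M02"]
        host = pd.DataFrame([[0.02, 0.005, 0.0005]], index=["A"], columns=months)
        viral = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
                             index=["v1", "v2"], columns=months)
        pairs = _pairs_frame([("A", "v1", 0.9, 1e-3, 1e-2, True, True)])
        out = rank_vs_density(viral, host, pairs)
        assert out.loc[">1%", "n"] == 1
        assert out.loc["0.1-1%", "n"] == 1
        assert out.loc["<0.1%", "n"] == 1

    def test_planted_monotonicity(self, dataset):
        from seaphage.pipeline import run_cooccurrence

        run = run_cooccurrence(dataset)
        out = rank_vs_density(run.viral_fpkm.loc[run.filtered_contigs],
                              run.asv_rel, run.pairs)
        assert out.loc[">1%", "median"] > out.loc["<0.1%", "median"]


def test_asv_asv_screen_family_is_symmetric_free(rng):
    months = _months()
    rel = pd.DataFrame(rng.dirichlet(np.ones(5), 18).T,
                       index=list("abcde"), columns=months)
    out = asv_asv_pairs(rel)
    assert len(out) == 10  # C(5,2) unordered pairs
    assert not (out["asv_a"] == out["asv_b"]).any()
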