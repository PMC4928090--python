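"""Fisher exact machinery, presence rule, TF catalog, subnetworks."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from xdiverge.tfbs import (
    fisher_pvalue,
    ContingencyTable,
    build_presence,
    define_apoptosis_tfs,
    enrich_tfbs,
    extract_subnetwork,
    fisher_exact,
)

# the published apoptosis-scope enrichment table: presence/absence counts
# among divergent vs non-divergent ortholog pairs, with the printed
# two-sided Fisher P and conditional-MLE odds ratio.
PUBLISHED_ROWS = [
    ("STAT1", 15, 9, 8, 33, 6.63, 9.84e-4),
    ("NFKB1", 13, 11, 8, 33, 4.74, 5.98e-3),
    ("Bcl6", 14, 10, 10, 31, 4.23, 8.44e-3),
    ("Esrrb", 10, 14, 6, 35, 4.06, 1.95e-2),
    ("CEBPA", 16, 8, 15, 26, 3.40, 2.31e-2),
    ("REL", 9, 15, 5, 36, 4.21, 2.73e-2),
    ("YY1", 12, 12, 9, 32, 3.48, 2.83e-2),
    ("Stat5a::Stat5b", 12, 12, 9, 32, 3.48, 2.83e-2),
    ("Nkx3-2", 10, 14, 7, 34, 3.40, 4.16e-2),
    ("ESRRA", 11, 13, 8, 33, 3.42, 4.61e-2),
]


def exact_two_sided_fisher(a, b, c, d) -> Fraction:
    """Full-support enumeration with exact rational point probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


class TestFisher:
    @pytest.mark.parametrize("tf,a,b,c,d,or_pub,p_pub", PUBLISHED_ROWS)
    def test_published_rows_reproduce(self, tf, a, b, c, d, or_pub, p_pub):
        p, orr = fisher_exact(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(p_pub, rel=5e-3)
        # printed to 2 decimals; allow CMLE solver slop at rounding edges
        assert orr == pytest.approx(or_pub, abs=0.01)

    def test_symmetric_table(self):
        p, orr = fisher_exact(ContingencyTable(5, 5, 5, 5))
        assert p == 1.0
        assert orr == pytest.approx(1.0, abs=1e-9)

    def test_diagonal_three_by_three(self):
        """(3,0,0,3): support of 4 tables, two with probability 1/20."""
        p, _ = fisher_exact(ContingencyTable(3, 0, 0, 3))
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_zero_margin_contract(self):
        p, orr = fisher_exact(ContingencyTable(0, 0, 3, 5))
        assert p == 1.0 and np.isnan(orr)

    def test_pvalues_match_full_support_enumeration(self):
        """Oracle suite: every 2x2 table with total N <= 40.

        The oracle enumerates the conditional support with exact integer
        numerators over the common denominator C(n, c1), so probability
        ties and the point-probability rule are decided exactly.
        """
        checked = 0
        for r1 in range(1, 40):
            for r2 in range(1, 41 - r1):
                n = r1 + r2
                for c1 in range(1, n):
                    lo, hi = max(0, c1 - r2), min(r1, c1)
                    nums = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
                    denom = comb(n, c1)
                    for a in range(lo, hi + 1):
                        obs = nums[a - lo]
                        expected = sum(v for v in nums if v <= obs) / denom
                        got = fisher_pvalue(a, r1 - a, c1 - a, r2 - (c1 - a))
                        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12), (
                            a, r1 - a, c1 - a, r2 - (c1 - a)
                        )
                        checked += 1
        assert checked > 100_000

    def test_pvalues_cross_check_scipy_fisher(self):
        """Independent route: scipy's own Fisher test on random tables."""
        from scipy.stats import fisher_exact as sp_fisher

        rng = np.random.default_rng(3)
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 25, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            ours = fisher_pvalue(a, b, c, d)
            ref = sp_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_cmle_is_shrunk_from_cross_product_toward_one(self):
        """For tables with a*d > b*c the conditional MLE lies in (1, OR_xp)."""
        for (_, a, b, c, d, *_rest) in PUBLISHED_ROWS:
            _, orr = fisher_exact(ContingencyTable(a, b, c, d))
            xp = (a * d) / (b * c)
            assert 1.0 < orr < xp
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 12, size=4)
            if a * d <= b * c:
                a, b = b, a
                c, d = d, c
            if a * d == b * c:
                continue
            _, orr = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert 0.0 < orr < (a * d) / (b * c) + 1e-9

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestPresence:
    def _pairs(self, n):
        ids = [f"gA{i}|gB{i}" for i in range(n)]
        return pd.DataFrame({
            "gene_a": [f"gA{i}" for i in range(n)],
            "gene_b": [f"gB{i}" for i in range(n)],
        }, index=ids)

    def test_either_species_rule(self):
        pairs = self._pairs(3)
        hits_a = pd.DataFrame({"gene_id": ["gA0"], "motif_id": ["M"]})
        hits_b = pd.DataFrame({"gene_id": ["gB1"], "motif_id": ["M"]})
        pres = build_presence(hits_a, hits_b, pairs)
        assert pres["M"].tolist() == [True, True, False]

    def test_presence_is_symmetric_in_species_order(self):
        rng = np.random.default_rng(10)
        pairs = self._pairs(20)
        ha = pd.DataFrame({
            "gene_id": rng.choice(pairs["gene_a"], size=12),
            "motif_id": rng.choice(["M1", "M2"], size=12),
        })
        hb = pd.DataFrame({
            "gene_id": rng.choice(pairs["gene_b"], size=12),
            "motif_id": rng.choice(["M1", "M2"], size=12),
        })
        fwd = build_presence(ha, hb, pairs)
        swapped_pairs = pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        rev = build_presence(hb, ha, swapped_pairs)
        assert fwd.equals(rev)

    def test_pair_without_promoter_is_excluded(self):
        pairs = self._pairs(3)
        hits = pd.DataFrame({"gene_id": [], "motif_id": []})
        pres = build_presence(hits, hits, pairs,
                              promoters_a={"gA0", "gA1"},
                              promoters_b={"gB0", "gB1", "gB2"})
        assert list(pres.index) == ["gA0|gB0", "gA1|gB1"]

    def test_known_planted_fixture(self):
        pairs = self._pairs(20)
        planted_a = {0, 3, 7}
        planted_b = {3, 11}
        ha = pd.DataFrame({"gene_id": [f"gA{i}" for i in planted_a],
                           "motif_id": "M"})
        hb = pd.DataFrame({"gene_id": [f"gB{i}" for i in planted_b],
                           "motif_id": "M"})
        pres = build_presence(ha, hb, pairs)
        expected = [i in (planted_a | planted_b) for i in range(20)]
        assert pres["M"].tolist() == expected


class TestEnrichTFBS:
    def test_reconstructed_contingency_row_matches_fisher_op(self):
        """A fixture with a=15, b=9, c=8, d=33 reproduces the direct test."""
        n_div, n_non = 24, 41
        ids = [f"p{i}" for i in range(n_div + n_non)]
        divergent = set(ids[:n_div])
        present = [True] * 15 + [False] * 9 + [True] * 8 + [False] * 33
        presence = pd.DataFrame({"STAT1": present}, index=ids)
        table = enrich_tfbs(presence, divergent)
        row = table.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (15, 9, 8, 33)
        p, orr = fisher_exact(ContingencyTable(15, 9, 8, 33))
        assert row["pvalue"] == p and row["odds_ratio"] == orr

    def test_motif_present_everywhere_is_uninformative(self):
        ids = [f"p{i}" for i in range(30)]
        presence = pd.DataFrame({"M": [True] * 30}, index=ids)
        table = enrich_tfbs(presence, set(ids[:10]))
        assert table.iloc[0]["pvalue"] == 1.0

    def test_empty_scope_rejected(self):
        presence = pd.DataFrame({"M": [True]}, index=["p0"])
        with pytest.raises(ValueError):
            enrich_tfbs(presence, set(), scope=set())

    def test_scope_must_be_subset_of_presence_rows(self):
        presence = pd.DataFrame({"M": [True]}, index=["p0"])
        with pytest.raises(ValueError, match="scope"):
            enrich_tfbs(presence, set(), scope={"p0", "zzz"})

    def test_permuted_labels_are_calibrated(self):
        """Permuting divergence labels yields near-uniform p-values."""
        rng = np.random.default_rng(20)
        ids = [f"p{i}" for i in range(120)]
        presence = pd.DataFrame(
            rng.uniform(size=(120, 10)) < 0.35, index=ids,
            columns=[f"M{k}" for k in range(10)],
        )
        frac_below = []
        for _ in range(50):
            labels = set(rng.choice(ids, size=40, replace=False))
            table = enrich_tfbs(presence, labels)
            frac_below.append(np.mean(table["pvalue"] < 0.05))
        assert np.mean(frac_below) <= 0.08


class TestCatalogAndNetwork:
    def test_apoptosis_keyword_rule(self):
        go = {
            "tf1": ["regulation of apoptotic process"],
            "tf2": ["programmed cell death"],
            "tf3": ["intrinsic apoptosis signaling"],
            "tf4": ["DNA repair"],
        }
        cat = define_apoptosis_tfs(["tf1", "tf2", "tf3", "tf4"], go).set_index("gene_id")
        assert cat.loc["tf1", "is_apoptosis_related"]
        assert not cat.loc["tf2", "is_apoptosis_related"]  # literal rule
        assert cat.loc["tf3", "is_apoptosis_related"]
        assert not cat.loc["tf4", "is_apoptosis_related"]
        assert cat["is_tf"].all()

    def test_fixture_count(self):
        go = {f"tf{i}": (["apoptotic process"] if i < 4 else ["metabolism"])
              for i in range(10)}
        cat = define_apoptosis_tfs(list(go), go)
        assert int(cat["is_apoptosis_related"].sum()) == 4

    def test_star_graph_fully_connected(self):
        edges = pd.DataFrame({
            "source": ["hub"] * 4,
            "target": [f"t{i}" for i in range(4)],
            "type": ["physical"] * 4,
        })
        _, summary = extract_subnetwork(edges, {"hub", "t0", "t1", "t2", "t3"})
        assert summary["fraction_connected"] == 1.0

    def test_disjoint_pairs_and_isolate(self):
        edges = pd.DataFrame({
            "source": ["a", "c"], "target": ["b", "d"],
            "type": ["physical", "genetic"],
        })
        _, summary = extract_subnetwork(edges, {"a", "b", "c", "d", "e"})
        assert summary["n_query_in_largest_component"] == 2
        assert summary["fraction_connected"] == pytest.approx(2 / 5)

    def test_intermediates_bridge_query_nodes(self):
        """Two TFs connected only through a shared non-query partner."""
        edges = pd.DataFrame({
            "source": ["tfA", "tfB", "x"], "target": ["mid", "mid", "y"],
            "type": ["physical", "physical", "physical"],
        })
        _, summary = extract_subnetwork(edges, {"tfA", "tfB"}, intermediates={"mid"})
        assert summary["fraction_connected"] == 1.0
        _, no_mid = extract_subnetwork(edges, {"tfA", "tfB"})
        assert no_mid["fraction_connected"] == 0.5
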