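"""Site projection, group consensus, p-distance, NJ tree and strain ranking."""

import numpy as np
import pandas as pd
import pytest

from gutsnp import strain_phylo as sp
from gutsnp.bias_snp import BiasSnpRecord, detect_bias_snps
from gutsnp.io_formats import MISSING, GenomeSiteMap, ValidationError

from conftest import make_site
from helpers import random_additive_tree


def bias(gene, pos, a="A", b="G"):
    return BiasSnpRecord(gene, pos, "A", a, 0.9, b, 0.9)


BIAS10 = [bias("g1", p) for p in range(1, 11)]


def gmap(strain, n_present, base="A"):
    entries = {
        ("g1", p): (base if p <= n_present else MISSING) for p in range(1, 11)
    }
    return GenomeSiteMap(strain, entries)


class TestProjectSites:
    def test_above_seventy_percent_kept(self):
        m = sp.project_sites(BIAS10, [gmap("s8", 8)], 0.7)
        assert list(m.index) == ["s8"]
        assert (m.loc["s8"][:8] == "A").all() and (m.loc["s8"][8:] == MISSING).all()

    def test_seventy_percent_exactly_dropped(self):
        with pytest.raises(ValidationError):  # no strain remains
            sp.project_sites(BIAS10, [gmap("s7", 7)], 0.7)

    def test_coverage_filter_monotone_in_min_cov(self):
        maps = [gmap(f"s{n}", n) for n in range(1, 11)]
        sizes = [
            len(sp.project_sites(BIAS10, maps, c)) for c in (0.1, 0.4, 0.7, 0.9)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_bias_set_rejected(self):
        with pytest.raises(ValidationError):
            sp.project_sites([], [gmap("s8", 8)])


class TestGroupConsensus:
    def test_unanimous(self):
        site = make_site("g1", 1, "A", **{f"s{i}": {"A": 10} for i in range(4)})
        cons = sp.group_consensus([site], [bias("g1", 1)], [f"s{i}" for i in range(4)])
        assert cons["g1:1"] == "A"

    def test_majority_three_to_two(self):
        counts = {f"s{i}": ({"A": 10} if i < 3 else {"G": 10}) for i in range(5)}
        site = make_site("g1", 1, "A", **counts)
        cons = sp.group_consensus([site], [bias("g1", 1)], list(counts))
        assert cons["g1:1"] == "A"

    def test_consensus_matches_detected_group_allele(self):
        # when detection succeeded at prevalence > 0.5, the majority of
        # dominants must equal the detected allele
        rng = np.random.default_rng(47)
        ga = [f"a{i}" for i in range(6)]
        gb = [f"b{i}" for i in range(6)]
        counts = {}
        for s in ga:
            dom = "A" if rng.random() < 0.85 else "G"
            counts[s] = {dom: 18, ("G" if dom == "A" else "A"): 2}
        for s in gb:
            dom = "G" if rng.random() < 0.85 else "A"
            counts[s] = {dom: 18, ("G" if dom == "G" else "A"): 2}
        site = make_site("g1", 1, "A", **counts)
        recs = detect_bias_snps([site], ga, gb)
        for rec in recs:
            cons_a = sp.group_consensus([site], recs, ga)
            cons_b = sp.group_consensus([site], recs, gb)
            assert cons_a["g1:1"] == rec.group_a_allele
            assert cons_b["g1:1"] == rec.group_b_allele


class TestPDistance:
    def _frame(self, rows):
        return pd.DataFrame(
            {name: list(seq) for name, seq in rows.items()}
        ).T

    def test_identical_rows_zero(self):
        d, _ = sp.p_distance(self._frame({"x": "ACGT", "y": "ACGT"}))
        assert d.at["x", "y"] == 0

    def test_one_mismatch_in_four(self):
        d, _ = sp.p_distance(self._frame({"x": "AAAA", "y": "AAAT"}))
        assert d.at["x", "y"] == pytest.approx(0.25)

    def test_pairwise_deletion(self):
        d, shared = sp.p_distance(self._frame({"x": "AA..", "y": "AAGG"}))
        assert d.at["x", "y"] == 0
        assert shared.at["x", "y"] == 2

    def test_no_shared_sites_rejected(self):
        with pytest.raises(ValidationError, match="share no"):
            sp.p_distance(self._frame({"x": "AA..", "y": "..GG"}))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(53)
        rows = {
            f"r{i}": "".join(rng.choice(list("ACGT"), size=20)) for i in range(5)
        }
        d, _ = sp.p_distance(self._frame(rows))
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0)


class TestNjTree:
    def _patristic(self, newick, names):
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        n = len(names)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = pdm.distance(tax[names[i]], tax[names[j]])
        return out

    def test_three_taxon_closed_form(self):
        # dAB=3, dAC=4, dBC=5 -> branches 1, 2, 3
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        newick = sp.nj_tree(d)
        pat = self._patristic(newick, list("ABC"))
        assert pat[0, 1] == pytest.approx(3, abs=1e-9)
        assert pat[0, 2] == pytest.approx(4, abs=1e-9)
        assert pat[1, 2] == pytest.approx(5, abs=1e-9)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(59)
        _, dist, names = random_additive_tree(rng, 4)
        d = pd.DataFrame(dist, index=names, columns=names)
        pat = self._patristic(sp.nj_tree(d), names)
        assert np.allclose(pat, dist, atol=1e-9)

    def test_matches_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(61)
        _, dist, names = random_additive_tree(rng, 6)
        d = pd.DataFrame(dist, index=names, columns=names)
        pat = self._patristic(sp.nj_tree(d), names)
        ref = skbio.tree.nj(skbio.DistanceMatrix(dist, ids=names))
        ref_pat = np.array(
            [[ref.find(a).distance(ref.find(b)) for b in names] for a in names]
        )
        assert np.allclose(pat, ref_pat, atol=1e-6)

    def test_fewer_than_three_taxa_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
        with pytest.raises(ValidationError):
            sp.nj_tree(d)

    def test_asymmetric_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC")
        )
        with pytest.raises(ValidationError):
            sp.nj_tree(d)


class TestClosestStrains:
    DIST = pd.DataFrame(
        [[0.0, 0.0, 0.3, 0.3], [0.0, 0.0, 0.3, 0.3],
         [0.3, 0.3, 0.0, 0.2], [0.3, 0.3, 0.2, 0.0]],
        index=["q", "hit", "s1", "s2"], columns=["q", "hit", "s1", "s2"],
    )

    def test_zero_distance_ranks_first(self):
        t = sp.closest_strains(self.DIST, "q")
        assert t["strain"].iloc[0] == "hit" and t["rank"].iloc[0] == 1

    def test_equidistant_strains_share_rank(self):
        t = sp.closest_strains(self.DIST, "q", ["s1", "s2"])
        assert list(t["rank"]) == [1, 1] and t["tie"].all()

    def test_missing_query_rejected(self):
        with pytest.raises(ValidationError):
            sp.closest_strains(self.DIST, "nope")


class TestAlignmentExport:
    MATRIX = pd.DataFrame(
        [["A", "C", MISSING], ["G", "T", "A"]],
        index=["r1", "r2"], columns=["g1:1", "g1:5", "g2:2"],
    )

    def test_fasta_roundtrip_with_missing_as_n(self, tmp_path):
        p = tmp_path / "aln.fasta"
        sp.export_alignment(self.MATRIX, p, "fasta")
        text = p.read_text()
        assert ">r1\nACN\n" in text
        back = sp.read_alignment_fasta(p, self.MATRIX.columns)
        pd.testing.assert_frame_equal(back, self.MATRIX)

    def test_phylip_header(self, tmp_path):
        p = tmp_path / "aln.phy"
        sp.export_alignment(self.MATRIX, p, "phylip")
        assert p.read_text().splitlines()[0].split() == ["2", "3"]

    def test_duplicate_names_rejected(self, tmp_path):
        m = self.MATRIX.copy()
        m.index = ["r1", "r1"]
        with pytest.raises(ValidationError):
            sp.export_alignment(m, tmp_path / "x.fasta")


class TestFlankMapping:
    GENE = "ATGCAGTTCGACAAGGTCTGGAATTAA"

    def test_unique_forward_hit(self):
        genome = "TTTT" + self.GENE + "CCCCC"
        m = sp.map_sites_by_flank({"g1": self.GENE}, [("g1", 10)], genome, "st", 5)
        assert m.entries[("g1", 10)] == self.GENE[9]

    def test_reverse_strand_hit(self):
        genome = "TT" + sp._revcomp(self.GENE) + "AA"
        m = sp.map_sites_by_flank({"g1": self.GENE}, [("g1", 10)], genome, "st", 5)
        assert m.entries[("g1", 10)] == self.GENE[9]

    def test_absent_or_ambiguous_is_missing(self):
        m = sp.map_sites_by_flank({"g1": self.GENE}, [("g1", 10)], "AAAATTTT", "st", 5)
        assert m.entries[("g1", 10)] == MISSING
        genome = self.GENE + self.GENE  # two hits
        m = sp.map_sites_by_flank({"g1": self.GENE}, [("g1", 10)], genome, "st", 5)
        assert m.entries[("g1", 10)] == MISSING
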