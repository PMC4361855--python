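"""Protein clustering and pan-genome statistics against independent oracles."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from poolvar.pangenome import (
    ProteinFamily,
    ProteinRecord,
    SimilarityEdge,
    build_similarity_edges,
    classify_and_summarize,
    cluster_families,
    density_profile,
    pairwise_similarity,
)
from poolvar.synthetic_data import simulate_proteomes

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def prot(pid, seq, sp="sp1", pos=None, clen=None):
    return ProteinRecord(
        protein_id=pid, species_id=sp, sequence=seq,
        chrom_pos=pos, chrom_length=clen,
    )


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def gotoh_local_score(a, b, gap_open=12, gap_extend=1):
    """Independent affine-gap Smith-Waterman DP (full matrices)."""
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(
                0.0,
                max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s,
            )
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            best = max(best, M[i, j])
    return best


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKA"
        e = pairwise_similarity(prot("a", seq), prot("b", seq))
        assert e.pct_identity == pytest.approx(100.0)
        assert e.cov_query == pytest.approx(1.0)
        assert e.cov_subject == pytest.approx(1.0)

    def test_half_sequence_coverage(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"
        half = seq[: len(seq) // 2]
        e = pairwise_similarity(prot("full", seq), prot("half", half))
        assert e.cov_subject == pytest.approx(1.0)
        assert e.cov_query == pytest.approx(0.5, abs=0.05)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity(prot("a", "MKT"), prot("b", ""))

    @pytest.mark.parametrize(
        "a,b",
        [
            ("MKTAYIAKQRQISFVKSHFSRQLEERLGLI", "MKTAYIAKQRQISFVKSHF"),
            ("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY"[::-1]),
            ("MKWVTFISLLLLFSSAYSRGVFRRDTHKSE", "MKWVTFISLLFLFSSAYSRGVFRRDAHKSE"),
            ("GGGGGGGGGGAAAAAAAAAA", "GGGGGGGGGGCCCCAAAAAAAAAA"),
        ],
    )
    def test_score_matches_dp_oracle(self, a, b):
        e = pairwise_similarity(prot("a", a), prot("b", b))
        assert e.score == pytest.approx(gotoh_local_score(a, b))

    def test_x_excluded_from_identity_numerator(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLI"
        withx = "MKTAYIAKQRXISFVKSHFSRQLEERLGLI"
        e = pairwise_similarity(prot("a", withx), prot("b", withx))
        # the X-X column aligns but does not count as a match
        assert e.pct_identity == pytest.approx(100.0 * 29 / 30)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def edge(q, s, ident=90.0, cov=0.9, evalue=1e-20):
    return SimilarityEdge(
        query_id=q, subject_id=s, pct_identity=ident,
        cov_query=cov, cov_subject=cov, evalue=evalue,
    )


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)


class TestClusterFamilies:
    def proteins(self, n, sp="sp1"):
        return [prot(f"p{i:03d}", "MKT", sp) for i in range(n)]

    def test_no_edges_all_singletons(self):
        fams = cluster_families(self.proteins(5), [])
        assert len(fams) == 5
        assert all(len(f.member_ids) == 1 for f in fams)

    def test_single_linkage_chain(self):
        fams = cluster_families(
            self.proteins(3),
            [edge("p000", "p001"), edge("p001", "p002")],
        )
        assert len(fams) == 1
        assert fams[0].member_ids == ("p000", "p001", "p002")
        assert fams[0].family_id == "p000"

    def test_identity_threshold_is_strict(self):
        fams = cluster_families(
            self.proteins(2), [edge("p000", "p001", ident=50.0)]
        )
        assert len(fams) == 2  # identity must exceed 50
        fams = cluster_families(
            self.proteins(2), [edge("p000", "p001", ident=50.1)]
        )
        assert len(fams) == 1

    def test_coverage_threshold_min_mode(self):
        e = SimilarityEdge("p000", "p001", 90.0, 0.95, 0.5, evalue=1e-20)
        assert len(cluster_families(self.proteins(2), [e])) == 2
        assert (
            len(
                cluster_families(
                    self.proteins(2), [e], coverage_mode="query"
                )
            )
            == 1
        )

    def test_evalue_gate(self):
        fams = cluster_families(
            self.proteins(2), [edge("p000", "p001", evalue=1e-3)]
        )
        assert len(fams) == 2

    def test_score_gate_for_builtin_edges(self):
        e = SimilarityEdge("p000", "p001", 90.0, 0.9, 0.9, score=30.0)
        assert len(cluster_families(self.proteins(2), [e])) == 2
        e2 = SimilarityEdge("p000", "p001", 90.0, 0.9, 0.9, score=80.0)
        assert len(cluster_families(self.proteins(2), [e2])) == 1

    def test_unknown_protein_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            cluster_families(self.proteins(2), [edge("p000", "ghost")])

    def test_random_graphs_match_union_find_oracle(self):
        rng = np.random.default_rng(89)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            proteins = self.proteins(n)
            ids = [p.protein_id for p in proteins]
            n_edges = int(rng.integers(0, 121))
            pairs = [
                (ids[int(rng.integers(0, n))], ids[int(rng.integers(0, n))])
                for _ in range(n_edges)
            ]
            edges = [edge(q, s) for q, s in pairs]
            fams = cluster_families(proteins, edges)
            uf = UnionFind(ids)
            for q, s in pairs:
                if q != s:
                    uf.union(q, s)
            from collections import defaultdict

            comps = defaultdict(set)
            for x in ids:
                comps[uf.find(x)].add(x)
            expected = sorted(
                tuple(sorted(c)) for c in comps.values()
            )
            got = sorted(f.member_ids for f in fams)
            assert got == expected


# ---------------------------------------------------------------------------
# Classification and summary statistics
# ---------------------------------------------------------------------------

def fam(members_by_species, cls=None):
    members = []
    species = []
    for sp, n in members_by_species.items():
        for i in range(n):
            members.append(f"{sp}_m{i}_{len(members)}")
            species.append(sp)
    order = sorted(range(len(members)), key=lambda i: members[i])
    return ProteinFamily(
        family_id=min(members),
        member_ids=tuple(members[i] for i in order),
        member_species=tuple(species[i] for i in order),
        family_class=cls,
    )


class TestClassifyAndSummarize:
    def test_printed_expansion_rate(self):
        # 1980 core families; species A holds 3105 genes in them
        families = []
        a_extra = 3105 - 1980
        for i in range(1980):
            counts = {"A": 2 if i < a_extra else 1, "B": 1, "C": 1}
            families.append(fam(counts))
        summary = classify_and_summarize(
            families, {"A": 8.0e6, "B": 9.0e6, "C": 1.0e7}
        )
        assert summary.per_species.loc["A", "core_genes"] == 3105
        assert summary.family_counts["core"] == 1980
        assert summary.per_species.loc["A", "expansion_rate"] == 1.56

    def test_printed_specific_core_ratio(self):
        # species A: 3985 core genes and 2172 specific singletons
        families = [fam({"A": 1, "B": 1}) for _ in range(3900)]
        families.append(fam({"A": 85, "B": 1}))
        families += [fam({"A": 1}) for _ in range(2172)]
        summary = classify_and_summarize(families, {"A": None, "B": None})
        row = summary.per_species.loc["A"]
        assert row["core_genes"] == 3985
        assert row["specific_genes"] == 2172
        assert row["specific_core_ratio"] == 0.545

    def test_one_protein_per_species_single_core_family(self):
        families = [fam({"A": 1, "B": 1, "C": 1})]
        summary = classify_and_summarize(
            families, {"A": None, "B": None, "C": None}
        )
        assert summary.family_counts == {
            "core": 1, "dispensable": 0, "specific": 0, "total": 1
        }
        assert (summary.per_species["expansion_rate"] == 1.0).all()
        assert (summary.per_species["specific_genes"] == 0).all()

    def test_class_definitions(self):
        families = [
            fam({"A": 1, "B": 1, "C": 1}),  # core
            fam({"A": 1, "B": 2}),  # dispensable
            fam({"C": 3}),  # specific (one species, several paralogs)
        ]
        classify_and_summarize(families, {"A": None, "B": None, "C": None})
        assert [f.family_class for f in families] == [
            "core", "dispensable", "specific"
        ]

    def test_perfect_linear_correlation(self):
        sizes = {"A": 6.0e6, "B": 8.0e6, "C": 10.0e6, "D": 12.0e6}
        families = []
        for sp, size in sizes.items():
            n_specific = int(size / 1e6)  # exactly linear in genome size
            families += [fam({sp: 1}) for _ in range(n_specific)]
        families.append(fam({sp: 1 for sp in sizes}))
        summary = classify_and_summarize(families, sizes)
        r2, p = summary.correlations["specific"]
        assert r2 == pytest.approx(1.0)
        assert p < 0.05

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            classify_and_summarize([fam({"A": 1})], {"A": None})

    def test_partition_invariants(self):
        rng = np.random.default_rng(97)
        species = ["A", "B", "C", "D"]
        families = []
        for _ in range(120):
            present = rng.choice(
                species,
                size=int(rng.integers(1, 5)),
                replace=False,
            )
            families.append(
                fam({sp: int(rng.integers(1, 4)) for sp in present})
            )
        summary = classify_and_summarize(
            families, {sp: None for sp in species}
        )
        fc = summary.family_counts
        assert fc["core"] + fc["dispensable"] + fc["specific"] == fc["total"]
        ps = summary.per_species
        assert (
            ps["total_genes"]
            == ps[["core_genes", "dispensable_genes", "specific_genes"]].sum(
                axis=1
            )
        ).all()


class TestDensityProfile:
    def test_all_in_first_bin(self):
        proteins = [
            prot(f"p{i}", "MKT", pos=1000 + i, clen=2_000_000)
            for i in range(5)
        ]
        families = [
            ProteinFamily(
                "p0",
                tuple(f"p{i}" for i in range(5)),
                tuple("sp1" for _ in range(5)),
                family_class="specific",
            )
        ]
        df = density_profile(proteins, families, bin_bp=400_000)
        first = df[df["bin"] == 0]["proportion"].iloc[0]
        assert first == pytest.approx(1.0)
        assert df["proportion"].sum() == pytest.approx(1.0)

    def test_uniform_placement_multinomial(self):
        rng = np.random.default_rng(101)
        n = 4000
        clen = 4_000_000  # 10 bins
        proteins = [
            prot(f"p{i:05d}", "MKT", pos=int(rng.integers(1, clen + 1)),
                 clen=clen)
            for i in range(n)
        ]
        families = [
            ProteinFamily(
                p.protein_id, (p.protein_id,), (p.species_id,),
                family_class="specific",
            )
            for p in proteins
        ]
        df = density_profile(proteins, families, bin_bp=400_000)
        assert len(df) == 10
        sd = np.sqrt(0.1 * 0.9 / n)
        assert np.all(np.abs(df["proportion"] - 0.1) < 4 * sd)
        assert df["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_short_chromosome_single_bin(self):
        proteins = [prot("p0", "MKT", pos=100, clen=50_000)]
        families = [
            ProteinFamily("p0", ("p0",), ("sp1",), family_class="core")
        ]
        df = density_profile(proteins, families, bin_bp=400_000)
        assert len(df) == 1
        assert df["proportion"].iloc[0] == pytest.approx(1.0)

    def test_missing_positions_listed(self):
        proteins = [prot("p0", "MKT")]
        families = [
            ProteinFamily("p0", ("p0",), ("sp1",), family_class="core")
        ]
        with pytest.raises(ValueError, match="p0"):
            density_profile(proteins, families)


class TestPlantedStructureRecovery:
    def test_planted_classes_recovered(self):
        proteins, planted = simulate_proteomes(
            n_species=5, n_core_families=12, n_dispensable_families=5,
            n_specific_per_species=3, protein_length=100,
            divergence=0.1, seed=11,
        )
        edges = build_similarity_edges(proteins)
        families = cluster_families(proteins, edges)
        summary = classify_and_summarize(
            families, {f"sp{i + 1}": 1e6 for i in range(5)}
        )
        predicted = {
            pid: f.family_class for f in families for pid in f.member_ids
        }
        acc = np.mean([predicted[p] == planted[p] for p in planted])
        assert acc >= 0.95
        assert summary.family_counts["core"] == 12
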