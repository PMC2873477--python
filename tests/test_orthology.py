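"""Orthology: identity, BBH grouping, occurrence matrix, regulator groups."""

import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from regulonkit.orthology import (
    OrthologGroup,
    SimilarityRecord,
    bbh_orthologs,
    build_occurrence_matrix,
    group_regulators,
    pairwise_identity,
    read_ortholog_table,
)

# ---------------------------------------------------------------------------
# independent Gotoh (affine-gap Needleman-Wunsch) oracle, terminal gaps
# penalized, same scoring parameters as the implementation


def _gotoh_oracle(a, b, open_=-11.0, ext=-1.0):
    sub = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a aligned to -)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_ + ext * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = open_ + ext * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext, X[i][j - 1] + open_)
    # traceback from the best terminal state
    state = max(("M", "X", "Y"), key=lambda t: {"M": M, "X": X, "Y": Y}[t][n][m])
    i, j, al_a, al_b = n, m, [], []
    while i > 0 or j > 0:
        if state == "M":
            s = sub[a[i - 1], b[j - 1]]
            prev = max(("M", "X", "Y"), key=lambda t: {"M": M, "X": X, "Y": Y}[t][i - 1][j - 1])
            al_a.append(a[i - 1]); al_b.append(b[j - 1]); i -= 1; j -= 1
        elif state == "X":
            cands = [("M", M[i - 1][j] + open_), ("X", X[i - 1][j] + ext), ("Y", Y[i - 1][j] + open_)]
            prev = max(cands, key=lambda t: t[1])[0]
            al_a.append(a[i - 1]); al_b.append("-"); i -= 1
        else:
            cands = [("M", M[i][j - 1] + open_), ("Y", Y[i][j - 1] + ext), ("X", X[i][j - 1] + open_)]
            prev = max(cands, key=lambda t: t[1])[0]
            al_a.append("-"); al_b.append(b[j - 1]); j -= 1
        if i == 0 and j > 0:
            prev = "Y"
        elif j == 0 and i > 0:
            prev = "X"
        state = prev
    row_a, row_b = "".join(al_a[::-1]), "".join(al_b[::-1])
    lo = 0
    while row_a[lo] == "-" or row_b[lo] == "-":
        lo += 1
    hi = len(row_a)
    while row_a[hi - 1] == "-" or row_b[hi - 1] == "-":
        hi -= 1
    matches = sum(
        x == y and x != "-" and x != "X" for x, y in zip(row_a[lo:hi], row_b[lo:hi])
    )
    score = max(M[n][m], X[n][m], Y[n][m])
    return round(100.0 * matches / (hi - lo), 1), score


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0

    def test_single_substitution(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKW") == 90.0

    def test_terminal_overhang_excluded_matches_oracle(self):
        expected, _ = _gotoh_oracle("ACDEFG", "ACDEF")
        assert expected == 100.0  # trailing gap is an overhang, not a column
        assert pairwise_identity("ACDEFG", "ACDEF") == expected

    @pytest.mark.parametrize(
        "a,b",
        [("MKVLA", "MKV"), ("ACDEFGHIK", "ACDQFGHIK"), ("WWWACDEF", "ACDEFYYY")],
    )
    def test_agrees_with_dp_oracle(self, a, b):
        expected, _ = _gotoh_oracle(*sorted((a, b)))
        assert pairwise_identity(a, b) == expected

    @settings(derandomize=True, max_examples=40)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=20),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=20),
    )
    def test_symmetry(self, a, b):
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACD")


def _bbh_oracle(records, gene_to_genome, min_identity):
    """Brute force: enumerate mutual best pairs, then connected components."""
    ident = {}
    for r in records:
        ident[(r.gene_a, r.gene_b)] = r.percent_identity
        ident[(r.gene_b, r.gene_a)] = r.percent_identity
    genes = sorted(gene_to_genome)

    def best(g, genome):
        cands = [
            (ident[(g, h)], h)
            for h in genes
            if gene_to_genome[h] == genome and (g, h) in ident
        ]
        if not cands:
            return None
        top = max(c[0] for c in cands)
        return min(h for s, h in cands if s == top)

    edges = set()
    for g in genes:
        for h in genes:
            if gene_to_genome[g] == gene_to_genome[h]:
                continue
            if (g, h) not in ident or ident[(g, h)] < min_identity:
                continue
            if best(g, gene_to_genome[h]) == h and best(h, gene_to_genome[g]) == g:
                edges.add(frozenset((g, h)))
    # connected components without networkx
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        a, b = sorted(e)
        parent[find(a)] = find(b)
    comps = {}
    for g in genes:
        comps.setdefault(find(g), set()).add(g)
    return sorted(
        (sorted(c) for c in comps.values() if len(c) > 1), key=lambda c: c[0]
    )


class TestBbhOrthologs:
    G2G = {
        "a1": "A", "a2": "A",
        "b1": "B", "b2": "B",
        "c1": "C", "c2": "C",
    }

    def test_single_reciprocal_pair(self):
        recs = [SimilarityRecord("a1", "b1", 80.0)]
        groups = bbh_orthologs(recs, {"a1": "A", "b1": "B"})
        assert [g.members for g in groups] == [{"A": ["a1"], "B": ["b1"]}]

    def test_non_reciprocal_best_is_rejected(self):
        # a1's best hit is b1, but b1's best is a2
        recs = [
            SimilarityRecord("a1", "b1", 60.0),
            SimilarityRecord("a2", "b1", 90.0),
            SimilarityRecord("a2", "b2", 95.0),
        ]
        groups = bbh_orthologs(recs, self.G2G)
        genes = [g.all_genes() for g in groups]
        assert ["a1", "b1"] not in genes

    def test_three_genome_table_matches_brute_force(self):
        rng = random.Random(5)
        genes = sorted(self.G2G)
        recs = []
        for i, g in enumerate(genes):
            for h in genes[i + 1 :]:
                if self.G2G[g] != self.G2G[h]:
                    recs.append(SimilarityRecord(g, h, round(rng.uniform(10, 99), 1)))
        groups = bbh_orthologs(recs, self.G2G, min_identity=30.0)
        got = [g.all_genes() for g in groups]
        assert got == _bbh_oracle(recs, self.G2G, 30.0)

    def test_independent_of_record_order(self):
        rng = random.Random(9)
        genes = sorted(self.G2G)
        recs = []
        for i, g in enumerate(genes):
            for h in genes[i + 1 :]:
                if self.G2G[g] != self.G2G[h]:
                    recs.append(SimilarityRecord(g, h, round(rng.uniform(10, 99), 1)))
        ref = [g.all_genes() for g in bbh_orthologs(recs, self.G2G)]
        for _ in range(5):
            rng.shuffle(recs)
            assert [g.all_genes() for g in bbh_orthologs(recs, self.G2G)] == ref

    def test_below_identity_threshold_dropped(self):
        recs = [SimilarityRecord("a1", "b1", 25.0)]
        assert bbh_orthologs(recs, {"a1": "A", "b1": "B"}, min_identity=30.0) == []


class TestOccurrenceMatrix:
    def test_absent_role_is_all_false(self):
        m = build_occurrence_matrix([], ["g1", "g2"], ["xylB"])
        assert not m.table["xylB"].any()

    def test_paralogs_collapse_to_single_presence(self):
        gr = OrthologGroup(role="xylB", members={"g1": ["x", "y"]})
        m = build_occurrence_matrix([gr], ["g1"], ["xylB"])
        assert m.table.loc["g1", "xylB"] == True  # noqa: E712
        assert m.genes[("g1", "xylB")] == ["x", "y"]

    def test_unknown_role_rejected(self):
        gr = OrthologGroup(role="mystery", members={"g1": ["x"]})
        with pytest.raises(ValueError, match="mystery"):
            build_occurrence_matrix([gr], ["g1"], ["xylB"])

    def test_exact_recovery_of_generator_truth(self, benchmark_dataset, tmp_path):
        ds, ds_dir = benchmark_dataset
        groups = read_ortholog_table(f"{ds_dir}/truth_orthologs.tsv")
        roles = sorted(ds.truth_orthologs.role.unique())
        m = build_occurrence_matrix(groups, ds.genome_ids(), roles)
        truth = {
            (r.genome, r.role) for r in ds.truth_orthologs.itertuples()
        }
        for genome in ds.genome_ids():
            for role in roles:
                assert m.table.loc[genome, role] == ((genome, role) in truth)
        # column sums equal ground-truth presence counts
        counts = ds.truth_orthologs.drop_duplicates(["genome", "role"]).role.value_counts()
        for role in roles:
            assert m.presence_counts()[role] == counts[role]

    def test_plus_rendering(self, tmp_path):
        gr = OrthologGroup(role="xylB", members={"g1": ["x"]})
        m = build_occurrence_matrix([gr], ["g1", "g2"], ["xylB", "xylT"])
        p = tmp_path / "occ.tsv"
        m.to_tsv(str(p))
        lines = p.read_text().splitlines()
        assert lines[0] == "genome\txylB\txylT"
        assert lines[1] == "g1\t+\t"
        assert lines[2] == "g2\t\t"


class TestGroupRegulators:
    def test_identical_proteins_one_group(self):
        prots = {f"r{i}": "MKVLAWE" for i in range(4)}
        groups = group_regulators(prots, method="identity_clustering", threshold=30.0)
        assert len(groups) == 1
        assert groups[0].members == ["r0", "r1", "r2", "r3"]

    def test_two_families_separate_below_threshold(self):
        # two families whose cross-identity (<21%) is below the 30% threshold
        names = ["a1", "a2", "b1", "b2"]
        ident = {}
        for i, x in enumerate(names):
            for y in names[i + 1 :]:
                same = x[0] == y[0]
                ident[(x, y)] = 85.0 if same else 20.5
        groups = group_regulators(
            {n: "M" for n in names}, method="identity_clustering",
            threshold=30.0, identities=ident,
        )
        assert [g.members for g in groups] == [["a1", "a2"], ["b1", "b2"]]

    def test_newick_maximal_coherent_clades(self):
        tree = "((a1,a2),(b1,b2));"
        ident = {
            ("a1", "a2"): 80.0, ("b1", "b2"): 75.0,
            ("a1", "b1"): 15.0, ("a1", "b2"): 15.0,
            ("a2", "b1"): 15.0, ("a2", "b2"): 15.0,
        }
        groups = group_regulators(
            {n: "M" for n in ["a1", "a2", "b1", "b2"]}, method="newick",
            threshold=30.0, tree=tree, identities=ident,
        )
        assert [g.members for g in groups] == [["a1", "a2"], ["b1", "b2"]]

    def test_newick_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaves"):
            group_regulators(
                {"a": "M", "b": "M"}, method="newick", threshold=30.0,
                tree="(a,c);", identities={("a", "b"): 50.0},
            )

    def test_clustering_equals_thresholded_graph_components(self):
        rng = np.random.default_rng(4)
        names = [f"p{i}" for i in range(8)]
        ident = {}
        for i, x in enumerate(names):
            for y in names[i + 1 :]:
                ident[(x, y)] = float(rng.uniform(0, 60))
        groups = group_regulators(
            {n: "M" for n in names}, method="identity_clustering",
            threshold=30.0, identities=ident,
        )
        # brute-force components of the thresholded identity graph
        adj = {n: set() for n in names}
        for (x, y), v in ident.items():
            if v >= 30.0:
                adj[x].add(y)
                adj[y].add(x)
        seen, comps = set(), []
        for n in names:
            if n in seen:
                continue
            stack, comp = [n], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            comps.append(sorted(comp))
        comps.sort(key=lambda c: c[0])
        assert [g.members for g in groups] == comps
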