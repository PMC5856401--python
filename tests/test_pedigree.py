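"""Pedigree parsing, kinship, relationship, contributions and MAC."""

import numpy as np
import pandas as pd
import pytest

import tuberpop as tp
from tuberpop.pedigree import PedigreeError


class TestReadPedigree:
    def test_basic_rows_and_auto_founders(self, tmp_path):
        (tmp_path / "p.csv").write_text("id,mother,father\nC,A,B\nD,C,\n")
        ped = tp.read_pedigree(tmp_path / "p.csv")
        assert ped.parents["C"] == ("A", "B")
        assert ped.parents["D"] == ("C", None)
        assert sorted(ped.founders()) == ["A", "B"]

    def test_self_parent_and_cycle_rejected(self, tmp_path):
        (tmp_path / "p.csv").write_text("id,mother,father\nA,A,B\n")
        with pytest.raises(PedigreeError):
            tp.read_pedigree(tmp_path / "p.csv")
        (tmp_path / "q.csv").write_text("id,mother,father\nA,B,\nB,A,\n")
        with pytest.raises(PedigreeError, match="cycle"):
            tp.read_pedigree(tmp_path / "q.csv")
        (tmp_path / "r.csv").write_text("id,mother,father\nA,,\nA,,\n")
        with pytest.raises(PedigreeError, match="duplicate"):
            tp.read_pedigree(tmp_path / "r.csv")


def random_pedigree(n_nodes, seed):
    rng = np.random.default_rng(seed)
    parents = {}
    ids = [f"i{k}" for k in range(n_nodes)]
    for k, name in enumerate(ids):
        if k < 4 or rng.random() < 0.2:
            parents[name] = (None, None)
        else:
            m, f = rng.choice(k, size=2, replace=False)
            parents[name] = (ids[m], ids[f])
    return tp.Pedigree(parents)


def gene_dropping_kinship(ped, pairs, n_drops, seed):
    """Monte-Carlo co-ancestry: drop unique founder alleles through the
    pedigree and average the per-drop IBD probability for each pair."""
    rng = np.random.default_rng(seed)
    order = ped.topological_order
    alleles = {}
    next_label = 0
    for name in order:
        m, f = ped.parents[name]
        a = np.empty((n_drops, 2), dtype=np.int64)
        for slot, parent in enumerate((m, f)):
            if parent is None:
                a[:, slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, n_drops)
                a[:, slot] = alleles[parent][np.arange(n_drops), pick]
        alleles[name] = a
    out = {}
    for i, j in pairs:
        ai, aj = alleles[i], alleles[j]
        ibd = (ai[:, :, None] == aj[:, None, :]).mean(axis=(1, 2))
        out[(i, j)] = (ibd.mean(), ibd.std(ddof=1) / np.sqrt(n_drops))
    return out


class TestKinship:
    def test_textbook_identities(self, toy_pedigree):
        kin = tp.kinship(toy_pedigree)
        assert kin.coancestry("A", "S1") == 0.25  # parent-offspring
        assert kin.coancestry("S1", "S2") == 0.25  # full sibs
        assert kin.F("X") == 0.25  # full-sib mating
        assert kin.coancestry("X", "X") == 0.5 * (1 + 0.25)
        assert kin.F("A") == 0.0
        assert kin.coancestry("A", "A") == 0.5
        assert kin.coancestry("A", "B") == 0.0
        assert np.all((kin.f >= 0) & (kin.f <= 1))
        np.testing.assert_array_equal(kin.f, kin.f.T)

    def test_matches_gene_dropping_within_three_se(self):
        ped = random_pedigree(30, seed=11)
        kin = tp.kinship(ped)
        rng = np.random.default_rng(0)
        ids = ped.individuals
        pairs = [tuple(np.array(ids)[rng.choice(len(ids), 2, replace=False)])
                 for _ in range(8)]
        mc = gene_dropping_kinship(ped, pairs, n_drops=100_000, seed=1)
        for (i, j), (est, se) in mc.items():
            assert abs(kin.coancestry(i, j) - est) <= max(3 * se, 1e-12), (i, j)


class TestCoefficientOfRelationship:
    def test_limits_and_summary(self, toy_pedigree):
        kin = tp.kinship(toy_pedigree)
        rel = tp.coefficient_of_relationship(kin)
        frame = rel.to_frame()
        assert frame.loc["S1", "S2"] == pytest.approx(0.5)  # non-inbred full sibs
        assert frame.loc["A", "B"] == 0.0
        # diagonal: CR(i,i) = 2 f(i,i) / (1 + F(i)) = 1
        np.testing.assert_allclose(np.diag(rel.cr), 1.0)
        sub = tp.coefficient_of_relationship(kin, subpop=["S1", "S2", "A"])
        # pairs: (S1,S2)=0.5 not >0.5; (S1,A)=~0.47; (S2,A) same -> none above
        assert sub.fraction_above == 0.0

    def test_fully_inbred_lines(self):
        # selfed-like duplicate lineage via repeated full-sib descent
        parents = {"A": (None, None), "B": (None, None)}
        prev = ("A", "B")
        for g in range(12):
            s1, s2 = f"x{g}", f"y{g}"
            parents[s1] = prev
            parents[s2] = prev
            prev = (s1, s2)
        kin = tp.kinship(tp.Pedigree(parents))
        F = kin.F(prev[0])
        cr = tp.coefficient_of_relationship(kin).to_frame().loc[prev[0], prev[1]]
        assert F > 0.9  # repeated sibbing approaches full inbreeding
        assert cr == pytest.approx(1.0, abs=0.05)


class TestAncestorPaths:
    @pytest.fixture
    def deep(self):
        parents = {f"a{k}": (f"a{k+1}", None) for k in range(7)}
        parents["a7"] = (None, None)
        parents["gmf"] = (None, None)
        parents["m"] = ("a1", "gmf")  # unused mother line
        return tp.Pedigree(parents)

    def test_maternal_grandfather_single_path(self, toy_pedigree):
        paths = tp.ancestor_paths(toy_pedigree, "X")
        assert ("A", 2, "maternal") in paths  # via S1 (mother)
        assert ("A", 2, "paternal") in paths  # via S2 (father)
        assert ("S1", 1, "maternal") in paths

    def test_generation_cap_is_inclusive_of_five(self, deep):
        paths = tp.ancestor_paths(deep, "a0", max_gen=5)
        ancestors = {a for a, _, _ in paths}
        assert "a5" in ancestors and "a6" not in ancestors
        with pytest.raises(PedigreeError):
            tp.ancestor_paths(deep, "nope")

    def test_contribution_path_sums(self, toy_pedigree):
        assert tp.genetic_contribution(toy_pedigree, "S1", "X") == 0.5  # mother
        assert tp.genetic_contribution(toy_pedigree, "A", "X") == 0.5  # both sides
        assert tp.genetic_contribution(toy_pedigree, "A", "X", side="maternal") == 0.25
        assert tp.genetic_contribution(toy_pedigree, "A", "X", side="paternal") == 0.25
        assert tp.genetic_contribution(toy_pedigree, "B", "S1", side="paternal") == 0.5
        assert tp.genetic_contribution(toy_pedigree, "X", "A") == 0.0

    def test_founder_contributions_sum_to_one(self):
        ped = random_pedigree(25, seed=3)
        for ind in ped.individuals:
            m, f = ped.parents[ind]
            if m is None or f is None:
                continue
            total = sum(
                tp.genetic_contribution(ped, fo, ind, max_gen=100)
                for fo in ped.founders()
            )
            assert total == pytest.approx(1.0)
            capped = sum(
                tp.genetic_contribution(ped, fo, ind, max_gen=5)
                for fo in ped.founders()
            )
            assert capped <= 1.0 + 1e-12


def mac_oracle(ped, subpop, side, max_gen):
    """Brute-force MAC via explicit path enumeration with BFS path lists."""
    members = [
        s for s in subpop
        if s in ped.parents and any(p is not None for p in ped.parents[s])
    ]
    contrib, occur = {}, {}
    for s in members:
        frontier = []
        m, f = ped.parents[s]
        if m is not None:
            frontier.append((m, 1, "maternal"))
        if f is not None:
            frontier.append((f, 1, "paternal"))
        per = {}
        while frontier:
            node, lvl, sd = frontier.pop()
            if lvl > max_gen:
                continue
            if side in (sd, "both"):
                per[node] = per.get(node, 0.0) + 0.5**lvl
            pm, pf = ped.parents[node]
            if pm is not None:
                frontier.append((pm, lvl + 1, sd))
            if pf is not None:
                frontier.append((pf, lvl + 1, sd))
        for a, c in per.items():
            contrib[a] = contrib.get(a, 0.0) + c
            occur[a] = occur.get(a, 0) + 1
    return {
        a: (100.0 * occur[a] / len(members), 100.0 * contrib[a] / occur[a])
        for a in contrib
    }


class TestMAC:
    def test_defined_formula_on_two_member_subpop(self):
        ped = tp.Pedigree(
            {"A": (None, None), "P": (None, None), "Q": (None, None),
             "i1": ("A", "P"), "i2": ("Q", "P")}
        )
        rep = tp.mac(ped, ["i1", "i2"], side="maternal")
        row = rep.table.set_index("ancestor").loc["A"]
        assert row["occurrence_pct"] == 50.0
        assert row["mac_pct"] == 50.0
        both = tp.Pedigree(
            {"A": (None, None), "P": (None, None),
             "i1": ("A", "P"), "i2": ("A", "P")}
        )
        row2 = tp.mac(both, ["i1", "i2"], side="maternal").table.set_index("ancestor").loc["A"]
        assert row2["occurrence_pct"] == 100.0
        assert row2["mac_pct"] == 50.0

    def test_matches_exhaustive_path_oracle(self):
        ped, _ = tp.simulate_pedigree(
            tp.PedigreeSimConfig(founders=6, generations=5,
                                 offspring_per_generation=12, seed=2)
        )
        subpop = [i for i in ped.individuals if i.startswith("G5")]
        for side in ("maternal", "paternal", "both"):
            rep = tp.mac(ped, subpop, side=side, max_gen=5)
            oracle = mac_oracle(ped, subpop, side, 5)
            got = {
                r["ancestor"]: (r["occurrence_pct"], r["mac_pct"])
                for _, r in rep.table.iterrows()
            }
            assert got.keys() == oracle.keys()
            for a in oracle:
                assert got[a][0] == pytest.approx(oracle[a][0])
                assert got[a][1] == pytest.approx(oracle[a][1])

    def test_row_order_invariance_and_side_additivity(self, tmp_path):
        rows = ["id,mother,father", "C,A,B", "D,A,C", "E,C,D"]
        (tmp_path / "f.csv").write_text("\n".join(rows) + "\n")
        (tmp_path / "r.csv").write_text("\n".join([rows[0]] + rows[1:][::-1]) + "\n")
        ped1 = tp.read_pedigree(tmp_path / "f.csv")
        ped2 = tp.read_pedigree(tmp_path / "r.csv")
        t1 = tp.mac(ped1, ["C", "D", "E"], side="both").table
        t2 = tp.mac(ped2, ["C", "D", "E"], side="both").table
        pd.testing.assert_frame_equal(t1, t2)
        for ind in ("D", "E"):
            for anc in ("A", "B", "C"):
                mat = tp.genetic_contribution(ped1, anc, ind, side="maternal")
                pat = tp.genetic_contribution(ped1, anc, ind, side="paternal")
                assert mat + pat == pytest.approx(
                    tp.genetic_contribution(ped1, anc, ind)
                )

    def test_frequent_remote_ancestor_ranks_below_rare_close_one(self):
        # "old workhorse" W is a remote maternal ancestor of every member;
        # "recent" R is the mother of just one. W's occurrence is higher,
        # R's mean contribution (MAC) is higher.
        parents = {"W": (None, None), "R": (None, None)}
        members = []
        for k in range(5):
            gm, m = f"gm{k}", f"m{k}"
            parents[gm] = ("W", None) if k else ("W", None)
            parents[m] = (gm, None)
            child = f"c{k}"
            parents[child] = (m, None)
            members.append(child)
        parents["cR"] = ("R", None)
        members.append("cR")
        ped = tp.Pedigree(parents)
        rep = tp.mac(ped, members, side="maternal").table.set_index("ancestor")
        assert rep.loc["W", "occurrence_pct"] > rep.loc["R", "occurrence_pct"]
        assert rep.loc["W", "mac_pct"] < rep.loc["R", "mac_pct"]
        # report is sorted by MAC descending
        assert rep["mac_pct"].is_monotonic_decreasing
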