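"""Pedigree kinship, relationship, and ancestor-contribution accounting.

Co-ancestry (kinship) coefficients come from the tabular method run in
topological order; unknown parents are founders contributing zero
kinship. The contribution machinery enumerates upward parent chains with
a generation cap (parents are level 1) and splits paths into a maternal
and a paternal side by the first step from the focal individual, which is
how breeding-programme ancestor tables separate "maternal path" and
"paternal path" contributors. MAC — maximum average contribution — is the
mean path-sum contribution (sum over qualifying paths of (1/2)^level) of
an ancestor among the subpopulation members in whose capped ancestry it
occurs, paired with that occurrence frequency; a very frequent but remote
ancestor can therefore rank below a rarer, closer one.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "RelationshipSummary",
    "ContributionReport",
    "read_pedigree",
    "kinship",
    "coefficient_of_relationship",
    "ancestor_paths",
    "genetic_contribution",
    "mac",
]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Acyclic ancestry graph: individual -> (mother, father), None = unknown."""

    parents: dict

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, (m, f) in self.parents.items():
            if child in (m, f):
                raise PedigreeError(f"{child!r} listed as its own parent")
            for p in (m, f):
                if p is not None:
                    if p not in self.parents:
                        raise PedigreeError(f"parent {p!r} of {child!r} undefined")
                    g.add_edge(p, child)
        try:
            self._topo = list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise PedigreeError(f"pedigree contains a cycle: {cycle}") from None
        self._graph = g

    @property
    def individuals(self) -> list:
        return list(self.parents)

    @property
    def topological_order(self) -> list:
        return self._topo

    def founders(self) -> list:
        return [i for i, (m, f) in self.parents.items() if m is None and f is None]

    def generation_depth(self, individual) -> int:
        depth = {}
        for i in self._topo:
            m, f = self.parents[i]
            depth[i] = max(
                depth[m] + 1 if m is not None else 0,
                depth[f] + 1 if f is not None else 0,
            )
        return depth[individual]


@dataclass
class KinshipMatrix:
    ids: list
    f: np.ndarray  # co-ancestry coefficients, symmetric
    inbreeding: np.ndarray  # F(i) = f(mother_i, father_i)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f, index=self.ids, columns=self.ids)

    def coancestry(self, i, j) -> float:
        ix = {s: k for k, s in enumerate(self.ids)}
        return float(self.f[ix[i], ix[j]])

    def F(self, i) -> float:
        ix = {s: k for k, s in enumerate(self.ids)}
        return float(self.inbreeding[ix[i]])


@dataclass
class RelationshipSummary:
    ids: list
    cr: np.ndarray  # coefficient-of-relationship matrix
    threshold: float
    fraction_above: float  # fraction of distinct pairs with CR > threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cr, index=self.ids, columns=self.ids)


@dataclass
class ContributionReport:
    side: str  # "maternal" | "paternal" | "both"
    max_generations: int
    n_members: int  # subpopulation members with pedigree records
    table: pd.DataFrame  # ancestor, occurrence_pct, mac_pct; MAC-descending


def read_pedigree(path, auto_founders: bool = True) -> Pedigree:
    """Read a three-column CSV ``id,mother,father`` (empty field = unknown).

    Parents referenced but never defined as individuals become founders
    when ``auto_founders`` is set, otherwise raise.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs columns: id, mother, father")
    df.columns = ["id", "mother", "father"] + list(df.columns[3:])
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise PedigreeError(f"duplicate individual {dup!r}")
    parents = {}
    for _, row in df.iterrows():
        m = row["mother"] or None
        f = row["father"] or None
        parents[row["id"]] = (m, f)
    if auto_founders:
        referenced = {p for mf in parents.values() for p in mf if p is not None}
        for p in referenced - set(parents):
            parents[p] = (None, None)
    return Pedigree(parents)


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Tabular-method co-ancestry and inbreeding coefficients.

    In topological order: f(i,j) = (f(mother_i,j) + f(father_i,j)) / 2 for
    prior j, f(i,i) = (1 + f(mother_i, father_i)) / 2; unknown parents
    contribute 0. F(i) is the co-ancestry of i's parents.
    """
    order = ped.topological_order
    ix = {s: k for k, s in enumerate(order)}
    n = len(order)
    f = np.zeros((n, n))
    F = np.zeros(n)
    for i_id in order:
        i = ix[i_id]
        m, p = ped.parents[i_id]
        mi = ix[m] if m is not None else None
        pi = ix[p] if p is not None else None
        for j_id in order[: i]:
            j = ix[j_id]
            val = 0.0
            if mi is not None:
                val += f[mi, j]
            if pi is not None:
                val += f[pi, j]
            f[i, j] = f[j, i] = val / 2.0
        F[i] = f[mi, pi] if (mi is not None and pi is not None) else 0.0
        f[i, i] = 0.5 * (1.0 + F[i])
    return KinshipMatrix(ids=order, f=f, inbreeding=F)


def coefficient_of_relationship(
    k: KinshipMatrix, subpop=None, threshold: float = 0.5
) -> RelationshipSummary:
    """CR(i,j) = 2 f(i,j) / sqrt((1+F_i)(1+F_j)); pair summary above threshold.

    With ``subpop`` the matrix and the above-threshold fraction are
    restricted to those individuals.
    """
    if subpop is None:
        ids = list(k.ids)
        f = k.f
        F = k.inbreeding
    else:
        ix = {s: i for i, s in enumerate(k.ids)}
        idx = np.array([ix[s] for s in subpop])
        ids = list(subpop)
        f = k.f[np.ix_(idx, idx)]
        F = k.inbreeding[idx]
    denom = np.sqrt(np.outer(1.0 + F, 1.0 + F))
    cr = 2.0 * f / denom
    n = len(ids)
    if n > 1:
        iu = np.triu_indices(n, k=1)
        frac = float(np.mean(cr[iu] > threshold))
    else:
        frac = 0.0
    return RelationshipSummary(ids=ids, cr=cr, threshold=threshold, fraction_above=frac)


def ancestor_paths(ped: Pedigree, individual, max_gen: int = 5) -> list[tuple]:
    """All upward parent chains of length 1..max_gen from ``individual``.

    Returns (ancestor, level, side) triples; level counts parent steps
    (parents are level 1) and side is "maternal" or "paternal" by the
    first step. The same ancestor may appear on several paths.
    """
    if individual not in ped.parents:
        raise PedigreeError(f"unknown individual {individual!r}")
    out: list[tuple] = []

    def climb(node, level, side):
        if level > max_gen:
            return
        out.append((node, level, side))
        m, f = ped.parents[node]
        if m is not None:
            climb(m, level + 1, side)
        if f is not None:
            climb(f, level + 1, side)

    m, f = ped.parents[individual]
    if m is not None:
        climb(m, 1, "maternal")
    if f is not None:
        climb(f, 1, "paternal")
    return out


def genetic_contribution(
    ped: Pedigree, ancestor, individual, max_gen: int = 5, side: str | None = None
) -> float:
    """Expected contribution of ``ancestor`` to ``individual``.

    Sum over qualifying paths (within ``max_gen``, restricted to a side
    if given) of (1/2)^level; 0 when no qualifying path exists.
    """
    if ancestor not in ped.parents:
        raise PedigreeError(f"unknown individual {ancestor!r}")
    total = 0.0
    for a, level, s in ancestor_paths(ped, individual, max_gen):
        if a == ancestor and (side is None or s == side):
            total += 0.5**level
    return total


def mac(
    ped: Pedigree,
    subpop,
    side: str = "maternal",
    max_gen: int = 5,
) -> ContributionReport:
    """Occurrence frequency and MAC of every ancestor on one parental side.

    Over the subpopulation members with pedigree records (at least one
    known parent): occurrence% is the share of members whose capped
    ancestry contains the ancestor on that side; MAC% is 100 x the mean
    path-sum contribution among exactly those members.
    """
    if side not in ("maternal", "paternal", "both"):
        raise PedigreeError(f"side must be maternal|paternal|both, got {side!r}")
    members = [
        s
        for s in subpop
        if s in ped.parents and any(p is not None for p in ped.parents[s])
    ]
    if not members:
        raise PedigreeError("no subpopulation member has pedigree records")
    contrib: dict = {}
    occurs: dict = {}
    for s in members:
        per_anc: dict = {}
        for a, level, pside in ancestor_paths(ped, s, max_gen):
            if side != "both" and pside != side:
                continue
            per_anc[a] = per_anc.get(a, 0.0) + 0.5**level
        for a, c in per_anc.items():
            contrib[a] = contrib.get(a, 0.0) + c
            occurs[a] = occurs.get(a, 0) + 1
    rows = [
        {
            "ancestor": a,
            "occurrence_pct": 100.0 * occurs[a] / len(members),
            "mac_pct": 100.0 * contrib[a] / occurs[a],
        }
        for a in contrib
    ]
    table = pd.DataFrame(rows, columns=["ancestor", "occurrence_pct", "mac_pct"])
    table = table.sort_values(
        ["mac_pct", "ancestor"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return ContributionReport(
        side=side, max_generations=max_gen, n_members=len(members), table=table
    )
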