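"""Synthetic mixed-ploidy panels and pedigrees with known ground truth.

Population panels follow the Balding-Nichols model: ancestral allele
frequencies p_l are drawn uniformly, each of K subpopulations draws
p_{k,l} ~ Beta(p_l (1-Fst)/Fst, (1-p_l)(1-Fst)/Fst), and genotypes are
binomial allele dosages Binomial(ploidy_k, p_{k,l}) — polysomic
inheritance, appropriate for an autotetraploid crop. The default
configuration mirrors a potato diversity panel: four tetraploid
subpopulations plus one diploid wild-species group, with a small rate of
missing calls. Pedigrees are generational random-mating crosses (no
selfing) whose exact founder contributions are tracked during
construction as ground truth for the contribution statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .pedigree import Pedigree

__all__ = [
    "SimConfig",
    "SimTruth",
    "PedigreeSimConfig",
    "simulate_panel",
    "simulate_structural_panel",
    "simulate_pedigree",
]


@dataclass
class SimConfig:
    """Study conditions for a Balding-Nichols dosage panel.

    ``fst`` may be a scalar or a per-locus array; a per-locus array lets a
    chosen subset of loci carry all the between-population divergence
    (the rest at fst 0 share the ancestral frequency exactly).
    """

    K: int = 5
    n_per_pop: int = 40
    L: int = 500
    fst: float | np.ndarray = 0.2
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    ploidy_per_pop: tuple[int, ...] | None = None  # default: tetraploid + 1 diploid
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.n_per_pop < 1 or self.L < 1:
            raise ValueError("K, n_per_pop and L must be positive")
        fst = np.asarray(self.fst, dtype=float)
        if np.any(fst < 0) or np.any(fst >= 1):
            raise ValueError("fst must lie in [0, 1)")
        if fst.ndim == 1 and fst.size != self.L:
            raise ValueError("per-locus fst must have length L")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.ploidy_per_pop is None:
            self.ploidy_per_pop = tuple([4] * (self.K - 1) + [2]) if self.K > 1 else (4,)
        if len(self.ploidy_per_pop) != self.K:
            raise ValueError("ploidy_per_pop must have one entry per population")


@dataclass
class SimTruth:
    labels: np.ndarray  # true subpopulation per sample, "pop1".."popK"
    ancestral_freq: np.ndarray  # per-locus ancestral p
    pop_freq: np.ndarray  # K x L realized subpopulation frequencies
    fst: np.ndarray
    seed: int


@dataclass
class PedigreeSimConfig:
    founders: int = 6
    generations: int = 3
    offspring_per_generation: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders < 2:
            raise ValueError("need at least 2 founders")
        if self.generations < 1:
            raise ValueError("need at least 1 generation")


def simulate_panel(cfg: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Draw a genotype panel and its ground truth from the configuration."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=cfg.L)
    fst = np.broadcast_to(np.asarray(cfg.fst, dtype=float), (cfg.L,)).copy()
    pop_freq = np.empty((cfg.K, cfg.L))
    diff = fst > 0
    with np.errstate(divide="ignore"):
        a = np.where(diff, p * (1 - fst) / np.where(diff, fst, 1.0), 1.0)
        b = np.where(diff, (1 - p) * (1 - fst) / np.where(diff, fst, 1.0), 1.0)
    for k in range(cfg.K):
        draws = rng.beta(a[diff], b[diff]) if diff.any() else np.empty(0)
        row = np.array(p)
        row[diff] = draws
        pop_freq[k] = row
    ploidy = np.repeat(cfg.ploidy_per_pop, cfg.n_per_pop)
    labels = np.repeat([f"pop{k + 1}" for k in range(cfg.K)], cfg.n_per_pop)
    dosage = np.empty((cfg.K * cfg.n_per_pop, cfg.L))
    for k in range(cfg.K):
        sl = slice(k * cfg.n_per_pop, (k + 1) * cfg.n_per_pop)
        dosage[sl] = rng.binomial(
            cfg.ploidy_per_pop[k], pop_freq[k][None, :], size=(cfg.n_per_pop, cfg.L)
        )
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = np.nan
    panel = GenotypePanel(
        sample_ids=[f"s{i + 1:04d}" for i in range(dosage.shape[0])],
        locus_ids=[f"snp{l + 1:05d}" for l in range(cfg.L)],
        dosage=dosage,
        ploidy=ploidy,
        group=labels.tolist(),
    )
    truth = SimTruth(
        labels=labels, ancestral_freq=p, pop_freq=pop_freq, fst=fst, seed=cfg.seed
    )
    return panel, truth


def simulate_structural_panel(
    n_per_pop: int = 40,
    L: int = 200,
    n_structural: int = 10,
    fst: float = 0.4,
    ploidy: int = 4,
    seed: int = 0,
) -> tuple[GenotypePanel, SimTruth, list[str]]:
    """Two populations where a chosen set of loci carries all divergence.

    The structural loci get deterministic frequency pairs p_bar -/+ delta
    with delta = sqrt(fst * p_bar * (1 - p_bar)) — the two-population Fst
    identity — so each of them genuinely carries the stated contrast; all
    other loci share the ancestral frequency exactly (fst 0). Returns the
    panel, the truth, and the structural locus ids.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.2, 0.8, size=L)
    pop_freq = np.tile(p, (2, 1))
    delta = np.sqrt(fst * p[:n_structural] * (1 - p[:n_structural]))
    pop_freq[0, :n_structural] = np.clip(p[:n_structural] - delta, 0.02, 0.98)
    pop_freq[1, :n_structural] = np.clip(p[:n_structural] + delta, 0.02, 0.98)
    dosage = np.vstack(
        [
            rng.binomial(ploidy, pop_freq[k][None, :], size=(n_per_pop, L))
            for k in range(2)
        ]
    ).astype(float)
    labels = np.repeat(["pop1", "pop2"], n_per_pop)
    locus_ids = [f"snp{l + 1:05d}" for l in range(L)]
    panel = GenotypePanel(
        sample_ids=[f"s{i + 1:04d}" for i in range(2 * n_per_pop)],
        locus_ids=locus_ids,
        dosage=dosage,
        ploidy=np.full(2 * n_per_pop, ploidy),
        group=labels.tolist(),
    )
    fst_vec = np.zeros(L)
    fst_vec[:n_structural] = fst
    truth = SimTruth(
        labels=labels, ancestral_freq=p, pop_freq=pop_freq, fst=fst_vec, seed=seed
    )
    return panel, truth, locus_ids[:n_structural]


def simulate_pedigree(cfg: PedigreeSimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Generational random-mating pedigree with exact founder contributions.

    Each generation draws its parents (mother then father, distinct
    individuals) from the previous generation. The returned table holds,
    for every final-generation individual and founder, the exact
    (uncapped) expected contribution accumulated during construction:
    c(child) = (c(mother) + c(father)) / 2 with founders as unit vectors.
    """
    rng = np.random.default_rng(cfg.seed)
    founders = [f"F{i + 1}" for i in range(cfg.founders)]
    parents: dict = {f: (None, None) for f in founders}
    contrib = {f: {f: 1.0} for f in founders}
    previous = list(founders)
    final = previous
    for g in range(1, cfg.generations + 1):
        current = []
        for o in range(cfg.offspring_per_generation):
            mother, father = rng.choice(len(previous), size=2, replace=False)
            m, f = previous[mother], previous[father]
            child = f"G{g}_{o + 1}"
            parents[child] = (m, f)
            c: dict = {}
            for anc, w in contrib[m].items():
                c[anc] = c.get(anc, 0.0) + w / 2.0
            for anc, w in contrib[f].items():
                c[anc] = c.get(anc, 0.0) + w / 2.0
            contrib[child] = c
            current.append(child)
        previous = current
        final = current
    rows = [
        {"individual": ind, "founder": fo, "contribution": contrib[ind].get(fo, 0.0)}
        for ind in final
        for fo in founders
    ]
    return Pedigree(parents), pd.DataFrame(rows)
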