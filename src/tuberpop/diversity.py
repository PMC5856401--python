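"""Heterozygosity summaries and allele-level AMOVA with permutation tests.

The AMOVA follows the Excoffier-style decomposition of pairwise squared
Euclidean distances into among- and within-population sums of squares.
The units are allele copies: every individual contributes ploidy-many
0/1 copies per locus, so the within level includes the variation among
copies inside an individual, and Phi_st = Va/(Va+Vw) (reported in the
field's tables as Fst) consistently estimates the allele-frequency
differentiation parameter — codominant-software convention, visible in
published tables whose within-population df exceed the genotype count.
Because squared Euclidean distance adds over loci, the copy-level sums
of squares depend only on per-locus allele counts, never on phase, and
SS equals the direct deviation-from-centroid sum of the allele-copy
expansion. The permutation null for Phi_st shuffles whole individuals
among populations. Fis is the ratio-of-means heterozygote-deficit
statistic 1 - mean(Ho)/mean(He); its null permutes allele copies among
individuals within each population, which preserves allele frequencies
(hence He) while randomising Ho.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel, allele_frequency

__all__ = [
    "DiversitySummary",
    "AMOVATable",
    "FStatistics",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "diversity_summary",
    "amova",
    "fis",
    "permutation_test",
    "pairwise_phi",
    "report_amova",
]


@dataclass
class DiversitySummary:
    table: pd.DataFrame  # rows per subpopulation: N, Ho/He mean+SE, %P


@dataclass
class AMOVATable:
    """Two-level AMOVA bookkeeping (among vs within populations)."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    va: float  # among-population variance component, raw (may be negative)
    vw: float  # within-population variance component (= MS within)
    n0: float  # weighted average subpopulation size coefficient

    @property
    def df_total(self) -> int:
        return self.df_among + self.df_within

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    @property
    def ms_among(self) -> float:
        if self.df_among == 0:
            raise ZeroDivisionError("df_among is 0")
        return self.ss_among / self.df_among

    @property
    def ms_within(self) -> float:
        if self.df_within == 0:
            raise ZeroDivisionError("df_within is 0")
        return self.ss_within / self.df_within

    @property
    def va_truncated(self) -> float:
        return max(self.va, 0.0)

    @property
    def total_variance(self) -> float:
        return self.va_truncated + self.vw

    @property
    def pct_among(self) -> float:
        return 100.0 * self.va_truncated / self.total_variance

    @property
    def pct_within(self) -> float:
        return 100.0 * self.vw / self.total_variance

    @property
    def phi_st(self) -> float:
        return self.va_truncated / self.total_variance


@dataclass
class FStatistics:
    phi_st: float
    f_is: float | None = None
    p_phi: float | None = None
    p_fis: float | None = None
    n_permutations: int | None = None


def observed_heterozygosity(panel: GenotypePanel, subset=None) -> np.ndarray:
    """Per-locus Ho: fraction of scored individuals carrying both alleles,
    i.e. dosage strictly between 0 and the individual's ploidy."""
    if subset is None:
        subset = np.arange(panel.n_samples)
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("empty sample subset")
    dos = panel.dosage[subset]
    plo = panel.ploidy[subset][:, None]
    present = ~np.isnan(dos)
    het = present & (dos > 0) & (dos < plo)
    n = present.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het.sum(axis=0) / n, np.nan)


def expected_heterozygosity(panel: GenotypePanel, subset=None) -> np.ndarray:
    """Per-locus He = 1 - p^2 - (1-p)^2 from the pooled subset frequency
    (no small-sample correction)."""
    p = allele_frequency(panel, subset)
    return 1.0 - p**2 - (1.0 - p) ** 2


def diversity_summary(panel: GenotypePanel, grouping=None) -> DiversitySummary:
    """Per-subpopulation N, Ho and He (mean and SE over loci) and %P.

    SE is sd/sqrt(L) over scored loci; %P is the percentage of loci with
    both alleles present (0 < p < 1) in the subpopulation.
    """
    grouping = np.asarray(grouping if grouping is not None else panel.group)
    rows = []
    for g in dict.fromkeys(grouping.tolist()):
        idx = np.flatnonzero(grouping == g)
        ho = observed_heterozygosity(panel, idx)
        he = expected_heterozygosity(panel, idx)
        p = allele_frequency(panel, idx)
        ho = ho[~np.isnan(ho)]
        he_v = he[~np.isnan(he)]
        p_v = p[~np.isnan(p)]
        L = len(ho)
        rows.append(
            {
                "subpop": g,
                "N": len(idx),
                "Ho_mean": ho.mean() if L else np.nan,
                "Ho_se": ho.std(ddof=1) / np.sqrt(L) if L > 1 else 0.0,
                "He_mean": he_v.mean() if len(he_v) else np.nan,
                "He_se": he_v.std(ddof=1) / np.sqrt(len(he_v)) if len(he_v) > 1 else 0.0,
                "pct_polymorphic": 100.0 * np.mean((p_v > 0) & (p_v < 1))
                if len(p_v)
                else np.nan,
            }
        )
    return DiversitySummary(table=pd.DataFrame(rows).set_index("subpop"))


def _amova_from_labels(
    alt: np.ndarray, copies: np.ndarray, ploidy: np.ndarray, codes: np.ndarray, K: int
) -> AMOVATable:
    """Allele-copy AMOVA sums from per-individual alt counts.

    ``alt``: samples x loci alt-copy counts (0 where missing);
    ``copies``: samples x loci scored copies (0 where missing);
    ``codes``: integer population label per sample. For a set of M
    0/1-valued copies with c ones, the pairwise-SS identity
    sum_{i<j} (x_i - x_j)^2 / M = c (M - c) / M is the
    deviation-from-centroid sum, so every SS below is a genuine squared-
    Euclidean AMOVA term on the copy expansion.
    """
    G = np.zeros((K, alt.shape[0]))
    G[codes, np.arange(alt.shape[0])] = 1.0
    c1 = G @ alt  # K x L alt copies per group
    m = G @ copies  # K x L scored copies per group
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_within = float(np.nansum(np.where(m > 0, c1 * (m - c1) / m, 0.0)))
        C1 = c1.sum(axis=0)
        M_l = m.sum(axis=0)
        ss_total = float(
            np.nansum(np.where(M_l > 0, C1 * (M_l - C1) / M_l, 0.0))
        )
    ss_among = ss_total - ss_within
    # df from nominal copy counts (sum of ploidies); missing calls thin SS
    # and df proportionally, so the mean squares stay consistent
    M_k = G @ ploidy.astype(float)
    M = float(M_k.sum())
    df_among = K - 1
    df_within = int(round(M)) - K
    n0 = (M - (M_k**2).sum() / M) / (K - 1)
    vw = ss_within / df_within if df_within > 0 else np.nan
    va = ((ss_among / df_among) - vw) / n0
    return AMOVATable(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        va=va,
        vw=vw,
        n0=n0,
    )


def amova(
    panel: GenotypePanel,
    grouping=None,
    n_permutations: int = 0,
    seed: int = 0,
) -> tuple[AMOVATable, FStatistics]:
    """Two-level AMOVA on squared Euclidean distances between allele copies.

    SS_total = (1/M) sum over copy pairs of d2; SS_within sums the
    analogous within-group terms; variance components follow from the
    mean squares with n0 the weighted average subpopulation copy count.
    Phi_st = Va/(Va+Vw) with Va truncated at 0. With ``n_permutations``
    > 0 a permutation p-value is attached by shuffling whole individuals
    among populations.
    """
    grouping = np.asarray(grouping if grouping is not None else panel.group)
    if grouping is None or grouping.size != panel.n_samples:
        raise ValueError("grouping must label every sample")
    names, codes = np.unique(grouping, return_inverse=True)
    if len(names) < 2:
        raise ValueError("AMOVA needs at least 2 subpopulations")
    if len(set(panel.sample_ids)) != panel.n_samples:
        raise ValueError("duplicate sample ids")
    present = ~np.isnan(panel.dosage)
    alt = np.where(present, panel.dosage, 0.0)
    copies = present * panel.ploidy[:, None].astype(float)
    table = _amova_from_labels(alt, copies, panel.ploidy, codes, len(names))
    if table.va < 0:
        warnings.warn("negative among-population variance component truncated to 0")
    stats = FStatistics(phi_st=table.phi_st)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)

        def permuted() -> float:
            perm = rng.permutation(len(codes))
            return _amova_from_labels(
                alt[perm], copies[perm], panel.ploidy[perm], codes, len(names)
            ).phi_st

        stats.p_phi = permutation_test(table.phi_st, permuted, n_permutations)
        stats.n_permutations = n_permutations
    return table, stats


def _ho_he_cells(panel: GenotypePanel, grouping):
    """Per (subpopulation, locus) Ho and He with subpopulation sizes."""
    grouping = np.asarray(grouping)
    hos, hes, ws = [], [], []
    for g in dict.fromkeys(grouping.tolist()):
        idx = np.flatnonzero(grouping == g)
        ho = observed_heterozygosity(panel, idx)
        he = expected_heterozygosity(panel, idx)
        ok = ~np.isnan(ho) & ~np.isnan(he) & (he > 0)
        hos.append(ho[ok])
        hes.append(he[ok])
        ws.append(np.full(ok.sum(), float(len(idx))))
    return np.concatenate(hos), np.concatenate(hes), np.concatenate(ws)


def fis(
    panel: GenotypePanel,
    grouping=None,
    n_permutations: int = 0,
    seed: int = 0,
) -> FStatistics:
    """Within-population inbreeding coefficient Fis = 1 - mean(Ho)/mean(He).

    Means run over subpopulation x locus cells with He > 0, weighted by
    subpopulation size; negative values indicate heterozygote excess. The
    permutation null redistributes allele copies among individuals within
    each subpopulation; the reported p is one-sided, Pr(perm Fis >= observed),
    so a strong heterozygote excess shows up as p near 1.
    """
    grouping = np.asarray(grouping if grouping is not None else panel.group)
    ho, he, w = _ho_he_cells(panel, grouping)
    if ho.size == 0:
        raise ValueError("no polymorphic subpopulation x locus cell")
    observed = 1.0 - np.average(ho, weights=w) / np.average(he, weights=w)
    stats = FStatistics(phi_st=np.nan, f_is=observed)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        groups = dict.fromkeys(grouping.tolist())
        perm_templates = []
        for g in groups:
            idx = np.flatnonzero(grouping == g)
            perm_templates.append((idx, panel.ploidy[idx]))

        def permuted() -> float:
            shuffled = _shuffle_alleles_within_pops(panel, perm_templates, rng)
            ho_p, he_p, w_p = _ho_he_cells(shuffled, grouping)
            return 1.0 - np.average(ho_p, weights=w_p) / np.average(he_p, weights=w_p)

        stats.p_fis = permutation_test(observed, permuted, n_permutations)
        stats.n_permutations = n_permutations
    return stats


def _shuffle_alleles_within_pops(panel, perm_templates, rng) -> GenotypePanel:
    """Redistribute allele copies among individuals within each population.

    Per population and locus the alt-allele copies carried by scored
    individuals are pooled and dealt back into the same ploidy slots, a
    multivariate-hypergeometric reshuffle that keeps per-locus frequencies
    fixed.
    """
    new = np.array(panel.dosage)
    for idx, ploidy in perm_templates:
        dos = panel.dosage[idx]
        n, L = dos.shape
        slots = np.repeat(np.arange(n), ploidy)  # allele slot -> individual
        A = len(slots)
        present = ~np.isnan(dos)
        # build allele matrix: for each locus, slot carries 1 for alt copies
        alle = np.zeros((A, L))
        starts = np.concatenate(([0], np.cumsum(ploidy)[:-1]))
        for i in range(n):
            s = starts[i]
            d = dos[i]
            for k in range(ploidy[i]):
                alle[s + k] = np.where(present[i] & (d > k), 1.0, 0.0)
        alle[~present[slots]] = np.nan
        # independent column-wise permutation via random keys
        keys = rng.random((A, L))
        keys[np.isnan(alle)] = np.inf  # keep missing slots at the bottom
        order = np.argsort(keys, axis=0)
        shuffled = np.take_along_axis(alle, order, axis=0)
        # deal back in slot order: individual i gets its ploidy-many rows
        out = np.add.reduceat(np.where(np.isnan(shuffled), 0.0, shuffled), starts, axis=0)
        counts = np.add.reduceat((~np.isnan(shuffled)).astype(float), starts, axis=0)
        out[counts < ploidy[:, None]] = np.nan  # not enough copies -> missing
        new[idx] = out
    return GenotypePanel(
        sample_ids=panel.sample_ids,
        locus_ids=panel.locus_ids,
        dosage=new,
        ploidy=panel.ploidy,
        group=panel.group,
    )


def permutation_test(observed: float, permuted_stat, n_perm: int = 999) -> float:
    """p = (1 + #{permuted >= observed}) / (n_perm + 1).

    ``permuted_stat`` is a zero-argument callable returning one draw from
    the permutation null; the +1 convention never yields p = 0.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    count = sum(1 for _ in range(n_perm) if permuted_stat() >= observed)
    return (1 + count) / (n_perm + 1)


def pairwise_phi(
    panel: GenotypePanel,
    grouping=None,
    n_permutations: int = 0,
    seed: int = 0,
):
    """Pairwise Phi_st between all subpopulation pairs (AMOVA per pair)."""
    from .distance import DistanceMatrix

    grouping = np.asarray(grouping if grouping is not None else panel.group)
    groups = list(dict.fromkeys(grouping.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 subpopulations")
    K = len(groups)
    phi = np.zeros((K, K))
    pval = np.full((K, K), np.nan)
    for a in range(K):
        for b in range(a + 1, K):
            mask = (grouping == groups[a]) | (grouping == groups[b])
            sub = panel.subset_samples(mask)
            table, stats = amova(
                sub, grouping[mask], n_permutations=n_permutations, seed=seed
            )
            phi[a, b] = phi[b, a] = table.phi_st
            if stats.p_phi is not None:
                pval[a, b] = pval[b, a] = stats.p_phi
    return DistanceMatrix(ids=groups, matrix=phi, metric="phi_st"), pval


def report_amova(table: AMOVATable, f_is: float | None = None) -> tuple[str, dict]:
    """Recompute the derived AMOVA quantities and format the standard table.

    From SS and df: mean squares; from the variance components: the total
    variance, among/within percentages and Phi_st. Returns (text, values).
    """
    values = {
        "ms_among": table.ms_among,
        "ms_within": table.ms_within,
        "ss_total": table.ss_total,
        "df_total": table.df_total,
        "total_variance": table.total_variance,
        "pct_among": table.pct_among,
        "pct_within": table.pct_within,
        "phi_st": table.phi_st,
    }
    lines = [
        "SV\tDf\tSS\tMS\tEst.Var\t%",
        f"Among Pops\t{table.df_among}\t{table.ss_among:.3f}\t"
        f"{table.ms_among:.3f}\t{table.va:.3f}\t{table.pct_among:.0f}%",
        f"Within Pops\t{table.df_within}\t{table.ss_within:.3f}\t"
        f"{table.ms_within:.3f}\t{table.vw:.3f}\t{table.pct_within:.0f}%",
        f"Total\t{table.df_total}\t{table.ss_total:.3f}\t\t"
        f"{table.total_variance:.3f}\t100%",
        f"Fst: {table.phi_st:.3f}",
    ]
    if f_is is not None:
        lines.append(f"Fis: {f_is:.3f}")
        values["f_is"] = f_is
    return "\n".join(lines), values
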