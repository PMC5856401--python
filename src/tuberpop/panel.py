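"""Mixed-ploidy allele-dosage genotype panels: I/O, validation, filtering.

A panel stores, for biallelic SNPs, the per-sample count of the alternate
allele (the "dosage"): 0..2 for a diploid, 0..4 for an autotetraploid.
Missing calls are kept as NaN in a float matrix so that "missing" is always
distinguishable from dosage 0. Allele frequencies on mixed-ploidy panels
use per-sample ploidy in the denominator, which keeps frequencies unbiased
when diploid wild-species accessions sit alongside tetraploid cultivars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypePanel",
    "read_dosage_table",
    "write_dosage_table",
    "read_vcf",
    "allele_frequency",
    "filter_maf",
    "impute_missing_mean",
]

MISSING_TOKEN = "NA"


class PanelFormatError(ValueError):
    """Raised when a genotype table or VCF violates the dosage contract."""


@dataclass
class GenotypePanel:
    """Samples x loci allele-dosage matrix with per-sample ploidy.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    locus_ids
        Unique marker names, one per matrix column.
    dosage
        Float matrix of alternate-allele counts; NaN encodes a missing call.
    ploidy
        Integer ploidy per sample (2 and 4 in a potato panel; any >= 1).
    group
        Optional per-sample category (taxon or prior population label).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    ploidy: np.ndarray
    group: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.ploidy = np.asarray(self.ploidy, dtype=int)
        n, L = self.dosage.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != L:
            raise PanelFormatError(
                f"dosage matrix is {n}x{L} but there are "
                f"{len(self.sample_ids)} sample ids and {len(self.locus_ids)} locus ids"
            )
        if len(set(self.sample_ids)) != n:
            raise PanelFormatError("duplicate sample ids")
        if len(set(self.locus_ids)) != L:
            raise PanelFormatError("duplicate locus ids")
        if self.ploidy.shape != (n,) or np.any(self.ploidy < 1):
            raise PanelFormatError("ploidy must be a positive integer per sample")
        if self.group is not None and len(self.group) != n:
            raise PanelFormatError("group labels do not match sample count")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > self.ploidy[:, None])
        bad &= ~np.isnan(self.dosage)
        if np.any(bad):
            i, l = map(int, np.argwhere(bad)[0])
            raise PanelFormatError(
                f"dosage {self.dosage[i, l]:g} at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_ids[l]!r} exceeds ploidy {self.ploidy[i]}"
            )
        frac = self.dosage[~np.isnan(self.dosage)]
        if frac.size and np.any(frac != np.round(frac)):
            raise PanelFormatError("non-integer dosage entries")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def subset_samples(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in index],
            locus_ids=list(self.locus_ids),
            dosage=self.dosage[index],
            ploidy=self.ploidy[index],
            group=None if self.group is None else [self.group[i] for i in index],
        )

    def subset_loci(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[l] for l in index],
            dosage=self.dosage[:, index],
            ploidy=self.ploidy,
            group=self.group,
        )


def _read_metadata(metadata_path, sample_ids: list[str]):
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})
    if "sample_id" not in meta.columns or "ploidy" not in meta.columns:
        raise PanelFormatError("metadata needs columns: sample_id, ploidy[, group]")
    meta = meta.set_index("sample_id")
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise PanelFormatError(f"samples absent from metadata: {missing[:5]}")
    ploidy = meta.loc[sample_ids, "ploidy"]
    if ploidy.isna().any():
        raise PanelFormatError("ploidy missing for some samples")
    group = None
    if "group" in meta.columns:
        group = meta.loc[sample_ids, "group"].astype(str).tolist()
    return ploidy.astype(int).to_numpy(), group


def read_dosage_table(path, metadata_path) -> GenotypePanel:
    """Read a dosage CSV/TSV (rows = samples, columns = loci) plus metadata.

    The first column holds sample ids; the header row holds locus ids;
    cells are integers or ``NA``. Metadata is a CSV with columns
    ``sample_id, ploidy[, group]`` covering every sample.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep, index_col=0, na_values=[MISSING_TOKEN])
    table.index = table.index.astype(str)
    sample_ids = table.index.tolist()
    dosage = table.to_numpy(dtype=float)
    # locate non-integer cells before the panel constructor for a named error
    bad = ~np.isnan(dosage) & (dosage != np.round(dosage))
    if np.any(bad):
        i, l = map(int, np.argwhere(bad)[0])
        raise PanelFormatError(
            f"non-integer dosage at row {sample_ids[i]!r}, column {table.columns[l]!r}"
        )
    ploidy, group = _read_metadata(metadata_path, sample_ids)
    return GenotypePanel(
        sample_ids=sample_ids,
        locus_ids=[str(c) for c in table.columns],
        dosage=dosage,
        ploidy=ploidy,
        group=group,
    )


def write_dosage_table(panel: GenotypePanel, path, metadata_path=None) -> None:
    """Write a panel back to the dosage CSV (and optionally metadata CSV)."""
    df = pd.DataFrame(panel.dosage, index=panel.sample_ids, columns=panel.locus_ids)
    # keep integer cells integral in the text form; NaN -> "NA"
    df = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df = df.replace("", MISSING_TOKEN)
    df.index.name = "sample_id"
    df.to_csv(path)
    if metadata_path is not None:
        meta = pd.DataFrame(
            {
                "sample_id": panel.sample_ids,
                "ploidy": panel.ploidy,
                "group": panel.group if panel.group is not None else "",
            }
        )
        meta.to_csv(metadata_path, index=False)


def read_vcf(path, metadata_path, strict_biallelic: bool = True) -> GenotypePanel:
    """Read called genotypes from a VCF whose GT arity equals sample ploidy.

    A tetraploid call ``0/1/1/1`` becomes dosage 3; ``./././.`` is missing.
    Multi-allelic records are rejected under ``strict_biallelic`` (default)
    or skipped otherwise.
    """
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        ploidy, group = _read_metadata(metadata_path, sample_ids)
        locus_ids: list[str] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                if strict_biallelic:
                    raise PanelFormatError(
                        f"non-biallelic record {rec.id or rec.pos} "
                        f"with alts {rec.alts}"
                    )
                continue
            col = np.empty(len(sample_ids))
            for i, s in enumerate(sample_ids):
                gt = rec.samples[s].get("GT")
                alleles = tuple() if gt is None else tuple(gt)
                if all(a is None for a in alleles):
                    col[i] = np.nan
                    continue
                if len(alleles) != ploidy[i] or any(a is None for a in alleles):
                    raise PanelFormatError(
                        f"GT arity {len(alleles)} != ploidy {ploidy[i]} for "
                        f"sample {s!r} at {rec.id or rec.pos}"
                    )
                col[i] = sum(a == 1 for a in alleles)
            locus_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            rows.append(col)
    dosage = np.column_stack(rows) if rows else np.empty((len(sample_ids), 0))
    return GenotypePanel(sample_ids, locus_ids, dosage, ploidy, group)


def allele_frequency(panel: GenotypePanel, subset=None) -> np.ndarray:
    """Per-locus alternate-allele frequency over a sample subset.

    freq(l) = sum_i dosage[i,l] / sum_i ploidy[i] over non-missing samples;
    a locus with every entry missing gets NaN.
    """
    if subset is None:
        dosage, ploidy = panel.dosage, panel.ploidy
    else:
        subset = np.asarray(subset)
        if subset.dtype == bool:
            subset = np.flatnonzero(subset)
        if subset.size == 0:
            raise ValueError("empty sample subset")
        dosage, ploidy = panel.dosage[subset], panel.ploidy[subset]
    if dosage.shape[0] == 0:
        raise ValueError("empty sample subset")
    present = ~np.isnan(dosage)
    num = np.nansum(dosage, axis=0)
    denom = (present * ploidy[:, None]).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, num / denom, np.nan)
    return freq


def filter_maf(panel: GenotypePanel, threshold: float = 0.05) -> GenotypePanel:
    """Keep loci whose minor-allele frequency strictly exceeds ``threshold``.

    The inequality is strict: a locus at MAF exactly 0.05 is removed under
    the default. All-missing loci (undefined frequency) are removed too.
    The number of removed loci is recorded on the returned panel as
    ``panel.maf_removed``.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold {threshold} outside [0, 0.5]")
    freq = allele_frequency(panel)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
        keep = maf > threshold
    keep &= ~np.isnan(maf)
    out = panel.subset_loci(keep)
    out.maf_removed = int(panel.n_loci - out.n_loci)  # type: ignore[attr-defined]
    return out


def impute_missing_mean(panel: GenotypePanel) -> np.ndarray:
    """Complete matrix for PCA/DAPC: missing cells get the locus mean dosage.

    Diversity and distance statistics never see this matrix; they use
    pairwise-complete observations, because imputation biases heterozygosity.
    """
    dosage = panel.dosage
    if np.all(np.isnan(dosage), axis=0).any():
        raise ValueError("all-missing locus: filter loci before imputation")
    col_mean = np.nanmean(dosage, axis=0)
    out = np.array(dosage)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out
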