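"""End-to-end structure pipeline: filter, cluster, DAPC, trees, AMOVA.

``run_structure_pipeline`` chains the stages the analysis of a diversity
panel needs — MAF filter, BIC cluster search, cross-validation, DAPC,
structural-SNP selection, Nei/Ward dendrogram with partition agreement,
AMOVA / Fis / diversity summaries and optionally the pedigree statistics
— writing every artifact as deterministic text plus a JSON manifest with
the parameters and seed, so a run can be reproduced byte-for-byte.
Nested re-analysis of one detected subpopulation reuses the same code
path through a sample mask.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dapc import cross_validate, find_clusters, fit_dapc, snpzip
from .distance import cluster_agreement, cut_tree, nei_distance, to_newick, ward_cluster
from .diversity import amova, diversity_summary, fis, report_amova
from .panel import GenotypePanel, filter_maf, impute_missing_mean
from .pedigree import Pedigree, coefficient_of_relationship, kinship, mac

__all__ = ["RunConfig", "run_structure_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults follow standard practice
    for SNP diversity panels (MAF 0.05, 10% holdout, 999 permutations,
    five pedigree generations)."""

    maf_threshold: float = 0.05
    k_max: int = 10
    n_pca: int = 10
    n_pca_grid: tuple[int, ...] = (5, 10, 20)
    n_da: int | None = None
    xval_replicates: int = 30
    holdout: float = 0.1
    n_permutations: int = 999
    max_generations: int = 5
    seed: int = 0
    scale: bool = False


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def run_structure_pipeline(
    panel: GenotypePanel,
    out_dir,
    cfg: RunConfig | None = None,
    pedigree: Pedigree | None = None,
    sample_mask=None,
) -> dict:
    """Run every stage on ``panel`` and write reports under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``). With
    ``sample_mask`` the analysis is restricted to a subset — the nested
    within-subpopulation re-analysis.
    """
    cfg = cfg or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sample_mask is not None:
        panel = panel.subset_samples(np.asarray(sample_mask))

    manifest: dict = {
        "tool": "tuberpop",
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()
        },
        "stages": {},
    }

    # -- filter ------------------------------------------------------------
    filtered = filter_maf(panel, cfg.maf_threshold)
    manifest["stages"]["filter"] = {
        "samples": filtered.n_samples,
        "loci_in": panel.n_loci,
        "loci_retained": filtered.n_loci,
        "loci_removed": getattr(filtered, "maf_removed", panel.n_loci - filtered.n_loci),
    }
    matrix = impute_missing_mean(filtered)

    # -- cluster search ----------------------------------------------------
    k_max = min(cfg.k_max, filtered.n_samples)
    # cluster search keeps the full PC spectrum; only the DAPC stage reduces
    search = find_clusters(filtered, k_max=k_max, seed=cfg.seed, scale=cfg.scale)
    _write_tsv(
        pd.DataFrame({"K": search.k_grid, "WSS": search.wss, "BIC": search.bic}),
        out / "bic_curve.tsv",
        index=False,
    )
    clusters = np.array([f"cluster{c}" for c in search.assignments])
    manifest["stages"]["find_clusters"] = {"best_k": search.best_k, "k_max": k_max}

    if search.best_k < 2:
        manifest["stages"]["dapc"] = {"skipped": "single cluster detected"}
        _finalize(manifest, filtered, clusters, out, cfg, pedigree)
        return manifest

    # -- cross-validation of retained PCs ----------------------------------
    grid = [g for g in cfg.n_pca_grid if g < filtered.n_samples - 1]
    xval = None
    if len(grid) >= 1 and min(np.bincount(pd.factorize(clusters)[0])) >= 2:
        xval = cross_validate(
            matrix,
            clusters,
            grid,
            replicates=cfg.xval_replicates,
            holdout=cfg.holdout,
            seed=cfg.seed,
            scale=cfg.scale,
        )
        _write_tsv(
            pd.DataFrame(
                {
                    "n_pca": xval.n_pca_grid,
                    "mean_success": xval.success.mean(axis=1),
                    "rmse": xval.rmse,
                }
            ),
            out / "xval.tsv",
            index=False,
        )
        manifest["stages"]["cross_validate"] = {"best_n_pca": xval.best_n_pca}
    n_pca = xval.best_n_pca if xval is not None else min(cfg.n_pca, filtered.n_samples - 1)

    # -- DAPC ---------------------------------------------------------------
    model = fit_dapc(matrix, clusters, n_pca=n_pca, n_da=cfg.n_da, scale=cfg.scale)
    _write_tsv(
        pd.DataFrame(model.memberships, index=filtered.sample_ids, columns=model.group_names),
        out / "memberships.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            model.individual_coords,
            index=filtered.sample_ids,
            columns=[f"LD{i + 1}" for i in range(model.n_da)],
        ),
        out / "dapc_coords.tsv",
    )
    _write_tsv(
        pd.DataFrame(
            model.variable_loadings,
            index=filtered.locus_ids,
            columns=[f"LD{i + 1}" for i in range(model.n_da)],
        ),
        out / "loadings.tsv",
    )
    manifest["stages"]["dapc"] = {
        "n_pca": model.n_pca,
        "n_da": model.n_da,
        "variance_conserved": float(model.pca.variance_fraction[model.n_pca - 1]),
        "da_eigenvalues": [float(x) for x in model.da_eigenvalues],
        "membership_min": float(model.memberships.max(axis=1).min()),
    }

    # -- structural SNPs ----------------------------------------------------
    try:
        zipres = snpzip(model, filtered.locus_ids, axis=0)
        (out / "structural_snps.txt").write_text("\n".join(zipres.structural) + "\n")
        manifest["stages"]["snpzip"] = {"n_structural": len(zipres.structural)}
    except ValueError as e:
        manifest["stages"]["snpzip"] = {"skipped": str(e)}

    # -- Nei distance / Ward dendrogram -------------------------------------
    dist = nei_distance(filtered, level="individual")
    _write_tsv(dist.to_frame(), out / "nei_distance.tsv")
    tree = ward_cluster(dist)
    (out / "dendrogram.nwk").write_text(to_newick(tree) + "\n")
    partition = cut_tree(tree, search.best_k)
    tree_labels = np.array([partition[s] for s in filtered.sample_ids])
    _write_tsv(
        pd.DataFrame({"sample": filtered.sample_ids, "tree_cluster": tree_labels}),
        out / "tree_partition.tsv",
        index=False,
    )
    agreement = cluster_agreement(tree_labels, clusters)
    manifest["stages"]["dendrogram"] = {"agreement_pct": agreement}

    _finalize(manifest, filtered, clusters, out, cfg, pedigree)
    return manifest


def _finalize(manifest, filtered, clusters, out: Path, cfg: RunConfig, pedigree) -> None:
    """AMOVA, Fis, diversity and pedigree stages plus the manifest file."""
    if len(set(clusters)) >= 2:
        table, phi_stats = amova(
            filtered, clusters, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        fis_stats = fis(
            filtered, clusters, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        text, values = report_amova(table, f_is=fis_stats.f_is)
        (out / "amova.tsv").write_text(text + "\n")
        manifest["stages"]["amova"] = {
            "phi_st": table.phi_st,
            "p_phi": phi_stats.p_phi,
            "f_is": fis_stats.f_is,
            "p_fis": fis_stats.p_fis,
        }
    summary = diversity_summary(filtered, clusters)
    _write_tsv(summary.table, out / "diversity.tsv")

    if pedigree is not None:
        kin = kinship(pedigree)
        in_ped = [s for s in filtered.sample_ids if s in pedigree.parents]
        manifest["stages"]["pedigree"] = {"samples_with_records": len(in_ped)}
        for label in dict.fromkeys(clusters.tolist()):
            members = [
                s for s, c in zip(filtered.sample_ids, clusters) if c == label
            ]
            sub = [s for s in members if s in pedigree.parents]
            if not sub:
                continue
            rel = coefficient_of_relationship(kin, sub)
            manifest["stages"]["pedigree"][f"{label}_cr_above_0.5"] = rel.fraction_above
            for side in ("maternal", "paternal"):
                try:
                    report = mac(pedigree, sub, side=side, max_gen=cfg.max_generations)
                except Exception:
                    continue
                _write_tsv(
                    report.table, out / f"mac_{label}_{side}.tsv", index=False
                )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
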