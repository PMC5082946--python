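"""End-to-end orchestration and publication-style outputs.

``run_all`` executes simulate -> (optional SAM round trip) -> rRNA removal
-> normalization -> phage fraction -> temporal clustering (light and dark)
-> differential expression over all contrasts -> reports, writing every
stage artifact plus a manifest with checksums so a rerun with the same
seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import Annotation, write_gff3
from .cluster import (
    cluster_concordance,
    dendrogram_newick,
    gap_select_k,
    hierarchical_cluster,
    kl_distance_matrix,
    label_timing,
    pam,
    temporal_profiles,
)
from .counting import StrandedCountTable, remove_rrna
from .de import Contrast, all_contrasts, run_contrast
from .normalize import antisense_sense_ratio, normalize_dual, phage_fraction
from .simulate import SimulationConfig, generate_annotations, simulate_counts

FLOAT_FORMAT = "%.6g"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def deg_report(
    de_table: pd.DataFrame,
    ann: Annotation,
    include_hypothetical: bool = False,
) -> pd.DataFrame:
    """Publication-style DEG listing for one contrast family.

    Keeps consensus DEGs only, orders rows by chromosome position, adds
    product annotations, and (by default) excludes hypothetical proteins
    as the published tables do."""
    meta = {f.feature_id: f for f in ann.features}
    degs = de_table[de_table["deg"]].copy()
    if degs.empty:
        cols = list(de_table.columns) + ["start", "product"]
        return pd.DataFrame(columns=cols)
    degs["start"] = [meta[g].start for g in degs.index]
    degs["product"] = [meta[g].product or "" for g in degs.index]
    if not include_hypothetical:
        degs = degs[degs["product"] != "hypothetical protein"]
    return degs.sort_values(["start", "time_h"])


def fold_change_matrix(
    de_tables: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x (contrast, time point) log2FC matrix plus significance mask.

    The mask is True exactly where the nonparametric probability q exceeds
    0.95 (the published heat-map marking rule); genes never tested in a
    column are NaN in the matrix and False in the mask."""
    lfc = de_tables.pivot_table(
        index=de_tables.index, columns=["contrast"], values="log2fc", aggfunc="first"
    )
    qmat = de_tables.pivot_table(
        index=de_tables.index, columns=["contrast"], values="q", aggfunc="first"
    )
    mask = (qmat > 0.95).fillna(False).astype(bool).reindex_like(lfc)
    return lfc, mask


def render_heatmap(
    lfc: pd.DataFrame, mask: pd.DataFrame, path: str, title: str = ""
) -> None:
    """Convenience heat-map rendering of a fold-change matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = lfc.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * lfc.shape[1] + 2), max(3, 0.08 * lfc.shape[0] + 1))
    )
    vmax = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    im = ax.imshow(data, aspect="auto", cmap="PiYG", vmin=-vmax, vmax=vmax)
    ys, xs = np.where(mask.to_numpy())
    ax.scatter(xs, ys, marker="x", s=8, c="black", linewidths=0.5)
    ax.set_xticks(range(lfc.shape[1]))
    ax.set_xticklabels(lfc.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=120, metadata={"Software": "dualrna"})
    plt.close(fig)


def run_all(
    config: SimulationConfig,
    outdir: str,
    cluster_k: int | str = "auto",
    gap_b: int = 20,
    render_figures: bool = True,
) -> dict:
    """Run the full synthetic-mode pipeline into ``outdir``; return manifest."""
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_flat_dict(),
        "stages": {},
        "outputs": {},
    }

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, **kw)
        manifest["outputs"][name] = _sha256(path)

    # --- simulate
    ann = generate_annotations(config)
    table, truth = simulate_counts(config, ann)
    write_gff3(ann, os.path.join(outdir, "annotations.gff3"))
    manifest["outputs"]["annotations.gff3"] = _sha256(
        os.path.join(outdir, "annotations.gff3")
    )
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=True)
    manifest["outputs"]["config.yaml"] = _sha256(os.path.join(outdir, "config.yaml"))
    truth.to_json(os.path.join(outdir, "truth.json"))
    manifest["outputs"]["truth.json"] = _sha256(os.path.join(outdir, "truth.json"))
    save_df(table.samples, "sample_sheet.tsv")
    table.to_tsv(os.path.join(outdir, "counts_raw.tsv"), ann)
    manifest["outputs"]["counts_raw.tsv"] = _sha256(
        os.path.join(outdir, "counts_raw.tsv")
    )
    manifest["stages"]["simulate"] = {
        "n_features": len(ann.features),
        "n_samples": len(table.samples),
        "total_counts": int(table.counts.to_numpy().sum()),
    }

    # --- rRNA removal
    table_clean, rrna_frac = remove_rrna(table, ann)
    save_df(rrna_frac.rename("rrna_fraction").to_frame(), "rrna_removed.tsv")
    table_clean.to_tsv(os.path.join(outdir, "counts.tsv"), ann)
    manifest["outputs"]["counts.tsv"] = _sha256(os.path.join(outdir, "counts.tsv"))
    manifest["stages"]["remove_rrna"] = {
        "mean_removed_fraction": float(rrna_frac.mean())
    }

    # --- normalization + phage fraction + antisense ratios
    norm = normalize_dual(table_clean, ann)
    norm.to_tsv(os.path.join(outdir, "normalized.tsv"))
    manifest["outputs"]["normalized.tsv"] = _sha256(
        os.path.join(outdir, "normalized.tsv")
    )
    frac = phage_fraction(table_clean, ann)
    save_df(
        frac.rename("phage_fraction").to_frame().join(table_clean.samples),
        "phage_fraction.tsv",
    )
    ratios = antisense_sense_ratio(norm)
    save_df(ratios, "antisense_sense_ratio.tsv")
    manifest["stages"]["normalize"] = {
        "n_rows": int(len(norm.values)),
        "n_high_antisense": int(ratios["high_antisense"].sum()),
    }

    # --- temporal clustering of phage genes, light and dark
    labels = {}
    phage_ids = [
        f.feature_id
        for f in ann.features
        if f.organism == "phage" and f.feature_class == "ORF"
    ]
    for condition in config.light_levels:
        prof = temporal_profiles(
            norm.values.loc[norm.pool == "combined_pool"],
            table_clean.samples,
            light=condition,
        )
        prof = prof.loc[prof.index.intersection(phage_ids)]
        if cluster_k == "auto":
            curve, result = gap_select_k(
                prof, b_reference=max(gap_b, 10), seed=config.seed
            )
            save_df(curve.to_frame(), f"gap_curve_{condition}.tsv", index=False)
        else:
            d = kl_distance_matrix(prof)
            result = pam(d, int(cluster_k))
        result = label_timing(result, prof, list(config.time_points_h))
        lab = result.labels()
        labels[condition] = lab
        assign = pd.DataFrame(
            {
                "cluster": result.assignment,
                "timing": lab,
                "medoid": [
                    prof.index[result.medoids[c]] for c in result.assignment
                ],
            },
            index=prof.index,
        )
        save_df(assign, f"clusters_{condition}.tsv")
        z, _ = hierarchical_cluster(prof)
        newick = dendrogram_newick(z, list(prof.index))
        nwk_path = os.path.join(outdir, f"dendrogram_{condition}.nwk")
        with open(nwk_path, "w") as fh:
            fh.write(newick)
        manifest["outputs"][f"dendrogram_{condition}.nwk"] = _sha256(nwk_path)
        manifest["stages"][f"cluster_{condition}"] = {
            "k": result.k,
            "n_genes": int(len(prof)),
            "cost": float(result.cost),
        }
    concordance = None
    if "light" in labels and "dark" in labels:
        concordance = cluster_concordance(labels["light"], labels["dark"])
        manifest["stages"]["cluster_concordance"] = {
            "light_vs_dark": concordance
        }

    # --- differential expression
    meta = {f.feature_id: f for f in ann.features}
    host_genes = [
        g
        for g in norm.values.index.get_level_values("feature_id").unique()
        if meta[g].organism == "host"
    ]
    de_frames = []
    for contrast in all_contrasts(table_clean.samples):
        counts_slice = (
            table_clean.counts.xs(contrast.orientation, level="orientation")
            .loc[lambda df: df.index.isin(host_genes)]
        )
        norm_slice = (
            norm.values.xs(contrast.orientation, level="orientation")
            .loc[lambda df: df.index.isin(host_genes)]
        )
        de_frames.append(
            run_contrast(counts_slice, norm_slice, table_clean.samples, contrast)
        )
    de_all = pd.concat(de_frames)
    de_all.index.name = "gene"
    save_df(de_all, "de_all.tsv")
    manifest["stages"]["differential_expression"] = {
        "n_tests": int(len(de_all)),
        "n_degs": int(de_all["deg"].sum()),
    }

    # --- reports
    for kind in ("infected_vs_uninfected", "dark_vs_light"):
        sub = de_all[de_all["contrast"].str.startswith(kind)]
        rep = deg_report(sub, ann)
        save_df(rep, f"deg_report_{kind}.tsv")
    lfc, mask = fold_change_matrix(de_all[de_all["orientation"] == "sense"])
    save_df(lfc, "fold_change_matrix.tsv")
    save_df(mask, "fold_change_mask.tsv")
    if render_figures:
        render_heatmap(
            lfc,
            mask,
            os.path.join(outdir, "heatmap.png"),
            title="host log2FC (x: q > 0.95)",
        )
        manifest["outputs"]["heatmap.png"] = _sha256(
            os.path.join(outdir, "heatmap.png")
        )

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
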