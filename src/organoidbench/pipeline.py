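"""End-to-end orchestration: simulate → DE → PCA → signature → deconvolution
→ enrichment → effect sizes, with a machine-readable report and a manifest.

Every stage writes its outputs under the run directory and is re-runnable
in isolation from those files; the report JSON contains only computed
quantities (no timestamps) so two runs with the same config and seed
produce byte-identical reports. The manifest records the config hash, root
seed, per-file SHA-256 hashes and timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, deconv, effects, enrichment, reference, variance
from .io import (
    GeneSet,
    read_counts,
    read_sample_sheet,
    write_counts,
    write_gmt,
    write_json,
    write_mtx,
    write_sample_sheet,
)
from .simulate import EffectSpec, SimulationConfig, simulate_study

__version__ = "0.1.0"

__all__ = ["run_all", "report_summary", "config_from_mapping"]


def config_from_mapping(mapping: dict | None, seed: int | None = None) -> SimulationConfig:
    """Build a SimulationConfig from a (YAML-loaded) plain mapping."""
    mapping = dict(mapping or {})
    effect = mapping.pop("effect_spec", None)
    cfg = SimulationConfig(**mapping)
    if effect is not None:
        cfg = dataclasses.replace(
            cfg,
            effect_spec={
                f: dataclasses.replace(cfg.effect_spec.get(f, EffectSpec()), **spec)
                for f, spec in effect.items()
            },
        )
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: SimulationConfig) -> str:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if dataclasses.is_dataclass(obj):
            return _clean(dataclasses.asdict(obj))
        return obj

    blob = json.dumps(_clean(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_all(config: SimulationConfig, out_dir, gsea_permutations: int = 1000) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Writes ``counts.tsv``, ``samples.tsv``, the single-cell MTX triplet,
    ``ground_truth.json``, per-contrast DEG tables, PCA outputs, the
    signature TSV + marker GMT, composition estimates and tests, the GSEA
    table, effect sizes, ``report.json`` and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list = []
    report: dict = {"seed": config.seed, "n_genes": config.n_genes}

    # --- stage: simulate -------------------------------------------------
    design, truth, bulk, cells, labels = simulate_study(config)
    write_counts(bulk, out / "counts.tsv")
    write_sample_sheet(design, out / "samples.tsv")
    write_mtx(cells, out / "sc")
    truth_json = {
        "planted_variance_share": truth.planted_variance_share,
        "affected_gene_sets": truth.affected_gene_sets,
        "marker_genes": truth.marker_genes,
        "true_log2fc": truth.true_log2fc.to_dict(orient="index"),
        "true_log2fc_in_vitro": truth.true_log2fc_in_vitro.to_dict(orient="index"),
        "true_compositions": truth.true_compositions.to_dict(orient="index"),
    }
    write_json(truth_json, out / "ground_truth.json")
    stages.append("simulate")
    report["design"] = {"n_samples": len(design), "n_cells": cells.n_cells}

    # --- stage: normalization + DE --------------------------------------
    sf = de.size_factors(bulk)
    norm = de.normalized_frame(bulk, sf)
    in_vivo, in_vitro = config.factor_levels["sample_type"][:2]
    contrasts = [de.Contrast("sample_type", in_vitro, in_vivo)]
    for stype in (in_vivo, in_vitro):
        contrasts += de.standard_contrasts(stype)
    deg_tables: dict = {}
    for contrast in contrasts:
        table = de.nb_wald_test(bulk, design, contrast)
        deg_tables[contrast.label] = table
        fname = contrast.label.replace(":", "_").replace("|", "__").replace("=", "-")
        with open(out / f"deg_{fname}.tsv", "w") as fh:
            fh.write(f"# contrast: {contrast.label}\n")
            table.to_csv(fh, sep="\t")
    report["deg_counts"] = {
        label: int((t["padj"] < 0.05).sum()) for label, t in deg_tables.items()
    }
    stages.append("de")

    # --- stage: variance decomposition ----------------------------------
    kept = variance.filter_genes(norm, design)
    pca = variance.run_pca(norm.loc[kept])
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pca.contribution.to_csv(out / "pca_contributions.tsv", sep="\t")
    n_assoc = min(6, len(pca.components))
    associations = {
        comp: {
            factor: variance.pc_factor_association(pca, design, comp, factor)
            for factor in config.factor_levels
        }
        for comp in pca.components[:n_assoc]
    }
    contributing = {
        comp: int(len(variance.contributing_genes(pca, comp)))
        for comp in pca.components[:n_assoc]
    }
    report["variance"] = {
        "n_filtered_genes": len(kept),
        "variance_fraction": {
            c: float(pca.variance_fraction[c]) for c in pca.components[:n_assoc]
        },
        "planted_variance_share": truth.planted_variance_share,
        "association_p": associations,
        "n_contributing_genes": contributing,
    }
    stages.append("varpart")

    # --- stage: single-cell reference ------------------------------------
    norm_cells = reference.normalize_cells(cells)
    k = len(config.cell_types)
    cluster_labels = reference.cluster_cells(norm_cells, k=k, seed=config.seed)
    truth_sets = [GeneSet(t, tuple(g)) for t, g in truth.marker_genes.items()]
    assignment = reference.assign_cell_types(cluster_labels, truth_sets, norm_cells)
    type_of_cluster = assignment["cell_type"].to_dict()
    cell_types_assigned = np.array(
        [type_of_cluster.get(int(c)) for c in cluster_labels], dtype=object
    )
    markers_per_type: dict = {}
    for cluster, ctype in type_of_cluster.items():
        if ctype is None:
            continue
        table = reference.define_markers(norm_cells, cluster_labels, cluster)
        markers_per_type[ctype] = list(table.index[table["selected"]])
    markers_per_type = {t: g for t, g in markers_per_type.items() if g}
    signature = reference.build_signature(
        norm_cells,
        cell_types_assigned,
        markers_per_type,
        type_order=tuple(t for t in config.cell_types if t in markers_per_type),
    )
    signature.profiles.to_csv(out / "signature.tsv", sep="\t")
    write_gmt(
        [GeneSet(t, tuple(g)) for t, g in markers_per_type.items()],
        out / "markers.gmt",
    )
    report["reference"] = {
        "n_clusters": int(len(assignment)),
        "assigned_types": sorted(t for t in type_of_cluster.values() if t),
        "n_markers": {t: len(g) for t, g in markers_per_type.items()},
    }
    stages.append("signature")

    # --- stage: deconvolution --------------------------------------------
    estimates = deconv.deconvolve_samples(norm, signature)
    estimates.to_csv(out / "compositions.tsv", sep="\t")
    validation = deconv.validate_simulated(signature, seed=config.seed)
    comp_tests = deconv.compare_compositions(
        estimates.loc[design.sample_ids], design
    )
    comp_tests.to_csv(out / "composition_tests.tsv", sep="\t")
    shared_types = [t for t in signature.cell_types if t in truth.true_compositions.columns]
    est_mat = estimates.loc[design.sample_ids, shared_types].to_numpy()
    true_mat = truth.true_compositions[shared_types].to_numpy()
    recovery_r2 = float(np.corrcoef(est_mat.ravel(), true_mat.ravel())[0, 1] ** 2)
    report["deconvolution"] = {
        "validation_r_squared": validation.r_squared,
        "bulk_recovery_r_squared": recovery_r2,
        "mean_composition": {
            stype: {
                t: float(estimates.loc[design.mask(sample_type=stype), t].mean())
                for t in signature.cell_types
            }
            for stype in config.factor_levels["sample_type"]
        },
        "welch_p_sample_type": {
            t: float(comp_tests.loc[t, "welch_p_sample_type"])
            for t in signature.cell_types
        },
    }
    stages.append("deconv")

    # --- stage: enrichment ------------------------------------------------
    ranked = enrichment.rank_genes(deg_tables[contrasts[0].label])
    gsea_table = enrichment.gsea(
        ranked, truth_sets, n_permutations=gsea_permutations, seed=config.seed
    )
    gsea_table.to_csv(out / "gsea.tsv", sep="\t")
    report["enrichment"] = {
        "contrast": contrasts[0].label,
        "es": {t: float(gsea_table.loc[t, "es"]) for t in gsea_table.index},
        "padj": {t: float(gsea_table.loc[t, "padj"]) for t in gsea_table.index},
    }
    stages.append("gsea")

    # --- stage: effect sizes ----------------------------------------------
    def _matrix(stype: str) -> effects.DEGMatrix:
        tables = {
            c.factor: deg_tables[c.label] for c in de.standard_contrasts(stype)
        }
        return effects.build_deg_matrix(tables, rule="padj")

    vivo_mat, vitro_mat = _matrix(in_vivo), _matrix(in_vitro)
    retention = effects.feature_retention(
        vivo_mat, vitro_mat, features=("compartment", "gender", "age")
    )
    aging_results = {}
    for stype in (in_vivo, in_vitro):
        strata_tables, strata_meta = {}, {}
        for comp in config.factor_levels["compartment"]:
            for gender in config.factor_levels["gender"]:
                contrast = de.Contrast(
                    "age",
                    config.factor_levels["age"][1],
                    config.factor_levels["age"][0],
                    (("sample_type", stype), ("compartment", comp), ("gender", gender)),
                )
                strata_tables[contrast.label] = de.nb_wald_test(bulk, design, contrast)
                strata_meta[contrast.label] = {"compartment": comp, "gender": gender}
        aging_matrix = effects.build_deg_matrix(strata_tables, rule="pvalue")
        if aging_matrix.empty:
            aging_results[stype] = None
            continue
        strata = pd.DataFrame(strata_meta).T
        aging_results[stype] = {
            label: res.as_dict()
            for label, res in effects.aging_modifiers(aging_matrix, strata).items()
        }
    overlaps = effects.deg_overlap(
        {
            f"{feature}_{stype}": genes
            for stype, mat in (("in_vivo", vivo_mat), ("in_vitro", vitro_mat))
            for feature, genes in mat.gene_sets().items()
        }
    )
    overlaps.to_csv(out / "deg_overlaps.tsv", sep="\t", index=False)
    report["effect_size"] = {
        "retention": {
            f: {kind: res.as_dict() for kind, res in models.items()}
            for f, models in retention.items()
        },
        "aging_modifiers": aging_results,
    }
    stages.append("effects")

    write_json(report, out / "report.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": stages,
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
        "elapsed_seconds": time.time() - t0,
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def report_summary(run_dir) -> str:
    """Human-readable, six-section summary of a finished run."""
    run_dir = Path(run_dir)
    with open(run_dir / "report.json") as fh:
        report = json.load(fh)
    lines: list = []

    def section(title: str) -> None:
        lines.append("")
        lines.append(f"== {title} ==")

    section("Design")
    lines.append(f"samples: {report['design']['n_samples']}  cells: {report['design']['n_cells']}")

    section("Differential expression (adjusted p < 0.05)")
    for label, n in report["deg_counts"].items():
        lines.append(f"{label}: {n} DEGs")

    section("Variance decomposition")
    for comp, frac in report["variance"]["variance_fraction"].items():
        n_contrib = report["variance"]["n_contributing_genes"].get(comp, "-")
        lines.append(f"{comp}: {100 * frac:.1f}% of variance, {n_contrib} contributing genes")

    section("Cell-type composition")
    for stype, comps in report["deconvolution"]["mean_composition"].items():
        top = sorted(comps.items(), key=lambda kv: -kv[1])[:3]
        tops = ", ".join(f"{t} {v:.2f}" for t, v in top)
        lines.append(f"{stype}: {tops}")
    lines.append(
        "simulated-mixture R^2 = "
        f"{report['deconvolution']['validation_r_squared']:.3f}; "
        "bulk-recovery R^2 = "
        f"{report['deconvolution']['bulk_recovery_r_squared']:.3f}"
    )

    section("Cell-type enrichment (GSEA)")
    for name, es in report["enrichment"]["es"].items():
        padj = report["enrichment"]["padj"][name]
        lines.append(f"{name}: ES {es:+.2f}, adj p {padj:.3g}")

    section("Effect sizes (feature retention in vitro)")
    for feature, models in report["effect_size"]["retention"].items():
        simple = models["simple"]
        lines.append(
            f"{feature}: adjusted R^2 = {simple['adj_r_squared']:.3f} "
            f"(n = {simple['n_genes']}, F p = {simple['f_pvalue']:.3g})"
        )
    return "\n".join(lines[1:])
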