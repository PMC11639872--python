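"""End-to-end orchestration of the analysis stages over a bundle directory.

A bundle holds one sub-directory per species (counts.tsv, metadata.tsv,
hits.tsv, symbiont_hits.tsv, domains.tsv, optional truth.tsv /
sequences.fasta / isoforms.tsv) plus shared srg_families.tsv.  The pipeline
runs, per species: isoform filtering (skipped when no isoform table is
present) -> host/symbiont binning -> SRG cataloguing -> normalization ->
time-matched differential expression -> multivariate statistics (PCA,
PERMANOVA, plasticity, ANOVA + Tukey) -> frontloading classification, and
writes every stage table as TSV together with a JSON manifest of stage
status, thresholds, seed, and output checksums.  Re-running with the same
config reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .core_data import (
    CountMatrix,
    SampleMetadata,
    read_count_matrix,
    read_domain_table,
    read_hit_table,
    read_metadata,
    read_srg_families,
    validate_design,
)
from .binning import affiliation_summary, assign_bins, gc_content
from .diffexpr import DEOptions, de_analysis, summarize_deg_counts
from .expression import cpm, expression_filter, size_factors_median_ratio, vst_transform
from .frontloading import (
    frontloading_calls,
    frontloading_report,
    responsive_srg_summary,
    srg_expression_summary,
)
from .isoforms import filter_isoforms, read_isoform_table
from .multivariate import (
    anova_oneway,
    euclidean_distance_matrix,
    pca,
    permanova,
    plasticity_distance,
    tukey_hsd,
)
from .srg import assign_srg_families

logger = logging.getLogger(__name__)

STAGES = (
    "filter",
    "bin",
    "catalog",
    "normalize",
    "de",
    "multivariate",
    "frontloading",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the input."""


@dataclass
class PipelineConfig:
    bundle_dir: str
    outdir: str
    seed: int = 0
    n_permutations: int = 999
    cpm_min: float = 2.0
    lib_min: int = 2
    lfc_de: float = 4.0
    fdr_max: float = 0.05
    lfc_front: float = 2.0
    evalue_max: float = 1e-5
    plasticity_space: str = "full"  # or "pca"
    frontloading_unit: str = "cpm"  # cpm | tpm | vst
    frontloading_timepoint_rule: str = "both"  # both | either

    def __post_init__(self) -> None:
        for name in ("cpm_min", "lfc_de", "fdr_max", "lfc_front", "evalue_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every species sub-directory of the bundle.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    """
    bundle = Path(config.bundle_dir)
    if not bundle.exists():
        raise PipelineError(f"bundle directory not found: {bundle}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species_dirs = sorted(
        d for d in bundle.iterdir() if d.is_dir() and (d / "counts.tsv").exists()
    )
    if not species_dirs:
        raise PipelineError(f"no species directories with counts.tsv under {bundle}")
    fam_path = bundle / "srg_families.tsv"
    families = read_srg_families(fam_path) if fam_path.exists() else None
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config),
        "stages": list(STAGES),
        "species": {},
        "files": {},
    }
    for sdir in species_dirs:
        manifest["species"][sdir.name] = _run_species(
            config, sdir, outdir / sdir.name, families
        )
    for path in sorted(outdir.rglob("*.tsv")) + sorted(outdir.rglob("*.json")):
        if path.name == "manifest.json":
            continue
        manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _stage(name: str, sdir: Path):
    logger.info("stage %s [%s]", name, sdir.name)
    return time.perf_counter()


def _run_species(
    config: PipelineConfig, sdir: Path, out: Path, families: pd.DataFrame | None
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    stage_status: dict[str, str] = {}
    summary: dict = {"stages": stage_status}
    try:
        counts = read_count_matrix(sdir / "counts.tsv")
        meta = read_metadata(sdir / "metadata.tsv")
        design = validate_design(meta, counts)
        summary["design"] = {"n_samples": design["n_samples"], "warnings": design["warnings"]}
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage load [{sdir.name}]: {err}") from err

    # 1. isoform filtering ---------------------------------------------------
    _stage("filter", sdir)
    iso_path = sdir / "isoforms.tsv"
    if iso_path.exists():
        try:
            iso = filter_isoforms(read_isoform_table(iso_path))
            _write(iso, out / "isoforms_filtered.tsv", index=False)
            keep = counts.gene_ids.intersection(iso["isoform_id"])
            if len(keep):
                counts = counts.subset_genes(keep)
            stage_status["filter"] = "ok"
        except Exception as err:  # noqa: BLE001
            raise PipelineError(f"stage filter [{sdir.name}]: {err}") from err
    else:
        stage_status["filter"] = "skipped (no isoform table)"

    # 2. binning -------------------------------------------------------------
    _stage("bin", sdir)
    try:
        hits = read_hit_table(sdir / "hits.tsv")
        assignments = assign_bins(counts.gene_ids, hits, config.evalue_max)
        _write(assignments, out / "bin_assignments.tsv")
        sym_path = sdir / "symbiont_hits.tsv"
        if sym_path.exists():
            affil = affiliation_summary(
                assignments, read_hit_table(sym_path), config.evalue_max
            )
            _write(affil, out / "symbiont_affiliation.tsv")
        fasta = sdir / "sequences.fasta"
        if fasta.exists():
            seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")}
            gc = gc_content(seqs, assignments)
            _write(gc.to_frame(), out / "gc_content.tsv")
        stage_status["bin"] = "ok"
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage bin [{sdir.name}]: {err}") from err

    # 3. SRG catalog ---------------------------------------------------------
    _stage("catalog", sdir)
    catalog = pd.DataFrame(columns=["family", "category"]).rename_axis("gene_id")
    dom_path = sdir / "domains.tsv"
    if dom_path.exists() and families is not None:
        try:
            catalog = assign_srg_families(
                read_domain_table(dom_path), families, config.evalue_max
            )
            host_genes = assignments.index[assignments["bin"] == "host"]
            catalog = catalog.loc[catalog.index.intersection(host_genes)]
            _write(catalog, out / "srg_catalog.tsv")
            stage_status["catalog"] = "ok"
        except Exception as err:  # noqa: BLE001
            raise PipelineError(f"stage catalog [{sdir.name}]: {err}") from err
    else:
        stage_status["catalog"] = "skipped (no domain table or family definitions)"

    # 4. normalization -------------------------------------------------------
    _stage("normalize", sdir)
    try:
        cpm_mat = cpm(counts)
        keep = expression_filter(cpm_mat, config.cpm_min, config.lib_min)
        summary["n_genes_total"] = int(counts.counts.shape[0])
        summary["n_genes_filtered"] = int(len(keep))
        filtered = counts.subset_genes(keep)
        size_factors = size_factors_median_ratio(filtered.counts)
        vst = vst_transform(filtered.counts, size_factors)
        _write(vst, out / "vst.tsv")
        _write(cpm_mat.loc[keep], out / "cpm_filtered.tsv")
        stage_status["normalize"] = "ok"
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage normalize [{sdir.name}]: {err}") from err

    # 5. differential expression --------------------------------------------
    _stage("de", sdir)
    try:
        opts = DEOptions(
            min_cpm=config.cpm_min,
            min_libraries=config.lib_min,
            lfc_min=config.lfc_de,
            fdr_max=config.fdr_max,
        )
        results = []
        for tp in meta.timepoints:
            res = de_analysis(counts, meta, tp, opts)
            res["origin"] = assignments["bin"].reindex(res.index)
            res["species"] = sdir.name
            results.append(res)
        de_results = pd.concat(results)
        _write(de_results, out / "de_results.tsv")
        deg_counts = summarize_deg_counts(de_results)
        _write(deg_counts, out / "deg_counts.tsv", index=False)
        summary["deg_counts"] = deg_counts.to_dict(orient="records")
        stage_status["de"] = "ok"
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage de [{sdir.name}]: {err}") from err

    # 6. multivariate --------------------------------------------------------
    _stage("multivariate", sdir)
    try:
        rng = np.random.default_rng(config.seed)
        mv: dict = {}
        for bin_name in ("host", "symbiont"):
            genes = assignments.index[assignments["bin"] == bin_name]
            sub = vst.loc[vst.index.intersection(genes)]
            if sub.shape[0] < 3:
                continue
            pres = pca(sub)
            _write(pres.scores, out / f"pca_scores_{bin_name}.tsv")
            dist = euclidean_distance_matrix(sub)
            groups = meta.group_labels().reindex(dist.index)
            seed_t = int(rng.integers(2**31))
            per_t = permanova(
                dist, meta.table["treatment"].reindex(dist.index),
                n_perm=config.n_permutations, seed=seed_t,
            )
            seed_c = int(rng.integers(2**31))
            per_cell = permanova(
                dist, groups, n_perm=config.n_permutations, seed=seed_c
            )
            plast = plasticity_distance(
                sub, meta, space=config.plasticity_space
            )
            _write(plast, out / f"plasticity_{bin_name}.tsv")
            f, p_anova = anova_oneway(plast["distance"], plast["group"])
            tukey = tukey_hsd(plast["distance"], plast["group"])
            _write(tukey, out / f"tukey_{bin_name}.tsv", index=False)
            mv[bin_name] = {
                "pca_variance_ratio": [float(v) for v in pres.variance_ratio[:2]],
                "permanova_treatment": {
                    "pseudo_f": per_t.pseudo_f, "r2": per_t.r2, "p": per_t.pvalue
                },
                "permanova_cells": {
                    "pseudo_f": per_cell.pseudo_f, "r2": per_cell.r2, "p": per_cell.pvalue
                },
                "plasticity_anova": {"f": f, "p": p_anova},
            }
        summary["multivariate"] = mv
        stage_status["multivariate"] = "ok"
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage multivariate [{sdir.name}]: {err}") from err

    # 7. frontloading --------------------------------------------------------
    _stage("frontloading", sdir)
    try:
        if config.frontloading_unit == "cpm":
            unit_mat = cpm_mat.loc[keep]
        elif config.frontloading_unit == "vst":
            unit_mat = vst
        else:
            raise ValueError(
                f"frontloading unit {config.frontloading_unit!r} needs gene "
                "lengths; supply a lengths table or use cpm/vst"
            )
        calls = frontloading_calls(
            unit_mat,
            meta,
            de_results,
            lfc_bound=config.lfc_front,
            timepoint_rule=config.frontloading_timepoint_rule,
        )
        _write(calls, out / "frontloading_calls.tsv")
        if not catalog.empty:
            report = frontloading_report(calls, catalog)
            _write(report, out / "frontloading_report.tsv", index=False)
            summary["srg_summary"] = srg_expression_summary(
                unit_mat, catalog, meta, de_results
            )
            summary["responsive_summary"] = responsive_srg_summary(
                calls, de_results, catalog
            )
            srg_calls = calls.loc[calls.index.intersection(catalog.index)]
            summary["n_srg_frontloaded"] = int(srg_calls["frontloaded"].sum())
        summary["n_frontloaded"] = int(calls["frontloaded"].sum())
        stage_status["frontloading"] = "ok"
    except Exception as err:  # noqa: BLE001
        raise PipelineError(f"stage frontloading [{sdir.name}]: {err}") from err

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
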