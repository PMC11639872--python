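"""Synthetic holobiont fixture bundles with planted ground truth.

Emulates the study design the analysis assumes: per species, 12 RNA-seq
libraries (3 colonies x 2 treatments x 2 timepoints), a mixed host/symbiont
transcript pool, negative-binomially distributed counts (variance
mu + phi mu^2), planted differential expression at |log2FC| = 4 in heated
samples, and a stress-response-gene (SRG) compartment split into
*frontloaded* genes (basal expression above the transcriptome median,
|planted log2FC| < 0.5) and *responsive* genes (basal below the median,
planted log2FC = 4 under heat), with the remainder low-basal and stable.
Companion generators emit best-hit tables (lineage labels for host/symbiont
binning plus Symbiodiniaceae reference labels for affiliation), Pfam-style
domain annotations for SRG cataloguing, and FASTA sequences with
origin-specific GC content.

Every generator is deterministic given the config seed; a
:class:`GroundTruth` table records each planted label exactly once per gene
so downstream recovery is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core_data import (
    BLAST6_COLUMNS,
    CountMatrix,
    SampleMetadata,
    default_srg_families,
    write_hit_table,
)

SYMBIODINIACEAE = ("Smic", "Bmin", "Cgor", "Dtre", "Fkaw")

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "simulate_hits",
    "simulate_domains",
    "simulate_sequences",
    "write_bundle",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic holobiont experiment (defaults mirror the
    4-species, 12-libraries-per-species heat-stress design)."""

    seed: int = 0
    n_species: int = 4
    n_genes_host: int = 2000
    n_genes_symbiont: int = 1000
    replicates_per_cell: int = 3
    timepoints: tuple[int, ...] = (4, 24)
    dispersion: float = 0.1  # NB phi: variance = mu + phi mu^2
    mean_log2_expression: float = 5.0
    sd_log2_expression: float = 2.0
    library_size_mean: float = 1e6
    library_size_sigma: float = 0.3  # log-normal sigma so CPM != raw counts
    de_fraction: float = 0.05
    de_log2fc: float = 4.0
    de_timepoints: tuple[int, ...] = (4, 24)
    srg_fraction: float = 0.1  # of host genes
    frontloaded_fraction: float = 0.5  # of SRGs
    responsive_fraction: float = 0.3  # of SRGs
    frontloaded_max_abs_log2fc: float = 0.5
    hit_accuracy: float = 0.98
    symbiont_mixture: dict = field(
        default_factory=lambda: {
            "Cgor": 0.53, "Dtre": 0.07, "Smic": 0.15, "Bmin": 0.15, "Fkaw": 0.10
        }
    )
    host_gc: float = 0.42
    symbiont_gc: float = 0.55
    sequence_length: int = 300

    def __post_init__(self) -> None:
        for name in (
            "de_fraction",
            "srg_fraction",
            "frontloaded_fraction",
            "responsive_fraction",
            "hit_accuracy",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frontloaded_fraction + self.responsive_fraction > 1.0:
            raise ValueError("frontloaded + responsive fractions exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.replicates_per_cell < 2:
            raise ValueError("need at least 2 replicates per design cell")
        if self.n_genes_host <= 0 and self.n_genes_symbiont <= 0:
            raise ValueError("no genes to simulate")
        for name in ("host_gc", "symbiont_gc"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        total = sum(self.symbiont_mixture.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"symbiont mixture must sum to 1, got {total}")

    def species_names(self) -> list[str]:
        return [f"sp{chr(ord('A') + i)}" for i in range(self.n_species)]


def _design(cfg: SimulationConfig, species: str) -> pd.DataFrame:
    rows = []
    for colony in range(1, cfg.replicates_per_cell + 1):
        for trt in ("control", "heated"):
            for tp in cfg.timepoints:
                rows.append(
                    {
                        "sample_id": f"{species}_c{colony}_{trt}_{tp}h",
                        "species": species,
                        "colony": f"colony{colony}",
                        "treatment": trt,
                        "timepoint_h": tp,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(
    cfg: SimulationConfig, species: str | None = None, seed: int | None = None
) -> tuple[CountMatrix, SampleMetadata, pd.DataFrame]:
    """Simulate one species' count matrix, metadata, and ground truth.

    Baseline log2 mean expression is normal(mean_log2_expression,
    sd_log2_expression); planted DE genes (non-SRG host genes, half up, half
    down) shift by ``de_log2fc`` in heated cells at the configured
    timepoints.  Frontloaded SRGs draw basal log2 means well above the
    baseline median with |planted log2FC| < 0.5; responsive SRGs draw below
    the median with log2FC = ``de_log2fc``; remaining SRGs are low-basal and
    stable.  Counts are NB(mu, phi) with log-normal library sizes.
    """
    species = species or cfg.species_names()[0]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    meta_df = _design(cfg, species)
    n_host, n_sym = cfg.n_genes_host, cfg.n_genes_symbiont
    gene_ids = np.array(
        [f"{species}_h{i:05d}" for i in range(n_host)]
        + [f"{species}_s{i:05d}" for i in range(n_sym)]
    )
    origin = np.array(["host"] * n_host + ["symbiont"] * n_sym)
    n_genes = n_host + n_sym

    base_log2 = rng.normal(cfg.mean_log2_expression, cfg.sd_log2_expression, n_genes)
    median_log2 = cfg.mean_log2_expression  # median of the baseline normal
    lfc = np.zeros(n_genes)
    status = np.array(["null"] * n_genes, dtype=object)
    is_srg = np.zeros(n_genes, dtype=bool)
    srg_family = np.array([""] * n_genes, dtype=object)
    frontloaded = np.zeros(n_genes, dtype=bool)

    host_idx = np.arange(n_host)
    n_srg = round(cfg.srg_fraction * n_host)
    srg_idx = rng.choice(host_idx, size=n_srg, replace=False)
    is_srg[srg_idx] = True
    families = default_srg_families()["family"].to_numpy()
    srg_family[srg_idx] = rng.choice(families, size=n_srg)

    n_front = round(cfg.frontloaded_fraction * n_srg)
    n_resp = round(cfg.responsive_fraction * n_srg)
    shuffled = rng.permutation(srg_idx)
    front_idx = shuffled[:n_front]
    resp_idx = shuffled[n_front : n_front + n_resp]
    low_idx = shuffled[n_front + n_resp :]
    # frontloaded: clearly above the transcriptome median, flat under heat
    base_log2[front_idx] = rng.uniform(median_log2 + 1.5, median_log2 + 4.0, n_front)
    lfc[front_idx] = rng.uniform(
        -cfg.frontloaded_max_abs_log2fc * 0.8,
        cfg.frontloaded_max_abs_log2fc * 0.8,
        n_front,
    )
    frontloaded[front_idx] = True
    # responsive: below the median at baseline, strongly induced under heat
    base_log2[resp_idx] = rng.uniform(median_log2 - 3.0, median_log2 - 1.0, n_resp)
    lfc[resp_idx] = cfg.de_log2fc
    status[resp_idx] = "de_up"
    # remaining SRGs: low-basal, stable
    base_log2[low_idx] = rng.uniform(median_log2 - 3.0, median_log2 - 1.0, len(low_idx))

    non_srg_host = np.setdiff1d(host_idx, srg_idx)
    n_de = round(cfg.de_fraction * n_host)
    if n_de > len(non_srg_host):
        raise ValueError("de_fraction too large for the non-SRG host gene pool")
    de_idx = rng.choice(non_srg_host, size=n_de, replace=False)
    half = n_de // 2
    up_idx, down_idx = de_idx[: n_de - half], de_idx[n_de - half :]
    lfc[up_idx] = cfg.de_log2fc
    lfc[down_idx] = -cfg.de_log2fc
    status[up_idx] = "de_up"
    status[down_idx] = "de_down"

    lib_sizes = cfg.library_size_mean * np.exp(
        rng.normal(-cfg.library_size_sigma**2 / 2, cfg.library_size_sigma, len(meta_df))
    )
    heated = (meta_df["treatment"] == "heated").to_numpy()
    in_de_tp = meta_df["timepoint_h"].isin(cfg.de_timepoints).to_numpy()
    counts = np.empty((n_genes, len(meta_df)), dtype=np.int64)
    base_mu = 2.0**base_log2
    # scale so a library's expected total matches its drawn size (baseline
    # composition; DE shifts perturb totals, which is what TMM corrects)
    depth_unit = base_mu.sum()
    for j in range(len(meta_df)):
        mu = base_mu.copy()
        if heated[j] and in_de_tp[j]:
            mu = mu * 2.0**lfc
        mu *= lib_sizes[j] / depth_unit
        counts[:, j] = _nb_draw(rng, mu, cfg.dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=meta_df.index))
    meta = SampleMetadata(meta_df, timepoints=tuple(cfg.timepoints))
    truth = pd.DataFrame(
        {
            "origin": origin,
            "is_srg": is_srg,
            "srg_family": srg_family,
            "planted_status": status,
            "planted_log2fc": lfc,
            "planted_frontloaded": frontloaded,
            "base_log2_mean": base_log2,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return cm, meta, truth


def simulate_hits(
    truth: pd.DataFrame, cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Best-hit tables for binning and symbiont affiliation.

    Returns ``(hits, symbiont_hits)``: outfmt-6 frames with a 13th taxon
    column.  Each gene draws 1-3 nr-style hits whose best entry carries the
    lineage of its true origin with probability ``hit_accuracy`` (otherwise a
    wrong lineage, so binning recovery is imperfect by the configured
    amount).  Each symbiont gene additionally draws one best hit against a
    Symbiodiniaceae reference genome sampled from ``symbiont_mixture``.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    wrong = {"host": ["Dinophyceae", "Bacteria"], "symbiont": ["Cnidaria", "Bacteria"]}
    correct = {"host": "Cnidaria", "symbiont": "Dinophyceae"}
    rows = []
    for gene_id, rec in truth.iterrows():
        n_hits = int(rng.integers(1, 4))
        ok = rng.random() < cfg.hit_accuracy
        best_taxon = (
            correct[rec["origin"]] if ok else wrong[rec["origin"]][int(rng.integers(2))]
        )
        best_e = 10.0 ** -rng.uniform(20, 100)
        best_ident = rng.uniform(70, 99)
        taxa = [best_taxon] + [
            ["Cnidaria", "Dinophyceae", "Bacteria", "Metazoa"][int(rng.integers(4))]
            for _ in range(n_hits - 1)
        ]
        evalues = [best_e] + sorted(10.0 ** -rng.uniform(6, 19, n_hits - 1))
        for k in range(n_hits):
            ident = best_ident if k == 0 else rng.uniform(40, best_ident)
            length = int(rng.integers(80, 400))
            rows.append(
                (
                    gene_id,
                    f"ref|{taxa[k][:4].lower()}_{rng.integers(1e6):06d}",
                    round(ident, 2),
                    length,
                    int(length * (100 - ident) / 100),
                    int(rng.integers(0, 4)),
                    1,
                    length,
                    1,
                    length,
                    evalues[k],
                    round(length * ident / 50, 1),
                    taxa[k],
                )
            )
    hits = pd.DataFrame(rows, columns=BLAST6_COLUMNS + ["taxon"])

    sym = truth.index[truth["origin"] == "symbiont"]
    labels = list(cfg.symbiont_mixture)
    probs = np.array([cfg.symbiont_mixture[k] for k in labels])
    chosen = rng.choice(labels, size=len(sym), p=probs)
    srows = []
    for gene_id, label in zip(sym, chosen):
        length = int(rng.integers(80, 400))
        ident = rng.uniform(60, 99)
        srows.append(
            (
                gene_id,
                f"{label}_prot{rng.integers(1e6):06d}",
                round(ident, 2),
                length,
                int(length * (100 - ident) / 100),
                0,
                1,
                length,
                1,
                length,
                10.0 ** -rng.uniform(10, 80),
                round(length * ident / 50, 1),
                label,
            )
        )
    symbiont_hits = pd.DataFrame(srows, columns=BLAST6_COLUMNS + ["taxon"])
    return hits, symbiont_hits


def simulate_domains(
    truth: pd.DataFrame,
    families: pd.DataFrame | None = None,
    seed: int | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Pfam-style domain annotations: defining domains for SRGs, decoys otherwise."""
    families = families if families is not None else default_srg_families()
    rng = np.random.default_rng(base_seed + 2 if seed is None else seed)
    fam_acc = families.set_index("family")["accessions"].to_dict()
    rows = []
    for gene_id, rec in truth.iterrows():
        if rec["is_srg"]:
            accs = fam_acc[rec["srg_family"]]
            acc = accs[int(rng.integers(len(accs)))]
        else:
            acc = f"PF9{rng.integers(1000, 9999):04d}"  # decoy accession
        rows.append(
            {
                "gene_id": gene_id,
                "accession": acc,
                "evalue": 10.0 ** -rng.uniform(8, 30),
            }
        )
    return pd.DataFrame(rows)


def simulate_sequences(
    truth: pd.DataFrame, cfg: SimulationConfig, seed: int | None = None
) -> list[SeqRecord]:
    """Random nucleotide sequences with origin-specific expected GC content."""
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    records = []
    for gene_id, rec in truth.iterrows():
        gc = cfg.host_gc if rec["origin"] == "host" else cfg.symbiont_gc
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = "".join(rng.choice(list("ACGT"), size=cfg.sequence_length, p=p))
        records.append(SeqRecord(Seq(seq), id=str(gene_id), description=""))
    return records


def write_bundle(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Write the full fixture bundle: one directory per species plus shared
    SRG family definitions and the config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    families = default_srg_families()
    fam_out = families.assign(accessions=families["accessions"].map(",".join))
    fam_out.to_csv(outdir / "srg_families.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
    root_rng = np.random.SeedSequence(cfg.seed)
    children = root_rng.spawn(cfg.n_species)
    for species, child in zip(cfg.species_names(), children):
        sdir = outdir / species
        sdir.mkdir(exist_ok=True)
        seeds = [int(s.generate_state(1)[0] % 2**31) for s in child.spawn(4)]
        cm, meta, truth = simulate_counts(cfg, species=species, seed=seeds[0])
        hits, sym_hits = simulate_hits(truth, cfg, seed=seeds[1])
        domains = simulate_domains(truth, families, seed=seeds[2])
        seqs = simulate_sequences(truth, cfg, seed=seeds[3])
        cm.to_tsv(sdir / "counts.tsv")
        meta.to_tsv(sdir / "metadata.tsv")
        write_hit_table(hits, sdir / "hits.tsv")
        write_hit_table(sym_hits, sdir / "symbiont_hits.tsv")
        domains.to_csv(sdir / "domains.tsv", sep="\t", index=False)
        truth.to_csv(sdir / "truth.tsv", sep="\t")
        SeqIO.write(seqs, sdir / "sequences.fasta", "fasta")
    return outdir
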