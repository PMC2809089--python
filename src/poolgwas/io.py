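"""Readers, writers, run configuration and the end-to-end pipeline.

Tables are TSV throughout; gene annotation is read from BED (0-based
half-open, converted on read) or GFF3 (1-based inclusive).  Coordinates are
1-based inclusive internally.  Every written table carries a header comment
recording the config hash and seed so each number is traceable to a run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import signal as sig
from .cluster import (ConvergenceCriteria, GenomeIndex, TABLE_CRITERIA_GRID,
                      converge_then_cluster, cluster_then_converge,
                      criteria_grid_summary)
from .empirical import (mc_overlap_p, mc_cluster_p, mc_gene_convergence_p,
                        reproducible_count_permutation, true_positive_fraction)
from .signal import IntensityPanel, associate_panel, filter_snps, nominal_positive_set

logger = logging.getLogger(__name__)

__all__ = [
    "read_snp_map", "read_bim", "read_bed", "read_gff3",
    "read_pool_design", "read_panel", "write_panel",
    "write_table", "RunConfig", "run_pipeline", "qq_data",
]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_snp_map(path) -> pd.DataFrame:
    """3-column TSV (snp_id, chrom, pos), 1-based; header optional."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns[:3]) != ["snp_id", "chrom", "pos"]:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                         names=["snp_id", "chrom", "pos"])
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    return df[["snp_id", "chrom", "pos"]]


def read_bim(path) -> pd.DataFrame:
    """PLINK .bim-like 6-column file (chrom, snp_id, cM, pos, a1, a2)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                     names=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    return df[["snp_id", "chrom", "pos"]]


def read_bed(path) -> pd.DataFrame:
    """BED gene intervals; 0-based half-open converted to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 4:
        raise ValueError("BED annotation needs chrom, start, end, name columns")
    out = pd.DataFrame({
        "gene_id": df.iloc[:, 3],
        "chrom": df.iloc[:, 0],
        "start": df.iloc[:, 1].astype(np.int64) + 1,
        "end": df.iloc[:, 2].astype(np.int64),
    })
    return out[["gene_id", "chrom", "start", "end"]]


def write_bed(annotation: pd.DataFrame, path) -> None:
    bed = pd.DataFrame({
        "chrom": annotation["chrom"],
        "start": annotation["start"].astype(np.int64) - 1,
        "end": annotation["end"].astype(np.int64),
        "name": annotation["gene_id"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path, feature: str = "gene", id_attr: str = "ID") -> pd.DataFrame:
    """Feature intervals from GFF3 (1-based inclusive).

    ``gene_id`` comes from the ``id_attr`` attribute — ``ID`` for genes,
    typically ``Parent`` when reading exon features.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise ValueError(f"{path}: malformed GFF3 line {ln}")
        if parts[2] != feature:
            continue
        attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
        rows.append({"gene_id": attrs.get(id_attr, f"{feature}{ln}"),
                     "chrom": parts[0], "start": int(parts[3]), "end": int(parts[4])})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def read_pool_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"pool_id", "sample", "phenotype", "n_individuals"}
    if not need <= set(df.columns):
        raise ValueError(f"pool design must have columns {sorted(need)}")
    return df


def read_panel(panel_path, design_path) -> IntensityPanel:
    """Long-format panel TSV (pool_id, replicate, snp_id, arctan_ab) or
    (pool_id, replicate, snp_id, a_intensity, b_intensity)."""
    design = read_pool_design(design_path)
    long = pd.read_csv(panel_path, sep="\t", comment="#")
    if "arctan_ab" not in long.columns:
        if {"a_intensity", "b_intensity"} <= set(long.columns):
            long["arctan_ab"] = sig.arctan_allele_measure(
                long["a_intensity"].to_numpy(), long["b_intensity"].to_numpy())
        else:
            raise ValueError("panel needs arctan_ab or a_intensity/b_intensity")
    pools = design["pool_id"].to_list()
    reps = sorted(long["replicate"].unique())
    snps = long.loc[(long["pool_id"] == pools[0])
                    & (long["replicate"] == reps[0]), "snp_id"].to_list()
    wide = long.set_index(["pool_id", "replicate", "snp_id"])["arctan_ab"]
    values = np.full((len(pools), len(reps), len(snps)), np.nan)
    snp_pos = {s: j for j, s in enumerate(snps)}
    rep_pos = {r: j for j, r in enumerate(reps)}
    pool_pos = {p: j for j, p in enumerate(pools)}
    idx = wide.index
    values[
        [pool_pos[p] for p in idx.get_level_values(0)],
        [rep_pos[r] for r in idx.get_level_values(1)],
        [snp_pos[s] for s in idx.get_level_values(2)],
    ] = wide.to_numpy()
    return IntensityPanel(design, np.array(snps), values)


def write_panel(panel: IntensityPanel, panel_path, design_path) -> None:
    panel.design.to_csv(design_path, sep="\t", index=False)
    panel.to_long().to_csv(panel_path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, *, config_hash: str = "", seed=None) -> None:
    """TSV with a traceability header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML losslessly."""

    alpha: float = 0.05
    flank: int = 10_000
    criteria_grid: list = field(default_factory=lambda: [
        [c.min_cluster_size, c.max_gap] for c in TABLE_CRITERIA_GRID])
    primary_criteria_1: list = field(default_factory=lambda: [3, 25_000])
    primary_criteria_2: list = field(default_factory=lambda: [4, 10_000])
    gene_support_rule: str = "count"        # or "any"
    mc2_size_convention: str = "raw"        # or "clustered"
    exon_only: bool = False                 # gene support from exons+flanks only
    exons: str | None = None                # GFF3 exon table for exon_only
    mc_overlap_trials: int = 100_000
    mc_cluster_trials: int = 2_000
    mc_gene_convergence_trials: int = 200
    permutation_trials: int = 10_000
    seed: int = 1
    snp_map: str | None = None
    annotation: str | None = None
    panel_a: str | None = None
    design_a: str | None = None
    panel_b: str | None = None
    design_b: str | None = None

    def criteria(self, pair) -> ConvergenceCriteria:
        return ConvergenceCriteria(pair[0], pair[1], self.alpha)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    assoc_a: pd.DataFrame
    assoc_b: pd.DataFrame
    summary: pd.DataFrame
    gene_table_1: pd.DataFrame
    gene_table_2: pd.DataFrame
    significance: pd.DataFrame
    config: RunConfig


def run_pipeline(config: RunConfig, *, snp_map=None, annotation=None,
                 panel_a=None, panel_b=None, out_dir=None) -> PipelineResult:
    """Associations per sample -> positive sets -> both convergence analyses
    over the criteria grid -> Monte Carlo / permutation significance.

    In-memory inputs take precedence over the file paths in ``config``.
    Deterministic given config + seed; when ``out_dir`` is set, writes the
    summary, gene and significance tables there as traceable TSVs.
    """
    if snp_map is None:
        snp_map = read_snp_map(config.snp_map)
    if annotation is None:
        annotation = read_bed(config.annotation) if str(
            config.annotation).endswith(".bed") else read_gff3(config.annotation)
    if panel_a is None:
        panel_a = read_panel(config.panel_a, config.design_a)
    if panel_b is None:
        panel_b = read_panel(config.panel_b, config.design_b)
    if set(panel_a.snp_ids) != set(panel_b.snp_ids):
        raise ValueError("SNP universe mismatch between the two samples")

    snp_map = filter_snps(snp_map)
    keep = set(snp_map["snp_id"])
    exons = None
    if config.exon_only:
        exons = read_gff3(config.exons, feature="exon", id_attr="Parent")
    index = GenomeIndex(snp_map, annotation, flank=config.flank,
                        exons=exons, exon_only=config.exon_only)

    assoc_a = associate_panel(panel_a)
    assoc_b = associate_panel(panel_b)
    assoc_a = assoc_a[assoc_a["snp_id"].isin(keep)].reset_index(drop=True)
    assoc_b = assoc_b[assoc_b["snp_id"].isin(keep)].reset_index(drop=True)
    pos_a = nominal_positive_set(assoc_a, config.alpha)
    pos_b = nominal_positive_set(assoc_b, config.alpha)
    logger.info("nominal positives: %d (A), %d (B) of %d SNPs",
                len(pos_a), len(pos_b), len(snp_map))

    grid = [config.criteria(c) for c in config.criteria_grid]
    summary = criteria_grid_summary(assoc_a, assoc_b, index, grid,
                                    rule=config.gene_support_rule)

    c1 = config.criteria(config.primary_criteria_1)
    c2 = config.criteria(config.primary_criteria_2)
    r1 = converge_then_cluster(assoc_a, assoc_b, index, c1,
                               rule=config.gene_support_rule)
    r2 = cluster_then_converge(assoc_a, assoc_b, index, c2,
                               rule=config.gene_support_rule)
    logger.info("approach 1: %d reproducible SNPs, %d clusters, %d genes",
                len(r1.reproducible_snps), len(r1.clusters), len(r1.gene_hits))
    logger.info("approach 2: %d convergent genes", len(r2.gene_hits))

    sig_rows = []
    seed = config.seed
    n_univ = len(snp_map)
    ov = mc_overlap_p(n_univ, len(pos_a), len(pos_b), len(r1.reproducible_snps),
                      config.mc_overlap_trials, seed)
    sig_rows.append(("mc_overlap_reproducible_snps", ov))
    mc1 = mc_cluster_p(index, len(r1.reproducible_snps), c1,
                       len(r1.clustered_snps), config.mc_cluster_trials, seed + 1)
    sig_rows.append(("mc1_clustered_snps", mc1))
    if config.mc2_size_convention == "clustered":
        na, nb = len(r2.clustered_snps_a), len(r2.clustered_snps_b)
    else:
        na, nb = len(pos_a), len(pos_b)
    mc2 = mc_gene_convergence_p(index, na, nb, c2, len(r2.gene_hits),
                                config.mc_gene_convergence_trials, seed + 2,
                                rule=config.gene_support_rule)
    sig_rows.append(("mc2_convergent_genes", mc2))
    perm = reproducible_count_permutation(panel_a, panel_b,
                                          config.permutation_trials, seed + 3,
                                          config.alpha)
    sig_rows.append(("permutation_reproducible_snps", perm))

    sig_df = pd.DataFrame([
        {"test": name, "observed": e.observed_stat, "n_trials": e.n_trials,
         "n_exceed": e.n_exceed, "p": e.p, "null_mean": e.null.mean,
         "null_sd": e.null.sd, "seed": e.seed, "method": e.method}
        for name, e in sig_rows])
    if len(r2.gene_hits):
        tgf = true_positive_fraction(len(r2.gene_hits), mc2.null)
        sig_df.loc[len(sig_df)] = {
            "test": "true_gene_fraction_approach2", "observed": tgf,
            "n_trials": mc2.n_trials, "n_exceed": np.nan, "p": np.nan,
            "null_mean": mc2.null.mean, "null_sd": mc2.null.sd,
            "seed": mc2.seed, "method": "derived"}

    g1 = r1.gene_hits.drop(columns=["clusters"], errors="ignore")
    g2 = r2.gene_hits
    result = PipelineResult(assoc_a, assoc_b, summary, g1, g2, sig_df, config)
    if out_dir is not None:
        out = Path(out_dir)
        h = config.hash()
        write_table(summary.drop(columns=["genes"]), out / "criteria_summary.tsv",
                    config_hash=h, seed=seed)
        write_table(_stringify(g1), out / "genes_approach1.tsv", config_hash=h, seed=seed)
        write_table(_stringify(g2), out / "genes_approach2.tsv", config_hash=h, seed=seed)
        write_table(sig_df, out / "significance.tsv", config_hash=h, seed=seed)
    return result


def _stringify(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, (list, set))).any():
            out[col] = out[col].map(lambda v: ",".join(map(str, sorted(v))))
    return out


# ---------------------------------------------------------------------------
# QQ report data
# ---------------------------------------------------------------------------


def qq_data(assoc: pd.DataFrame, n_null_draws: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Observed t values paired with null t quantiles of matching group sizes.

    The null is simulated: ``n_null_draws`` Welch t statistics from standard
    normal groups sized like the observed comparison; expected quantiles are
    read off the null sample at the observed ranks' plotting positions.
    Output has one row per tested SNP.
    """
    tested = assoc[assoc["tested"]] if "tested" in assoc else assoc.dropna(subset=["t_value"])
    t_obs = np.sort(tested["t_value"].to_numpy())
    if t_obs.size < 2:
        raise ValueError("need at least two associations for a QQ table")
    if np.ptp(t_obs) == 0:
        logger.warning("qq_data: constant t values; degenerate QQ table")
    n1 = int(tested["n_case_pools"].iloc[0])
    n2 = int(tested["n_control_pools"].iloc[0])
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_null_draws, n1))
    y = rng.standard_normal((n_null_draws, n2))
    from .signal import welch_t
    t_null, _, _, _ = welch_t(x.T, y.T)
    probs = (np.arange(1, t_obs.size + 1) - 0.5) / t_obs.size
    expected = np.quantile(t_null, probs)
    return pd.DataFrame({"expected_t": expected, "observed_t": t_obs})
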