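"""Per-SNP allele-frequency proxies and case/control association from pooled arrays.

Pooled genotyping estimates allele frequencies by hybridizing DNA pooled from
~20 individuals to a genotyping array.  The per-SNP allele-frequency proxy is
the arctangent of the ratio of A-allele to B-allele hybridization intensities,
a bounded, monotone transform of the allele ratio.  Each pool is assayed on
several replicate arrays; the replicate arctan values are averaged to one
value per pool, and the pool means are the experimental units of a Welch
two-sample t test between case and control pools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

logger = logging.getLogger(__name__)

HALF_PI = np.pi / 2.0

#: chromosome labels treated as non-autosomal or unplaced and removed by filter_snps
NON_AUTOSOMAL = {"x", "y", "xy", "mt", "m", "un", "0", "na", "none", ""}

DEFAULT_ALPHA = 0.05

__all__ = [
    "arctan_allele_measure",
    "summarize_snp_array",
    "filter_snps",
    "welch_t",
    "snp_t_test",
    "associate_panel",
    "nominal_positive_set",
    "qc_report",
    "IntensityPanel",
    "SnpAssociation",
    "QcReport",
]


def arctan_allele_measure(a_intensity, b_intensity):
    """arctan(A/B) allele-frequency proxy, in radians within [0, pi/2].

    Accepts scalars or arrays of nonnegative hybridization intensities.
    ``A=0 -> 0`` and ``B=0 -> pi/2`` (fixed-allele boundaries); both zero is
    an undefined measure and raises ``ValueError``.
    """
    a = np.asarray(a_intensity, dtype=float)
    b = np.asarray(b_intensity, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("hybridization intensities must be nonnegative")
    if np.any((a == 0) & (b == 0)):
        raise ValueError("arctan(A/B) undefined when both intensities are zero")
    out = np.arctan2(a, b)
    return float(out) if out.ndim == 0 else out


def summarize_snp_array(probe_a, probe_b):
    """One arctan(A/B) value for a SNP on one array from its perfect-match probes.

    The 3-4 perfect-match probe intensities per allele are averaged first and
    the arctangent taken of the ratio of means (mean-then-arctan, not
    arctan-then-mean).
    """
    probe_a = np.asarray(probe_a, dtype=float)
    probe_b = np.asarray(probe_b, dtype=float)
    if probe_a.size == 0 or probe_b.size == 0:
        raise ValueError("need at least one perfect-match probe per allele")
    return arctan_allele_measure(probe_a.mean(), probe_b.mean())


def _is_autosome(chrom) -> bool:
    label = str(chrom).lower().removeprefix("chr")
    if label in NON_AUTOSOMAL:
        return False
    try:
        return int(label) > 0
    except ValueError:
        return False


def filter_snps(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Drop sex-chromosome, mitochondrial and position-less SNPs.

    Sex-chromosome SNPs are removed so male and female subjects can be pooled
    together; SNPs whose chromosomal position is undetermined cannot enter
    distance-based clustering.  Row order is preserved; idempotent.
    """
    keep = snp_map["chrom"].map(_is_autosome) & snp_map["pos"].notna()
    keep &= pd.to_numeric(snp_map["pos"], errors="coerce").fillna(0) > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_snps: removed %d non-autosomal/unmapped SNPs", dropped)
    out = snp_map.loc[keep].copy()
    out["pos"] = out["pos"].astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# pooled intensity panel
# ---------------------------------------------------------------------------


@dataclass
class IntensityPanel:
    """Replicate pooled-array measurements for one sample (population).

    Parameters
    ----------
    design
        One row per pool with columns ``pool_id``, ``sample``, ``phenotype``
        (``case``/``control``) and ``n_individuals``; row order matches the
        first axis of ``values``.
    snp_ids
        SNP identifiers along the last axis of ``values``.
    values
        Array of shape ``(n_pools, n_replicates, n_snps)`` holding arctan(A/B)
        in radians; NaN marks a missing (pool, replicate, SNP) measurement.
    """

    design: pd.DataFrame
    snp_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_pools, n_replicates, n_snps)")
        if self.values.shape[0] != len(self.design):
            raise ValueError("design rows and values pools disagree")
        if self.values.shape[2] != len(self.snp_ids):
            raise ValueError("snp_ids and values SNP axis disagree")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > HALF_PI + 1e-9):
            raise ValueError("arctan values must lie in [0, pi/2]")

    @property
    def n_pools(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def n_snps(self) -> int:
        return self.values.shape[2]

    def pool_means(self) -> np.ndarray:
        """Per-pool mean over replicate arrays, shape (n_pools, n_snps)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            return np.nanmean(self.values, axis=1)

    def case_mask(self) -> np.ndarray:
        return (self.design["phenotype"] == "case").to_numpy()

    def to_long(self) -> pd.DataFrame:
        """Long-format table (pool_id, replicate, snp_id, arctan_ab)."""
        n_pools, n_reps, n_snps = self.values.shape
        pool_ids = np.repeat(self.design["pool_id"].to_numpy(), n_reps * n_snps)
        reps = np.tile(np.repeat(np.arange(1, n_reps + 1), n_snps), n_pools)
        snps = np.tile(self.snp_ids, n_pools * n_reps)
        return pd.DataFrame(
            {
                "pool_id": pool_ids,
                "replicate": reps,
                "snp_id": snps,
                "arctan_ab": self.values.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# Welch t test on pool means
# ---------------------------------------------------------------------------

#: nominal p reported for zero-variance groups with unequal means
DEGENERATE_P = np.nextafter(0.0, 1.0)


def welch_t(case: np.ndarray, control: np.ndarray):
    """Vectorized Welch two-sample t over the columns of two matrices.

    ``case`` is ``(n1, m)`` and ``control`` ``(n2, m)``; returns
    ``(t, p, df, degenerate)`` arrays of length ``m``.  Zero variance in both
    groups yields ``t=0, p=1`` at equal means, or ``p`` = smallest positive
    float (flagged degenerate) at unequal means.
    """
    case = np.atleast_2d(np.asarray(case, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n2 = case.shape[0], control.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two pools per group")
    m1 = case.mean(axis=0)
    m2 = control.mean(axis=0)
    v1 = case.var(axis=0, ddof=1)
    v2 = control.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * special.stdtr(df, -np.abs(t))
    zero_eq = degenerate & (diff == 0)
    zero_ne = degenerate & (diff != 0)
    t[zero_eq], p[zero_eq] = 0.0, 1.0
    t[zero_ne] = np.where(diff[zero_ne] > 0, np.inf, -np.inf)
    p[zero_ne] = DEGENERATE_P
    df[degenerate] = np.nan
    return t, p, df, zero_ne


@dataclass
class SnpAssociation:
    """Case-vs-control Welch t result for one SNP (pool means as units)."""

    snp_id: str
    t_value: float
    p_value: float
    direction: int
    n_case_pools: int
    n_control_pools: int
    degenerate: bool = False


def snp_t_test(case_values, control_values, snp_id: str = "") -> SnpAssociation:
    """Welch t test of one SNP's per-pool mean arctan values, two-sided."""
    case = np.asarray(case_values, dtype=float)[:, None]
    control = np.asarray(control_values, dtype=float)[:, None]
    t, p, _, deg = welch_t(case, control)
    diff = case.mean() - control.mean()
    return SnpAssociation(
        snp_id=snp_id,
        t_value=float(t[0]),
        p_value=float(p[0]),
        direction=int(np.sign(diff)),
        n_case_pools=case.shape[0],
        n_control_pools=control.shape[0],
        degenerate=bool(deg[0]),
    )


def associate_panel(panel: IntensityPanel) -> pd.DataFrame:
    """Per-SNP case-vs-control association table for one sample's panel.

    Collapses replicates to pool means, then applies the Welch t test with
    pools as the experimental units.  A SNP missing in any pool is dropped
    from the test (NaN row) and counted in the log.  The abuser/control ratio
    of mean arctan values is carried as a descriptive column only.
    """
    means = panel.pool_means()
    case = means[panel.case_mask()]
    control = means[~panel.case_mask()]
    complete = ~np.isnan(means).any(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("associate_panel: %d SNPs missing in >=1 pool, dropped", n_dropped)
    t = np.full(panel.n_snps, np.nan)
    p = np.full(panel.n_snps, np.nan)
    deg = np.zeros(panel.n_snps, dtype=bool)
    t[complete], p[complete], _, deg[complete] = welch_t(
        case[:, complete], control[:, complete]
    )
    mean_case = case.mean(axis=0)
    mean_control = control.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mean_case / mean_control
    return pd.DataFrame(
        {
            "snp_id": panel.snp_ids,
            "t_value": t,
            "p_value": p,
            "direction": np.sign(np.nan_to_num(mean_case - mean_control)).astype(int),
            "mean_case": mean_case,
            "mean_control": mean_control,
            "case_control_ratio": ratio,
            "n_case_pools": case.shape[0],
            "n_control_pools": control.shape[0],
            "degenerate": deg,
            "tested": complete,
        }
    )


def nominal_positive_set(assoc: pd.DataFrame | list, alpha: float = DEFAULT_ALPHA) -> set:
    """SNP ids with strictly p < alpha (no multiple-testing correction)."""
    if isinstance(assoc, pd.DataFrame):
        hit = assoc["p_value"] < alpha
        return set(assoc.loc[hit.fillna(False), "snp_id"])
    return {a.snp_id for a in assoc if a.p_value < alpha}


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    """Variance summaries of a pooled panel.

    ``replicate_sem`` is per pool: sqrt(mean over SNPs of the within-pool
    replicate variance) / sqrt(n_replicates) — the RMS standard error of the
    pool's replicate mean.  ``pool_sem`` is per (sample, phenotype) group:
    the analogous RMS standard error across that group's pool means.
    ``array_extremes`` summarizes the top and bottom 5% of each array's
    values; ``flagged_arrays`` lists (pool_id, replicate) whose mean offset
    from the pool's other replicates exceeds the flag threshold.
    """

    replicate_sem: pd.Series
    pool_sem: pd.Series
    array_extremes: pd.DataFrame
    flagged_arrays: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "replicate_sem", "unit": str(k), "value": v}
            for k, v in self.replicate_sem.items()
        ]
        rows += [
            {"metric": "pool_sem", "unit": str(k), "value": v}
            for k, v in self.pool_sem.items()
        ]
        return pd.DataFrame(rows)


#: an array is flagged when its mean offset from the pool's other replicates
#: exceeds this multiple of the panel's RMS replicate SD
ARRAY_FLAG_SIGMA = 3.0


def qc_report(panel: IntensityPanel) -> QcReport:
    """Replicate and pool-to-pool variance summaries with array flagging."""
    values = panel.values
    if panel.n_replicates < 2:
        raise ValueError("replicate SEM undefined with a single replicate array")
    rep_var = np.nanvar(values, axis=1, ddof=1)  # (n_pools, n_snps)
    replicate_sem = pd.Series(
        np.sqrt(np.nanmean(rep_var, axis=1) / panel.n_replicates),
        index=panel.design["pool_id"],
        name="replicate_sem",
    )
    means = panel.pool_means()
    groups = {}
    for (sample, phenotype), idx in panel.design.groupby(
        ["sample", "phenotype"], sort=False
    ).groups.items():
        rows = panel.design.index.get_indexer(idx)
        if len(rows) < 2:
            continue
        gvar = np.nanvar(means[rows], axis=0, ddof=1)
        groups[f"{sample}:{phenotype}"] = float(
            np.sqrt(np.nanmean(gvar) / len(rows))
        )
    pool_sem = pd.Series(groups, name="pool_sem", dtype=float)

    sigma_rep = float(np.sqrt(np.nanmean(rep_var)))
    extremes, flagged = [], []
    n_reps = panel.n_replicates
    for i, pool_id in enumerate(panel.design["pool_id"]):
        for r in range(n_reps):
            arr = values[i, r]
            finite = arr[np.isfinite(arr)]
            if finite.size == 0:
                continue
            q = np.quantile(finite, [0.05, 0.95])
            others = np.delete(values[i], r, axis=0)
            offset = float(np.nanmean(arr - np.nanmean(others, axis=0)))
            extremes.append(
                {
                    "pool_id": pool_id,
                    "replicate": r + 1,
                    "bottom5_mean": float(finite[finite <= q[0]].mean()),
                    "top5_mean": float(finite[finite >= q[1]].mean()),
                    "mean_offset": offset,
                }
            )
            if sigma_rep > 0 and abs(offset) > ARRAY_FLAG_SIGMA * sigma_rep:
                flagged.append((pool_id, r + 1))
                logger.warning(
                    "qc_report: array (pool %s, replicate %d) offset %.4f "
                    "exceeds %.1f x replicate SD",
                    pool_id,
                    r + 1,
                    offset,
                    ARRAY_FLAG_SIGMA,
                )
    return QcReport(replicate_sem, pool_sem, pd.DataFrame(extremes), flagged)
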