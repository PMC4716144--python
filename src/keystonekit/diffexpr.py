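"""Z-score / z-ratio differential expression with FDR control and an ANOVA gate.

The chain mirrors spreadsheet-era microarray practice: per-array z-scoring of
log intensities, a z-ratio statistic (between-group difference of mean
z-scores standardised by the dispersion of those differences across all
genes), Benjamini-Hochberg FDR, and a one-way ANOVA filter across all
condition groups.  A transcript is called differential when
|z-ratio| >= 1.50 (inclusive), FDR q < 0.05 and ANOVA p < 0.05 (both strict),
matching the asymmetric threshold notation of the source workflow.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

Z_CUT_DEFAULT = 1.50
Q_CUT_DEFAULT = 0.05
P_CUT_DEFAULT = 0.05


@dataclass
class ZScoreMatrix:
    """Per-sample standardised log-intensities (mean 0, sd 1 over genes)."""

    gene_ids: list[str]
    sample_ids: list[str]
    zscores: np.ndarray
    groups: dict[str, str]
    log_base: float = 10.0

    def samples_in_group(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids) if self.groups[s] == group]


@dataclass
class DifferentialRecord:
    gene_id: str
    z_ratio: float
    anova_p: float
    fdr_q: float
    significant: bool


def _log_intensities(matrix: ExpressionMatrix, log_base: float) -> np.ndarray:
    """Log-transform after floor-clipping non-positive cells to the smallest
    positive value in the matrix (count of clipped cells is logged)."""
    values = matrix.values
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive intensities")
    floor = positive.min()
    clipped = int(np.count_nonzero(values <= 0))
    if clipped:
        logger.info("floor-clipped %d non-positive cells to %g", clipped, floor)
    values = np.where(values > 0, values, floor)
    return np.log(values) / np.log(log_base)


def filter_low_intensity(
    matrix: ExpressionMatrix, floor: float
) -> ExpressionMatrix:
    """Optional pre-filter: drop genes whose mean raw intensity is below
    ``floor`` (off by default in the calling chain)."""
    keep = matrix.values.mean(axis=1) >= floor
    if not keep.any():
        raise ValueError(f"no gene passes the intensity floor {floor}")
    dropped = int(np.count_nonzero(~keep))
    if dropped:
        logger.info("intensity floor %g dropped %d genes", floor, dropped)
    return ExpressionMatrix(
        [g for g, k in zip(matrix.gene_ids, keep) if k],
        list(matrix.sample_ids),
        matrix.values[keep],
        dict(matrix.groups),
    )


def zscore_normalize(matrix: ExpressionMatrix, log_base: float = 10.0) -> ZScoreMatrix:
    """Standardise log-intensities within each sample across genes.

    Uses the population (n) standard deviation, so every sample column has
    mean exactly 0 and sd exactly 1 over genes.
    """
    logged = _log_intensities(matrix, log_base)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        bad = matrix.sample_ids[int(zero_var[0])]
        raise ValueError(f"sample {bad!r} has zero variance across genes")
    z = (logged - mean) / sd
    return ZScoreMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), z, dict(matrix.groups), log_base
    )


def z_ratio(z: ZScoreMatrix, group_a: str, group_b: str) -> dict[str, float]:
    """Per-gene z-ratio for group_a vs group_b (positive = higher in group_a).

    d_g = mean z in group_a - mean z in group_b; the z-ratio is d_g divided by
    the sample (n-1) standard deviation of {d_g} over all genes.
    """
    idx_a = z.samples_in_group(group_a)
    idx_b = z.samples_in_group(group_b)
    for label, idx in ((group_a, idx_a), (group_b, idx_b)):
        if not idx:
            raise ValueError(f"group {label!r} has no samples")
        if len(idx) < 2:
            warnings.warn(
                f"group {label!r} has a single sample; z-ratio dispersion "
                "may be unstable",
                stacklevel=2,
            )
    d = z.zscores[:, idx_a].mean(axis=1) - z.zscores[:, idx_b].mean(axis=1)
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("no dispersion: sd of z-score differences is zero")
    return dict(zip(z.gene_ids, (d / sd).tolist()))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q.tolist()


def z_ratio_pvalues(z_ratios: Mapping[str, float]) -> dict[str, float]:
    """Two-sided normal-tail p-value per gene, treating the z-ratio as
    approximately standard normal under the null (the convention of the
    spreadsheet z-ratio workflow this chain mirrors)."""
    genes = list(z_ratios)
    z = np.abs(np.array([z_ratios[g] for g in genes], dtype=float))
    return dict(zip(genes, (2.0 * stats.norm.sf(z)).tolist()))


def anova_gate(
    matrix: ExpressionMatrix,
    groups: Sequence[str] | None = None,
    log_base: float = 10.0,
) -> dict[str, float]:
    """One-way fixed-effects ANOVA p-value per gene across all condition
    groups, on log-intensities.

    Genes whose within-group variance is zero in every group get p = 0 and
    are counted in the log as degenerate (the group means differ with zero
    residual noise; if the means are also all equal the gene gets p = 1).
    """
    labels = list(groups) if groups is not None else matrix.group_labels()
    if len(labels) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    logged = _log_intensities(matrix, log_base)
    blocks = []
    for g in labels:
        idx = [i for i, s in enumerate(matrix.sample_ids) if matrix.groups[s] == g]
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        blocks.append(logged[:, idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warnings handled below
        _, pvals = stats.f_oneway(*blocks, axis=1)
    pvals = np.asarray(pvals, dtype=float)

    within_var = np.stack([b.var(axis=1) for b in blocks])  # (n_groups, n_genes)
    group_means = np.stack([b.mean(axis=1) for b in blocks])
    degenerate = np.all(within_var == 0, axis=0)
    n_degen = int(np.count_nonzero(degenerate))
    if n_degen:
        logger.info("%d genes with zero within-group variance in all groups", n_degen)
        means_equal = np.all(group_means == group_means[0], axis=0)
        pvals = np.where(degenerate & means_equal, 1.0, pvals)
        pvals = np.where(degenerate & ~means_equal, 0.0, pvals)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    return dict(zip(matrix.gene_ids, pvals.tolist()))


def call_differential(
    z_ratios: Mapping[str, float],
    q_values: Mapping[str, float],
    anova_p: Mapping[str, float],
    z_cut: float = Z_CUT_DEFAULT,
    q_cut: float = Q_CUT_DEFAULT,
    p_cut: float = P_CUT_DEFAULT,
) -> list[DifferentialRecord]:
    """Combine the three gates; |z-ratio| cut is inclusive, q and p strict.

    Output is sorted by |z-ratio| descending.
    """
    for name, mapping in (("q_values", q_values), ("anova_p", anova_p)):
        missing = set(z_ratios) - set(mapping)
        if missing:
            raise ValueError(f"gene {sorted(missing)[0]!r} missing from {name}")
    records = [
        DifferentialRecord(
            gene_id=g,
            z_ratio=float(z_ratios[g]),
            anova_p=float(anova_p[g]),
            fdr_q=float(q_values[g]),
            significant=(
                abs(z_ratios[g]) >= z_cut
                and q_values[g] < q_cut
                and anova_p[g] < p_cut
            ),
        )
        for g in z_ratios
    ]
    records.sort(key=lambda r: -abs(r.z_ratio))
    return records


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    z_cut: float = Z_CUT_DEFAULT,
    q_cut: float = Q_CUT_DEFAULT,
    p_cut: float = P_CUT_DEFAULT,
    log_base: float = 10.0,
    intensity_floor: float | None = None,
) -> list[DifferentialRecord]:
    """Convenience wrapper running the full sequential chain for one
    two-group contrast.  ``intensity_floor`` optionally removes
    low-intensity probes before normalisation (off by default).

    The gates are applied the way the source workflow describes them:
    (1) the |z-ratio| >= z_cut filter selects candidate genes; (2) the FDR
    refines *those candidates* — BH q-values over the candidates'
    normal-tail z-ratio p-values (genes outside the filter get q = 1);
    (3) the one-way ANOVA across all condition groups gates at p < p_cut.
    """
    if intensity_floor is not None:
        matrix = filter_low_intensity(matrix, intensity_floor)
    z = zscore_normalize(matrix, log_base=log_base)
    ratios = z_ratio(z, group_a, group_b)
    zp = z_ratio_pvalues(ratios)
    passed = [g for g in ratios if abs(ratios[g]) >= z_cut]
    qvals = {g: 1.0 for g in ratios}
    if passed:
        qvals.update(zip(passed, bh_fdr([zp[g] for g in passed])))
    pvals = anova_gate(matrix, log_base=log_base)
    return call_differential(ratios, qvals, pvals, z_cut=z_cut, q_cut=q_cut, p_cut=p_cut)
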