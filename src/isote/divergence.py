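"""Bootstrap testing of TE divergence between alternative TSS isoform pairs.

For each pair of isoforms of one gene the plug-in statistic is the log2 fold
change of TE, ``log2(TE_A / TE_B)``.  Since both isoforms share the gene's
ORF, the ORF length cancels and the statistic equals the log2 ratio of their
ribosomes-per-mRNA values.  Uncertainty from finite tag counts is assessed by
resampling each fraction's tags at the original sequencing depth: a
multinomial draw over {cluster A, cluster B, all other tags} per fraction is
exactly equivalent to read-level resampling as far as the two cluster counts
are concerned.  The B bootstrap values of the statistic are summarized into a
mean and standard deviation; significance comes from the Z score of the mean
against zero, with Benjamini-Hochberg adjustment across pairs, a fold-change
threshold applied in both replicates, and an empirical false discovery rate
from label permutation between replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .quant import N_FRACTIONS, RIBOSOME_WEIGHTS


@dataclass
class BootstrapSummary:
    mean: float     # mean of bootstrap log2 fold changes
    sd: float       # standard deviation of bootstrap log2 fold changes
    n_used: int     # draws contributing to the summary
    n_dropped: int  # draws dropped because a resampled total (or load) was zero


def bootstrap_pair(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    fraction_totals: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    norm_multipliers: np.ndarray | None = None,
) -> BootstrapSummary:
    """Bootstrap the log2 TE fold change between two isoform clusters.

    Parameters
    ----------
    counts_a, counts_b
        Raw (pre-normalization) tag counts per fraction, length 7.
    fraction_totals
        Total tag depth of each fraction (>= counts_a + counts_b); the
        resampling is done at this original depth.
    n_boot
        Number of bootstrap replicates (B).
    rng
        numpy Generator or seed; fixing it fixes the summary exactly.
    norm_multipliers
        Optional per-fraction spike normalization multipliers re-applied to
        the resampled counts inside every draw.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    totals = np.asarray(fraction_totals, dtype=float)
    if a.shape != (N_FRACTIONS,) or b.shape != (N_FRACTIONS,) or totals.shape != (N_FRACTIONS,):
        raise ValueError("counts and totals must be 7-vectors")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both isoforms need a nonzero total count")
    if np.any(totals < a + b):
        raise ValueError("fraction totals smaller than the cluster counts")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    res_a = np.zeros((n_boot, N_FRACTIONS))
    res_b = np.zeros((n_boot, N_FRACTIONS))
    for j in range(N_FRACTIONS):
        n_j = int(round(totals[j]))
        if n_j == 0:
            continue
        p = np.array([a[j], b[j], totals[j] - a[j] - b[j]]) / totals[j]
        draws = rng.multinomial(n_j, p, size=n_boot)
        res_a[:, j] = draws[:, 0]
        res_b[:, j] = draws[:, 1]
    if norm_multipliers is not None:
        mult = np.asarray(norm_multipliers, dtype=float)
        res_a = res_a * mult
        res_b = res_b * mult

    t_a = res_a.sum(axis=1)
    t_b = res_b.sum(axis=1)
    r_a = res_a @ RIBOSOME_WEIGHTS
    r_b = res_b @ RIBOSOME_WEIGHTS
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((r_a / t_a) / (r_b / t_b))
    ok = np.isfinite(lfc)
    n_used = int(ok.sum())
    if n_used < 2:
        raise ValueError("fewer than 2 informative bootstrap draws")
    vals = lfc[ok]
    return BootstrapSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n_used=n_used,
        n_dropped=n_boot - n_used,
    )


def z_pvalue(boot_mean: float, boot_sd: float) -> float:
    """Two-sided normal p-value for the bootstrap mean deviating from zero.

    ``p = 2 * (1 - Phi(|mean / sd|))``; with ``sd == 0`` the p-value is 0 for
    a nonzero mean and 1 otherwise.
    """
    if boot_sd < 0:
        raise ValueError("negative standard deviation")
    if boot_sd == 0:
        return 0.0 if boot_mean != 0 else 1.0
    return float(2.0 * norm.sf(abs(boot_mean / boot_sd)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(
    pairs: pd.DataFrame,
    p_thresh: float = 0.01,
    fc_thresh: float = 1.5,
) -> pd.DataFrame:
    """Flag pairs with significant TE divergence.

    ``pairs`` must have per-replicate columns ``lfc_rep1``, ``lfc_rep2``
    (plug-in log2 fold changes, oriented distal/longer over proximal/shorter)
    and ``adj_p_rep1``, ``adj_p_rep2``.  A pair is significant iff the
    adjusted p-value is below ``p_thresh`` and |log2FC| exceeds
    ``log2(fc_thresh)`` in *both* replicates with agreeing sign.  Adds
    ``significant`` and ``direction`` columns.
    """
    needed = {"lfc_rep1", "lfc_rep2", "adj_p_rep1", "adj_p_rep2"}
    missing = needed - set(pairs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = pairs.copy()
    log_fc = np.log2(fc_thresh)
    l1 = out["lfc_rep1"].to_numpy(float)
    l2 = out["lfc_rep2"].to_numpy(float)
    sig = (
        (out["adj_p_rep1"].to_numpy(float) < p_thresh)
        & (out["adj_p_rep2"].to_numpy(float) < p_thresh)
        & (np.abs(l1) > log_fc)
        & (np.abs(l2) > log_fc)
        & (np.sign(l1) == np.sign(l2))
        & (np.sign(l1) != 0)
    )
    out["significant"] = sig
    direction = np.where(l1 < 0, "longer-lower", "longer-higher")
    out["direction"] = np.where(sig, direction, "")
    return out


def permutation_fdr(
    pairs: pd.DataFrame,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.01,
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Empirical FDR of the dual-replicate significance call by label permutation.

    The pairing between replicate-1 and replicate-2 results is permuted
    across comparisons, breaking the cross-replicate concordance that real
    biology produces; in each shuffle the number of pseudo-pairs passing the
    full criterion (|FC| > fc_thresh, adjusted p < p_thresh, both replicates,
    same direction) is counted.  FDR = mean shuffled count / real count.
    Returns NaN when no real pair passes.
    """
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    if len(pairs) < 2:
        raise ValueError("need at least two comparisons to permute")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    log_fc = np.log2(fc_thresh)
    l1 = pairs["lfc_rep1"].to_numpy(float)
    l2 = pairs["lfc_rep2"].to_numpy(float)
    p1 = pairs["adj_p_rep1"].to_numpy(float)
    p2 = pairs["adj_p_rep2"].to_numpy(float)

    pass1 = (p1 < p_thresh) & (np.abs(l1) > log_fc)
    pass2 = (p2 < p_thresh) & (np.abs(l2) > log_fc)
    concordant = np.sign(l1) == np.sign(l2)
    real = int(np.sum(pass1 & pass2 & concordant))
    if real == 0:
        return float("nan")

    n = len(pairs)
    fp = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(n)
        fp[s] = np.sum(pass1 & pass2[perm] & (np.sign(l1) == np.sign(l2[perm])))
    return float(fp.mean() / real)
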