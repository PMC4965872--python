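"""Group-level statistics linking 5'UTR features to TE divergence.

All analyses operate on per-pair records: the log2 TE fold change of the
longer-UTR isoform over the shorter one, together with the feature content
of the divergent region (the 5' sequence unique to the longer isoform) and
the 5'UTR length difference.  Because longer divergent regions carry more of
everything, every two-group comparison is preceded by matching the
distribution of UTR length differences between the groups (random
down-sampling to per-bin minima).  Group differences are tested with the
Mann-Whitney U test; directional enrichments with Fisher's exact test;
per-hexamer effects with a matched Mann-Whitney scan under BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from .divergence import bh_adjust
from .utr import AUG_FREE_HEXAMERS

DEFAULT_BINS = np.arange(0, 2001, 100)


def match_length_diff(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    bins: np.ndarray = DEFAULT_BINS,
    rng: np.random.Generator | int | None = None,
    column: str = "dlength",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equalize the UTR length-difference distributions of two pair groups.

    Within each bin of ``column`` both groups are randomly down-sampled to
    the per-bin minimum count; bins empty in either group are dropped.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bins = np.asarray(bins, dtype=float)
    ia = np.digitize(group_a[column].to_numpy(float), bins)
    ib = np.digitize(group_b[column].to_numpy(float), bins)
    picks_a: list[np.ndarray] = []
    picks_b: list[np.ndarray] = []
    for b in np.union1d(ia, ib):
        idx_a = np.flatnonzero(ia == b)
        idx_b = np.flatnonzero(ib == b)
        n = min(len(idx_a), len(idx_b))
        if n == 0:
            continue
        picks_a.append(rng.choice(idx_a, n, replace=False))
        picks_b.append(rng.choice(idx_b, n, replace=False))
    if not picks_a:
        raise ValueError("no length-difference bin is populated in both groups")
    sel_a = np.sort(np.concatenate(picks_a))
    sel_b = np.sort(np.concatenate(picks_b))
    return group_a.iloc[sel_a], group_b.iloc[sel_b]


def group_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on per-pair log2 TE fold changes.

    Uses the exact null for group sizes <= 20 (no ties), the tie-corrected
    normal approximation otherwise.  Returns (U, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(len(a) * len(b) / 2), 1.0
    small = max(len(a), len(b)) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = mannwhitneyu(a, b, alternative="two-sided",
                       method="exact" if small else "asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DoseResponse:
    strata: list[str]
    counts: list[int]
    medians: list[float]
    pairwise_p: dict[tuple[str, str], float]
    monotone_decreasing: bool


def uorf_dose_response(pairs: pd.DataFrame, value: str = "lfc",
                       n_uorf: str = "n_uorf") -> DoseResponse:
    """Median TE divergence stratified by uORF count in the divergent region.

    Strata are 0, 1, 2 and >=3 uORFs; adjacent strata are compared with
    Mann-Whitney tests and the monotone decrease of stratum medians is
    reported.
    """
    counts = pairs[n_uorf].to_numpy(int)
    labels = np.where(counts >= 3, "3+", counts.astype(str))
    order = [s for s in ["0", "1", "2", "3+"] if (labels == s).sum() > 0]
    if len(order) < 2:
        raise ValueError("need at least two populated uORF strata")
    groups = {s: pairs.loc[labels == s, value].to_numpy(float) for s in order}
    medians = [float(np.median(groups[s])) for s in order]
    pairwise = {}
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            a, b = groups[order[i]], groups[order[j]]
            if len(a) >= 3 and len(b) >= 3:
                pairwise[(order[i], order[j])] = group_compare(a, b)[1]
    return DoseResponse(
        strata=order,
        counts=[len(groups[s]) for s in order],
        medians=medians,
        pairwise_p=pairwise,
        monotone_decreasing=all(
            medians[i + 1] <= medians[i] for i in range(len(medians) - 1)
        ),
    )


def fisher_direction_enrichment(
    pairs: pd.DataFrame, feature_flag: str,
    direction: str = "direction", value: str = "longer-lower",
) -> tuple[float, float, np.ndarray]:
    """Fisher's exact test: feature presence vs longer-isoform-lower TE.

    The 2x2 table crosses {feature present, absent} with {longer-lower,
    remaining pairs}; all margins must be positive.  Returns (odds ratio,
    two-sided p, table).
    """
    present = pairs[feature_flag].to_numpy(bool)
    lower = (pairs[direction] == value).to_numpy()
    table = np.array([
        [int(np.sum(present & lower)), int(np.sum(present & ~lower))],
        [int(np.sum(~present & lower)), int(np.sum(~present & ~lower))],
    ])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margin in the 2x2 table")
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p), table


def hexamer_scan(
    pairs: pd.DataFrame,
    hexamer_presence: np.ndarray,
    value: str = "lfc",
    bins: np.ndarray = DEFAULT_BINS,
    rng: np.random.Generator | int | None = None,
    min_group: int = 3,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-hexamer association between presence and TE divergence.

    ``hexamer_presence`` is a boolean (n_pairs, 3841) matrix over the
    AUG-free hexamers (presence in the pair's divergent region).  For each
    hexamer present in at least ``min_group`` and absent from at least
    ``min_group`` pairs, the groups are length-difference matched and
    compared with a Mann-Whitney test; p-values are BH-adjusted across all
    tested hexamers.  Returns a table with raw/adjusted p, the median
    difference direction, and a ``significant`` flag at ``alpha``.
    """
    if len(pairs) < 20:
        raise ValueError("need at least 20 pairs for the hexamer scan")
    presence = np.asarray(hexamer_presence, dtype=bool)
    if presence.shape != (len(pairs), len(AUG_FREE_HEXAMERS)):
        raise ValueError("presence matrix must be (n_pairs, 3841)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(pairs)
    rows = []
    for h in range(presence.shape[1]):
        with_h = presence[:, h]
        k = int(with_h.sum())
        if k < min_group or k > n - min_group:
            continue
        try:
            g_with, g_without = match_length_diff(
                pairs[with_h], pairs[~with_h], bins, rng
            )
        except ValueError:
            continue
        if len(g_with) < min_group or len(g_without) < min_group:
            continue
        _, p = group_compare(g_with[value], g_without[value])
        delta = float(np.median(g_with[value]) - np.median(g_without[value]))
        rows.append(dict(hexamer=AUG_FREE_HEXAMERS[h], n_with=k, p=p,
                         median_delta=delta))
    result = pd.DataFrame(rows, columns=["hexamer", "n_with", "p", "median_delta"])
    if len(result):
        result["adj_p"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["adj_p"] < alpha
        result["direction"] = np.sign(result["median_delta"]).astype(int)
    else:
        result["adj_p"] = result["significant"] = result["direction"] = None
    return result


def top_comparison(
    top_pairs: pd.DataFrame,
    control_pairs: pd.DataFrame,
    rng: np.random.Generator | int | None = None,
    value: str = "lfc",
) -> tuple[np.ndarray, np.ndarray, float]:
    """TOP-gene TE fold changes against randomly oriented controls.

    ``top_pairs`` holds genes with exactly one TOP and >=1 non-TOP isoform;
    their ``value`` column is log2(TE_TOP / TE_nonTOP).  Control pairs (no
    TOP difference) are randomly re-oriented (sign flipped with probability
    1/2), emulating an arbitrary numerator/denominator assignment.  Returns
    (top values, control values, Mann-Whitney p).
    """
    if len(top_pairs) < 3:
        raise ValueError("need at least 3 TOP genes")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    top_vals = top_pairs[value].to_numpy(float)
    ctrl = control_pairs[value].to_numpy(float).copy()
    flip = rng.random(len(ctrl)) < 0.5
    ctrl[flip] = -ctrl[flip]
    _, p = group_compare(top_vals, ctrl)
    return top_vals, ctrl, p
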