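"""T-cell marker expression ratios and between-endotype rank tests.

Seven canonical T-cell marker genes are tracked: CD3E (all T cells), CD8A
(CD8+), CD4 (CD4+), TBX21 (Th1), GATA3 (Th2), FOXP3 (Treg) and RORC (Th17).
Per-sample ratios of variance-stabilized values (numerator/denominator,
with a small epsilon guarding empty denominators) are compared between
endotypes A and B with the two-sided Wilcoxon rank-sum test: exact
enumeration for small tie-free samples, a tie- and continuity-corrected
normal approximation otherwise.  A log-scale difference of stabilized
values is available as an alternative ratio definition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .endotype import EndotypeAssignment
from .preprocess import VstMatrix

RATIO_EPSILON = 0.01
EXACT_MAX_N = 12

T_CELL_MARKERS = ("CD3E", "CD8A", "CD4", "TBX21", "GATA3", "FOXP3", "RORC")
DEFAULT_PAIRS = (
    ("TBX21", "GATA3"),   # Th1 : Th2 balance
    ("FOXP3", "CD3E"),    # Treg fraction of the T-cell pool
    ("GATA3", "CD3E"),    # Th2 fraction of the T-cell pool
)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration of the rank-sum distribution when the combined sample
    size is at most 12 and the pooled values are tie-free; otherwise the
    normal approximation with tie correction and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    has_ties = len(np.unique(pooled)) < pooled.size

    if n + m <= EXACT_MAX_N and not has_ties:
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n].sum()
        mean_w = n * (n + m + 1) / 2.0
        # enumerate all C(n+m, n) placements of the x-ranks
        dev_obs = abs(w_obs - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(1, n + m + 1), n):
            total += 1
            if abs(sum(combo) - mean_w) >= dev_obs - 1e-9:
                count += 1
        return count / total

    ranks = stats.rankdata(pooled)
    w = ranks[:n].sum()
    mean_w = n * (n + m + 1) / 2.0
    # tie correction on the variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_w = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1.0)))
    if var_w <= 0:
        return 1.0
    z = (abs(w - mean_w) - 0.5) / np.sqrt(var_w)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


@dataclass
class MarkerRatioResult:
    """Per-pair expression ratios and their endotype comparison."""

    ratios: pd.DataFrame                # samples × pairs, ratio values
    medians: pd.DataFrame               # endotype × pairs
    p_values: pd.Series                 # per pair, A vs B
    levels: pd.DataFrame = field(default_factory=pd.DataFrame)  # raw vst per marker

    def summary(self) -> pd.DataFrame:
        out = self.medians.T.copy()
        out.columns = [f"median_{c}" for c in out.columns]
        out["wilcoxon_p"] = self.p_values
        return out


def marker_ratios(vst_matrix: VstMatrix, pairs=None,
                  assignment: EndotypeAssignment | None = None,
                  mode: str = "quotient") -> MarkerRatioResult:
    """Per-sample marker expression ratios grouped by endotype.

    ``mode='quotient'`` computes (vst_num + eps) / (vst_den + eps) with
    eps = 0.01; ``mode='difference'`` computes vst_num − vst_den (a
    log-scale ratio, since stabilized values are approximately logarithmic).
    """
    if pairs is None:
        pairs = DEFAULT_PAIRS
    if mode not in ("quotient", "difference"):
        raise ValueError("mode must be 'quotient' or 'difference'")
    needed = sorted({g for pair in pairs for g in pair})
    missing = [g for g in needed if g not in set(vst_matrix.gene_ids)]
    if missing:
        raise ValueError(f"marker genes absent from expression matrix: {missing}")

    frame = vst_matrix.to_frame()
    cols = {}
    for num, den in pairs:
        if mode == "quotient":
            cols[f"{num}:{den}"] = (frame.loc[num] + RATIO_EPSILON) / (
                frame.loc[den] + RATIO_EPSILON
            )
        else:
            cols[f"{num}:{den}"] = frame.loc[num] - frame.loc[den]
    ratios = pd.DataFrame(cols)

    present_markers = [g for g in T_CELL_MARKERS if g in set(vst_matrix.gene_ids)]
    levels = frame.loc[present_markers].T if present_markers else pd.DataFrame()

    if assignment is None:
        return MarkerRatioResult(
            ratios=ratios, medians=ratios.median().to_frame("all").T,
            p_values=pd.Series(np.nan, index=ratios.columns), levels=levels,
        )

    labels = assignment.labels.reindex(ratios.index)
    medians = ratios.groupby(labels).median()
    a_idx = labels.index[labels == "A"]
    b_idx = labels.index[labels == "B"]
    pvals = {}
    for name in ratios.columns:
        pvals[name] = wilcoxon_rank_sum(
            ratios.loc[a_idx, name].to_numpy(), ratios.loc[b_idx, name].to_numpy()
        )
    return MarkerRatioResult(
        ratios=ratios, medians=medians,
        p_values=pd.Series(pvals, name="wilcoxon_p"), levels=levels,
    )
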