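"""Per-gene differential expression between the two major endotypes.

An explicit negative-binomial Wald test on size-factor-normalized counts:
group means with a 0.5 pseudocount give the log2 fold change (positive =
higher in endotype A), its standard error comes from the NB delta method
using the per-gene dispersion (Var = mu + alpha*mu^2), and two-sided normal
p-values are adjusted by Benjamini–Hochberg.  Samples labeled "other" are
excluded — the contrast is strictly A versus B.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .endotype import EndotypeAssignment
from .io import CountMatrix
from .preprocess import DispersionModel, SizeFactors, normalized_counts

PSEUDOCOUNT = 0.5


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_de(counts: CountMatrix, sf: SizeFactors,
               assignment: EndotypeAssignment,
               model: DispersionModel) -> pd.DataFrame:
    """NB Wald test of endotype A vs B for every gene.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2_fc``, ``se``, ``wald_z``, ``p_value``, ``q_value``.
    """
    a_samples = [s for s in assignment.samples("A") if s in counts.sample_ids]
    b_samples = [s for s in assignment.samples("B") if s in counts.sample_ids]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("both endotypes need at least 2 samples for the Wald test")

    x = normalized_counts(counts, sf)
    col = {s: i for i, s in enumerate(counts.sample_ids)}
    ia = [col[s] for s in a_samples]
    ib = [col[s] for s in b_samples]
    sf_map = dict(zip(sf.sample_ids, sf.factors))
    inv_s_a = np.array([1.0 / sf_map[s] for s in a_samples])
    inv_s_b = np.array([1.0 / sf_map[s] for s in b_samples])

    xa, xb = x[:, ia], x[:, ib]
    mu_a = xa.mean(axis=1)
    mu_b = xb.mean(axis=1)
    n_a, n_b = len(ia), len(ib)

    alpha = np.asarray(model.alpha, dtype=float)
    log2_fc = np.log2((mu_a + PSEUDOCOUNT) / (mu_b + PSEUDOCOUNT))

    # delta method on log(mean + pseudocount): Var(x_ij) = mu/s_j + alpha mu^2
    def var_log_mean(mu: np.ndarray, inv_s: np.ndarray, n: int) -> np.ndarray:
        mu_c = mu + PSEUDOCOUNT
        var_mean = (mu_c * inv_s.mean() + alpha * mu_c**2) / n
        return var_mean / mu_c**2

    var_log2 = (var_log_mean(mu_a, inv_s_a, n_a) + var_log_mean(mu_b, inv_s_b, n_b)) / (
        np.log(2.0) ** 2
    )
    se = np.sqrt(var_log2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2_fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    # degenerate genes: all-zero in both groups carry no evidence
    zero_both = (mu_a == 0) & (mu_b == 0)
    log2_fc[zero_both] = 0.0
    z[zero_both] = 0.0
    p[zero_both] = 1.0
    p = np.clip(p, 0.0, 1.0)

    q = bh_fdr(p)
    base_mean = x[:, ia + ib].mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "se": se,
            "wald_z": z,
            "p_value": p,
            "q_value": q,
        },
        index=pd.Index(counts.gene_ids, name="gene_id"),
    )


def de_genes(res: pd.DataFrame, fc_min: float = 1.5,
             fdr_max: float = 0.05) -> tuple[set[str], set[str]]:
    """Split significant genes into up-in-A and up-in-B at the thresholds.

    up_in_A: fold change (2**log2_fc) >= fc_min and q <= fdr_max; up_in_B
    symmetric with fold change <= 1/fc_min.  The sets are disjoint for any
    fc_min >= 1.
    """
    if fc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    sig = res["q_value"] <= fdr_max
    fc = 2.0 ** res["log2_fc"]
    up_a = set(res.index[sig & (fc >= fc_min)])
    up_b = set(res.index[sig & (fc <= 1.0 / fc_min)])
    if fc_min == 1.0:
        up_b -= up_a & up_b  # fc == 1 exactly would fall in both; keep A
    return up_a, up_b
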