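"""Minimal discriminative gene-signature selection and validation.

From all genes differentially expressed between the two endotypes, the
selector keeps those that (i) are significant at FDR <= 0.05 with fold
change > 1.5, (ii) differ at least 2-fold between cluster means of
normalized counts, (iii) sit in the least-variable half of genes (variance
of variance-stabilized values) within BOTH clusters separately, and (iv)
average at least 100 normalized counts.  Survivors are ranked by a
signal-to-noise divergence score — |mean_A − mean_B| over the pooled
within-cluster SD of stabilized values — and the top k (default 20) form
the signature.  Validation re-clusters an independent cohort on the
signature genes alone and reports concordance with a reference assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .endotype import (ConcordanceReport, EndotypeAssignment, assign_endotypes,
                       cluster_samples, concordance)
from .io import CountMatrix
from .preprocess import SizeFactors, VstMatrix, normalized_counts

logger = logging.getLogger(__name__)


class SelectionError(RuntimeError):
    """No gene survives the filter chain."""


@dataclass
class SignatureGene:
    gene_id: str
    direction: int            # +1 up in A, -1 up in B
    divergence: float         # |mean_A - mean_B| / pooled within-cluster SD
    passed_de: bool = True
    passed_fc2: bool = True
    passed_var50: bool = True
    passed_count100: bool = True


@dataclass
class Signature:
    """Ordered minimal gene signature (descending divergence score)."""

    genes: list[SignatureGene] = field(default_factory=list)
    k: int = 20
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.genes) > self.k:
            raise ValueError("signature longer than k")
        scores = [g.divergence for g in self.genes]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("signature must be sorted by descending divergence")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "direction": g.direction,
                    "divergence": g.divergence,
                    "passed_de": g.passed_de,
                    "passed_fc2": g.passed_fc2,
                    "passed_var50": g.passed_var50,
                    "passed_count100": g.passed_count100,
                }
                for g in self.genes
            ]
        ).set_index("gene_id")

    def to_dict(self) -> dict:
        return {"k": self.k, "params": self.params,
                "genes": self.to_frame().reset_index().to_dict(orient="records")}

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        genes = [
            SignatureGene(
                gene_id=g["gene_id"], direction=int(g["direction"]),
                divergence=float(g["divergence"]),
                passed_de=bool(g.get("passed_de", True)),
                passed_fc2=bool(g.get("passed_fc2", True)),
                passed_var50=bool(g.get("passed_var50", True)),
                passed_count100=bool(g.get("passed_count100", True)),
            )
            for g in d["genes"]
        ]
        return cls(genes=genes, k=int(d.get("k", 20)), params=d.get("params", {}))


def select_signature(vst_matrix: VstMatrix, counts: CountMatrix,
                     assignment: EndotypeAssignment, de: pd.DataFrame,
                     sf: SizeFactors | None = None, k: int = 20,
                     fc_min: float = 2.0, var_quantile: float = 0.5,
                     min_mean_count: float = 100.0,
                     de_fc_min: float = 1.5, de_fdr_max: float = 0.05) -> Signature:
    """Apply the four conjunctive filters, rank by divergence, return top k.

    The within-cluster variance quantile is taken over all genes in the
    expression matrix, separately per cluster; the fold-change filter and
    the abundance filter operate on size-factor-normalized counts (raw
    scale) over the A/B samples.  Ties in divergence break lexicographically
    by gene identifier.
    """
    a_samples = [s for s in assignment.samples("A") if s in vst_matrix.sample_ids]
    b_samples = [s for s in assignment.samples("B") if s in vst_matrix.sample_ids]
    if not a_samples or not b_samples:
        raise ValueError("assignment must contain samples of both endotypes")

    genes = [g for g in vst_matrix.gene_ids if g in de.index and g in counts.gene_ids]
    vsub = vst_matrix.subset_genes(genes)
    col = {s: i for i, s in enumerate(vsub.sample_ids)}
    ia = [col[s] for s in a_samples]
    ib = [col[s] for s in b_samples]
    va, vb = vsub.values[:, ia], vsub.values[:, ib]

    # (i) significant DE at the discovery thresholds
    sub_de = de.loc[genes]
    fc_de = 2.0 ** sub_de["log2_fc"].to_numpy()
    passed_de = (sub_de["q_value"].to_numpy() < de_fdr_max) & (
        (fc_de > de_fc_min) | (fc_de < 1.0 / de_fc_min)
    )

    # (ii) >= fc_min-fold between cluster means of normalized counts
    if sf is None:
        x = counts.counts.astype(float)
    else:
        x = normalized_counts(counts, sf)
    gi = {g: i for i, g in enumerate(counts.gene_ids)}
    rows = [gi[g] for g in genes]
    ccol = {s: i for i, s in enumerate(counts.sample_ids)}
    ca = [ccol[s] for s in a_samples]
    cb = [ccol[s] for s in b_samples]
    mean_a = x[np.ix_(rows, ca)].mean(axis=1)
    mean_b = x[np.ix_(rows, cb)].mean(axis=1)
    ratio = (mean_a + 0.5) / (mean_b + 0.5)
    passed_fc2 = (ratio >= fc_min) | (ratio <= 1.0 / fc_min)

    # (iii) least-variable var_quantile within both clusters separately
    var_a = va.var(axis=1, ddof=1)
    var_b = vb.var(axis=1, ddof=1)
    thr_a = np.quantile(var_a, var_quantile)
    thr_b = np.quantile(var_b, var_quantile)
    passed_var = (var_a <= thr_a) & (var_b <= thr_b)

    # (iv) overall mean normalized count over the A/B samples
    overall_mean = x[np.ix_(rows, ca + cb)].mean(axis=1)
    passed_count = overall_mean >= min_mean_count

    candidate = passed_de & passed_fc2 & passed_var & passed_count
    if not candidate.any():
        eliminated = {
            "de": int((~passed_de).sum()),
            "fc2": int((~passed_fc2).sum()),
            "var50": int((~passed_var).sum()),
            "count100": int((~passed_count).sum()),
        }
        worst = max(eliminated, key=eliminated.get)
        raise SelectionError(
            f"no gene passes all filters; the '{worst}' filter eliminated the most "
            f"genes ({eliminated})"
        )

    pooled_sd = np.sqrt(
        ((len(ia) - 1) * va.var(axis=1, ddof=1) + (len(ib) - 1) * vb.var(axis=1, ddof=1))
        / (len(ia) + len(ib) - 2)
    )
    pooled_sd = np.maximum(pooled_sd, 1e-12)
    divergence = np.abs(va.mean(axis=1) - vb.mean(axis=1)) / pooled_sd
    direction = np.where(va.mean(axis=1) >= vb.mean(axis=1), 1, -1)

    order = sorted(
        np.flatnonzero(candidate), key=lambda i: (-divergence[i], genes[i])
    )
    if len(order) < k:
        warnings.warn(
            f"only {len(order)} genes pass all filters; signature shorter than k={k}",
            stacklevel=2,
        )
    chosen = order[:k]
    sig_genes = [
        SignatureGene(
            gene_id=genes[i], direction=int(direction[i]), divergence=float(divergence[i])
        )
        for i in chosen
    ]
    return Signature(
        genes=sig_genes, k=k,
        params={
            "fc_min": fc_min, "var_quantile": var_quantile,
            "min_mean_count": min_mean_count, "de_fc_min": de_fc_min,
            "de_fdr_max": de_fdr_max, "n_candidates": len(order),
        },
    )


def validate_signature(sig: Signature, vst_new: VstMatrix,
                       reference: EndotypeAssignment) -> ConcordanceReport:
    """Re-cluster a cohort on the signature genes and compare to a reference.

    The signature submatrix is clustered (average linkage, Euclidean) and
    cut into two clusters; concordance is reported against the reference
    assignment restricted to its A/B samples.
    """
    present = [g for g in sig.gene_ids if g in set(vst_new.gene_ids)]
    missing = sorted(set(sig.gene_ids) - set(present))
    if missing:
        logger.info("signature genes missing from validation matrix: %s", missing)
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present in the new cohort")
    ab_samples = [
        s for s in vst_new.sample_ids
        if s in set(reference.labels.index) and reference.labels[s] in ("A", "B")
    ]
    sub = vst_new.subset_genes(present)
    keep = [i for i, s in enumerate(sub.sample_ids) if s in set(ab_samples)]
    sub = VstMatrix(
        sub.gene_ids, [sub.sample_ids[i] for i in keep], sub.values[:, keep],
        globin_removed=sub.globin_removed, batch_adjusted=sub.batch_adjusted,
    )
    dend = cluster_samples(sub)
    new_assignment = assign_endotypes(dend, n_clusters=2)
    ref = EndotypeAssignment(labels=reference.labels.loc[sub.sample_ids])
    return concordance(new_assignment, ref)
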