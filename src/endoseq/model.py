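"""Statsmodels-style front end: an :class:`EndotypeModel` built from counts
and sample metadata whose :meth:`~EndotypeModel.fit` runs the full endotype
pipeline and returns an :class:`EndotypeResults` carrying the stabilized
expression matrix, dendrogram, endotype assignment, differential-expression
table and minimal signature, with ``summary()`` and plotting attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, endotype, preprocess, signature as signature_mod
from .io import (CountMatrix, check_samples_match, default_anchor_genes,
                 default_globin_genes, read_counts, read_samples)


class EndotypeModel:
    """Unsupervised endotype-discovery model for a bulk RNA-seq cohort.

    Parameters
    ----------
    counts
        Raw gene × sample counts.
    samples
        Optional metadata indexed by sample id; a ``batch`` column triggers
        empirical-Bayes batch adjustment.
    globin_genes, anchor_genes
        Hemoglobin genes to drop, and the anchor set that orients the A/B
        labels (anchor-high cluster becomes A); both default to packaged
        lists.
    n_clusters
        Flat-cut size: the two largest clusters become the endotypes, the
        rest "other".
    """

    def __init__(self, counts: CountMatrix, samples: pd.DataFrame | None = None,
                 *, globin_genes=None, anchor_genes=None, n_clusters: int = 3,
                 fc_min: float = 1.5, fdr_max: float = 0.05,
                 signature_k: int = 20):
        self.counts = counts
        self.samples = samples
        if samples is not None:
            check_samples_match(counts, samples)
        self.globin_genes = set(globin_genes) if globin_genes is not None \
            else set(default_globin_genes())
        self.anchor_genes = set(anchor_genes) if anchor_genes is not None \
            else set(default_anchor_genes())
        self.n_clusters = n_clusters
        self.fc_min = fc_min
        self.fdr_max = fdr_max
        self.signature_k = signature_k

    @classmethod
    def from_files(cls, counts_path, samples_path=None, **kwargs) -> "EndotypeModel":
        counts = read_counts(counts_path)
        samples = read_samples(samples_path) if samples_path else None
        return cls(counts, samples, **kwargs)

    def fit(self, select_signature: bool = True) -> "EndotypeResults":
        """Run preprocess → cluster → label → DE → signature."""
        vst, filtered, sf, disp = preprocess.preprocess_pipeline(
            self.counts, self.samples, self.globin_genes
        )
        dend = endotype.cluster_samples(vst)
        assignment = endotype.assign_endotypes(dend, self.n_clusters)
        assignment = endotype.label_endotypes(assignment, vst, self.anchor_genes)
        de = diffexpr.nb_wald_de(filtered, sf, assignment, disp)
        up_a, up_b = diffexpr.de_genes(de, self.fc_min, self.fdr_max)
        sig = None
        if select_signature:
            try:
                sig = signature_mod.select_signature(
                    vst, filtered, assignment, de, sf=sf, k=self.signature_k
                )
            except signature_mod.SelectionError:
                sig = None
        return EndotypeResults(
            model=self, vst=vst, filtered_counts=filtered, size_factors=sf,
            dispersion=disp, dendrogram=dend, assignment=assignment, de=de,
            up_in_a=up_a, up_in_b=up_b, signature=sig,
        )


@dataclass
class EndotypeResults:
    """Everything the fitted pipeline produced."""

    model: EndotypeModel
    vst: preprocess.VstMatrix
    filtered_counts: CountMatrix
    size_factors: preprocess.SizeFactors
    dispersion: preprocess.DispersionModel
    dendrogram: endotype.Dendrogram
    assignment: endotype.EndotypeAssignment
    de: pd.DataFrame
    up_in_a: set = field(default_factory=set)
    up_in_b: set = field(default_factory=set)
    signature: signature_mod.Signature | None = None

    @property
    def endotypes(self) -> pd.Series:
        return self.assignment.labels

    def cluster_sizes(self) -> dict[str, int]:
        return self.assignment.sizes()

    def validate(self, vst_new: preprocess.VstMatrix,
                 reference: endotype.EndotypeAssignment):
        """Validate the fitted signature on an independent cohort."""
        if self.signature is None:
            raise RuntimeError("no signature was selected on this fit")
        return signature_mod.validate_signature(self.signature, vst_new, reference)

    def concordance_with(self, other: endotype.EndotypeAssignment):
        return endotype.concordance(self.assignment, other)

    def report(self) -> dict:
        """Headline numbers as a JSON-serializable dictionary."""
        sizes = self.cluster_sizes()
        rep = {
            "n_samples": len(self.assignment.labels),
            "n_genes": self.filtered_counts.n_genes,
            "pooled_dispersion": self.dispersion.pooled_alpha,
            "cluster_sizes": sizes,
            "n_de_genes": len(self.up_in_a) + len(self.up_in_b),
            "n_up_in_a": len(self.up_in_a),
            "n_up_in_b": len(self.up_in_b),
            "signature": self.signature.gene_ids if self.signature else [],
        }
        return rep

    def summary(self) -> str:
        """Human-readable fit summary."""
        rep = self.report()
        lines = [
            "Endotype discovery results",
            "==========================",
            f"Samples: {rep['n_samples']}   Genes (post-globin): {rep['n_genes']}",
            f"Pooled NB dispersion: {rep['pooled_dispersion']:.4g}",
            "Cluster sizes: "
            + ", ".join(f"{k}={v}" for k, v in rep["cluster_sizes"].items()),
            f"DE genes (|FC|>={self.model.fc_min}, q<={self.model.fdr_max}): "
            f"{rep['n_de_genes']} ({rep['n_up_in_a']} up in A, "
            f"{rep['n_up_in_b']} up in B)",
        ]
        if self.signature:
            lines.append(
                f"Signature ({len(self.signature)} genes): "
                + ", ".join(self.signature.gene_ids)
            )
        return "\n".join(lines)

    def save_report(self, path) -> None:
        Path(path).write_text(json.dumps(self.report(), indent=1))

    def plot_dendrogram(self, ax=None):
        """Dendrogram of the sample tree, colored leaves by endotype."""
        import matplotlib.pyplot as plt
        from scipy.cluster import hierarchy as hc

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        hc.dendrogram(
            self.dendrogram.linkage, labels=self.dendrogram.leaf_ids, ax=ax,
            leaf_rotation=90,
        )
        colors = {"A": "tab:blue", "B": "tab:green", "other": "tab:red"}
        for tick in ax.get_xticklabels():
            tick.set_color(colors[self.assignment.labels[tick.get_text()]])
        ax.set_ylabel("average-linkage height (Euclidean)")
        return ax
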