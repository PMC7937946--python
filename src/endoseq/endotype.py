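"""Sample clustering and endotype assignment.

Samples are clustered by average-linkage agglomeration on Euclidean
distances between their variance-stabilized expression profiles.  Cutting
the tree into ``n_clusters`` flat clusters yields two major endotypes (the
two largest clusters) plus an "other" group for everything else.  The A/B
orientation is decided by an anchor gene set — by default neutrophil
degranulation markers, so that the neutrophil-high endotype is labeled A —
rather than by cluster size, which can be nearly tied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .preprocess import VstMatrix

logger = logging.getLogger(__name__)


class LabelingError(ValueError):
    """Anchor genes absent from the expression matrix."""


@dataclass
class Dendrogram:
    """Average-linkage merge tree over samples.

    ``linkage`` is a scipy linkage matrix (merge left, merge right, height,
    size); ``leaf_ids`` are sample identifiers in leaf order 0..n-1.
    """

    leaf_ids: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 merges")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("average-linkage heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster memberships (1..k) for a k-cluster cut."""
        return hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialize with branch lengths derived from merge heights."""
        n = len(self.leaf_ids)
        node_height = {i: 0.0 for i in range(n)}
        node_str = {i: self.leaf_ids[i].replace(" ", "_") for i in range(n)}
        for k, (left, right, h, _size) in enumerate(self.linkage):
            left, right = int(left), int(right)
            bl = h - node_height[left]
            br = h - node_height[right]
            node_str[n + k] = f"({node_str[left]}:{bl:.6g},{node_str[right]}:{br:.6g})"
            node_height[n + k] = h
        return node_str[2 * n - 2] + ";"


@dataclass
class EndotypeAssignment:
    """Per-sample endotype labels in {A, B, other}."""

    labels: pd.Series                       # index sample_id, values A/B/other
    anchor_score: pd.Series | None = None   # mean anchor-gene vst per sample
    cluster_ids: pd.Series | None = None    # raw flat-cut memberships

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"A", "B", "other"}
        if bad:
            raise ValueError(f"unknown endotype labels {sorted(bad)}")
        if self.labels.index.has_duplicates:
            raise ValueError("duplicate sample ids in assignment")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def samples(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict[str, int]:
        return {lab: int((self.labels == lab).sum()) for lab in ("A", "B", "other")}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"endotype": self.labels})
        if self.anchor_score is not None:
            df["anchor_score"] = self.anchor_score
        return df


@dataclass
class ConcordanceReport:
    """Agreement between two endotype assignments on shared samples."""

    agreement_fraction: float
    adjusted_rand_index: float
    discordant_samples: list[str] = field(default_factory=list)
    n_shared: int = 0


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_samples(vst_matrix: VstMatrix) -> Dendrogram:
    """Average-linkage dendrogram on Euclidean distances between samples.

    Samples are ordered lexicographically by identifier before linkage so the
    result is invariant to input column order (and ties resolve the same way
    on any run).
    """
    if vst_matrix.values.shape[1] < 3:
        raise ValueError("clustering needs at least 3 samples")
    if not np.all(np.isfinite(vst_matrix.values)):
        raise ValueError("vst matrix contains non-finite values")
    order = np.argsort(np.asarray(vst_matrix.sample_ids, dtype=object))
    ids = [vst_matrix.sample_ids[i] for i in order]
    x = vst_matrix.values[:, order].T  # samples × genes
    z = hierarchy.linkage(x, method="average", metric="euclidean")
    # guard against numerically negative height steps
    z[:, 2] = np.maximum.accumulate(np.maximum(z[:, 2], 0.0))
    return Dendrogram(ids, z)


def assign_endotypes(dend: Dendrogram, n_clusters: int = 3) -> EndotypeAssignment:
    """Cut the tree into flat clusters; the two largest become A and B.

    Remaining samples are labeled "other".  The provisional A/B orientation
    (by descending size, ties broken by lower mean within-cluster distance,
    then lower cluster id) is arbitrary until :func:`label_endotypes`
    orients it with anchor genes.
    """
    n = len(dend.leaf_ids)
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if n_clusters > n:
        raise ValueError("n_clusters exceeds the number of samples")
    flat = dend.cut(n_clusters)
    ids = np.array(dend.leaf_ids, dtype=object)
    sizes = pd.Series(flat).value_counts()
    # mean within-cluster cophenetic distance, used to break size ties
    coph = squareform(hierarchy.cophenet(dend.linkage))

    def mean_within(cid: int) -> float:
        members = np.flatnonzero(flat == cid)
        if len(members) < 2:
            return 0.0
        sub = coph[np.ix_(members, members)]
        return float(sub[np.triu_indices(len(members), 1)].mean())

    def first_member(cid: int) -> str:
        return sorted(ids[flat == cid])[0]

    ranked = sorted(sizes.index, key=lambda c: (-sizes[c], mean_within(c), first_member(c)))
    major = ranked[:2]
    labels = pd.Series("other", index=ids, dtype=object)
    labels[flat == major[0]] = "A"
    labels[flat == major[1]] = "B"
    return EndotypeAssignment(
        labels=labels, cluster_ids=pd.Series(flat, index=ids)
    )


def label_endotypes(assignment: EndotypeAssignment, vst_matrix: VstMatrix,
                    anchor_genes) -> EndotypeAssignment:
    """Orient the two major clusters: anchor-high cluster becomes A.

    ``anchor_genes`` is a set of genes expected to be elevated in the
    neutrophil-degranulation endotype; the major cluster with the higher
    mean variance-stabilized anchor expression is labeled A.
    """
    anchors = [g for g in vst_matrix.gene_ids if g in set(anchor_genes)]
    if not anchors:
        raise LabelingError(
            "none of the anchor genes are present in the expression matrix; "
            "supply anchors that overlap its gene identifiers"
        )
    sub = vst_matrix.subset_genes(anchors)
    score = pd.Series(sub.values.mean(axis=0), index=sub.sample_ids, name="anchor_score")
    labels = assignment.labels.copy()
    mean_a = score[labels.index[labels == "A"]].mean()
    mean_b = score[labels.index[labels == "B"]].mean()
    if mean_b > mean_a:
        swapped = labels.map({"A": "B", "B": "A", "other": "other"})
        labels = swapped
    return EndotypeAssignment(
        labels=labels, anchor_score=score.loc[labels.index],
        cluster_ids=assignment.cluster_ids,
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def concordance(a: EndotypeAssignment, b: EndotypeAssignment) -> ConcordanceReport:
    """Agreement between two assignments after optimal A/B label matching.

    The agreement fraction is maximized over the two matchings of {A, B}
    ("other" always maps to "other"); the adjusted Rand index is computed on
    the full three-label partition and is matching-free by construction.
    """
    shared = [s for s in a.labels.index if s in set(b.labels.index)]
    if not shared:
        raise ValueError("assignments share no samples")
    if len(shared) < len(a.labels) or len(shared) < len(b.labels):
        logger.info("concordance computed on %d shared samples", len(shared))
    la = a.labels.loc[shared]
    lb = b.labels.loc[shared]
    ari = float(adjusted_rand_score(la.to_numpy(), lb.to_numpy()))
    best_frac, best_map = -1.0, None
    for mapping in ({"A": "A", "B": "B", "other": "other"},
                    {"A": "B", "B": "A", "other": "other"}):
        frac = float((la.map(mapping) == lb).mean())
        if frac > best_frac:
            best_frac, best_map = frac, mapping
    discordant = [s for s in shared if best_map[la[s]] != lb[s]]
    return ConcordanceReport(
        agreement_fraction=best_frac, adjusted_rand_index=ari,
        discordant_samples=discordant, n_shared=len(shared),
    )


# ---------------------------------------------------------------------------
# clinical summaries
# ---------------------------------------------------------------------------

ACTIVE_SCORE_THRESHOLD = 2  # activity score > 2 counts as active disease


def clinical_summary(clin: pd.DataFrame) -> pd.DataFrame:
    """Per-endotype clinical summary.

    For each endotype label: patient count, sex counts, counts per clinical
    classification, ANCA serotype counts, mean activity score rounded to the
    nearest integer, and the number of patients with active disease
    (activity score > 2).
    """
    if len(clin) == 0:
        return pd.DataFrame()
    bad = set(clin["endotype"]) - {"A", "B", "other"}
    if bad:
        raise ValueError(f"unknown endotype labels {sorted(bad)}")
    rows = {}
    for label, grp in clin.groupby("endotype"):
        row: dict[str, object] = {"n": len(grp)}
        for sex, cnt in grp["sex"].value_counts().items():
            row[f"sex_{sex}"] = int(cnt)
        for cls, cnt in grp["ema_class"].value_counts().items():
            row[f"class_{cls}"] = int(cnt)
        anca = grp["anca"].value_counts()
        for level in ("PR3", "MPO", "PR3+MPO", "NEG"):
            row[f"anca_{level}"] = int(anca.get(level, 0))
        scores = grp["activity_score"].astype(float)
        row["mean_activity_score"] = int(np.floor(scores.mean() + 0.5))
        row["n_active"] = int((scores > ACTIVE_SCORE_THRESHOLD).sum())
        rows[label] = row
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0)
    count_cols = [c for c in out.columns if c != "mean_activity_score"]
    out[count_cols] = out[count_cols].astype(int)
    out.index.name = "endotype"
    assert int(out["n"].sum()) == len(clin)
    return out
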