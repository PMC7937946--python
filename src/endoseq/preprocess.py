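"""Count preprocessing: globin removal, library-size normalization,
negative-binomial dispersion estimation, variance-stabilizing transformation,
and empirical-Bayes batch adjustment.

The transformation chain mirrors the standard bulk RNA-seq workflow for
whole-blood samples: hemoglobin transcripts (which can dominate whole-blood
libraries) are dropped, per-sample size factors are estimated by the
median-of-ratios rule, a closed-form NB variance-stabilizing transform

    g(x) = (2 / sqrt(alpha)) * asinh(sqrt(alpha * x))

is applied to normalized counts with a pooled method-of-moments dispersion
``alpha`` (Var = mu + alpha * mu^2), and known batches (sequencing dates)
are adjusted by parametric empirical-Bayes location/scale shrinkage, the
same model family ComBat fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-4


class EstimationError(RuntimeError):
    """Raised when a preprocessing estimator has no usable input."""


class DegenerateInputError(ValueError):
    """Raised when an operation would return an empty or meaningless result."""


@dataclass
class SizeFactors:
    """Per-sample library-size factors, anchored to geometric mean 1."""

    sample_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise EstimationError("size factors must be positive and finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.factors, index=self.sample_ids, name="size_factor")


@dataclass
class DispersionModel:
    """Per-gene NB dispersions and the pooled dispersion the VST uses."""

    gene_ids: list[str]
    alpha: np.ndarray          # per-gene, >= 0
    pooled_alpha: float        # median of positive alphas, floored

    def to_series(self) -> pd.Series:
        return pd.Series(self.alpha, index=self.gene_ids, name="alpha")


@dataclass
class VstMatrix:
    """Variance-stabilized gene × sample expression values with provenance."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    globin_removed: bool = False
    batch_adjusted: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("vst value shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "VstMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), **kw)

    def subset_genes(self, gene_ids) -> "VstMatrix":
        wanted = set(gene_ids)
        keep = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        return VstMatrix(
            [self.gene_ids[i] for i in keep],
            list(self.sample_ids),
            self.values[keep, :],
            globin_removed=self.globin_removed,
            batch_adjusted=self.batch_adjusted,
            provenance=dict(self.provenance),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def remove_globin(counts: CountMatrix, globin_ids) -> CountMatrix:
    """Drop hemoglobin genes from a count matrix.

    Removes exactly the genes whose identifiers appear in ``globin_ids``;
    counts of the remaining genes are untouched.
    """
    globin_ids = set(globin_ids)
    if not globin_ids:
        raise ValueError("globin_ids must be non-empty")
    keep = [i for i, g in enumerate(counts.gene_ids) if g not in globin_ids]
    if not keep:
        raise DegenerateInputError("globin removal would leave zero genes")
    removed = counts.n_genes - len(keep)
    if removed:
        logger.info("removed %d globin genes", removed)
    if removed == 0:
        return counts
    return CountMatrix(
        [counts.gene_ids[i] for i in keep], list(counts.sample_ids), counts.counts[keep, :]
    )


def size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For each sample j, s_j is the median over reference genes (genes with a
    nonzero count in every sample) of count_gj divided by the gene's
    geometric mean across samples; the factors are then rescaled to have
    geometric mean 1.
    """
    k = counts.counts.astype(float)
    reference = np.all(k > 0, axis=1)
    if not reference.any():
        raise EstimationError(
            "no gene has nonzero counts in every sample; "
            "median-of-ratios needs reference genes (consider a pseudo-reference)"
        )
    ref = k[reference, :]
    log_geomean = np.mean(np.log(ref), axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return SizeFactors(list(counts.sample_ids), s)


def normalized_counts(counts: CountMatrix, sf: SizeFactors) -> np.ndarray:
    """Counts divided by their sample's size factor (genes × samples)."""
    if list(counts.sample_ids) != list(sf.sample_ids):
        order = [sf.sample_ids.index(s) for s in counts.sample_ids]
        factors = sf.factors[order]
    else:
        factors = sf.factors
    return counts.counts / factors[None, :]


def estimate_dispersion(counts: CountMatrix, sf: SizeFactors) -> DispersionModel:
    """Method-of-moments NB dispersion per gene on normalized counts.

    alpha_g = max(0, (var_g - mean_g) / mean_g^2); the pooled dispersion is
    the median of the positive per-gene values, floored at 1e-4 so the VST
    stays defined for near-Poisson data.
    """
    if counts.n_samples < 2:
        raise EstimationError("dispersion estimation needs at least 2 samples")
    x = normalized_counts(counts, sf)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, 0.0)
    positive = alpha[alpha > 0]
    pooled = float(np.median(positive)) if positive.size else DISPERSION_FLOOR
    pooled = max(pooled, DISPERSION_FLOOR)
    return DispersionModel(list(counts.gene_ids), alpha, pooled)


def vst_transform(x: np.ndarray, alpha: float) -> np.ndarray:
    """Closed-form NB variance-stabilizing transform g(x) = (2/√α)·asinh(√(αx))."""
    if alpha <= 0:
        raise ValueError("pooled dispersion must be positive")
    x = np.asarray(x, dtype=float)
    return (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * x))


def vst(counts: CountMatrix, sf: SizeFactors, model: DispersionModel) -> VstMatrix:
    """Variance-stabilize normalized counts with the pooled dispersion.

    The transform is monotone increasing, maps 0 to 0, behaves like 2·√x for
    small ``alpha·x`` and like a scaled log for large ``alpha·x``.
    """
    x = normalized_counts(counts, sf)
    values = vst_transform(x, model.pooled_alpha)
    return VstMatrix(
        list(counts.gene_ids),
        list(counts.sample_ids),
        values,
        provenance={"pooled_alpha": model.pooled_alpha},
    )


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------


def _eb_iterate(z_b: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
                gamma_bar: float, tau2: float, lam: float, theta: float,
                tol: float = 1e-6, max_iter: int = 200):
    """Iterative solution of the EB location/scale posterior modes per gene."""
    n_b = z_b.shape[1]
    gamma_star = gamma_hat.copy()
    delta_star = delta_hat.copy()
    for _ in range(max_iter):
        gamma_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
            n_b * tau2 + delta_star
        )
        ssq = np.sum((z_b - gamma_new[:, None]) ** 2, axis=1)
        delta_new = (theta + 0.5 * ssq) / (n_b / 2.0 + lam - 1.0)
        change = max(
            np.max(np.abs(gamma_new - gamma_star)), np.max(np.abs(delta_new - delta_star))
        )
        gamma_star, delta_star = gamma_new, delta_new
        if change < tol:
            break
    return gamma_star, delta_star


def batch_adjust(vst_matrix: VstMatrix, samples: pd.DataFrame,
                 batch_col: str = "batch") -> VstMatrix:
    """Remove additive and multiplicative batch effects per gene.

    Parametric empirical-Bayes location/scale adjustment: each gene is
    standardized against its batch-weighted grand mean and pooled variance,
    per-batch means and variances are estimated and shrunk toward priors
    fitted across genes (normal prior for locations, inverse-gamma for
    scales), and the standardized data are recentered/rescaled and restored
    to the original gene scale.  A single-batch matrix is returned
    unchanged; a batch with fewer than 2 samples is a contract error.
    """
    batches = samples.loc[vst_matrix.sample_ids, batch_col].astype(str)
    levels = sorted(batches.unique())
    if len(levels) == 1:
        out = VstMatrix(
            list(vst_matrix.gene_ids), list(vst_matrix.sample_ids),
            vst_matrix.values.copy(), globin_removed=vst_matrix.globin_removed,
            batch_adjusted=True, provenance=dict(vst_matrix.provenance),
        )
        out.provenance["batch_levels"] = levels
        return out
    masks = [np.asarray(batches == lev) for lev in levels]
    sizes = np.array([m.sum() for m in masks])
    if np.any(sizes < 2):
        small = [lev for lev, n in zip(levels, sizes) if n < 2]
        raise ValueError(f"cannot estimate batch scale for singleton batch(es) {small}")

    y = vst_matrix.values
    n = y.shape[1]
    batch_means = np.stack([y[:, m].mean(axis=1) for m in masks], axis=1)  # G × B
    grand = batch_means @ (sizes / n)
    # pooled residual variance around the batch-mean fit
    resid = y.copy()
    for m, bm in zip(masks, batch_means.T):
        resid[:, m] -= bm[:, None]
    pooled_var = np.sum(resid**2, axis=1) / n
    pooled_var = np.maximum(pooled_var, 1e-12)
    sd = np.sqrt(pooled_var)
    z = (y - grand[:, None]) / sd[:, None]

    adjusted = np.empty_like(z)
    for m, n_b in zip(masks, sizes):
        z_b = z[:, m]
        gamma_hat = z_b.mean(axis=1)
        delta_hat = z_b.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gamma_bar = float(gamma_hat.mean())
        tau2 = float(gamma_hat.var(ddof=1))
        tau2 = max(tau2, 1e-12)
        v = float(delta_hat.mean())
        s2 = float(delta_hat.var(ddof=1))
        s2 = max(s2, 1e-12)
        lam = (v**2 + 2.0 * s2) / s2          # inverse-gamma shape (moment match)
        theta = (v**3 + v * s2) / s2          # inverse-gamma scale
        gamma_star, delta_star = _eb_iterate(
            z_b, gamma_hat, delta_hat, gamma_bar, tau2, lam, theta
        )
        adjusted[:, m] = (z_b - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out_values = adjusted * sd[:, None] + grand[:, None]
    out = VstMatrix(
        list(vst_matrix.gene_ids), list(vst_matrix.sample_ids), out_values,
        globin_removed=vst_matrix.globin_removed, batch_adjusted=True,
        provenance=dict(vst_matrix.provenance),
    )
    out.provenance["batch_levels"] = levels
    return out


def preprocess_pipeline(counts: CountMatrix, samples: pd.DataFrame | None = None,
                        globin_ids=None, batch_col: str = "batch"):
    """Run the full chain: globin removal → size factors → dispersion → VST
    → (optional) batch adjustment.

    Returns ``(vst_matrix, filtered_counts, size_factors, dispersion_model)``.
    """
    from .io import default_globin_genes

    if globin_ids is None:
        globin_ids = default_globin_genes()
    filtered = remove_globin(counts, globin_ids)
    sf = size_factors(filtered)
    disp = estimate_dispersion(filtered, sf)
    vmat = vst(filtered, sf, disp)
    vmat.globin_removed = True
    if samples is not None and batch_col in samples.columns:
        vmat = batch_adjust(vmat, samples, batch_col=batch_col)
    return vmat, filtered, sf, disp
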