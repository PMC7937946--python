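"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the analysis assumes in a whole-blood
bulk RNA-seq cohort of two disease endotypes plus a small outlier group:

* negative-binomial counts with gene-specific dispersion (Var = mu + a*mu^2);
* two latent endotypes differing in a planted fraction of DE genes whose
  |log2 fold changes| straddle the 1.5- and 2-fold analysis thresholds;
* a small "other" group drawn from a third mean profile;
* multiplicative per-gene batch effects (sequencing date) and log-normal
  library sizes;
* a high-abundance hemoglobin block (a fixed share of reads);
* named marker and anchor gene blocks (T-cell markers, neutrophil
  degranulation genes) with planted direction;
* gene sets (GMT-style) of which a subset is enriched for planted DE genes.

Everything derives from a single seed; the returned truth object records
group and batch membership, per-gene effects and dispersions, and true size
factors, so every downstream stage can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneSet, GeneSetCollection

GLOBIN_GENES = ("HBB", "HBA1", "HBA2", "HBG1", "HBG2")
ANCHOR_GENES = ("S100A8", "S100A9", "FCGR3B", "CSF3R", "MMP9")
MARKER_EFFECTS = {  # log2FC, A over B; negative = higher in B
    "CD3E": 0.0, "CD8A": 0.0, "CD4": -0.5, "TBX21": 0.7,
    "GATA3": -1.0, "FOXP3": -0.7, "RORC": 0.0,
}
ANCHOR_LOG2FC = 1.5


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults mirror the discovery cohort
    (13 + 14 samples in the two endotypes, 3 outliers, two sequencing
    batches, 10% DE genes)."""

    n_genes: int = 2000
    n_samples_a: int = 13
    n_samples_b: int = 14
    n_samples_other: int = 3
    n_batches: int = 2
    pi_de: float = 0.10
    log2fc_low: float = 1.0
    log2fc_high: float = 3.0
    alpha_low: float = 0.05
    alpha_high: float = 0.5
    libsize_sigma: float = 0.3
    batch_sigma: float = 0.15
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sigma: float = 1.0
    globin_read_fraction: float = 0.20
    n_other_de: int = 150
    other_log2fc_low: float = 1.0
    other_log2fc_high: float = 3.0
    n_gene_sets: int = 20
    set_size_low: int = 20
    set_size_high: int = 100
    n_enriched_sets: int = 5
    enriched_de_fraction: float = 0.5
    clinical_pvas: dict = field(default_factory=lambda: {
        "A": (21.0, 7.0), "B": (14.0, 5.0), "other": (21.0, 8.0)})
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pi_de <= 1.0:
            raise ValueError("pi_de must lie in [0, 1]")
        if not 0.0 <= self.globin_read_fraction < 1.0:
            raise ValueError("globin_read_fraction must lie in [0, 1)")
        for lo, hi, name in [
            (self.log2fc_low, self.log2fc_high, "log2fc"),
            (self.alpha_low, self.alpha_high, "alpha"),
            (self.set_size_low, self.set_size_high, "set_size"),
        ]:
            if lo > hi:
                raise ValueError(f"{name} range is not ordered")
        if min(self.n_genes, self.n_samples_a, self.n_samples_b, self.n_batches) < 1:
            raise ValueError("sizes must be positive")
        if self.n_samples_other < 0:
            raise ValueError("n_samples_other must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted parameters behind a simulated cohort."""

    sample_ids: list[str]
    group: list[str]                   # per sample: A / B / other
    batch: list[str]
    size_factors: list[float]
    gene_ids: list[str]
    baseline_mu: list[float]
    is_de: list[bool]
    true_log2fc: list[float]           # A over B
    other_log2fc: list[float]          # other group over baseline
    alpha: list[float]
    is_globin: list[bool]
    batch_log2fc: list[list[float]]    # n_batches × n_genes, log2 factors
    set_membership: dict = field(default_factory=dict)

    def de_genes(self) -> set[str]:
        return {g for g, de in zip(self.gene_ids, self.is_de) if de}

    def group_series(self) -> pd.Series:
        return pd.Series(self.group, index=self.sample_ids, name="group")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self)))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _gene_names(config: SimulationConfig) -> tuple[list[str], dict[str, int]]:
    special = list(GLOBIN_GENES) + list(ANCHOR_GENES) + list(MARKER_EFFECTS)
    if config.n_genes <= len(special):
        raise ValueError("n_genes too small for the named gene blocks")
    generic = [f"G{i:05d}" for i in range(config.n_genes - len(special))]
    names = special + generic
    return names, {g: i for i, g in enumerate(names)}


def simulate(config: SimulationConfig | None = None, seed: int | None = None,
             truth: SyntheticTruth | None = None):
    """Draw a synthetic cohort.

    Returns ``(CountMatrix, sample table DataFrame, GeneSetCollection,
    SyntheticTruth)``.  Passing an existing ``truth`` re-uses the planted
    gene-level parameters (baselines, effects, dispersions, batch factors,
    set memberships) and redraws only the sample-level randomness — a fresh
    cohort from the same generative truth, for cross-cohort validation.
    """
    config = config or SimulationConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    gene_ids, gene_index = _gene_names(config)
    g = config.n_genes

    if truth is None:
        baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sigma, g)
        is_globin = np.array([gid in GLOBIN_GENES for gid in gene_ids])
        # scale the hemoglobin block to carry its share of reads
        non_globin_total = baseline[~is_globin].sum()
        f = config.globin_read_fraction
        if f > 0:
            target = non_globin_total * f / (1.0 - f)
            baseline[is_globin] *= target / baseline[is_globin].sum()

        alpha = rng.uniform(config.alpha_low, config.alpha_high, g)

        log2fc = np.zeros(g)
        is_de = np.zeros(g, dtype=bool)
        eligible = np.array([
            gid not in GLOBIN_GENES and gid not in MARKER_EFFECTS
            and gid not in ANCHOR_GENES
            for gid in gene_ids
        ])
        n_de = int(round(config.pi_de * g))
        if n_de > 0:
            de_idx = rng.choice(np.flatnonzero(eligible), size=n_de, replace=False)
            magnitude = rng.uniform(config.log2fc_low, config.log2fc_high, n_de)
            sign = rng.choice([-1.0, 1.0], size=n_de)
            log2fc[de_idx] = magnitude * sign
            is_de[de_idx] = True
        if config.pi_de > 0:  # a null cohort plants no effects anywhere
            for gid, eff in MARKER_EFFECTS.items():
                log2fc[gene_index[gid]] = eff
                if eff != 0:
                    is_de[gene_index[gid]] = True
            for gid in ANCHOR_GENES:
                log2fc[gene_index[gid]] = ANCHOR_LOG2FC
                is_de[gene_index[gid]] = True

        other_fc = np.zeros(g)
        if config.n_other_de > 0 and config.n_samples_other > 0:
            pool = np.flatnonzero(eligible & ~is_de)
            n_other = min(config.n_other_de, pool.size)
            oidx = rng.choice(pool, size=n_other, replace=False)
            other_fc[oidx] = rng.uniform(
                config.other_log2fc_low, config.other_log2fc_high, n_other
            ) * rng.choice([-1.0, 1.0], size=n_other)

        batch_fc = rng.normal(0.0, config.batch_sigma, (config.n_batches, g))
        batch_fc[0, :] = 0.0  # first batch is the reference

        collection, membership = _draw_gene_sets(rng, config, gene_ids, is_de)
    else:
        baseline = np.asarray(truth.baseline_mu)
        alpha = np.asarray(truth.alpha)
        log2fc = np.asarray(truth.true_log2fc)
        is_de = np.asarray(truth.is_de, dtype=bool)
        other_fc = np.asarray(truth.other_log2fc)
        is_globin = np.asarray(truth.is_globin, dtype=bool)
        batch_fc = np.asarray(truth.batch_log2fc)
        gene_ids = list(truth.gene_ids)
        membership = dict(truth.set_membership)
        collection = GeneSetCollection(
            [GeneSet(name, "synthetic gene set", frozenset(genes))
             for name, genes in membership.items()]
        )

    n_a, n_b, n_o = config.n_samples_a, config.n_samples_b, config.n_samples_other
    n = n_a + n_b + n_o
    sample_ids = [f"S{i:03d}" for i in range(n)]
    group = ["A"] * n_a + ["B"] * n_b + ["other"] * n_o
    batch_idx = np.array([i % config.n_batches for i in range(n)])

    size_fac = rng.lognormal(0.0, config.libsize_sigma, n)
    size_fac /= np.exp(np.mean(np.log(size_fac)))

    is_a = np.array([gr == "A" for gr in group], dtype=float)
    is_other = np.array([gr == "other" for gr in group], dtype=float)
    log2_mu = (
        np.log2(baseline)[:, None]
        + np.outer(log2fc, is_a)
        + np.outer(other_fc, is_other)
        + batch_fc[batch_idx, :].T
    )
    mu = (2.0 ** log2_mu) * size_fac[None, :]

    counts = np.empty((config.n_genes, n), dtype=np.int64)
    pos = alpha > 0
    r = np.empty_like(alpha)
    r[pos] = 1.0 / alpha[pos]
    for j in range(n):
        mj = mu[:, j]
        cj = np.empty(config.n_genes, dtype=np.int64)
        if pos.any():
            p = r[pos] / (r[pos] + mj[pos])
            cj[pos] = rng.negative_binomial(r[pos], p)
        if (~pos).any():
            cj[~pos] = rng.poisson(mj[~pos])
        counts[:, j] = cj

    cm = CountMatrix(gene_ids, sample_ids, counts)
    samples = pd.DataFrame(
        {
            "batch": [f"batch{b}" for b in batch_idx],
            "cohort": ["synthetic"] * n,
            "sex": rng.choice(["F", "M"], size=n).tolist(),
            "timepoint": ["Diagnosis"] * n,
            "group": group,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_out = SyntheticTruth(
        sample_ids=sample_ids, group=group,
        batch=[f"batch{b}" for b in batch_idx],
        size_factors=size_fac.tolist(), gene_ids=list(gene_ids),
        baseline_mu=np.asarray(baseline).tolist(), is_de=np.asarray(is_de).tolist(),
        true_log2fc=np.asarray(log2fc).tolist(),
        other_log2fc=np.asarray(other_fc).tolist(),
        alpha=np.asarray(alpha).tolist(), is_globin=np.asarray(is_globin).tolist(),
        batch_log2fc=np.asarray(batch_fc).tolist(),
        set_membership={k: sorted(v) for k, v in membership.items()},
    )
    return cm, samples, collection, truth_out


def _draw_gene_sets(rng, config: SimulationConfig, gene_ids, is_de):
    """Random gene sets; the first ``n_enriched_sets`` over-sample DE genes."""
    de_pool = [g for g, d in zip(gene_ids, is_de) if d]
    non_de_pool = [g for g, d in zip(gene_ids, is_de) if not d]
    sets = []
    membership = {}
    for i in range(config.n_gene_sets):
        size = int(rng.integers(config.set_size_low, config.set_size_high + 1))
        enriched = i < config.n_enriched_sets and len(de_pool) > 0
        if enriched:
            n_from_de = min(int(round(size * config.enriched_de_fraction)), len(de_pool))
            chosen = list(rng.choice(de_pool, size=n_from_de, replace=False))
            chosen += list(rng.choice(non_de_pool, size=size - n_from_de, replace=False))
        else:
            chosen = list(rng.choice(non_de_pool, size=min(size, len(non_de_pool)),
                                     replace=False))
        name = f"SET{i:02d}{'_DE' if enriched else ''}"
        membership[name] = set(map(str, chosen))
        sets.append(GeneSet(name, "synthetic gene set", frozenset(map(str, chosen))))
    return GeneSetCollection(sets), membership


def simulate_clinical(truth: SyntheticTruth, config: SimulationConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Clinical covariates conditioned on the planted groups.

    Activity scores are rounded truncated normals with group-specific means
    (higher in endotype A, as observed clinically); categorical covariates
    follow the discovery cohort's observed frequencies.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    freq = {
        "A": {"ema": (["GPA", "uAAV"], [9 / 13, 4 / 13]),
              "anca": (["PR3", "MPO"], [9 / 13, 4 / 13])},
        "B": {"ema": (["GPA", "MPA", "PAN", "uAAV", "UCV"],
                      [5 / 14, 4 / 14, 2 / 14, 2 / 14, 1 / 14]),
              "anca": (["MPO", "PR3", "NEG"], [6 / 14, 5 / 14, 3 / 14])},
        "other": {"ema": (["GPA", "uAAV"], [2 / 3, 1 / 3]),
                  "anca": (["PR3", "MPO"], [1 / 3, 2 / 3])},
    }
    rows = []
    for pid, grp in zip(truth.sample_ids, truth.group):
        mean, sd = config.clinical_pvas[grp]
        score = max(0, int(np.floor(rng.normal(mean, sd) + 0.5))) if sd > 0 else int(mean)
        f = freq[grp]
        rows.append(
            {
                "patient_id": pid, "endotype": grp,
                "ema_class": str(rng.choice(f["ema"][0], p=f["ema"][1])),
                "anca": str(rng.choice(f["anca"][0], p=f["anca"][1])),
                "timepoint": "Diagnosis",
                "sex": str(rng.choice(["F", "M"])),
                "organ_systems": "Renal",
                "activity_score": score,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
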