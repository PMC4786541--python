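"""Poisson-binomial moments and Monte-Carlo chromosome-bias tests.

Under the codon-redundancy null model the motif count of a gene (or gene
set) is a sum of independent Bernoulli variables with unequal probabilities,
i.e. Poisson-binomial with mean ``sum(P)`` and standard deviation
``sqrt(sum(P * (1 - P)))``; observed counts are reported as z-scores.

Chromosome-scale biases compare per-gene z-scores between two gene classes
(leading/lagging strand, coding/template strand, ori/ter half, left/right
replichore, or a gene subset against the whole genome). The observed mean
difference is standardized against a Monte-Carlo null built by randomizing
gene orientations (strand biases) or class labels (positional biases), with
10,000 replicates by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

BIAS_KINDS = (
    "leading_lagging",
    "coding_template",
    "ori_ter",
    "replichore",
    "subset",
)


def poisson_binomial_summary(probabilities) -> tuple[float, float]:
    """Mean and standard deviation of a Poisson-binomial count.

    Empty input gives (0, 0).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        return 0.0, 0.0
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(p.sum()), float(math.sqrt(float((p * (1.0 - p)).sum())))


def zscore(m: float, mean: float, sd: float) -> float:
    """Standard score (m - mean) / sd.

    With sd = 0 the distribution is degenerate: returns 0 when m equals the
    mean and a signed infinity otherwise (an undefined-extreme marker, never
    silently 0).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        if m == mean:
            return 0.0
        return math.inf if m > mean else -math.inf
    return (m - mean) / sd


@dataclass(frozen=True)
class BiasResult:
    """Outcome of one Monte-Carlo bias test.

    ``observed`` is the mean z-score difference between the two gene classes
    (first-named class minus second); ``z_bias`` standardizes it against the
    randomization null.
    """

    bias_kind: str
    observed: float
    null_mean: float
    null_sd: float
    z_bias: float
    n_replicates: int
    n_genes: int
    seed: int | None

    def to_row(self) -> dict:
        return {
            "bias_kind": self.bias_kind,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z_bias": self.z_bias,
            "n_replicates": self.n_replicates,
            "n_genes": self.n_genes,
            "seed": self.seed,
        }


def _finite(a: np.ndarray) -> np.ndarray:
    return a[np.isfinite(a)]


def _sign_flip_null(d: np.ndarray, n_replicates: int, rng) -> tuple[float, float]:
    """Null distribution of mean(d) under independent per-gene sign flips."""
    n = d.size
    stats = np.empty(n_replicates)
    chunk = max(1, int(2e7) // max(n, 1))
    done = 0
    while done < n_replicates:
        c = min(chunk, n_replicates - done)
        signs = rng.integers(0, 2, size=(c, n)) * 2 - 1
        stats[done : done + c] = signs @ d / n
        done += c
    return float(stats.mean()), float(stats.std())


def _label_perm_null(
    v: np.ndarray, n_a: int, n_replicates: int, rng
) -> tuple[float, float]:
    """Null of mean(class A) - mean(class B) under random label assignment."""
    n = v.size
    n_b = n - n_a
    total = v.sum()
    stats = np.empty(n_replicates)
    for r in range(n_replicates):
        idx = rng.permutation(n)[:n_a]
        sa = v[idx].sum()
        stats[r] = sa / n_a - (total - sa) / n_b
    return float(stats.mean()), float(stats.std())


def _subset_null(
    v: np.ndarray, n_sub: int, n_replicates: int, rng
) -> tuple[float, float]:
    """Null of mean(random size-matched subset) - mean(all genes)."""
    n = v.size
    overall = v.mean()
    stats = np.empty(n_replicates)
    for r in range(n_replicates):
        idx = rng.permutation(n)[:n_sub]
        stats[r] = v[idx].mean() - overall
    return float(stats.mean()), float(stats.std())


def bias_test(
    gene_table: pd.DataFrame,
    kind: str,
    n_replicates: int = 10_000,
    seed: int | None = None,
    subset: set[str] | None = None,
    value_col: str = "z_coding",
) -> BiasResult:
    """Monte-Carlo bias z-score for one chromosome-scale comparison.

    ``gene_table`` is the per-gene table from :func:`distamo.genome_scan`
    (one row per gene, with ``z_coding``/``z_template`` and, for positional
    biases, the replication-context columns). Genes with a missing z-score
    in either required quantity are dropped (complete-case). Sign
    convention: positive ``observed`` means the first-named class of the
    bias kind (leading, coding, ori, left, subset) is enriched.

    Strand biases randomize gene orientation (which flips each gene's
    leading/lagging and coding/template difference); positional biases
    shuffle class labels at fixed class sizes; the subset bias resamples
    random gene sets of the subset's size without replacement.
    """
    if kind not in BIAS_KINDS:
        raise ValueError(f"unknown bias kind {kind!r}; expected one of {BIAS_KINDS}")
    rng = np.random.default_rng(seed)

    if kind in ("leading_lagging", "coding_template"):
        zc = gene_table["z_coding"].to_numpy(dtype=float)
        zt = gene_table["z_template"].to_numpy(dtype=float)
        d = zc - zt
        if kind == "leading_lagging":
            lead = gene_table["strand_class"].to_numpy() == "leading"
            # z_leading - z_lagging per gene
            d = np.where(lead, d, -d)
        keep = np.isfinite(d)
        d = d[keep]
        if d.size < 2:
            raise ValueError(f"{kind}: fewer than 2 genes with usable z-scores")
        observed = float(d.mean())
        null_mean, null_sd = _sign_flip_null(d, n_replicates, rng)
    elif kind in ("ori_ter", "replichore"):
        col, first = ("half", "ori") if kind == "ori_ter" else ("replichore", "left")
        v = gene_table[value_col].to_numpy(dtype=float)
        labels = gene_table[col].to_numpy()
        keep = np.isfinite(v)
        v, labels = v[keep], labels[keep]
        in_a = labels == first
        n_a, n_b = int(in_a.sum()), int((~in_a).sum())
        if n_a < 2 or n_b < 2:
            raise ValueError(f"{kind}: each class needs >= 2 genes with z-scores")
        observed = float(v[in_a].mean() - v[~in_a].mean())
        # randomize class membership at fixed sizes, ordered A-first
        null_mean, null_sd = _label_perm_null(
            np.concatenate([v[in_a], v[~in_a]]), n_a, n_replicates, rng
        )
        v = np.concatenate([v[in_a], v[~in_a]])
    else:  # subset
        if not subset:
            raise ValueError("subset bias requires a non-empty subset of gene ids")
        v = gene_table[value_col].to_numpy(dtype=float)
        in_sub = gene_table["gene_id"].isin(subset).to_numpy()
        keep = np.isfinite(v)
        v, in_sub = v[keep], in_sub[keep]
        n_sub = int(in_sub.sum())
        if n_sub < 2 or v.size - n_sub < 2:
            raise ValueError("subset bias: subset and complement each need >= 2 genes")
        observed = float(v[in_sub].mean() - v.mean())
        null_mean, null_sd = _subset_null(v, n_sub, n_replicates, rng)

    z_bias = zscore(observed, null_mean, null_sd)
    n_genes = int(d.size) if kind in ("leading_lagging", "coding_template") else int(v.size)
    return BiasResult(
        bias_kind=kind,
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_bias=z_bias,
        n_replicates=n_replicates,
        n_genes=n_genes,
        seed=seed,
    )
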