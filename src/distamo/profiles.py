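"""Chromosome-wide motif-distribution profiles.

Sliding-window rings: merged-set z-scores in circular windows of 50-500 kb
(50 kb steps by default, ten rings), the standard whole-chromosome view.
Scaled averaging: per-gene z-scores of several genomes mapped onto 1000
bins of scaled circular distance from the replication origin (ori at bin
0/1000) and averaged across genomes with the standard error of the mean.

Window membership is by gene midpoint, and merging uses the additivity of
the Poisson-binomial sufficient statistics (sum P, sum P(1-P), m), so rings
are computed from the per-gene scan table without re-enumerating windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_WINDOW_SIZES = tuple(range(50_000, 500_001, 50_000))


@dataclass(frozen=True)
class WindowRing:
    """One sliding-window ring: window centers and merged z-scores."""

    window_size: int
    step: int
    centers: np.ndarray
    z: np.ndarray
    n_genes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_size": self.window_size,
                "window_center": self.centers,
                "n_genes": self.n_genes,
                "z": self.z,
            }
        )


@dataclass(frozen=True)
class ScaledProfile:
    """Ori-anchored, length-scaled average motif profile over genomes."""

    n_bins: int
    mean: np.ndarray
    sem: np.ndarray
    n_genomes_per_bin: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "mean_z": self.mean,
                "sem": self.sem,
                "n_genomes": self.n_genomes_per_bin,
            }
        )


def _merged_z(m: np.ndarray, m_bar: np.ndarray, s2: np.ndarray, sel: np.ndarray):
    if not sel.any():
        return math.nan
    mm, mb, ss = m[sel].sum(), m_bar[sel].sum(), s2[sel].sum()
    if ss == 0:
        return 0.0 if mm == mb else math.copysign(math.inf, mm - mb)
    return (mm - mb) / math.sqrt(ss)


def sliding_window_rings(
    gene_table: pd.DataFrame,
    length: int,
    window_sizes=DEFAULT_WINDOW_SIZES,
    step: int | None = None,
    strand_mode: str = "coding",
) -> list[WindowRing]:
    """Merged z-score in circular sliding windows, one ring per window size.

    ``gene_table`` is the per-gene table from :func:`distamo.genome_scan`.
    Each window's z is the merged-set z of all genes whose midpoint falls in
    the circular interval [center - w/2, center + w/2); windows with no
    usable gene get NaN. Step defaults to window_size / 10.
    """
    mid = gene_table["midpoint"].to_numpy(dtype=float) % length
    m = gene_table[f"m_{strand_mode}"].to_numpy(dtype=float)
    m_bar = gene_table[f"m_bar_{strand_mode}"].to_numpy(dtype=float)
    s2 = gene_table[f"s_{strand_mode}"].to_numpy(dtype=float) ** 2
    usable = gene_table[f"n_windows_{strand_mode}"].to_numpy() > 0
    rings = []
    for w in window_sizes:
        if w > length:
            raise ValueError(f"window size {w} exceeds replicon length {length}")
        st = step if step is not None else max(1, w // 10)
        centers = np.arange(0, length, st)
        z = np.empty(centers.size)
        ng = np.empty(centers.size, dtype=int)
        for i, c in enumerate(centers):
            inside = ((mid - (c - w / 2)) % length) < w
            sel = inside & usable
            ng[i] = int(sel.sum())
            z[i] = _merged_z(m, m_bar, s2, sel)
        rings.append(WindowRing(window_size=w, step=st, centers=centers, z=z, n_genes=ng))
    return rings


def scale_and_average(
    gene_tables: list[pd.DataFrame],
    ori_positions: list[int],
    lengths: list[int],
    n_bins: int = 1000,
    strand_mode: str = "coding",
) -> ScaledProfile:
    """Average per-gene z-scores across genomes on a scaled circular axis.

    Each gene is assigned to bin ``floor(n_bins * ((midpoint - ori) mod L)
    / L)``; per genome the bin value is the mean z of its genes, and bins
    are then averaged across genomes with SEM (0 where a single genome
    contributes). Anchoring at ori makes the profile invariant to the
    arbitrary start point of the sequence coordinates.
    """
    if not gene_tables:
        raise ValueError("need at least one genome")
    if not (len(gene_tables) == len(ori_positions) == len(lengths)):
        raise ValueError("gene_tables, ori_positions and lengths must align")
    per_genome = np.full((len(gene_tables), n_bins), np.nan)
    for g, (tab, ori, L) in enumerate(zip(gene_tables, ori_positions, lengths)):
        z = tab[f"z_{strand_mode}"].to_numpy(dtype=float)
        mid = tab["midpoint"].to_numpy(dtype=float)
        keep = np.isfinite(z)
        bins = np.floor(n_bins * (((mid[keep] - ori) % L) / L)).astype(int)
        bins = np.clip(bins, 0, n_bins - 1)
        sums = np.bincount(bins, weights=z[keep], minlength=n_bins)
        cnts = np.bincount(bins, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            per_genome[g] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    n_contrib = np.sum(np.isfinite(per_genome), axis=0)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / ddof slices
        mean = np.nanmean(per_genome, axis=0)
        sd = np.nanstd(per_genome, axis=0, ddof=1)
    sem = np.where(n_contrib > 1, sd / np.sqrt(np.maximum(n_contrib, 1)), 0.0)
    sem[n_contrib == 0] = np.nan
    return ScaledProfile(n_bins=n_bins, mean=mean, sem=sem, n_genomes_per_bin=n_contrib)


def render_rings(
    rings: list[WindowRing],
    length: int,
    highlight_threshold: float = 2.0,
    gene_positions: np.ndarray | None = None,
    ori_position: int | None = None,
    title: str | None = None,
):
    """Circular ring plot of sliding-window z-scores.

    Rings run outside-in from the smallest to the largest window (finest
    granularity outermost); the diverging color map saturates red at
    z >= +threshold and blue at z <= -threshold. Returns the matplotlib
    figure (save with ``fig.savefig``).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    norm = colors.Normalize(vmin=-highlight_threshold, vmax=highlight_threshold)
    cmap = matplotlib.colormaps["RdBu_r"]
    n_rings = len(rings)
    r0, band = 1.0, 0.6 / max(n_rings, 1)
    for i, ring in enumerate(sorted(rings, key=lambda r: r.window_size)):
        radius = r0 - i * band
        theta = 2 * np.pi * ring.centers / length
        width = 2 * np.pi * ring.step / length
        vals = np.clip(ring.z, -highlight_threshold, highlight_threshold)
        cols = cmap(norm(np.nan_to_num(vals)))
        cols[~np.isfinite(ring.z)] = (0.85, 0.85, 0.85, 1.0)
        ax.bar(theta, band * 0.9, width=width, bottom=radius - band, color=cols,
               align="edge", linewidth=0)
    if gene_positions is not None:
        theta = 2 * np.pi * (np.asarray(gene_positions) % length) / length
        ax.plot(theta, np.full(theta.shape, r0 + 0.03), ".", ms=2, color="black")
    if ori_position is not None:
        ax.plot([2 * np.pi * ori_position / length] * 2, [r0 - n_rings * band, r0 + 0.06],
                color="green", lw=1.5)
    ax.set_ylim(0, r0 + 0.1)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.6,
                 label="z-score")
    return fig


def render_scaled_profile(profile: ScaledProfile, title: str | None = None):
    """Line plot of the scaled average profile with its SEM band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(profile.n_bins)
    ax.plot(x, profile.mean, color="C0", lw=1.2)
    ax.fill_between(
        x, profile.mean - profile.sem, profile.mean + profile.sem,
        color="C0", alpha=0.3, linewidth=0,
    )
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel("scaled chromosome position (ori at 0/1000)")
    ax.set_ylabel("mean z-score")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
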