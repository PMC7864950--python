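"""Mapping-by-sequencing: SNP indexes from pooled allele counts and
detection of the linkage cluster that localizes the causal gene.

The SNP index at a site is alt_count / depth — the mutant allele frequency
in the phenotype-selected pool. A recessive causal mutation sits where the
index reaches 1 in the homozygous-mutant pool, visible as a contiguous
cluster of high-index EMS SNPs on one chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "LinkageCluster",
    "compute_snp_index",
    "filter_ems_type",
    "detect_linkage_clusters",
    "sliding_window_profile",
    "candidate_region",
]

DEFAULT_MIN_DEPTH = 10
DEFAULT_INDEX_THRESHOLD = 0.95
DEFAULT_MIN_SNPS = 3
DEFAULT_MAX_GAP_BP = 2_000_000


@dataclass(frozen=True)
class LinkageCluster:
    """A maximal run of consecutive high-index SNPs — the mapping signal."""

    interval: GenomicInterval
    n_snps: int
    min_index: float
    mean_index: float
    positions: tuple[int, ...]

    def contains(self, chromosome: str, position: int) -> bool:
        return self.interval.contains(chromosome, position)


def compute_snp_index(
    counts: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH
) -> pd.DataFrame:
    """SNP-index track: one record per site with depth >= min_depth,
    snp_index = alt_count/depth, sorted by (chrom, pos)."""
    if ((counts["alt_count"] < 0) | (counts["alt_count"] > counts["depth"])).any():
        raise ValueError("invalid counts: need 0 <= alt_count <= depth")
    track = counts[counts["depth"] >= min_depth].copy()
    if track.empty:
        logger.warning("compute_snp_index: every site filtered at min_depth=%d",
                       min_depth)
    track["snp_index"] = track["alt_count"] / track["depth"]
    track = track.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return track


def filter_ems_type(track: pd.DataFrame) -> pd.DataFrame:
    """Keep the canonical EMS transitions: G→A and C→T only."""
    keep = ((track["ref"] == "G") & (track["alt"] == "A")) | (
        (track["ref"] == "C") & (track["alt"] == "T")
    )
    return track[keep].reset_index(drop=True)


def detect_linkage_clusters(
    track: pd.DataFrame,
    index_threshold: float = DEFAULT_INDEX_THRESHOLD,
    min_snps: int = DEFAULT_MIN_SNPS,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
) -> list[LinkageCluster]:
    """Maximal runs of consecutive records with index >= threshold.

    Run members share a chromosome and adjacent members are <= max_gap_bp
    apart; runs shorter than min_snps are dropped. Clusters are ranked by
    (n_snps desc, mean_index desc, chromosome asc, start asc).
    """
    clusters: list[LinkageCluster] = []
    if track.empty:
        return clusters
    current: list[tuple[int, float]] = []  # (pos, index)
    current_chrom: str | None = None

    def flush() -> None:
        if len(current) >= min_snps:
            positions = tuple(p for p, _ in current)
            indexes = np.array([x for _, x in current])
            clusters.append(
                LinkageCluster(
                    interval=GenomicInterval(current_chrom, positions[0], positions[-1]),
                    n_snps=len(current),
                    min_index=float(indexes.min()),
                    mean_index=float(indexes.mean()),
                    positions=positions,
                )
            )

    for row in track.itertuples(index=False):
        qualifies = row.snp_index >= index_threshold
        breaks = (
            row.chrom != current_chrom
            or (current and row.pos - current[-1][0] > max_gap_bp)
        )
        if not qualifies or breaks:
            flush()
            current = []
        if qualifies:
            current_chrom = row.chrom
            current.append((row.pos, row.snp_index))
    flush()

    clusters.sort(
        key=lambda c: (
            -c.n_snps,
            -c.mean_index,
            c.interval.chromosome,
            c.interval.start,
        )
    )
    return clusters


def sliding_window_profile(
    track: pd.DataFrame, window_bp: int, step_bp: int
) -> pd.DataFrame:
    """Tile each chromosome with windows and average the member indexes.

    Windows run from position 1 to the last SNP of the chromosome; empty
    windows are reported with n_snps 0 and NaN mean (undefined).
    """
    if window_bp < step_bp:
        raise ValueError("window must be >= step")
    rows = []
    for chrom, sub in track.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        idx = sub["snp_index"].to_numpy()
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window_bp - 1
            mask = (pos >= start) & (pos <= end)
            n = int(mask.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": n,
                    "mean_index": float(idx[mask].mean()) if n else float("nan"),
                }
            )
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "mean_index"])


def candidate_region(
    clusters: list[LinkageCluster], margin_bp: int = 50_000
) -> GenomicInterval:
    """The top-ranked cluster's interval, padded by margin_bp (clipped at 1)."""
    if not clusters:
        raise ValueError("no linkage clusters detected: mapping failed")
    top = clusters[0].interval
    return GenomicInterval(
        top.chromosome, max(1, top.start - margin_bp), top.end + margin_bp
    )


def clusters_to_frame(clusters: list[LinkageCluster]) -> pd.DataFrame:
    """Tabular view for TSV output."""
    return pd.DataFrame(
        [
            {
                "chrom": c.interval.chromosome,
                "start": c.interval.start,
                "end": c.interval.end,
                "n_snps": c.n_snps,
                "min_index": c.min_index,
                "mean_index": c.mean_index,
            }
            for c in clusters
        ],
        columns=["chrom", "start", "end", "n_snps", "min_index", "mean_index"],
    )


def plot_index_track(track: pd.DataFrame, path, clusters=None) -> None:
    """Per-chromosome SNP-index scatter (position vs index)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted(track["chrom"].unique())
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(4 * len(chroms), 3), sharey=True, squeeze=False
    )
    for ax, chrom in zip(axes[0], chroms):
        sub = track[track["chrom"] == chrom]
        ax.scatter(sub["pos"] / 1e6, sub["snp_index"], s=12, color="tab:blue")
        if clusters:
            for c in clusters:
                if c.interval.chromosome == chrom:
                    ax.axvspan(
                        c.interval.start / 1e6,
                        c.interval.end / 1e6,
                        color="tab:red",
                        alpha=0.2,
                    )
        ax.set_title(chrom)
        ax.set_xlabel("position (Mb)")
        ax.set_ylim(-0.05, 1.05)
    axes[0][0].set_ylabel("SNP index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
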