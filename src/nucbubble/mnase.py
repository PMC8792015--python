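"""MNase fragment occupancy: size filtering, 1-bp coverage tracks,
TSS-oriented matrices and aggregate profiles, IP/control fold enrichment,
and windowed occupancy differences.

All genomic intervals are 0-based half-open (BED convention).  Position
+0 in TSS-relative coordinates is the first transcribed base; positive
offsets run in the direction of transcription, so minus-strand rows are
reversed in genomic space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "GeneAnchor",
    "FragmentSet",
    "OccupancyMatrix",
    "filter_by_insert_size",
    "occupancy_track",
    "tss_matrix",
    "aggregate_profile",
    "gene_enrichment",
    "window_occupancy_difference",
]


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int
    sample: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"fragment {self.chrom}:{self.start}-{self.end}: start >= end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnchor:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


class FragmentSet:
    """Fragments for one sample, held per chromosome as sorted arrays."""

    def __init__(self, fragments: Iterable[Fragment] | pd.DataFrame, sample: str = ""):
        if isinstance(fragments, pd.DataFrame):
            df = fragments[["chrom", "start", "end"]].copy()
        else:
            df = pd.DataFrame(
                [(f.chrom, f.start, f.end) for f in fragments],
                columns=["chrom", "start", "end"],
            )
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("all fragments require start < end")
        self.sample = sample
        self.df = df.astype({"start": np.int64, "end": np.int64}) if len(df) else df
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            s = np.sort(sub["start"].to_numpy())
            e = np.sort(sub["end"].to_numpy())
            self._by_chrom[str(chrom)] = (s, e)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(sorted starts, independently sorted ends) for one chromosome."""
        return self._by_chrom.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        """Number of fragments overlapping [start, end)."""
        s, e = self.chrom_arrays(chrom)
        if s.size == 0:
            return 0
        # overlap iff frag.start < end and frag.end > start
        return int(np.searchsorted(s, end, side="left") - np.searchsorted(e, start, side="right"))


@dataclass
class OccupancyMatrix:
    """Genes x TSS-relative positions coverage matrix, window [-W, W)."""

    genes: list[str]
    window_bp: int
    values: np.ndarray  # (n_genes, 2 * window_bp)
    normalization: str = "raw"
    clipped: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (len(self.genes), 2 * self.window_bp):
            raise ValueError("values must be (n_genes, 2 * window_bp)")
        if np.any(v < 0):
            raise ValueError("coverage values must be >= 0")
        self.values = v
        if not self.clipped:
            self.clipped = [False] * len(self.genes)

    @property
    def positions(self) -> np.ndarray:
        """TSS-relative position of each column (transcription direction)."""
        return np.arange(-self.window_bp, self.window_bp)


def filter_by_insert_size(frags: FragmentSet, min_bp: int = 120, max_bp: int = 180) -> FragmentSet:
    """Keep mononucleosome-sized inserts: min_bp <= length <= max_bp."""
    if min_bp > max_bp:
        raise ValueError("min_bp must be <= max_bp")
    ln = frags.df["end"] - frags.df["start"]
    return FragmentSet(frags.df[(ln >= min_bp) & (ln <= max_bp)], sample=frags.sample)


def occupancy_track(frags: FragmentSet, chrom: str, region: tuple[int, int]) -> np.ndarray:
    """Per-bp fragment coverage over a half-open region, 1-bp bins.

    coverage[i] = number of fragments overlapping base region[0] + i.
    """
    start, end = region
    if start >= end:
        raise ValueError("region must be half-open with start < end")
    n = end - start
    cov = np.zeros(n + 1, dtype=np.int64)
    sub = frags.df[frags.df["chrom"] == chrom]
    if len(sub):
        s = np.clip(sub["start"].to_numpy() - start, 0, n)
        e = np.clip(sub["end"].to_numpy() - start, 0, n)
        keep = s < e
        np.add.at(cov, s[keep], 1)
        np.add.at(cov, e[keep], -1)
    return np.cumsum(cov)[:n]


def tss_matrix(
    frags: FragmentSet,
    anchors: Sequence[GeneAnchor],
    window_bp: int = 1000,
) -> OccupancyMatrix:
    """TSS-centered, transcription-oriented coverage matrix at 1-bp bins.

    Column +k is k bp downstream of the TSS in the transcription
    direction; minus-strand rows are therefore reversed in genomic
    coordinates.  Row order follows the input anchor list.  Windows that
    would cross position 0 of the chromosome are zero-padded and flagged.
    """
    if not anchors:
        raise ValueError("anchors must be nonempty")
    w = window_bp
    rows, clipped = [], []
    for a in anchors:
        if a.strand == "+":
            g_lo, g_hi = a.tss - w, a.tss + w
        else:
            g_lo, g_hi = a.tss - w + 1, a.tss + w + 1
        lo = max(g_lo, 0)
        row = np.zeros(2 * w, dtype=float)
        if lo < g_hi:
            cov = occupancy_track(frags, a.chrom, (lo, g_hi))
            row[lo - g_lo :] = cov
        clipped.append(lo != g_lo)
        if a.strand == "-":
            row = row[::-1]
        rows.append(row)
    return OccupancyMatrix(
        genes=[a.gene_id for a in anchors],
        window_bp=w,
        values=np.vstack(rows),
        normalization="raw",
        clipped=clipped,
    )


def normalize_rows(m: OccupancyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to unit mean; returns (scaled values, nonzero-row mask)."""
    row_mean = m.values.mean(axis=1)
    nonzero = row_mean > 0
    scaled = np.zeros_like(m.values)
    scaled[nonzero] = m.values[nonzero] / row_mean[nonzero, None]
    return scaled, nonzero


def aggregate_profile(m: OccupancyMatrix, normalization: str = "per-gene-mean") -> np.ndarray:
    """Aggregate per-position occupancy across genes.

    Default: scale each row to unit mean over the window (all-zero rows
    excluded), then take the column-wise mean.  normalization="none"
    averages raw rows.
    """
    if m.values.shape[0] < 1:
        raise ValueError("empty matrix")
    if normalization == "none":
        return m.values.mean(axis=0)
    if normalization != "per-gene-mean":
        raise ValueError(f"unknown normalization {normalization!r}")
    scaled, nonzero = normalize_rows(m)
    if not nonzero.any():
        return np.zeros(m.values.shape[1])
    return scaled[nonzero].mean(axis=0)


def gene_enrichment(
    ip: FragmentSet,
    control: FragmentSet,
    anchors: Sequence[GeneAnchor],
    window_bp: int = 1000,
    fold_threshold: float = 4.7,
) -> pd.DataFrame:
    """Library-size-normalized IP/control fold enrichment per TSS window.

    fold = ((ip count + 1) / ip library size) / ((control count + 1) /
    control library size), counting fragments overlapping the +/- window
    around each TSS.  Genes with fold strictly above ``fold_threshold``
    are flagged enriched.
    """
    n_ip, n_ctl = len(ip), len(control)
    if n_ip == 0 or n_ctl == 0:
        raise ValueError("both samples must be nonempty")
    recs = []
    for a in anchors:
        ws, we = max(a.tss - window_bp, 0), a.tss + window_bp
        c_ip = ip.count_overlapping(a.chrom, ws, we)
        c_ctl = control.count_overlapping(a.chrom, ws, we)
        fold = ((c_ip + 1) / n_ip) / ((c_ctl + 1) / n_ctl)
        recs.append((a.gene_id, c_ip, c_ctl, fold, fold > fold_threshold))
    return pd.DataFrame(
        recs, columns=["gene_id", "ip_count", "control_count", "fold", "enriched"]
    )


def window_occupancy_difference(
    a: OccupancyMatrix,
    b: OccupancyMatrix,
    windows: Sequence[tuple[int, int]] = ((100, 200), (-200, -100)),
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bootstrap comparison of mean normalized occupancy in TSS-relative windows.

    Both matrices are row-normalized to unit mean; for each half-open
    window (relative to the TSS in transcription direction) the effect is
    mean_a - mean_b of per-gene window means, with a two-sided percentile
    bootstrap p-value from gene-level resampling (independent in each
    matrix).  Matrices with different gene sets are compared on the
    intersection.
    """
    common = [g for g in a.genes if g in set(b.genes)]
    if not common:
        raise ValueError("empty gene intersection")
    ia = [a.genes.index(g) for g in common]
    ib = [b.genes.index(g) for g in common]
    va, _ = normalize_rows(a)
    vb, _ = normalize_rows(b)
    va, vb = va[ia], vb[ib]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for lo, hi in windows:
        if not (-a.window_bp <= lo < hi <= a.window_bp):
            raise ValueError(f"window ({lo}, {hi}) outside matrix range")
        ca, cb = lo + a.window_bp, hi + a.window_bp
        ga = va[:, ca:cb].mean(axis=1)
        gb = vb[:, lo + b.window_bp : hi + b.window_bp].mean(axis=1)
        effect = float(ga.mean() - gb.mean())
        na, nb = ga.size, gb.size
        boot = (
            ga[rng.integers(0, na, size=(n_boot, na))].mean(axis=1)
            - gb[rng.integers(0, nb, size=(n_boot, nb))].mean(axis=1)
        )
        p_lo = (np.sum(boot <= 0.0) + 1) / (n_boot + 1)
        p_hi = (np.sum(boot >= 0.0) + 1) / (n_boot + 1)
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        out.append(((lo, hi), effect, float(p)))
    return pd.DataFrame(out, columns=["window", "effect", "p_value"])
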