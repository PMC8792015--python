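"""Bubble segmentation and nucleosome calling from distance profiles.

A base pair is labeled single-stranded when its inter-strand distance
exceeds a threshold; maximal runs of single-stranded bases form
"bubbles"; a bubble longer than 90 bp is scored as one nucleosome.
Fused bubbles (two adjacent nucleosomes merged into one long bubble)
still count as a single nucleosome under the default policy, and are
flagged for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .geometry import DistanceProfile

__all__ = [
    "Bubble",
    "BubbleCall",
    "calibrate_threshold",
    "label_single_stranded",
    "segment_bubbles",
    "call_nucleosomes",
]

NUCLEOSOME_MIN_LEN_BP = 90  # strictly-greater-than rule
FUSION_SUSPECT_LEN_BP = 240  # ~1.6 nucleosome footprints


@dataclass(frozen=True)
class Bubble:
    """A contiguous single-stranded span, 0-based half-open."""

    molecule_id: str
    start_bp: int
    end_bp: int
    is_nucleosome: bool = False
    is_fusion_suspect: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start_bp < self.end_bp):
            raise ValueError("require 0 <= start_bp < end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class BubbleCall:
    """Per-molecule bubble list with the nucleosome count."""

    molecule_id: str
    bubbles: tuple[Bubble, ...]
    nucleosome_count: int
    threshold_px: float
    fusion_policy: str = "single"

    def __post_init__(self) -> None:
        starts = [b.start_bp for b in self.bubbles]
        if starts != sorted(starts):
            raise ValueError("bubbles must be sorted by start")
        for prev, nxt in zip(self.bubbles, self.bubbles[1:]):
            if prev.end_bp > nxt.start_bp:
                raise ValueError("bubbles must be disjoint")


def _otsu_midplateau(values: np.ndarray, nbins: int) -> float:
    """Two-class Otsu split with mid-plateau tie-breaking.

    Between-class variance is constant across an empty gap between two
    well-separated modes, so the argmax is a plateau; taking its middle
    places the threshold mid-gap rather than hugging one mode.
    """
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(hist)[:-1].astype(float)
    w1 = hist.sum() - w0
    s0 = np.cumsum(hist * centers)[:-1]
    total = (hist * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = s0 / w0
        m1 = (total - s0) / w1
        var = w0 * w1 * (m0 - m1) ** 2
    var[(w0 == 0) | (w1 == 0)] = -np.inf
    vmax = var.max()
    if not np.isfinite(vmax) or vmax <= 0.0:
        raise ValueError(
            "degenerate distance distribution (zero between-class variance); "
            "supply a fixed threshold"
        )
    plateau = np.flatnonzero(var == vmax)
    cut = int(plateau[plateau.size // 2])
    return float(edges[cut + 1])


def calibrate_threshold(
    profiles: Iterable[DistanceProfile],
    method: str = "otsu",
    fixed_value: float | None = None,
    nbins: int = 256,
) -> float:
    """Empirical single-stranded distance threshold from pooled profiles.

    Default is a two-class Otsu split of the pooled distance histogram;
    a fixed threshold can be supplied instead (method="fixed").
    """
    if method == "fixed":
        if fixed_value is None or fixed_value <= 0:
            raise ValueError("fixed threshold requires a positive value")
        return float(fixed_value)
    if method != "otsu":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([p.distances_px for p in profiles])
    if pooled.size < 100:
        raise ValueError("need >=100 pooled base records to calibrate")
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi - lo <= 0 or np.std(pooled) == 0.0:
        raise ValueError(
            "degenerate distance distribution (no separation between classes); "
            "supply a fixed threshold"
        )
    thr = _otsu_midplateau(pooled, nbins)
    if not (lo < thr < hi):  # pathological binning
        raise ValueError(
            "calibration failed to find a threshold strictly inside the pooled "
            "range; supply a fixed threshold"
        )
    return thr


def label_single_stranded(profile: DistanceProfile, threshold_px: float) -> np.ndarray:
    """Boolean per-bp vector: True iff distance strictly exceeds the threshold."""
    if threshold_px <= 0:
        raise ValueError("threshold_px must be positive")
    return profile.distances_px > threshold_px


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) spans."""
    lab = np.asarray(labels, dtype=bool)
    if lab.size == 0:
        return []
    padded = np.concatenate([[False], lab, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def segment_bubbles(
    labels: np.ndarray,
    molecule_id: str = "",
    close_gaps_bp: int = 2,
    drop_runs_bp: int = 3,
) -> list[Bubble]:
    """Segment a label vector into bubbles with optional morphological cleanup.

    Gaps of duplex label <= close_gaps_bp between two bubbles are closed,
    then runs of length <= drop_runs_bp are dropped.  Setting both to 0
    gives the literal run-length behavior.
    """
    lab = np.asarray(labels, dtype=bool).copy()
    if close_gaps_bp > 0:
        for gs, ge in _runs(~lab):
            # only interior gaps (flanked by single-stranded on both sides)
            if gs > 0 and ge < lab.size and (ge - gs) <= close_gaps_bp:
                lab[gs:ge] = True
    spans = _runs(lab)
    if drop_runs_bp > 0:
        spans = [(s, e) for s, e in spans if (e - s) > drop_runs_bp]
    return [Bubble(molecule_id, s, e) for s, e in spans]


def call_nucleosomes(
    bubbles: Sequence[Bubble],
    threshold_px: float,
    min_len_bp: int = NUCLEOSOME_MIN_LEN_BP,
    fusion_policy: str = "single",
    fusion_suspect_len_bp: int = FUSION_SUSPECT_LEN_BP,
    molecule_id: str | None = None,
) -> BubbleCall:
    """Score bubbles as nucleosomes and count them per molecule.

    A bubble is a nucleosome iff its length strictly exceeds ``min_len_bp``.
    Bubbles longer than ``fusion_suspect_len_bp`` are flagged as possible
    fusions of adjacent nucleosomes; under policy "single" (default) a
    fused bubble still counts as exactly one nucleosome.  Policy "divide"
    (sensitivity analysis only) counts floor(length / 147) per fused bubble.
    """
    if fusion_policy not in ("single", "divide"):
        raise ValueError(f"unknown fusion_policy {fusion_policy!r}")
    mol = molecule_id if molecule_id is not None else (bubbles[0].molecule_id if bubbles else "")
    scored: list[Bubble] = []
    count = 0
    for b in sorted(bubbles, key=lambda b: b.start_bp):
        is_nuc = b.length_bp > min_len_bp
        suspect = b.length_bp > fusion_suspect_len_bp
        scored.append(
            Bubble(b.molecule_id or mol, b.start_bp, b.end_bp, is_nuc, suspect)
        )
        if is_nuc:
            if fusion_policy == "divide" and suspect:
                count += max(1, b.length_bp // 147)
            else:
                count += 1
    return BubbleCall(mol, tuple(scored), count, float(threshold_px), fusion_policy)


def call_molecule(
    profile: DistanceProfile,
    threshold_px: float,
    close_gaps_bp: int = 2,
    drop_runs_bp: int = 3,
    min_len_bp: int = NUCLEOSOME_MIN_LEN_BP,
    fusion_policy: str = "single",
) -> BubbleCall:
    """Label -> segment -> call, for one molecule's distance profile."""
    labels = label_single_stranded(profile, threshold_px)
    bubbles = segment_bubbles(
        labels, profile.molecule_id, close_gaps_bp=close_gaps_bp, drop_runs_bp=drop_runs_bp
    )
    return call_nucleosomes(
        bubbles,
        threshold_px,
        min_len_bp=min_len_bp,
        fusion_policy=fusion_policy,
        molecule_id=profile.molecule_id,
    )
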