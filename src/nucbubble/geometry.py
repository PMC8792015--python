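"""Strand-pair geometry: orientation, base-pair calibration, inter-strand distance profiles.

A traced molecule is two ordered 2D polylines (one per strand) in pixel
units.  The first point of each polyline marks the traced "end" of the
molecule, so the two strands can be co-oriented by endpoint matching.
Base positions are assigned along each strand by arc length using the
known template length, and the per-base-pair inter-strand distance is the
Euclidean distance from each base point to the closest point on the
opposite polyline (point-to-segment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "StrandTrace",
    "MoleculeTrace",
    "DistanceProfile",
    "OrientationAmbiguousError",
    "orient_strands",
    "assign_base_positions",
    "pair_and_profile",
]


class OrientationAmbiguousError(ValueError):
    """Raised when the two endpoint pairings are indistinguishable."""


@dataclass(frozen=True)
class StrandTrace:
    """One traced strand: ordered (x, y) points in pixels.

    The first point is the designated molecule end.  Consecutive points
    must be distinct so arc length is strictly increasing.
    """

    strand_id: str
    points: np.ndarray  # shape (n, 2), float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError(f"strand {self.strand_id}: need >=2 (x, y) points")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError(f"strand {self.strand_id}: consecutive duplicate points")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    def reversed(self) -> "StrandTrace":
        return StrandTrace(self.strand_id, self.points[::-1].copy())


@dataclass(frozen=True)
class MoleculeTrace:
    """A pair of strand traces plus the known template length in bp."""

    molecule_id: str
    strand_a: StrandTrace
    strand_b: StrandTrace
    template_len_bp: int

    def __post_init__(self) -> None:
        if self.template_len_bp <= 0:
            raise ValueError("template_len_bp must be positive")


@dataclass(frozen=True)
class DistanceProfile:
    """Per-base-pair inter-strand distance for one molecule."""

    molecule_id: str
    distances_px: np.ndarray  # shape (template_len_bp,), float, >= 0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_px, dtype=float)
        if d.ndim != 1 or d.size == 0:
            raise ValueError("distances_px must be a nonempty 1D array")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "distances_px", d)

    @property
    def template_len_bp(self) -> int:
        return self.distances_px.size


def orient_strands(m: MoleculeTrace, ambiguity_margin_px: float = 1e-6) -> MoleculeTrace:
    """Co-orient the two strands so they run in the same template direction.

    The orientation minimizing the summed endpoint-to-endpoint distance
    (start-start + end-end) wins; if the two pairings differ by less than
    ``ambiguity_margin_px`` the molecule is rejected as ambiguous.
    """
    a0, a1 = m.strand_a.points[0], m.strand_a.points[-1]
    b0, b1 = m.strand_b.points[0], m.strand_b.points[-1]
    keep = np.hypot(*(a0 - b0)) + np.hypot(*(a1 - b1))
    flip = np.hypot(*(a0 - b1)) + np.hypot(*(a1 - b0))
    if abs(keep - flip) < ambiguity_margin_px:
        raise OrientationAmbiguousError(
            f"molecule {m.molecule_id}: endpoint pairings differ by "
            f"{abs(keep - flip):.3g} px (< margin {ambiguity_margin_px:g})"
        )
    if flip < keep:
        return replace(m, strand_b=m.strand_b.reversed())
    return m


def _cumulative_arc(points: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def assign_base_positions(s: StrandTrace, template_len_bp: int) -> np.ndarray:
    """Place each base at arc length (k + 0.5) * scale along the strand.

    scale = total arc length / template_len_bp, i.e. the calibration of
    pixel distance to base pairs from the known template length.  Returns
    an array of shape (template_len_bp, 2).
    """
    cum = _cumulative_arc(s.points)
    total = cum[-1]
    if total <= 0.0:
        raise ValueError(f"strand {s.strand_id}: zero total arc length")
    scale = total / template_len_bp
    targets = (np.arange(template_len_bp) + 0.5) * scale
    x = np.interp(targets, cum, s.points[:, 0])
    y = np.interp(targets, cum, s.points[:, 1])
    return np.column_stack([x, y])


def _point_to_polyline_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each query point to a polyline (point-to-segment).

    Exact: a cheap vertex-distance prescreen bounds which segments can
    hold the closest point (a segment whose nearer endpoint is farther
    than best-vertex-distance + longest-segment-length cannot win), and
    point-to-segment distance is evaluated only on those candidates.
    """
    p0 = poly[:-1]
    d = np.diff(poly, axis=0)  # (S, 2)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    seg_len_max = float(np.sqrt(seg_len2.max()))
    dv2 = cdist(points, poly, "sqeuclidean")  # (Q, V) squared vertex distances
    d_vstar = np.sqrt(dv2.min(axis=1))
    vseg_min2 = np.minimum(dv2[:, :-1], dv2[:, 1:])
    qi, si = np.nonzero(vseg_min2 <= ((d_vstar + seg_len_max) ** 2)[:, None])
    diff = points[qi] - p0[si]
    t = np.clip(np.einsum("ij,ij->i", diff, d[si]) / seg_len2[si], 0.0, 1.0)
    proj = diff - t[:, None] * d[si]
    dist2 = np.einsum("ij,ij->i", proj, proj)
    out = np.full(points.shape[0], np.inf)
    np.minimum.at(out, qi, dist2)
    return np.sqrt(out)


def pair_and_profile(
    m: MoleculeTrace,
    mode: str = "reference",
    arc_mismatch_warn: float = 0.15,
) -> DistanceProfile:
    """Per-base inter-strand distance profile of an oriented molecule.

    mode="reference" (default): anchor bases on the longer-arc strand and
    measure the closest distance to the opposite polyline.
    mode="symmetric": average of the A-anchored and B-anchored profiles.

    Molecules whose strand arc lengths differ by more than
    ``arc_mismatch_warn`` (fractional) are likely tracing errors; the
    profile is still computed but the caller can pre-screen with
    :func:`arc_length_mismatch`.
    """
    t = m.template_len_bp
    a, b = m.strand_a, m.strand_b
    if mode == "reference":
        if b.arc_length > a.arc_length:
            a, b = b, a
        base_pts = assign_base_positions(a, t)
        dist = _point_to_polyline_distances(base_pts, b.points)
    elif mode == "symmetric":
        da = _point_to_polyline_distances(assign_base_positions(a, t), b.points)
        db = _point_to_polyline_distances(assign_base_positions(b, t), a.points)
        dist = 0.5 * (da + db)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DistanceProfile(m.molecule_id, dist)


def arc_length_mismatch(m: MoleculeTrace) -> float:
    """Fractional arc-length disagreement between the two strands."""
    la, lb = m.strand_a.arc_length, m.strand_b.arc_length
    return abs(la - lb) / max(la, lb)
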