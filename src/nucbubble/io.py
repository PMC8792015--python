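"""Readers and writers for the package's on-disk formats.

Traces: one CSV per molecule (strand_id, point_index, x_px, y_px) plus a
dataset manifest TSV.  Fragments: BED6 / BEDPE.  Anchors: BED6 with the
TSS as a single-base interval and strand in column 6.  Titrations: TSV
(conc_molar, polarization, replicate).  All coordinates are 0-based
half-open; parsers report malformed rows with file and line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import TitrationSeries
from .bubbles import BubbleCall
from .geometry import DistanceProfile, MoleculeTrace, StrandTrace
from .mnase import FragmentSet, GeneAnchor

__all__ = [
    "ParseError",
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_dataset",
    "read_trace_dataset",
    "write_bed",
    "read_bed_fragments",
    "read_bedpe_fragments",
    "write_anchors_bed",
    "read_anchors_bed",
    "write_titration_tsv",
    "read_titration_tsv",
    "write_profiles_tsv",
    "read_profiles_tsv",
    "write_bubble_table",
    "write_json",
    "read_json",
]


class ParseError(ValueError):
    """Malformed input row, reported as file:line."""

    def __init__(self, path: Path | str, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path, self.line = str(path), line


# ---------------------------------------------------------------- traces


def write_trace_csv(m: MoleculeTrace, path: Path | str) -> None:
    rows = []
    for strand in (m.strand_a, m.strand_b):
        for i, (x, y) in enumerate(strand.points):
            rows.append((strand.strand_id, i, repr(float(x)), repr(float(y))))
    pd.DataFrame(rows, columns=["strand_id", "point_index", "x_px", "y_px"]).to_csv(
        path, index=False
    )


def read_trace_csv(path: Path | str, molecule_id: str, template_len_bp: int) -> MoleculeTrace:
    df = pd.read_csv(path, dtype={"strand_id": str}, float_precision="round_trip")
    for col in ("strand_id", "point_index", "x_px", "y_px"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing column {col!r}")
    strands = {}
    for sid, sub in df.groupby("strand_id", sort=True):
        sub = sub.sort_values("point_index")
        idx = sub["point_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            line = int(sub.index[0]) + 2
            raise ParseError(path, line, f"strand {sid}: point_index not contiguous from 0")
        strands[sid] = StrandTrace(str(sid), sub[["x_px", "y_px"]].to_numpy(dtype=float))
    if set(strands) != {"A", "B"}:
        raise ParseError(path, 1, f"expected strands A and B, got {sorted(strands)}")
    return MoleculeTrace(molecule_id, strands["A"], strands["B"], template_len_bp)


def write_trace_dataset(
    molecules: Sequence[MoleculeTrace], out_dir: Path | str, meta: dict | None = None
) -> Path:
    """Write per-molecule CSVs plus a manifest TSV; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in molecules:
        fname = f"{m.molecule_id}.csv"
        write_trace_csv(m, out / fname)
        rows.append((m.molecule_id, fname, m.template_len_bp))
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows, columns=["molecule_id", "file", "template_len_bp"]).to_csv(
        manifest, sep="\t", index=False
    )
    if meta is not None:
        write_json(meta, out / "metadata.json")
    return manifest


def read_trace_dataset(manifest_path: Path | str) -> list[MoleculeTrace]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    return [
        read_trace_csv(
            manifest_path.parent / row.file, str(row.molecule_id), int(row.template_len_bp)
        )
        for row in df.itertuples()
    ]


# ------------------------------------------------------------- intervals


def _check_interval(path, line, start, end) -> tuple[int, int]:
    try:
        s, e = int(start), int(end)
    except (TypeError, ValueError):
        raise ParseError(path, line, f"non-integer coordinates {start!r}, {end!r}") from None
    if s < 0 or s >= e:
        raise ParseError(path, line, f"invalid half-open interval [{s}, {e})")
    return s, e


def read_bed_fragments(path: Path | str, sample: str = "") -> FragmentSet:
    """BED (>=3 columns) to a FragmentSet."""
    recs = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise ParseError(path, ln, f"expected >=3 BED columns, got {len(parts)}")
            s, e = _check_interval(path, ln, parts[1], parts[2])
            recs.append((parts[0], s, e))
    return FragmentSet(pd.DataFrame(recs, columns=["chrom", "start", "end"]), sample=sample)


def read_bedpe_fragments(path: Path | str, sample: str = "") -> FragmentSet:
    """BEDPE mate pairs to whole-insert fragments (min start to max end)."""
    recs = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 6:
                raise ParseError(path, ln, f"expected >=6 BEDPE columns, got {len(parts)}")
            if parts[0] != parts[3]:
                raise ParseError(path, ln, "interchromosomal pair not supported")
            s1, e1 = _check_interval(path, ln, parts[1], parts[2])
            s2, e2 = _check_interval(path, ln, parts[4], parts[5])
            recs.append((parts[0], min(s1, s2), max(e1, e2)))
    return FragmentSet(pd.DataFrame(recs, columns=["chrom", "start", "end"]), sample=sample)


def write_bed(frags: FragmentSet, path: Path | str) -> None:
    frags.df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_anchors_bed(anchors: Sequence[GeneAnchor], path: Path | str) -> None:
    rows = [(a.chrom, a.tss, a.tss + 1, a.gene_id, 0, a.strand) for a in anchors]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_anchors_bed(path: Path | str) -> list[GeneAnchor]:
    anchors = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 6:
                raise ParseError(path, ln, f"anchors need 6 BED columns, got {len(parts)}")
            s, e = _check_interval(path, ln, parts[1], parts[2])
            if e - s != 1:
                raise ParseError(path, ln, "TSS anchor must be a single-base interval")
            if parts[5] not in ("+", "-"):
                raise ParseError(path, ln, f"bad strand {parts[5]!r}")
            anchors.append(GeneAnchor(parts[3], parts[0], s, parts[5]))
    return anchors


# ----------------------------------------------------- titrations & misc


def write_titration_tsv(series: TitrationSeries, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# probe_conc_molar={series.probe_conc!r}\n")
        series.points.to_csv(fh, sep="\t", index=False)


def read_titration_tsv(path: Path | str) -> TitrationSeries:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# probe_conc_molar="):
            raise ParseError(path, 1, "missing probe_conc_molar header")
        probe = float(header.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    for col in ("conc_molar", "polarization", "replicate"):
        if col not in df.columns:
            raise ParseError(path, 2, f"missing column {col!r}")
    return TitrationSeries(probe_conc=probe, points=df)


def write_profiles_tsv(profiles: Sequence[DistanceProfile], path: Path | str) -> None:
    frames = [
        pd.DataFrame(
            {
                "molecule_id": p.molecule_id,
                "bp_index": np.arange(p.template_len_bp),
                "distance_px": [repr(float(v)) for v in p.distances_px],
            }
        )
        for p in profiles
    ]
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: Path | str) -> list[DistanceProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"molecule_id": str}, float_precision="round_trip")
    out = []
    for mol, sub in df.groupby("molecule_id", sort=False):
        sub = sub.sort_values("bp_index")
        idx = sub["bp_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            raise ParseError(path, int(sub.index[0]) + 2, f"{mol}: bp_index not contiguous")
        out.append(DistanceProfile(str(mol), sub["distance_px"].to_numpy(dtype=float)))
    return out


def write_bubble_table(calls: Sequence[BubbleCall], path: Path | str) -> None:
    rows = [
        (c.molecule_id, b.start_bp, b.end_bp, b.length_bp, b.is_nucleosome, b.is_fusion_suspect)
        for c in calls
        for b in c.bubbles
    ]
    pd.DataFrame(
        rows,
        columns=["molecule_id", "start_bp", "end_bp", "length_bp", "is_nucleosome", "is_fusion_suspect"],
    ).to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())
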