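"""Ground-truth-annotated synthetic data for every pipeline stage.

Three generators:

* EM molecule traces — two strand polylines per molecule along a smooth
  random backbone, separated by a duplex baseline outside planted
  bubbles and opening to a wider separation inside them.  Per-molecule
  nucleosome-sized bubble counts are Poisson, truncated to what
  physically fits on the template.
* MNase fragment populations — IP and input samples with a planted,
  sharply positioned +1 nucleosome downstream of oriented TSSs.
* FP titrations — single-site binding isotherms with Gaussian noise in
  replicate.

All generators consume one seeded RNG and are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .binding import TitrationSeries, fraction_bound_quadratic
from .geometry import MoleculeTrace, StrandTrace
from .mnase import FragmentSet, GeneAnchor

__all__ = [
    "TraceSimConfig",
    "FragmentSimConfig",
    "TitrationSimConfig",
    "TraceSimResult",
    "FragmentSimResult",
    "simulate_trace_dataset",
    "simulate_mnase_fragments",
    "simulate_fp_titration",
    "max_bubbles_fit",
]

NUCLEOSOME_MIN_LEN_BP = 90


def max_bubbles_fit(template_len_bp: int, min_bubble_bp: int = 91, gap_bp: int = 1) -> int:
    """Largest k with k * min_bubble_bp + (k - 1) * gap_bp <= template_len_bp."""
    k = 0
    while (k + 1) * min_bubble_bp + k * gap_bp <= template_len_bp:
        k += 1
    return k


# --------------------------------------------------------------------------
# EM trace simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceSimConfig:
    """Study conditions for the EM trace generator.

    Defaults mirror the reconstitution experiment: a 461-bp template
    carrying Poisson-distributed nucleosome-sized bubbles of ~147 bp.
    Pixel-scale parameters are placeholders for the (unreported) spread
    geometry and are fully exposed.
    """

    template_len_bp: int = 461
    n_molecules: int = 150
    lambda_true: float = 1.3
    bubble_len_mean_bp: float = 147.0
    bubble_len_sd_bp: float = 15.0
    small_bubble_rate: float = 0.3
    small_bubble_len_range_bp: tuple[int, int] = (15, 60)
    px_per_bp: float = 2.0
    duplex_sep_px: float = 2.0
    open_sep_px: float = 10.0
    coord_noise_px: float = 0.6
    curvature_sd_rad: float = 0.02
    curvature_smooth_bp: float = 10.0
    shoulder_bp: float = 3.0
    min_gap_bp: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.template_len_bp <= 0 or self.n_molecules < 0:
            raise ValueError("template_len_bp and n_molecules must be positive")
        if self.lambda_true < 0 or self.small_bubble_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.px_per_bp <= 0 or self.duplex_sep_px < 0:
            raise ValueError("px_per_bp > 0 and duplex_sep_px >= 0 required")
        if self.open_sep_px <= self.duplex_sep_px:
            raise ValueError("open_sep_px must exceed duplex_sep_px")
        if self.open_sep_px - self.duplex_sep_px < 2.0 * self.coord_noise_px:
            raise ValueError(
                "open/duplex separations not distinguishable given noise: "
                "open_sep_px - duplex_sep_px must be >= 2 * coord_noise_px"
            )
        if self.lambda_true * self.bubble_len_mean_bp > self.template_len_bp:
            warnings.warn(
                "lambda_true x mean bubble length exceeds the template length; "
                "counts will be heavily truncated by packing"
            )


@dataclass
class TraceSimResult:
    molecules: list[MoleculeTrace]
    truth: pd.DataFrame  # molecule_id, start_bp, end_bp, length_bp, size_class
    meta: dict

    def planted_nucleosome_counts(self) -> pd.Series:
        """Planted nucleosome-sized bubble count per molecule (index: molecule_id)."""
        ids = [m.molecule_id for m in self.molecules]
        if len(self.truth):
            nuc = self.truth[self.truth["size_class"] == "nucleosome"]
            counts = nuc.groupby("molecule_id").size()
        else:
            counts = pd.Series(dtype=np.int64)
        return counts.reindex(ids, fill_value=0).astype(np.int64)


def _draw_nucleosome_length(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Normal length rounded to int, truncated to > 90 bp (nucleosome-sized)."""
    while True:
        ln = int(round(rng.normal(mean, sd)))
        if ln > NUCLEOSOME_MIN_LEN_BP:
            return ln


def _place_bubbles(
    rng: np.random.Generator, cfg: TraceSimConfig
) -> list[tuple[int, int, str]]:
    """Draw counts, lengths and non-overlapping positions for one molecule.

    Counts are Poisson(lambda_true) rejection-resampled until the drawn
    bubbles pack onto the template with the minimum duplex gap.
    """
    t, g = cfg.template_len_bp, cfg.min_gap_bp
    for _ in range(10_000):
        k_nuc = rng.poisson(cfg.lambda_true)
        k_small = rng.poisson(cfg.small_bubble_rate)
        lens = [
            _draw_nucleosome_length(rng, cfg.bubble_len_mean_bp, cfg.bubble_len_sd_bp)
            for _ in range(k_nuc)
        ]
        lo, hi = cfg.small_bubble_len_range_bp
        lens += [int(rng.integers(lo, hi + 1)) for _ in range(k_small)]
        classes = ["nucleosome"] * k_nuc + ["small"] * k_small
        order = rng.permutation(len(lens))
        lens = [lens[i] for i in order]
        classes = [classes[i] for i in order]
        k = len(lens)
        slack = t - sum(lens) - g * max(k - 1, 0)
        if slack >= 0:
            break
    else:  # pragma: no cover - config guards make this unreachable in practice
        raise RuntimeError("could not pack bubbles onto template")
    if k == 0:
        return []
    extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
    spans = []
    pos = int(extra[0])
    for i in range(k):
        spans.append((pos, pos + lens[i], classes[i]))
        pos += lens[i] + g + int(extra[i + 1])
    return spans


def _separation_field(cfg: TraceSimConfig, spans: list[tuple[int, int, str]], x: np.ndarray) -> np.ndarray:
    """Inter-strand separation (px) at template coordinates x (bp).

    Flat-top opening with raised-cosine shoulders of half-width
    ``shoulder_bp``; the 50% crossing of each shoulder sits exactly on
    the planted span boundary, so every base inside a span is above the
    open/duplex midpoint and every base outside is below it.
    Overlapping shoulder tails from adjacent bubbles combine by max.
    """
    delta = cfg.open_sep_px - cfg.duplex_sep_px
    r = cfg.shoulder_bp
    w = np.zeros_like(x, dtype=float)
    for s, e, _cls in spans:
        d = np.minimum(x - s, e - x)  # signed depth inside the span
        wi = np.where(
            d >= r, 1.0, np.where(d <= -r, 0.0, 0.5 * (1.0 + np.sin(0.5 * np.pi * np.clip(d, -r, r) / r)))
        )
        np.maximum(w, wi, out=w)
    return cfg.duplex_sep_px + delta * w


def _render_molecule(
    rng: np.random.Generator,
    cfg: TraceSimConfig,
    spans: list[tuple[int, int, str]],
    molecule_id: str,
) -> MoleculeTrace:
    t = cfg.template_len_bp
    x_bp = np.arange(t + 1, dtype=float)  # one vertex per bp boundary
    sep = _separation_field(cfg, spans, x_bp)
    dtheta = rng.normal(0.0, cfg.curvature_sd_rad, size=t)
    if cfg.curvature_smooth_bp > 0:
        dtheta = gaussian_filter1d(dtheta, cfg.curvature_smooth_bp, mode="nearest")
    # bend only in duplex regions: curvature inside a bubble makes the two
    # offset strands traverse different arc lengths there, which would bias
    # the arc-length base calibration around planted spans
    margin = cfg.shoulder_bp + 2.0
    for s, e, _cls in spans:
        lo = max(int(np.floor(s - margin)), 0)
        hi = min(int(np.ceil(e + margin)), t)
        dtheta[lo:hi] = 0.0
    theta = rng.uniform(0.0, 2.0 * np.pi) + np.concatenate([[0.0], np.cumsum(dtheta)])
    # compensate backbone advance inside bubble shoulders so that each
    # offset strand keeps a uniform arc length of px_per_bp per base pair
    dhalf = 0.5 * np.diff(sep)
    ds = np.sqrt(np.maximum(cfg.px_per_bp**2 - dhalf**2, (0.25 * cfg.px_per_bp) ** 2))
    steps = ds[:, None] * np.column_stack([np.cos(theta[:t]), np.sin(theta[:t])])
    backbone = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
    # unit normals from the local tangent (central differences)
    tang = np.gradient(backbone, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])
    half = 0.5 * sep[:, None] * normal
    pts_a = backbone + half
    pts_b = backbone - half
    if cfg.coord_noise_px > 0:
        pts_a = pts_a + rng.normal(0.0, cfg.coord_noise_px, size=pts_a.shape)
        pts_b = pts_b + rng.normal(0.0, cfg.coord_noise_px, size=pts_b.shape)
    if rng.random() < 0.5:  # tracing direction of the second strand is arbitrary
        pts_b = pts_b[::-1]
    return MoleculeTrace(
        molecule_id=molecule_id,
        strand_a=StrandTrace("A", pts_a),
        strand_b=StrandTrace("B", pts_b),
        template_len_bp=t,
    )


def simulate_trace_dataset(cfg: TraceSimConfig) -> TraceSimResult:
    """Simulate a traced-molecule dataset with planted bubble ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    molecules, records = [], []
    for i in range(cfg.n_molecules):
        mol_id = f"mol{i:05d}"
        spans = _place_bubbles(rng, cfg)
        molecules.append(_render_molecule(rng, cfg, spans, mol_id))
        for s, e, cls in spans:
            records.append((mol_id, s, e, e - s, cls))
    truth = pd.DataFrame(
        records, columns=["molecule_id", "start_bp", "end_bp", "length_bp", "size_class"]
    )
    planted = (
        truth[truth["size_class"] == "nucleosome"].groupby("molecule_id").size()
        if len(truth)
        else pd.Series(dtype=np.int64)
    )
    all_ids = [m.molecule_id for m in molecules]
    counts = planted.reindex(all_ids, fill_value=0)
    meta = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "planted_mean_nucleosomes": float(counts.mean()) if len(counts) else 0.0,
        "note": "counts are Poisson truncated to the template packing limit",
    }
    return TraceSimResult(molecules, truth, meta)


# --------------------------------------------------------------------------
# MNase fragment simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentSimConfig:
    """Study conditions for the MNase fragment generator.

    The IP sample concentrates mononucleosome-sized fragments on a
    planted +1 nucleosome dyad downstream of enriched genes' TSSs; the
    input sample doubles as the enrichment control and is dominated by
    uniform background (``input_background_frac``) with a weak positioned
    component at every gene.
    """

    n_genes: int = 100
    genome_len: int = 2_000_000
    plus_one_offset_bp: int = 110
    fuzziness_bp: float = 20.0
    frag_len_mean: float = 150.0
    frag_len_sd: float = 20.0
    frags_per_gene_ip: int = 200
    frags_per_gene_input: int = 200
    background_frac: float = 0.1
    input_background_frac: float = 0.9
    enriched_gene_frac: float = 0.5
    chrom: str = "chrSim"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.genome_len < 1:
            raise ValueError("n_genes and genome_len must be positive")
        for frac in (self.background_frac, self.input_background_frac, self.enriched_gene_frac):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.frags_per_gene_ip < 0 or self.frags_per_gene_input < 0:
            raise ValueError("fragment counts must be non-negative")
        if self.genome_len // self.n_genes < 4000:
            raise ValueError("genes too dense: need >=4 kb spacing for TSS windows")


@dataclass
class FragmentSimResult:
    ip: FragmentSet
    input: FragmentSet
    anchors: list[GeneAnchor]
    truth: pd.DataFrame  # gene_id, chrom, tss, strand, dyad, enriched
    meta: dict


def _fragments_at(
    rng: np.random.Generator, cfg: FragmentSimConfig, mids: np.ndarray
) -> np.ndarray:
    """(start, end) int array for fragments with given midpoints."""
    lens = np.maximum(np.round(rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, size=mids.size)), 1).astype(np.int64)
    starts = mids.astype(np.int64) - lens // 2
    starts = np.clip(starts, 0, cfg.genome_len - lens)
    return np.column_stack([starts, starts + lens])


def _uniform_mids(rng: np.random.Generator, cfg: FragmentSimConfig, n: int) -> np.ndarray:
    return rng.integers(0, cfg.genome_len, size=n)


def _positioned_mids(
    rng: np.random.Generator, cfg: FragmentSimConfig, dyad: int, n: int
) -> np.ndarray:
    jitter = rng.normal(0.0, cfg.fuzziness_bp, size=n) if cfg.fuzziness_bp > 0 else np.zeros(n)
    return np.clip(np.round(dyad + jitter), 0, cfg.genome_len - 1)


def simulate_mnase_fragments(cfg: FragmentSimConfig) -> FragmentSimResult:
    """Simulate IP/input fragment sets, TSS anchors, and the dyad truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    spacing = cfg.genome_len // cfg.n_genes
    n_enriched = int(round(cfg.enriched_gene_frac * cfg.n_genes))
    enriched_idx = set(rng.choice(cfg.n_genes, size=n_enriched, replace=False).tolist())
    anchors, truth_recs = [], []
    ip_rows, input_rows = [], []
    for i in range(cfg.n_genes):
        gene_id = f"g{i:04d}"
        tss = i * spacing + spacing // 2
        strand = "+" if rng.random() < 0.5 else "-"
        sgn = 1 if strand == "+" else -1
        dyad = tss + sgn * cfg.plus_one_offset_bp
        enriched = i in enriched_idx
        anchors.append(GeneAnchor(gene_id, cfg.chrom, tss, strand))
        truth_recs.append((gene_id, cfg.chrom, tss, strand, dyad, enriched))
        # IP: positioned at the planted dyad only for enriched genes
        if enriched:
            n_bg = rng.binomial(cfg.frags_per_gene_ip, cfg.background_frac)
            n_pos = cfg.frags_per_gene_ip - n_bg
        else:
            n_bg, n_pos = cfg.frags_per_gene_ip, 0
        if n_pos:
            ip_rows.append(_fragments_at(rng, cfg, _positioned_mids(rng, cfg, dyad, n_pos)))
        if n_bg:
            ip_rows.append(_fragments_at(rng, cfg, _uniform_mids(rng, cfg, n_bg)))
        # input/control: mostly background, weak +1 positioning at every gene
        n_bg_in = rng.binomial(cfg.frags_per_gene_input, cfg.input_background_frac)
        n_pos_in = cfg.frags_per_gene_input - n_bg_in
        if n_pos_in:
            input_rows.append(_fragments_at(rng, cfg, _positioned_mids(rng, cfg, dyad, n_pos_in)))
        if n_bg_in:
            input_rows.append(_fragments_at(rng, cfg, _uniform_mids(rng, cfg, n_bg_in)))

    def _to_set(rows: list[np.ndarray], sample: str) -> FragmentSet:
        if rows:
            arr = np.vstack(rows)
            df = pd.DataFrame({"chrom": cfg.chrom, "start": arr[:, 0], "end": arr[:, 1]})
        else:
            df = pd.DataFrame(columns=["chrom", "start", "end"])
        return FragmentSet(df, sample=sample)

    truth = pd.DataFrame(
        truth_recs, columns=["gene_id", "chrom", "tss", "strand", "dyad", "enriched"]
    )
    meta = {"seed": cfg.seed, "config": asdict(cfg)}
    return FragmentSimResult(_to_set(ip_rows, "ip"), _to_set(input_rows, "input"), anchors, truth, meta)


# --------------------------------------------------------------------------
# FP titration simulation
# --------------------------------------------------------------------------


def _default_titration() -> tuple[float, ...]:
    # 3-fold dilution series from 30 uM plus a zero-titrant well
    return tuple([0.0] + [3e-5 / 3**i for i in range(9)][::-1])


@dataclass(frozen=True)
class TitrationSimConfig:
    """Study conditions for the FP titration generator (concentrations in M)."""

    kd_true: float = 1e-6
    probe_conc: float = 20e-9
    titrant_concs: tuple[float, ...] = field(default_factory=_default_titration)
    fp_free: float = 50.0
    fp_bound: float = 150.0
    noise_sd: float = 2.0
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.kd_true <= 0:
            raise ValueError("kd_true must be positive")
        if self.probe_conc < 0 or any(c < 0 for c in self.titrant_concs):
            raise ValueError("all concentrations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def simulate_fp_titration(cfg: TitrationSimConfig) -> TitrationSeries:
    """Simulate a replicated FP titration from the single-site model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    concs = np.asarray(cfg.titrant_concs, dtype=float)
    f = fraction_bound_quadratic(cfg.kd_true, concs, cfg.probe_conc)
    mean_fp = cfg.fp_free + (cfg.fp_bound - cfg.fp_free) * f
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        noise = rng.normal(0.0, cfg.noise_sd, size=concs.size) if cfg.noise_sd > 0 else 0.0
        vals = mean_fp + noise
        for c, v in zip(concs, np.atleast_1d(vals + np.zeros_like(mean_fp))):
            rows.append((float(c), float(v), f"rep{rep}"))
    points = pd.DataFrame(rows, columns=["conc_molar", "polarization", "replicate"])
    return TitrationSeries(probe_conc=cfg.probe_conc, points=points)
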