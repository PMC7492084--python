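"""Synthetic data generators with ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding
analysis assumes, at desk scale, and emits the planted truth alongside
the data so that recovery can be tested without any external download:

* barrel-grid fluorescence images with known hollow/septa/background
  intensities (the true contrast is analytically known);
* small genomes with assembly gaps (N runs), ATAC-like peaks, and motif
  consensus sites planted at controlled per-peak rates;
* expression tables with planted layer-specific differential structure
  (a configurable fraction of L4-marked genes down, L5-marked genes up,
  on top of background differential rates);
* per-layer RNAscope-like cell centroids and Poisson puncta counts;
* a coordinate-level enrichment fixture (genes, peaks, shuffled control
  regions, planted motif instances) for power and calibration studies of
  the dual Fisher reporting rule.

Everything is exactly reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imagequant import RoiSet
from .motifscan import BASES, MotifInstance, Pwm
from .regenrich import GenomicInterval, shuffle_control_regions

__all__ = [
    "BarrelImageSpec",
    "GenomeFixtureSpec",
    "ExpressionTruthSpec",
    "EnrichmentFixtureSpec",
    "BarrelTruth",
    "GenomeFixture",
    "simulate_barrel_image",
    "simulate_genome_fixture",
    "simulate_expression_table",
    "simulate_puncta",
    "simulate_enrichment_fixture",
    "write_fasta",
    "read_fasta",
]


# ---------------------------------------------------------------------------
# barrel images


@dataclass(frozen=True)
class BarrelImageSpec:
    """Geometry and intensity model of a synthetic barrel-field image.

    Discs of intensity ``intensity_barrel`` sit on a septa field of
    ``intensity_septa`` inside the barrel-field rectangle, with
    ``intensity_background`` outside; i.i.d. Gaussian noise is added and
    then a Gaussian blur applied.  Disc barrels on a regular grid keep
    the true contrast analytically known; ``hex_grid`` offsets alternate
    rows by half a spacing.
    """

    grid_rows: int = 5
    grid_cols: int = 5
    barrel_radius_px: float = 30.0
    spacing_px: float = 72.0
    intensity_barrel: float = 200.0
    intensity_septa: float = 100.0
    intensity_background: float = 10.0
    noise_sd: float = 0.0
    blur_sigma_px: float = 0.0
    seed: int = 0
    hex_grid: bool = False
    margin_px: int = 40
    image_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if min(self.intensity_barrel, self.intensity_septa, self.intensity_background) < 0:
            raise ValueError("intensities must be >= 0")
        if self.intensity_barrel + self.intensity_septa <= 0:
            raise ValueError("barrel + septa intensity must be positive")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be >= 0")
        if 2 * self.barrel_radius_px >= self.spacing_px:
            raise ValueError("barrel discs must not touch: need 2*radius < spacing")

    @property
    def true_contrast(self) -> float:
        return (self.intensity_barrel - self.intensity_septa) / (
            self.intensity_barrel + self.intensity_septa
        )

    def field_shape(self) -> tuple[int, int]:
        extra = self.spacing_px / 2.0 if self.hex_grid else 0.0
        h = int(np.ceil(self.grid_rows * self.spacing_px))
        w = int(np.ceil(self.grid_cols * self.spacing_px + extra))
        return h, w


@dataclass
class BarrelTruth:
    """Ground truth emitted with a simulated barrel image."""

    true_contrast: float
    roi_set: RoiSet
    label_mask: np.ndarray  # 0 background, 1 septa, 2.. barrel index+2


def simulate_barrel_image(spec: BarrelImageSpec) -> tuple[np.ndarray, BarrelTruth]:
    """Render a barrel-grid image and its ground-truth ROI set.

    The truth ROI set contains one mask per barrel disc, the barrel-field
    rectangle as the enclosing ROI, and two background ROIs outside the
    field.  Quantifying the noiseless image with these ROIs returns the
    true contrast exactly.
    """
    fh, fw = spec.field_shape()
    m = spec.margin_px
    shape = (fh + 2 * m, fw + 2 * m) if spec.image_shape is None else tuple(spec.image_shape)
    if shape[0] < fh + 2 * m or shape[1] < fw + 2 * m:
        raise ValueError(
            f"image shape {shape} too small for a {spec.grid_rows}x{spec.grid_cols} "
            f"grid with spacing {spec.spacing_px} and margin {m}"
        )
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    field = (rr >= m) & (rr < m + fh) & (cc >= m) & (cc < m + fw)

    img = np.full(shape, spec.intensity_background, dtype=float)
    img[field] = spec.intensity_septa
    label = np.zeros(shape, dtype=np.int32)
    label[field] = 1

    barrel_masks = []
    k = 2
    for i in range(spec.grid_rows):
        for j in range(spec.grid_cols):
            dx = spec.spacing_px / 2.0 if (spec.hex_grid and i % 2 == 1) else 0.0
            cy = m + (i + 0.5) * spec.spacing_px
            cx = m + (j + 0.5) * spec.spacing_px + dx
            disc = (rr - cy) ** 2 + (cc - cx) ** 2 <= spec.barrel_radius_px**2
            img[disc] = spec.intensity_barrel
            label[disc] = k
            barrel_masks.append(disc)
            k += 1

    # two background ROIs in opposite corners, clear of the field
    bg_sz = max(4, m // 2)
    bg1 = np.zeros(shape, dtype=bool)
    bg1[2 : 2 + bg_sz, 2 : 2 + bg_sz] = True
    bg2 = np.zeros(shape, dtype=bool)
    bg2[-2 - bg_sz : -2, -2 - bg_sz : -2] = True

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    if spec.blur_sigma_px > 0:
        img = gaussian_filter(img, spec.blur_sigma_px)

    roi_set = RoiSet(
        barrel_rois=barrel_masks,
        enclosing_roi=field,
        background_rois=[bg1, bg2],
        section_id="synthetic",
    )
    return img, BarrelTruth(spec.true_contrast, roi_set, label)


# ---------------------------------------------------------------------------
# genome fixtures


@dataclass(frozen=True)
class GenomeFixtureSpec:
    """A small genome with gaps, peaks, and planted motif sites.

    Background sequence is i.i.d. with a symmetric GC split (pA = pT,
    pC = pG).  ``frac_target`` of the peaks are labelled "target"
    (emulating differential peaks) and receive a planted consensus site
    with probability ``plant_rate_target``; the rest are "background"
    peaks planted at ``plant_rate_background``.
    """

    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chr1": 100_000})
    gap_intervals: tuple[GenomicInterval, ...] = ()
    gc_content: float = 0.42
    n_peaks: int = 50
    peak_length_bp: int = 300
    plant_rate_target: float = 1.0
    plant_rate_background: float = 0.0
    frac_target: float = 0.5
    seed: int = 0
    max_placement_tries: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must lie in (0, 1)")
        for r in (self.plant_rate_target, self.plant_rate_background, self.frac_target):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        for g in self.gap_intervals:
            if g.chrom not in self.chrom_sizes or g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(f"gap {g} outside its chromosome")


@dataclass
class GenomeFixture:
    """Sequences plus interval annotations and planted-instance truth."""

    sequences: dict[str, str]
    gaps: list[GenomicInterval]
    peaks: list[GenomicInterval]
    planted_instances: list[MotifInstance]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_genome_fixture(spec: GenomeFixtureSpec, pwm: Pwm) -> GenomeFixture:
    """Generate sequences, gaps, peaks and planted consensus motif sites.

    Peaks are placed uniformly over gap-free positions (retrying on
    overlap with an already-placed peak up to a bounded number of times);
    a planted site is the PWM consensus, inserted at a uniform offset on
    a uniform strand, recorded in the truth with its coordinates.
    """
    K = len(pwm)
    if K >= spec.peak_length_bp:
        raise ValueError("PWM must be shorter than the peak length")
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    seqs: dict[str, np.ndarray] = {}
    for chrom, size in spec.chrom_sizes.items():
        codes = rng.choice(4, size=size, p=probs)
        seqs[chrom] = codes

    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    sequences = {c: codes.astype(np.uint8) for c, codes in seqs.items()}

    # place peaks uniformly over gap-free starts, avoiding peak overlap
    placed: list[GenomicInterval] = []
    n_target = int(round(spec.n_peaks * spec.frac_target))
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_sizes}
    for i in range(spec.n_peaks):
        ok = None
        for _ in range(spec.max_placement_tries):
            cand = shuffle_control_regions(
                [GenomicInterval("chr0", 0, spec.peak_length_bp)],
                spec.chrom_sizes,
                spec.gap_intervals,
                seed=rng,
            )[0]
            if all(not (cand.start < e and s < cand.end) for s, e in occupied[cand.chrom]):
                ok = cand
                break
        if ok is None:
            raise ValueError("could not place peaks without overlap; genome too crowded")
        occupied[ok.chrom].append((ok.start, ok.end))
        placed.append(
            GenomicInterval(ok.chrom, ok.start, ok.end,
                            label="target" if i < n_target else "background")
        )

    consensus = pwm.consensus()
    cons_codes = np.array([BASES.index(b) for b in consensus], dtype=np.uint8)
    rc_codes = np.array([3 - c for c in cons_codes[::-1]], dtype=np.uint8)
    planted: list[MotifInstance] = []
    for pk in placed:
        rate = spec.plant_rate_target if pk.label == "target" else spec.plant_rate_background
        if rng.random() >= rate:
            continue
        off = int(rng.integers(0, len(pk) - K + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        word = cons_codes if strand == "+" else rc_codes
        sequences[pk.chrom][pk.start + off : pk.start + off + K] = word
        planted.append(
            MotifInstance(
                chrom=pk.chrom, start=pk.start + off, end=pk.start + off + K,
                strand=strand, score=float("nan"), pvalue=float("nan"),
                motif_id=pwm.motif_id, scanner_id="truth",
            )
        )

    out_seqs: dict[str, str] = {}
    for chrom, codes in sequences.items():
        s = base_arr[codes].tobytes().decode()
        arr = np.frombuffer(s.encode(), dtype="S1").copy()
        for g in spec.gap_intervals:
            if g.chrom == chrom:
                arr[g.start : g.end] = b"N"
        out_seqs[chrom] = arr.tobytes().decode()
    return GenomeFixture(out_seqs, list(spec.gap_intervals), placed, planted)


# ---------------------------------------------------------------------------
# expression tables


@dataclass(frozen=True)
class ExpressionTruthSpec:
    """Planted layer-specific differential-expression structure.

    A fraction of L4-marked genes is planted down-regulated and a
    fraction of L5-marked genes up-regulated (defaults echo the observed
    26% / 19% with background rates of 1% down and 2% up among all other
    genes); null genes carry log fold change noise around zero and
    uniform adjusted p-values.
    """

    n_genes: int = 5000
    n_l4: int = 102
    n_l5: int = 240
    effect_lfc_l4: float = 2.0
    effect_lfc_l5: float = 2.0
    frac_l4_responsive: float = 0.26
    frac_l5_responsive: float = 0.19
    background_rate_down: float = 0.01
    background_rate_up: float = 0.02
    lfc_noise_sd: float = 0.15
    planted_padj: float = 1e-6
    baseline_tpm_log_mean: float = 3.0
    baseline_tpm_log_sd: float = 1.2
    n_replicates: int = 4
    ages: tuple[str, ...] = ("P2", "P7", "P30")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_l4 + self.n_l5 > self.n_genes:
            raise ValueError("layer-marked genes exceed the gene universe")
        if self.n_replicates < 2:
            raise ValueError("need at least two replicates per group")
        for f in (self.frac_l4_responsive, self.frac_l5_responsive,
                  self.background_rate_down, self.background_rate_up):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


def simulate_expression_table(spec: ExpressionTruthSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression/DE table per gene per age, plus truth labels.

    Returns a DataFrame indexed by gene_id with a ``layer`` column and,
    per age, ``tpm_{age}_ctl``, ``tpm_{age}_ko``, ``lfc_{age}`` and
    ``padj_{age}`` columns, and a dict mapping gene_id to its planted
    status ("L4-down", "L5-up" or "null").
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    layer = np.array(["none"] * n, dtype=object)
    layer[: spec.n_l4] = "L4"
    layer[spec.n_l4 : spec.n_l4 + spec.n_l5] = "L5"
    perm = rng.permutation(n)
    layer = layer[perm]

    l4_idx = np.nonzero(layer == "L4")[0]
    l5_idx = np.nonzero(layer == "L5")[0]
    planted_down = set(rng.choice(l4_idx, size=int(round(spec.frac_l4_responsive * l4_idx.size)), replace=False))
    planted_up = set(rng.choice(l5_idx, size=int(round(spec.frac_l5_responsive * l5_idx.size)), replace=False))

    truth = {}
    for i, g in enumerate(gene_ids):
        truth[g] = "L4-down" if i in planted_down else ("L5-up" if i in planted_up else "null")

    baseline = np.exp(rng.normal(spec.baseline_tpm_log_mean, spec.baseline_tpm_log_sd, size=n))
    cols: dict[str, np.ndarray] = {"layer": layer}
    for age in spec.ages:
        lfc = rng.normal(0.0, spec.lfc_noise_sd, size=n)
        padj = rng.uniform(0.0, 1.0, size=n)
        # background differential genes, uniform over the whole universe
        u = rng.uniform(size=n)
        bg_down = u < spec.background_rate_down
        bg_up = (u >= spec.background_rate_down) & (u < spec.background_rate_down + spec.background_rate_up)
        eff = rng.normal(0.0, spec.lfc_noise_sd, size=n)
        lfc[bg_down] = -max(spec.effect_lfc_l4, 1.0) + eff[bg_down]
        lfc[bg_up] = max(spec.effect_lfc_l5, 1.0) + eff[bg_up]
        padj[bg_down | bg_up] = spec.planted_padj
        # planted layer-specific effects
        for i in planted_down:
            lfc[i] = -spec.effect_lfc_l4 + eff[i]
            padj[i] = spec.planted_padj
        for i in planted_up:
            lfc[i] = spec.effect_lfc_l5 + eff[i]
            padj[i] = spec.planted_padj
        tpm_ctl = baseline * rng.lognormal(0.0, 0.05, size=n)
        tpm_ko = tpm_ctl * np.exp2(lfc) * rng.lognormal(0.0, 0.05, size=n)
        cols[f"tpm_{age}_ctl"] = tpm_ctl
        cols[f"tpm_{age}_ko"] = tpm_ko
        cols[f"lfc_{age}"] = lfc
        cols[f"padj_{age}"] = padj
    table = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return table, truth


# ---------------------------------------------------------------------------
# puncta


def simulate_puncta(
    cells_per_layer: Mapping[str, int],
    rates: Mapping[str, float],
    field_size: tuple[float, float] = (512.0, 512.0),
    seed: int = 0,
    cell_radius: float = 5.0,
    image_id: str = "img1",
    animal_id: str = "a1",
    genotype: str = "Ctl",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Cell centroids in layer bands with Poisson puncta per cell.

    Layers occupy equal horizontal bands of the field in the given order;
    centroids are uniform within their band and per-cell puncta counts
    are Poisson with the layer's rate, scattered within one cell radius
    of the centroid.  Returns (cells, puncta, truth rates).
    """
    for layer, lam in rates.items():
        if lam < 0:
            raise ValueError(f"negative puncta rate for layer {layer}")
    rng = np.random.default_rng(seed)
    w, h = field_size
    layers = list(cells_per_layer)
    band = h / max(1, len(layers))
    cell_rows, puncta_rows = [], []
    cid = 0
    for li, layer in enumerate(layers):
        lam = rates.get(layer, 0.0)
        for _ in range(cells_per_layer[layer]):
            x = rng.uniform(0.0, w)
            y = rng.uniform(li * band, (li + 1) * band)
            cell_rows.append(
                {"cell_id": cid, "x": x, "y": y, "layer": layer,
                 "image_id": image_id, "animal_id": animal_id, "genotype": genotype}
            )
            k = rng.poisson(lam)
            for _ in range(k):
                ang = rng.uniform(0.0, 2 * np.pi)
                rad = cell_radius * np.sqrt(rng.uniform())
                puncta_rows.append({"x": x + rad * np.cos(ang), "y": y + rad * np.sin(ang)})
            cid += 1
    cells = pd.DataFrame(cell_rows)
    puncta = pd.DataFrame(puncta_rows, columns=["x", "y"])
    return cells, puncta, dict(rates)


# ---------------------------------------------------------------------------
# enrichment fixture (coordinate level)


@dataclass(frozen=True)
class EnrichmentFixtureSpec:
    """Fixture for power/calibration studies of the dual Fisher rule.

    One peak per gene sits near its TSS; motif instances are planted in
    peaks and control regions with probability ``rate_near_deg`` when the
    region is near (midpoint within the window of) a DEG TSS, and
    ``rate_elsewhere`` otherwise.
    """

    chrom_length: int = 10_000_000
    n_deg: int = 200
    n_control_genes: int = 1000
    window_bp: int = 10_000
    rate_near_deg: float = 0.5
    rate_elsewhere: float = 0.05
    peak_length_bp: int = 500
    motif_length_bp: int = 10
    seed: int = 0


def simulate_enrichment_fixture(spec: EnrichmentFixtureSpec):
    """Gene table, peaks, shuffled controls, and planted/null instances.

    Returns ``(deg_genes, control_genes, peaks, control_regions,
    instances)`` where ``instances`` maps motif_id "planted" (rates as in
    the spec) and "unplanted" (background rate everywhere) to instance
    lists.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_deg + spec.n_control_genes
    spacing = spec.chrom_length // (n + 1)
    tss = np.arange(1, n + 1) * spacing
    is_deg = np.zeros(n, dtype=bool)
    is_deg[rng.choice(n, size=spec.n_deg, replace=False)] = True

    genes = pd.DataFrame(
        {"chrom": "chr1", "tss": tss, "strand": "+", "is_deg": is_deg},
        index=pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id"),
    )
    peaks = []
    for t in tss:
        off = int(rng.integers(-spec.window_bp // 2, spec.window_bp // 2))
        s = max(0, t + off - spec.peak_length_bp // 2)
        peaks.append(GenomicInterval("chr1", s, s + spec.peak_length_bp, label="peak"))
    controls = shuffle_control_regions(peaks, {"chr1": spec.chrom_length}, (), seed=rng)

    deg_tss = np.sort(tss[is_deg])

    def near_deg(region: GenomicInterval) -> bool:
        m = region.midpoint
        j = np.searchsorted(deg_tss, m - spec.window_bp, side="left")
        return j < deg_tss.size and deg_tss[j] <= m + spec.window_bp

    def plant(motif_id: str, near_rate: float, far_rate: float) -> list[MotifInstance]:
        # control regions are shuffled genomic background, so they carry the
        # background rate everywhere, even when they land near a DEG TSS
        out = []
        for region, is_peak in [*((p, True) for p in peaks), *((c, False) for c in controls)]:
            rate = near_rate if (is_peak and near_deg(region)) else far_rate
            if rng.random() < rate:
                mid = int(region.midpoint)
                out.append(
                    MotifInstance(
                        chrom=region.chrom, start=mid, end=mid + spec.motif_length_bp,
                        strand="+", score=10.0, pvalue=1e-5, motif_id=motif_id,
                        scanner_id="xval",
                    )
                )
        return out

    instances = {
        "planted": plant("planted", spec.rate_near_deg, spec.rate_elsewhere),
        "unplanted": plant("unplanted", spec.rate_elsewhere, spec.rate_elsewhere),
    }
    deg_genes = genes[genes["is_deg"]]
    control_genes = genes[~genes["is_deg"]]
    return deg_genes, control_genes, peaks, controls, instances


# ---------------------------------------------------------------------------
# FASTA round-trip helpers (60-column wrapped)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
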