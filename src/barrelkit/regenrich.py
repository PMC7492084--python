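"""Control-region generation and the enrichment statistics of the
regulatory analysis.

Differential ATAC peaks are tested for motif enrichment against control
regions obtained by shuffling the peaks uniformly over the gap-free
genome (length-preserving, bedtools-shuffle style).  Regulatory
assignment of regions to genes uses a symmetric distance window around
the TSS, with the region midpoint deciding proximity.  A motif is
"reported" for a differentially-expressed gene (DEG) group when two
Fisher exact tests are simultaneously significant at p < 0.03: motif
enrichment in nearby ATAC peaks over nearby control regions, and
enrichment of DEGs carrying a nearby motif over a control group of genes
(expressed above 5 TPM and never differential).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motifscan import MotifInstance
from .statcore import ContingencyTable2x2, fisher_exact_2x2

__all__ = [
    "GenomicInterval",
    "EnrichmentResult",
    "DualEnrichment",
    "shuffle_control_regions",
    "region_motif_enrichment",
    "select_control_genes",
    "tss_window_dual_enrichment",
    "tss_window_scan",
    "layer_overrepresentation",
    "regions_near_tss",
]

#: per-test significance level of the dual reporting rule
DUAL_ALPHA = 0.03

#: default TSS distance windows, bp
DEFAULT_WINDOWS = (1_000, 5_000, 10_000, 25_000, 50_000)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 enrichment outcome: counts, odds ratio, Fisher p."""

    motif_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_value: float
    test: str
    window_bp: int | None = None
    significant: bool = False
    fraction: float | None = None

    @property
    def table(self) -> ContingencyTable2x2:
        return ContingencyTable2x2(self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class DualEnrichment:
    """Outcome of the dual region/gene enrichment rule at one window."""

    motif_id: str
    window_bp: int
    region_test: EnrichmentResult
    gene_test: EnrichmentResult
    reported: bool


# ---------------------------------------------------------------------------
# control regions


def _gap_free_runs(
    chrom_sizes: Mapping[str, int], gaps: Sequence[GenomicInterval]
) -> list[tuple[str, int, int]]:
    by_chrom: dict[str, list[GenomicInterval]] = {c: [] for c in chrom_sizes}
    for g in gaps:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gap on unknown chromosome {g.chrom}")
        if g.end > chrom_sizes[g.chrom]:
            raise ValueError(f"gap {g.chrom}:{g.start}-{g.end} exceeds chromosome")
        by_chrom[g.chrom].append(g)
    runs = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        for g in sorted(by_chrom[chrom], key=lambda g: g.start):
            if g.start > pos:
                runs.append((chrom, pos, g.start))
            pos = max(pos, g.end)
        if pos < size:
            runs.append((chrom, pos, size))
    return runs


def shuffle_control_regions(
    regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    gaps: Sequence[GenomicInterval] = (),
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Length-preserving uniform re-placement of regions over the gap-free genome.

    Each input region yields one control of the same length, placed
    uniformly at random over every admissible start position genome-wide
    (positions whose whole extent avoids assembly gaps).  Controls may
    overlap one another.  Raises when a region is longer than every
    gap-free stretch.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    runs = _gap_free_runs(chrom_sizes, gaps)
    out = []
    for r in regions:
        L = len(r)
        counts = np.array([max(0, (e - s) - L + 1) for _, s, e in runs], dtype=np.int64)
        total = int(counts.sum())
        if total == 0:
            raise ValueError(f"no gap-free stretch can hold a region of length {L}")
        u = int(rng.integers(total))
        k = int(np.searchsorted(np.cumsum(counts), u, side="right"))
        chrom, s, _ = runs[k]
        offset = u - int(np.concatenate([[0], np.cumsum(counts)])[k])
        out.append(GenomicInterval(chrom, s + offset, s + offset + L, label="control"))
    return out


# ---------------------------------------------------------------------------
# enrichment tests


def _regions_with_motif(
    regions: Sequence[GenomicInterval], instances: Sequence[MotifInstance]
) -> np.ndarray:
    """Boolean mask: region contains >= 1 instance lying fully within it."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in instances:
        by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    for v in by_chrom.values():
        v.sort()
    mask = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        for s, e in by_chrom.get(r.chrom, ()):
            if s >= r.start and e <= r.end:
                mask[i] = True
                break
            if s >= r.end:
                break
    return mask


def region_motif_enrichment(
    target_regions: Sequence[GenomicInterval],
    control_regions: Sequence[GenomicInterval],
    xval_instances: Sequence[MotifInstance],
    window_bp: int | None = None,
) -> EnrichmentResult:
    """Fisher test of motif presence in target vs control regions."""
    if not target_regions or not control_regions:
        raise ValueError("both region sets must be non-empty")
    ids = {m.motif_id for m in xval_instances}
    if len(ids) > 1:
        raise ValueError(f"instances carry multiple motif_ids: {sorted(ids)}")
    motif_id = ids.pop() if ids else "none"
    t_with = int(_regions_with_motif(target_regions, xval_instances).sum())
    c_with = int(_regions_with_motif(control_regions, xval_instances).sum())
    a, b = t_with, len(target_regions) - t_with
    c, d = c_with, len(control_regions) - c_with
    orr, p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    return EnrichmentResult(
        motif_id, a, b, c, d, orr, p, test="region_vs_control",
        window_bp=window_bp, significant=p < DUAL_ALPHA,
    )


def select_control_genes(gene_table: pd.DataFrame, tpm_threshold: float = 5.0) -> pd.Index:
    """Genes expressed above the TPM threshold in every condition and never differential.

    Expects columns ``tpm_*`` (one per age/genotype condition) and
    ``deg_*`` (per-age status in {"up", "down", "none"}); returns the
    index of genes with min TPM strictly above the threshold and status
    "none" at every age.
    """
    tpm_cols = [c for c in gene_table.columns if c.startswith("tpm_")]
    deg_cols = [c for c in gene_table.columns if c.startswith("deg_")]
    if not tpm_cols or not deg_cols:
        raise ValueError("gene table needs tpm_* and deg_* columns")
    expressed = (gene_table[tpm_cols] > tpm_threshold).all(axis=1)
    unchanged = (gene_table[deg_cols] == "none").all(axis=1)
    return gene_table.index[expressed & unchanged]


def regions_near_tss(
    regions: Sequence[GenomicInterval],
    tss: pd.DataFrame,
    window_bp: int,
    rule: str = "midpoint",
) -> np.ndarray:
    """Mask of regions near any TSS in ``tss`` (columns chrom, tss).

    "midpoint": the region midpoint lies within +/- window of a TSS
    (default); "overlap": any overlap between the region and the window.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if rule not in ("midpoint", "overlap"):
        raise ValueError("rule must be 'midpoint' or 'overlap'")
    by_chrom: dict[str, np.ndarray] = {
        str(c): np.sort(g["tss"].to_numpy(dtype=float))
        for c, g in tss.groupby("chrom")
    }
    mask = np.zeros(len(regions), dtype=bool)
    for i, r in enumerate(regions):
        sites = by_chrom.get(r.chrom)
        if sites is None or sites.size == 0:
            continue
        if rule == "midpoint":
            lo, hi = r.midpoint - window_bp, r.midpoint + window_bp
        else:
            lo, hi = r.start - window_bp, (r.end - 1) + window_bp
        j = np.searchsorted(sites, lo, side="left")
        mask[i] = j < sites.size and sites[j] <= hi
    return mask


def _genes_with_nearby_motif_region(
    genes: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    instances: Sequence[MotifInstance],
    window_bp: int,
    rule: str,
) -> np.ndarray:
    """Mask over genes: gene has >= 1 nearby region containing the motif."""
    with_motif = _regions_with_motif(regions, instances)
    mids = {}
    for i, r in enumerate(regions):
        if with_motif[i]:
            mids.setdefault(r.chrom, []).append((r.midpoint, r.start, r.end))
    mask = np.zeros(len(genes), dtype=bool)
    for k, (_, row) in enumerate(genes.iterrows()):
        for mid, s, e in mids.get(str(row["chrom"]), ()):
            if rule == "midpoint":
                near = abs(mid - row["tss"]) <= window_bp
            else:
                near = s - window_bp <= row["tss"] <= (e - 1) + window_bp
            if near:
                mask[k] = True
                break
    return mask


def tss_window_dual_enrichment(
    deg_genes: pd.DataFrame,
    control_genes: pd.DataFrame,
    atac_peaks: Sequence[GenomicInterval],
    control_regions: Sequence[GenomicInterval],
    xval_instances: Sequence[MotifInstance],
    window_bp: int,
    rule: str = "midpoint",
    restrict_controls: bool = True,
) -> DualEnrichment:
    """The dual Fisher rule for one motif, one DEG group, one window.

    Test 1 compares motif frequency between ATAC peaks near any DEG TSS
    and control regions near any DEG TSS (``restrict_controls=False``
    uses all control regions as the denominator instead).  Test 2
    compares the fraction of DEGs vs control genes having at least one
    nearby motif-containing ATAC peak.  The motif is reported when both
    p-values are < 0.03.
    """
    if len(deg_genes) == 0 or len(control_genes) == 0:
        raise ValueError("DEG and control gene sets must be non-empty")
    overlap = set(deg_genes.index) & set(control_genes.index)
    if overlap:
        raise ValueError(f"genes cannot be both DEG and control: {sorted(overlap)[:5]}")
    ids = {m.motif_id for m in xval_instances}
    if len(ids) > 1:
        raise ValueError(f"instances carry multiple motif_ids: {sorted(ids)}")
    motif_id = ids.pop() if ids else "none"

    deg_tss = deg_genes[["chrom", "tss"]]
    near_peaks = [p for p, keep in zip(atac_peaks, regions_near_tss(atac_peaks, deg_tss, window_bp, rule)) if keep]
    if restrict_controls:
        near_controls = [
            r for r, keep in zip(control_regions, regions_near_tss(control_regions, deg_tss, window_bp, rule)) if keep
        ]
    else:
        near_controls = list(control_regions)

    if near_peaks and near_controls:
        test1 = region_motif_enrichment(near_peaks, near_controls, xval_instances, window_bp)
        test1 = EnrichmentResult(
            motif_id, test1.a, test1.b, test1.c, test1.d, test1.odds_ratio,
            test1.p_value, test="region_vs_control", window_bp=window_bp,
            significant=test1.p_value < DUAL_ALPHA,
        )
    else:
        # no assessable regions: vacuous, not reported
        test1 = EnrichmentResult(
            motif_id, 0, len(near_peaks), 0, len(near_controls), 1.0, 1.0,
            test="region_vs_control", window_bp=window_bp, significant=False,
        )

    deg_hit = _genes_with_nearby_motif_region(deg_genes, atac_peaks, xval_instances, window_bp, rule)
    ctl_hit = _genes_with_nearby_motif_region(control_genes, atac_peaks, xval_instances, window_bp, rule)
    a, b = int(deg_hit.sum()), int(len(deg_genes) - deg_hit.sum())
    c, d = int(ctl_hit.sum()), int(len(control_genes) - ctl_hit.sum())
    orr, p2 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    test2 = EnrichmentResult(
        motif_id, a, b, c, d, orr, p2, test="gene_vs_controlgene",
        window_bp=window_bp, significant=p2 < DUAL_ALPHA,
    )
    reported = test1.significant and test2.significant
    return DualEnrichment(motif_id, window_bp, test1, test2, reported)


def tss_window_scan(
    deg_genes: pd.DataFrame,
    control_genes: pd.DataFrame,
    atac_peaks: Sequence[GenomicInterval],
    control_regions: Sequence[GenomicInterval],
    xval_instances: Sequence[MotifInstance],
    windows: Iterable[int] = DEFAULT_WINDOWS,
    rule: str = "midpoint",
) -> tuple[list[DualEnrichment], bool]:
    """Evaluate the dual rule over a window list; reported if it holds anywhere."""
    results = [
        tss_window_dual_enrichment(
            deg_genes, control_genes, atac_peaks, control_regions,
            xval_instances, w, rule=rule,
        )
        for w in windows
    ]
    return results, any(r.reported for r in results)


def layer_overrepresentation(
    layer_genes: Iterable[str],
    direction_deg_set: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Fisher test of DEG overrepresentation within a layer-specific gene set.

    The 2x2 table crosses layer membership with DEG membership over the
    gene universe; ``fraction`` is the share of layer genes that are DEGs.
    """
    uni = set(universe)
    layer = set(layer_genes) & uni
    deg = set(direction_deg_set) & uni
    if set(layer_genes) - uni or set(direction_deg_set) - uni:
        raise ValueError("layer and DEG sets must be subsets of the universe")
    a = len(layer & deg)
    b = len(layer) - a
    c = len(deg) - a
    d = len(uni) - a - b - c
    orr, p = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
    frac = a / len(layer) if layer else 0.0
    return EnrichmentResult(
        "layer", a, b, c, d, orr, p, test="layer_overrep",
        significant=p < DUAL_ALPHA, fraction=frac,
    )


# ---------------------------------------------------------------------------
# BED input/output (plain 3/4-column, 0-based half-open)


def intervals_to_bed(intervals: Sequence[GenomicInterval]) -> str:
    lines = [
        "\t".join([iv.chrom, str(iv.start), str(iv.end)] + ([iv.label] if iv.label else []))
        for iv in intervals
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def intervals_from_bed(text: str) -> list[GenomicInterval]:
    out = []
    for line in text.strip().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else None))
    return out
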