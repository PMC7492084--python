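"""PWM log-odds scanning with exact p-value thresholds and two-scanner
cross-validation of motif instances.

The scanning model is the standard one behind FIMO-style motif calling: a
position weight matrix (PWM) of per-position base probabilities is turned
into a log2 odds matrix against a 0-order background, every window of the
sequence (both strands) is scored by summing matrix entries, and a window
is called an instance when its score reaches the threshold whose exact
null tail probability (computed by dynamic programming over the
discretized score distribution) is at most alpha (default 1e-4, the FIMO
default).

Instances found by two scanner configurations are cross-validated by
keeping only occurrences reported by both, allowing a 1 bp difference in
the start or the end coordinate to absorb ambiguity between motif models.

Scores are discretized on a fixed grid of 1e-4 bits with conservative
(floor) rounding, so reported tail probabilities are upper bounds and a
discretization error can never create a hit that the exact score would
not have produced.
"""

from __future__ import annotations

import io as _io
import warnings
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BASES",
    "GRID_BITS",
    "Pwm",
    "BackgroundModel",
    "MotifInstance",
    "ScoreDistribution",
    "ScanThreshold",
    "build_logodds",
    "score_distribution",
    "pvalue_threshold",
    "scan_sequence",
    "cross_validate",
    "parse_jaspar",
    "pwm_from_counts",
    "instances_to_bed",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: width of the score-discretization grid, in bits
GRID_BITS = 1e-4

#: finite floor substituted for log2(0) entries (pseudocount 0 with a zero
#: probability); any window containing such a base can never reach a
#: meaningful threshold
NEG_FLOOR_BITS = -64.0


@dataclass(frozen=True)
class BackgroundModel:
    """0-order background: base frequencies over A, C, G, T."""

    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,):
            raise ValueError("background needs exactly four frequencies (A,C,G,T)")
        if (f <= 0).any():
            raise ValueError("background frequencies must be strictly positive")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        object.__setattr__(self, "freqs", tuple(float(x) for x in f))

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls((0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_sequence(cls, seq: str, pseudocount: float = 1.0) -> "BackgroundModel":
        """Base composition of ``seq`` (N and other letters ignored)."""
        counts = np.full(4, float(pseudocount))
        for ch in seq.upper():
            i = _BASE_INDEX.get(ch)
            if i is not None:
                counts[i] += 1.0
        return cls(tuple(counts / counts.sum()))

    def array(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix of base probabilities, one row per position.

    ``matrix`` has shape (K, 4) with columns ordered A, C, G, T.  The
    pseudocount regularizes each probability as ``(p + pc/4) / (1 + pc)``
    before log-odds conversion.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.001
    source: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (K, 4) with K >= 1")
        if (m < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("each PWM position must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def regularized(self) -> np.ndarray:
        """Pseudocount-regularized probabilities; rows sum to 1 within 1e-9."""
        pc = self.pseudocount
        return (self.matrix + pc / 4.0) / (1.0 + pc)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        # reversing the base axis maps A<->T and C<->G because the column
        # order A,C,G,T reversed is T,G,C,A
        return replace(self, matrix=self.matrix[::-1, ::-1])


@dataclass(frozen=True)
class MotifInstance:
    """A scored, stranded occurrence of a motif in forward coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    motif_id: str
    scanner_id: str = "A"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def sort_key(self):
        return (self.chrom, self.start, self.strand, self.end)


def build_logodds(pwm: Pwm, bg: BackgroundModel) -> np.ndarray:
    """Log2-odds matrix (bits): log2(regularized p / background)."""
    p = pwm.regularized()
    with np.errstate(divide="ignore"):
        lo = np.log2(p) - np.log2(bg.array())[None, :]
    return np.where(np.isfinite(lo), lo, NEG_FLOOR_BITS)


def _integerize(logodds: np.ndarray) -> np.ndarray:
    """Floor scores onto the GRID_BITS grid (conservative rounding down).

    A tiny epsilon absorbs float representation error so that values that
    are exactly on a grid line do not fall to the bin below.
    """
    return np.floor(logodds / GRID_BITS + 1e-9).astype(np.int64)


@dataclass
class ScoreDistribution:
    """Exact distribution of the integerized window score under background.

    ``pmf[i]`` is the probability of integer score ``offset + i`` for a
    background-generated word.  The survival function is a valid tail:
    non-increasing, 1 at the minimum score.
    """

    offset: int
    pmf: np.ndarray
    _surv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._surv = np.cumsum(self.pmf[::-1])[::-1]

    @property
    def min_score(self) -> int:
        return self.offset

    @property
    def max_score(self) -> int:
        nz = np.nonzero(self.pmf)[0]
        return self.offset + int(nz[-1]) if nz.size else self.offset

    def tail(self, iscore) -> np.ndarray | float:
        """P(score >= iscore) under the background model."""
        iscore = np.asarray(iscore)
        idx = np.clip(iscore - self.offset, 0, self._surv.size)
        padded = np.append(self._surv, 0.0)
        out = np.where(iscore - self.offset < 0, 1.0, padded[idx])
        return float(out) if out.ndim == 0 else out


def score_distribution(int_logodds: np.ndarray, bg: BackgroundModel) -> ScoreDistribution:
    """Exact pmf of the summed integer score by column-wise convolution."""
    freqs = bg.array()
    pmf = np.ones(1)
    offset = 0
    for col in int_logodds:
        cmin = int(col.min())
        width = int(col.max()) - cmin
        new = np.zeros(pmf.size + width)
        for b in range(4):
            s = int(col[b]) - cmin
            new[s : s + pmf.size] += freqs[b] * pmf
        pmf = new
        offset += cmin
    return ScoreDistribution(offset, pmf)


@dataclass(frozen=True)
class ScanThreshold:
    """Score threshold realizing an exact p-value cut, plus the null pmf."""

    int_threshold: int
    alpha: float
    distribution: ScoreDistribution
    attainable: bool = True

    @property
    def threshold_bits(self) -> float:
        return self.int_threshold * GRID_BITS


def pvalue_threshold(
    logodds: np.ndarray, bg: BackgroundModel, alpha: float = 1e-4
) -> ScanThreshold:
    """Smallest achievable score whose exact null tail is <= alpha.

    When even the best-scoring word has tail probability above alpha the
    threshold is placed one grid step above the maximum score (no window
    can ever reach it) and a warning is issued.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    ilo = _integerize(np.asarray(logodds, dtype=float))
    dist = score_distribution(ilo, bg)
    achievable = np.nonzero(dist.pmf)[0] + dist.offset
    tails = dist.tail(achievable)
    ok = np.nonzero(tails <= alpha)[0]
    if ok.size == 0:
        warnings.warn(
            "no attainable hits below alpha: even the best-scoring word has "
            f"tail probability {tails.min():.3g} > {alpha:g}",
            stacklevel=2,
        )
        return ScanThreshold(int(achievable[-1]) + 1, alpha, dist, attainable=False)
    return ScanThreshold(int(achievable[ok[0]]), alpha, dist)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, others=4."""
    table = np.full(256, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, ilo: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score of every window plus a validity mask (no N inside)."""
    K = ilo.shape[0]
    W = codes.size - K + 1
    # pad the score table with a 5th column for N; masked out below
    padded = np.concatenate([ilo, np.zeros((K, 1), dtype=ilo.dtype)], axis=1)
    scores = np.zeros(W, dtype=np.int64)
    has_n = np.zeros(W, dtype=bool)
    isn = codes == 4
    for j in range(K):
        scores += padded[j][codes[j : j + W]]
        has_n |= isn[j : j + W]
    return scores, ~has_n


def scan_sequence(
    seq: str,
    pwm: Pwm,
    bg: BackgroundModel | None = None,
    alpha: float = 1e-4,
    both_strands: bool = True,
    chrom: str = "seq",
    offset: int = 0,
    scanner_id: str = "A",
) -> list[MotifInstance]:
    """Report every window scoring at or above the exact-p threshold.

    Reverse-strand matches are scored with the reverse-complemented matrix
    against its own null distribution (the two coincide for a
    strand-symmetric background) and reported in forward coordinates.
    ``offset`` shifts reported coordinates, for sequences that are slices
    of a larger chromosome.  Windows containing N are skipped.
    """
    if bg is None:
        bg = BackgroundModel.uniform()
    K = len(pwm)
    codes = encode_sequence(seq)
    if codes.size < K:
        return []

    out: list[MotifInstance] = []
    strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if both_strands else [])
    for strand, mat in strands:
        lo = build_logodds(mat, bg)
        ilo = _integerize(lo)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = pvalue_threshold(lo, bg, alpha)
        scores, valid = _window_scores(codes, ilo)
        hits = np.nonzero(valid & (scores >= thr.int_threshold))[0]
        if hits.size == 0:
            continue
        real = np.zeros(hits.size)
        for j in range(K):
            real += lo[j][codes[hits + j]]
        tails = np.atleast_1d(thr.distribution.tail(scores[hits]))
        for i, h in enumerate(hits):
            out.append(
                MotifInstance(
                    chrom=chrom,
                    start=offset + int(h),
                    end=offset + int(h) + K,
                    strand=strand,
                    score=float(real[i]),
                    pvalue=float(tails[i]),
                    motif_id=pwm.motif_id,
                    scanner_id=scanner_id,
                )
            )
    out.sort(key=lambda m: m.sort_key)
    return out


def scan_sequences(
    sequences: dict[str, str],
    pwm: Pwm,
    scanner: str = "A",
    alpha: float = 1e-4,
    both_strands: bool = True,
) -> list[MotifInstance]:
    """Scan a named sequence collection with one of the two scanner setups.

    Scanner "A" scores against a uniform background; scanner "B" against
    the pooled base composition of the scanned sequences.  Two instance
    sets produced this way feed :func:`cross_validate`.
    """
    if scanner == "A":
        bg = BackgroundModel.uniform()
    elif scanner == "B":
        bg = BackgroundModel.from_sequence("".join(sequences.values()))
    else:
        raise ValueError("scanner must be 'A' or 'B'")
    out: list[MotifInstance] = []
    for chrom, seq in sequences.items():
        out.extend(
            scan_sequence(
                seq, pwm, bg, alpha=alpha, both_strands=both_strands,
                chrom=chrom, scanner_id=scanner,
            )
        )
    out.sort(key=lambda m: m.sort_key)
    return out


def cross_validate(
    instances_a: Sequence[MotifInstance],
    instances_b: Sequence[MotifInstance],
    slack: int = 1,
    require_strand: bool = True,
    criterion: str = "and",
) -> list[MotifInstance]:
    """Retain instances from A that a partner in B confirms within slack.

    A partner must lie on the same chromosome (and strand, unless
    ``require_strand=False``) with |delta start| <= slack AND
    |delta end| <= slack (``criterion="or"`` relaxes AND to OR).  Matching
    is one-to-one and greedy in ascending (start, end) order; retained
    instances keep A's coordinates.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    if criterion not in ("and", "or"):
        raise ValueError("criterion must be 'and' or 'or'")
    ids = {m.motif_id for m in instances_a} | {m.motif_id for m in instances_b}
    if len(ids) > 1:
        raise ValueError(f"mixed motif_ids in cross-validation: {sorted(ids)}")

    def group_key(m: MotifInstance):
        return (m.chrom, m.strand) if require_strand else (m.chrom,)

    b_groups: dict[tuple, list[MotifInstance]] = {}
    for m in sorted(instances_b, key=lambda m: (m.start, m.end)):
        b_groups.setdefault(group_key(m), []).append(m)
    b_starts = {k: [m.start for m in v] for k, v in b_groups.items()}
    matched: dict[tuple, list[bool]] = {k: [False] * len(v) for k, v in b_groups.items()}

    out: list[MotifInstance] = []
    for a in sorted(instances_a, key=lambda m: (m.chrom, m.start, m.end, m.strand)):
        key = group_key(a)
        cands = b_groups.get(key)
        if not cands:
            continue
        starts = b_starts[key]
        lo = bisect_left(starts, a.start - slack)
        hi = bisect_left(starts, a.start + slack + 1) if criterion == "and" else len(starts)
        for j in range(lo if criterion == "and" else 0, hi):
            if matched[key][j]:
                continue
            b = cands[j]
            ds, de = abs(b.start - a.start), abs(b.end - a.end)
            hit = (ds <= slack and de <= slack) if criterion == "and" else (ds <= slack or de <= slack)
            if hit:
                matched[key][j] = True
                out.append(a)
                break
    out.sort(key=lambda m: m.sort_key)
    return out


# ---------------------------------------------------------------------------
# PWM input/output


def pwm_from_counts(motif_id: str, counts: np.ndarray, pseudocount: float = 0.001,
                    source: str = "") -> Pwm:
    """Column counts (K, 4) -> probability PWM."""
    counts = np.asarray(counts, dtype=float)
    probs = counts / counts.sum(axis=1, keepdims=True)
    return Pwm(motif_id, probs, pseudocount=pseudocount, source=source)


def parse_jaspar(text: str, pseudocount: float = 0.001) -> list[Pwm]:
    """Parse JASPAR-format PWM text (count matrices) via Bio.motifs."""
    from Bio import motifs as bio_motifs

    out = []
    for m in bio_motifs.parse(_io.StringIO(text), "jaspar"):
        counts = np.array([[m.counts[b][i] for b in BASES] for i in range(m.length)])
        name = m.matrix_id or m.name
        out.append(pwm_from_counts(name, counts, pseudocount=pseudocount, source="jaspar"))
    return out


def parse_probability_tsv(text: str, motif_id: str, pseudocount: float = 0.001) -> Pwm:
    """Parse a simple 4-column (A, C, G, T) probability table, one row per position."""
    rows = [
        [float(x) for x in line.split()]
        for line in text.strip().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return Pwm(motif_id, np.array(rows), pseudocount=pseudocount)


def instances_to_bed(instances: Iterable[MotifInstance]) -> str:
    """Serialize instances as BED6+2 (score = bits x 100, extra pvalue, scanner)."""
    lines = []
    for m in instances:
        score = 0 if np.isnan(m.score) else int(round(m.score * 100))
        lines.append(
            "\t".join(
                [
                    m.chrom,
                    str(m.start),
                    str(m.end),
                    m.motif_id,
                    str(score),
                    m.strand,
                    f"{m.pvalue:.6g}",
                    m.scanner_id,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def instances_from_bed(text: str) -> list[MotifInstance]:
    out = []
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        out.append(
            MotifInstance(
                chrom=f[0], start=int(f[1]), end=int(f[2]), motif_id=f[3],
                score=int(f[4]) / 100.0, strand=f[5],
                pvalue=float(f[6]) if len(f) > 6 else 1.0,
                scanner_id=f[7] if len(f) > 7 else "A",
            )
        )
    return out
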