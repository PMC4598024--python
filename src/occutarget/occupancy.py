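"""TSS-window occupancy scoring (Total Gene Score) and density profiles.

The Total Gene Score (TGS) of a gene is the amount of ChIP signal falling
in a fixed window around its transcription start site: for read datasets,
the number of reads assigned to the window; for peak datasets, the summed
signalValue (or count) of peaks whose summit falls in the window.  Scores
are normalized to the dataset mean over a gene universe, and genes scoring
strictly above that mean (normalized TGS > 1) are called targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneAnnotation, Interval, Peak


@dataclass(frozen=True)
class WindowSpec:
    """TSS window geometry and read/peak assignment rules.

    half_width
        Window half-width in bp; the window is [tss - half_width,
        tss + half_width), half-open, truncated at coordinate 0.
    read_assignment
        ``"midpoint"`` (default) assigns a read by its midpoint;
        ``"five_prime"`` by its 5' end (strand-aware).
    peak_assignment
        ``"summit"`` (default) assigns a peak by its called summit, falling
        back to the midpoint for peaks without one; ``"midpoint"`` always
        uses the midpoint.
    """

    half_width: int = 10_000
    read_assignment: str = "midpoint"
    peak_assignment: str = "summit"

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.read_assignment not in ("midpoint", "five_prime"):
            raise ValueError("read_assignment must be 'midpoint' or 'five_prime'")
        if self.peak_assignment not in ("summit", "midpoint"):
            raise ValueError("peak_assignment must be 'summit' or 'midpoint'")


@dataclass(frozen=True)
class OccupancyScore:
    """Raw and mean-normalized TGS for one gene in one ChIP dataset."""

    gene_id: str
    raw_tgs: float
    normalized_tgs: float
    is_target: bool

    def __post_init__(self) -> None:
        if self.raw_tgs < 0:
            raise ValueError("raw_tgs must be >= 0")
        if self.is_target != (self.normalized_tgs > 1):
            raise ValueError("is_target must equal (normalized_tgs > 1)")


@dataclass(frozen=True)
class DensityProfile:
    """TSS-centered reads-per-million binned density, reported 5'->3'."""

    label: str
    bin_width: int
    half_width: int
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 2 * self.half_width // self.bin_width:
            raise ValueError("bin count must equal 2*half_width / bin_width")
        if any(v < 0 for v in self.values):
            raise ValueError("density values must be >= 0")


def _read_positions(reads: list[Interval], rule: str) -> dict[str, np.ndarray]:
    """Sorted assignment positions per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for r in reads:
        if rule == "midpoint":
            pos = r.midpoint
        else:  # five_prime
            pos = r.start if r.strand != "-" else r.end - 1
        by_chrom.setdefault(r.chrom, []).append(pos)
    return {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in by_chrom.items()}


def _window(gene: GeneAnnotation, half_width: int) -> tuple[int, int]:
    return max(0, gene.tss - half_width), gene.tss + half_width


def compute_tgs(
    reads: list[Interval],
    genes: list[GeneAnnotation],
    window: WindowSpec | None = None,
) -> dict[str, float]:
    """Count reads assigned to each gene's TSS window (read-dataset TGS)."""
    if not genes:
        raise ValueError("gene list must be non-empty")
    window = window or WindowSpec()
    positions = _read_positions(reads, window.read_assignment)
    scores: dict[str, float] = {}
    for g in genes:
        lo, hi = _window(g, window.half_width)
        pos = positions.get(g.chrom)
        if pos is None:
            scores[g.gene_id] = 0.0
        else:
            scores[g.gene_id] = float(
                np.searchsorted(pos, hi, side="left")
                - np.searchsorted(pos, lo, side="left")
            )
    return scores


def compute_tgs_from_peaks(
    peaks: list[Peak],
    genes: list[GeneAnnotation],
    window: WindowSpec | None = None,
    use_count: bool = False,
) -> dict[str, float]:
    """Sum peak signal (or count peaks) with summit in each TSS window.

    ``use_count=True`` counts qualifying peaks instead of summing their
    signalValues; both readings of a summed-peak score are supported.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    window = window or WindowSpec()
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for p in peaks:
        pos = p.summit if window.peak_assignment == "summit" else (p.start + p.end) // 2
        by_chrom.setdefault(p.chrom, []).append((pos, 1.0 if use_count else p.signal))
    chrom_arrays = {}
    for c, pairs in by_chrom.items():
        pairs.sort()
        pos = np.asarray([x[0] for x in pairs], dtype=np.int64)
        val = np.asarray([x[1] for x in pairs], dtype=float)
        chrom_arrays[c] = (pos, np.concatenate([[0.0], np.cumsum(val)]))
    scores: dict[str, float] = {}
    for g in genes:
        lo, hi = _window(g, window.half_width)
        if g.chrom not in chrom_arrays:
            scores[g.gene_id] = 0.0
            continue
        pos, cum = chrom_arrays[g.chrom]
        i, j = np.searchsorted(pos, lo, side="left"), np.searchsorted(pos, hi, side="left")
        scores[g.gene_id] = float(cum[j] - cum[i])
    return scores


def normalize_tgs(
    raw: dict[str, float], universe: set[str] | None = None
) -> dict[str, float]:
    """Divide every raw TGS by the mean raw TGS over the gene universe.

    The universe defaults to all supplied genes; pass the expressed-gene set
    to normalize against expressed genes only.
    """
    if universe is None:
        universe = set(raw)
    missing = universe - raw.keys()
    if missing:
        raise ValueError(f"universe contains genes without scores: {sorted(missing)[:5]}")
    if not universe:
        raise ValueError("universe must be non-empty")
    mean = float(np.mean([raw[g] for g in universe]))
    if mean <= 0:
        raise ValueError("degenerate dataset: mean TGS over the universe is 0")
    return {g: v / mean for g, v in raw.items()}


def call_targets(normalized: dict[str, float], threshold: float = 1.0) -> set[str]:
    """Genes with normalized TGS strictly above the threshold (dataset mean)."""
    for g, v in normalized.items():
        if not np.isfinite(v):
            raise ValueError(f"non-finite normalized TGS for {g}")
    return {g for g, v in normalized.items() if v > threshold}


def score_dataset(
    raw: dict[str, float],
    universe: set[str] | None = None,
    threshold: float = 1.0,
) -> list[OccupancyScore]:
    """Bundle raw score, normalized score and target call per gene."""
    normalized = normalize_tgs(raw, universe)
    targets = call_targets(normalized, threshold)
    return [
        OccupancyScore(g, raw[g], normalized[g], g in targets)
        for g in sorted(raw)
    ]


def tss_profile(
    reads: list[Interval],
    gene: GeneAnnotation,
    half_width: int = 1_500,
    bin_width: int = 50,
    library_size: int | None = None,
    read_assignment: str = "midpoint",
) -> DensityProfile:
    """Reads-per-million density in fixed bins around a gene's TSS.

    Bins are reported 5'->3' with respect to the gene: profiles of
    minus-strand genes are reversed so that upstream flank comes first.
    """
    if half_width <= 0 or bin_width <= 0 or (2 * half_width) % bin_width != 0:
        raise ValueError("bin_width must divide 2*half_width")
    if library_size is None:
        library_size = len(reads)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    n_bins = 2 * half_width // bin_width
    counts = np.zeros(n_bins, dtype=float)
    positions = _read_positions(reads, read_assignment).get(gene.chrom)
    if positions is not None:
        offsets = positions - gene.tss
        in_win = (offsets >= -half_width) & (offsets < half_width)
        idx = (offsets[in_win] + half_width) // bin_width
        np.add.at(counts, idx.astype(int), 1.0)
    values = counts * 1e6 / library_size
    if gene.strand == "-":
        values = values[::-1]
    return DensityProfile(
        label=gene.gene_id,
        bin_width=bin_width,
        half_width=half_width,
        values=tuple(float(v) for v in values),
    )
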