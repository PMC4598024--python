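"""Seeded generators for every input the occupancy pipeline consumes.

The generators emulate the statistical structure the analysis assumes:

- a single chromosome with well-spaced gene TSSs, a subset designated as
  factor-occupied;
- uniform Poisson background reads plus, at occupied TSSs, a planted
  point-source of extra reads placed Normal(TSS, sigma), with companion
  narrowPeak records whose signal is proportional to the planted reads;
- RPKM expression matrices in which occupied genes carry a fixed log2
  shift, with species-specific per-stage decline schedules emulating
  early-decline ("mouse") versus late-decline ("human") differentiation;
- promoter sequences with consensus motifs planted at known ATG-relative
  positions, returned together with the ground-truth hits.

Every generator is deterministic given the configuration seed; distinct
generators consume independent seeded streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import GeneAnnotation, Interval, Peak, PromoterSequence
from .motif import (
    IUPAC_CODES,
    MotifHit,
    MotifPattern,
    compile_pattern,
    from_promoter_coords,
    scan,
)

__all__ = [
    "SimulationConfig",
    "make_annotation",
    "make_reads",
    "make_expression",
    "make_promoter",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome, ChIP and expression data.

    Defaults follow the planted-signal regime the pipeline is validated
    under: 200 genes on a 6 Mb chromosome, 15% occupied, 5e-4 background
    reads/bp with 40 extra reads per occupied TSS placed at sigma = 300 bp,
    and a +1 log2-RPKM expression shift for occupied genes.
    """

    seed: int = 0
    # genome / annotation
    n_genes: int = 200
    chrom: str = "chr1"
    chrom_length: int = 6_000_000
    min_gene_spacing: int = 25_000
    fraction_rp: float = 0.3
    fraction_dba_of_rp: float = 0.3
    fraction_occupied: float = 0.15
    # ChIP reads and peaks
    background_rate: float = 5e-4  # reads per bp (Poisson)
    enrichment_reads: float = 40.0  # mean extra reads per occupied TSS
    enrichment_sigma: float = 300.0  # bp spread of planted reads around TSS
    read_length: int = 36
    peak_half_width: int = 250
    # expression
    stages: tuple[str, ...] = ("ProE", "Baso", "Poly", "Ortho")
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.0
    occupied_shift: float = 1.0  # log2 units added to occupied genes
    decline_schedules: tuple[tuple[str, tuple[float, ...]], ...] = (
        ("mouse", (0.0, -2.0, -3.0, -3.5)),  # steep early drop
        ("human", (0.0, -0.5, -2.5, -3.5)),  # drop delayed to later stages
    )
    # promoter
    promoter_length: int = 1_200
    promoter_atg_index: int = 1_000
    motif_plantings: tuple[tuple[str, str, int], ...] = (
        ("GATA1", "WGATAR", -694),
        ("PU1", "RRGGAA", -709),
        ("PU1", "RRGGAA", -653),
    )
    background_alphabet: tuple[str, ...] = ("A", "C", "G", "T")

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.chrom_length <= 0 or self.min_gene_spacing <= 0:
            raise ValueError("genome dimensions must be positive")
        for frac in (self.fraction_rp, self.fraction_dba_of_rp, self.fraction_occupied):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.background_rate < 0 or self.enrichment_reads < 0:
            raise ValueError("read rates must be >= 0")
        if self.enrichment_sigma < 0:
            raise ValueError("enrichment_sigma must be >= 0")
        for _, sched in self.decline_schedules:
            if len(sched) != len(self.stages):
                raise ValueError("decline schedule length must match stage count")
        for _, _, pos in self.motif_plantings:
            if pos == 0:
                raise ValueError("the ATG frame has no position 0")

    def schedule(self, species: str) -> tuple[float, ...]:
        for name, sched in self.decline_schedules:
            if name == species:
                return sched
        raise KeyError(f"no decline schedule for species {species!r}")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.decline_schedules)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def make_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], set[str]]:
    """Generate gene annotations and the designated occupied gene set.

    TSSs keep pairwise spacing >= ``min_gene_spacing``; exactly
    ``round(fraction_occupied * n_genes)`` genes are occupied.
    """
    n, spacing = config.n_genes, config.min_gene_spacing
    if n * spacing > config.chrom_length:
        raise ValueError(
            f"{n} genes at spacing {spacing} do not fit in {config.chrom_length} bp"
        )
    rng = _rng(config, 0)
    slack = config.chrom_length - n * spacing
    offsets = np.sort(rng.uniform(0, slack, size=n)).astype(np.int64)
    tss = offsets + spacing * np.arange(n) + spacing // 2
    strands = rng.choice(["+", "-"], size=n)
    n_rp = round(config.fraction_rp * n)
    rp_idx = set(rng.choice(n, size=n_rp, replace=False).tolist())
    n_dba = round(config.fraction_dba_of_rp * n_rp)
    dba_idx = set(rng.choice(sorted(rp_idx), size=n_dba, replace=False).tolist())
    n_occ = round(config.fraction_occupied * n)
    occ_idx = set(rng.choice(n, size=n_occ, replace=False).tolist())

    width = len(str(n))
    genes = [
        GeneAnnotation(
            gene_id=f"g{i + 1:0{width}d}",
            gene_name=f"G{i + 1}",
            chrom=config.chrom,
            strand=str(strands[i]),
            tss=int(tss[i]),
            is_rp=i in rp_idx,
            is_dba=i in dba_idx,
        )
        for i in range(n)
    ]
    occupied = {genes[i].gene_id for i in occ_idx}
    return genes, occupied


def make_reads(
    genes: list[GeneAnnotation],
    occupied: set[str],
    config: SimulationConfig,
) -> tuple[list[Interval], list[Peak]]:
    """Simulate ChIP reads and companion narrowPeak records.

    Background reads are uniform on the chromosome with per-bp Poisson rate
    ``background_rate``; each occupied TSS receives Poisson(enrichment_reads)
    extra reads centred Normal(TSS, enrichment_sigma).  One narrowPeak per
    occupied TSS carries the planted read count as its signalValue, summit
    at the TSS.
    """
    rng = _rng(config, 1)
    rl = config.read_length
    hi = config.chrom_length - rl
    starts: list[np.ndarray] = []

    n_bg = rng.poisson(config.background_rate * config.chrom_length)
    starts.append(rng.integers(0, hi, size=n_bg))

    peaks: list[Peak] = []
    for g in genes:
        if g.gene_id not in occupied:
            continue
        n_extra = int(rng.poisson(config.enrichment_reads))
        if n_extra > 0:
            centers = rng.normal(g.tss, config.enrichment_sigma, size=n_extra)
            starts.append(
                np.clip(np.round(centers).astype(np.int64) - rl // 2, 0, hi)
            )
        p_start = max(0, g.tss - config.peak_half_width)
        p_end = min(config.chrom_length, g.tss + config.peak_half_width)
        peaks.append(
            Peak(
                chrom=g.chrom,
                start=p_start,
                end=p_end,
                name=f"peak_{g.gene_id}",
                signal=float(n_extra),
                summit_offset=g.tss - p_start,
            )
        )
    all_starts = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    reads = [
        Interval(config.chrom, int(s), int(s) + rl, ".") for s in all_starts
    ]
    return reads, peaks


def make_expression(
    genes: list[GeneAnnotation],
    occupied: set[str],
    config: SimulationConfig,
    species: str = "mouse",
):
    """Simulate an RPKM matrix with the occupied-gene log2 shift.

    Per (gene, stage): log2 RPKM ~ Normal(baseline_log2_mean,
    baseline_log2_sd) + occupied_shift * [gene occupied] + schedule[stage],
    exponentiated to the RPKM scale.
    """
    from .genome_io import ExpressionMatrix

    schedule = np.asarray(config.schedule(species), dtype=float)
    stream = 2 + 10 * list(config.species).index(species)
    rng = _rng(config, stream)
    n, s = len(genes), len(config.stages)
    occ = np.array([g.gene_id in occupied for g in genes], dtype=float)
    log2 = (
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=(n, s))
        + config.occupied_shift * occ[:, None]
        + schedule[None, :]
    )
    return ExpressionMatrix(
        [g.gene_id for g in genes], list(config.stages), 2.0**log2, species
    )


def _violating_base(allowed: frozenset[str]) -> str | None:
    """A deterministic base outside ``allowed``, preferring pyrimidines."""
    for base in ("C", "T", "A", "G"):
        if base not in allowed:
            return base
    return None


def make_promoter(
    config: SimulationConfig,
) -> tuple[PromoterSequence, list[MotifHit]]:
    """Generate a promoter with motifs planted at ATG-relative positions.

    The background is random over ``background_alphabet``; each planting
    writes one concrete realization of its consensus at the stated
    position.  Spurious background matches of any planted pattern are
    eliminated by pointwise base changes outside the planted spans, so that
    scanning each pattern recovers exactly its planted sites.
    """
    rng = _rng(config, 3)
    length, atg = config.promoter_length, config.promoter_atg_index
    chars = list(rng.choice(config.background_alphabet, size=length))

    spans: list[tuple[int, int]] = []
    truth: list[MotifHit] = []
    for name, iupac, pos in config.motif_plantings:
        compiled = compile_pattern(iupac)
        k = len(compiled)
        start = from_promoter_coords(pos, atg)
        if start < 0 or start + k > length:
            raise ValueError(
                f"planting {name} at {pos} falls outside the {length} nt sequence"
            )
        for s0, s1 in spans:
            if start < s1 and s0 < start + k:
                raise ValueError(f"planting {name} at {pos} overlaps a previous planting")
        word = "".join(
            rng.choice(sorted(s)) for s in compiled.position_sets
        )
        chars[start : start + k] = list(word)
        spans.append((start, start + k))
        truth.append(MotifHit(name, start, "+", word, pos))

    patterns = {
        (name, iupac) for name, iupac, _ in config.motif_plantings
    }
    planted_keys = {(h.pattern, h.seq_index, h.strand) for h in truth}

    def in_planted_span(i: int) -> bool:
        return any(s0 <= i < s1 for s0, s1 in spans)

    for _ in range(1000):
        dirty = False
        for name, iupac in sorted(patterns):
            pat = MotifPattern(name, iupac, "both")
            oriented = {
                "+": compile_pattern(iupac),
                "-": compile_pattern(iupac).reverse_complement(),
            }
            for hit in scan("".join(chars), pat):
                if (hit.pattern, hit.seq_index, hit.strand) in planted_keys:
                    continue
                comp = oriented[hit.strand]
                for off, allowed in enumerate(comp.position_sets):
                    idx = hit.seq_index + off
                    if in_planted_span(idx):
                        continue
                    base = _violating_base(allowed)
                    if base is not None:
                        chars[idx] = base
                        dirty = True
                        break
                else:
                    raise RuntimeError(
                        f"spurious {name} match at {hit.seq_index} lies entirely "
                        "within planted spans and cannot be removed"
                    )
                break  # rescan after each edit
            if dirty:
                break
        if not dirty:
            break
    else:
        raise RuntimeError("failed to remove spurious motif matches")

    seq = PromoterSequence("".join(chars), atg)
    truth.sort(key=lambda h: h.seq_index)
    return seq, truth
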