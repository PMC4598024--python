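"""End-to-end pipeline runner: score, call targets, scan, associate.

The runner composes the library modules over files on disk and writes a
result bundle with a manifest recording the tool version, a hash of the
configuration, and per-stage record counts.  Outputs use fixed float
formatting (6 significant digits) so reruns on identical inputs are
byte-identical.  A manifest is always written, marking failure when any
stage raises.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import association as assoc_mod
from . import genome_io, motif, occupancy

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""

    def __init__(self, stage: str, path: str | None, cause: Exception) -> None:
        where = f" ({path})" if path else ""
        super().__init__(f"stage {stage!r}{where}: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    genes_path: str
    outdir: str
    reads_path: str | None = None
    peaks_path: str | None = None
    expression_paths: tuple[str, ...] = ()
    promoter_fasta: str | None = None
    atg_index: int = 0
    patterns: tuple[tuple[str, str], ...] = (("GATA1", "WGATAR"), ("PU1", "RRGGAA"))
    half_width: int = 10_000
    use_peak_count: bool = False
    universe_path: str | None = None
    epsilon: float = 0.1
    exact_cutoff: int = assoc_mod.EXACT_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.reads_path is None) == (self.peaks_path is None):
            raise ValueError("provide exactly one of reads_path or peaks_path")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_scores(scores: list[occupancy.OccupancyScore], path: Path) -> None:
    df = pd.DataFrame(
        [(s.gene_id, s.raw_tgs, s.normalized_tgs, int(s.is_target)) for s in scores],
        columns=["gene_id", "raw_tgs", "normalized_tgs", "is_target"],
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_hits(hits: list[motif.MotifHit], path: Path) -> None:
    df = pd.DataFrame(
        [(h.pattern, h.seq_index, h.strand, h.match, h.promoter_pos) for h in hits],
        columns=["pattern", "seq_index", "strand", "match", "promoter_pos"],
    )
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run scoring, target calling, motif scanning and association.

    Returns the result bundle (scores, target set, hits, association
    tables, manifest) and writes each component under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "occutarget",
        "version": __version__,
        "config_hash": _config_hash(config),
        "status": "failed",
        "counts": {},
    }
    counts = manifest["counts"]
    try:
        result = _run_stages(config, outdir, counts)
        manifest["status"] = "ok"
        result["manifest"] = manifest
        return result
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage(stage: str, path: str | None, fn):
    try:
        return fn()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, path, exc) from exc


def _run_stages(config: RunConfig, outdir: Path, counts: dict) -> dict:
    genes = _stage(
        "annotation", config.genes_path,
        lambda: genome_io.read_table(config.genes_path, "annotation"),
    )
    counts["genes"] = len(genes)

    window = occupancy.WindowSpec(half_width=config.half_width)
    if config.reads_path is not None:
        reads = _stage(
            "reads", config.reads_path,
            lambda: genome_io.read_intervals(config.reads_path),
        )
        counts["reads"] = len(reads)
        raw = _stage(
            "tgs", config.reads_path, lambda: occupancy.compute_tgs(reads, genes, window)
        )
    else:
        peaks = _stage(
            "peaks", config.peaks_path,
            lambda: genome_io.read_narrowpeak(config.peaks_path),
        )
        counts["peaks"] = len(peaks)
        raw = _stage(
            "tgs", config.peaks_path,
            lambda: occupancy.compute_tgs_from_peaks(
                peaks, genes, window, use_count=config.use_peak_count
            ),
        )

    universe = None
    if config.universe_path is not None:
        universe = _stage(
            "universe", config.universe_path,
            lambda: {
                line.strip()
                for line in open(config.universe_path)
                if line.strip()
            },
        )
    scores = _stage(
        "normalize", None, lambda: occupancy.score_dataset(raw, universe)
    )
    targets = {s.gene_id for s in scores if s.is_target}
    counts["targets"] = len(targets)
    write_scores(scores, outdir / "scores.tsv")
    with open(outdir / "targets.txt", "w") as fh:
        fh.writelines(f"{g}\n" for g in sorted(targets))

    hits: list[motif.MotifHit] = []
    if config.promoter_fasta is not None:
        seqs = _stage(
            "promoter", config.promoter_fasta,
            lambda: genome_io.read_fasta(config.promoter_fasta),
        )
        for seq in seqs.values():
            prom = genome_io.PromoterSequence(seq, config.atg_index)
            for name, iupac in config.patterns:
                hits.extend(motif.scan(prom, motif.MotifPattern(name, iupac)))
        counts["motif_hits"] = len(hits)
        write_hits(hits, outdir / "hits.tsv")

    association_tables: dict[str, pd.DataFrame] = {}
    for expr_path in config.expression_paths:
        expr = _stage(
            "expression", expr_path,
            lambda p=expr_path: genome_io.read_table(p, "expression"),
        )
        table = _stage(
            "association", expr_path,
            lambda e=expr: assoc_mod.occupancy_expression_association(
                e, targets & set(e.genes), exact_cutoff=config.exact_cutoff
            ),
        )
        label = Path(expr_path).stem
        association_tables[label] = table
        table.reset_index().to_csv(
            outdir / f"association_{label}.tsv",
            sep="\t", index=False, float_format=FLOAT_FMT,
        )
    counts["association_tables"] = len(association_tables)

    return {
        "scores": scores,
        "targets": targets,
        "hits": hits,
        "association": association_tables,
    }
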