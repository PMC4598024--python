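"""ChIP-qPCR fold enrichment versus input and qRT-PCR relative expression.

Both calculations use the comparative-Ct method with a reference amplicon
(typically GAPDH).  ChIP enrichment of a target region is

    fold = E ** (dCt_input - dCt_IP),   dCt = Ct(target) - Ct(reference)

with amplification efficiency E = 2 by default (one doubling per cycle).
Relative expression is the standard 2^(-ddCt) against a calibrator sample.
Replicates are summarized by the mean Ct; dispersion is propagated by
evaluating the formula over every combination of technical replicates,
which is exhaustive at qPCR scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .genome_io import CtMeasurement


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold enrichment of one amplicon, with replicate-combination spread."""

    amplicon: str
    fold_enrichment: float
    dispersion: float

    def __post_init__(self) -> None:
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def _index(measurements: list[CtMeasurement], what: str) -> dict[str, CtMeasurement]:
    idx: dict[str, CtMeasurement] = {}
    for m in measurements:
        if m.amplicon in idx:
            raise ValueError(f"duplicate amplicon {m.amplicon!r} in {what} set")
        idx[m.amplicon] = m
    return idx


def chip_enrichment(
    ip: list[CtMeasurement],
    input_: list[CtMeasurement],
    reference: str,
    efficiency: float = 2.0,
) -> dict[str, EnrichmentResult]:
    """Fold enrichment versus input for every non-reference amplicon.

    ``ip`` and ``input_`` are the Ct measurements of the immunoprecipitated
    and the input chromatin; ``reference`` names the normalizer amplicon
    (e.g. GAPDH), which must be present in both sets.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ip_idx = _index(ip, "IP")
    in_idx = _index(input_, "input")
    for what, idx in (("IP", ip_idx), ("input", in_idx)):
        if reference not in idx:
            raise ValueError(f"reference amplicon {reference!r} missing from {what} set")
    targets = sorted((set(ip_idx) & set(in_idx)) - {reference})
    if not targets:
        raise ValueError("no target amplicon present in both IP and input sets")

    results: dict[str, EnrichmentResult] = {}
    for t in targets:
        d_ip = ip_idx[t].mean_ct - ip_idx[reference].mean_ct
        d_in = in_idx[t].mean_ct - in_idx[reference].mean_ct
        fold = float(efficiency ** (d_in - d_ip))
        combos = [
            float(efficiency ** ((ci_t - ci_r) - (cp_t - cp_r)))
            for cp_t, cp_r, ci_t, ci_r in itertools.product(
                ip_idx[t].ct_values,
                ip_idx[reference].ct_values,
                in_idx[t].ct_values,
                in_idx[reference].ct_values,
            )
        ]
        sd = float(np.std(combos, ddof=1)) if len(combos) > 1 else 0.0
        results[t] = EnrichmentResult(t, fold, sd)
    return results


def relative_expression(
    measurements: list[CtMeasurement],
    reference_gene: str,
    calibrator_sample: str,
    efficiency: float = 2.0,
) -> dict[tuple[str, str], float]:
    """2^(-ddCt) relative expression per (gene, sample) versus a calibrator.

    Every sample must include the reference gene; the calibrator sample
    (e.g. the 0-hour timepoint) defines fold change 1 for every gene.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    by_sample: dict[str, dict[str, CtMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample, {})[m.amplicon] = m
    if calibrator_sample not in by_sample:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not measured")
    for sample, amps in by_sample.items():
        if reference_gene not in amps:
            raise ValueError(
                f"reference gene {reference_gene!r} missing from sample {sample!r}"
            )

    dct: dict[tuple[str, str], float] = {}
    for sample, amps in by_sample.items():
        for gene, m in amps.items():
            if gene == reference_gene:
                continue
            dct[(gene, sample)] = m.mean_ct - amps[reference_gene].mean_ct

    folds: dict[tuple[str, str], float] = {}
    for (gene, sample), d in dct.items():
        if (gene, calibrator_sample) not in dct:
            raise ValueError(
                f"gene {gene!r} not measured in calibrator sample "
                f"{calibrator_sample!r}"
            )
        ddct = d - dct[(gene, calibrator_sample)]
        folds[(gene, sample)] = float(efficiency ** (-ddct))
    return folds
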