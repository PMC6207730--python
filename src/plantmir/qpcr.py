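"""Stem-loop RT-qPCR primer design and efficiency-corrected expression.

Mature miRNAs (~21 nt) are too short for conventional RT-qPCR; the stem-loop
method extends them during reverse transcription with a 50-nt primer whose
first 44 nt are a universal hairpin-forming backbone and whose last 6 nt
reverse-complement the 3' end of the specific miRNA. The forward PCR primer
carries the miRNA sequence minus those last 6 nt, padded at the 5' end with
5-7 GC-biased bases to raise its melting temperature; the reverse primer is
universal (derived from the backbone) and shared by every assay.

Amplification efficiency E is estimated per assay from a standard curve of
a 1:5 serial dilution: the slope of Cq against log10(relative concentration)
gives E = 10^(-1/slope) - 1 (slope -3.32 <=> E = 100%). Relative expression
between two conditions uses the efficiency-corrected comparative Cq ratio,
normalised by the geometric mean of reference-gene ratios (U6 and 5.8S by
convention).
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqs import revcomp_dna, rna_to_dna

logger = logging.getLogger(__name__)

#: canonical published universal stem-loop backbone (44 nt)
DEFAULT_BACKBONE = "GTCGTATCCAGTGCAGGGTCCGAGGTATTCGCACTGGATACGAC"


@dataclass(frozen=True)
class PrimerConfig:
    universal_backbone: str = DEFAULT_BACKBONE
    specific_len: int = 6
    pad_min: int = 5
    pad_max: int = 7
    target_tm: float = 60.0
    tm_method: str = "nearest-neighbor"     # or "simple" (Wallace 2/4 rule)
    reverse_segment: Tuple[int, int] = (10, 26)   # backbone slice primed by the reverse primer
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.universal_backbone) != 44:
            raise ValueError("universal backbone must be exactly 44 nt")
        if self.pad_min > self.pad_max:
            raise ValueError("pad_min must be <= pad_max")


@dataclass(frozen=True)
class PrimerSet:
    mirna_id: str
    stemloop_rt: str
    forward: str
    reverse: str
    forward_tm: float


@dataclass(frozen=True)
class DilutionCurve:
    mirna_id: str
    points: Tuple[Tuple[float, float], ...]   # (log10 relative concentration, Cq)
    slope: float
    intercept: float
    r_squared: float
    efficiency: float


@dataclass(frozen=True)
class ExpressionResult:
    target_id: str
    condition_pair: Tuple[str, str]           # (reference/baseline, test)
    ratio: float
    normalization_factor: float


def _melting_temperature(primer: str, method: str) -> float:
    if method == "simple":
        from Bio.SeqUtils import MeltingTemp
        return float(MeltingTemp.Tm_Wallace(primer))
    from Bio.SeqUtils import MeltingTemp
    return float(MeltingTemp.Tm_NN(primer))


def design_stemloop(mirna: str, mirna_id: str = "", config: PrimerConfig = PrimerConfig()) -> PrimerSet:
    """Design the stem-loop RT / forward / reverse primer trio for one miRNA.

    The forward-primer pad is drawn GC-biased from a generator seeded by
    (config.seed, mirna id) so repeated designs are reproducible; the
    smallest pad length in [pad_min, pad_max] reaching the target Tm is
    used (falling back to pad_max with a warning).
    """
    dna = rna_to_dna(mirna.strip())
    if not (19 <= len(dna) <= 24):
        raise ValueError(f"mature miRNA must be 19-24 nt, got {len(dna)}")
    core = dna[:-config.specific_len]
    if len(core) < 13:
        raise ValueError("miRNA too short after removing the 3' specific segment")
    specific = revcomp_dna(dna[-config.specific_len:])
    stemloop_rt = config.universal_backbone + specific

    rng = np.random.default_rng(
        (config.seed * 2654435761 + zlib.crc32(mirna_id.encode() or dna.encode())) % (2**31)
    )
    pad_pool = rng.choice(list("GCGCAT"), size=config.pad_max)   # 2/3 G or C
    chosen: Optional[str] = None
    tm = 0.0
    for pad_len in range(config.pad_min, config.pad_max + 1):
        candidate = "".join(pad_pool[:pad_len]) + core
        tm = _melting_temperature(candidate, config.tm_method)
        if tm >= config.target_tm:
            chosen = candidate
            break
    if chosen is None:
        chosen = "".join(pad_pool) + core
        tm = _melting_temperature(chosen, config.tm_method)
        logger.warning(
            "forward primer for %s reaches Tm %.1f < target %.1f even at maximum pad",
            mirna_id or dna, tm, config.target_tm,
        )
    seg_start, seg_end = config.reverse_segment
    reverse = revcomp_dna(config.universal_backbone[seg_start:seg_end])
    return PrimerSet(
        mirna_id=mirna_id or dna,
        stemloop_rt=stemloop_rt,
        forward=chosen,
        reverse=reverse,
        forward_tm=tm,
    )


def fit_standard_curve(
    points: Sequence[Tuple[float, float]],
    mirna_id: str = "",
) -> DilutionCurve:
    """Least-squares Cq-vs-log10(concentration) line and the efficiency
    E = 10^(-1/slope) - 1.

    ``points`` are (relative concentration, Cq) pairs; at least three
    distinct concentrations are required and all must be positive.
    """
    if len(points) < 3:
        raise ValueError("standard curve requires at least 3 dilution points")
    conc = np.asarray([p[0] for p in points], dtype=float)
    cq = np.asarray([p[1] for p in points], dtype=float)
    if np.any(conc <= 0):
        raise ValueError("dilution concentrations must be positive")
    logc = np.log10(conc)
    if np.unique(logc).size < 2:
        raise ValueError("singular fit: all concentrations identical")
    fit = sps.linregress(logc, cq)
    if fit.slope == 0:
        raise ValueError("singular fit: zero slope")
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return DilutionCurve(
        mirna_id=mirna_id,
        points=tuple(zip(logc.tolist(), cq.tolist())),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency=float(efficiency),
    )


def fit_dilution_table(table: pd.DataFrame) -> Dict[str, DilutionCurve]:
    """Fit one standard curve per gene from a long-format dilution table
    with columns gene, concentration, cq."""
    curves: Dict[str, DilutionCurve] = {}
    for gene, grp in table.groupby("gene", sort=True):
        pts = list(zip(grp["concentration"].tolist(), grp["cq"].tolist()))
        curves[str(gene)] = fit_standard_curve(pts, mirna_id=str(gene))
    return curves


def relative_expression(
    cq_table: pd.DataFrame,
    efficiencies: Dict[str, float],
    reference_genes: Sequence[str],
    baseline: str,
    test: Optional[str] = None,
) -> List[ExpressionResult]:
    """Efficiency-corrected comparative-Cq fold changes.

    ``cq_table`` is long format with columns gene, condition, replicate, cq.
    Replicate Cq values are arithmetically averaged per (gene, condition);
    then for every non-reference gene

        ratio = (1+E_t)^(Cq_baseline - Cq_test) / NF,
        NF    = geometric mean over reference genes of (1+E_r)^(Cq_baseline - Cq_test).

    ``test`` defaults to the single other condition present.
    """
    required = {"gene", "condition", "replicate", "cq"}
    if not required.issubset(cq_table.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    means = cq_table.groupby(["gene", "condition"], sort=True)["cq"].mean()
    conditions = sorted(cq_table["condition"].unique())
    if baseline not in conditions:
        raise ValueError(f"baseline condition {baseline!r} absent from the table")
    if test is None:
        others = [c for c in conditions if c != baseline]
        if len(others) != 1:
            raise ValueError("test condition is ambiguous; pass it explicitly")
        test = others[0]

    def corrected(gene: str) -> float:
        for cond in (baseline, test):
            if (gene, cond) not in means.index:
                raise ValueError(f"gene {gene!r} has no Cq values in condition {cond!r}")
        if gene not in efficiencies:
            raise ValueError(f"no efficiency available for gene {gene!r}")
        dcq = means[(gene, baseline)] - means[(gene, test)]
        return (1.0 + efficiencies[gene]) ** dcq

    for ref in reference_genes:
        if ref not in set(cq_table["gene"]):
            raise ValueError(f"reference gene {ref!r} missing from the Cq table")
    ref_ratios = [corrected(r) for r in reference_genes]
    nf = float(np.exp(np.mean(np.log(ref_ratios))))

    results: List[ExpressionResult] = []
    targets = [g for g in sorted(cq_table["gene"].unique()) if g not in set(reference_genes)]
    for gene in targets:
        ratio = corrected(gene) / nf
        results.append(
            ExpressionResult(
                target_id=gene,
                condition_pair=(baseline, test),
                ratio=float(ratio),
                normalization_factor=nf,
            )
        )
    return results
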