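"""Thermodynamic/compositional descriptors of pre-miRNA candidates and the
filter cascade that turns hairpin candidates into precursor calls.

The descriptor set mirrors the variables conventionally tabulated for plant
pre-miRNAs: base composition, GC/AU content, minimum free energy (MFE), the
length-adjusted MFE per 100 nt (AMFE = MFE/length × 100) and the minimal
folding free energy index (MFEI = |AMFE| / GC%), plus ensemble quantities
when the folding backend provides them. MFEI is reported as a positive
magnitude; values above ~0.85 are characteristic of plant pre-miRNAs and
separate them from tRNA/rRNA and mRNA hairpins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .folding import FoldResult
from .seqs import encode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptorSet:
    length: int
    a_pct: float
    u_pct: float
    c_pct: float
    g_pct: float
    gc_pct: float
    au_pct: float
    gc_ratio: float       # G% / C%
    au_ratio: float       # A% / U%
    mfe: float
    amfe: float
    mfei: Optional[float]
    ensemble_mfe: Optional[float] = None
    diversity: Optional[float] = None
    ensemble_frequency: Optional[float] = None

    def as_dict(self) -> Dict[str, object]:
        return {
            "length": self.length,
            "a_pct": self.a_pct, "u_pct": self.u_pct,
            "c_pct": self.c_pct, "g_pct": self.g_pct,
            "gc_pct": self.gc_pct, "au_pct": self.au_pct,
            "gc_ratio": self.gc_ratio, "au_ratio": self.au_ratio,
            "mfe": self.mfe, "amfe": self.amfe, "mfei": self.mfei,
            "ensemble_mfe": self.ensemble_mfe,
            "diversity": self.diversity,
            "ensemble_frequency": self.ensemble_frequency,
        }


def compute_descriptors(sequence: str, fold: FoldResult) -> DescriptorSet:
    """Composition and energy descriptors for a folded candidate.

    Percentages are computed over A/C/G/U positions of the full sequence.
    When GC% is zero the MFEI is undefined and recorded as missing.
    """
    seq = sequence.upper()
    if len(seq) != len(fold.structure):
        raise ValueError("fold result does not correspond to the sequence")
    n = len(seq)
    counts = {b: seq.count(b) for b in "ACG"}
    counts["U"] = seq.count("U") + seq.count("T")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no A/C/G/U positions")
    pct = {b: counts[b] / total * 100.0 for b in "ACGU"}
    gc_pct = pct["G"] + pct["C"]
    au_pct = pct["A"] + pct["U"]
    amfe = fold.mfe / n * 100.0
    if gc_pct == 0.0:
        logger.warning("GC content is zero; MFEI undefined for this candidate")
        mfei: Optional[float] = None
    else:
        mfei = abs(amfe) / gc_pct
    return DescriptorSet(
        length=n,
        a_pct=pct["A"], u_pct=pct["U"], c_pct=pct["C"], g_pct=pct["G"],
        gc_pct=gc_pct, au_pct=au_pct,
        gc_ratio=(pct["G"] / pct["C"]) if pct["C"] > 0 else math.inf,
        au_ratio=(pct["A"] / pct["U"]) if pct["U"] > 0 else math.inf,
        mfe=fold.mfe, amfe=amfe, mfei=mfei,
        ensemble_mfe=fold.ensemble_mfe,
        diversity=fold.diversity,
        ensemble_frequency=fold.ensemble_frequency,
    )


@dataclass
class FilterConfig:
    """Thresholds of the precursor filter cascade.

    GC bounds are inclusive at both ends. The MFE cutoff keeps candidates at
    least as stable as −18 kcal/mol; the MFEI floor (0.85) is the standard
    plant pre-miRNA discriminator. Exclusion sets are FASTA files of other
    ncRNA / repeat sequences screened by ungapped identity.
    """

    gc_min: float = 20.0
    gc_max: float = 65.0
    mfe_max: float = -18.0
    mfei_min: float = 0.85
    exclusion_sets: Sequence[str] = field(default_factory=tuple)
    exclusion_identity: float = 0.9

    def __post_init__(self) -> None:
        if not self.gc_min < self.gc_max:
            raise ValueError("gc_min must be < gc_max")
        if not self.mfe_max < 0:
            raise ValueError("mfe_max must be negative")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_rules: tuple

    def __post_init__(self) -> None:
        assert self.passed == (len(self.failed_rules) == 0)


def sliding_identity(candidate: str, other: str) -> float:
    """Best ungapped identity of the shorter sequence slid along the longer,
    as a fraction of the shorter length."""
    a, b = candidate.upper(), other.upper()
    if len(a) < len(b):
        a, b = b, a
    if len(b) == 0:
        return 0.0
    ca, cb = encode(a), encode(b)
    nwin = len(a) - len(b) + 1
    windows = np.lib.stride_tricks.sliding_window_view(ca, len(b))[:nwin]
    matches = (windows == cb).sum(axis=1)
    return float(matches.max()) / len(b)


def exclusion_screen(
    candidate_seq: str,
    exclusion_records: Dict[str, str],
    identity: float = 0.9,
) -> Optional[str]:
    """Return the id of the first exclusion record matching the candidate at
    ``>= identity`` over the shorter length, or None when clear."""
    for rec_id, rec_seq in exclusion_records.items():
        if sliding_identity(candidate_seq, rec_seq) >= identity:
            return rec_id
    return None


def apply_filters(
    descriptors: DescriptorSet,
    mature_hits: Sequence,
    config: FilterConfig,
    exclusion_match: Optional[str] = None,
) -> FilterVerdict:
    """Evaluate every precursor filter rule independently.

    Rules: ``gc_range`` (GC% within [gc_min, gc_max]), ``mfe_cutoff``
    (MFE <= mfe_max), ``mfei_floor`` (MFEI >= mfei_min, failing when MFEI is
    undefined), ``mature_homology`` (at least one mature-miRNA hit) and
    ``exclusion`` (no ncRNA/repeat exclusion-set match).
    """
    failed = []
    if not (config.gc_min <= descriptors.gc_pct <= config.gc_max):
        failed.append("gc_range")
    if not descriptors.mfe <= config.mfe_max:
        failed.append("mfe_cutoff")
    if descriptors.mfei is None or descriptors.mfei < config.mfei_min:
        failed.append("mfei_floor")
    if len(mature_hits) == 0:
        failed.append("mature_homology")
    if exclusion_match is not None:
        failed.append("exclusion")
    return FilterVerdict(passed=not failed, failed_rules=tuple(failed))
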