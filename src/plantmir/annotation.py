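"""Genomic annotation of precursor loci.

Three classifications mirror how plant miRNA catalogs are reported:
intergenic vs intragenic localization (any >= 1 bp strand-agnostic overlap
with an annotated gene counts as intragenic), multi-locus precursors (the
same precursor sequence present at more than one genomic position), and
miRNA gene clusters (loci chained single-linkage per chromosome whenever
the gap between consecutive loci is at most 10 kb, the conventional
clustering distance; a cluster spanning both strands is flagged
antiparallel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

logger = logging.getLogger(__name__)

GeneIntervals = Dict[str, List[Tuple[int, int]]]


@dataclass(frozen=True)
class PrecursorLocus:
    precursor_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"locus {self.precursor_id}: start > end")


@dataclass(frozen=True)
class ClusterConfig:
    max_gap: int = 10_000

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass(frozen=True)
class ClusterCall:
    cluster_id: str
    member_loci: Tuple[PrecursorLocus, ...]
    antiparallel: bool


def load_gene_intervals(gff_path: str, featuretype: str = "gene") -> GeneIntervals:
    """Read gene features from a GFF3 file into per-chromosome interval lists."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: GeneIntervals = {}
    for feat in db.features_of_type(featuretype):
        genes.setdefault(feat.seqid, []).append((feat.start, feat.end))
    for chrom in genes:
        genes[chrom].sort()
    return genes


def classify_localization(locus: PrecursorLocus, genes: GeneIntervals) -> str:
    """"intragenic" iff the locus overlaps any gene by >= 1 bp, else "intergenic"."""
    if locus.chrom not in genes:
        logger.warning(
            "chromosome %s absent from annotation; classifying %s as intergenic",
            locus.chrom, locus.precursor_id,
        )
        return "intergenic"
    for g_start, g_end in genes[locus.chrom]:
        if g_start > locus.end:
            break
        if locus.start <= g_end and g_start <= locus.end:
            return "intragenic"
    return "intergenic"


def find_multilocus(
    precursors: Iterable[Tuple[str, str, PrecursorLocus]],
) -> Dict[str, List[PrecursorLocus]]:
    """Group loci whose precursor sequences are exactly identical.

    Input: iterable of (precursor_id, sequence, locus). Output maps a group
    id (the id of the first-seen member) to all loci carrying the identical
    sequence. Near-identical copies stay in separate groups.
    """
    by_seq: Dict[str, Tuple[str, List[PrecursorLocus]]] = {}
    for pid, seq, locus in precursors:
        key = seq.upper().replace("T", "U")
        if key in by_seq:
            by_seq[key][1].append(locus)
        else:
            by_seq[key] = (pid, [locus])
    return {pid: loci for pid, loci in by_seq.values()}


def detect_clusters(
    loci: Sequence[PrecursorLocus],
    config: ClusterConfig = ClusterConfig(),
) -> List[ClusterCall]:
    """Single-linkage chaining of loci per chromosome.

    Consecutive loci (sorted by start) join one cluster when the inter-locus
    gap (next.start − prev.end − 1) is at most ``max_gap``, inclusive; strand
    is ignored for membership. Only chains of >= 2 loci are reported.
    """
    by_chrom: Dict[str, List[PrecursorLocus]] = {}
    for locus in loci:
        by_chrom.setdefault(locus.chrom, []).append(locus)
    calls: List[ClusterCall] = []
    n = 0
    for chrom in sorted(by_chrom):
        chain: List[PrecursorLocus] = []
        members = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end))
        for locus in members:
            if chain and (locus.start - chain[-1].end - 1) <= config.max_gap:
                chain.append(locus)
            else:
                if len(chain) >= 2:
                    n += 1
                    calls.append(_make_call(n, chain))
                chain = [locus]
        if len(chain) >= 2:
            n += 1
            calls.append(_make_call(n, chain))
    return calls


def _make_call(n: int, chain: List[PrecursorLocus]) -> ClusterCall:
    strands = {l.strand for l in chain}
    return ClusterCall(
        cluster_id=f"cluster-{n}",
        member_loci=tuple(chain),
        antiparallel=strands == {"+", "-"},
    )
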