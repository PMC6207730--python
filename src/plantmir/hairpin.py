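"""Genome-wide inverted-repeat (hairpin) discovery and mature-miRNA homology.

The scanner finds loci where a sequence segment (left arm) aligns to the
reverse complement of a downstream segment (right arm), separated by a loop.
Scoring follows the classic inverted-repeat convention: +3 per complementary
pair, −3 per mismatch, −7 per gap position; repeats scoring at least 25 over
at most 336 nt of total extent (arm + loop + arm) are reported — the
classic einverted-style operating point for plant genome scans. The search
is an exact local dynamic program over anti-diagonal arm pairings, run in
overlapping windows of twice the maximum extent so that any repeat within
the extent bound is fully contained in some window.

Candidates are then compared against known mature miRNAs by sliding
equal-length windows and counting substitutions (Hamming distance, no
indels); up to 5 mismatches qualify a hit, and the hit's arm (5p/3p) is
assigned by its position relative to the loop midpoint.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .seqs import DNA_ALPHABET, dna_to_rna, encode, revcomp_dna

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IRScoringConfig:
    match_score: int = 3
    mismatch_score: int = -3
    gap_penalty: int = -7
    min_score: int = 25
    max_extent: int = 336
    min_loop: int = 3

    def __post_init__(self) -> None:
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.max_extent < 2 * 2 + self.min_loop:
            raise ValueError("max_extent too small for any stem")


@dataclass(frozen=True)
class InvertedRepeat:
    """An inverted-repeat locus. All coordinates 1-based inclusive."""

    chrom: str
    left_arm: Tuple[int, int]
    right_arm: Tuple[int, int]
    loop: Tuple[int, int]
    score: int
    arm_alignment: Tuple[Tuple[Optional[int], Optional[int], str], ...]

    @property
    def start(self) -> int:
        return self.left_arm[0]

    @property
    def end(self) -> int:
        return self.right_arm[1]

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class HairpinCandidate:
    """A candidate precursor sequence extracted around an inverted repeat."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str                 # RNA alphabet, 5'->3' on `strand`
    loop_mid_offset: Optional[int] = None   # 0-based within `sequence`
    repeat: Optional[InvertedRepeat] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HomologyConfig:
    max_mismatch: int = 5
    reference: Optional[str] = None   # mature FASTA path (pipeline use)

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class MatureHit:
    reference_id: str
    family: str
    offset: int        # 0-based start of the window within the candidate
    length: int
    mismatches: int
    arm: str           # "5p" | "3p"


_FAMILY_RE = re.compile(r"(mir[0-9]+[a-z]*)", re.IGNORECASE)


def family_of(reference_id: str) -> str:
    """Extract the miRNA family label from a miRBase-style identifier."""
    m = _FAMILY_RE.search(reference_id)
    return m.group(1) if m else reference_id


@njit(cache=True)
def _ir_fill(codes, match, mismatch, gap, min_loop):
    """Local arm-pairing DP.

    Cell (i, j) scores the best arm alignment whose innermost column pairs
    position i (left arm) with position j (right arm); arms extend outward.
    Origin arrays track the outermost coordinates of the optimal path so the
    total extent can be bounded without traceback.
    """
    n = codes.size
    NEG = np.int32(-(10 ** 9))
    H = np.full((n, n), NEG, dtype=np.int32)
    P = np.zeros((n, n), dtype=np.uint8)
    Oi = np.zeros((n, n), dtype=np.int32)
    Oj = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            a = codes[i]
            b = codes[j]
            if (a == 0 and b == 3) or (a == 3 and b == 0) or \
               (a == 1 and b == 2) or (a == 2 and b == 1):
                s = match
            else:
                s = mismatch
            best = s            # fresh local start with this pair
            p = np.uint8(0)
            oi = i
            oj = j
            if i > 0 and j < n - 1 and H[i - 1, j + 1] > NEG:
                v = H[i - 1, j + 1] + s
                if v > best:
                    best = v
                    p = np.uint8(1)
                    oi = Oi[i - 1, j + 1]
                    oj = Oj[i - 1, j + 1]
            if i > 0 and H[i - 1, j] > NEG:
                v = H[i - 1, j] + gap
                if v > best:
                    best = v
                    p = np.uint8(2)
                    oi = Oi[i - 1, j]
                    oj = Oj[i - 1, j]
            if j < n - 1 and H[i, j + 1] > NEG:
                v = H[i, j + 1] + gap
                if v > best:
                    best = v
                    p = np.uint8(3)
                    oi = Oi[i, j + 1]
                    oj = Oj[i, j + 1]
            H[i, j] = best
            P[i, j] = p
            Oi[i, j] = oi
            Oj[i, j] = oj
    return H, P, Oi, Oj


def _collect_window(codes: np.ndarray, cfg: IRScoringConfig):
    """Best repeat per origin within one window: (score, i0, j0, ii, jj)."""
    H, P, Oi, Oj = _ir_fill(
        codes, cfg.match_score, cfg.mismatch_score, cfg.gap_penalty, cfg.min_loop
    )
    ii, jj = np.nonzero(H >= cfg.min_score)
    if ii.size == 0:
        return [], P
    oi = Oi[ii, jj]
    oj = Oj[ii, jj]
    scores = H[ii, jj]
    span_ok = (oj - oi + 1) <= cfg.max_extent
    ii, jj, oi, oj, scores = ii[span_ok], jj[span_ok], oi[span_ok], oj[span_ok], scores[span_ok]
    best: Dict[Tuple[int, int], Tuple[int, int, int]] = {}
    for k in range(ii.size):
        key = (int(oi[k]), int(oj[k]))
        cand = (-int(scores[k]), int(ii[k]), -int(jj[k]))
        if key not in best or cand < best[key]:
            best[key] = cand
    out = []
    for (o_i, o_j), (neg_s, i_in, neg_j) in best.items():
        out.append((-neg_s, o_i, o_j, i_in, -neg_j))
    return out, P


def _traceback_alignment(P: np.ndarray, i: int, j: int):
    """Walk pointers from the innermost cell back to the fresh-start origin."""
    cols: List[Tuple[Optional[int], Optional[int], int]] = []
    while True:
        p = P[i, j]
        if p == 0:
            cols.append((i, j, 1))
            break
        if p == 1:
            cols.append((i, j, 1))
            i, j = i - 1, j + 1
        elif p == 2:
            cols.append((i, None, 2))
            i = i - 1
        else:
            cols.append((None, j, 3))
            j = j + 1
    cols.reverse()
    return cols


def find_inverted_repeats(
    sequence: str,
    config: IRScoringConfig = IRScoringConfig(),
    chrom: str = "seq",
) -> List[InvertedRepeat]:
    """Scan a sequence for inverted repeats above the scoring floor.

    Overlapping repeats are reduced to local-score maxima (ties broken by
    higher score, then smaller span, then leftmost start). Returns repeats
    sorted by start coordinate (1-based inclusive).
    """
    seq = sequence.upper().replace("U", "T")
    if not seq:
        return []
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"genomic sequence contains invalid characters: {sorted(bad)}")
    codes_full = encode(seq)
    n = len(seq)
    win = min(n, 2 * config.max_extent)
    step = config.max_extent

    # candidates keyed by (outer start, outer end), 0-based, window-deduped
    found: Dict[Tuple[int, int], Tuple[int, int, int, int]] = {}
    offset = 0
    while True:
        sub = codes_full[offset:offset + win]
        if sub.size > config.min_loop + 2:
            cands, _ = _collect_window(sub, config)
            for score, o_i, o_j, i_in, j_in in cands:
                key = (o_i + offset, o_j + offset)
                val = (score, i_in + offset, j_in + offset, offset)
                if key not in found or score > found[key][0]:
                    found[key] = val
        if offset + win >= n:
            break
        offset += step

    if not found:
        return []

    # greedy overlap reduction: higher score, then smaller span, then leftmost
    items = [
        (score, start, end, i_in, j_in)
        for (start, end), (score, i_in, j_in, _off) in found.items()
    ]
    items.sort(key=lambda t: (-t[0], t[2] - t[1], t[1]))
    kept: List[Tuple[int, int, int, int, int]] = []
    occupied: List[Tuple[int, int]] = []
    for score, start, end, i_in, j_in in items:
        if any(start <= e and s <= end for s, e in occupied):
            continue
        kept.append((score, start, end, i_in, j_in))
        occupied.append((start, end))

    repeats: List[InvertedRepeat] = []
    for score, start, end, i_in, j_in in kept:
        sub = codes_full[start:end + 1]
        _, P, Oi, Oj = _ir_fill(
            sub, config.match_score, config.mismatch_score,
            config.gap_penalty, config.min_loop,
        )
        cols = _traceback_alignment(P, i_in - start, j_in - start)
        left_positions = [c[0] for c in cols if c[0] is not None]
        right_positions = [c[1] for c in cols if c[1] is not None]
        left_arm = (start + min(left_positions) + 1, start + max(left_positions) + 1)
        right_arm = (start + min(right_positions) + 1, start + max(right_positions) + 1)
        loop = (left_arm[1] + 1, right_arm[0] - 1)
        alignment = []
        for li, rj, _p in cols:
            if li is None:
                alignment.append((None, start + rj + 1, "gap"))
            elif rj is None:
                alignment.append((start + li + 1, None, "gap"))
            else:
                a, b = codes_full[start + li], codes_full[start + rj]
                is_match = (int(a), int(b)) in {(0, 3), (3, 0), (1, 2), (2, 1)}
                alignment.append(
                    (start + li + 1, start + rj + 1, "match" if is_match else "mismatch")
                )
        repeats.append(
            InvertedRepeat(
                chrom=chrom,
                left_arm=left_arm,
                right_arm=right_arm,
                loop=loop,
                score=score,
                arm_alignment=tuple(alignment),
            )
        )
    repeats.sort(key=lambda r: (r.start, r.end))
    return repeats


def extract_candidate(
    repeat: InvertedRepeat,
    genome: Dict[str, str],
    flank: int = 0,
    strand: str = "+",
    candidate_id: Optional[str] = None,
) -> HairpinCandidate:
    """Extract the (flanked) genomic span of a repeat as an RNA candidate.

    Out-of-bounds flanks are truncated with a logged warning. On the minus
    strand the sequence is reverse-complemented and the loop midpoint
    mirrored accordingly.
    """
    chrom_seq = genome[repeat.chrom]
    start = repeat.start - flank
    end = repeat.end + flank
    if start < 1:
        logger.warning(
            "candidate at %s:%d truncated at chromosome start", repeat.chrom, repeat.start
        )
        start = 1
    if end > len(chrom_seq):
        logger.warning(
            "candidate at %s:%d truncated at chromosome end", repeat.chrom, repeat.start
        )
        end = len(chrom_seq)
    dna = chrom_seq[start - 1:end].upper()
    loop_mid_genomic = (repeat.loop[0] + repeat.loop[1]) / 2.0
    if strand == "+":
        seq = dna_to_rna(dna)
        loop_mid = int(round(loop_mid_genomic - start))
    elif strand == "-":
        seq = dna_to_rna(revcomp_dna(dna))
        loop_mid = int(round(end - loop_mid_genomic))
    else:
        raise ValueError(f"invalid strand {strand!r}")
    cid = candidate_id or f"{repeat.chrom}:{start}-{end}({strand})"
    return HairpinCandidate(
        id=cid, chrom=repeat.chrom, start=start, end=end, strand=strand,
        sequence=seq, loop_mid_offset=min(max(loop_mid, 0), len(seq) - 1),
        repeat=repeat,
    )


def scan_mature_homology(
    candidate: HairpinCandidate,
    matures: Dict[str, str],
    config: HomologyConfig = HomologyConfig(),
) -> List[MatureHit]:
    """Slide each reference mature along the candidate and count substitutions.

    For each reference the best window (fewest mismatches, then leftmost) is
    retained when its Hamming distance is within ``max_mismatch``. No indels
    are considered. The hit arm is 5p when the window midpoint precedes the
    hairpin loop midpoint, else 3p.
    """
    if not matures:
        raise ValueError("mature reference set is empty")
    cand_rna = candidate.sequence.upper().replace("T", "U")
    cand_codes = encode(cand_rna)
    loop_mid = (
        candidate.loop_mid_offset
        if candidate.loop_mid_offset is not None
        else len(cand_rna) / 2.0
    )
    hits: List[MatureHit] = []
    for ref_id, ref_seq in matures.items():
        ref_rna = ref_seq.upper().replace("T", "U")
        bad = set(ref_rna) - {"A", "C", "G", "U"}
        if bad:
            raise ValueError(
                f"mature reference {ref_id!r} contains non-nucleotide characters: {sorted(bad)}"
            )
        L = len(ref_rna)
        if L > len(cand_rna):
            continue
        ref_codes = encode(ref_rna)
        windows = np.lib.stride_tricks.sliding_window_view(cand_codes, L)
        mism = (windows != ref_codes).sum(axis=1)
        best = int(mism.min())
        if best > config.max_mismatch:
            continue
        offset = int(np.argmax(mism == best))   # leftmost best window
        midpoint = offset + L / 2.0
        arm = "5p" if midpoint < loop_mid else "3p"
        hits.append(
            MatureHit(
                reference_id=ref_id,
                family=family_of(ref_id),
                offset=offset,
                length=L,
                mismatches=best,
                arm=arm,
            )
        )
    return hits
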