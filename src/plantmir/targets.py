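"""miRNA target prediction by expectation-penalty scoring.

A mature miRNA is aligned antiparallel against a transcript window and each
alignment column is penalised: perfect pair 0, G:U wobble 0.5, mismatch 1,
gap (either strand) 2. Penalties are doubled at miRNA positions 2–13
(1-based from the 5' end) — the seed-proximal region where plant
miRNA-target pairing is most constrained. The total penalty is the
expectation score (Exp); hits are kept at Exp <= 3.0 by default, the strict
operating point that minimises false-positive target calls. A central
mismatch or gap at positions 10–11 marks the duplex as acting by
translational inhibition rather than cleavage.

The aligner is an exact semi-global dynamic program: the full miRNA is
consumed, the transcript end offsets are free, and at most two gap columns
are allowed. Site accessibility (UPE — the energy needed to unpair the
target site) is a pluggable optional stage backed by the folding-engine
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .folding import Engine, get_engine
from .seqs import encode

#: integer penalty half-units used inside the DP (value = penalty * 2)
_PEN_MATCH, _PEN_GU, _PEN_MISMATCH, _PEN_GAP = 0, 1, 2, 4
_INF = 32000


@dataclass(frozen=True)
class TargetConfig:
    max_expectation: float = 3.0
    hsp_size: int = 19
    top_per_mirna: int = 200
    upe_max: float = 25.0
    flank_before: int = 17
    flank_after: int = 13
    central_range: Tuple[int, int] = (10, 11)
    seed_range: Tuple[int, int] = (2, 13)
    max_gaps: int = 2

    def __post_init__(self) -> None:
        if self.max_expectation < 0 or self.top_per_mirna <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class DuplexAlignment:
    mirna_id: str
    transcript_id: str
    window_start: int            # 1-based inclusive on the scanned sequence
    window_end: int
    states: Tuple[str, ...]      # per miRNA position 1..len: match|gu_wobble|mismatch|gap
    target_bulges: Tuple[int, ...]   # miRNA positions preceding a target-side bulge
    expectation: float
    n_gaps: int

    @property
    def duplex_string(self) -> str:
        marks = {"match": "|", "gu_wobble": "o", "mismatch": ".", "gap": "-"}
        return "".join(marks[s] for s in self.states)


@dataclass(frozen=True)
class TargetHit:
    alignment: DuplexAlignment
    mode: str                    # cleavage | translational_inhibition
    upe: Optional[float] = None


def position_penalty(position: int, state: str, config: TargetConfig = TargetConfig()) -> float:
    """Penalty of one alignment column at a 1-based miRNA position."""
    base = {"match": 0.0, "gu_wobble": 0.5, "mismatch": 1.0, "gap": 2.0}[state]
    lo, hi = config.seed_range
    return base * 2.0 if lo <= position <= hi else base


@njit(cache=True)
def _duplex_dp(mc, wc, seed_lo, seed_hi, max_gaps):
    """Semi-global min-penalty alignment of miRNA codes vs reversed-window codes.

    Returns (cost, ptr) over states (i consumed miRNA bases, j consumed
    reversed-window bases, g gaps used). Penalties in half-units.
    """
    m = mc.size
    w = wc.size
    G = max_gaps
    cost = np.full((m + 1, w + 1, G + 1), _INF, dtype=np.int16)
    ptr = np.zeros((m + 1, w + 1, G + 1), dtype=np.uint8)
    for j in range(w + 1):
        cost[0, j, 0] = 0
    for i in range(m + 1):
        for j in range(w + 1):
            for g in range(G + 1):
                c = cost[i, j, g]
                if c >= _INF:
                    continue
                pos = i + 1
                dbl = 2 if (seed_lo <= pos <= seed_hi) else 1
                if i < m and j < w:
                    a = mc[i]
                    b = wc[j]
                    # antiparallel pairing: miRNA base vs target base
                    if (a == 0 and b == 3) or (a == 3 and b == 0) or \
                       (a == 1 and b == 2) or (a == 2 and b == 1):
                        p = _PEN_MATCH
                    elif (a == 2 and b == 3) or (a == 3 and b == 2):
                        p = _PEN_GU
                    else:
                        p = _PEN_MISMATCH
                    v = c + p * dbl
                    if v < cost[i + 1, j + 1, g]:
                        cost[i + 1, j + 1, g] = v
                        ptr[i + 1, j + 1, g] = 1
                if i < m and g < G:
                    v = c + _PEN_GAP * dbl
                    if v < cost[i + 1, j, g + 1]:
                        cost[i + 1, j, g + 1] = v
                        ptr[i + 1, j, g + 1] = 2
                if 0 < i < m and g < G and j < w:
                    v = c + _PEN_GAP * dbl
                    if v < cost[i, j + 1, g + 1]:
                        cost[i, j + 1, g + 1] = v
                        ptr[i, j + 1, g + 1] = 3
    return cost, ptr


def _pair_state(a: int, b: int) -> str:
    if (a, b) in {(0, 3), (3, 0), (1, 2), (2, 1)}:
        return "match"
    if (a, b) in {(2, 3), (3, 2)}:
        return "gu_wobble"
    return "mismatch"


def score_duplex(
    mirna: str,
    window: str,
    config: TargetConfig = TargetConfig(),
    mirna_id: str = "",
    transcript_id: str = "",
) -> Optional[DuplexAlignment]:
    """Minimal-penalty antiparallel alignment of a mature miRNA to a window.

    The whole miRNA is aligned; the window may be longer (free ends, e.g. a
    full transcript). Ties are broken toward fewer gaps, then the leftmost
    window on the given sequence. Returns None when the window cannot host
    the miRNA even with the allowed gaps.
    """
    m_rna = mirna.upper().replace("T", "U")
    w_rna = window.upper().replace("T", "U")
    if not (10 <= len(m_rna) <= 30):
        raise ValueError("mature miRNA length out of supported range")
    if len(w_rna) < len(m_rna) - config.max_gaps:
        return None
    mc = encode(m_rna)
    wc = encode(w_rna)[::-1].copy()   # miRNA 5' end pairs the window 3' end
    cost, ptr = _duplex_dp(
        mc, wc, config.seed_range[0], config.seed_range[1], config.max_gaps
    )
    m, w = len(mc), len(wc)
    best = (_INF, 0, -1)
    for g in range(config.max_gaps + 1):
        for j in range(w + 1):
            c = int(cost[m, j, g])
            # ties: fewer gaps, then larger j in reversed coords = leftmost window
            if (c, g, -j) < best:
                best = (c, g, -j)
    if best[0] >= _INF:
        return None
    total_half, n_gaps, j = best[0], best[1], -best[2]

    # traceback
    i, g = m, n_gaps
    states: List[Tuple[int, str]] = []
    bulges: List[int] = []
    j_end = j
    while not (i == 0 and g == 0):
        p = ptr[i, j, g]
        if p == 1:
            states.append((i, _pair_state(int(mc[i - 1]), int(wc[j - 1]))))
            i, j = i - 1, j - 1
        elif p == 2:
            states.append((i, "gap"))
            i, g = i - 1, g - 1
        elif p == 3:
            bulges.append(i)
            j, g = j - 1, g - 1
        else:   # start cell (0, j, 0)
            break
    j_start = j
    states.sort()
    per_pos = tuple(s for _, s in states)
    window_start = w - j_end + 1          # 1-based on the original orientation
    window_end = w - j_start
    return DuplexAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        window_start=window_start,
        window_end=window_end,
        states=per_pos,
        target_bulges=tuple(sorted(bulges)),
        expectation=total_half / 2.0,
        n_gaps=n_gaps,
    )


def classify_mode(alignment: DuplexAlignment, config: TargetConfig = TargetConfig()) -> str:
    """Cleavage unless a central (positions 10-11 by default) mismatch/gap
    redirects the duplex to translational inhibition."""
    lo, hi = config.central_range
    for pos in range(lo, hi + 1):
        if pos - 1 < len(alignment.states) and alignment.states[pos - 1] in ("mismatch", "gap"):
            return "translational_inhibition"
        if pos in alignment.target_bulges:
            return "translational_inhibition"
    return "cleavage"


AccessibilityEngine = Callable[[str, int, int], float]


def make_fold_accessibility(engine: Engine = "fallback") -> AccessibilityEngine:
    """Build a site-accessibility scorer from a folding engine.

    The returned callable takes (flanked sequence, site start, site end;
    0-based half-open within the flanked sequence) and reports the energy
    required to keep the site unpaired: E(structure with site blocked) minus
    E(unconstrained MFE), a non-negative opening energy in kcal/mol.
    """
    fold = get_engine(engine)

    def upe(flanked: str, site_start: int, site_end: int) -> float:
        free = fold(flanked).mfe
        blocked_seq = (
            flanked[:site_start] + "N" * (site_end - site_start) + flanked[site_end:]
        )
        blocked = fold(blocked_seq).mfe
        return max(0.0, blocked - free)

    return upe


def filter_hits(
    alignments: Sequence[DuplexAlignment],
    config: TargetConfig = TargetConfig(),
    transcripts: Optional[Dict[str, str]] = None,
    accessibility: Optional[AccessibilityEngine] = None,
) -> List[TargetHit]:
    """Retain alignments at expectation <= max_expectation, optionally apply
    the UPE accessibility cut, rank per miRNA and cap at top_per_mirna."""
    by_mirna: Dict[str, List[TargetHit]] = {}
    for aln in alignments:
        if aln.expectation > config.max_expectation:
            continue
        upe_value: Optional[float] = None
        if accessibility is not None:
            if transcripts is None:
                raise ValueError("accessibility scoring requires transcript sequences")
            tseq = transcripts[aln.transcript_id]
            s = max(0, aln.window_start - 1 - config.flank_before)
            e = min(len(tseq), aln.window_end + config.flank_after)
            site_s = aln.window_start - 1 - s
            site_e = aln.window_end - s
            upe_value = accessibility(tseq[s:e].replace("T", "U"), site_s, site_e)
            if upe_value > config.upe_max:
                continue
        hit = TargetHit(alignment=aln, mode=classify_mode(aln, config), upe=upe_value)
        by_mirna.setdefault(aln.mirna_id, []).append(hit)
    out: List[TargetHit] = []
    for mirna_id in sorted(by_mirna):
        hits = sorted(
            by_mirna[mirna_id],
            key=lambda h: (h.alignment.expectation, h.alignment.transcript_id),
        )
        out.extend(hits[: config.top_per_mirna])
    return out


def predict_targets(
    matures: Dict[str, str],
    transcripts: Dict[str, str],
    config: TargetConfig = TargetConfig(),
    accessibility: Optional[AccessibilityEngine] = None,
) -> List[TargetHit]:
    """Score every miRNA against every transcript (best site per pair) and
    filter/rank the resulting alignments."""
    alignments: List[DuplexAlignment] = []
    for mirna_id in sorted(matures):
        for transcript_id in sorted(transcripts):
            aln = score_duplex(
                matures[mirna_id],
                transcripts[transcript_id],
                config,
                mirna_id=mirna_id,
                transcript_id=transcript_id,
            )
            if aln is not None:
                alignments.append(aln)
    return filter_hits(alignments, config, transcripts=transcripts, accessibility=accessibility)
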