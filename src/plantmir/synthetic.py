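"""Synthetic genomes with planted pre-miRNA hairpins, plus matched mature
references, target transcriptomes and qPCR tables — every input the pipeline
consumes, with a machine-readable truth table.

The generator emulates the structure of a plant genome scan at desk scale:
a multi-chromosome genome of ~38% GC first-order-Markov background (the
composition typical of Solanum pre-miRNA surveys) carrying hairpin
precursors of known coordinates and strands — some inside annotated genes,
some intergenic, some clustered within 10 kb (including an antiparallel
pair), optionally repeated at multiple loci. Every planted precursor is
rejection-sampled until it passes the full structural filter cascade under
the built-in folding engine, so a correct pipeline must recover 100% of
them; designated decoy regions are actively scrubbed of inverted repeats so
a correct pipeline must call nothing there.

Intragenic and clustered counts follow a fixed rounding rule:
``round(frac * n_precursors)`` precursors are planted inside genes /
grouped into clusters of 2-3 members.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .descriptors import FilterConfig, apply_filters, compute_descriptors
from .folding import fold_fallback
from .hairpin import IRScoringConfig, find_inverted_repeats
from .io import write_fasta, write_gff3
from .seqs import revcomp_dna, revcomp_rna, rna_to_dna
from .targets import TargetConfig, position_penalty

_BASES = np.array(list("ACGT"))
_BASE_PROBS = np.array([0.31, 0.19, 0.19, 0.31])   # ~38% GC, strand-balanced (hairpin arms)
#: background composition: ~38% GC but strongly purine-skewed, so Watson-Crick
#: partners (A/T, C/G) rarely co-occur and the background cannot seed hairpins
_BG_PROBS = np.array([0.50, 0.06, 0.32, 0.12])
_COMP_IDX = np.array([3, 2, 1, 0])                 # A<->T, C<->G


@dataclass
class PlantedPrecursor:
    id: str
    chrom: str
    start: int                      # 1-based inclusive
    end: int
    strand: str
    sequence: str                   # RNA, 5'->3' on `strand`
    family: str
    mature_5p: str
    mature_5p_offset: int           # 0-based within `sequence`
    mature_3p: str
    mature_3p_offset: int
    is_intragenic: bool = False
    cluster_id: Optional[str] = None
    copy_loci: List[Tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class TargetSiteTruth:
    transcript_id: str
    mirna_id: str
    position: int                   # 1-based start of the site on the transcript
    designed_expectation: float
    edits: List[Tuple[int, str]]    # (miRNA position, "gu" | "mm")


@dataclass
class TruthTable:
    precursors: List[PlantedPrecursor] = field(default_factory=list)
    decoy_regions: List[Tuple[str, int, int]] = field(default_factory=list)
    target_sites: List[TargetSiteTruth] = field(default_factory=list)
    qpcr_truth: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    def matures(self) -> Dict[str, str]:
        """All planted mature sequences keyed by their reference ids."""
        out: Dict[str, str] = {}
        for p in self.precursors:
            out[f"{p.id}-5p"] = p.mature_5p
            out[f"{p.id}-3p"] = p.mature_3p
        return out

    def to_json(self, path) -> None:
        doc = {
            "precursors": [asdict(p) for p in self.precursors],
            "decoy_regions": [list(d) for d in self.decoy_regions],
            "target_sites": [asdict(t) for t in self.target_sites],
            "qpcr_truth": {k: list(v) for k, v in self.qpcr_truth.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        doc = json.loads(Path(path).read_text())
        return cls(
            precursors=[
                PlantedPrecursor(**{**p, "copy_loci": [tuple(c) for c in p["copy_loci"]]})
                for p in doc["precursors"]
            ],
            decoy_regions=[tuple(d) for d in doc["decoy_regions"]],
            target_sites=[TargetSiteTruth(**{**t, "edits": [tuple(e) for e in t["edits"]]})
                          for t in doc["target_sites"]],
            qpcr_truth={k: tuple(v) for k, v in doc["qpcr_truth"].items()},
        )


@dataclass
class SyntheticGenome:
    genome: Dict[str, str]                          # chrom -> DNA
    genes: List[Tuple[str, int, int, str]]          # (chrom, start, end, gene_id)
    truth: TruthTable

    def write(self, outdir) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gff": outdir / "annotation.gff3",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.genome, paths["genome"])
        rows = []
        for chrom, start, end, gid in self.genes:
            rows.append((chrom, "plantmir_sim", "gene", start, end, ".", "+", f"ID={gid}"))
        for p in self.truth.precursors:
            rows.append((p.chrom, "plantmir_sim", "miRNA_primary_transcript",
                         p.start, p.end, ".", p.strand, f"ID={p.id}"))
            for arm, off, mat in (("5p", p.mature_5p_offset, p.mature_5p),
                                  ("3p", p.mature_3p_offset, p.mature_3p)):
                if p.strand == "+":
                    ms = p.start + off
                    me = ms + len(mat) - 1
                else:
                    me = p.end - off
                    ms = me - len(mat) + 1
                rows.append((p.chrom, "plantmir_sim", "miRNA", ms, me, ".", p.strand,
                             f"ID={p.id}-{arm};Derives_from={p.id}"))
        rows.sort(key=lambda r: (r[0], r[3], r[4], r[2]))
        write_gff3(rows, paths["gff"])
        self.truth.to_json(paths["truth"])
        return paths


@njit(cache=True)
def _markov_chain(n, start, trans, u):
    out = np.empty(n, dtype=np.int8)
    state = start
    for i in range(n):
        r = u[i]
        acc = 0.0
        nxt = 3
        for b in range(4):
            acc += trans[state, b]
            if r < acc:
                nxt = b
                break
        out[i] = nxt
        state = nxt
    return out


def _background(rng: np.random.Generator, n: int) -> np.ndarray:
    """First-order Markov background at ~38% GC.

    The composition is purine-skewed and the probability of a base being
    followed by its complement is additionally damped, so self-complementary
    runs (incidental hairpin seeds) are rare; residual inverted repeats are
    scrubbed explicitly after assembly."""
    trans = np.tile(_BG_PROBS, (4, 1))
    for b in range(4):
        trans[b, _COMP_IDX[b]] *= 0.6
        trans[b] /= trans[b].sum()
    start = int(rng.integers(0, 4))
    u = rng.random(n)
    return _markov_chain(n, start, trans, u)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


MATURE_LEN = 21


def _sample_hairpin(
    rng: np.random.Generator,
    filters: FilterConfig,
    ir_config: IRScoringConfig,
    max_tries: int = 100,
) -> Tuple[str, int, int]:
    """Sample one precursor hairpin (RNA) passing the full filter cascade
    under the built-in folding engine. Returns (sequence, offset of the 5p
    mature, offset of the 3p mature)."""
    for _ in range(max_tries):
        arm_len = int(rng.integers(30, 55))
        loop_len = int(rng.integers(8, 16))
        left = rng.choice(4, size=arm_len, p=_BASE_PROBS / _BASE_PROBS.sum())
        right = _COMP_IDX[left[::-1]].copy()
        # degrade ~10% of right-arm positions: imperfect stems, >=60% pairing
        n_mut = max(1, int(round(0.10 * arm_len)))
        mut_pos = rng.choice(arm_len, size=n_mut, replace=False)
        for p in mut_pos:
            right[p] = (right[p] + int(rng.integers(1, 4))) % 4
        loop = rng.choice(4, size=loop_len, p=np.array([0.4, 0.1, 0.1, 0.4]))
        codes = np.concatenate([left, loop, right])
        rna = _codes_to_str(codes).replace("T", "U")

        # choose a 5p window whose mirrored 3' window carries >= 1 stem
        # mutation, so the two arms' matures are never exact reverse
        # complements and the precursor strand stays resolvable
        valid_offsets = [
            o for o in range(1, arm_len - MATURE_LEN)
            if any(arm_len - o - MATURE_LEN <= p < arm_len - o for p in mut_pos)
        ]
        if not valid_offsets:
            continue
        off5 = int(valid_offsets[int(rng.integers(0, len(valid_offsets)))])
        # mirrored window on the 3' arm (pairing partner of the 5p window)
        off3 = arm_len + loop_len + (arm_len - off5 - MATURE_LEN)

        fold = fold_fallback(rna)
        desc = compute_descriptors(rna, fold)
        verdict = apply_filters(desc, ["planted"], filters)
        if not verdict.passed:
            continue
        if not find_inverted_repeats(rna_to_dna(rna), ir_config):
            continue
        return rna, off5, off3
    raise RuntimeError("failed to sample a filter-passing hairpin in 100 tries")


def _overlaps(a_lo: int, a_hi: int, spans) -> bool:
    """Half-open interval overlap against a span list."""
    return any(a_lo < hi and lo < a_hi for lo, hi in spans)


def _break_hairpins(
    chrom_codes: np.ndarray,
    core_start: int,
    core_end: int,
    rng: np.random.Generator,
    ir_config: IRScoringConfig,
    protected=(),
    max_rounds: int = 40,
) -> bool:
    """Mutate the region until no inverted repeat overlaps [core_start,
    core_end) (0-based half-open). Scans the core extended by max_extent so
    boundary-straddling repeats are caught. Repeats overlapping a protected
    span (a planted precursor) are left untouched."""
    margin = ir_config.max_extent
    lo = max(0, core_start - margin)
    hi = min(chrom_codes.size, core_end + margin)
    for _ in range(max_rounds):
        sub = _codes_to_str(chrom_codes[lo:hi])
        reps = find_inverted_repeats(sub, ir_config)
        offending = [
            r for r in reps
            if (lo + r.start - 1) < core_end and core_start < (lo + r.end)
            and not _overlaps(lo + r.start - 1, lo + r.end, protected)
        ]
        if not offending:
            return True
        for r in offending:
            arm_lo = lo + r.right_arm[0] - 1
            arm_hi = lo + r.right_arm[1]
            for p in range(arm_lo, arm_hi, 2):
                if not _overlaps(p, p + 1, protected):
                    chrom_codes[p] = (chrom_codes[p] + int(rng.integers(1, 4))) % 4
    return False


def _scrub_chromosome(
    chrom_codes: np.ndarray,
    protected,
    rng: np.random.Generator,
    ir_config: IRScoringConfig,
    max_rounds: int = 6,
) -> bool:
    """Remove every inverted repeat outside the protected (planted) spans.

    The purine-skewed background leaves only a handful of incidental
    repeats per chromosome; each is broken locally, then the chromosome is
    re-scanned until clean."""
    for _ in range(max_rounds):
        reps = find_inverted_repeats(_codes_to_str(chrom_codes), ir_config)
        offending = [
            r for r in reps
            if not _overlaps(r.start - 1, r.end, protected)
        ]
        if not offending:
            return True
        for r in offending:
            _break_hairpins(
                chrom_codes, r.start - 1, r.end, rng, ir_config,
                protected=protected,
            )
    return False


def generate_genome(
    n_chroms: int = 2,
    chrom_len: int = 250_000,
    n_precursors: int = 20,
    frac_intragenic: float = 0.2,
    frac_clustered: float = 0.3,
    seed: int = 0,
    n_multilocus: int = 0,
    copies_per_multilocus: int = 2,
    decoys_per_chrom: int = 3,
    decoy_len: int = 1_000,
    filters: FilterConfig = FilterConfig(),
    ir_config: IRScoringConfig = IRScoringConfig(),
) -> SyntheticGenome:
    """Generate a genome with planted precursor hairpins and its truth table.

    ``round(frac_intragenic * n_precursors)`` precursors are covered by gene
    features; ``round(frac_clustered * n_precursors)`` are grouped into
    clusters of 2-3 loci spaced well under 10 kb (the first cluster pair is
    forced antiparallel); ``n_multilocus`` precursors are additionally
    copied verbatim to ``copies_per_multilocus - 1`` extra loci. All
    randomness derives from ``seed``; identical calls are byte-identical.
    """
    if n_chroms < 1 or chrom_len < 1:
        raise ValueError("need at least one chromosome of positive length")
    if n_precursors > 0 and chrom_len < 10 * (300 * n_precursors / n_chroms):
        raise ValueError(
            f"infeasible packing: {n_precursors} precursors do not fit "
            f"{n_chroms} x {chrom_len} bp at the required spacing"
        )
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    chroms = {name: _background(rng, chrom_len) for name in chrom_names}
    truth = TruthTable()
    genes: List[Tuple[str, int, int, str]] = []

    if n_precursors > 0:
        hairpins = [
            _sample_hairpin(rng, filters, ir_config) for _ in range(n_precursors)
        ]
        n_clustered = int(round(frac_clustered * n_precursors))
        n_intragenic = int(round(frac_intragenic * n_precursors))

        # units: cluster groups of 2 (one group of 3 for an odd remainder), then singles
        units: List[List[int]] = []
        idx = list(range(n_precursors))
        ci = 0
        if n_clustered >= 2:
            while n_clustered - ci >= 2:
                size = 3 if (n_clustered - ci) == 3 else 2
                units.append(idx[ci:ci + size])
                ci += size
        singles_start = ci
        n_cluster_units = len(units)
        for k in idx[ci:]:
            units.append([k])

        # round-robin units over chromosomes, then lay out with random gaps
        per_chrom: Dict[str, List[List[int]]] = {name: [] for name in chrom_names}
        for u, unit in enumerate(units):
            per_chrom[chrom_names[u % n_chroms]].append(unit)

        min_gap, cluster_gap_lo, cluster_gap_hi = 12_000, 200, 8_000
        loci: Dict[int, Tuple[str, int, int, str]] = {}
        antiparallel_done = False
        for name in chrom_names:
            chrom_units = per_chrom[name]
            # presample intra-cluster gaps so unit lengths are exact
            unit_gaps = [
                [int(rng.integers(cluster_gap_lo, cluster_gap_hi))
                 for _ in range(len(unit) - 1)]
                for unit in chrom_units
            ]
            total_len = sum(
                sum(len(hairpins[k][0]) for k in unit) + sum(gaps)
                for unit, gaps in zip(chrom_units, unit_gaps)
            )
            slack = chrom_len - total_len - (len(chrom_units) + 1) * min_gap
            if slack < 0:
                raise ValueError("infeasible packing: units do not fit the chromosome")
            extra = rng.random(len(chrom_units) + 1)
            extra = np.floor(extra / extra.sum() * slack).astype(int)
            cursor = 1
            for ui, unit in enumerate(chrom_units):
                cursor += min_gap + int(extra[ui])
                strands = [str(rng.choice(["+", "-"])) for _ in unit]
                if len(unit) >= 2 and not antiparallel_done:
                    strands[0], strands[1] = "+", "-"
                    antiparallel_done = True
                for pos_in_unit, (k, strand) in enumerate(zip(unit, strands)):
                    seq_len = len(hairpins[k][0])
                    loci[k] = (name, cursor, cursor + seq_len - 1, strand)
                    cursor += seq_len
                    if pos_in_unit < len(unit) - 1:
                        cursor += unit_gaps[ui][pos_in_unit]

        # choose intragenic preferentially among singles
        single_ids = [unit[0] for unit in units[n_cluster_units:]]
        pool = single_ids + [k for k in range(n_precursors) if k not in single_ids]
        intragenic_ids = set(pool[:n_intragenic])

        cluster_of: Dict[int, str] = {}
        cnum = 0
        for unit in units:
            if len(unit) >= 2:
                cnum += 1
                for k in unit:
                    cluster_of[k] = f"simclust-{cnum}"

        for k in range(n_precursors):
            rna, off5, off3 = hairpins[k]
            chrom, start, end, strand = loci[k]
            dna = rna_to_dna(rna) if strand == "+" else revcomp_dna(rna_to_dna(rna))
            arr = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in dna], dtype=np.int8)
            chroms[chrom][start - 1:end] = arr
            fam = f"miR{9001 + k}"
            pid = f"sim-{fam}"
            prec = PlantedPrecursor(
                id=pid, chrom=chrom, start=start, end=end, strand=strand,
                sequence=rna, family=fam,
                mature_5p=rna[off5:off5 + MATURE_LEN], mature_5p_offset=off5,
                mature_3p=rna[off3:off3 + MATURE_LEN], mature_3p_offset=off3,
                is_intragenic=k in intragenic_ids,
                cluster_id=cluster_of.get(k),
            )
            truth.precursors.append(prec)
            if prec.is_intragenic:
                pad_l = int(rng.integers(100, 500))
                pad_r = int(rng.integers(100, 500))
                g_start = max(1, start - pad_l)
                g_end = min(chrom_len, end + pad_r)
                for other_k, (oc, os, oe, _ostr) in loci.items():
                    if other_k != k and oc == chrom and other_k not in intragenic_ids:
                        if os <= g_end and g_start <= oe:       # trim away from neighbours
                            if oe < start:
                                g_start = max(g_start, oe + 2)
                            if os > end:
                                g_end = min(g_end, os - 2)
                genes.append((chrom, g_start, g_end, f"simgene-{len(genes) + 1}"))

        # verbatim extra copies for multi-locus precursors
        for m in range(min(n_multilocus, n_precursors)):
            prec = truth.precursors[m]
            dna_plus = rna_to_dna(prec.sequence)
            for _c in range(copies_per_multilocus - 1):
                for _try in range(50):
                    chrom = chrom_names[int(rng.integers(0, n_chroms))]
                    pos = int(rng.integers(1, chrom_len - len(dna_plus)))
                    c_end = pos + len(dna_plus) - 1
                    clear = all(
                        not (p.chrom == chrom and p.start - min_gap <= c_end
                             and pos <= p.end + min_gap)
                        for p in truth.precursors
                    ) and all(
                        not (cc == chrom and cs - min_gap <= c_end and pos <= ce + min_gap)
                        for p in truth.precursors for (cc, cs, ce, _s) in p.copy_loci
                    )
                    if clear:
                        break
                else:
                    raise ValueError("infeasible packing: no room for multi-locus copies")
                strand = str(rng.choice(["+", "-"]))
                dna = dna_plus if strand == "+" else revcomp_dna(dna_plus)
                arr = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[c] for c in dna],
                               dtype=np.int8)
                chroms[chrom][pos - 1:c_end] = arr
                prec.copy_loci.append((chrom, pos, c_end, strand))

    # scrub residual incidental inverted repeats outside the planted loci
    all_spans: Dict[str, List[Tuple[int, int]]] = {name: [] for name in chrom_names}
    for p in truth.precursors:
        all_spans[p.chrom].append((p.start - 1, p.end))       # 0-based half-open
        for (cc, cs, ce, _s) in p.copy_loci:
            all_spans[cc].append((cs - 1, ce))
    for name in chrom_names:
        if not _scrub_chromosome(chroms[name], sorted(all_spans[name]), rng, ir_config):
            raise RuntimeError(f"could not scrub incidental hairpins from {name}")

    # decoy regions: hairpin-free intervals away from any planted locus
    for name in chrom_names:
        spans = sorted(all_spans[name])
        placed = 0
        for _try in range(60):
            if placed >= decoys_per_chrom or chrom_len < decoy_len + 2:
                break
            pos = int(rng.integers(1, chrom_len - decoy_len))
            d_end = pos + decoy_len - 1
            margin = ir_config.max_extent + 10
            if any(s - margin <= d_end and pos - 1 <= e + margin for s, e in spans):
                continue
            if any(ds - margin <= d_end and pos <= de + margin
                   for (dc, ds, de) in truth.decoy_regions if dc == name):
                continue
            if _break_hairpins(chroms[name], pos - 1, d_end, rng, ir_config,
                               protected=spans):
                truth.decoy_regions.append((name, pos, d_end))
                placed += 1

    genome = {name: _codes_to_str(chroms[name]) for name in chrom_names}
    return SyntheticGenome(genome=genome, genes=genes, truth=truth)


def generate_mature_reference(
    truth: TruthTable,
    n_decoys: int = 0,
    seed: int = 0,
) -> Dict[str, str]:
    """Planted mature sequences plus composition-matched shuffled decoys.

    Decoys are rejection-sampled (brute-force Hamming scan) so that none is
    within 5 substitutions of any planted mature of equal length.
    """
    if not truth.precursors:
        raise ValueError("truth table contains no precursors")
    rng = np.random.default_rng(seed)
    out = dict(truth.matures())
    planted = list(out.values())
    for d in range(n_decoys):
        template = planted[int(rng.integers(0, len(planted)))]
        for _try in range(100):
            letters = np.array(list(template))
            rng.shuffle(letters)
            decoy = "".join(letters)
            if all(
                len(p) != len(decoy) or sum(x != y for x, y in zip(p, decoy)) > 5
                for p in planted
            ):
                break
        else:
            raise RuntimeError("could not sample a decoy distinct from planted matures")
        out[f"decoy-miR{8000 + d}"] = decoy
    return out


_MISMATCH_CHOICE = {"A": "C", "C": "U", "G": "A", "U": "C"}


def _apply_edits(mature: str, edits: Sequence[Tuple[int, str]]) -> str:
    """Build a target site (transcript 5'->3') = reverse complement of the
    miRNA with the listed penalty edits applied at miRNA positions."""
    site = list(revcomp_rna(mature))
    n = len(mature)
    for pos, kind in edits:
        m_base = mature[pos - 1]
        site_idx = n - pos
        if kind == "gu":
            if m_base == "G":
                site[site_idx] = "U"
            elif m_base == "U":
                site[site_idx] = "G"
            else:
                raise ValueError(f"no G:U wobble possible at position {pos} ({m_base})")
        elif kind == "mm":
            site[site_idx] = _MISMATCH_CHOICE[m_base]
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    return "".join(site)


def designed_expectation(
    mature: str,
    edits: Sequence[Tuple[int, str]],
    config: TargetConfig = TargetConfig(),
) -> float:
    """Expectation score implied by an edit list, straight from the penalty
    table (independently of any aligner)."""
    total = 0.0
    for pos, kind in edits:
        total += position_penalty(pos, "gu_wobble" if kind == "gu" else "mismatch", config)
    return total


def _pick_position(mature: str, kind: str, in_seed: bool, rng,
                   config: TargetConfig = TargetConfig()) -> Optional[int]:
    lo, hi = config.seed_range
    candidates = []
    for pos in range(2, len(mature)):        # avoid terminal positions
        seeded = lo <= pos <= hi
        if seeded != in_seed:
            continue
        if kind == "gu" and mature[pos - 1] not in "GU":
            continue
        candidates.append(pos)
    if not candidates:
        return None
    return int(candidates[int(rng.integers(0, len(candidates)))])


#: default graded site designs: (label, [(position request)]) where a request
#: is (kind, in_seed); scores depend on the positions actually available
DEFAULT_GRADES = (
    ("perfect", ()),
    ("gu_out", (("gu", False),)),
    ("mm_seed", (("mm", True),)),
    ("mm_out_gu_out", (("mm", False), ("gu", False))),
    ("two_mm_seed", (("mm", True), ("mm", True))),
)


def generate_target_transcriptome(
    truth: TruthTable,
    seed: int = 0,
    grades: Sequence = DEFAULT_GRADES,
    extra_perfect: Optional[Dict[str, int]] = None,
    transcript_len: Tuple[int, int] = (200, 400),
) -> Dict[str, str]:
    """Transcripts carrying target sites of graded complementarity for each
    planted 5p mature. Site positions, applied edits and their implied
    expectation scores are recorded in ``truth.target_sites``.
    """
    if not truth.precursors:
        raise ValueError("truth table contains no mature miRNAs")
    rng = np.random.default_rng(seed)
    config = TargetConfig()
    transcripts: Dict[str, str] = {}
    t = 0

    def add_transcript(mirna_id: str, mature: str, edits: List[Tuple[int, str]]) -> None:
        nonlocal t
        t += 1
        tid = f"simtx-{t:04d}"
        site = _apply_edits(mature, edits)
        length = int(rng.integers(*transcript_len))
        body = _codes_to_str(_background(rng, length)).replace("T", "U")
        pos = int(rng.integers(10, length - len(site) - 10))
        transcript = body[:pos] + site + body[pos + len(site):]
        transcripts[tid] = transcript
        truth.target_sites.append(
            TargetSiteTruth(
                transcript_id=tid, mirna_id=mirna_id, position=pos + 1,
                designed_expectation=designed_expectation(mature, edits, config),
                edits=list(edits),
            )
        )

    for p in truth.precursors:
        mirna_id = f"{p.id}-5p"
        mature = p.mature_5p
        for _label, requests in grades:
            edits: List[Tuple[int, str]] = []
            feasible = True
            used = set()
            for kind, in_seed in requests:
                for _try in range(20):
                    pos = _pick_position(mature, kind, in_seed, rng)
                    if pos is None:
                        feasible = False
                        break
                    if pos not in used:
                        used.add(pos)
                        edits.append((pos, kind))
                        break
                else:
                    feasible = False
                if not feasible:
                    break
            if feasible:
                add_transcript(mirna_id, mature, edits)

    for mirna_id, count in (extra_perfect or {}).items():
        matures = truth.matures()
        for _ in range(count):
            add_transcript(mirna_id, matures[mirna_id], [])
    return transcripts


def generate_qpcr_tables(
    true_E: Dict[str, float],
    true_fold: Dict[str, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_genes: Sequence[str] = ("U6", "5.8S"),
    conditions: Tuple[str, str] = ("leaf", "flower"),
    n_dilutions: int = 5,
    n_replicates: int = 3,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Dilution-series and two-condition Cq tables with known truth.

    The dilution table holds ``n_dilutions`` points per gene at 1:5 steps
    with Cq = intercept − log10(dilution)/log10(1+E) + noise. The expression
    table holds triplicate Cq per condition for each target plus the
    reference genes (fold forced to 1 for references); the test-condition Cq
    is shifted by −log(fold)/log(1+E) so the efficiency-corrected ratio
    recovers the designed fold.
    """
    for gene, e in true_E.items():
        if not (0.0 < e <= 1.2):
            raise ValueError(f"efficiency for {gene!r} outside (0, 1.2]")
    rng = np.random.default_rng(seed)
    genes = sorted(set(true_E) | set(true_fold) | set(reference_genes))

    dil_rows = []
    for gene in genes:
        e = true_E.get(gene, 1.0)
        intercept = float(rng.uniform(18.0, 24.0))
        for k in range(n_dilutions):
            conc = 5.0 ** (-k)
            cq = intercept - math.log10(conc) / math.log10(1.0 + e)
            cq += float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
            dil_rows.append({"gene": gene, "dilution_step": k,
                             "concentration": conc, "cq": cq})
    dilution = pd.DataFrame(dil_rows)

    baseline, test = conditions
    expr_rows = []
    for gene in genes:
        e = true_E.get(gene, 1.0)
        fold = 1.0 if gene in reference_genes else true_fold.get(gene, 1.0)
        base_cq = float(rng.uniform(20.0, 28.0))
        test_cq = base_cq - math.log(fold) / math.log(1.0 + e)
        for cond, cq0 in ((baseline, base_cq), (test, test_cq)):
            for rep in range(1, n_replicates + 1):
                cq = cq0 + (float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0)
                expr_rows.append({"gene": gene, "condition": cond,
                                  "replicate": rep, "cq": cq})
    expression = pd.DataFrame(expr_rows)
    return dilution, expression
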