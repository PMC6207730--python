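"""End-to-end orchestration: discover -> extract -> fold -> descriptors ->
filters -> annotate -> (optional) targets / primers, with a run manifest.

Candidate strand is resolved by mature homology (a candidate is emitted on
the strand of its mature hit; hits on both strands emit two records), so
the homology scan runs at extraction time and its verdict is recorded with
the other filter rules. Precursor calls are named
``<prefix>-<family>-<n>`` with their matures as ``...-5p`` / ``...-3p``,
following the conventional novel-miRNA naming style.
"""

from __future__ import annotations

import configparser
import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .annotation import (
    ClusterConfig, PrecursorLocus, classify_localization, detect_clusters,
    find_multilocus, load_gene_intervals,
)
from .descriptors import (
    DescriptorSet, FilterConfig, FilterVerdict, apply_filters, compute_descriptors,
    exclusion_screen,
)
from .folding import FoldResult, fold_mfe
from .hairpin import (
    HairpinCandidate, HomologyConfig, IRScoringConfig, MatureHit,
    extract_candidate, find_inverted_repeats, scan_mature_homology,
)
from .io import read_fasta
from .qpcr import PrimerConfig, design_stemloop
from .targets import TargetConfig, predict_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str = ""
    matures: str = ""
    gff: Optional[str] = None
    transcripts: Optional[str] = None
    exclusions: Tuple[str, ...] = ()
    outdir: str = "plantmir_out"
    prefix: str = "sim"
    engine: str = "fallback"
    flank: int = 0
    seed: int = 0
    log_level: str = "INFO"
    ir: IRScoringConfig = field(default_factory=IRScoringConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    homology: HomologyConfig = field(default_factory=HomologyConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    target: TargetConfig = field(default_factory=TargetConfig)
    primer: PrimerConfig = field(default_factory=PrimerConfig)
    run_targets: bool = True
    run_primers: bool = True

    def validate(self) -> None:
        for label, path in (("genome", self.genome), ("matures", self.matures)):
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{label} FASTA not found: {path!r}")
        for opt in (self.gff, self.transcripts, *self.exclusions):
            if opt and not Path(opt).exists():
                raise FileNotFoundError(f"input path not found: {opt!r}")

    # --- flat key=value serialization -------------------------------------
    _SECTIONS = {
        "paths": ("genome", "matures", "gff", "transcripts", "outdir"),
        "run": ("prefix", "engine", "flank", "seed", "log_level",
                "run_targets", "run_primers"),
    }
    _SUB = {"ir": IRScoringConfig, "filters": FilterConfig, "homology": HomologyConfig,
            "cluster": ClusterConfig, "target": TargetConfig, "primer": PrimerConfig}

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {k: json.dumps(getattr(self, k)) for k in keys}
        cp["paths"]["exclusions"] = json.dumps(list(self.exclusions))
        for section, cls in self._SUB.items():
            sub = getattr(self, section)
            cp[section] = {
                f.name: json.dumps(getattr(sub, f.name))
                for f in dataclasses.fields(cls)
                if not isinstance(getattr(sub, f.name), (list,)) or True
            }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        kwargs: Dict[str, object] = {}
        for section, keys in cls._SECTIONS.items():
            for k in keys:
                if cp.has_option(section, k):
                    kwargs[k] = json.loads(cp.get(section, k))
        if cp.has_option("paths", "exclusions"):
            kwargs["exclusions"] = tuple(json.loads(cp.get("paths", "exclusions")))
        for section, sub_cls in cls._SUB.items():
            if cp.has_section(section):
                sub_kwargs = {
                    f.name: _retuple(json.loads(cp.get(section, f.name)))
                    for f in dataclasses.fields(sub_cls)
                    if cp.has_option(section, f.name)
                }
                kwargs[section] = sub_cls(**sub_kwargs)
        return cls(**kwargs)


def _retuple(value):
    return tuple(value) if isinstance(value, list) else value


@dataclass
class PrecursorCall:
    id: str
    candidate: HairpinCandidate
    fold: FoldResult
    descriptors: DescriptorSet
    hits: List[MatureHit]
    verdict: FilterVerdict
    family: str
    localization: str = "intergenic"
    cluster_id: Optional[str] = None
    antiparallel: bool = False
    multilocus_group: Optional[str] = None

    @property
    def locus(self) -> PrecursorLocus:
        c = self.candidate
        return PrecursorLocus(self.id, c.chrom, c.start, c.end, c.strand)

    def mature_sequences(self) -> Dict[str, str]:
        """Best hit window per arm, named ``<call id>-<arm>``."""
        best: Dict[str, MatureHit] = {}
        for h in self.hits:
            if h.arm not in best or h.mismatches < best[h.arm].mismatches:
                best[h.arm] = h
        return {
            f"{self.id}-{arm}": self.candidate.sequence[h.offset:h.offset + h.length]
            for arm, h in sorted(best.items())
        }


@dataclass
class RunManifest:
    config: Dict[str, object]
    counts: Dict[str, int] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path=None, include_timings: bool = True) -> str:
        doc = {"version": self.version, "config": self.config, "counts": self.counts}
        if include_timings:
            doc["timings"] = {k: round(v, 3) for k, v in self.timings.items()}
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


class StageFailure(RuntimeError):
    def __init__(self, stage: str, record: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed at record {record!r}: {cause}")
        self.stage = stage
        self.record = record


def run_pipeline(config: PipelineConfig) -> Tuple[RunManifest, List[PrecursorCall]]:
    """Run the full cascade and write all stage outputs under config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_snapshot(config))
    t_all = time.perf_counter()

    genome = read_fasta(config.genome)
    matures = read_fasta(config.matures)
    exclusion_records: Dict[str, str] = {}
    for path in config.exclusions:
        exclusion_records.update(read_fasta(path))
    manifest.counts["chromosomes"] = len(genome)
    manifest.counts["reference_matures"] = len(matures)

    # --- discover ---------------------------------------------------------
    t0 = time.perf_counter()
    repeats = []
    for chrom in sorted(genome):
        try:
            repeats.extend(find_inverted_repeats(genome[chrom], config.ir, chrom=chrom))
        except Exception as exc:   # pragma: no cover - defensive
            raise StageFailure("discover", chrom, exc) from exc
    manifest.counts["inverted_repeats"] = len(repeats)
    manifest.timings["discover"] = time.perf_counter() - t0

    # --- extract + homology (strand resolution) ---------------------------
    t0 = time.perf_counter()
    candidates: List[Tuple[HairpinCandidate, List[MatureHit]]] = []
    for k, repeat in enumerate(repeats):
        per_strand = {}
        for strand in "+-":
            cand = extract_candidate(
                repeat, genome, flank=config.flank, strand=strand,
                candidate_id=f"cand-{k + 1}{strand}",
            )
            per_strand[strand] = (cand, scan_mature_homology(cand, matures, config.homology))
        with_hits = {s: ch for s, ch in per_strand.items() if ch[1]}
        if len(with_hits) == 2:
            # hairpins are quasi-palindromic, so matures often hit both
            # orientations; keep the strictly better strand, both on a tie
            mm = {s: min(h.mismatches for h in hits)
                  for s, (_c, hits) in with_hits.items()}
            if mm["+"] != mm["-"]:
                best_strand = "+" if mm["+"] < mm["-"] else "-"
                with_hits = {best_strand: with_hits[best_strand]}
        if with_hits:
            candidates.extend(v for _s, v in sorted(with_hits.items()))
        else:
            candidates.append(per_strand["+"])
    manifest.counts["candidates"] = len(candidates)
    manifest.counts["candidates_with_homology"] = sum(1 for _, h in candidates if h)
    manifest.timings["extract"] = time.perf_counter() - t0

    # --- fold + descriptors -----------------------------------------------
    t0 = time.perf_counter()
    folded = []
    for cand, hits in candidates:
        try:
            fold = fold_mfe(cand.sequence, engine=config.engine)
            desc = compute_descriptors(cand.sequence, fold)
        except Exception as exc:
            raise StageFailure("fold", cand.id, exc) from exc
        folded.append((cand, hits, fold, desc))
    manifest.counts["folded"] = len(folded)
    manifest.timings["fold"] = time.perf_counter() - t0

    # --- filters ------------------------------------------------------------
    t0 = time.perf_counter()
    calls: List[PrecursorCall] = []
    family_counter: Dict[str, int] = {}
    for cand, hits, fold, desc in folded:
        excl = exclusion_screen(cand.sequence, exclusion_records,
                                config.filters.exclusion_identity) \
            if exclusion_records else None
        verdict = apply_filters(desc, hits, config.filters, exclusion_match=excl)
        if not verdict.passed:
            logger.debug("rejected %s: %s", cand.id, ",".join(verdict.failed_rules))
            continue
        best = min(hits, key=lambda h: (h.mismatches, h.offset))
        family_counter[best.family] = family_counter.get(best.family, 0) + 1
        call_id = f"{config.prefix}-{best.family}-{family_counter[best.family]}"
        calls.append(PrecursorCall(
            id=call_id, candidate=cand, fold=fold, descriptors=desc,
            hits=hits, verdict=verdict, family=best.family,
        ))
    manifest.counts["precursor_calls"] = len(calls)
    manifest.timings["filter"] = time.perf_counter() - t0

    # --- annotate -----------------------------------------------------------
    t0 = time.perf_counter()
    genes = load_gene_intervals(config.gff) if config.gff else {}
    for call in calls:
        call.localization = classify_localization(call.locus, genes)
    groups = find_multilocus((c.id, c.candidate.sequence, c.locus) for c in calls)
    for gid, loci in groups.items():
        if len(loci) > 1:
            for call in calls:
                if any(l.precursor_id == call.id for l in loci):
                    call.multilocus_group = gid
    clusters = detect_clusters([c.locus for c in calls], config.cluster)
    by_id = {c.id: c for c in calls}
    for cl in clusters:
        for locus in cl.member_loci:
            call = by_id[locus.precursor_id]
            call.cluster_id = cl.cluster_id
            call.antiparallel = cl.antiparallel
    manifest.counts["intergenic"] = sum(c.localization == "intergenic" for c in calls)
    manifest.counts["intragenic"] = sum(c.localization == "intragenic" for c in calls)
    manifest.counts["clusters"] = len(clusters)
    manifest.counts["clustered_precursors"] = sum(len(c.member_loci) for c in clusters)
    manifest.timings["annotate"] = time.perf_counter() - t0

    _write_outputs(outdir, repeats, candidates, calls, clusters)

    call_matures: Dict[str, str] = {}
    for call in calls:
        call_matures.update(call.mature_sequences())
    manifest.counts["mature_calls"] = len(call_matures)

    # --- optional downstream stages -----------------------------------------
    if config.run_targets and config.transcripts:
        t0 = time.perf_counter()
        transcripts = read_fasta(config.transcripts)
        hits = predict_targets(call_matures, transcripts, config.target)
        manifest.counts["target_hits"] = len(hits)
        manifest.timings["targets"] = time.perf_counter() - t0
        _write_targets(outdir / "targets.tsv", hits)

    if config.run_primers:
        t0 = time.perf_counter()
        primer_rows = []
        for mid, seq in sorted(call_matures.items()):
            if 19 <= len(seq) <= 24:
                ps = design_stemloop(seq, mirna_id=mid, config=config.primer)
                primer_rows.append({
                    "mirna_id": ps.mirna_id, "stemloop_rt": ps.stemloop_rt,
                    "forward": ps.forward, "reverse": ps.reverse,
                    "forward_tm": round(ps.forward_tm, 2),
                })
        manifest.counts["primer_sets"] = len(primer_rows)
        manifest.timings["primers"] = time.perf_counter() - t0
        pd.DataFrame(primer_rows).to_csv(outdir / "primers.tsv", sep="\t", index=False)

    summary = summarize_catalog(calls)
    pd.DataFrame([summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    manifest.timings["total"] = time.perf_counter() - t_all
    manifest.to_json(outdir / "manifest.json")
    return manifest, calls


def summarize_catalog(calls: Sequence[PrecursorCall]) -> Dict[str, object]:
    """Catalog-level counts: precursors, matures by arm, families,
    localization percentages and clustering."""
    n = len(calls)
    arms = {"5p": 0, "3p": 0}
    for call in calls:
        for key in call.mature_sequences():
            arms[key.rsplit("-", 1)[1]] += 1
    n_intra = sum(c.localization == "intragenic" for c in calls)
    clusters = {c.cluster_id for c in calls if c.cluster_id}
    return {
        "precursors": n,
        "matures": arms["5p"] + arms["3p"],
        "matures_5p": arms["5p"],
        "matures_3p": arms["3p"],
        "families": len({c.family for c in calls}),
        "pct_intergenic": round(100.0 * (n - n_intra) / n, 2) if n else 0.0,
        "pct_intragenic": round(100.0 * n_intra / n, 2) if n else 0.0,
        "clustered": sum(1 for c in calls if c.cluster_id),
        "clusters": len(clusters),
        "antiparallel_clustered": sum(1 for c in calls if c.antiparallel),
        "multilocus_groups": len({c.multilocus_group for c in calls
                                  if c.multilocus_group}),
    }


def _snapshot(config: PipelineConfig) -> Dict[str, object]:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [convert(o) for o in obj]
        return obj
    return convert(config)


def _write_outputs(outdir: Path, repeats, candidates, calls, clusters) -> None:
    pd.DataFrame([
        {"chrom": r.chrom, "start": r.start, "end": r.end, "score": r.score,
         "left_arm": f"{r.left_arm[0]}-{r.left_arm[1]}",
         "right_arm": f"{r.right_arm[0]}-{r.right_arm[1]}"}
        for r in repeats
    ]).to_csv(outdir / "repeats.tsv", sep="\t", index=False)
    pd.DataFrame([
        {"id": c.id, "chrom": c.chrom, "start": c.start, "end": c.end,
         "strand": c.strand, "n_mature_hits": len(h), "sequence": c.sequence}
        for c, h in candidates
    ]).to_csv(outdir / "candidates.tsv", sep="\t", index=False)

    desc_rows = []
    structures = []
    for call in calls:
        d = call.descriptors
        desc_rows.append({
            "id": call.id, "chrom": call.candidate.chrom,
            "start": call.candidate.start, "end": call.candidate.end,
            "strand": call.candidate.strand, "family": call.family,
            "length": d.length,
            "a_pct": round(d.a_pct, 2), "u_pct": round(d.u_pct, 2),
            "c_pct": round(d.c_pct, 2), "g_pct": round(d.g_pct, 2),
            "gc_pct": round(d.gc_pct, 2), "au_pct": round(d.au_pct, 2),
            "mfe": round(d.mfe, 2), "amfe": round(d.amfe, 2),
            "mfei": round(d.mfei, 4) if d.mfei is not None else "NA",
            "mfee": d.ensemble_mfe if d.ensemble_mfe is not None else "NA",
            "diversity": d.diversity if d.diversity is not None else "NA",
            "frequency": d.ensemble_frequency
            if d.ensemble_frequency is not None else "NA",
            "localization": call.localization,
            "cluster_id": call.cluster_id or "NA",
            "antiparallel": call.antiparallel,
            "multilocus_group": call.multilocus_group or "NA",
        })
        structures.append(f">{call.id}\n{call.candidate.sequence}\n{call.fold.structure}"
                          f" ({call.fold.mfe:.2f})")
    pd.DataFrame(desc_rows).to_csv(outdir / "precursors.tsv", sep="\t", index=False)
    (outdir / "structures.txt").write_text("\n".join(structures) + ("\n" if structures else ""))
    with open(outdir / "precursors.fa", "w") as fh:
        for call in calls:
            fh.write(f">{call.id}\n{call.candidate.sequence}\n")


def _write_targets(path: Path, hits) -> None:
    pd.DataFrame([
        {"mirna": h.alignment.mirna_id, "transcript": h.alignment.transcript_id,
         "window_start": h.alignment.window_start,
         "window_end": h.alignment.window_end,
         "expectation": h.alignment.expectation,
         "upe": h.upe if h.upe is not None else "NA",
         "mode": h.mode, "duplex": h.alignment.duplex_string}
        for h in hits
    ]).to_csv(path, sep="\t", index=False)
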