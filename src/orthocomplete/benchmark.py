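"""Gene-depletion benchmark: does reported missingness track true gene loss?

Two protocols are supported.  Protocol A (``full_gene_set``) removes a stated
fraction of *all* genes and only measures score degradation.  Protocol B
(``marker_only``) first freezes a marker-to-gene ground-truth mapping, then
removes genes exclusively from that mapped set (adding an exhaustive 100%
level), so false positives (marker still reported although its gene was
removed), false negatives (marker reported missing although its gene remains)
and precision TP/(TP+FP) are well defined.  Genome-mode depletion masks the
removed genes' spans with N using the GFF3 annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import numpy as np
import pandas as pd

from .classify import AssessmentResult, assess
from .datasets import MarkerDataset
from .genes import SearchConfig
from .profile import search

__all__ = [
    "DepletionPlan",
    "EvalCounts",
    "DepletionReport",
    "deplete_gene_set",
    "mask_genome",
    "map_ground_truth",
    "evaluate",
    "run_benchmark",
]

PROTOCOL_A = "full_gene_set"
PROTOCOL_B = "marker_only"


@dataclass(frozen=True)
class DepletionPlan:
    """Levels, replication and protocol of one benchmark run.

    Five replicates per level by default; the exhaustive 100% level (protocol
    B only) always runs a single replicate since removal is no longer random.
    """

    levels: tuple[float, ...] = (0.0, 0.10, 0.30, 0.50)
    replicates: int = 5
    protocol: str = PROTOCOL_A
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= lv <= 1 for lv in self.levels):
            raise ValueError("levels must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.protocol not in (PROTOCOL_A, PROTOCOL_B):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol == PROTOCOL_A and 1.0 in self.levels:
            raise ValueError("exhaustive depletion requires the marker_only protocol")

    @classmethod
    def protocol_b(cls, replicates: int = 5, seed: int = 0) -> "DepletionPlan":
        return cls(
            levels=(0.0, 0.10, 0.30, 0.50, 1.0),
            replicates=replicates,
            protocol=PROTOCOL_B,
            seed=seed,
        )

    def replicates_for(self, level: float) -> int:
        return 1 if level == 1.0 else self.replicates


def deplete_gene_set(
    genes: Mapping[str, str],
    fraction: float,
    eligible: Optional[Iterable[str]] = None,
    seed: int = 0,
) -> tuple[dict[str, str], tuple[str, ...]]:
    """Remove ``round(fraction x |eligible|)`` genes (half-up), sampled
    without replacement with a seeded generator.  Deterministic per seed."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    pool = sorted(eligible) if eligible is not None else sorted(genes)
    missing = [g for g in pool if g not in genes]
    if missing:
        raise ValueError(f"eligible genes absent from the collection: {missing[:5]}")
    k = math.floor(fraction * len(pool) + 0.5)
    rng = np.random.default_rng(seed)
    removed = tuple(sorted(rng.choice(pool, size=k, replace=False))) if k else ()
    kept = {g: s for g, s in genes.items() if g not in set(removed)}
    return kept, removed


def mask_genome(
    genome: Mapping[str, str],
    annotation: "str | Path",
    removed_gene_ids: Iterable[str],
) -> dict[str, str]:
    """Replace each removed gene's span with N (union of spans, both strands
    identically); every other position and all lengths are untouched.

    ``annotation`` is GFF3 text or a path to a GFF3 file; removed ids must
    each have a ``gene`` feature.
    """
    removed = set(removed_gene_ids)
    text = annotation
    if isinstance(annotation, Path) or (
        isinstance(annotation, str) and "\t" not in annotation and Path(annotation).is_file()
    ):
        text = Path(annotation).read_text()
    db = gffutils.create_db(
        str(text), dbfn=":memory:", from_string=True, merge_strategy="create_unique"
    )
    spans: dict[str, list[tuple[int, int]]] = {}
    found = set()
    for feature in db.features_of_type("gene"):
        if feature.id in removed:
            found.add(feature.id)
            spans.setdefault(feature.seqid, []).append((feature.start, feature.end))
    absent = removed - found
    if absent:
        raise ValueError(f"removed genes absent from annotation: {sorted(absent)}")
    masked = {}
    for contig, seq in genome.items():
        if contig not in spans:
            masked[contig] = seq
            continue
        buf = bytearray(seq, "ascii")
        for start, end in spans[contig]:
            buf[start - 1 : end] = b"N" * (end - start + 1)
        masked[contig] = buf.decode("ascii")
    return masked


def map_ground_truth(
    genes: Mapping[str, str],
    dataset: MarkerDataset,
    config: Optional[SearchConfig] = None,
) -> dict[str, str]:
    """Assign each marker its best-scoring complete-quality gene (exhaustive
    proteins-mode search); the mapping is frozen as the truth reference."""
    del config  # the mapping is always exhaustive
    hits = search(dataset, dict(genes), sensitivity=7.0)
    mapping: dict[str, str] = {}
    for family in dataset.markers:
        best = None
        for h in hits[family.marker_id]:
            if h.bit_score < family.score_cutoff:
                continue
            if abs(h.aligned_length - family.length_mean) > 2.0 * family.length_sigma:
                continue
            if best is None or h.bit_score > best.bit_score:
                best = h
        if best is not None:
            mapping[family.marker_id] = best.sequence_id
    return mapping


@dataclass(frozen=True)
class EvalCounts:
    """FP/FN bookkeeping against a frozen truth mapping."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> Optional[float]:
        if self.tp + self.fp == 0:
            return None
        return self.tp / (self.tp + self.fp)


def evaluate(
    result: AssessmentResult,
    truth: Mapping[str, str],
    removed_ids: Iterable[str],
) -> EvalCounts:
    """For each truth-mapped marker: still present and found -> TP; present
    and missed -> FN; removed but found -> FP."""
    removed = set(removed_ids)
    tp = fp = fn = 0
    for marker_id, gene_id in truth.items():
        status = result.per_marker[marker_id].status
        found = status != "missing"
        if gene_id in removed:
            if found:
                fp += 1
        else:
            if found:
                tp += 1
            else:
                fn += 1
    return EvalCounts(tp=tp, fp=fp, fn=fn)


@dataclass(frozen=True)
class RunRecord:
    """One depletion run: what was removed and what the engine reported."""

    level: float
    replicate: int
    mode: str
    removed: tuple[str, ...]
    result: AssessmentResult
    counts: EvalCounts


@dataclass
class DepletionReport:
    plan: DepletionPlan
    truth: dict[str, str]
    records: list[RunRecord] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Tidy summary: one row per (level, replicate, mode)."""
        rows = []
        for rec in self.records:
            r = rec.result
            rows.append(
                {
                    "level": rec.level,
                    "replicate": rec.replicate,
                    "mode": rec.mode,
                    "C": r.complete,
                    "S": r.single,
                    "D": r.duplicated,
                    "F": r.fragmented,
                    "M": r.missing,
                    "n": r.n,
                    "n_removed": len(rec.removed),
                    "TP": rec.counts.tp,
                    "FP": rec.counts.fp,
                    "FN": rec.counts.fn,
                    "precision": rec.counts.precision,
                }
            )
        return pd.DataFrame(rows)


def _child_seed(master: int, level_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(level_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(
    genes: Mapping[str, str],
    dataset: MarkerDataset,
    plan: DepletionPlan,
    genome: Optional[Mapping[str, str]] = None,
    annotation: Optional[str] = None,
    config: Optional[SearchConfig] = None,
    modes: Sequence[str] = ("proteins",),
) -> DepletionReport:
    """Run the full depletion protocol.

    For every level x replicate the gene set is depleted (and, in genome
    mode, the removed genes masked out of the assembly), the depleted input
    assessed, and the outcome evaluated against the frozen truth mapping.
    One master seed spawns per-(level, replicate) child seeds, so replicates
    are independent yet the whole report is reproducible.
    """
    if config is None:
        config = SearchConfig()
    if "genome" in modes and (genome is None or annotation is None):
        raise ValueError("genome mode requires the assembly and its GFF3 annotation")
    truth = map_ground_truth(genes, dataset, config)
    eligible = sorted(truth.values()) if plan.protocol == PROTOCOL_B else None
    report = DepletionReport(plan=plan, truth=truth)
    for li, level in enumerate(plan.levels):
        for rep in range(plan.replicates_for(level)):
            seed = _child_seed(plan.seed, li, rep)
            kept, removed = deplete_gene_set(genes, level, eligible=eligible, seed=seed)
            for mode in modes:
                if mode == "proteins":
                    result = assess(
                        kept, dataset, mode="proteins", config=config,
                        input_id=f"depleted_L{level}_r{rep}",
                    )
                elif mode == "genome":
                    masked = mask_genome(genome, annotation, removed)
                    result = assess(
                        masked, dataset, mode="genome", config=config,
                        input_id=f"masked_L{level}_r{rep}",
                    )
                else:
                    raise ValueError(f"unknown benchmark mode {mode!r}")
                counts = evaluate(result, truth, removed)
                report.records.append(
                    RunRecord(
                        level=level,
                        replicate=rep,
                        mode=mode,
                        removed=removed,
                        result=result,
                        counts=counts,
                    )
                )
    return report
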