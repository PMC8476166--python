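"""Per-marker status calls and aggregate completeness scoring.

A marker is Complete when some locus scores at or above the family's bit
cutoff with an aligned length inside the family length band (mean +/- 2
sigma of the ungapped seed lengths); Complete markers split into Single and
Duplicated by the number of distinct loci, a cutoff-passing hit outside the
length band makes the marker Fragmented, and everything else is Missing.
Counts aggregate into the canonical one-line score string

    C:99.1%[S:9.6%,D:89.5%],F:0.1%,M:0.8%,n:4896

with percentages rounded half-up to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .datasets import MarkerDataset, MarkerFamily
from .genes import SearchConfig, six_frame_peptides, two_pass_genome_search
from .profile import SearchHit, search

__all__ = [
    "MarkerStatus",
    "AssessmentResult",
    "ScreenReport",
    "classify_marker",
    "assess",
    "format_summary",
    "parasitic_recalculate",
    "cross_domain_screen",
    "percentage",
]

COMPLETE_SINGLE = "complete_single"
COMPLETE_DUPLICATED = "complete_duplicated"
FRAGMENTED = "fragmented"
MISSING = "missing"

STATUSES = (COMPLETE_SINGLE, COMPLETE_DUPLICATED, FRAGMENTED, MISSING)

LENGTH_BAND_SIGMAS = 2.0
LOCUS_OVERLAP_FRACTION = 0.5  # envelopes overlapping by >= this (of the
# shorter envelope) on the same sequence are one locus


@dataclass(frozen=True)
class MarkerStatus:
    """Status of one marker with its supporting loci (best hit per locus)."""

    status: str
    loci: tuple[SearchHit, ...] = ()

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == MISSING and self.loci:
            raise ValueError("missing status cannot carry loci")
        if self.status == COMPLETE_DUPLICATED and len(self.loci) < 2:
            raise ValueError("complete_duplicated requires >= 2 loci")


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def _cluster_loci(hits: Sequence[SearchHit]) -> list[SearchHit]:
    """Collapse hits into distinct loci, keeping the best-scoring hit of each.

    Two hits belong to the same locus when their (genomic, if available)
    envelopes lie on the same sequence and overlap by at least half of the
    shorter envelope.
    """
    reps: list[SearchHit] = []
    for hit in sorted(hits, key=lambda h: (-h.bit_score, h.locus_key)):
        seq, s, e = hit.locus_key
        merged = False
        for rep in reps:
            rseq, rs, re_ = rep.locus_key
            if rseq != seq:
                continue
            ov = _overlap_len((s, e), (rs, re_))
            shorter = min(e - s + 1, re_ - rs + 1)
            if ov >= LOCUS_OVERLAP_FRACTION * shorter:
                merged = True  # rep already has the better score
                break
        if not merged:
            reps.append(hit)
    return reps


def classify_marker(hits: Sequence[SearchHit], family: MarkerFamily) -> MarkerStatus:
    """Turn the hits for one marker into a status call."""
    if any(h.marker_id != family.marker_id for h in hits):
        raise ValueError("hits from a different marker passed to classify_marker")
    reps = _cluster_loci(hits)
    complete = []
    fragments = []
    band = LENGTH_BAND_SIGMAS * family.length_sigma
    for rep in reps:
        if rep.bit_score < family.score_cutoff:
            continue
        if abs(rep.aligned_length - family.length_mean) <= band:
            complete.append(rep)
        else:
            fragments.append(rep)
    if len(complete) >= 2:
        return MarkerStatus(COMPLETE_DUPLICATED, tuple(complete))
    if len(complete) == 1:
        return MarkerStatus(COMPLETE_SINGLE, tuple(complete))
    if fragments:
        return MarkerStatus(FRAGMENTED, tuple(fragments))
    return MarkerStatus(MISSING)


def percentage(count: int, n: int) -> float:
    """100 * count / n rounded half-up to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float((Decimal(100 * count) / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP))


@dataclass(frozen=True)
class AssessmentResult:
    """Per-marker statuses and aggregate counts for one input/dataset pair."""

    input_id: str
    dataset_name: str
    mode: str
    workflow_label: str
    per_marker: Mapping[str, MarkerStatus]
    genetic_code_used: Optional[int] = None

    def __post_init__(self) -> None:
        counts = self.counts
        if sum(counts.values()) != self.n:
            raise AssertionError("status counts do not sum to n")

    @property
    def n(self) -> int:
        return len(self.per_marker)

    @property
    def counts(self) -> dict[str, int]:
        c = {s: 0 for s in STATUSES}
        for ms in self.per_marker.values():
            c[ms.status] += 1
        return c

    @property
    def single(self) -> int:
        return self.counts[COMPLETE_SINGLE]

    @property
    def duplicated(self) -> int:
        return self.counts[COMPLETE_DUPLICATED]

    @property
    def fragmented(self) -> int:
        return self.counts[FRAGMENTED]

    @property
    def missing(self) -> int:
        return self.counts[MISSING]

    @property
    def complete(self) -> int:
        return self.single + self.duplicated

    @property
    def complete_pct(self) -> float:
        return percentage(self.complete, self.n)

    def percentages(self) -> dict[str, float]:
        return {
            "C": percentage(self.complete, self.n),
            "S": percentage(self.single, self.n),
            "D": percentage(self.duplicated, self.n),
            "F": percentage(self.fragmented, self.n),
            "M": percentage(self.missing, self.n),
        }

    def summary_line(self) -> str:
        return format_summary(self)

    def to_json(self) -> str:
        payload = {
            "input": self.input_id,
            "dataset": self.dataset_name,
            "mode": self.mode,
            "workflow": self.workflow_label,
            "genetic_code": self.genetic_code_used,
            "n": self.n,
            "counts": {
                "S": self.single,
                "D": self.duplicated,
                "F": self.fragmented,
                "M": self.missing,
            },
            "percentages": self.percentages(),
            "summary": self.summary_line(),
        }
        return json.dumps(payload, indent=2)

    def full_table(self) -> str:
        """Per-marker TSV: marker_id, status, sequence, start, end, score, length."""
        lines = ["marker_id\tstatus\tsequence\tstart\tend\tscore\tlength"]
        for marker_id in self.per_marker:
            ms = self.per_marker[marker_id]
            if not ms.loci:
                lines.append(f"{marker_id}\t{ms.status}\t-\t-\t-\t-\t-")
                continue
            for hit in ms.loci:
                seq, s, e = hit.locus_key
                lines.append(
                    f"{marker_id}\t{ms.status}\t{seq}\t{s}\t{e}"
                    f"\t{hit.bit_score:.1f}\t{hit.aligned_length}"
                )
        return "\n".join(lines) + "\n"


def format_summary(result: AssessmentResult) -> str:
    """The canonical one-line score string."""
    p = result.percentages()
    return (
        f"C:{p['C']}%[S:{p['S']}%,D:{p['D']}%],"
        f"F:{p['F']}%,M:{p['M']}%,n:{result.n}"
    )


def _classify_all(
    hits: Mapping[str, Sequence[SearchHit]], dataset: MarkerDataset
) -> dict[str, MarkerStatus]:
    return {
        m.marker_id: classify_marker(hits.get(m.marker_id, ()), m) for m in dataset.markers
    }


def assess(
    inputs: Mapping[str, str],
    dataset: MarkerDataset,
    mode: str = "genome",
    config: Optional[SearchConfig] = None,
    input_id: str = "input",
) -> AssessmentResult:
    """Assess one sequence collection against one dataset.

    ``mode`` is ``genome`` (nucleotide contigs, two-pass ORF workflow),
    ``proteins`` (amino-acid gene set, direct search) or ``transcriptome``
    (nucleotide transcripts, six-frame translation then direct search).
    """
    if config is None:
        config = SearchConfig()
    if not inputs or all(len(s) == 0 for s in inputs.values()):
        raise ValueError(f"{input_id}: empty input")
    genetic_code: Optional[int] = None
    if mode == "genome":
        gsr = two_pass_genome_search(inputs, dataset, config)
        hits = gsr.hits
        genetic_code = gsr.genetic_code_used
        workflow = "genome_orf_two_pass"
    elif mode == "proteins":
        hits = search(dataset, inputs, sensitivity=config.sensitivity_pass2)
        workflow = "proteins"
    elif mode == "transcriptome":
        code = dataset.genetic_codes[0] if dataset.genetic_codes else 1
        peptides, loci = six_frame_peptides(inputs, code, min_aa=config.min_orf_nt // 3)
        raw = search(dataset, peptides, sensitivity=config.sensitivity_pass2)
        hits = {
            m: [replace(h, locus=loci[h.sequence_id]) for h in hs] for m, hs in raw.items()
        }
        genetic_code = code
        workflow = "transcriptome_sixframe"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return AssessmentResult(
        input_id=input_id,
        dataset_name=dataset.name,
        mode=mode,
        workflow_label=workflow,
        per_marker=_classify_all(hits, dataset),
        genetic_code_used=genetic_code,
    )


def parasitic_recalculate(
    result: AssessmentResult, exclusion_list: Iterable[str]
) -> AssessmentResult:
    """Rescore after excluding markers known to be absent in genome-reduced
    parasites, so their absence is not counted as incompleteness.

    Excluded ids not present in the result are ignored; removing every marker
    is an error.
    """
    excluded = set(exclusion_list)
    kept = {m: s for m, s in result.per_marker.items() if m not in excluded}
    if not kept:
        raise ValueError("exclusion list removes every marker")
    return AssessmentResult(
        input_id=result.input_id,
        dataset_name=result.dataset_name,
        mode=result.mode,
        workflow_label=result.workflow_label + "+parasitic_check",
        per_marker=kept,
        genetic_code_used=result.genetic_code_used,
    )


@dataclass(frozen=True)
class ScreenReport:
    """Cross-domain contamination screen: completeness against each root set.

    A background level of cross-matches between domains is expected (markers
    from one domain routinely score in genomes of another), so only an
    off-domain completeness above the advisory threshold raises a flag, and
    the flag is advisory evidence, not a verdict.
    """

    completeness: Mapping[str, float]  # domain -> C%
    best_domain: str
    flags: tuple[str, ...]
    threshold: float
    results: Mapping[str, AssessmentResult] = field(default_factory=dict)


def cross_domain_screen(
    inputs: Mapping[str, str],
    root_datasets: Sequence[MarkerDataset],
    config: Optional[SearchConfig] = None,
    mode: str = "genome",
    input_id: str = "input",
) -> ScreenReport:
    """Assess the input against each domain-level root dataset and flag any
    off-domain root whose completeness exceeds the advisory threshold."""
    if config is None:
        config = SearchConfig()
    results = {}
    for ds in root_datasets:
        results[ds.domain] = assess(inputs, ds, mode=mode, config=config, input_id=input_id)
    completeness = {dom: r.complete_pct for dom, r in results.items()}
    best = max(completeness, key=lambda d: completeness[d])
    flags = tuple(
        dom
        for dom in completeness
        if dom != best and completeness[dom] > config.advisory_threshold
    )
    return ScreenReport(
        completeness=completeness,
        best_domain=best,
        flags=flags,
        threshold=config.advisory_threshold,
        results=results,
    )
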