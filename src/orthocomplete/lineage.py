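"""Automatic dataset selection for inputs of unknown taxonomic origin.

The input is first assessed against the domain-level root datasets; from the
winning root a greedy descent walks the dataset hierarchy, moving to the
child dataset with the highest completeness as long as that completeness does
not fall more than a small tolerance below the parent's (higher-resolution
sets carry more markers and score slightly more conservatively).  The
stopping node is the selected dataset.

This score-driven descent is a functional stand-in for phylogenetic
placement: the contract — root scoring first, then the most specific dataset
supported by the input — is the same, the mechanism is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .classify import AssessmentResult, assess
from .datasets import DatasetTree, MarkerDataset
from .genes import SearchConfig

__all__ = [
    "LineageDecision",
    "select_root",
    "descend",
    "auto_assess",
    "run_batch",
    "categorise_decision",
]

DOMAIN_ORDER = ("bacteria", "archaea", "eukaryota", "viruses")
PROK_DOMAINS = ("bacteria", "archaea")


@dataclass(frozen=True)
class LineageDecision:
    """Outcome of auto-lineage selection for one input."""

    chosen_dataset: str
    path: tuple[str, ...]  # root ... chosen
    root_scores: Mapping[str, float]  # root dataset name -> C%
    result: AssessmentResult  # assessment with the chosen dataset
    category: Optional[str] = None  # correct | suboptimal | disagreement


def _rank_key(ds: MarkerDataset, result: AssessmentResult) -> tuple:
    # higher C% first, then fewer missing, then fixed domain order, then name
    return (
        -result.complete_pct,
        result.missing,
        DOMAIN_ORDER.index(ds.domain),
        ds.name,
    )


def select_root(
    inputs: Mapping[str, str],
    tree: DatasetTree,
    config: Optional[SearchConfig] = None,
    mode: str = "genome",
    prok_only: bool = False,
    input_id: str = "input",
) -> tuple[MarkerDataset, dict[str, float], dict[str, AssessmentResult]]:
    """Assess the input against every candidate root dataset and pick the
    best one (max completeness; ties by fewer missing, then domain order)."""
    if config is None:
        config = SearchConfig()
    candidates = tree.roots
    if prok_only:
        candidates = tuple(ds for ds in candidates if ds.domain in PROK_DOMAINS)
    if not candidates:
        raise ValueError("no root dataset available")
    results = {
        ds.name: assess(inputs, ds, mode=mode, config=config, input_id=input_id)
        for ds in candidates
    }
    best = min(candidates, key=lambda ds: _rank_key(ds, results[ds.name]))
    scores = {name: r.complete_pct for name, r in results.items()}
    return best, scores, results


def descend(
    inputs: Mapping[str, str],
    tree: DatasetTree,
    root: MarkerDataset,
    config: Optional[SearchConfig] = None,
    mode: str = "genome",
    input_id: str = "input",
    root_scores: Optional[Mapping[str, float]] = None,
    root_result: Optional[AssessmentResult] = None,
) -> LineageDecision:
    """Greedy descent from ``root`` to the most specific supported dataset.

    At each node every child dataset is assessed; the walk moves to the child
    with the highest completeness provided it is within
    ``config.descent_tolerance`` percentage points of the current node's, and
    stops otherwise (or at a leaf).
    """
    if config is None:
        config = SearchConfig()
    node = root
    node_result = root_result or assess(inputs, node, mode=mode, config=config, input_id=input_id)
    path = [node.name]
    while True:
        children = tree.children(node.name)
        if not children:
            break
        child_results = {
            ds.name: assess(inputs, ds, mode=mode, config=config, input_id=input_id)
            for ds in children
        }
        best_child = min(children, key=lambda ds: _rank_key(ds, child_results[ds.name]))
        best_result = child_results[best_child.name]
        if best_result.complete_pct < node_result.complete_pct - config.descent_tolerance:
            break
        node, node_result = best_child, best_result
        path.append(node.name)
    return LineageDecision(
        chosen_dataset=node.name,
        path=tuple(path),
        root_scores=dict(root_scores or {root.name: node_result.complete_pct}),
        result=node_result,
    )


def auto_assess(
    inputs: Mapping[str, str],
    tree: DatasetTree,
    config: Optional[SearchConfig] = None,
    mode: str = "genome",
    prok_only: bool = False,
    input_id: str = "input",
) -> LineageDecision:
    """Full auto-lineage workflow: root selection followed by descent."""
    root, scores, root_results = select_root(
        inputs, tree, config, mode=mode, prok_only=prok_only, input_id=input_id
    )
    return descend(
        inputs,
        tree,
        root,
        config,
        mode=mode,
        input_id=input_id,
        root_scores=scores,
        root_result=root_results[root.name],
    )


def categorise_decision(decision: LineageDecision, truth: str, tree: DatasetTree) -> str:
    """Benchmark-harness categorisation of a decision against a known truth:
    ``correct`` (most specific available dataset), ``suboptimal`` (an ancestor
    was selected) or ``disagreement`` (a non-ancestral dataset)."""
    if decision.chosen_dataset == truth:
        return "correct"
    if tree.is_ancestor(decision.chosen_dataset, truth):
        return "suboptimal"
    return "disagreement"


# ---------------------------------------------------------------------------
# batch mode
# ---------------------------------------------------------------------------

_SUMMARY_COLUMNS = [
    "input_id",
    "status",
    "dataset",
    "C_pct",
    "S_pct",
    "D_pct",
    "F_pct",
    "M_pct",
    "n",
    "genetic_code",
    "workflow",
]


def _read_fasta(path: str | Path) -> dict[str, str]:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def run_batch(
    inputs: Sequence[tuple[str, "Mapping[str, str] | str | Path"]],
    tree: DatasetTree,
    config: Optional[SearchConfig] = None,
    mode: str = "genome",
    prok_only: bool = False,
) -> tuple[list[Optional[LineageDecision]], pd.DataFrame]:
    """Auto-lineage assessment of several inputs with a summary table.

    ``inputs`` is a sequence of ``(input_id, source)`` pairs where the source
    is either an in-memory ``{sequence_id: sequence}`` mapping or a FASTA
    path.  A failing input produces an error row, not an abort; rows keep the
    input order.
    """
    if not inputs:
        raise ValueError("batch requires at least one input")
    decisions: list[Optional[LineageDecision]] = []
    rows = []
    for input_id, source in inputs:
        try:
            seqs = source if isinstance(source, Mapping) else _read_fasta(source)
            decision = auto_assess(
                seqs, tree, config, mode=mode, prok_only=prok_only, input_id=input_id
            )
        except Exception as exc:  # isolation: one bad input must not stop the batch
            decisions.append(None)
            rows.append(
                {c: None for c in _SUMMARY_COLUMNS}
                | {"input_id": input_id, "status": f"error: {exc}"}
            )
            continue
        decisions.append(decision)
        r = decision.result
        p = r.percentages()
        rows.append(
            {
                "input_id": input_id,
                "status": "ok",
                "dataset": decision.chosen_dataset,
                "C_pct": p["C"],
                "S_pct": p["S"],
                "D_pct": p["D"],
                "F_pct": p["F"],
                "M_pct": p["M"],
                "n": r.n,
                "genetic_code": r.genetic_code_used,
                "workflow": r.workflow_label,
            }
        )
    return decisions, pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)
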