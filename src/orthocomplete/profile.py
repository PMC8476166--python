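"""Position-specific scoring profiles and protein search.

Each marker family is compiled into a small local-alignment profile: match
columns are the alignment columns with gap fraction below one half, emissions
come from residue counts with add-one smoothing over the 20-letter amino-acid
alphabet, and transition penalties are fixed constants.  Scoring supports the
max-path (viterbi) and sum-over-paths (forward) semantics; both are exact and
are validated against exhaustive path enumeration on small cases.

The profile engine replaces the external HMM search stage of conventional
completeness pipelines so that scores are fully reproducible and testable
without third-party binaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from . import _dp

__all__ = [
    "AMINO_ACIDS",
    "ProteinProfile",
    "SearchHit",
    "build_profile",
    "score_sequence",
    "search",
    "profiles_for",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_WILDCARD = len(AMINO_ACIDS)  # unknown residues score as background (log-odds 0)

LN2 = math.log(2.0)

# fixed transition log-probabilities (nats); estimation is deliberately not done
TRANSITIONS = {
    "mm": math.log(0.90),
    "mi": math.log(0.05),
    "md": math.log(0.05),
    "ii": math.log(0.40),
    "im": math.log(0.60),
    "dd": math.log(0.40),
    "dm": math.log(0.60),
}
_T = (
    TRANSITIONS["mm"],
    TRANSITIONS["mi"],
    TRANSITIONS["md"],
    TRANSITIONS["ii"],
    TRANSITIONS["im"],
    TRANSITIONS["dd"],
    TRANSITIONS["dm"],
)

MAX_GAP_FRACTION = 0.5  # columns at or above this gap fraction are dropped
REPORTING_FLOOR = 0.5  # hits are reported down to this fraction of the cutoff
EXHAUSTIVE_SENSITIVITY = 6.0  # at or above this the k-mer prefilter is off
PREFILTER_K = 4


class DegenerateProfileError(ValueError):
    """Raised when an alignment retains zero match columns."""


@dataclass(frozen=True)
class ProteinProfile:
    """Compiled position-specific scoring model for one marker family."""

    marker_id: str
    match_columns: int
    emissions: np.ndarray  # (M, 21) log-odds; column 20 is the wildcard (0.0)
    transition_penalties: Mapping[str, float]
    background: np.ndarray  # (20,) frequencies summing to 1

    def __post_init__(self) -> None:
        if self.match_columns < 1:
            raise DegenerateProfileError(f"{self.marker_id}: profile needs >= 1 match column")
        if abs(float(self.background.sum()) - 1.0) > 1e-12:
            raise ValueError(f"{self.marker_id}: background must sum to 1")


@dataclass(frozen=True)
class SearchHit:
    """A scored local match of one target protein against one profile.

    ``env_start``/``env_end`` are 1-based inclusive positions on the target of
    the residues consumed by the best viterbi path.  ``locus`` optionally
    carries genomic coordinates ``(contig, nt_start, nt_end)`` when the target
    protein was extracted from nucleotide sequence; classification merges hits
    into loci on these coordinates.  ``search_pass`` records which search pass
    produced the hit in two-pass genome mode.
    """

    marker_id: str
    sequence_id: str
    bit_score: float
    env_start: int
    env_end: int
    locus: Optional[tuple[str, int, int]] = None
    search_pass: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.env_start <= self.env_end:
            raise ValueError(f"bad envelope {self.env_start}..{self.env_end}")

    @property
    def aligned_length(self) -> int:
        return self.env_end - self.env_start + 1

    @property
    def locus_key(self) -> tuple[str, int, int]:
        """Coordinates used for locus clustering (genomic when available)."""
        return self.locus if self.locus is not None else (
            self.sequence_id,
            self.env_start,
            self.env_end,
        )


def encode(protein: str) -> np.ndarray:
    """Encode a protein as indices; residues outside the 20-letter alphabet
    (X, B, Z, ...) map to the background wildcard."""
    return np.array([_AA_INDEX.get(c, _WILDCARD) for c in protein.upper()], dtype=np.int64)


def build_profile(family, background: Optional[np.ndarray] = None) -> ProteinProfile:
    """Compile a :class:`~orthocomplete.datasets.MarkerFamily` into a profile.

    Match columns are alignment columns whose gap fraction is below 0.5;
    emissions use add-one smoothing over the 20 amino acids, so a single-seed
    column emits its residue with probability 2/21 and any other with 1/21.
    """
    if background is None:
        background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    seeds = family.seed_alignment
    n = len(seeds)
    width = len(seeds[0])
    columns = []
    for j in range(width):
        col = [s[j] for s in seeds]
        if col.count("-") / n < MAX_GAP_FRACTION:
            columns.append(col)
    if not columns:
        raise DegenerateProfileError(f"{family.marker_id}: no match columns retained")
    em = np.zeros((len(columns), len(AMINO_ACIDS) + 1))
    for k, col in enumerate(columns):
        counts = np.zeros(len(AMINO_ACIDS))
        n_res = 0
        for c in col:
            if c == "-":
                continue
            n_res += 1
            idx = _AA_INDEX.get(c.upper())
            if idx is not None:
                counts[idx] += 1
            # unknown residues contribute to the denominator only
        probs = (counts + 1.0) / (n_res + len(AMINO_ACIDS))
        em[k, :-1] = np.log(probs / background)
    return ProteinProfile(
        marker_id=family.marker_id,
        match_columns=len(columns),
        emissions=em,
        transition_penalties=dict(TRANSITIONS),
        background=background,
    )


def score_sequence(
    profile: ProteinProfile,
    protein: str,
    mode: str = "viterbi",
    sequence_id: str = "query",
) -> Optional[SearchHit]:
    """Score one protein against one profile; returns ``None`` for an empty
    protein (a no-hit, not an error).

    The bit score is the best local path (viterbi) or the log-sum over all
    local paths (forward), divided by ln 2.  The envelope always comes from
    the viterbi traceback.
    """
    if mode not in ("viterbi", "forward"):
        raise ValueError(f"unknown mode {mode!r}")
    x = encode(protein)
    if x.size == 0:
        return None
    score_nats, start, end = _dp.viterbi(profile.emissions, x, *_T)
    if mode == "forward":
        score_nats = _dp.forward(profile.emissions, x, *_T)
    return SearchHit(
        marker_id=profile.marker_id,
        sequence_id=sequence_id,
        bit_score=score_nats / LN2,
        env_start=start + 1,
        env_end=end + 1,
    )


# ---------------------------------------------------------------------------
# dataset-level search
# ---------------------------------------------------------------------------

_profile_cache: dict[int, dict[str, ProteinProfile]] = {}


def profiles_for(dataset) -> dict[str, ProteinProfile]:
    """Compiled profiles for every marker of ``dataset`` (memoised)."""
    key = id(dataset)
    cached = _profile_cache.get(key)
    if cached is None or len(cached) != dataset.n_markers:
        cached = {m.marker_id: build_profile(m) for m in dataset.markers}
        _profile_cache.clear()  # keep at most one dataset resident
        _profile_cache[key] = cached
    return cached


def _kmers(seq: str, k: int = PREFILTER_K) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _prefilter_min_shared(sensitivity: float) -> int:
    # a target must share this many exact 4-mers with a seed to be scored
    return max(1, math.ceil(8.0 - sensitivity))


def search(
    dataset,
    proteins: Mapping[str, str],
    sensitivity: float = 4.5,
    floor_fraction: float = REPORTING_FLOOR,
) -> dict[str, list[SearchHit]]:
    """Score a protein collection against every marker of a dataset.

    ``sensitivity`` in [1, 7] dials a k-mer prefilter: at low values a target
    is only scored against a marker when it shares enough exact 4-mers with a
    seed sequence; at 6 and above every pair is scored exhaustively.  Raising
    sensitivity can only add hits.  Hits are reported down to
    ``floor_fraction x score_cutoff`` (half the cutoff by default); the
    classification stage applies the full cutoff.
    """
    if not 1.0 <= sensitivity <= 7.0:
        raise ValueError("sensitivity must be in [1, 7]")
    profs = profiles_for(dataset)
    use_prefilter = sensitivity < EXHAUSTIVE_SENSITIVITY
    min_shared = _prefilter_min_shared(sensitivity)
    target_kmers = {sid: _kmers(seq) for sid, seq in proteins.items()} if use_prefilter else {}
    hits: dict[str, list[SearchHit]] = {m.marker_id: [] for m in dataset.markers}
    for family in dataset.markers:
        prof = profs[family.marker_id]
        if use_prefilter:
            seed_kmers: set[str] = set()
            for s in family.ungapped_seeds():
                seed_kmers |= _kmers(s)
        floor = floor_fraction * family.score_cutoff
        for sid, seq in proteins.items():
            if not seq:
                continue
            if use_prefilter and len(target_kmers[sid] & seed_kmers) < min_shared:
                continue
            hit = score_sequence(prof, seq, sequence_id=sid)
            if hit is not None and hit.bit_score >= floor:
                hits[family.marker_id].append(hit)
    return hits
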