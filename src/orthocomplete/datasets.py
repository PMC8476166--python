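"""Marker datasets: lineage-specific collections of single-copy ortholog families.

A marker dataset bundles, for one lineage, the seed alignments of its marker
families together with per-family score and length cutoffs, the candidate
genetic codes of the lineage (for prokaryotic and viral sets) and a pointer to
the parent dataset in the lineage hierarchy.  Datasets live on disk as a small
documented directory (``dataset.cfg``, two cutoff tables, one aligned FASTA
per marker) so that they can be versioned, diffed and regenerated.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MarkerFamily",
    "MarkerDataset",
    "DatasetTree",
    "DatasetFormatError",
    "DatasetConsistencyError",
    "load_dataset",
    "write_dataset",
    "build_dataset",
    "load_dataset_tree",
]

DOMAINS = ("bacteria", "archaea", "eukaryota", "viruses")
#: domains whose datasets must declare candidate genetic codes
CODED_DOMAINS = ("bacteria", "archaea", "viruses")


class DatasetFormatError(ValueError):
    """A dataset file could not be parsed (names the file and line)."""


class DatasetConsistencyError(ValueError):
    """Dataset files disagree with each other (e.g. a marker lacks a cutoff)."""


@dataclass(frozen=True)
class MarkerFamily:
    """One single-copy ortholog family.

    Parameters
    ----------
    marker_id:
        Unique label without whitespace.
    seed_alignment:
        Aligned amino-acid seed sequences ('-' is the gap character); all
        members share the same aligned length.
    score_cutoff:
        Bit-score threshold a hit must reach to count as found.
    length_mean, length_sigma:
        Mean and population standard deviation of the ungapped seed lengths,
        in amino acids; the classification length band is ``mean +/- 2 sigma``.
    """

    marker_id: str
    seed_alignment: tuple[str, ...]
    score_cutoff: float
    length_mean: float
    length_sigma: float

    def __post_init__(self) -> None:
        if not self.marker_id or any(c.isspace() for c in self.marker_id):
            raise ValueError(f"marker_id must be non-empty without whitespace: {self.marker_id!r}")
        if not self.seed_alignment:
            raise ValueError(f"{self.marker_id}: empty seed alignment")
        width = len(self.seed_alignment[0])
        if width < 1 or any(len(s) != width for s in self.seed_alignment):
            raise ValueError(f"{self.marker_id}: seed sequences must share an aligned length >= 1")
        if not self.score_cutoff > 0:
            raise ValueError(f"{self.marker_id}: score_cutoff must be > 0")
        if not self.length_mean > 0:
            raise ValueError(f"{self.marker_id}: length_mean must be > 0")
        if self.length_sigma < 0:
            raise ValueError(f"{self.marker_id}: length_sigma must be >= 0")

    @property
    def alignment_width(self) -> int:
        return len(self.seed_alignment[0])

    def ungapped_seeds(self) -> list[str]:
        """Seed sequences with gap characters removed."""
        return [s.replace("-", "") for s in self.seed_alignment]


@dataclass(frozen=True)
class MarkerDataset:
    """A named lineage set of marker families with cutoffs and metadata."""

    name: str
    domain: str
    markers: tuple[MarkerFamily, ...]
    genetic_codes: tuple[int, ...] = ()
    parent: Optional[str] = None
    creation_meta: str = ""

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}; expected one of {DOMAINS}")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError(f"dataset {self.name}: duplicate marker_ids")
        if self.domain in CODED_DOMAINS and not self.genetic_codes:
            raise ValueError(
                f"dataset {self.name}: domain {self.domain} requires at least one genetic code"
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(m.marker_id for m in self.markers)

    def family(self, marker_id: str) -> MarkerFamily:
        for m in self.markers:
            if m.marker_id == marker_id:
                return m
        raise KeyError(marker_id)


@dataclass
class DatasetTree:
    """The dataset hierarchy: parent links from specific to general datasets.

    Roots are the datasets without a parent (at most one per domain); every
    other node names exactly one parent, and the parent graph is acyclic.
    """

    datasets: dict[str, MarkerDataset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        root_domains: dict[str, str] = {}
        for name, ds in self.datasets.items():
            if ds.name != name:
                raise ValueError(f"tree key {name!r} != dataset name {ds.name!r}")
            if ds.parent is None:
                if ds.domain in root_domains:
                    raise ValueError(
                        f"two roots for domain {ds.domain}: {root_domains[ds.domain]}, {name}"
                    )
                root_domains[ds.domain] = name
            elif ds.parent not in self.datasets:
                raise ValueError(f"dataset {name} names unknown parent {ds.parent!r}")
        # acyclicity: walk every parent chain; it must terminate at a root
        for name in self.datasets:
            seen = set()
            node: Optional[str] = name
            while node is not None:
                if node in seen:
                    raise ValueError(f"cycle in dataset tree through {node!r}")
                seen.add(node)
                node = self.datasets[node].parent

    @property
    def roots(self) -> tuple[MarkerDataset, ...]:
        return tuple(ds for ds in self.datasets.values() if ds.parent is None)

    def root_for_domain(self, domain: str) -> MarkerDataset:
        for ds in self.roots:
            if ds.domain == domain:
                return ds
        raise KeyError(f"no root dataset for domain {domain!r}")

    def children(self, name: str) -> tuple[MarkerDataset, ...]:
        return tuple(ds for ds in self.datasets.values() if ds.parent == name)

    def path_to_root(self, name: str) -> tuple[str, ...]:
        """Names from ``name`` up to (and including) its root."""
        path = [name]
        while self.datasets[path[-1]].parent is not None:
            path.append(self.datasets[path[-1]].parent)  # type: ignore[arg-type]
        return tuple(path)

    def is_ancestor(self, ancestor: str, name: str) -> bool:
        """True when ``ancestor`` lies on the path from ``name`` to its root
        (a dataset is considered an ancestor of itself)."""
        return ancestor in self.path_to_root(name)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

CONFIG_NAME = "dataset.cfg"
SCORES_NAME = "scores_cutoff.tsv"
LENGTHS_NAME = "lengths_cutoff.tsv"
SEEDS_DIR = "seeds"


def _parse_cfg(path: Path) -> dict[str, str]:
    cfg: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise DatasetFormatError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        cfg[key.strip()] = value.strip()
    return cfg


def _parse_table(path: Path, n_values: int) -> dict[str, tuple[float, ...]]:
    table: dict[str, tuple[float, ...]] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 1 + n_values:
            raise DatasetFormatError(
                f"{path}:{lineno}: expected {1 + n_values} tab-separated fields, got {len(parts)}"
            )
        try:
            values = tuple(float(v) for v in parts[1:])
        except ValueError as exc:
            raise DatasetFormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
        if parts[0] in table:
            raise DatasetFormatError(f"{path}:{lineno}: duplicate marker {parts[0]!r}")
        table[parts[0]] = values
    return table


def load_dataset(path: str | os.PathLike) -> MarkerDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises :class:`DatasetFormatError` for malformed files and
    :class:`DatasetConsistencyError` when a listed marker lacks its cutoff row
    or seed file.
    """
    root = Path(path)
    cfg_path = root / CONFIG_NAME
    if not cfg_path.is_file():
        raise DatasetFormatError(f"{cfg_path}: missing config file")
    cfg = _parse_cfg(cfg_path)
    for key in ("name", "domain", "n"):
        if key not in cfg:
            raise DatasetFormatError(f"{cfg_path}: missing required key {key!r}")
    scores = _parse_table(root / SCORES_NAME, 1)
    lengths = _parse_table(root / LENGTHS_NAME, 2)
    if set(scores) != set(lengths):
        only = set(scores).symmetric_difference(lengths)
        raise DatasetConsistencyError(
            f"{root}: score and length tables disagree on markers: {sorted(only)}"
        )
    markers = []
    for marker_id in scores:  # score-table row order defines marker order
        seed_path = root / SEEDS_DIR / f"{marker_id}.faa"
        if not seed_path.is_file():
            raise DatasetConsistencyError(f"{root}: marker {marker_id} listed without seed file")
        seeds = tuple(str(rec.seq) for rec in SeqIO.parse(str(seed_path), "fasta"))
        if not seeds:
            raise DatasetConsistencyError(f"{seed_path}: empty seed alignment")
        markers.append(
            MarkerFamily(
                marker_id=marker_id,
                seed_alignment=seeds,
                score_cutoff=scores[marker_id][0],
                length_mean=lengths[marker_id][0],
                length_sigma=lengths[marker_id][1],
            )
        )
    try:
        n_declared = int(cfg["n"])
    except ValueError as exc:
        raise DatasetFormatError(f"{cfg_path}: n must be an integer") from exc
    if n_declared != len(markers):
        raise DatasetConsistencyError(
            f"{root}: config declares n={n_declared} but {len(markers)} markers found"
        )
    codes = tuple(int(c) for c in cfg.get("codes", "").split(",") if c.strip())
    return MarkerDataset(
        name=cfg["name"],
        domain=cfg["domain"],
        markers=tuple(markers),
        genetic_codes=codes,
        parent=cfg.get("parent") or None,
        creation_meta=cfg.get("meta", ""),
    )


def write_dataset(ds: MarkerDataset, path: str | os.PathLike) -> Path:
    """Write ``ds`` to a dataset directory.

    The output is byte-stable: fixed key order in the config, markers in
    dataset order, floats formatted to two decimals.  Refuses to write a
    dataset with zero markers.
    """
    if ds.n_markers == 0:
        raise ValueError(f"refusing to write empty dataset {ds.name!r}")
    root = Path(path)
    (root / SEEDS_DIR).mkdir(parents=True, exist_ok=True)
    cfg_lines = [f"name={ds.name}", f"domain={ds.domain}"]
    if ds.genetic_codes:
        cfg_lines.append("codes=" + ",".join(str(c) for c in ds.genetic_codes))
    if ds.parent:
        cfg_lines.append(f"parent={ds.parent}")
    if ds.creation_meta:
        cfg_lines.append(f"meta={ds.creation_meta}")
    cfg_lines.append(f"n={ds.n_markers}")
    (root / CONFIG_NAME).write_text("\n".join(cfg_lines) + "\n")
    (root / SCORES_NAME).write_text(
        "".join(f"{m.marker_id}\t{m.score_cutoff:.2f}\n" for m in ds.markers)
    )
    (root / LENGTHS_NAME).write_text(
        "".join(
            f"{m.marker_id}\t{m.length_mean:.2f}\t{m.length_sigma:.2f}\n" for m in ds.markers
        )
    )
    for m in ds.markers:
        records = [
            SeqRecord(Seq(s), id=f"{m.marker_id}_{i}", description="")
            for i, s in enumerate(m.seed_alignment)
        ]
        SeqIO.write(records, str(root / SEEDS_DIR / f"{m.marker_id}.faa"), "fasta")
    return root


def load_dataset_tree(path: str | os.PathLike) -> DatasetTree:
    """Assemble a :class:`DatasetTree` from a directory of dataset directories."""
    root = Path(path)
    datasets = {}
    for entry in sorted(root.iterdir()):
        if entry.is_dir() and (entry / CONFIG_NAME).is_file():
            ds = load_dataset(entry)
            datasets[ds.name] = ds
    if not datasets:
        raise DatasetFormatError(f"{root}: no dataset directories found")
    return DatasetTree(datasets)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

CUTOFF_FRACTION = 0.9  # score cutoff as a fraction of the minimum seed self-score


def _length_stats(seeds: Sequence[str]) -> tuple[float, float]:
    lengths = [len(s.replace("-", "")) for s in seeds]
    mean = sum(lengths) / len(lengths)
    var = sum((x - mean) ** 2 for x in lengths) / len(lengths)
    return mean, math.sqrt(var)


def build_dataset(
    orthology_table: Mapping[str, Mapping[str, int]],
    alignments: Mapping[str, Sequence[str]],
    single_copy_threshold: float = 0.9,
    *,
    name: str,
    domain: str,
    genetic_codes: Iterable[int] = (),
    parent: Optional[str] = None,
    creation_meta: str = "",
) -> MarkerDataset:
    """Construct a marker dataset from per-species orthogroup copy numbers.

    An orthogroup is retained as a marker when it is present in exactly one
    copy in at least ``single_copy_threshold`` of the species covered by the
    orthology table.  Each retained family's score cutoff is calibrated to
    ``0.9 x`` the minimum self-score of its seed members against the family
    profile, and the length band from the ungapped seed lengths.

    Parameters
    ----------
    orthology_table:
        ``orthogroup -> species -> copy number``.  Must cover >= 2 species.
    alignments:
        ``orthogroup -> aligned seed sequences`` for every orthogroup in the
        table (gap character '-').
    """
    from .profile import build_profile, score_sequence  # deferred: avoids an import cycle

    if not 0 < single_copy_threshold <= 1:
        raise ValueError("single_copy_threshold must be in (0, 1]")
    species = sorted({sp for row in orthology_table.values() for sp in row})
    if len(species) < 2:
        raise ValueError("orthology table must cover at least 2 species")
    markers = []
    for og in orthology_table:
        counts = orthology_table[og]
        single = sum(1 for sp in species if counts.get(sp, 0) == 1)
        if single / len(species) < single_copy_threshold:
            continue
        seeds = tuple(alignments[og])
        mean, sigma = _length_stats(seeds)
        # provisional family (placeholder cutoff) to build the scoring profile
        provisional = MarkerFamily(og, seeds, score_cutoff=1.0, length_mean=mean, length_sigma=sigma)
        prof = build_profile(provisional)
        self_scores = [
            score_sequence(prof, s).bit_score for s in provisional.ungapped_seeds()
        ]
        cutoff = CUTOFF_FRACTION * min(self_scores)
        if cutoff <= 0:
            raise ValueError(f"orthogroup {og}: non-positive calibrated cutoff")
        markers.append(replace(provisional, score_cutoff=cutoff))
    if not markers:
        raise ValueError("no orthogroup passes the single-copy threshold: empty dataset")
    return MarkerDataset(
        name=name,
        domain=domain,
        markers=tuple(markers),
        genetic_codes=tuple(genetic_codes),
        parent=parent,
        creation_meta=creation_meta,
    )
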