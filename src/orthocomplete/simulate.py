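"""Synthetic lineages: marker families evolved along a species tree, with
genomes, gene sets and GFF3 truth, so every pipeline stage is testable
without downloads.

The substitution model is deliberately minimal: ancestor proteins are drawn
i.i.d. from a background distribution, each site substitutes along a branch
of length t with probability 1 - exp(-t), and replacements are drawn from
the background excluding the current residue.  Proteins are reverse-
translated with uniformly chosen synonymous codons (then synonymously
re-encoded to scrub code-discriminating stop motifs from non-coding frames)
and placed on random strands, separated by intergenic spacers.  Spacers are
flanked by short stop-dense walls (TTAA repeats, stop codons in all six
frames) so that reading frames are insulated: each gene's ORF is exactly its
annotated span, which keeps ground truth exact.

There are no indels, no rate heterogeneity and no realistic codon usage;
passing tests on these fixtures demonstrates the engine's bookkeeping and
score semantics, not performance on real genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from Bio.Seq import Seq

from .datasets import DatasetTree, MarkerDataset, build_dataset
from .profile import AMINO_ACIDS

__all__ = [
    "LineageSpec",
    "GeneFeature",
    "FixtureBundle",
    "ContaminatedGenome",
    "simulate_lineage",
    "inject_duplications",
    "inject_contamination",
    "dataset_hierarchy",
]

WALL = "TTAATTAATTAA"  # TAA at offsets 1/5/9: stops in all six frames; palindromic
_DUP_SPACER = WALL + "CAGT" * 8 + WALL
_UNIVERSAL_STOPS = ("TAA", "TAG")  # stops under every candidate code used here

DEFAULT_TREE = "(sp1:0.05,sp2:0.05,sp3:0.05,sp4:0.05,sp5:0.05);"


@dataclass(frozen=True)
class LineageSpec:
    """Parameters of one simulated lineage (all randomness from ``seed``)."""

    tree: str = DEFAULT_TREE  # newick with branch lengths (subst./site)
    n_markers: int = 30
    marker_length_range: tuple[int, int] = (60, 120)  # amino acids
    marker_lengths: Optional[tuple[int, ...]] = None  # explicit override
    background_frequencies: Optional[tuple[float, ...]] = None  # len 20
    genetic_code: int = 11
    intergenic_length_range: tuple[int, int] = (60, 100)  # nt, walls included
    n_background_genes: int = 0  # non-marker genes per species
    genes_per_contig: Optional[int] = None  # None: single contig
    domain: str = "bacteria"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.marker_length_range[0] < 2 or self.intergenic_length_range[0] < 2 * len(WALL):
            raise ValueError("length ranges too small")
        if self.marker_lengths is not None and len(self.marker_lengths) != self.n_markers:
            raise ValueError("marker_lengths must have n_markers entries")

    def background(self) -> np.ndarray:
        if self.background_frequencies is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        bg = np.asarray(self.background_frequencies, dtype=float)
        if bg.shape != (len(AMINO_ACIDS),) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background_frequencies must be 20 values summing to 1")
        return bg


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene span (1-based inclusive, forward-strand coords)."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str


@dataclass(frozen=True)
class ContaminatedGenome:
    """A host assembly with appended contigs from a second organism."""

    genome: Mapping[str, str]
    host_species: str
    contaminant_species: str
    contaminant_contigs: tuple[str, ...]
    contaminant_genes: tuple[str, ...]


@dataclass
class FixtureBundle:
    """Everything a pipeline stage needs about one simulated lineage."""

    spec: LineageSpec
    species: tuple[str, ...]
    marker_ids: tuple[str, ...]
    marker_proteins: dict[str, dict[str, str]]  # marker -> species -> protein
    gene_sets: dict[str, dict[str, str]]  # species -> gene_id -> protein
    genomes: dict[str, dict[str, str]]  # species -> contig -> sequence
    annotations: dict[str, tuple[GeneFeature, ...]]  # species -> features
    truth: dict[str, dict[str, str]]  # species -> marker -> gene_id
    gene_cds: dict[str, dict[str, str]]  # species -> gene_id -> coding seq (+stop)

    def gff3(self, species: str) -> str:
        lines = ["##gff-version 3"]
        for f in self.annotations[species]:
            lines.append(
                f"{f.contig}\torthocomplete_sim\tgene\t{f.start}\t{f.end}\t."
                f"\t{f.strand}\t.\tID={f.gene_id}"
            )
        return "\n".join(lines) + "\n"

    def build_dataset(
        self,
        name: str,
        species: Optional[Sequence[str]] = None,
        domain: Optional[str] = None,
        genetic_codes: Optional[Sequence[int]] = None,
        parent: Optional[str] = None,
        single_copy_threshold: float = 0.9,
    ) -> MarkerDataset:
        """Derive a marker dataset from a subset of the simulated species.

        The orthology table is single-copy everywhere by construction; the
        seed "alignments" are the species proteins themselves (the model has
        no indels, so same-marker proteins share their length).
        """
        chosen = tuple(species) if species is not None else self.species
        table = {m: {sp: 1 for sp in chosen} for m in self.marker_ids}
        alignments = {
            m: [self.marker_proteins[m][sp] for sp in chosen] for m in self.marker_ids
        }
        domain = domain or self.spec.domain
        if genetic_codes is None:
            genetic_codes = (self.spec.genetic_code,) if domain != "eukaryota" else ()
        return build_dataset(
            table,
            alignments,
            single_copy_threshold,
            name=name,
            domain=domain,
            genetic_codes=genetic_codes,
            parent=parent,
            creation_meta=f"simulated seed={self.spec.seed}",
        )

    def write(self, path: str | Path) -> Path:
        """Materialise genome FASTA, gene-set FASTA and GFF3 per species."""
        root = Path(path)
        root.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            with open(root / f"{sp}_genome.fna", "w") as fh:
                for contig, seq in self.genomes[sp].items():
                    fh.write(f">{contig}\n{seq}\n")
            with open(root / f"{sp}_proteins.faa", "w") as fh:
                for gid, prot in self.gene_sets[sp].items():
                    fh.write(f">{gid}\n{prot}\n")
            (root / f"{sp}.gff3").write_text(self.gff3(sp))
        return root


def _mutate(protein: str, branch_length: float, bg: np.ndarray, rng: np.random.Generator) -> str:
    """Per-site substitution with probability 1 - exp(-t); replacement drawn
    from the background excluding the current residue.  Position 0 (the
    start methionine) is held fixed so genes keep a start codon."""
    if branch_length <= 0:
        return protein
    p = 1.0 - math.exp(-branch_length)
    chars = list(protein)
    for i in range(1, len(chars)):
        if rng.random() < p:
            current = AMINO_ACIDS.index(chars[i])
            weights = bg.copy()
            weights[current] = 0.0
            weights /= weights.sum()
            chars[i] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=weights)]
    return "".join(chars)


def _random_protein(length: int, bg: np.ndarray, rng: np.random.Generator) -> str:
    body = "".join(AMINO_ACIDS[i] for i in rng.choice(len(AMINO_ACIDS), size=length - 1, p=bg))
    return "M" + body


def _reverse_translate(
    protein: str, codons_by_aa: Mapping[str, list[str]], rng: np.random.Generator
) -> str:
    out = []
    for aa in protein:
        options = codons_by_aa[aa]
        out.append(options[rng.integers(len(options))])
    return "".join(_scrub_offframe_stops(out, protein, codons_by_aa))


def _violations(seq: str) -> list[int]:
    """Positions of TGA in a non-coding phase or TCA in any phase.

    These are the only motifs whose stop status differs between the nested
    candidate codes used here (TGA is a stop for table 11 but tryptophan for
    table 4; TCA is the reverse-strand mirror of TGA): any such motif outside
    the coding frame makes the set of called ORFs — and hence the coding
    density — depend on the candidate code for reasons unrelated to the
    gene's true code.  A coding-phase TGA (tryptophan under table 4) is the
    biological signal and is never touched.
    """
    out = []
    for p in range(len(seq) - 2):
        w = seq[p : p + 3]
        if w == "TCA" or (w == "TGA" and p % 3 != 0):
            out.append(p)
    return out


def _scrub_offframe_stops(
    codons: list[str], protein: str, codons_by_aa: Mapping[str, list[str]]
) -> list[str]:
    """Synonymously re-encode codons until non-coding frames carry no
    code-discriminating stop motif (where composition allows it)."""
    codons = list(codons)
    hopeless: set[int] = set()
    for _ in range(10 * len(codons) + 10):
        seq = "".join(codons)
        todo = [p for p in _violations(seq) if p not in hopeless]
        if not todo:
            break
        p = todo[0]
        i, j = p // 3, min((p + 2) // 3, len(codons) - 1)
        fixed = False
        for ci in codons_by_aa[protein[i]]:
            for cj in codons_by_aa[protein[j]] if j != i else [codons[j]]:
                trial = codons.copy()
                trial[i] = ci
                trial[j] = cj
                t = "".join(trial)
                lo, hi = max(0, 3 * i - 2), 3 * (j + 1)
                before = [q for q in _violations(seq) if lo <= q < hi]
                after = [q for q in _violations(t) if lo <= q < hi]
                if len(after) < len(before):
                    codons = trial
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            hopeless.add(p)  # e.g. a fixed ATG followed by an A-starting codon
    return codons


def _intergenic(length: int, rng: np.random.Generator) -> str:
    mid = "".join("ACGT"[i] for i in rng.integers(0, 4, size=max(0, length - 2 * len(WALL))))
    return WALL + mid + WALL


def _leaf_label(leaf: dendropy.Node) -> str:
    return leaf.taxon.label.replace(" ", "_")


def simulate_lineage(spec: LineageSpec) -> FixtureBundle:
    """Simulate marker evolution along the species tree and assemble per-
    species genomes with exact annotation.  Deterministic per seed."""
    from .genes import TranslationTable  # deferred import keeps modules acyclic

    rng = np.random.default_rng(spec.seed)
    bg = spec.background()
    tree = dendropy.Tree.get(data=spec.tree, schema="newick")
    leaves = [_leaf_label(leaf) for leaf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        raise ValueError("species tree has duplicate leaf labels")

    if spec.marker_lengths is not None:
        lengths = list(spec.marker_lengths)
    else:
        lo, hi = spec.marker_length_range
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_markers)]
    marker_ids = tuple(f"marker{i:04d}" for i in range(spec.n_markers))
    ancestors = [_random_protein(L, bg, rng) for L in lengths]

    # evolve the whole marker complement down the tree
    node_proteins: dict[int, list[str]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_proteins[id(node)] = list(ancestors)
        else:
            bl = node.edge.length or 0.0
            parent = node_proteins[id(node.parent_node)]
            node_proteins[id(node)] = [_mutate(p, bl, bg, rng) for p in parent]
    leaf_proteins = {
        _leaf_label(leaf): node_proteins[id(leaf)] for leaf in tree.leaf_node_iter()
    }

    table = TranslationTable.from_ncbi(spec.genetic_code)
    codons_by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.codon_map.items()):
        if aa != "*":
            codons_by_aa.setdefault(aa, []).append(codon)
    stops = sorted(set(_UNIVERSAL_STOPS) & table.stop_codons)

    marker_proteins: dict[str, dict[str, str]] = {m: {} for m in marker_ids}
    gene_sets: dict[str, dict[str, str]] = {}
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, tuple[GeneFeature, ...]] = {}
    truth: dict[str, dict[str, str]] = {}
    gene_cds: dict[str, dict[str, str]] = {}

    lo_i, hi_i = spec.intergenic_length_range
    for sp in leaves:
        genes: list[tuple[str, str]] = []  # (gene_id, protein)
        truth[sp] = {}
        for m, prot in zip(marker_ids, leaf_proteins[sp]):
            gid = f"{sp}|{m}"
            genes.append((gid, prot))
            marker_proteins[m][sp] = prot
            truth[sp][m] = gid
        for j in range(spec.n_background_genes):
            lo, hi = spec.marker_length_range
            genes.append(
                (f"{sp}|bg{j:03d}", _random_protein(int(rng.integers(lo, hi + 1)), bg, rng))
            )

        per_contig = spec.genes_per_contig or len(genes)
        contigs: dict[str, str] = {}
        features: list[GeneFeature] = []
        gene_sets[sp] = {}
        gene_cds[sp] = {}
        for c_idx in range(0, len(genes), per_contig):
            chunk = genes[c_idx : c_idx + per_contig]
            contig_id = f"{sp}_c{c_idx // per_contig + 1}"
            parts = [_intergenic(int(rng.integers(lo_i, hi_i + 1)), rng)]
            pos = len(parts[0])
            for gid, prot in chunk:
                cds = _reverse_translate(prot, codons_by_aa, rng) + stops[
                    rng.integers(len(stops))
                ]
                strand = "+" if rng.random() < 0.5 else "-"
                segment = cds if strand == "+" else str(Seq(cds).reverse_complement())
                start, end = pos + 1, pos + len(segment)
                parts.append(segment)
                pos = end
                spacer = _intergenic(int(rng.integers(lo_i, hi_i + 1)), rng)
                parts.append(spacer)
                pos += len(spacer)
                features.append(GeneFeature(contig_id, start, end, strand, gid))
                gene_sets[sp][gid] = prot
                gene_cds[sp][gid] = cds
            contigs[contig_id] = "".join(parts)
        genomes[sp] = contigs
        annotations[sp] = tuple(features)

    return FixtureBundle(
        spec=spec,
        species=tuple(leaves),
        marker_ids=marker_ids,
        marker_proteins=marker_proteins,
        gene_sets=gene_sets,
        genomes=genomes,
        annotations=annotations,
        truth=truth,
        gene_cds=gene_cds,
    )


def inject_duplications(
    bundle: FixtureBundle, species: str, marker_ids: Sequence[str]
) -> FixtureBundle:
    """Append an exact copy of each listed marker gene at a new genomic
    location (with a new annotation feature and gene-set entry)."""
    unknown = [m for m in marker_ids if m not in bundle.truth[species]]
    if unknown:
        raise ValueError(f"{species}: unknown markers {unknown}")
    genomes = {sp: dict(c) for sp, c in bundle.genomes.items()}
    gene_sets = {sp: dict(g) for sp, g in bundle.gene_sets.items()}
    gene_cds = {sp: dict(g) for sp, g in bundle.gene_cds.items()}
    features = list(bundle.annotations[species])
    contig_id = sorted(genomes[species])[-1]
    seq = genomes[species][contig_id]
    for m in marker_ids:
        gid = bundle.truth[species][m]
        cds = bundle.gene_cds[species][gid]
        dup_id = f"{gid}_dup"
        seq += _DUP_SPACER
        start = len(seq) + 1
        seq += cds
        features.append(GeneFeature(contig_id, start, start + len(cds) - 1, "+", dup_id))
        gene_sets[species][dup_id] = bundle.gene_sets[species][gid]
        gene_cds[species][dup_id] = cds
    genomes[species][contig_id] = seq
    annotations = dict(bundle.annotations)
    annotations[species] = tuple(features)
    return replace(
        bundle,
        genomes=genomes,
        gene_sets=gene_sets,
        gene_cds=gene_cds,
        annotations=annotations,
    )


def inject_contamination(
    bundle_a: FixtureBundle,
    bundle_b: FixtureBundle,
    fraction: float,
    species_a: Optional[str] = None,
    species_b: Optional[str] = None,
) -> ContaminatedGenome:
    """Append contigs from a second lineage totalling about ``fraction`` of
    the host assembly's length; the contaminant's annotation is preserved for
    truth-tracking."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    sp_a = species_a or bundle_a.species[0]
    sp_b = species_b or bundle_b.species[0]
    host = dict(bundle_a.genomes[sp_a])
    host_len = sum(len(s) for s in host.values())
    target = fraction * host_len
    added = 0
    taken: list[str] = []
    for contig, seq in bundle_b.genomes[sp_b].items():
        if added >= target:
            break
        host[f"contam|{contig}"] = seq
        taken.append(contig)
        added += len(seq)
    genes = tuple(
        f.gene_id for f in bundle_b.annotations[sp_b] if f.contig in set(taken)
    )
    return ContaminatedGenome(
        genome=host,
        host_species=sp_a,
        contaminant_species=sp_b,
        contaminant_contigs=tuple(taken),
        contaminant_genes=genes,
    )


def dataset_hierarchy(
    bundle: FixtureBundle,
    domain: Optional[str] = None,
    genetic_codes: Optional[Sequence[int]] = None,
    prefix: str = "clade",
    min_species: int = 2,
    exclude: Sequence[str] = (),
) -> tuple[DatasetTree, dict[str, str]]:
    """Build one marker dataset per internal clade of the species tree.

    Returns the dataset tree (root = all species) and, per species, the name
    of the most specific dataset containing it — the ground truth for
    lineage-selection benchmarks.  ``exclude`` drops species from all seed
    sets (held-out assessment).
    """
    tree = dendropy.Tree.get(data=bundle.spec.tree, schema="newick")
    excluded = set(exclude)
    datasets: dict[str, MarkerDataset] = {}
    truth: dict[str, str] = {}
    counter = 0
    order: list[tuple[dendropy.Node, str, Optional[str]]] = []
    names: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        members = [
            _leaf_label(leaf)
            for leaf in node.leaf_iter()
            if _leaf_label(leaf) not in excluded
        ]
        if len(members) < min_species:
            continue
        name = f"{prefix}_root" if node.parent_node is None else f"{prefix}{counter}"
        counter += 1
        names[id(node)] = name
        parent_name = None
        anc = node.parent_node
        while anc is not None and id(anc) not in names:
            anc = anc.parent_node
        if anc is not None:
            parent_name = names[id(anc)]
        order.append((node, name, parent_name))
    for node, name, parent_name in order:
        members = [
            _leaf_label(leaf)
            for leaf in node.leaf_iter()
            if _leaf_label(leaf) not in excluded
        ]
        datasets[name] = bundle.build_dataset(
            name,
            species=members,
            domain=domain,
            genetic_codes=genetic_codes,
            parent=parent_name,
        )
        for leaf in node.leaf_iter():
            truth[_leaf_label(leaf)] = name  # preorder: deeper nodes overwrite
    return DatasetTree(datasets), truth
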