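"""Status calls, score-string formatting, parasitic rescoring and the
cross-domain screen."""

from __future__ import annotations

import pytest

from orthocomplete.classify import (
    AssessmentResult,
    MarkerStatus,
    assess,
    classify_marker,
    cross_domain_screen,
    format_summary,
    parasitic_recalculate,
    percentage,
)
from orthocomplete.datasets import MarkerFamily
from orthocomplete.genes import SearchConfig
from orthocomplete.profile import AMINO_ACIDS, SearchHit
from orthocomplete.simulate import (
    LineageSpec,
    inject_contamination,
    inject_duplications,
    simulate_lineage,
)

FAM = MarkerFamily("m1", ("ACDEFGHIKL",) * 2, 50.0, 100.0, 5.0)


def hit(score=60.0, seq="s1", start=1, end=100, locus=None):
    return SearchHit("m1", seq, score, start, end, locus=locus)


class TestClassifyMarker:
    def test_boundary_score_and_length_is_complete_single(self):
        ms = classify_marker([hit(score=50.0, end=100)], FAM)
        assert ms.status == "complete_single"

    def test_two_loci_on_distinct_sequences_is_duplicated(self):
        ms = classify_marker([hit(seq="s1"), hit(seq="s2")], FAM)
        assert ms.status == "complete_duplicated"
        assert len(ms.loci) == 2

    def test_length_outside_two_sigma_is_fragmented(self):
        ms = classify_marker([hit(end=85)], FAM)  # |85 - 100| > 2*5
        assert ms.status == "fragmented"

    def test_below_cutoff_hits_are_ignored(self):
        ms = classify_marker([hit(score=49.9)], FAM)
        assert ms.status == "missing"
        assert ms.loci == ()

    def test_overlapping_hits_merge_into_one_locus(self):
        a = hit(score=70.0, start=1, end=100)
        b = hit(score=60.0, start=30, end=129)  # 71% of the shorter envelope
        ms = classify_marker([a, b], FAM)
        assert ms.status == "complete_single"
        assert ms.loci[0].bit_score == 70.0

    def test_sigma_zero_requires_exact_length(self):
        fam = MarkerFamily("m1", ("ACDEFGHIKL",) * 2, 50.0, 100.0, 0.0)
        assert classify_marker([hit(end=100)], fam).status == "complete_single"
        assert classify_marker([hit(end=99)], fam).status == "fragmented"

    def test_genomic_locus_coordinates_drive_merging(self):
        # same gene found through two overlapping ORFs on different frames
        a = hit(score=70.0, seq="orf1", locus=("contig", 1000, 1299))
        b = hit(score=60.0, seq="orf2", locus=("contig", 1003, 1302))
        assert classify_marker([a, b], FAM).status == "complete_single"

    def test_wrong_marker_hits_rejected(self):
        stray = SearchHit("other", "s", 60.0, 1, 100)
        with pytest.raises(ValueError):
            classify_marker([stray], FAM)


class TestFormatSummary:
    def build(self, S, D, F, M, mode="proteins"):
        per_marker = {}
        for i in range(S):
            per_marker[f"s{i}"] = MarkerStatus("complete_single", (hit(),))
        for i in range(D):
            per_marker[f"d{i}"] = MarkerStatus(
                "complete_duplicated", (hit(seq="a"), hit(seq="b"))
            )
        for i in range(F):
            per_marker[f"f{i}"] = MarkerStatus("fragmented", (hit(end=85),))
        for i in range(M):
            per_marker[f"m{i}"] = MarkerStatus("missing")
        return AssessmentResult("in", "ds", mode, mode, per_marker)

    def test_published_wheat_score_string(self):
        # the worked example: counts that round to the printed percentages
        result = self.build(S=470, D=4382, F=5, M=39)
        assert format_summary(result) == "C:99.1%[S:9.6%,D:89.5%],F:0.1%,M:0.8%,n:4896"

    def test_all_single(self):
        assert format_summary(self.build(12, 0, 0, 0)) == (
            "C:100.0%[S:100.0%,D:0.0%],F:0.0%,M:0.0%,n:12"
        )

    def test_all_missing(self):
        assert format_summary(self.build(0, 0, 0, 7)) == (
            "C:0.0%[S:0.0%,D:0.0%],F:0.0%,M:100.0%,n:7"
        )

    def test_rounding_is_half_up(self):
        assert percentage(1, 8) == 12.5
        assert percentage(1, 40) == 2.5
        assert percentage(5, 4896) == 0.1
        assert percentage(470, 4896) == 9.6

    def test_conservation_after_parasitic_recalculation(self):
        result = self.build(6, 0, 0, 4)
        trimmed = parasitic_recalculate(result, [f"m{i}" for i in range(4)])
        assert trimmed.n == 6
        assert trimmed.complete_pct == 100.0
        c = trimmed.counts
        assert sum(c.values()) == trimmed.n

    def test_parasitic_identity_and_single_removal(self):
        result = self.build(6, 0, 0, 4)
        assert parasitic_recalculate(result, []).per_marker == result.per_marker
        dropped = parasitic_recalculate(result, ["s0"])
        assert dropped.single == 5 and dropped.n == 9

    def test_parasitic_cannot_remove_everything(self):
        result = self.build(2, 0, 0, 0)
        with pytest.raises(ValueError):
            parasitic_recalculate(result, ["s0", "s1"])


class TestAssess:
    def test_full_genome_recovers_every_marker(self, zero_bundle, zero_dataset):
        sp = zero_bundle.species[4]
        res = assess(zero_bundle.genomes[sp], zero_dataset, mode="genome", input_id=sp)
        assert res.missing == 0
        assert res.single + res.duplicated == res.n
        assert res.genetic_code_used == 11

    def test_proteins_and_genome_modes_agree_on_clean_fixture(self, zero_bundle, zero_dataset):
        sp = zero_bundle.species[4]
        res_g = assess(zero_bundle.genomes[sp], zero_dataset, mode="genome")
        res_p = assess(zero_bundle.gene_sets[sp], zero_dataset, mode="proteins")
        assert {m: s.status for m, s in res_g.per_marker.items()} == {
            m: s.status for m, s in res_p.per_marker.items()
        }

    def test_transcriptome_mode_on_gene_transcripts(self, zero_bundle, zero_dataset):
        sp = zero_bundle.species[4]
        transcripts = dict(zero_bundle.gene_cds[sp])
        res = assess(transcripts, zero_dataset, mode="transcriptome")
        assert res.missing == 0
        assert res.workflow_label == "transcriptome_sixframe"

    def test_empty_input_is_error(self, zero_dataset):
        with pytest.raises(ValueError, match="empty input"):
            assess({}, zero_dataset, mode="proteins")

    def test_determinism(self, zero_bundle, zero_dataset):
        sp = zero_bundle.species[4]
        a = assess(zero_bundle.genomes[sp], zero_dataset, mode="genome")
        b = assess(zero_bundle.genomes[sp], zero_dataset, mode="genome")
        assert a == b

    def test_appending_random_sequences_never_loses_markers(self, zero_bundle,
                                                            zero_dataset, rng):
        sp = zero_bundle.species[4]
        base = assess(zero_bundle.gene_sets[sp], zero_dataset, mode="proteins")
        padded = dict(zero_bundle.gene_sets[sp])
        for i in range(10):
            padded[f"junk{i}"] = "".join(rng.choice(list(AMINO_ACIDS), size=90))
        after = assess(padded, zero_dataset, mode="proteins")
        for m, status in base.per_marker.items():
            if status.status == "complete_single":
                assert after.per_marker[m].status != "missing"

    def test_duplication_injection_counts_exactly(self, zero_bundle, zero_dataset):
        sp = zero_bundle.species[4]
        dup = inject_duplications(zero_bundle, sp, list(zero_bundle.marker_ids[:3]))
        res = assess(dup.genomes[sp], zero_dataset, mode="genome")
        assert res.duplicated == 3
        for m in zero_bundle.marker_ids[:3]:
            assert res.per_marker[m].status == "complete_duplicated"


@pytest.fixture(scope="module")
def roots():
    bact = simulate_lineage(LineageSpec(seed=31, n_markers=12, domain="bacteria"))
    arch = simulate_lineage(LineageSpec(seed=32, n_markers=12, domain="archaea"))
    euk = simulate_lineage(
        LineageSpec(seed=33, n_markers=12, domain="eukaryota", genetic_code=1,
                    genes_per_contig=3)
    )
    datasets = [
        b.build_dataset(f"{b.spec.domain}_root", species=b.species[:4])
        for b in (bact, arch, euk)
    ]
    return (bact, arch, euk), datasets


class TestCrossDomainScreen:
    def test_pure_genome_not_flagged(self, roots):
        (bact, _, _), datasets = roots
        report = cross_domain_screen(
            bact.genomes[bact.species[4]], datasets, mode="genome"
        )
        assert report.best_domain == "bacteria"
        assert report.flags == ()
        assert report.completeness["bacteria"] > report.completeness["eukaryota"]

    def test_mixture_flags_off_domain_root(self, roots):
        (bact, _, euk), datasets = roots
        mixed = inject_contamination(bact, euk, 0.5,
                                     species_a=bact.species[4], species_b=euk.species[4])
        report = cross_domain_screen(dict(mixed.genome), datasets, mode="genome")
        assert report.best_domain == "bacteria"
        assert "eukaryota" in report.flags

    def test_screen_is_deterministic(self, roots):
        (bact, _, _), datasets = roots
        g = bact.genomes[bact.species[4]]
        a = cross_domain_screen(g, datasets, mode="genome")
        b = cross_domain_screen(g, datasets, mode="genome")
        assert a.completeness == b.completeness and a.flags == b.flags
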