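"""GO over-representation and promoter extraction."""

import math

import pytest

from genexpand.enrichment import (
    GOAnnotation,
    extract_promoters,
    go_enrichment,
    hypergeom_tail,
    load_go_annotation,
    propagate_annotations,
    read_gene2terms,
    write_promoter_fasta,
)
from genexpand.model import DataFormatError


def brute_tail(k, M, K, n):
    """Independent oracle: explicit hypergeometric sum P(X >= k)."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
    return min(total, 1.0)


class TestPropagation:
    def test_true_path_rule(self):
        ann = GOAnnotation(
            gene2terms={"g": {"child"}},
            term_parents={"child": {"parent"}, "parent": set()},
        )
        prop = propagate_annotations(ann)
        assert prop.gene2terms["g"] == {"child", "parent"}

    def test_idempotent(self):
        ann = GOAnnotation(
            gene2terms={"g": {"a"}},
            term_parents={"a": {"b"}, "b": {"c"}, "c": set()},
        )
        once = propagate_annotations(ann)
        twice = propagate_annotations(once)
        assert once.gene2terms == twice.gene2terms

    def test_diamond_counted_once(self):
        # a -> b, a -> c, b -> d, c -> d: ancestor d appears once (set semantics)
        ann = GOAnnotation(
            gene2terms={"g": {"a"}},
            term_parents={"a": {"b", "c"}, "b": {"d"}, "c": {"d"}, "d": set()},
        )
        prop = propagate_annotations(ann)
        assert prop.gene2terms["g"] == {"a", "b", "c", "d"}

    def test_cycle_detected(self):
        ann = GOAnnotation(
            gene2terms={"g": {"a"}},
            term_parents={"a": {"b"}, "b": {"a"}},
        )
        with pytest.raises(DataFormatError, match="cycle"):
            propagate_annotations(ann)


def flat_annotation(mapping):
    terms = {t for ts in mapping.values() for t in ts}
    return GOAnnotation(
        gene2terms={g: set(ts) for g, ts in mapping.items()},
        term_parents={t: set() for t in terms},
        term_names={t: (t, "BP") for t in terms},
        propagated=True,
    )


class TestEnrichment:
    def test_study_equals_population_all_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        ann = flat_annotation({g: {"T1"} if i < 7 else {"T2"} for i, g in enumerate(genes)})
        table = go_enrichment(genes, genes, ann)
        assert (table["p_value"] == 1.0).all()

    def test_tail_matches_brute_force_example(self):
        # study 10 with 5 in term; population 100 with 10 in term
        genes = [f"g{i}" for i in range(100)]
        in_term = set(genes[:5]) | set(genes[10:15])
        study = genes[:10]
        ann = flat_annotation({g: {"T"} for g in in_term})
        table = go_enrichment(study, genes, ann)
        row = table.set_index("term").loc["T"]
        assert row["study_count"] == 5 and row["pop_count"] == 10
        assert row["p_value"] == pytest.approx(brute_tail(5, 100, 10, 10), rel=1e-12)
        assert row["expected"] == pytest.approx(10 * 10 / 100)

    def test_term_without_study_genes_excluded(self):
        genes = [f"g{i}" for i in range(10)]
        ann = flat_annotation({genes[0]: {"A"}, genes[9]: {"B"}})
        table = go_enrichment(genes[:5], genes, ann)
        assert set(table["term"]) == {"A"}

    def test_study_outside_population_rejected(self):
        ann = flat_annotation({"a": {"T"}})
        with pytest.raises(ValueError, match="absent"):
            go_enrichment(["a", "zzz"], ["a", "b"], ann)

    def test_relabeling_invariance(self):
        genes = [f"g{i}" for i in range(30)]
        mapping = {g: {"T"} for g in genes[:8]}
        t1 = go_enrichment(genes[:10], genes, flat_annotation(mapping))
        relabel = {g: f"x_{g}" for g in genes}
        t2 = go_enrichment(
            [relabel[g] for g in genes[:10]],
            [relabel[g] for g in genes],
            flat_annotation({relabel[g]: ts for g, ts in mapping.items()}),
        )
        assert list(t1["p_value"]) == list(t2["p_value"])

    def test_bh_preserves_p_ordering(self):
        genes = [f"g{i}" for i in range(40)]
        mapping = {}
        for i, g in enumerate(genes):
            terms = set()
            if i < 12:
                terms.add("A")
            if i % 3 == 0:
                terms.add("B")
            if i % 2 == 0:
                terms.add("C")
            if terms:
                mapping[g] = terms
        table = go_enrichment(genes[:15], genes, flat_annotation(mapping))
        p = list(table["p_value"])
        q = list(table["p_adjusted"])
        assert p == sorted(p)
        assert all(b >= a - 1e-15 for a, b in zip(q, q[1:]))

    def test_namespace_filter(self):
        ann = GOAnnotation(
            gene2terms={"a": {"T_bp", "T_mf"}, "b": {"T_bp"}},
            term_parents={"T_bp": set(), "T_mf": set()},
            term_names={"T_bp": ("x", "BP"), "T_mf": ("y", "MF")},
            propagated=True,
        )
        table = go_enrichment(["a"], ["a", "b"], ann, namespace="MF")
        assert set(table["term"]) == {"T_mf"}

    @pytest.mark.parametrize("M", [8, 17, 30])
    def test_tail_function_against_enumeration(self, M):
        for n in range(1, M + 1, 5):
            for K in range(0, M + 1, 4):
                for k in range(0, min(n, K) + 1):
                    assert hypergeom_tail(k, M, K, n) == pytest.approx(
                        brute_tail(k, M, K, n), rel=1e-10, abs=1e-14
                    )


GENOME = {
    "chr1": "acgt" * 1500,  # 6000 bp, lowercase to check case preservation
    "chr2": "ACGTTGCA" * 100,  # 800 bp
}


@pytest.fixture()
def genome_files(tmp_path):
    fa = tmp_path / "genome.fa"
    with fa.open("w") as fh:
        for name, seq in GENOME.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    gff = tmp_path / "ann.gff3"
    rows = [
        # seqid, source, type, start, end, score, strand, phase, attrs
        ("chr1", ".", "gene", "5001", "5500", ".", "+", ".", "ID=geneA"),
        ("chr1", ".", "gene", "4500", "5000", ".", "-", ".", "ID=geneB"),
        ("chr1", ".", "gene", "500", "900", ".", "+", ".", "ID=geneC"),
        ("chr2", ".", "gene", "100", "700", ".", "-", ".", "ID=geneD"),
    ]
    gff.write_text("##gff-version 3\n" + "\n".join("\t".join(r) for r in rows) + "\n")
    return fa, gff


class TestPromoters:
    def test_plus_strand_upstream_kb(self, genome_files):
        fa, gff = genome_files
        ((gene, seq),) = extract_promoters(fa, gff, ["geneA"], length=1000)
        assert gene == "geneA"
        assert seq == GENOME["chr1"][4000:5000]  # 1-based 4001..5000

    def test_minus_strand_reverse_complement(self, genome_files):
        from Bio.Seq import Seq

        fa, gff = genome_files
        ((_, seq),) = extract_promoters(fa, gff, ["geneB"], length=1000)
        assert seq == str(Seq(GENOME["chr1"][5000:6000]).reverse_complement())

    def test_clipped_at_chromosome_start(self, genome_files):
        fa, gff = genome_files
        ((_, seq),) = extract_promoters(fa, gff, ["geneC"], length=1000)
        assert seq == GENOME["chr1"][0:499]  # bases 1..499 only
        assert len(seq) == 499

    def test_clipped_at_chromosome_end_minus_strand(self, genome_files):
        from Bio.Seq import Seq

        fa, gff = genome_files
        ((_, seq),) = extract_promoters(fa, gff, ["geneD"], length=1000)
        assert seq == str(Seq(GENOME["chr2"][700:800]).reverse_complement())

    def test_case_preserved(self, genome_files):
        fa, gff = genome_files
        ((_, seq),) = extract_promoters(fa, gff, ["geneA"], length=100)
        assert seq == seq.lower()

    def test_missing_gene_listed(self, genome_files):
        fa, gff = genome_files
        with pytest.raises(ValueError, match="ghost"):
            extract_promoters(fa, gff, ["geneA", "ghost"])

    def test_fasta_round_trip_bytes(self, genome_files, tmp_path):
        from Bio import SeqIO

        fa, gff = genome_files
        proms = extract_promoters(fa, gff, ["geneA", "geneB", "geneC"])
        p1, p2 = tmp_path / "p1.fa", tmp_path / "p2.fa"
        write_promoter_fasta(proms, p1)
        back = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(p1), "fasta")]
        assert back == proms
        write_promoter_fasta(back, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestGoFiles:
    def test_read_gene2terms(self, tmp_path):
        p = tmp_path / "g2t.tsv"
        p.write_text("# comment\ng1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
        assert read_gene2terms(p) == {"g1": {"GO:1", "GO:2"}, "g2": {"GO:1"}}

    def test_read_obo_parents_and_namespaces(self, tmp_path):
        obo = tmp_path / "mini.obo"
        obo.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: GO:0000001\nname: root process\nnamespace: biological_process\n\n"
            "[Term]\nid: GO:0000002\nname: child process\nnamespace: biological_process\n"
            "is_a: GO:0000001 ! root process\n\n"
            "[Term]\nid: GO:0000003\nname: some function\nnamespace: molecular_function\n"
            "relationship: part_of GO:0000001 ! root\n"
        )
        g2t = tmp_path / "g2t.tsv"
        g2t.write_text("g1\tGO:0000002\ng2\tGO:0000003\n")
        ann = propagate_annotations(load_go_annotation(g2t, obo))
        assert ann.gene2terms["g1"] == {"GO:0000002", "GO:0000001"}
        assert ann.gene2terms["g2"] == {"GO:0000003", "GO:0000001"}
        assert ann.namespace_of("GO:0000002") == "BP"
        assert ann.namespace_of("GO:0000003") == "MF"
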