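"""Parsing, per-source policy filtering, identifier normalization and
multi-browser consensus aggregation."""

from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sterolnet.consensus import (
    ConfigurationError,
    SourceRecord,
    SourceRegistryEntry,
    aggregate_consensus,
    build_mapping,
    default_registry,
    normalize_identifiers,
    parse_source_table,
    filter_by_source_policy,
    summarize_retrieval,
)


class TestParsing:
    def test_tsv_line_maps_fields_directly(self, tmp_path):
        path = tmp_path / "hippie.tsv"
        path.write_text("hippie\tP04035\tP55072\t0.73\n")
        records, bad = parse_source_table(path, SourceRegistryEntry("hippie"))
        assert bad == 0
        (rec,) = records
        assert (rec.source_name, rec.id_a, rec.id_b) == ("hippie", "P04035", "P55072")
        assert rec.confidence == pytest.approx(0.73)
        assert rec.id_namespace == "uniprot_ac"

    def test_mitab_prefix_stripping(self, tmp_path):
        cols = ["uniprotkb:Q14534", "uniprotkb:P04035"] + ["-"] * 6 + [
            "pubmed:1|pubmed:2", "taxid:9606", "taxid:9606",
            'psi-mi:"MI:0915"(physical association)', "-", "-", "score:0.8",
        ]
        path = tmp_path / "mint.mitab"
        path.write_text("\t".join(cols) + "\n")
        records, _ = parse_source_table(
            path, SourceRegistryEntry("mint", dialect="mitab25")
        )
        (rec,) = records
        assert rec.id_a == "Q14534" and rec.id_namespace == "uniprot_ac"
        assert rec.evidence_type == "physical association"
        assert rec.publication_count == 2
        assert rec.confidence == pytest.approx(0.8)

    def test_malformed_lines_counted_not_fatal(self, tmp_path):
        good = "src\tA\tB\t0.5\n"
        lines = [good] * 97 + ["broken line\n", "a\tb\n", "x\t\t\t\n"]
        path = tmp_path / "src.tsv"
        path.write_text("".join(lines))
        records, bad = parse_source_table(path, SourceRegistryEntry("src"))
        assert len(records) == 97
        assert bad == 3

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        records, bad = parse_source_table(path, SourceRegistryEntry("e"))
        assert records == [] and bad == 0

    def test_unknown_dialect_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            SourceRegistryEntry("x", dialect="xml")


class TestPolicyFilter:
    REG = default_registry()

    @pytest.mark.parametrize(
        "record,kept",
        [
            (SourceRecord("hippie", "A", "B", confidence=0.59), False),
            (SourceRecord("hippie", "A", "B", confidence=0.61), True),
            (SourceRecord("bioplex", "A", "B", confidence=0.95), True),
            (SourceRecord("bioplex", "A", "B", confidence=0.90), False),
            (SourceRecord("funcoup", "A", "B", confidence=0.91), True),
            (SourceRecord("corum", "A", "B", confidence=None), True),
            (SourceRecord("apid", "A", "B", publication_count=1), True),
            (SourceRecord("apid", "A", "B", publication_count=0), False),
            (SourceRecord("mentha", "A", "B", evidence_type="physical association"), True),
            (SourceRecord("mentha", "A", "B", evidence_type="genetic"), False),
        ],
    )
    def test_threshold_policies(self, record, kept):
        assert (filter_by_source_policy([record], self.REG) == [record]) is kept

    def test_unregistered_source_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_by_source_policy([SourceRecord("nope", "A", "B")], self.REG)


class TestNormalization:
    MAPPING = build_mapping(
        [("P04035", "HMGCR"), ("GSK3β", "GSK3B"), ("Q14534", "SQLE")]
    )

    def test_accession_and_greek_alias(self):
        records = [
            SourceRecord("s", "P04035", "Q14534"),
            SourceRecord("s", "GSK3β", "HMGCR"),
        ]
        normed, unmapped = normalize_identifiers(records, self.MAPPING)
        assert [(r.id_a, r.id_b) for r in normed] == [("HMGCR", "SQLE"), ("GSK3B", "HMGCR")]
        assert unmapped == []

    def test_orientation_symmetry(self):
        a = normalize_identifiers([SourceRecord("s", "P04035", "Q14534")], self.MAPPING)[0][0]
        b = normalize_identifiers([SourceRecord("s", "Q14534", "P04035")], self.MAPPING)[0][0]
        assert (a.id_a, a.id_b) == (b.id_a, b.id_b)

    def test_unmapped_excluded_and_reported(self):
        normed, unmapped = normalize_identifiers(
            [SourceRecord("s", "XXX", "P04035")], self.MAPPING
        )
        assert normed == [] and len(unmapped) == 1

    def test_conflicting_mapping_rows_rejected(self):
        with pytest.raises(ConfigurationError):
            build_mapping([("X", "A"), ("X", "B")])


def _brute_force(records, enzymes, min_sources):
    """Naive nested-loop counting oracle (independent of the implementation)."""
    counts = defaultdict(set)
    for enz in enzymes:
        for rec in records:
            if rec.id_a == enz and rec.id_b != enz:
                counts[(enz, rec.id_b)].add(rec.source_name)
            elif rec.id_b == enz and rec.id_a != enz:
                counts[(enz, rec.id_a)].add(rec.source_name)
    return {pair for pair, srcs in counts.items() if len(srcs) >= min_sources}


def _random_records(rng, n_records, n_sources=13):
    sources = [f"s{i}" for i in range(n_sources)]
    names = [f"E{i}" for i in range(5)] + [f"P{i}" for i in range(30)]
    recs = []
    for _ in range(n_records):
        a, b = rng.choice(names, size=2, replace=False)
        recs.append(SourceRecord(str(rng.choice(sources)), *sorted((a, b))))
    return recs, [f"E{i}" for i in range(5)]


class TestAggregation:
    def test_three_sources_kept(self):
        recs = [SourceRecord(s, "E", "P") for s in ("mentha", "iid", "hippie")]
        edges = aggregate_consensus(recs, ["E"], min_sources=3)
        assert len(edges) == 1 and edges[0].n_sources == 3

    def test_within_source_duplicates_count_once(self):
        recs = [SourceRecord("mentha", "E", "P"), SourceRecord("mentha", "E", "P")]
        assert aggregate_consensus(recs, ["E"], min_sources=2) == []

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            recs, enzymes = _random_records(rng, 200)
            got = {e.pair for e in aggregate_consensus(recs, enzymes, 3)}
            assert got == _brute_force(recs, enzymes, 3)

    def test_monotone_in_min_sources(self):
        rng = np.random.default_rng(2)
        recs, enzymes = _random_records(rng, 400)
        prev = None
        for k in range(1, 14):
            kept = {e.pair for e in aggregate_consensus(recs, enzymes, k)}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        recs, enzymes = _random_records(rng, 300)
        edges = aggregate_consensus(recs, enzymes, 2)
        rerun_records = [
            SourceRecord(src, e.enzyme, e.partner)
            for e in edges
            for src in e.supporting_sources
        ]
        rerun = aggregate_consensus(rerun_records, enzymes, 2)
        assert {(e.pair, e.supporting_sources) for e in rerun} == {
            (e.pair, e.supporting_sources) for e in edges
        }

    def test_self_interactions_dropped_by_default(self):
        recs = [SourceRecord(s, "E", "E") for s in ("a", "b", "c")]
        assert aggregate_consensus(recs, ["E"], 3) == []
        kept = aggregate_consensus(recs, ["E"], 3, keep_self=True)
        assert len(kept) == 1

    def test_enzyme_enzyme_edges_flagged(self):
        recs = [SourceRecord(s, "E1", "E2") for s in ("a", "b", "c")]
        (edge,) = aggregate_consensus(recs, ["E1", "E2"], 3)
        assert edge.is_enzyme_enzyme

    def test_empty_enzyme_list_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_consensus([], [], 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_property_pair_orientation_never_matters(self, seed):
        rng = np.random.default_rng(seed)
        recs, enzymes = _random_records(rng, 60)
        flipped = [SourceRecord(r.source_name, r.id_b, r.id_a) for r in recs]
        a = {e.pair for e in aggregate_consensus(recs, enzymes, 2)}
        b = {e.pair for e in aggregate_consensus(flipped, enzymes, 2)}
        assert a == b


class TestRetrievalSummary:
    def test_empty_records(self):
        counts, grand = summarize_retrieval([], ["E1"])
        assert counts == {"E1": 0} and grand == 0

    def test_hand_counted_fixture(self):
        recs = [SourceRecord("s", "E1", f"P{i}") for i in range(5)]
        recs += [SourceRecord("s", "E2", f"P{i}") for i in range(3)]
        counts, grand = summarize_retrieval(recs, ["E1", "E2"])
        assert counts == {"E1": 5, "E2": 3} and grand == 8

    def test_grand_total_equals_planted_union(self, small_config):
        from sterolnet.synthetic import gen_interactome_sources

        tables, truth = gen_interactome_sources(small_config)
        records = [r for recs in tables.values() for r in recs]
        _, grand = summarize_retrieval(records, small_config.enzymes)
        assert grand == len(set(truth.true_edges) | set(truth.noise_edges))
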