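import io
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from h2sguilds import FilterPolicy, ProfileHit, filter_hits, genes_present, parse_hmmer_table
from h2sguilds.errors import HmmerParseError

PAD = "0.1 1.0 1 1 0 1 1 1 1 -"  # trailing tblout bookkeeping columns


def tblout_line(phmm, query, e, score):
    return f"{phmm} - {query} - {e} {score} 0.1 {e} {score} {PAD}"


TBLOUT_FIXTURE = "\n".join([
    "# comment line",
    tblout_line("PH_mgl", "g1|p1", "1e-120", "350.0"),
    tblout_line("PH_dsrA", "g2|p9", "2.5e-150", "410.0"),
    tblout_line("PH_tnaA", "g1|p3", "1e-50", "80.0"),
]) + "\n"


def domtblout_line(phmm, query, i_evalue, score):
    return (
        f"{phmm} - 400 {query} - 380 1e-200 500.0 0.1 1 2 "
        f"1e-150 {i_evalue} {score} 0.1 1 380 1 380 1 380 0.98 -"
    )


class TestParseTblout:
    def test_three_rows_map_evalue_and_score_columns(self):
        hits = parse_hmmer_table(io.StringIO(TBLOUT_FIXTURE))
        assert [h.e_value for h in hits] == [1e-120, 2.5e-150, 1e-50]
        assert [h.bit_score for h in hits] == [350.0, 410.0, 80.0]
        assert [h.phmm_id for h in hits] == ["PH_mgl", "PH_dsrA", "PH_tnaA"]

    def test_query_name_splits_into_genome_and_protein(self):
        hits = parse_hmmer_table(io.StringIO(TBLOUT_FIXTURE))
        assert (hits[0].genome_id, hits[0].protein_id) == ("g1", "p1")

    def test_explicit_genome_id_overrides_query_splitting(self):
        hits = parse_hmmer_table(
            io.StringIO(TBLOUT_FIXTURE), genome_id="G42"
        )
        assert {h.genome_id for h in hits} == {"G42"}
        assert hits[0].protein_id == "g1|p1"

    def test_comment_only_file_yields_no_hits(self):
        stream = io.StringIO("# one\n# two\n")
        assert parse_hmmer_table(stream) == []

    def test_non_numeric_evalue_reports_line_number(self):
        text = tblout_line("P", "g|p", "1e-120", "10") + "\n" + \
            tblout_line("P", "g|q", "oops", "10") + "\n"
        with pytest.raises(HmmerParseError, match="line 2"):
            parse_hmmer_table(io.StringIO(text))

    def test_short_row_reports_line_number(self):
        with pytest.raises(HmmerParseError, match="line 1"):
            parse_hmmer_table(io.StringIO("only three fields\n"))

    def test_unknown_dialect_rejected(self):
        with pytest.raises(ValueError, match="dialect"):
            parse_hmmer_table(io.StringIO(""), dialect="csv")


class TestParseDomtblout:
    def test_best_domain_per_protein_profile_pair(self):
        text = "\n".join([
            domtblout_line("P1", "g|p1", "1e-120", "300.0"),
            domtblout_line("P1", "g|p1", "1e-140", "350.0"),
            domtblout_line("P1", "g|p2", "1e-115", "280.0"),
        ]) + "\n"
        hits = parse_hmmer_table(io.StringIO(text), dialect="domtblout")
        assert len(hits) == 2
        assert hits[0].e_value == 1e-140  # best domain wins
        assert hits[1].protein_id == "p2"

    def test_evalue_tie_broken_by_higher_score(self):
        text = "\n".join([
            domtblout_line("P1", "g|p1", "1e-120", "300.0"),
            domtblout_line("P1", "g|p1", "1e-120", "360.0"),
        ]) + "\n"
        (hit,) = parse_hmmer_table(io.StringIO(text), dialect="domtblout")
        assert hit.bit_score == 360.0


class TestFilterHits:
    def _hit(self, phmm, e, score, genome="g1"):
        return ProfileHit(genome_id=genome, protein_id="p", phmm_id=phmm,
                          e_value=e, bit_score=score)

    def test_good_tigrfam_hit_retained(self, catalog):
        kept = filter_hits([self._hit("PH_dcyD", 1e-120, 500.0)], catalog)
        assert len(kept) == 1
        assert kept[0].gene_symbol == "dcyD"

    def test_evalue_cutoff_is_strict(self, catalog):
        at_boundary = self._hit("PH_yhaM", 1e-110, 500.0)
        below = self._hit("PH_yhaM", 0.99e-110, 500.0)
        assert filter_hits([at_boundary], catalog) == []
        assert len(filter_hits([below], catalog)) == 1

    def test_tigrfam_bit_floor_is_non_strict(self, catalog):
        floor = catalog.entry("dcyD").bit_score_min
        at_floor = self._hit("PH_dcyD", 1e-120, floor)
        under = self._hit("PH_dcyD", 1e-120, floor - 0.5)
        assert len(filter_hits([at_floor], catalog)) == 1
        assert filter_hits([under], catalog) == []

    def test_custom_and_hamap_profiles_exempt_from_bit_floor(self, catalog):
        low_scores = [
            self._hit("PH_yhaM", 1e-115, 1.0),  # custom
            self._hit("PH_sseA", 1e-115, 1.0),  # HAMAP
        ]
        assert len(filter_hits(low_scores, catalog)) == 2

    def test_unresolvable_phmm_dropped_without_raising(self, catalog, caplog):
        hits = [self._hit("PH_unknown", 1e-120, 500.0),
                self._hit("PH_mgl", 1e-120, 500.0)]
        with caplog.at_level("WARNING"):
            kept = filter_hits(hits, catalog)
        assert [h.gene_symbol for h in kept] == ["mgl"]
        assert "1/2" in caplog.text

    def test_filtering_is_idempotent(self, catalog, rng):
        hits = [
            self._hit("PH_dcyD", 10.0 ** -rng.uniform(50, 200),
                      rng.uniform(0, 600))
            for _ in range(200)
        ]
        once = filter_hits(hits, catalog)
        assert filter_hits(once, catalog) == once

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        e_max=hst.floats(min_value=1e-180, max_value=1e-60),
        floor=hst.floats(min_value=0, max_value=600),
        data=hst.lists(
            hst.tuples(hst.floats(min_value=1e-200, max_value=1.0),
                       hst.floats(min_value=0, max_value=700)),
            max_size=60,
        ),
    )
    def test_tightening_thresholds_never_adds_hits(self, catalog, e_max,
                                                   floor, data):
        hits = [self._hit("PH_dcyD", e, s) for e, s in data]
        loose = filter_hits(hits, catalog, FilterPolicy(e_max=e_max))
        tighter_e = filter_hits(hits, catalog, FilterPolicy(e_max=e_max / 10))
        raised_floor = filter_hits(
            hits,
            catalog.with_overrides({"bit_score_min": {"dcyD": floor + 10}}),
            FilterPolicy(e_max=e_max),
        ) if floor is not None else loose
        assert len(tighter_e) <= len(loose)
        assert len(raised_floor) <= len(
            filter_hits(
                hits,
                catalog.with_overrides({"bit_score_min": {"dcyD": floor}}),
                FilterPolicy(e_max=e_max),
            )
        )


class TestGenesPresent:
    def _resolved(self, genome, gene):
        return ProfileHit(genome_id=genome, protein_id="p", phmm_id="P",
                          e_value=1e-120, bit_score=100.0, gene_symbol=gene)

    def test_deduplicates_repeated_genes(self):
        hits = [self._resolved("g1", "mgl"), self._resolved("g1", "mgl"),
                self._resolved("g2", "dsrA")]
        assert genes_present(hits) == {"g1": {"mgl"}, "g2": {"dsrA"}}

    def test_empty_hits_give_empty_mapping(self):
        assert genes_present([]) == {}

    def test_matches_brute_force_grouping_on_random_rows(self):
        rnd = random.Random(7)
        genomes = [f"g{i}" for i in range(30)]
        genes = ["mgl", "dcyD", "dsrA", "cysK", "tnaA"]
        hits = [
            self._resolved(rnd.choice(genomes), rnd.choice(genes))
            for _ in range(1000)
        ]
        expected = {}
        for h in hits:  # row-by-row oracle
            expected.setdefault(h.genome_id, set()).add(h.gene_symbol)
        assert genes_present(hits) == expected

    def test_unresolved_symbol_raises(self):
        hit = ProfileHit(genome_id="g", protein_id="p", phmm_id="P",
                         e_value=1e-120, bit_score=1.0)
        with pytest.raises(ValueError, match="filter_hits"):
            genes_present([hit])
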