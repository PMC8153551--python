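import pytest

from nomenmatch.matching import (
    classify_result,
    match_name,
    match_parsed_name,
    reparse_authority_check,
    species_level_candidates,
)
from nomenmatch.nameparse import parse_name
from nomenmatch.options import MatchOptions
from nomenmatch.textnorm import normalize_string
from nomenmatch.thesaurus import build_thesaurus


class TestMatchParsedName:
    def test_paper_typo_composes_to_91_82(self, small_thesaurus):
        parsed = parse_name("Achillea milefolius L.")
        candidates = match_parsed_name(parsed, small_thesaurus)
        top = candidates[0]
        assert small_thesaurus.entries[top.entry_id].full_name == "Achillea millefolium L."
        species = next(r for r in top.breakdown.components if r.component == "species")
        assert species.ed == 2
        expected = ((1.0 + (1 - 2 / 11)) / 2 * 0.9 + 1.0 * 0.1) * 100
        assert top.score == pytest.approx(expected, abs=1e-6)
        assert top.score == pytest.approx(91.82, abs=0.005)

    def test_identical_name_scores_100(self, small_thesaurus):
        parsed = parse_name("Achillea millefolium L.")
        candidates = match_parsed_name(parsed, small_thesaurus)
        assert candidates[0].score == pytest.approx(100.0)

    def test_unknown_genus_yields_no_candidates(self, small_thesaurus):
        parsed = parse_name("Xyzqwv abcus")
        assert match_parsed_name(parsed, small_thesaurus) == []

    def test_wrong_rank_indicator_costs_nine_points(self):
        thesaurus = build_thesaurus(
            [("Achillea millefolium L. subsp. millefolium", "accepted", "")]
        )
        parsed = parse_name("Achillea millefolium L. var. millefolium")
        top = match_parsed_name(parsed, thesaurus)[0]
        infra = next(r for r in top.breakdown.components if r.component == "infra1")
        assert infra.rank_penalty_applied
        assert infra.component_score == pytest.approx(0.7)
        assert top.score == pytest.approx(((1 + 1 + 0.7) / 3 * 0.9 + 0.1) * 100)

    def test_disabling_phonetics_never_adds_candidates(self, synthetic_thesaurus):
        names = [e.full_name for e in synthetic_thesaurus.entries.values()][:40]
        for name in names:
            parsed = parse_name(normalize_string(name))
            with_ph = {c.entry_id for c in match_parsed_name(parsed, synthetic_thesaurus)}
            without = {
                c.entry_id
                for c in match_parsed_name(
                    parsed, synthetic_thesaurus, MatchOptions(phonetic_enabled=False)
                )
            }
            assert without <= with_ph

    def test_phonetic_match_survives_large_edit_distance(self):
        # "sseelaagoo" keys to SILAGA like "selago" but sits at MDLD 4,
        # beyond the orthographic cap: only the phonetic test admits it
        thesaurus = build_thesaurus([("Bromus selago L.", "accepted", "")])
        parsed = parse_name("Bromus sseelaagoo L.")
        assert parsed.species_phonetic == "SILAGA"
        on = match_parsed_name(parsed, thesaurus, MatchOptions(threshold=50))
        off = match_parsed_name(parsed, thesaurus, MatchOptions(threshold=50, phonetic_enabled=False))
        assert len(on) == 1 and on[0].matched_via["species"] == "phonetic"
        assert off == []


class TestReparseAuthorityCheck:
    def test_filius_token_absorbed_into_authority(self, small_thesaurus):
        options = MatchOptions(force_case_insensitive=True)
        parsed = parse_name("SALIX ALBA L. F. KERN.", options)
        assert parsed.parse_flag == "ambiguous_rank_token"
        survivors = species_level_candidates(parsed, small_thesaurus, options)
        fixed = reparse_authority_check(parsed, survivors, small_thesaurus, options)
        assert fixed.infra == ()
        assert fixed.parse_flag == "clean"
        assert "f." in fixed.species_authority.casefold()

    def test_low_infraspecific_ed_means_no_change(self):
        # flagged, but the best match agrees at the infraspecific level
        thesaurus = build_thesaurus([("SALIX ALBA F. ALPINA", "accepted", "")])
        options = MatchOptions(force_case_insensitive=True)
        parsed = parse_name("SALIX ALBA F. ALPINA", options)
        assert parsed.parse_flag == "ambiguous_rank_token"
        survivors = species_level_candidates(parsed, thesaurus, options)
        assert reparse_authority_check(parsed, survivors, thesaurus, options) is parsed

    def test_token_absent_from_candidate_authorities_means_no_change(self):
        thesaurus = build_thesaurus([("Salix alba L.", "accepted", "")])
        options = MatchOptions(force_case_insensitive=True)
        parsed = parse_name("SALIX ALBA F. KERN.", options)
        assert parsed.parse_flag == "ambiguous_rank_token"
        survivors = species_level_candidates(parsed, thesaurus, options)
        assert reparse_authority_check(parsed, survivors, thesaurus, options) is parsed

    def test_full_pipeline_recovers_filius_name(self, small_thesaurus):
        options = MatchOptions(force_case_insensitive=True)
        result = match_name("SALIX ALBA L. F. KERN.", small_thesaurus, options)
        assert result.status in ("exact", "unambiguous")
        assert result.accepted_name == "Salix alba L. f. Kern."


class TestClassifyResult:
    def test_single_candidate_is_unambiguous(self, small_thesaurus):
        parsed = parse_name("Achillea milefolius L.")
        candidates = match_parsed_name(parsed, small_thesaurus)
        result = classify_result(candidates, "Achillea milefolius L.", small_thesaurus)
        assert result.status == "unambiguous"
        assert result.chosen == candidates[0].entry_id

    def test_exact_short_circuits(self, small_thesaurus):
        result = match_name("Achillea millefolium L.", small_thesaurus)
        assert result.status == "exact"
        assert result.candidates[0].score == 100.0
        assert result.accepted_name == "Achillea millefolium L."

    def test_synonym_hit_resolves_accepted(self, small_thesaurus):
        result = match_name("Achillea sudetica Opiz", small_thesaurus)
        assert result.synonym_name == "Achillea sudetica Opiz"
        assert result.accepted_name == "Achillea millefolium L."

    def test_close_scores_are_ambiguous(self):
        thesaurus = build_thesaurus(
            [("Aus bustamantus L.", "accepted", ""), ("Aus bustamintus L.", "accepted", "")]
        )
        result = match_name("Aus bustamentus L.", thesaurus)
        assert result.status == "ambiguous"
        assert len(result.candidates) == 2

    def test_zero_candidates_is_none(self, small_thesaurus):
        result = match_name("Xyzqwv abcus", small_thesaurus)
        assert result.status == "none"
        assert result.candidates == ()

    def test_every_reference_name_classifies_exact(self, synthetic_thesaurus):
        for entry in synthetic_thesaurus.entries.values():
            result = match_name(entry.full_name, synthetic_thesaurus)
            assert result.status == "exact", entry.full_name
            assert result.candidates[0].score == 100.0

    def test_threshold_100_rejects_fuzzy_matches(self, small_thesaurus):
        options = MatchOptions(threshold=100)
        assert match_name("Achillea milefolius L.", small_thesaurus, options).status == "none"
        assert match_name("Achillea millefolium L.", small_thesaurus, options).status == "exact"
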