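import pytest

from nomenmatch.nameparse import (
    ParseError,
    Rank,
    canonical_rank,
    parse_name,
    recapitalize,
    reparse_as_authority,
)
from nomenmatch.options import MatchOptions
from nomenmatch.synthdata import generate_checklist
from nomenmatch.textnorm import normalize_string


class TestCanonicalRank:
    @pytest.mark.parametrize(
        ("token", "rank"),
        [
            ("subsp.", Rank.SUBSPECIES),
            ("Subsp.", Rank.SUBSPECIES),
            ("susp", Rank.SUBSPECIES),
            ("subs.", Rank.SUBSPECIES),
            ("ssp", Rank.SUBSPECIES),
            ("var.", Rank.VARIETY),
            ("varietas", Rank.VARIETY),
            ("v.", Rank.VARIETY),
            ("f.", Rank.FORM),
            ("forma", Rank.FORM),
            ("cv.", Rank.CULTIVAR),
        ],
    )
    def test_aliases_and_typos(self, token, rank):
        assert canonical_rank(token) is rank

    @pytest.mark.parametrize("token", ["grandiflora", "L.", "s.", "c.", "ex", "(Opiz)"])
    def test_non_indicators(self, token):
        assert canonical_rank(token) is None

    def test_user_aliases_consulted_first(self):
        options = MatchOptions(rank_aliases={"subspecies": {"s"}})
        assert canonical_rank("s.", options) is Rank.SUBSPECIES

    def test_ambiguous_alias_distance_tie_warns_and_abstains(self):
        # "vat" is at distance 1 from both "var" (variety) and "cat"-free
        # tables; construct a genuine tie with custom aliases
        options = MatchOptions(rank_aliases={"subspecies": {"xxa"}, "variety": {"xxb"}})
        with pytest.warns(UserWarning):
            assert canonical_rank("xxc", options) is None


class TestParseName:
    def test_worked_trinomial(self):
        p = parse_name("Achillea millefolium L. subsp. sudetica (Opiz) Oborny")
        assert p.genus == "Achillea"
        assert p.species_epithet == "millefolium"
        assert p.species_authority == "L."
        assert len(p.infra) == 1
        part = p.infra[0]
        assert part.rank is Rank.SUBSPECIES
        assert part.epithet == "sudetica"
        assert part.authority == "(Opiz) Oborny"
        assert p.parse_flag == "clean"

    def test_phonetic_keys_attached(self):
        p = parse_name(normalize_string("Huperzia selago (L.) Bernh. ex Schrank & Mart. subsp. selago"))
        assert p.genus_phonetic == "HIPIRSA"
        assert p.species_phonetic == "SILAGA"
        assert p.infra[0].epithet_phonetic == "SILAGA"

    def test_uppercase_input_parses_case_insensitively(self):
        p = parse_name("ACHILLEA MILLEFOLIUM L.")
        assert p.case_insensitive
        assert (p.genus, p.species_epithet, p.species_authority) == ("Achillea", "millefolium", "L.")

    def test_forced_case_insensitive(self):
        p = parse_name("Achillea Millefolium L.", MatchOptions(force_case_insensitive=True))
        assert (p.genus, p.species_epithet) == ("Achillea", "millefolium")

    def test_capitalized_epithet_still_species(self):
        p = parse_name("Achillea Millefolium L.")
        assert p.species_epithet == "millefolium"

    def test_two_infraspecific_levels(self):
        p = parse_name("Genus species L. subsp. alpha var. beta")
        assert [part.rank for part in p.infra] == [Rank.SUBSPECIES, Rank.VARIETY]
        assert [part.epithet for part in p.infra] == ["alpha", "beta"]

    def test_filius_after_author_stays_in_authority(self):
        p = parse_name("Salix alba L. f. Kern.")
        assert p.infra == ()
        assert p.species_authority == "L. f. Kern."
        assert p.parse_flag == "clean"

    def test_form_after_epithet_is_rank_indicator(self):
        p = parse_name("Achillea millefolium f. alpina")
        assert p.parse_flag == "clean"
        assert p.infra[0].rank is Rank.FORM
        assert p.infra[0].epithet == "alpina"

    def test_conflicting_signals_raise_ambiguity_flag(self):
        # author token before "f.", epithet-shaped token after: undecidable
        p = parse_name("SALIX ALBA L. F. KERN.", MatchOptions(force_case_insensitive=True))
        assert p.parse_flag == "ambiguous_rank_token"
        assert p.ambiguous_token == "F."

    def test_s_token_ignored_unless_enabled(self):
        p = parse_name("Carex flava s. alpina")
        assert p.infra == ()
        assert "s." in p.species_authority
        p2 = parse_name("Carex flava s. alpina", MatchOptions(rank_aliases={"subspecies": {"s"}}))
        assert p2.infra and p2.infra[0].rank is Rank.SUBSPECIES

    def test_errors(self):
        with pytest.raises(ParseError):
            parse_name("")
        with pytest.raises(ParseError):
            parse_name("...")

    def test_deterministic_and_reparse_fixed_point(self):
        text = "Achillea millefolium L. subsp. sudetica (Opiz) Oborny"
        p1, p2 = parse_name(text), parse_name(text)
        assert p1 == p2
        again = parse_name(p1.reassemble())
        assert again.genus == p1.genus
        assert again.species_epithet == p1.species_epithet
        assert again.infra == p1.infra

    def test_reassembly_roundtrip_on_synthetic_names(self):
        _, rows = generate_checklist(60, synonym_fraction=0.2, infra_fraction=0.4, seed=9)
        for name, _, _ in rows:
            p = parse_name(normalize_string(name))
            assert p.reassemble() == name, name


class TestRecapitalize:
    def test_genus_and_epithet_repair(self):
        p = parse_name("aCHILLEA Millefolium L.", MatchOptions(force_case_insensitive=True))
        assert p.genus == "Achillea"
        assert p.species_epithet == "millefolium"

    def test_idempotent(self):
        p = parse_name("Achillea millefolium L. subsp. sudetica (Opiz) Oborny")
        assert recapitalize(p) == p

    def test_ci_authority_titlecased_with_small_words(self):
        p = parse_name("HUPERZIA SELAGO (L.) BERNH. EX SCHRANK & MART.")
        assert p.species_authority == "(L.) Bernh. ex Schrank & Mart."


def test_reparse_as_authority_moves_flagged_token():
    p = parse_name("SALIX ALBA L. F. KERN.", MatchOptions(force_case_insensitive=True))
    assert p.parse_flag == "ambiguous_rank_token"
    fixed = reparse_as_authority(p)
    assert fixed.parse_flag == "clean"
    assert fixed.infra == ()
    assert fixed.species_authority == "L. F. Kern."
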