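import pytest

from nomenmatch.options import MatchOptions
from nomenmatch.synthdata import generate_checklist
from nomenmatch.thesaurus import Thesaurus, build_thesaurus

#: Hand-picked reference rows exercising accepted/synonym structure,
#: parenthesized and filius-style authorities, and an infraspecific level.
SMALL_ROWS = [
    ("Achillea millefolium L.", "accepted", ""),
    ("Achillea millefolium L. subsp. sudetica (Opiz) Oborny", "accepted", ""),
    ("Huperzia selago (L.) Bernh. ex Schrank & Mart. subsp. selago", "accepted", ""),
    ("Calendula officinalis L.", "accepted", ""),
    ("Galega officinalis L.", "accepted", ""),
    ("Ailanthus altissima (Mill.) Swingle", "accepted", ""),
    ("Salix alba L. f. Kern.", "accepted", ""),
    ("Achillea sudetica Opiz", "synonym", "Achillea millefolium L."),
]


@pytest.fixture(scope="session")
def small_thesaurus() -> Thesaurus:
    return build_thesaurus(SMALL_ROWS)


@pytest.fixture(scope="session")
def synthetic_rows():
    manifest, rows = generate_checklist(200, synonym_fraction=0.3, infra_fraction=0.2, seed=42)
    return manifest, rows


@pytest.fixture(scope="session")
def synthetic_thesaurus(synthetic_rows) -> Thesaurus:
    _, rows = synthetic_rows
    return build_thesaurus(rows)


@pytest.fixture()
def default_options() -> MatchOptions:
    return MatchOptions()
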