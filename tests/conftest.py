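import pytest

from mediarec import GrowthDatabase, TaxonomyTree
from mediarec.recipes import default_compound_table
from mediarec.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def compounds():
    return default_compound_table()


@pytest.fixture(scope="session")
def eight_leaf_tree():
    """Balanced binary tree over a..h."""
    return TaxonomyTree.from_newick("(((a,b),(c,d)),((e,f),(g,h)));")


@pytest.fixture()
def chain_db():
    """Minimal database holding exactly the A-m1-B-m2-C-m3 chain pattern.

    Each medium is padded to three organisms so it passes the 3-organism
    floor; the pads have a single medium each.
    """
    db = GrowthDatabase(
        organisms=["A", "A2", "B", "C", "Q", "R", "S"],
        media=["m1", "m2", "m3"],
    )
    for org in ("A", "A2", "B"):
        db.add_pairing(org, "m1")
    for org in ("B", "C", "Q"):
        db.add_pairing(org, "m2")
    for org in ("C", "R", "S"):
        db.add_pairing(org, "m3")
    return db


@pytest.fixture(scope="session")
def s1_dataset():
    return generate(SynthConfig(signal=1.0, seed=11))


@pytest.fixture(scope="session")
def s0_dataset():
    return generate(SynthConfig(signal=0.0, seed=11))
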