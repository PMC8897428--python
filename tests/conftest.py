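import pytest

from retroae import chem, corpus, synth


@pytest.fixture(scope="session")
def diverse_smiles() -> list[str]:
    """Hand-picked molecules spanning aromatics, charges, rings, heteroatoms."""
    return [
        "c1ccccc1",            # benzene
        "CCO",                 # ethanol
        "C",                   # methane
        "CC(=O)OCC",           # ethyl acetate
        "O=C1CCCCO1",          # delta-valerolactone
        "Cc1ccc(cc1)C(=O)NC",  # N-methyl p-toluamide
        "[NH3+]CC([O-])=O",    # glycine zwitterion
        "C1CC1",               # cyclopropane
        "c1ccc2ccccc2c1",      # naphthalene
        "C#N",                 # hydrogen cyanide
        "CC(C)Cc1ccccc1",      # isobutylbenzene
        "COc1ccccc1",          # anisole
    ]


@pytest.fixture(scope="session")
def library_200():
    return synth.generate_library(200, seed=11)


@pytest.fixture(scope="session")
def library_vocab(library_200):
    return chem.build_vocabulary(library_200)


@pytest.fixture(scope="session")
def small_reaction_set():
    return synth.generate_dataset(120, seed=3)


@pytest.fixture(scope="session")
def small_curated(small_reaction_set):
    ds = corpus.curate(small_reaction_set.reactions)
    return corpus.split(ds, seed=3)
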