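"""Shared fixtures: synthetic benchmark sets and a small trained WLN.

Everything is generated programmatically with fixed seeds, so the suite
needs no data files and is fully reproducible.
"""

import numpy as np
import pytest
from rdkit import Chem

from ugtsom.substrate_models import EarlyStopPolicy, split_dataset
from ugtsom.som_wln import WLNConfig, train_wln
from ugtsom.synthetic import (GeneratorConfig, gen_reaction_set,
                              gen_substrate_set)

#: the worked reference reaction (3,5-dibromoanthranilic acid acyl
#: glucuronidation) in the balanced atom-mapped dialect
REFERENCE_SMIRKS = (
    "[O:1]=[C:2]([OH:3])[C:4]1=[CH:5][C:6]([Br:7])=[CH:8][C:9]([Br:10])="
    "[C:11]1[NH2:12].[O:13]=[C:14]([OH:15])[CH:16]1[O:17][CH*:18][CH:19]"
    "([OH:20])[CH:21]([OH:22])[CH:23]1[OH:24] >> [Br:7][C:6]1=[CH:8][C:9]"
    "([Br:10])=[C:11]([NH2:12])[C:4]([C:2]([O:3][CH:18]2[O:17][CH:16]"
    "([C:14]([OH:15])=[O:13])[CH:23]([CH:21]([CH:19]2[OH:20])[OH:22])"
    "[OH:24])=[O:1])=[CH:5]1"
)


@pytest.fixture(scope="session")
def reference_smirks():
    return REFERENCE_SMIRKS


@pytest.fixture(scope="session")
def reaction_set():
    """120 multi-site reactions with planted SOMs."""
    return gen_reaction_set(
        GeneratorConfig(n_molecules=120, site_ambiguity="multi", seed=11))


@pytest.fixture(scope="session")
def single_site_reactions():
    return gen_reaction_set(
        GeneratorConfig(n_molecules=40, site_ambiguity="single", seed=13))


@pytest.fixture(scope="session")
def substrate_set():
    """300 molecules labeled by the planted ArOH-or-COOH rule, noise-free."""
    return gen_substrate_set(GeneratorConfig(n_molecules=300, seed=21))


@pytest.fixture(scope="session")
def trained_wln(reaction_set):
    """A small WLN trained on the shared reaction set (held-out split)."""
    train, test = split_dataset(
        reaction_set, (0.8, 0.2), seed=5,
        group_key=lambda r: Chem.MolToSmiles(r.substrate))
    config = WLNConfig(hidden_width=48, seed=3,
                       early_stop=EarlyStopPolicy(max_epochs=120,
                                                  monitor="top1"))
    model = train_wln(train, config)
    return model, train, test


@pytest.fixture
def rng():
    return np.random.default_rng(0)
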