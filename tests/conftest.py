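import pytest

import moldqn as m


#: Fixture molecules for enumeration-oracle checks: small, chemically varied
#: (chains, branches, rings, aromatics, heteroatoms, multiple bonds).
ENUMERATION_FIXTURES = [
    "",
    "C",
    "CC",
    "CCC",
    "CCCC",
    "CC(C)(C)C",        # neopentane: saturated quaternary center
    "C=C",
    "C#C",
    "CC#CC",            # 2-butyne
    "C1CCCCC1",         # cyclohexane
    "C1CCCC1",          # cyclopentane
    "c1ccccc1",         # benzene
    "Cc1ccccc1",        # toluene
    "OC1CCCCC1",        # cyclohexanol
    "CCO",
    "CC(=O)O",
    "CNC",
    "C1CCOC1",          # THF ring
    "N#CC",             # acetonitrile
    "C=CC=C",           # butadiene
]

#: Larger pool for descriptor-oracle agreement tests.
PROPERTY_FIXTURES = ENUMERATION_FIXTURES[1:] + [
    "CCCCCCCC",
    "CCCCCCCCCCCCCCCC",
    "CC(C)CC(C)(C)C",
    "C1=CC=CC=C1O",
    "CC(N)C(=O)O",
    "c1ccc2ccccc2c1",
    "CC(=O)Nc1ccc(O)cc1",     # paracetamol
    "CC(=O)Oc1ccccc1C(=O)O",  # aspirin
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",  # caffeine
    "C1CCC2CCCCC2C1",
    "OCC(O)C(O)C(O)C(O)CO",
    "CCOC(=O)C",
    "CSC",
    "ClCCCl",
    "FC(F)(F)c1ccccc1",
    "O=S(=O)(N)c1ccccc1",
    "CC1=CC(=O)C=CC1=O",
    "N#Cc1ccccc1",
    "OC(=O)CCC(=O)O",
    "C1=CC2=CC=CC=C2N1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",  # ibuprofen
    "CCN(CC)CC",
    "COc1ccccc1",
    "CC1CCCCC1N",
    "O=C1CCCCC1",
    "C1CC2CCC1CC2",
    "CCCCC=O",
    "CC(C)=CCCC(C)=CC=O",  # citral
    "Nc1ccccc1",
    "OCc1ccccc1",
]


@pytest.fixture(scope="session")
def single_property_config():
    """The single-property optimization environment (ring sizes 5-7)."""
    return m.MDPConfig(
        element_set=frozenset({"C", "O", "N"}),
        max_steps=40,
        allowed_ring_sizes=frozenset({5, 6, 7}),
    )


@pytest.fixture(scope="session")
def qed_spec():
    return m.RewardSpec(kind="single_property", property_names=("qed",),
                        gamma=0.9, horizon=40)


@pytest.fixture(scope="session")
def tiny_agent_config():
    """A small network/replay configuration for fast learner tests."""
    return m.AgentConfig(
        network=m.QNetworkSpec(hidden_sizes=(32, 16), num_heads=4),
        learning_rate=1e-3,
        replay_capacity=500,
        batch_size=8,
        target_sync_every=10,
        warmup_steps=10,
        mask_prob=0.5,
    )


@pytest.fixture(scope="session")
def random_walk_episodes(single_property_config):
    """Shared random-walk rollouts (penalized logP task, T=38, 3 seeds).

    Session-scoped because several tests measure different aspects of the
    same baseline runs (terminal scores, validity of every visited state).
    """
    config = m.MDPConfig(
        element_set=frozenset({"C", "O", "N"}),
        max_steps=38,
        allowed_ring_sizes=frozenset({5, 6, 7}),
    )
    spec = m.RewardSpec(kind="single_property",
                        property_names=("penalized_logp",),
                        gamma=0.9, horizon=38)
    runs = {}
    for seed in (0, 1, 2):
        runs[seed] = m.run_baseline("random", config, spec, 100, seed=seed,
                                    last_n=100, return_episodes=True)
    return runs
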