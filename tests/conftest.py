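import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def aa_params():
    from llpsmd.forcefield import default_params
    return default_params()


@pytest.fixture(scope="session")
def table(aa_params):
    """Interaction table over a representative residue subset plus uridine."""
    from llpsmd.forcefield import build_interaction_table
    codes = list("ARNDGKFYSU")
    return build_interaction_table([aa_params[c] for c in codes])


@pytest.fixture(scope="session")
def reference_proteins():
    from llpsmd.sequences import load_reference_proteins
    return load_reference_proteins()


@pytest.fixture(scope="session")
def toy_mixed_system(table):
    """Two short protein chains plus one poly-U strand in a roomy box."""
    from llpsmd.sequences import ProteinSequence, make_polyU
    from llpsmd.simulator import ChainTopology, SystemState

    seq = ProteinSequence("toy", "ARNDGKFY")
    topo = ChainTopology.from_sequences([(seq, 2), (make_polyU(4), 1)], table)
    rng = np.random.default_rng(12345)
    # compact random-walk chains (bond-length steps) so every pair distance
    # stays well under half the box and rigid motions are exactly invariant
    pos = []
    for (a, b) in topo.chain_slices:
        while True:
            chain = [rng.uniform(2.5, 5.5, 3)]
            for _ in range(a + 1, b):
                for _ in range(100):
                    u = rng.normal(size=3)
                    cand = chain[-1] + 0.4 * u / np.linalg.norm(u)
                    near = [p for p in pos + chain[:-1]
                            if np.linalg.norm(cand - p) < 0.45]
                    if not near:
                        break
                chain.append(cand)
            if len(chain) == b - a:
                break
        pos.extend(chain)
    pos = np.array(pos)
    state = SystemState(pos, np.zeros_like(pos), np.array([8.0, 8.0, 8.0]))
    return topo, state
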