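import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hokc():
    from memtol.synthetic_data import hokc_reference

    return hokc_reference()


@pytest.fixture(scope="session")
def helix20():
    from memtol.synthetic_data import make_ideal_helix

    return make_ideal_helix(20)


def brute_force_contacts(chain, cutoff):
    """O(n^2) all-pairs oracle for residue contacts (strict < cutoff)."""
    edges = set()
    for a in chain.residues:
        for b in chain.residues:
            if a.index >= b.index:
                continue
            d = min(
                float(np.linalg.norm(x - y))
                for x in a.atoms.values()
                for y in b.atoms.values()
            )
            if d < cutoff:
                edges.add((a.index, b.index))
    return edges
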