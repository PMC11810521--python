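import numpy as np
import pytest

from richsrm.network_data import Individual, Roster, build_dyad_table
from richsrm.synthetic import coastal_like, generate_site


def make_roster(n: int = 6, groups=("afro", "embera"), site: str = "coastal",
                seed: int = 0) -> Roster:
    """Deterministic toy roster with alternating groups and varied covariates."""
    rng = np.random.default_rng(seed)
    individuals = []
    for k in range(n):
        individuals.append(
            Individual(
                id=f"p{k}",
                site=site,
                group=groups[k % len(groups)],
                wealth=float(np.exp(13.0 + 0.5 * rng.standard_normal())),
                income=float(np.exp(12.0 + 0.5 * rng.standard_normal())),
                food_insecurity=float(k % 5),
            )
        )
    return Roster(individuals)


@pytest.fixture
def toy_roster():
    return make_roster(6)


@pytest.fixture
def toy_dyads(toy_roster):
    return build_dyad_table(
        toy_roster,
        kin={("p0", "p2"): 0.5, ("p1", "p3"): 0.25},
        marriages=[("p0", "p1")],
    )


@pytest.fixture(scope="session")
def coastal_site():
    """One full coastal-like synthetic site shared across tests."""
    return generate_site(coastal_like(), seed=20)
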