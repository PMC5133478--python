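import numpy as np
import pytest

from triocausal.filtering import Trio
from triocausal.synthetic import TrioSpec, simulate_trio


def make_trio(label: str, seed: int, n: int = 600, effect: float = 0.5,
              maf: float = 0.3) -> Trio:
    """Simulate one trio under a named DAG and wrap it for the selectors."""
    s, g, p = simulate_trio(TrioSpec.for_dag(label, effect, n=n, maf=maf, seed=seed))
    return Trio("rs1", s, "probe0", g, "TRAIT", p,
                tuple(f"i{k}" for k in range(n)))


def random_trio(rng: np.random.Generator, n: int = 200) -> Trio:
    """Arbitrary (unstructured) trio data for oracle-equivalence checks."""
    s = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
    if np.ptp(s) == 0:  # ensure polymorphic
        s[0] = 1.0
    g = rng.normal(size=n) + 0.3 * s * rng.uniform(-1, 1)
    p = rng.normal(size=n) + 0.3 * g * rng.uniform(-1, 1)
    return Trio("rs1", s, "probe0", g, "TRAIT", p,
                tuple(f"i{k}" for k in range(n)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
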