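import numpy as np
import pytest

from oreomt import (AmpliconPanel, Amplicon, CircularRegion, ReferenceGenome,
                    synthetic_reference)


@pytest.fixture(scope="session")
def genome() -> ReferenceGenome:
    """The bundled synthetic stand-in genome with the rCRS length."""
    return synthetic_reference()


@pytest.fixture(scope="session")
def panel() -> AmpliconPanel:
    return AmpliconPanel.default()


@pytest.fixture(scope="session")
def toy_genome() -> ReferenceGenome:
    """A 60-base non-repetitive circular toy genome."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    return ReferenceGenome(name="toy", sequence=seq, circular=True)


def make_panel(spans: list[tuple[int, int]], genome_length: int
               ) -> AmpliconPanel:
    amps = [Amplicon(i + 1, CircularRegion(s, e))
            for i, (s, e) in enumerate(spans)]
    return AmpliconPanel(amps, genome_length)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
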