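import numpy as np
import pytest

from kinkloop import BendingModel


@pytest.fixture(scope="session")
def wlc():
    return BendingModel.wlc()


@pytest.fixture(scope="session")
def lsec():
    return BendingModel.lsec()


@pytest.fixture(scope="session")
def kwlc_na():
    """Kinkable model fit to the sodium-only data (h=22 kBT, b=0.3 rad)."""
    return BendingModel.kwlc(22.0, 0.3)


@pytest.fixture(scope="session")
def kwlc_mg():
    """Kinkable model fit to the magnesium data (h=17 kBT, b=0.7 rad)."""
    return BendingModel.kwlc(17.0, 0.7)


@pytest.fixture(scope="session")
def flexible():
    """A floppy chain (Lp = 5 nm, 0.34-nm links) whose short end separations
    are reachable by direct sampling — the oracle regime for WHAM tests."""
    from kinkloop import calibrate_rigidity

    return calibrate_rigidity("wlc", 5.0, 0.34)
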