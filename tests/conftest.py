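import pytest

from cohsi.infogrid import build_grid


@pytest.fixture(scope="session")
def default_grid():
    """The default information grid (t_max=200, a_max=30)."""
    return build_grid()


@pytest.fixture(scope="session")
def tall_grid():
    """A taller grid reaching t=450, enclosing roots near e^6 ~= 403."""
    return build_grid(450, 30)
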