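import pytest

from fluopeer.fixtures import gen_random_target
from fluopeer.pipeline import design_for_edit


@pytest.fixture(scope="session")
def random_targets():
    """A reusable batch of seeded (target, edit) pairs."""
    return [gen_random_target(9000 + i, 200, 0.5) for i in range(30)]


@pytest.fixture(scope="session")
def designed_bundle():
    """One successfully designed bundle (site, pegRNA, reporter insert)."""
    target, edit = gen_random_target(1001, 200, 0.5)
    return target, edit, design_for_edit(target, edit)
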