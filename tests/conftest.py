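"""Shared fixtures: session-scoped phantoms sized for test runtime.

The phantoms here are scaled-down (12x10x9 mm head, 0.3 mm CT / 0.5 mm MR)
relative to the generator defaults; the code paths are identical at all
scales and the finer defaults are exercised by the CLI.
"""

import numpy as np
import pytest

from marmoreg.geometry import RigidTransform
from marmoreg.phantom import PhantomSpec, generate_phantom

#: ground-truth CT->MR transform used by the main phantom pair
TRUE_CT_TO_MR = RigidTransform.from_euler_translation((10.0, 0.0, 0.0), (2.0, -3.0, 1.0))

#: spec kwargs for quick throwaway phantoms
TINY = dict(head_semiaxes=(10.0, 8.0, 7.0), ct_voxel=0.4, mr_voxel=0.8)


@pytest.fixture(scope="session")
def main_spec() -> PhantomSpec:
    return PhantomSpec(
        head_semiaxes=(12.0, 10.0, 9.0),
        ct_voxel=0.3,
        mr_voxel=0.5,
        true_ct_to_mr=TRUE_CT_TO_MR,
        seed=7,
    )


@pytest.fixture(scope="session")
def main_phantom(main_spec):
    """(ct, t1w, t2w, truth) for the standard registration test pair."""
    return generate_phantom(main_spec)


@pytest.fixture(scope="session")
def labelled_phantom():
    """Small phantom rendered with its ground-truth CT label volume."""
    spec = PhantomSpec(seed=3, **TINY)
    return spec, generate_phantom(spec, with_labels=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
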