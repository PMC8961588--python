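"""Shared synthetic fixtures.

Everything is generated programmatically with fixed seeds; no data files.
Session scope keeps the slower ensemble constructions to one run.
"""

import numpy as np
import pytest

from cadyn import (BundleSpec, HingeEnsembleSpec, hinge_ensemble, make_bundle,
                   perturb_family)


@pytest.fixture(scope="session")
def bundle():
    """A six-helix globular bundle, noise-free, with ground-truth helices."""
    return make_bundle(BundleSpec.default(seed=0))


@pytest.fixture(scope="session")
def small_bundle():
    """A smaller four-helix bundle for the heavier mode computations."""
    spec = BundleSpec.default(seed=3, n_helices=4)
    return make_bundle(spec)


@pytest.fixture(scope="session")
def core_family(bundle):
    """Ten structures with a planted conserved core (positions 30..49)."""
    core = list(range(30, 50))
    members = perturb_family(bundle, 10, core_positions=core,
                             core_sigma=0.05, elsewhere_sigma=2.0, seed=7)
    return members, core


@pytest.fixture(scope="session")
def hinge():
    """Two 30-residue rigid domains hinging 0–30° with 0.1 Å noise."""
    return hinge_ensemble(HingeEnsembleSpec(
        domain_a_size=30, domain_b_size=30, hinge_angles=[0.0, 30.0],
        noise_sigma=0.1, n_frames=12, seed=4))


@pytest.fixture(scope="session")
def two_families():
    """Two planted structural families with distinct architectures."""
    base_a = make_bundle(BundleSpec.default(seed=0, n_helices=5, label="famA"))
    base_b = make_bundle(BundleSpec.default(seed=5, n_helices=7, label="famB"))
    members = (perturb_family(base_a, 3, core_positions=range(10, 30),
                              core_sigma=0.05, elsewhere_sigma=0.3, seed=1)
               + perturb_family(base_b, 3, core_positions=range(10, 30),
                                core_sigma=0.05, elsewhere_sigma=0.3, seed=2))
    truth = np.array([0, 0, 0, 1, 1, 1])
    return members, truth


@pytest.fixture(scope="session")
def bundle_modes(small_bundle):
    from cadyn import build_hessian, normal_modes
    return normal_modes(build_hessian(small_bundle))
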