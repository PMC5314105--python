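import numpy as np
import pytest

from ieloc import phantom as ph
from ieloc import ecog, registration, seeg
from ieloc.volumes import Volume3D


@pytest.fixture(scope="session")
def head_ecog():
    """Default head used by the subdural-grid tests (seed 0)."""
    return ph.make_head(ph.PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def head_seeg():
    """Default head used by the depth-electrode tests (seed 1)."""
    return ph.make_head(ph.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def seeg_straight(head_seeg):
    """Noise-free straight 8-contact depth electrode plus its CT."""
    ct, truth = ph.implant_seeg(head_seeg, n_electrodes=1,
                                contacts_per_electrode=8, noise_sigma=0)
    return ct, truth


@pytest.fixture(scope="session")
def ecog_noisy(head_ecog):
    """4x5 grid phantom with the default 2%-of-metal CT noise."""
    ct, truth = ph.implant_ecog(head_ecog, rows=4, cols=5)
    return ct, truth


@pytest.fixture(scope="session")
def ecog_segmentation(head_ecog, ecog_noisy):
    """Shared result of the automatic grid segmentation on the noisy phantom."""
    ct, truth = ecog_noisy
    cfg = ecog.EcogSegConfig(n_target=20)
    cand, cand_ct, tau0 = ecog.dual_mask_strip(ct, head_ecog.brain_mask, cfg)
    clus, info = ecog.iterate_segmentation(cand, cand_ct, cfg, tau0=tau0)
    return clus, info, truth


@pytest.fixture(scope="session")
def reg_head():
    """Coarser head (2 mm grid) keeping the registration searches fast."""
    return ph.make_head(ph.PhantomSpec(shape=(96, 96, 96), voxel_mm=2.0,
                                       seed=3))


@pytest.fixture(scope="session")
def rigid_recovery(reg_head):
    """Recovery of a known 4/-3/2 mm + 5 deg rigid misalignment.

    The moving CT is the phantom CT with its affine premultiplied by the
    inverse of the true transform, so registration must find exactly that
    transform; shared across the capture-range tests.
    """
    head = reg_head
    ct, truth = ph.implant_seeg(head, 3, 8)
    true_t = registration.RigidTransform(
        rotation=np.deg2rad([0.0, 0.0, 5.0]),
        translation=np.array([4.0, -3.0, 2.0]))
    moving = Volume3D(ct.data, np.linalg.inv(true_t.matrix) @ ct.affine)
    recovered = registration.register_rigid(moving, head.t1)
    return recovered, true_t, truth


@pytest.fixture(scope="session")
def fine_seeg():
    """Half-millimetre phantom on which the 0.8 mm contacts are resolved."""
    spec = ph.PhantomSpec(shape=(160, 160, 160), voxel_mm=0.5,
                          brain_radii_mm=(26.0, 28.0, 25.0), seed=6)
    head = ph.make_head(spec)
    ct, truth = ph.implant_seeg(head, 2, 6, noise_sigma=0)
    return head, ct, truth


@pytest.fixture(scope="session")
def seeg_five(head_seeg):
    """Five-electrode noise-free SEEG phantom plus the full pipeline run."""
    head = ph.make_head(ph.PhantomSpec(seed=2))
    ct, truth = ph.implant_seeg(head, 5, 8, noise_sigma=0)
    es, info = seeg.run_seeg(ct, head.brain_mask, seeg.SeegSegConfig(), 8)
    return head, ct, truth, es, info
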