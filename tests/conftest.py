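import numpy as np
import pytest

from bronchoscore.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A 96x96 phantom with one mild lesion pinned to the left lower lobe."""
    return generate_phantom(
        PhantomSpec(
            image_size=96,
            n_lesions=1,
            severity_ratios=[1.5],
            lesion_lobes=[2],
            vessel_radius_px=3.0,
            n_distractor_vessels=2,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def coco_records(sample):
    """Phantom annotations as the dict records the training harness eats."""
    return [
        {"bbox": a.bbox, "category_id": a.severity_class, "mask": a.mask}
        for a in sample.annotations
    ]
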