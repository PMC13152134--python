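import numpy as np
import pytest

from otoaudit.synthetic import SyntheticConfig, generate_images


def provider_for(manifest, images):
    """Image provider closing over an in-memory generated dataset."""
    by_id = {r.image_id: im for r, im in zip(manifest.records, images)}
    return lambda record: by_id[record.image_id]


@pytest.fixture(scope="session")
def small_biased_dataset():
    """Saturation-biased, no clinical signal; shared across read-only tests."""
    cfg = SyntheticConfig(
        n_per_class=100, saturation_bias=1.0, clinical_contrast=0.0, seed=101
    )
    return generate_images(cfg)


@pytest.fixture(scope="session")
def sample_image():
    rng = np.random.default_rng(0)
    from otoaudit.synthetic import render_base_image

    return render_base_image(rng, "I", (64, 64))
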