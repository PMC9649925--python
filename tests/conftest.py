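import numpy as np
import pytest

from strokerad import phantom


@pytest.fixture(scope="session")
def lesion_subject():
    """One deterministic phantom subject (dwi, adc, mask) with a ~300-voxel lesion."""
    rng = np.random.default_rng(42)
    dwi, adc, mask = phantom.synthesize_lesion_pair((24, 40, 40), 300, 1.2, rng)
    return dwi, adc, mask


@pytest.fixture(scope="session")
def phantom_pool():
    """A reusable pool of 35 varied phantom subjects for segmentation studies."""
    rng = np.random.default_rng(5)
    subjects = []
    for _ in range(35):
        vol = int(np.exp(rng.uniform(np.log(60), np.log(400))))
        d, a, m = phantom.synthesize_lesion_pair(
            (24, 40, 40), vol, rng.uniform(0.6, 2.0), rng,
            dwi_contrast=rng.uniform(0.3, 0.5),
            adc_contrast=rng.uniform(0.25, 0.45),
            texture_amplitude=rng.uniform(0.04, 0.12))
        subjects.append((d, a, m))
    return subjects
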