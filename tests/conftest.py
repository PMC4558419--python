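import numpy as np
import pytest

from agnorfract import SyntheticSpec, generate_image


@pytest.fixture(scope="session")
def default_fixture():
    """Noise-free reference frame: 10 nuclei x exactly 3 dots = 30 dots."""
    spec = SyntheticSpec(seed=7, noise_sd=0.0, fixed_dot_count=True, stromal_dots_mean=0.0)
    return generate_image(spec)


@pytest.fixture(scope="session")
def noisy_fixture():
    spec = SyntheticSpec(seed=11)
    return generate_image(spec)


def flood_fill_components(mask: np.ndarray) -> int:
    """Independent 8-connected component count by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r0, c0 in zip(*np.nonzero(mask)):
        if seen[r0, c0]:
            continue
        count += 1
        stack = [(int(r0), int(c0))]
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return count
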