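import numpy as np
import pytest

from reefscore.synth.images import FishSpec, generate_fish_image


@pytest.fixture(scope="session")
def disc_image():
    """A gray disc: aspect 1, no fins, single achromatic color."""
    spec = FishSpec(
        body_aspect=1.0,
        fin_profile="none",
        n_stripes=0,
        palette=((0.5, 0.5, 0.5),),
        canvas_px=320,
    )
    return generate_fish_image(spec)


@pytest.fixture(scope="session")
def striped_image():
    """Two-tone fish with 5 stripes of the secondary color."""
    spec = FishSpec(
        body_aspect=2.0,
        n_stripes=5,
        palette=((0.9, 0.2, 0.1), (0.1, 0.2, 0.9)),
        fin_profile="caudal_only",
        canvas_px=200,
    )
    return generate_fish_image(spec)


@pytest.fixture(scope="session")
def striped_spec():
    return FishSpec(
        body_aspect=2.0,
        n_stripes=5,
        palette=((0.9, 0.2, 0.1), (0.1, 0.2, 0.9)),
        fin_profile="caudal_only",
        canvas_px=200,
    )


def flood_fill_components(binary: np.ndarray, connectivity: int = 2) -> int:
    """Independent connected-components oracle: iterative flood fill."""
    binary = np.asarray(binary, dtype=bool)
    visited = np.zeros_like(binary)
    if connectivity == 2:
        moves = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    h, w = binary.shape
    n_components = 0
    for i in range(h):
        for j in range(w):
            if binary[i, j] and not visited[i, j]:
                n_components += 1
                stack = [(i, j)]
                visited[i, j] = True
                while stack:
                    ci, cj = stack.pop()
                    for di, dj in moves:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < h and 0 <= nj < w and binary[ni, nj] and not visited[ni, nj]:
                            visited[ni, nj] = True
                            stack.append((ni, nj))
    return n_components
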