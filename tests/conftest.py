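import numpy as np
import pytest

import necroquant as nq


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def necrotic_cohort():
    """Default noise-free necrotic cohort (4 cells) with ground truth."""
    cfg = nq.scenario_config("mec-4(d)", n_cells=4, seed=0)
    return [nq.simulate_cell(cfg, i) for i in range(4)]


@pytest.fixture(scope="session")
def rendered_cell():
    """One noise-free necrotic cell rendered into frames."""
    cfg = nq.scenario_config("mec-4(d)", n_cells=1, seed=0)
    rec = nq.simulate_cell(cfg, 0)
    geom = nq.RenderGeometry(shape=(64, 64), centers=((32.0, 32.0),))
    return rec, nq.render_frames([rec], geom)


def brute_force_point_in_polygon(vertices, row, col):
    """Independent scalar even-odd test (on-edge counts as inside)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        # on-segment check
        cross = (r2 - r1) * (col - c1) - (c2 - c1) * (row - r1)
        if abs(cross) <= 1e-9 * max(np.hypot(r2 - r1, c2 - c1), 1.0):
            if min(r1, r2) - 1e-9 <= row <= max(r1, r2) + 1e-9 and min(c1, c2) - 1e-9 <= col <= max(
                c1, c2
            ) + 1e-9:
                return True
        if (r1 > row) != (r2 > row):
            c_int = (c2 - c1) * (row - r1) / (r2 - r1) + c1
            if col < c_int:
                inside = not inside
    return inside


def brute_force_mask(shape, vertices):
    """Per-pixel loop building the membership mask independently."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for r in range(h):
        for c in range(w):
            mask[r, c] = brute_force_point_in_polygon(vertices, float(r), float(c))
    return mask


def brute_force_measure(image, vertices):
    """(total signal, area) of a polygon via the per-pixel oracle mask."""
    mask = brute_force_mask(image.shape, vertices)
    return float(image[mask].sum()), int(mask.sum())
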