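import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gridstitch import (
    LinkTable,
    PairwiseLink,
    Tile,
    Translation,
    generate_texture_image,
)
from gridstitch.registration import NORTH, WEST

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def texture():
    """A 600x600 histology-like texture shared across tests."""
    return generate_texture_image(600, 600, seed=7)


@pytest.fixture(scope="session")
def tile_pair(texture):
    """Two 200x200 tiles cropped from one image with known west offset.

    Overlap 25%: true translation of the moving tile is (150, 0).
    """
    W = 200
    ref = Tile(row=0, col=0, pixels=texture[100:100 + W, 50:50 + W])
    mov = Tile(row=0, col=1, pixels=texture[100:100 + W, 200:200 + W])
    return ref, mov, (150.0, 0.0)


def make_link(direction, ref=(0, 0), t=None, n_matched=float("nan"),
              status=None, stage=None):
    """Construct a PairwiseLink with minimal boilerplate."""
    r, c = ref
    mov = (r + 1, c) if direction == NORTH else (r, c + 1)
    translation = Translation(*t) if t is not None else Translation.invalid()
    if status is None:
        status = "valid" if t is not None else "invalid"
    return PairwiseLink(
        reference=ref, moving=mov, direction=direction,
        translation=translation, n_matched=n_matched,
        stage_used=stage, status=status,
    )


def make_link_table(M, N, t_west=(150.0, 0.0), t_north=(0.0, 150.0),
                    n_matched=10.0, invalid=()):
    """Fully valid synthetic link table with uniform translations.

    ``invalid`` lists (direction, row, col) triples to blank out.
    """
    invalid = set(invalid)
    north = [
        [
            make_link(NORTH, (r, c), None if (NORTH, r, c) in invalid else t_north,
                      n_matched=float("nan") if (NORTH, r, c) in invalid else n_matched)
            for c in range(N)
        ]
        for r in range(M - 1)
    ]
    west = [
        [
            make_link(WEST, (r, c), None if (WEST, r, c) in invalid else t_west,
                      n_matched=float("nan") if (WEST, r, c) in invalid else n_matched)
            for c in range(N - 1)
        ]
        for r in range(M)
    ]
    return LinkTable(M=M, N=N, north=north, west=west)


def brute_force_msac(correspondences, inlier_tol):
    """Independent oracle: exhaustively score every single-correspondence
    translation hypothesis with the truncated quadratic loss."""
    corr = np.asarray(correspondences, dtype=np.float64)
    disp = corr[:, 0, :] - corr[:, 1, :]
    tol2 = inlier_tol ** 2
    best_score, best_idx = np.inf, -1
    for k in range(len(disp)):
        r2 = ((disp - disp[k]) ** 2).sum(axis=1)
        score = float(np.minimum(r2, tol2).sum())
        if score < best_score:
            best_score, best_idx = score, k
    return best_idx, best_score
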