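import numpy as np
import pytest

from beeland.smoothing import Trajectory3D
from beeland.synthetic import make_default_cameras


@pytest.fixture(scope="session")
def cameras():
    return make_default_cameras()


def straight_trajectory(
    speed: float = 0.1,
    n: int = 201,
    dt: float = 0.01,
    direction=(-1.0, 0.0, 0.0),
    with_abdomen: bool = False,
) -> Trajectory3D:
    """Uniform straight-line approach ending at the origin at the last frame."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    t = dt * (np.arange(n) - (n - 1))  # negative before touchdown
    X = np.outer(t, direction) * speed  # X(0) = origin, moving along `direction`
    U = np.tile(direction * speed, (n, 1))
    A = np.zeros((n, 3))
    X_abd = X - 0.012 * direction if with_abdomen else None
    return Trajectory3D(t=t, X=X, U=U, A=A, X_abd=X_abd, aligned=True)
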