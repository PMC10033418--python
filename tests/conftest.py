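import numpy as np
import pytest

from mitomap.synthetic import (MitoShapeParams, NucleusSpec, SceneSpec,
                               generate_cell_volume)


@pytest.fixture(scope="session")
def small_scene():
    """A small mixed scene: nucleus + 8 capsules + 2 droplets, anisotropic grid."""
    spec = SceneSpec(
        grid_shape=(24, 200, 200), voxel_size=(50, 10, 10),
        nucleus=NucleusSpec(semi_axes=(400, 500, 500), center=(600, 1000, 1000)),
        n_mitochondria=8,
        mito_shape=MitoShapeParams(radius_nm=80, length_mean_um=0.4, length_sd_um=0.0),
        n_lipid_droplets=2, ld_radius_mean_nm=150, ld_radius_sd_nm=20, seed=3)
    gray, truth = generate_cell_volume(spec)
    return spec, gray, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def dense_ellipse_oracle(point, ellipse, n_coarse=4096):
    """Independent minimum distance: dense boundary sampling + local refinement."""
    from scipy.optimize import minimize_scalar

    t = np.linspace(0.0, 2.0 * np.pi, n_coarse, endpoint=False)
    pts = ellipse.from_standard(
        np.column_stack([ellipse.a * np.cos(t), ellipse.b * np.sin(t)]))
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    i = int(np.argmin(d))

    def f(tt):
        q = ellipse.from_standard(
            np.array([[ellipse.a * np.cos(tt), ellipse.b * np.sin(tt)]]))[0]
        return float(np.hypot(q[0] - point[0], q[1] - point[1]))

    step = 2.0 * np.pi / n_coarse
    res = minimize_scalar(f, bounds=(t[i] - step, t[i] + step), method="bounded",
                          options={"xatol": 1e-14})
    return min(res.fun, float(d[i]))
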