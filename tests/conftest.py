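"""Shared fixtures: analytic surfaces and small synthetic inputs."""

import numpy as np
import pytest
import trimesh

from dentopo.mesh_io import ToothMesh


def grid_mesh(height_fn, extent=1.0, n=20, x0=0.0, y0=0.0):
    """Triangulated graph of z = height_fn(x, y) over a square grid."""
    xs = np.linspace(x0, x0 + extent, n)
    ys = np.linspace(y0, y0 + extent, n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = height_fn(X, Y)
    v = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    f = []
    for i in range(n - 1):
        for j in range(n - 1):
            a, b, c, d = i * n + j, (i + 1) * n + j, (i + 1) * n + j + 1, i * n + j + 1
            f.append((a, b, c))
            f.append((a, c, d))
    return ToothMesh(v, np.asarray(f), orientation_flag=True)


def hemisphere_mesh(n_theta=60, n_phi=120, radius=1.0):
    """UV hemisphere (pole fan + latitude bands), apex at +z."""
    theta = np.linspace(0, np.pi / 2, n_theta)[1:]
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    TH, PH = np.meshgrid(theta, phi, indexing="ij")
    verts = radius * np.column_stack(
        [
            (np.sin(TH) * np.cos(PH)).ravel(),
            (np.sin(TH) * np.sin(PH)).ravel(),
            np.cos(TH).ravel(),
        ]
    )
    pole = len(verts)
    verts = np.vstack([verts, [0.0, 0.0, radius]])

    def vid(i, j):
        return i * n_phi + (j % n_phi)

    faces = [(pole, vid(0, j), vid(0, j + 1)) for j in range(n_phi)]
    for i in range(n_theta - 2):
        for j in range(n_phi):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    return ToothMesh(verts, np.asarray(faces), orientation_flag=True)


@pytest.fixture(scope="session")
def flat_patch():
    return grid_mesh(lambda x, y: np.zeros_like(x), n=20)


@pytest.fixture(scope="session")
def unit_sphere():
    s = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return ToothMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def dense_sphere():
    s = trimesh.creation.icosphere(subdivisions=5, radius=1.0)  # 20480 faces
    return ToothMesh(np.asarray(s.vertices), np.asarray(s.faces))


@pytest.fixture(scope="session")
def hemisphere():
    return hemisphere_mesh()
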