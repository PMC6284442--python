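import numpy as np
import pytest

from shapesym import ShapeSample, SyntheticConfig, generate_population


def make_sphere_mesh(radius: float = 1.0, n_lat: int = 12, n_lon: int = 24):
    """Lat-long triangulation of a sphere (shared poles)."""
    verts = [(0.0, 0.0, radius)]
    for i in range(1, n_lat):
        phi = np.pi * i / n_lat
        for j in range(n_lon):
            lam = 2 * np.pi * j / n_lon
            verts.append((radius * np.sin(phi) * np.cos(lam),
                          radius * np.sin(phi) * np.sin(lam),
                          radius * np.cos(phi)))
    verts.append((0.0, 0.0, -radius))
    south = len(verts) - 1
    faces = []
    ring = lambda i, j: 1 + (i - 1) * n_lon + (j % n_lon)
    for j in range(n_lon):  # top cap
        faces.append((0, ring(1, j), ring(1, j + 1)))
    for i in range(1, n_lat - 1):
        for j in range(n_lon):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append((a, c, d))
            faces.append((a, d, b))
    for j in range(n_lon):  # bottom cap
        faces.append((south, ring(n_lat - 1, j + 1), ring(n_lat - 1, j)))
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=int)


@pytest.fixture(scope="session")
def sphere_mesh():
    points, faces = make_sphere_mesh()
    return ShapeSample(points=points, faces=faces, sample_id="sphere")


@pytest.fixture(scope="session")
def small_population():
    """12 subjects, tiny shapes, mild nuisance — shared across tests."""
    cfg = SyntheticConfig(
        n_subjects=12, n_points=40, n_modes_true=3,
        eigenvalues_true=(9.0, 4.0, 1.0), icc_per_mode=(0.9, 0.6, 0.3),
        noise_sd=0.02, rotation_max_deg=15.0, translation_max_mm=5.0,
        scale_range=(0.95, 1.05), seed=11)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def clean_population():
    """Noise- and nuisance-free population: shapes equal mean + modes @ latent."""
    cfg = SyntheticConfig(
        n_subjects=20, n_points=30, n_modes_true=3,
        eigenvalues_true=(9.0, 4.0, 1.0), icc_per_mode=(1.0, 0.5, 0.0),
        noise_sd=0.0, seed=7)
    return generate_population(cfg)
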