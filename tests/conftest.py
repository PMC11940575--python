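"""Shared fixtures: desk-scale trained models reused across test modules.

Both models take about a minute each to build on one CPU, so they are
session-scoped; every other fixture is cheap and generated on the fly.
"""

import numpy as np
import pytest
import trimesh

from beakmorph import pipeline, synthetic
from beakmorph.core import TriangleMesh

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def overfit_model():
    """10 random bills, latent dim 8, 2000 optimizer steps: the
    memorization regime in which reconstructions should be faithful."""
    table = pipeline.random_beak_table(10, seed=0)
    return pipeline.train_desk_model(
        table,
        latent_dim=8,
        hidden_size=128,
        resolution=32,
        n_sdf=1500,
        epochs=100,
        steps_per_epoch=20,
        seed=0,
    )


@pytest.fixture(scope="session")
def niche_model():
    """Three niche classes (one distinct, two overlapping), 45 bills each;
    the substrate for direction discovery, traversal and classification."""
    spec = pipeline.three_niche_spec(45)
    table = synthetic.sample_class_params(spec, seed=42)
    return pipeline.train_desk_model(
        table,
        latent_dim=8,
        hidden_size=128,
        resolution=32,
        n_sdf=1000,
        epochs=100,
        steps_per_epoch=20,
        seed=1,
    )


@pytest.fixture(scope="session")
def spread_model():
    """60 bills spanning the parametric family continuously; the substrate
    for direction discovery and traversal (a memorizing decoder trained on
    tight clusters is locally flat between them, so traversal needs
    continuous morphological variation)."""
    table = pipeline.random_beak_table(60, seed=5)
    return pipeline.train_desk_model(
        table,
        latent_dim=8,
        hidden_size=128,
        resolution=32,
        n_sdf=1000,
        epochs=100,
        steps_per_epoch=20,
        seed=2,
    )


@pytest.fixture()
def icosphere():
    """Unit icosphere at subdivision 4 (chord error ~1e-3)."""
    tm = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return TriangleMesh.from_trimesh(tm)


@pytest.fixture()
def simple_beak():
    params = synthetic.ShapeParams("beak", 4.0, 1.0, 1.0, curvature=0.2, hook=0.3)
    return synthetic.make_beak_mesh(params, resolution=32)


def box_mesh(lx, ly, lz, with_landmarks=True):
    """Axis-aligned solid box in canonical pose (base at x=0, tip at +x)."""
    tm = trimesh.creation.box(extents=(lx, ly, lz))
    tm.apply_translation((lx / 2.0, 0.0, 0.0))
    landmarks = None
    if with_landmarks:
        landmarks = {
            "tip": np.array([lx, 0.0, 0.0]),
            "base_top": np.array([0.0, 0.0, lz / 2.0]),
            "base_bottom": np.array([0.0, 0.0, -lz / 2.0]),
        }
    return TriangleMesh.from_trimesh(tm, landmarks=landmarks)
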