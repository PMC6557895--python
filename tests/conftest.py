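import numpy as np
import pytest

import facesculpt as fs


@pytest.fixture(scope="session")
def schema():
    return fs.default_schema()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def reference_vector(schema):
    return fs.FaceVector(schema.reference)


@pytest.fixture(scope="session")
def fixture_image(schema):
    """Small synthetic portrait + pixel landmarks (session-cached)."""
    return fs.make_fixture_image(150, 200, schema)


def random_face(schema, rng):
    """A random valid FaceVector, uniform within bounds then projected."""
    raw = rng.uniform(schema.lo, schema.hi)
    return fs.project_to_constraint(raw, schema)


@pytest.fixture()
def random_faces(schema, rng):
    return [random_face(schema, rng) for _ in range(6)]
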