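import numpy as np
import pytest

from respivol.imaging import LANDMARKS, MarkerSet
from respivol.synthetic import SubjectSpec


@pytest.fixture
def mean_subject() -> SubjectSpec:
    """Subject at the cohort anthropometric means."""
    return SubjectSpec(
        subject_id="MEAN",
        sex="M",
        age=15,
        body_mass=61.3,
        height=1.66,
        thorax_length=25.5,
        mm_per_px=0.8,
    )


@pytest.fixture
def flat_markers() -> MarkerSet:
    """Five markers at constant height 10 cm, spaced 5 cm apart."""
    return MarkerSet(
        coords={name: (5.0 * i, 10.0) for i, name in enumerate(LANDMARKS)}
    )


def random_markerset(rng: np.random.Generator) -> MarkerSet:
    """A random valid profile: positive heights, increasing x."""
    dx = rng.uniform(4.0, 14.0, size=4)
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = rng.uniform(2.0, 30.0, size=5)
    return MarkerSet(
        coords={name: (float(xi), float(yi)) for name, xi, yi in zip(LANDMARKS, x, y)}
    )
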