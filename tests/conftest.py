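import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from circaepi.io_formats import SampleMeta, TimeCourseMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ZTS8 = np.arange(0.0, 24.0, 3.0)


def design(zts=ZTS8, replicates=1, condition="CV"):
    return [
        SampleMeta(f"{condition}_ZT{z:g}_r{r + 1}", float(z), r + 1, condition)
        for z in zts
        for r in range(replicates)
    ]


@pytest.fixture
def samples8():
    """Single-replicate design: one sample per 3 h across one cycle."""
    return design()


@pytest.fixture
def samples16():
    """Duplicated design: 8 zts x 2 replicates."""
    return design(replicates=2)


def cosine_matrix(gene_specs, samples, noise_sd=0.0, seed=0):
    """Build a TimeCourseMatrix of mesor + amp*cos(2*pi*(t-phase)/period) genes.

    gene_specs: list of (gene_id, mesor, amp, phase) or (gene_id, mesor) for
    constant genes.
    """
    rng = np.random.default_rng(seed)
    zts = np.array([s.zt for s in samples])
    rows, ids = [], []
    for spec in gene_specs:
        if len(spec) == 2:
            gid, mesor = spec
            y = np.full(len(zts), float(mesor))
        else:
            gid, mesor, amp, phase = spec
            y = mesor + amp * np.cos(2 * np.pi * (zts - phase) / 24.0)
        if noise_sd:
            y = y + rng.normal(0, noise_sd, len(y))
        rows.append(np.clip(y, 0, None))
        ids.append(gid)
    return TimeCourseMatrix(ids, np.array(rows), samples)
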