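import numpy as np
import pytest

from toxpipe.core import ExpressionDataset, SampleGroup, SampleMeta


def make_meta(sample_id, compound="cpd", dose="Middle", time="4 day",
              control_key=None, platform="plat-r", species="rat"):
    return SampleMeta(
        sample_id=sample_id,
        compound=compound,
        dose_level=dose,
        exposure_time=time,
        organ="liver",
        species=species,
        platform=platform,
        test_type="in_vivo",
        control_group_key=control_key or f"{compound}|liver|{time}",
    )


def make_dataset(n_probes=10, n_treated=3, n_controls=3, seed=0, compound="cpd",
                 time="4 day"):
    """Small dataset: one treated group with matched controls."""
    rng = np.random.default_rng(seed)
    probes = [f"P{i:03d}" for i in range(n_probes)]
    samples = []
    for r in range(n_controls):
        samples.append(make_meta(f"{compound}_ctrl_{r}", compound=compound,
                                 dose="Control", time=time))
    for r in range(n_treated):
        samples.append(make_meta(f"{compound}_mid_{r}", compound=compound,
                                 dose="Middle", time=time))
    intensities = rng.lognormal(mean=2.0, sigma=0.5, size=(n_probes, len(samples)))
    return ExpressionDataset(probes, samples, intensities)


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def treated_group(small_dataset):
    treated = tuple(s.sample_id for s in small_dataset.samples if s.dose_level == "Middle")
    controls = tuple(s.sample_id for s in small_dataset.samples if s.dose_level == "Control")
    return SampleGroup(name="M4", sample_ids=treated, control_sample_ids=controls)
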