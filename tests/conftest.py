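import pytest

from artenh.synthetic import default_cohort_spec, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort_dir(tmp_path_factory):
    """A zero-noise synthetic cohort written to disk once per session."""
    d = tmp_path_factory.mktemp("cohort_clean")
    spec = default_cohort_spec(seed=7, noise_marks_per_track=0.0)
    cohort = generate_cohort(spec, d)
    return d, cohort


@pytest.fixture(scope="session")
def noisy_cohort(tmp_path_factory):
    """A cohort with background noise marks, written to disk."""
    d = tmp_path_factory.mktemp("cohort_noisy")
    spec = default_cohort_spec(seed=11, noise_marks_per_track=2.0)
    cohort = generate_cohort(spec, d)
    return d, cohort
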