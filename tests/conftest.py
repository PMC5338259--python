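import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The packaged worked-example fixture, built once per session."""
    from crisprbim import build_worked_example

    outdir = tmp_path_factory.mktemp("fixture")
    return build_worked_example(outdir, seed=42)


@pytest.fixture(scope="session")
def fixture_arrays(bundle):
    """Ancestor + BIM arrays parsed back from the fixture FASTA files."""
    from crisprbim import parse_array, read_fasta

    ancestor = parse_array(read_fasta(bundle.paths["ancestor.fasta"])[0], bundle.repeat)
    bims = [
        parse_array(rec, bundle.repeat)
        for rec in read_fasta(bundle.paths["bims.fasta"])
    ]
    return ancestor, bims


@pytest.fixture(scope="session")
def fixture_diffs(fixture_arrays):
    from crisprbim import diff_arrays

    ancestor, bims = fixture_arrays
    return ancestor, bims, {b.strain_id: diff_arrays(ancestor, b) for b in bims}
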