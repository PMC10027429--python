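import pytest

from multisyn.fixtures import FixtureSpec, make_fixture


@pytest.fixture
def write_text(tmp_path):
    """Write a text file under tmp_path and return its path."""

    def _write(name, content):
        p = tmp_path / name
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(content, encoding="utf-8")
        return p

    return _write


@pytest.fixture
def demo_fixture(tmp_path):
    """A small 3-genome dataset with converter dialect files."""
    spec = FixtureSpec(n_genomes=3, chroms_per_genome=2, n_links=6,
                       inversion_fraction=0.3, n_features=5, seed=42)
    paths = make_fixture(spec, tmp_path / "fix")
    return spec, paths
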