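import pytest

from neurometa import FixtureSpec, generate_project


@pytest.fixture()
def project_dir(tmp_path):
    """A small runnable project fixture: populations of 2 and 3 LIF cells."""
    out = tmp_path / "proj"
    generate_project(FixtureSpec(seed=7, n_nodes=10), str(out))
    return out


@pytest.fixture()
def project(project_dir):
    from neurometa import load_project

    return load_project(str(project_dir / "project.json"))
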