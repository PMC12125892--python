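import gzip
from pathlib import Path

import pytest

from mafkmers.synth_fixtures import FixtureConfig, generate_maf

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def toy_maf_path() -> Path:
    return DATA_DIR / "toy_two_block.maf"


@pytest.fixture(scope="session")
def toy_maf_text(toy_maf_path) -> str:
    return toy_maf_path.read_text()


@pytest.fixture(scope="session")
def mixed_maf_path() -> Path:
    """Pinned generator output with q lines (incl. F), minus strands,
    missing scores, gaps and ambiguous bases."""
    return DATA_DIR / "mixed_features.maf"


@pytest.fixture()
def make_fixture(tmp_path):
    """Write a seeded synthetic MAF into the test's tmp dir."""

    def _make(name="fixture.maf", **kwargs) -> Path:
        config = FixtureConfig(**kwargs)
        path = tmp_path / name
        path.write_text(generate_maf(config))
        return path

    return _make


@pytest.fixture()
def gzipped_copy(tmp_path):
    def _gz(path: Path) -> Path:
        out = tmp_path / (Path(path).name + ".gz")
        out.write_bytes(gzip.compress(Path(path).read_bytes()))
        return out

    return _gz
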