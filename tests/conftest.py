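import pytest

import ddialert as d


@pytest.fixture(scope="session")
def trees():
    return d.load_bundled_trees()


@pytest.fixture(scope="session")
def tree_by_id(trees):
    return {t.ddi_id: t for t in trees}


@pytest.fixture(scope="session")
def library():
    return d.load_bundled_library()


@pytest.fixture(scope="session")
def config():
    return d.ContextConfig()


@pytest.fixture(scope="session")
def vocab():
    return d.vocabulary_store()


@pytest.fixture(scope="session")
def replica():
    return d.generate_paper_replica(11)


@pytest.fixture(scope="session")
def replica_dir(tmp_path_factory, replica):
    path = tmp_path_factory.mktemp("replica_store")
    d.write_store(replica, path)
    return path
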