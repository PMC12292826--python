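import numpy as np
import pytest

from mvld import Corpus, build_model, generate_corpus


@pytest.fixture(scope="session")
def corpus_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("corpus")
    generate_corpus(8, image_size=32, patch_size=8, out_dir=d, seed=42)
    return d


@pytest.fixture(scope="session")
def corpus(corpus_dir):
    return Corpus(corpus_dir)


@pytest.fixture(scope="session")
def toy_student():
    return build_model("toy-student", seed=11)


@pytest.fixture(scope="session")
def toy_teacher():
    return build_model("toy-teacher", seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_batch(corpus, toy_student):
    images, token_ids = corpus.batch(range(4), toy_student.config.max_text_len)
    return images, token_ids
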