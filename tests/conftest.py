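from datetime import date

import pytest

from sigdose.nn import TrainConfig
from sigdose.models import train_nlp1, train_nlp2
from sigdose.pipeline import register_entries
from sigdose.records import PrescriptionRecord
from sigdose.synth import GeneratorConfig, generate_corpus, generate_register


def make_record(**kwargs) -> PrescriptionRecord:
    defaults = dict(
        person_id="P1",
        age=25,
        sex="male",
        atc="N06BA04",
        article_number="MPH-10-30",
        dispensation_date=date(2013, 3, 1),
        n_packages=1,
        package_size=30,
        strength_mg=10.0,
        specialty="psychiatry",
        county="county_01",
        free_text="1 tablett dagligen",
        returned=False,
    )
    defaults.update(kwargs)
    return PrescriptionRecord(**defaults)


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(1500, seed=11)


@pytest.fixture(scope="session")
def small_entries(small_corpus):
    return register_entries(small_corpus)


@pytest.fixture(scope="session")
def trained_models(small_entries):
    """NLP1/NLP2 trained on a reduced corpus; enough to be near-perfect on
    the synthetic grammar while keeping the suite fast."""
    cfg = TrainConfig(epochs=8)
    nlp1 = train_nlp1(small_entries, seed=3, config=cfg)
    nlp2 = train_nlp2(small_entries, seed=4, config=cfg, vocab=nlp1.vocab)
    return nlp1, nlp2


@pytest.fixture(scope="session")
def small_register():
    return generate_register(GeneratorConfig(n_persons=120, seed=7))
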