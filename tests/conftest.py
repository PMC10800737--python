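import pytest

from anthrofail.records import ChildRecord
from anthrofail.synthetic import SyntheticConfig, generate_population


def make_record(i=0, haz=-1.0, waz=-1.0, whz=0.0, **kwargs):
    defaults = dict(height_cm=80.0, weight_kg=10.0, survey_weight=1.0)
    defaults.update(kwargs)
    return ChildRecord(id=f"r{i:04d}", haz=haz, waz=waz, whz=whz, **defaults)


@pytest.fixture(scope="session")
def small_population():
    """2,000 clean synthetic children, fixed seed."""
    return generate_population(SyntheticConfig(n_children=2000, seed=42))


@pytest.fixture(scope="session")
def planted_population():
    """Population with known counts in every proposed-model group."""
    planted = [("I", 7), ("G", 11), ("E", 13), ("D", 5), ("B", 9)]
    config = SyntheticConfig(n_children=1500, seed=7, planted_records=planted)
    return generate_population(config), dict(planted)
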