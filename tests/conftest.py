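import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


PBDB_CSV = """occurrence_no,accepted_name,genus,family,min_ma,max_ma,environment,lng,lat,collection_no,primary_reso,flags
1,Acropora palmata,Acropora,Acroporidae,0.0,0.0117,reef,-80.1,25.5,101,,1
2,Acropora cervicornis,Acropora,Acroporidae,2.58,5.33,reef,-79.9,24.9,102,,1
3,Porites lobata,Porites,Poritidae,5.33,23.03,reef,150.2,-18.1,103,,1
"""


@pytest.fixture
def pbdb_csv_file(tmp_path):
    path = tmp_path / "occ.csv"
    path.write_text(PBDB_CSV)
    return path


def make_table(rows):
    """Build a core-schema occurrence table from compact row dicts."""
    defaults = dict(
        genus="G",
        family="Fam",
        environment="reef",
        lng=0.0,
        lat=0.0,
        site=0,
        qualifier="none",
        accepted=True,
        extant=False,
    )
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("occurrence_id", i)
        rec.setdefault("min_ma", rec.get("max_ma", 1.0))
        rec.setdefault("max_ma", rec["min_ma"])
        records.append(rec)
    return pd.DataFrame(records)


@pytest.fixture
def small_table():
    return make_table(
        [
            {"species": "Alpha one", "family": "A", "site": 1, "min_ma": 1.0, "max_ma": 2.0},
            {"species": "Alpha two", "family": "A", "site": 2, "min_ma": 2.0, "max_ma": 3.0},
            {"species": "Beta one", "family": "B", "site": 1, "min_ma": 0.5, "max_ma": 1.5},
            {"species": "Beta cf. two", "family": "B", "site": 2, "min_ma": 1.0, "max_ma": 2.0,
             "qualifier": "cf"},
            {"species": "Gamma one", "family": "C", "site": 2, "min_ma": 3.0, "max_ma": 4.0,
             "accepted": False},
        ]
    )


@pytest.fixture(scope="session")
def constant_history():
    """One constant-rate clade (lambda=0.4, mu=0.2) used by several tests."""
    import fossilbd as fb

    return fb.simulate_bd(
        fb.SimParams(t_root=24.0, lam=0.4, mu=0.2, n0=1, seed=11, family="Const")
    )


@pytest.fixture(scope="session")
def constant_occurrences(constant_history):
    """HPP (q=1.5) fossil record of the constant-rate clade."""
    import fossilbd as fb

    return fb.simulate_preservation(
        constant_history, fb.PreservationModel("HPP", q=1.5), seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
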