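import pandas as pd
import pytest

from troopmove.io import RankTable, validate_observations


@pytest.fixture
def three_fix_csv(tmp_path):
    p = tmp_path / "obs.csv"
    p.write_text(
        "animal_id,t,x,y\n"
        "a,0,0.0,0.0\n"
        "a,60,10.0,0.0\n"
        "a,120,20.0,0.0\n"
    )
    return p


@pytest.fixture
def small_obs():
    """Two animals, one day, regular fixes on known straight lines."""
    rows = []
    for k in range(6):
        rows.append(("a", 60.0 * k, 10.0 * k, 0.0))
        rows.append(("b", 60.0 * k + 30.0, 10.0 * k, 5.0))
    df = pd.DataFrame(rows, columns=["animal_id", "t", "x", "y"])
    return validate_observations(df)


@pytest.fixture
def troop_ranks():
    """The 13-adult labelling (2 males, 11 females) used throughout."""
    ids = ["M1", "M2"] + [f"F{i}" for i in range(1, 12)]
    sex = ["M", "M"] + ["F"] * 11
    rank = [1, 2] + list(range(1, 12))
    return RankTable(pd.DataFrame({"animal_id": ids, "sex": sex, "rank": rank}))
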