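import numpy as np
import pandas as pd
import pytest

from herdfert import tables
from herdfert.model import GeneticParameterSummary
from herdfert.simulate import HerdSimConfig, simulate_pedigree
from herdfert.tables import SchemaError, TableDialect
from herdfert.traits import TRAIT_ORDER


def _write(path, text):
    path.write_text(text)
    return path


def test_read_service_records_basic(tmp_path):
    p = _write(
        tmp_path / "svc.csv",
        "animal_id,herd,birth_date,sire,dam,event_type,event_date,event_value\n"
        "A1,H1,2000-01-01,S1,D1,SERVICE,2001-05-31,failure\n"
        "A1,H1,2000-01-01,S1,D1,SERVICE,2001-06-21,success\n"
        "A1,H1,2000-01-01,S1,D1,CALVING,2002-03-28,1\n",
    )
    recs, log = tables.read_service_records(p)
    assert len(recs) == 1 and len(log) == 0
    assert len(recs[0].services) == 2 and len(recs[0].calvings) == 1
    assert recs[0].sire_id == "S1"


def test_unparseable_date_rejected_not_silent(tmp_path):
    p = _write(
        tmp_path / "svc.csv",
        "animal_id,herd,birth_date,sire,dam,event_type,event_date,event_value\n"
        "A1,H1,01/01/2000,S1,D1,SERVICE,31/02/2020,failure\n"
        "A1,H1,01/01/2000,S1,D1,SERVICE,01/06/2001,success\n",
    )
    recs, log = tables.read_service_records(p, TableDialect(date_format="%d/%m/%Y"))
    assert len(log) == 1 and log.iloc[0]["reason"] == "unparseable date"
    assert len(recs[0].services) == 1


def test_missing_column_names_the_column(tmp_path):
    p = _write(tmp_path / "svc.csv", "animal_id,herd,birth_date\nA1,H1,2000-01-01\n")
    with pytest.raises(SchemaError, match="sire"):
        tables.read_service_records(p)


def test_service_records_round_trip(tmp_path, small_herd):
    _, _, records, _ = small_herd
    p = tmp_path / "svc.csv"
    tables.write_service_records(records, p)
    back, log = tables.read_service_records(p)
    assert len(log) == 0
    orig = {r.animal_id: r for r in records}
    assert set(orig) == {r.animal_id for r in back}
    for r in back:
        o = orig[r.animal_id]
        assert r.services == o.services
        assert r.calvings == o.calvings
        assert r.diagnoses == o.diagnoses
        assert (r.sire_id, r.dam_id, r.birth_date) == (o.sire_id, o.dam_id, o.birth_date)


def test_read_pedigree_trio_and_implied_founder(tmp_path):
    p = _write(
        tmp_path / "ped.csv",
        "animal,sire,dam,birth_date\nS,0,0,2000-01-01\nD,0,0,2000-02-01\nO,S,D,2002-01-01\n",
    )
    ped = tables.read_pedigree(p)
    assert ped.n == 3
    i = ped.index
    assert ped.sire[i["O"]] == i["S"] and ped.dam[i["O"]] == i["D"]

    p2 = _write(tmp_path / "ped2.csv", "animal,sire,dam,birth_date\nO,S1,0,2002-01-01\n")
    ped2 = tables.read_pedigree(p2)
    assert "S1" in set(ped2.ids)  # implied founder added


def test_read_pedigree_duplicate_raises(tmp_path):
    p = _write(
        tmp_path / "ped.csv",
        "animal,sire,dam,birth_date\nA,0,0,2000-01-01\nA,0,0,2000-01-01\n",
    )
    with pytest.raises(SchemaError, match="A"):
        tables.read_pedigree(p)


def test_large_pedigree_round_trip(tmp_path):
    ped = simulate_pedigree(HerdSimConfig(n_founders=400, n_generations=4,
                                          generation_size=600, seed=9))
    p = tmp_path / "ped.csv"
    tables.write_pedigree(ped, p)
    back = tables.read_pedigree(p)
    assert back.n == ped.n
    assert list(back.ids) == list(ped.ids)
    assert np.array_equal(back.sire, ped.sire) and np.array_equal(back.dam, ped.dam)
    assert np.allclose(back.birth, ped.birth, equal_nan=True)


def _summary(traits, seed=0):
    rng = np.random.default_rng(seed)
    t = len(traits)
    L = rng.normal(size=(t, t))
    M = L @ L.T + t * np.eye(t)
    d = np.sqrt(np.diag(M))
    corr = M / np.outer(d, d)
    return GeneticParameterSummary(
        traits=traits,
        h2_mean=rng.uniform(0.01, 0.4, t),
        h2_sd=rng.uniform(0.001, 0.05, t),
        rg_mean=corr,
        rg_sd=np.full((t, t), 0.02),
        rp_mean=0.5 * corr,
        rp_sd=np.full((t, t), 0.01),
    )


def test_write_results_two_traits(tmp_path):
    s = _summary(["CFS", "DO"])
    mpath = tmp_path / "m.csv"
    tables.write_results(s, mpath)
    mat = pd.read_csv(mpath, index_col=0)
    assert mat.shape == (2, 2)
    assert all("±" in str(v) for v in mat.to_numpy().ravel())


def test_results_long_round_trip_6_decimals(tmp_path):
    s = _summary(["AFS", "AFC", "SPCh"])
    tables.write_results(s, tmp_path / "m.csv", tmp_path / "l.csv")
    back = tables.read_results_long(tmp_path / "l.csv")
    for i, tr in enumerate(s.traits):
        row = back[(back.trait_a == tr) & (back.trait_b == tr) & (back.statistic == "h2")]
        assert row["posterior_mean"].iloc[0] == pytest.approx(s.h2_mean[i], abs=1e-6)
    row = back[(back.trait_a == "AFS") & (back.trait_b == "AFC") & (back.statistic == "rg")]
    assert row["posterior_mean"].iloc[0] == pytest.approx(s.rg_mean[0, 1], abs=1e-6)


def test_nine_trait_reporting_order(tmp_path):
    s = _summary(TRAIT_ORDER)
    mpath = tmp_path / "m.csv"
    tables.write_results(s, mpath)
    mat = pd.read_csv(mpath, index_col=0)
    assert list(mat.index) == TRAIT_ORDER
    assert list(mat.columns) == TRAIT_ORDER


def test_phenotype_round_trip(tmp_path):
    df = pd.DataFrame(
        {
            "animal_id": ["A1", "A2"],
            "parity": [1, 2],
            "herd": ["H1", "H1"],
            "cg_code": ["H1-2005-summer", "H1-2006-winter"],
            "age_months": [16.9, 27.3],
            "CFS": [90.0, np.nan],
        }
    )
    p = tmp_path / "ph.csv"
    tables.write_phenotypes(df, p)
    back = tables.read_phenotypes(p)
    pd.testing.assert_frame_equal(back, df)
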