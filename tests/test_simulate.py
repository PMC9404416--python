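import numpy as np
import pandas as pd
import pytest

from herdfert.pedigree import UNKNOWN
from herdfert.simulate import (
    HerdSimConfig,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_service_records,
)
from herdfert.traits import TRAIT_ORDER, build_rows


def test_single_generation_is_founders_only():
    ped = simulate_pedigree(HerdSimConfig(n_founders=30, n_generations=1, seed=1))
    assert ped.n == 30
    assert (ped.sire == UNKNOWN).all() and (ped.dam == UNKNOWN).all()


def test_halfsib_family_sizes_partition_generation():
    cfg = HerdSimConfig(n_founders=100, n_generations=3, generation_size=120, n_sires=5, seed=2)
    ped = simulate_pedigree(cfg)
    gen = ped.meta["generation"]
    for g in (1, 2):
        members = [i for i in range(ped.n) if gen[ped.ids[i]] == g]
        assert len(members) == 120
        sires = [ped.sire[i] for i in members]
        assert UNKNOWN not in sires
        sizes = pd.Series(sires).value_counts()
        assert sizes.sum() == 120 and len(sizes) <= 5


def test_halfsib_mean_relationship_quarter():
    cfg = HerdSimConfig(n_founders=60, n_generations=2, generation_size=300, n_sires=2, seed=3)
    ped = simulate_pedigree(cfg)
    A = ped.relationship_matrix()
    gen = ped.meta["generation"]
    kids = [i for i in range(ped.n) if gen[ped.ids[i]] == 1]
    rel = []
    for a in range(0, len(kids), 7):
        for b in range(a + 1, len(kids), 7):
            i, j = kids[a], kids[b]
            if ped.sire[i] == ped.sire[j] and ped.dam[i] != ped.dam[j]:
                rel.append(A[i, j])
    assert np.mean(rel) == pytest.approx(0.25, abs=0.02)


def test_breeding_values_zero_matrix():
    ped = simulate_pedigree(HerdSimConfig(n_founders=20, n_generations=2, seed=4))
    bv = simulate_breeding_values(ped, np.zeros((2, 2)), seed=1)
    assert not bv.any()


def test_founder_breeding_value_variance():
    ped = simulate_pedigree(HerdSimConfig(n_founders=10_000, n_generations=1, seed=5))
    bv = simulate_breeding_values(ped, np.array([[1.0]]), seed=6)
    assert 0.95 <= bv.var() <= 1.05


def test_breeding_value_covariance_matches_A_kron_G():
    """Across replicates, cov of the stacked BV vector approximates A x G0."""
    ped = simulate_pedigree(HerdSimConfig(n_founders=8, n_generations=2,
                                          generation_size=12, n_sires=2, seed=7))
    G0 = np.array([[1.0, 0.5], [0.5, 1.0]])
    reps = np.stack([simulate_breeding_values(ped, G0, seed=s) for s in range(300)])
    A = ped.relationship_matrix()
    # trait-1 variance of every animal ~ diag(A); sibling covariance ~ A_ij
    emp_var = reps[:, :, 0].var(axis=0)
    assert np.allclose(emp_var, np.diag(A), atol=0.25)
    i, j = ped.n - 2, ped.n - 1
    emp = np.cov(reps[:, i, 0], reps[:, j, 0])[0, 1]
    assert emp == pytest.approx(A[i, j] * G0[0, 0], abs=0.25)
    # cross-trait within animal ~ G0_01 * diag(A)
    emp_ct = np.mean([np.cov(reps[:, k, 0], reps[:, k, 1])[0, 1] for k in range(ped.n)])
    assert emp_ct == pytest.approx(G0[0, 1] * np.diag(A).mean(), abs=0.15)


def test_phenotypes_equal_bv_when_noise_free():
    ped = simulate_pedigree(HerdSimConfig(n_founders=20, n_generations=2,
                                          generation_size=20, seed=8))
    bv = simulate_breeding_values(ped, np.array([[0.5]]), seed=9)
    tab, _ = simulate_phenotypes(ped, bv, traits=["T1"], R0=np.array([[0.0]]),
                                 n_cg=3, cg_sd=0.0, seed=10)
    merged = tab.set_index("animal_id")["T1"]
    for aid, v in merged.items():
        assert v == pytest.approx(bv[ped.index[aid], 0], abs=1e-12)


def test_binary_trait_balanced_at_zero_liability_mean():
    ped = simulate_pedigree(HerdSimConfig(n_founders=10_000, n_generations=1, seed=11))
    bv = np.zeros((ped.n, 1))
    tab, _ = simulate_phenotypes(ped, bv, traits=["B1"], R0=np.array([[1.0]]),
                                 threshold=("B1",), n_cg=1, cg_sd=0.0, seed=12,
                                 phenotyped=ped.ids)
    freq = (tab["B1"] == 2).mean()
    assert freq == pytest.approx(0.5, abs=0.02)


def test_realized_h2_matches_variance_ratio():
    """Variance decomposition over replicates of a fixed design."""
    ped = simulate_pedigree(HerdSimConfig(n_founders=400, n_generations=1, seed=13))
    s2a, s2e = 0.4, 0.6
    tot, gen = [], []
    for s in range(200):
        bv = simulate_breeding_values(ped, np.array([[s2a]]), seed=1000 + s)
        tab, _ = simulate_phenotypes(ped, bv, traits=["T1"], R0=np.array([[s2e]]),
                                     n_cg=1, cg_sd=0.0, seed=2000 + s,
                                     phenotyped=ped.ids)
        y = tab["T1"].to_numpy()
        tot.append(y.var())
        gen.append(bv.var())
    h2 = np.mean(gen) / np.mean(tot)
    assert h2 == pytest.approx(s2a / (s2a + s2e), abs=0.02)


def test_certain_conception_gives_spc_one(small_herd):
    cfg, ped, _, _ = small_herd
    sure = HerdSimConfig(**{**cfg.__dict__, "conception_probability": 0.999999,
                            "heifer_conception_probability": 0.999999,
                            "liability_sd": 0.0})
    records, truth = simulate_service_records(ped, sure, seed=3)
    led = truth.ledger
    assert (led["SPC"].dropna() == 1).all()
    assert (led["SPCh"].dropna() == 1).all()
    both = led["DO"].notna() & led["CFS"].notna()
    assert (led.loc[both, "DO"] == led.loc[both, "CFS"]).all()


def test_impossible_conception_gives_no_calvings(small_herd):
    cfg, ped, _, _ = small_herd
    never = HerdSimConfig(**{**cfg.__dict__, "conception_probability": 1e-12,
                             "heifer_conception_probability": 1e-12,
                             "liability_sd": 0.0})
    records, truth = simulate_service_records(ped, never, seed=3)
    assert all(len(r.calvings) == 0 for r in records)
    assert truth.ledger["AFC"].isna().all()
    assert (truth.ledger["AFS"].notna()).any()


def test_derivation_reproduces_truth_ledger_exactly(small_herd):
    _, _, records, truth = small_herd
    table, _ = build_rows(records)
    der = table.set_index(["animal_id", "parity"])
    led = truth.ledger.set_index(["animal_id", "parity"])
    assert led.index.isin(der.index).all()
    for tr in TRAIT_ORDER:
        a = led[tr]
        b = der.loc[led.index, tr]
        same = (a.isna() & b.isna()) | (a == b)
        assert same.all(), tr


def test_same_seed_identical_outputs(small_herd):
    cfg, ped, _, _ = small_herd
    r1, t1 = simulate_service_records(ped, cfg, seed=5)
    r2, t2 = simulate_service_records(ped, cfg, seed=5)
    assert all(
        a.services == b.services and a.calvings == b.calvings and a.diagnoses == b.diagnoses
        for a, b in zip(r1, r2)
    )
    pd.testing.assert_frame_equal(t1.ledger, t2.ledger)
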