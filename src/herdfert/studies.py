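"""Validation studies: parameter recovery, oracle equivalence, exact identities.

Each study simulates data with known truth, runs the estimation machinery,
and returns the measured quantities.  The study conditions (pedigree shape,
variance components, chain lengths) are fixed here; the ``seed`` argument
moves every random draw.

Sizes are desk-scale: pedigrees of ~3,000 animals with ~2,000 phenotyped,
100 sire families per generation (so the realized genetic variance is close
to its parameter), and chains of 20,000 cycles (40,000 with a 10,000-cycle
burn-in where a permanent-environment effect must separate from the additive
one, which mixes slowly under single-site updates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diagnostics import effective_sample_size
from .model import AnimalModel
from .pedigree import Pedigree
from .simulate import (
    HerdSimConfig,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_service_records,
)
from .traits import TRAIT_ORDER, assign_season, build_rows, derive_phenotypes

__all__ = [
    "pedigree_algebra_study",
    "reml_gibbs_study",
    "linear_recovery_study",
    "threshold_recovery_study",
    "correlation_recovery_study",
    "derivation_identity_study",
]


def _subseeds(seed, n):
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ----------------------------------------------------------------------
# pedigree algebra
# ----------------------------------------------------------------------
def _random_pedigree(rng, n):
    """Random acyclic pedigree: later animals draw parents among earlier ones."""
    sires, dams = [None], [None]
    ids = [f"A{j}" for j in range(n)]
    for i in range(1, n):
        if i >= 2 and rng.random() < 0.8:
            s, d = rng.integers(0, i, size=2)
            sires.append(ids[int(s)])
            dams.append(ids[int(d)] if d != s else None)
        else:
            sires.append(None)
            dams.append(None)
    return Pedigree.from_frame(pd.DataFrame({"animal": ids, "sire": sires, "dam": dams}))


def pedigree_algebra_study(seed, n_pedigrees=20, max_animals=500):
    """A / A-inverse / inbreeding consistency on random pedigrees.

    Checks max |A A^-1 - I|, positive semi-definiteness of A,
    diag(A) - 1 == F, the sparsity bound on A^-1, and the textbook
    full-sib-mating inbreeding coefficient.
    """
    rng = np.random.default_rng(seed)
    max_err = 0.0
    min_eig = np.inf
    max_diag_err = 0.0
    sparsity_ok = True
    for _ in range(n_pedigrees):
        n = int(rng.integers(50, max_animals + 1))
        ped = _random_pedigree(rng, n)
        A = ped.relationship_matrix()
        Ainv = ped.a_inverse()
        max_err = max(max_err, np.abs(A @ Ainv.toarray() - np.eye(ped.n)).max())
        min_eig = min(min_eig, float(np.linalg.eigvalsh(A)[0]))
        max_diag_err = max(max_diag_err, np.abs(np.diag(A) - 1.0 - ped.inbreeding()).max())
        sparsity_ok &= Ainv.nnz <= 9 * ped.n
    fs = Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": ["P1", "P2", "S1", "S2", "O"],
                "sire": [None, None, "P1", "P1", "S1"],
                "dam": [None, None, "P2", "P2", "S2"],
            }
        )
    )
    return {
        "max_inverse_error": float(max_err),
        "min_eigenvalue": float(min_eig),
        "max_diag_minus_F_error": float(max_diag_err),
        "sparsity_ok": bool(sparsity_ok),
        "fullsib_mating_F": float(fs.inbreeding()[fs.index["O"]]),
    }


# ----------------------------------------------------------------------
# oracle equivalence and parameter recovery
# ----------------------------------------------------------------------
_PED_BIG = dict(n_founders=1000, n_generations=3, generation_size=1000, n_sires=100)
_PED_COW = dict(n_founders=500, n_generations=3, generation_size=1000, n_sires=100)


def _linear_dataset(seed, G0, R0, traits):
    s1, s2, s3 = _subseeds(seed, 3)
    ped = simulate_pedigree(HerdSimConfig(seed=s1, **_PED_BIG))
    bv = simulate_breeding_values(ped, G0, seed=s2)
    tab, _ = simulate_phenotypes(ped, bv, traits=traits, R0=R0, n_cg=50, cg_sd=0.5, seed=s3)
    return ped, tab


def reml_gibbs_study(seed):
    """Gibbs-vs-AI-REML equivalence on all-linear single- and two-trait data.

    Strongly identified conditions (h2 = 0.5, n = 2,000 phenotyped in a
    3,000-animal pedigree); chains of 20,000 cycles with 4,000 burn-in.
    Returns, per variance component, the |posterior mean - REML| distance in
    units of the posterior SD and of the Monte-Carlo SE of the mean.
    """
    out = {"components": []}
    s_uni, s_biv, s_c1, s_c2 = _subseeds(seed, 4)

    def compare(tag, samples, est):
        sd = samples.std(ddof=1)
        mcse = sd / np.sqrt(effective_sample_size(samples))
        diff = abs(samples.mean() - est)
        out["components"].append(
            {
                "component": tag,
                "gibbs_mean": float(samples.mean()),
                "reml": float(est),
                "posterior_sd_ratio": float(diff / sd),
                "mcse_ratio": float(diff / mcse),
            }
        )

    ped, tab = _linear_dataset(s_uni, np.array([[0.5]]), np.array([[0.5]]), ["T1"])
    m = AnimalModel(tab, ped, traits=["T1"])
    rr = m.fit(method="reml")
    res = m.fit(method="gibbs", n_iter=20_000, burn_in=4_000, thin=10, seed=s_c1)
    compare("uni_s2a", res.G[:, 0, 0], rr.G0[0, 0])
    compare("uni_s2e", res.R[:, 0, 0], rr.R0[0, 0])

    G0 = np.array([[0.5, 0.25], [0.25, 0.5]])
    R0 = np.array([[0.5, 0.1], [0.1, 0.5]])
    ped, tab = _linear_dataset(s_biv, G0, R0, ["T1", "T2"])
    m = AnimalModel(tab, ped, traits=["T1", "T2"])
    rr = m.fit(method="reml")
    res = m.fit(method="gibbs", n_iter=20_000, burn_in=4_000, thin=10, seed=s_c2)
    for k in range(2):
        compare(f"biv{k}_s2a", res.G[:, k, k], rr.G0[k, k])
        compare(f"biv{k}_s2e", res.R[:, k, k], rr.R0[k, k])

    out["max_posterior_sd_ratio"] = max(c["posterior_sd_ratio"] for c in out["components"])
    out["max_mcse_ratio"] = max(c["mcse_ratio"] for c in out["components"])
    return out


def linear_recovery_study(seed, n_seeds=3):
    """Posterior-mean h2 of a linear trait simulated with true h2 = 0.30."""
    h2 = []
    for s in _subseeds(seed, n_seeds):
        ped, tab = _linear_dataset(s, np.array([[0.30]]), np.array([[0.70]]), ["T1"])
        m = AnimalModel(tab, ped, traits=["T1"])
        res = m.fit(method="gibbs", n_iter=20_000, burn_in=4_000, thin=10, seed=s % 100_000)
        h2.append(float(res.summarize().h2_mean[0]))
    return {"true_h2": 0.30, "h2_by_seed": h2, "h2_mean": float(np.mean(h2))}


def _cow_dataset(seed, G0, P0, R0, traits, threshold):
    s1, s2, s3 = _subseeds(seed, 3)
    ped = simulate_pedigree(HerdSimConfig(seed=s1, **_PED_COW))
    bv = simulate_breeding_values(ped, G0, seed=s2)
    tab, _ = simulate_phenotypes(
        ped, bv, traits=traits, R0=R0, P0=P0, threshold=threshold,
        n_cg=50, cg_sd=0.3, records_per_animal=3, seed=s3,
    )
    return ped, tab


def threshold_recovery_study(seed, n_seeds=3):
    """Liability h2 of a binary cow trait simulated with true h2 = 0.25.

    Repeated records (3 per animal) with a permanent-environment effect:
    s2a = 0.25, s2pe = 0.15, s2e = 0.60 on the liability scale.
    """
    h2 = []
    for s in _subseeds(seed, n_seeds):
        ped, tab = _cow_dataset(
            s, np.array([[0.25]]), np.array([[0.15]]), np.array([[0.60]]), ["B1"], ("B1",)
        )
        m = AnimalModel(tab, ped, traits=["B1"], threshold=["B1"], pe_traits=["B1"])
        res = m.fit(method="gibbs", n_iter=40_000, burn_in=10_000, thin=10, seed=s % 100_000)
        h2.append(float(res.summarize().h2_mean[0]))
    return {"true_h2": 0.25, "h2_by_seed": h2, "h2_mean": float(np.mean(h2))}


def correlation_recovery_study(seed, n_seeds=3):
    """Genetic correlation between a linear and a binary cow trait, true 0.70."""
    rg = 0.70
    G0 = np.array([[0.30, rg * np.sqrt(0.30 * 0.25)], [rg * np.sqrt(0.30 * 0.25), 0.25]])
    P0 = np.array([[0.15, 0.05], [0.05, 0.15]])
    R0 = np.array([[0.55, 0.0], [0.0, 0.60]])
    vals = []
    for s in _subseeds(seed, n_seeds):
        ped, tab = _cow_dataset(s, G0, P0, R0, ["T1", "B1"], ("B1",))
        m = AnimalModel(tab, ped, traits=["T1", "B1"], threshold=["B1"],
                        pe_traits=["T1", "B1"])
        res = m.fit(method="gibbs", n_iter=40_000, burn_in=10_000, thin=10, seed=s % 100_000)
        vals.append(float(res.summarize().rg_mean[0, 1]))
    return {"true_rg": rg, "rg_by_seed": vals, "rg_mean": float(np.mean(vals))}


# ----------------------------------------------------------------------
# end-to-end derivation identity
# ----------------------------------------------------------------------
def derivation_identity_study(seed, n_animals=1000):
    """Trait derivation vs the simulator's truth ledger, plus edit-rule audit.

    Simulates service records for ~``n_animals`` females, derives the nine
    traits, and measures (a) the fraction of truth-ledger values reproduced
    exactly and (b) whether every edit rule holds on the edited table.
    """
    s1, s2 = _subseeds(seed, 2)
    gen = max(n_animals // 2, 10)
    cfg = HerdSimConfig(n_founders=gen // 2, n_generations=3, generation_size=gen,
                        n_sires=max(gen // 20, 2), seed=s1)
    ped = simulate_pedigree(cfg)
    records, truth = simulate_service_records(ped, cfg, seed=s2)

    raw, _ = build_rows(records)
    led = truth.ledger.set_index(["animal_id", "parity"])
    der = raw.set_index(["animal_id", "parity"])
    total = matched = 0
    for key in led.index:
        for tr in TRAIT_ORDER:
            a = led.loc[key, tr]
            if pd.isna(a) and (key not in der.index or pd.isna(der.loc[key, tr])):
                continue
            total += 1
            if key in der.index:
                b = der.loc[key, tr]
                matched += int((pd.isna(a) and pd.isna(b)) or a == b)
    table, _ = derive_phenotypes(records)

    cfs, do = table["CFS"], table["DO"]
    both = cfs.notna() & do.notna()
    spc = table["SPC"]
    rules = {
        "cfs_in_bounds": bool(cfs.dropna().between(21, 250).all()),
        "do_in_bounds": bool(do.dropna().between(21, 435).all()),
        "success_coding": bool(
            all(table[tr].dropna().isin([1.0, 2.0]).all() for tr in ("FS80d", "PD100d", "PD200d"))
        ),
        "do_ge_cfs": bool((do[both] >= cfs[both]).all()),
        "do_eq_cfs_iff_spc1": bool(
            ((do[both & spc.notna()] == cfs[both & spc.notna()]) == (spc[both & spc.notna()] == 1)).all()
        ),
        "pd_nesting": bool(
            ((table["PD100d"] == 2) <= (table["PD200d"] == 2))[
                table["PD100d"].notna() & table["PD200d"].notna()
            ].all()
        ),
        "season_boundaries": assign_season(pd.Timestamp("2005-03-31").date()) == "summer"
        and assign_season(pd.Timestamp("2005-04-30").date()) == "winter"
        and assign_season(pd.Timestamp("2005-09-30").date()) == "winter"
        and assign_season(pd.Timestamp("2005-10-01").date()) == "summer",
    }
    return {
        "n_truth_values": int(total),
        "match_fraction": float(matched / total) if total else 1.0,
        "rules": rules,
        "all_rules_hold": bool(all(rules.values())),
        "n_phenotype_rows": int(len(table)),
    }
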