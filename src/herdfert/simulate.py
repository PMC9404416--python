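"""Synthetic herds: pedigrees, service-event records and model-true phenotypes.

Everything needed to exercise the pipeline without farm data:

* :func:`simulate_pedigree` — a multi-generation pedigree with half-sib
  families (small sire pool per generation);
* :func:`simulate_breeding_values` — additive values with covariance
  ``A (x) G0`` generated by Mendelian-sampling recursion (no dense A formed);
* :func:`simulate_phenotypes` — phenotypes generated under the additive +
  permanent-environment + residual animal model, with binary traits produced
  by thresholding the latent liability at zero (coded 1 = no, 2 = yes);
* :func:`simulate_service_records` — an event-level reproduction simulator
  (21-day return cycles, per-service conception, 260-302 d gestation) whose
  per-service conception probability is linked to a fertility liability on
  the probit scale, with a truth ledger of every derivable trait value.

Default reproduction parameters are chosen to give realistic Holstein-like
trait distributions (first service around 16.5 months of age, conception
rate per AI of 0.65 in heifers and 0.45 in cows, 80-day voluntary waiting
period), so the simulated descriptive statistics resemble commercial herds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import datetime as dt

import numpy as np
import pandas as pd
from scipy.stats import norm

from .pedigree import Pedigree, UNKNOWN
from .tables import RawHerdData
from .traits import TRAIT_ORDER, months_between

__all__ = [
    "HerdSimConfig",
    "SimulationTruth",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_service_records",
    "simulate_herd",
]


@dataclass
class HerdSimConfig:
    """Parameters of the synthetic herd.

    Reproduction parameters are in days unless noted; conception
    probabilities are per service.
    """

    n_herds: int = 5
    n_founders: int = 100
    n_generations: int = 3
    generation_size: int = 100
    n_sires: int = 5  # sires used per generation (half-sib families)
    seed: int = 0
    # reproduction
    heat_interval: int = 21
    heat_jitter: int = 3  # uniform +/- days around the return cycle
    conception_probability: float = 0.45  # cows, per service (baseline)
    heifer_conception_probability: float = 0.65
    gestation_mean: float = 280.0
    gestation_sd: float = 5.0
    gestation_range: tuple = (260, 302)
    vwp_days: int = 60  # voluntary waiting period after calving
    heat_detection_rate: float = 0.55  # probability a 21-day heat is seen and served
    first_service_age_months: float = 16.5
    first_service_age_sd_days: float = 60.0
    max_services: int = 8  # cull cap per episode
    n_lactations: int = 3
    liability_sd: float = 0.3  # animal fertility effect on the probit scale
    fertility_h2: float = 0.3  # heritable fraction of that effect
    diagnosis_delay_days: int = 40
    base_year: int = 1995
    generation_gap_days: int = 900


@dataclass
class SimulationTruth:
    """Ground truth bookkept by the simulator.

    ``ledger`` holds one row per (animal, parity, trait) with the value the
    derivation stage must reproduce exactly from the emitted events.
    """

    G0: np.ndarray | None = None
    P0: np.ndarray | None = None
    R0: np.ndarray | None = None
    breeding_values: pd.DataFrame | None = None
    fixed_effects: dict = field(default_factory=dict)
    fertility_effect: pd.Series | None = None
    ledger: pd.DataFrame | None = None


# ----------------------------------------------------------------------
# pedigree
# ----------------------------------------------------------------------
def simulate_pedigree(config: HerdSimConfig, rng=None) -> Pedigree:
    """Discrete-generation pedigree with half-sib families.

    Generation 0 holds ``n_founders`` unrelated animals; each later
    generation has ``generation_size`` animals whose sires come from a pool
    of ``n_sires`` males of the previous generation and whose dams are
    sampled from its females.  Birth dates are spread within each
    generation's year band, so seasons vary.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if config.n_founders < 2 or config.n_generations < 1:
        raise ValueError("need n_founders >= 2 and n_generations >= 1")
    base = dt.date(config.base_year, 1, 1).toordinal()
    ids, sires, dams, births, sexes, herds = [], [], [], [], [], []

    def add(gen, i, s, d):
        aid = f"G{gen}A{i:05d}"
        ids.append(aid)
        sires.append(s)
        dams.append(d)
        births.append(base + gen * config.generation_gap_days + int(rng.integers(0, 365)))
        sexes.append("M" if (gen_males_left[0] > 0) else "F")
        gen_males_left[0] -= 1
        herds.append(f"H{int(rng.integers(1, config.n_herds + 1))}")
        return aid

    prev_males, prev_females = [], []
    n0 = config.n_founders
    for gen in range(config.n_generations):
        size = n0 if gen == 0 else config.generation_size
        n_males = max(config.n_sires, 1)
        gen_males_left = [n_males]
        males, females = [], []
        for i in range(size):
            if gen == 0:
                aid = add(gen, i, None, None)
            else:
                s = prev_males[int(rng.integers(0, len(prev_males)))]
                d = prev_females[int(rng.integers(0, len(prev_females)))]
                aid = add(gen, i, s, d)
            (males if sexes[-1] == "M" else females).append(aid)
        prev_males, prev_females = males, females
    df = pd.DataFrame(
        {
            "animal": ids,
            "sire": sires,
            "dam": dams,
            "birth_date": [dt.date.fromordinal(b).isoformat() for b in births],
        }
    )
    ped = Pedigree.from_frame(df)
    ped.meta = {
        "sex": dict(zip(ids, sexes)),
        "herd": dict(zip(ids, herds)),
        "generation": {a: int(a[1:].split("A")[0]) for a in ids},
    }
    return ped


# ----------------------------------------------------------------------
# breeding values
# ----------------------------------------------------------------------
def simulate_breeding_values(ped: Pedigree, G0, seed: int) -> np.ndarray:
    """Additive values with covariance A (x) G0 via Mendelian sampling.

    Founders are N(0, G0); a non-founder is the parent average plus a
    Mendelian deviation with covariance ``d_i * G0`` where ``d_i`` is the
    inbreeding-adjusted sampling variance.  Returns an (n_animals, t) array
    in pedigree order.
    """
    G0 = np.atleast_2d(np.asarray(G0, dtype=float))
    t = G0.shape[0]
    eig = np.linalg.eigvalsh(G0)
    if eig.min() < -1e-10:
        raise ValueError("G0 is not positive semi-definite")
    L = np.linalg.cholesky(G0 + 1e-12 * np.eye(t)) if eig.min() < 1e-14 else np.linalg.cholesky(G0)
    if np.allclose(G0, 0):
        return np.zeros((ped.n, t))
    rng = np.random.default_rng(seed)
    d = ped.mendelian_variance()
    bv = np.zeros((ped.n, t))
    z = rng.standard_normal((ped.n, t))
    for i in range(ped.n):
        mean = np.zeros(t)
        if ped.sire[i] != UNKNOWN:
            mean += 0.5 * bv[ped.sire[i]]
        if ped.dam[i] != UNKNOWN:
            mean += 0.5 * bv[ped.dam[i]]
        bv[i] = mean + np.sqrt(d[i]) * (L @ z[i])
    return bv


# ----------------------------------------------------------------------
# model-true phenotypes
# ----------------------------------------------------------------------
def simulate_phenotypes(
    ped: Pedigree,
    bv: np.ndarray,
    *,
    traits,
    R0,
    P0=None,
    threshold=(),
    n_cg: int = 50,
    cg_sd: float = 0.5,
    records_per_animal: int = 1,
    phenotyped=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Phenotypes under the animal model, with liability thresholding.

    Each phenotyped animal gets ``records_per_animal`` records of
    ``y = cg + a + pe + e`` per trait; traits in ``threshold`` are converted
    to 1/2 by the sign of the latent liability.  ``phenotyped`` defaults to
    animals with both parents known (non-founders).
    """
    rng = np.random.default_rng(seed)
    traits = list(traits)
    t = len(traits)
    R0 = np.atleast_2d(np.asarray(R0, dtype=float))
    P0 = None if P0 is None else np.atleast_2d(np.asarray(P0, dtype=float))
    if phenotyped is None:
        phenotyped = np.flatnonzero((ped.sire != UNKNOWN) & (ped.dam != UNKNOWN))
    else:
        phenotyped = np.asarray([ped.index[str(a)] for a in phenotyped])
    m = len(phenotyped)
    cg_eff = rng.normal(0.0, cg_sd, size=(n_cg, t))
    cg_of = rng.integers(0, n_cg, size=m)
    Lr = np.linalg.cholesky(R0 + 1e-12 * np.eye(t))
    pe = np.zeros((m, t))
    if P0 is not None and P0.any():
        pe = rng.standard_normal((m, t)) @ np.linalg.cholesky(P0 + 1e-12 * np.eye(t)).T
    rows = []
    liab_rows = []
    for rep in range(records_per_animal):
        e = rng.standard_normal((m, t)) @ Lr.T if R0.any() else np.zeros((m, t))
        y = cg_eff[cg_of] + bv[phenotyped][:, :t] + pe + e
        liab_rows.append(y.copy())
        for r, idx in enumerate(phenotyped):
            row = {
                "animal_id": ped.ids[idx],
                "parity": rep + 1,
                "row_type": "sim",
                "cg_code": f"CG{cg_of[r]:03d}",
                "age_months": np.nan,
            }
            for k, tr in enumerate(traits):
                v = y[r, k]
                row[tr] = (2.0 if v > 0 else 1.0) if tr in threshold else v
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = SimulationTruth(
        G0=None,
        P0=P0,
        R0=R0,
        breeding_values=pd.DataFrame(bv[phenotyped][:, :t], columns=traits,
                                     index=ped.ids[phenotyped]),
        fixed_effects={"cg": cg_eff},
    )
    truth.liabilities = np.concatenate(liab_rows, axis=0)
    return table, truth


# ----------------------------------------------------------------------
# event-level service records
# ----------------------------------------------------------------------
def simulate_service_records(
    ped: Pedigree, config: HerdSimConfig, seed: int | None = None
) -> tuple[list, SimulationTruth]:
    """Per-female reproductive event histories with a truth ledger.

    First service at the rearing-policy age plus an animal deviation;
    services repeat on a ~21-day return cycle until conception or the cull
    cap; conception per service is Bernoulli with probability
    ``Phi(probit(p0) + u)`` where ``u`` is the animal's fertility liability;
    calving follows at a truncated-normal gestation; later lactations repeat
    after a voluntary waiting period.  A pregnant diagnosis is emitted after
    each conception.  The ledger records every trait value the derivation
    stage should recover.
    """
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    sex = getattr(ped, "meta", {}).get("sex", {})
    herd_of = getattr(ped, "meta", {}).get("herd", {})
    females = [
        i
        for i in range(ped.n)
        if sex.get(ped.ids[i], "F") == "F" and np.isfinite(ped.birth[i])
    ]
    # fertility liability = heritable part (through the pedigree) + animal
    # environment, total SD = liability_sd on the probit scale
    var_a = config.fertility_h2 * config.liability_sd**2
    a = simulate_breeding_values(ped, np.array([[var_a]]), seed=(base_seed + 104729) % 2**31)
    env_sd = config.liability_sd * np.sqrt(max(1.0 - config.fertility_h2, 0.0))
    u = pd.Series(
        a[females, 0] + rng.normal(0.0, env_sd, size=len(females)),
        index=[ped.ids[i] for i in females],
    )
    gmin, gmax = config.gestation_range
    records, ledger = [], []

    def gestation():
        while True:
            g = rng.normal(config.gestation_mean, config.gestation_sd)
            if gmin <= g <= gmax:
                return int(round(g))

    def jitter():
        return int(rng.integers(-config.heat_jitter, config.heat_jitter + 1))

    def detected_heat(day):
        # heats recur every ~21 d; each is seen (and served) with the
        # detection rate, so service delays are geometric in whole cycles
        while rng.random() > config.heat_detection_rate:
            day += config.heat_interval + jitter()
        return day

    z0h = norm.ppf(config.heifer_conception_probability)
    z0c = norm.ppf(config.conception_probability)
    for i in females:
        aid = ped.ids[i]
        birth = dt.date.fromordinal(int(ped.birth[i]))
        rec = RawHerdData(
            animal_id=aid,
            herd_id=herd_of.get(aid, "H1"),
            birth_date=birth,
            sire_id=ped.ids[ped.sire[i]] if ped.sire[i] != UNKNOWN else None,
            dam_id=ped.ids[ped.dam[i]] if ped.dam[i] != UNKNOWN else None,
        )
        first_age = config.first_service_age_months * 30.4375 + rng.normal(
            0.0, config.first_service_age_sd_days
        )
        day = birth.toordinal() + max(int(round(first_age)), 300)
        lact = 0
        entry = {"animal_id": aid, "parity": 1}
        # heifer episode then cow lactations
        while lact <= config.n_lactations:
            p = norm.cdf((z0h if lact == 0 else z0c) + u[aid])
            n_serv, conceived, first_service, conception = 0, False, None, None
            while n_serv < config.max_services:
                d = dt.date.fromordinal(day)
                n_serv += 1
                if first_service is None:
                    first_service = d
                success = rng.random() < p
                rec.services.append((d, "success" if success else "failure"))
                if success:
                    conceived, conception = True, d
                    break
                day = detected_heat(day + config.heat_interval + jitter())
            if lact == 0:
                entry["AFS"] = months_between(birth, first_service)
                entry["age_months"] = entry["AFS"]
            else:
                c0 = rec.calvings[-1][0]
                cfs = first_service.toordinal() - c0.toordinal()
                ledger_row = {
                    "animal_id": aid,
                    "parity": lact + 1,
                    "CFS": float(cfs),
                    "FS80d": 2.0 if cfs <= 80 else 1.0,
                    "age_months": months_between(birth, c0),
                }
                if conceived:
                    do = conception.toordinal() - c0.toordinal()
                    ledger_row.update(
                        DO=float(do),
                        SPC=float(n_serv),
                        PD100d=2.0 if do <= 100 else 1.0,
                        PD200d=2.0 if do <= 200 else 1.0,
                    )
                ledger.append(ledger_row)
            if not conceived:
                break
            diag = conception.toordinal() + config.diagnosis_delay_days
            calv_day = conception.toordinal() + gestation()
            if diag < calv_day:
                rec.diagnoses.append((dt.date.fromordinal(diag), "pregnant"))
            lact += 1
            calv = dt.date.fromordinal(calv_day)
            rec.calvings.append((calv, lact))
            if lact == 1:
                entry["AFC"] = months_between(birth, calv)
                entry["SPCh"] = float(n_serv)
            if lact >= config.n_lactations:
                break
            day = detected_heat(
                calv_day + config.vwp_days + int(rng.integers(0, config.heat_interval))
            )
        if "AFS" in entry:
            ledger.append(entry)
        records.append(rec)

    cols = ["animal_id", "parity", "age_months"] + TRAIT_ORDER
    ldf = pd.DataFrame(ledger).reindex(columns=cols)
    ldf = ldf.sort_values(["animal_id", "parity"], kind="stable").reset_index(drop=True)
    truth = SimulationTruth(
        fertility_effect=u,
        breeding_values=pd.DataFrame({"fertility": a[:, 0]}, index=ped.ids),
        ledger=ldf,
    )
    return records, truth


def simulate_herd(config: HerdSimConfig):
    """Pedigree + service records + truth in one call (same seed semantics)."""
    ped = simulate_pedigree(config)
    records, truth = simulate_service_records(ped, config, seed=config.seed + 1)
    return ped, records, truth
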