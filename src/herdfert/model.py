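"""Multi-trait animal models: model object, fits and posterior summaries.

:class:`AnimalModel` is built from a phenotype table and a pedigree, in the
spirit of statsmodels model classes: the constructor assembles the design
(fixed effects, additive and permanent-environment maps, the sparse inverse
relationship matrix), and :meth:`AnimalModel.fit` returns a results object —
:class:`GibbsResults` for the Bayesian threshold-capable path or
:class:`REMLResults` for the all-linear AI-REML cross-check.

Fixed-effect structure follows dairy-fertility convention: a contemporary
group (herd-year-season) factor for every trait, a parity class for cow
traits, and an age covariate (age at insemination for heifer conception
count, age at calving for cow traits).  Heritability is
``h2 = s2_a / (s2_a + s2_pe + s2_e)`` with the permanent-environment term
present only for traits with repeated records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gibbs as _gibbs
from . import reml as _reml
from .pedigree import Pedigree
from .traits import TRAITS

__all__ = [
    "AnimalModel",
    "GibbsResults",
    "REMLResults",
    "GeneticParameterSummary",
    "summarize_samples",
]


def _csr_groups(codes, ngroups):
    """CSR (indptr, indices) mapping group -> member record positions."""
    codes = np.asarray(codes)
    order = np.argsort(codes, kind="stable")
    valid = codes[order] >= 0
    order = order[valid]
    counts = np.bincount(codes[codes >= 0], minlength=ngroups)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return indptr.astype(np.int64), order.astype(np.int64)


class AnimalModel:
    """Pedigree-based mixed model for a set of fertility traits.

    Parameters
    ----------
    phenotypes : DataFrame
        One row per heifer or per cow-lactation record; needs ``animal_id``,
        ``cg_code`` and one column per requested trait (NaN = missing).
        ``row_type`` ("heifer"/"cow") controls which traits a record's fixed
        effects apply to; simulated tables may use a single type.
    pedigree : Pedigree
        Must contain every phenotyped animal; it is pruned to the phenotyped
        animals and their ancestors.
    traits : list of str
        Analysis traits, in reporting order.
    threshold : list of str, optional
        Traits treated as binary on the liability scale (coded 1/2).
        Defaults to the success traits among ``traits``.
    pe_traits : list of str, optional
        Traits with a permanent-environment effect (repeated records).
        Defaults to the cow traits among ``traits`` when the table actually
        has repeated cow rows.
    """

    def __init__(self, phenotypes, pedigree: Pedigree, traits, threshold=None, pe_traits=None):
        self.traits = list(traits)
        t = len(self.traits)
        for tr in self.traits:
            if tr not in phenotypes.columns:
                raise ValueError(f"trait {tr!r} absent from the phenotype table")
        if threshold is None:
            threshold = [
                tr for tr in self.traits if tr in TRAITS and TRAITS[tr].category == "success"
            ]
        self.threshold = list(threshold)

        df = phenotypes.copy()
        if "row_type" not in df.columns:
            df["row_type"] = "sim"
        if "parity" not in df.columns:
            df["parity"] = 1
        keep = df[self.traits].notna().any(axis=1) & df["cg_code"].notna()
        df = df[keep]
        df = df.sort_values(
            ["animal_id", "row_type", "parity", "cg_code"], kind="stable"
        ).reset_index(drop=True)
        self.data = df
        n = len(df)
        if n == 0:
            raise ValueError("no usable records")

        missing_ped = sorted(set(df["animal_id"].astype(str)) - set(map(str, pedigree.ids)))
        if missing_ped:
            raise ValueError(f"animals missing from pedigree: {missing_ped[:10]}")
        self.pedigree = pedigree.prune(df["animal_id"].unique(), drop_unknown_birth=False)
        self._ainv = self.pedigree.a_inverse()
        an_of = self.pedigree.index
        rec_animal = np.array([an_of[str(a)] for a in df["animal_id"]], dtype=np.int64)

        if pe_traits is None:
            cow = [tr for tr in self.traits if tr in TRAITS and TRAITS[tr].animal_class == "cow"]
            cow_rows = df[df["row_type"] == "cow"]
            repeated = len(cow_rows) and cow_rows["animal_id"].duplicated().any()
            pe_traits = cow if (cow and repeated) else []
        self.pe_traits = list(pe_traits)

        # trait applicability per record (which rows carry the trait's effects)
        applies = np.zeros((n, t), dtype=bool)
        row_type = df["row_type"].to_numpy()
        for k, tr in enumerate(self.traits):
            if tr in TRAITS:
                applies[:, k] = (row_type == TRAITS[tr].animal_class) | (row_type == "sim")
            else:
                applies[:, k] = True

        # responses and augmentation status codes
        y = np.zeros((n, t))
        status = np.zeros((n, t), dtype=np.int8)
        vhat = np.ones(t)
        for k, tr in enumerate(self.traits):
            v = df[tr].to_numpy(dtype=float)
            obs = ~np.isnan(v)
            if tr in self.threshold:
                bad = obs & ~np.isin(v, (1.0, 2.0))
                if bad.any():
                    raise ValueError(f"success trait {tr} has values outside {{1, 2}}")
                status[:, k] = np.where(obs, np.where(v == 1.0, 2, 3), 1)
                y[:, k] = np.where(obs, np.where(v == 1.0, -0.7, 0.7), 0.0)
            else:
                status[:, k] = np.where(obs, 0, 1)
                mean = v[obs].mean() if obs.any() else 0.0
                vhat[k] = v[obs].var() if obs.sum() > 1 else 1.0
                y[:, k] = np.where(obs, v, mean)
        self._observed = status == 0
        self._obs_any = ~np.isnan(df[self.traits].to_numpy(dtype=float))

        # fixed effects: CG always; parity class and age covariate by convention
        eff_trait, eff_levels, eff_names = [], [], []
        cov_trait, cov_x, cov_names = [], [], []
        age = df["age_months"].to_numpy(dtype=float) if "age_months" in df.columns else np.full(n, np.nan)
        parity = df["parity"].to_numpy()
        for k, tr in enumerate(self.traits):
            app = applies[:, k]
            cg = np.where(app, df["cg_code"].astype(str), None)
            levels = pd.unique(pd.Series([c for c in cg if c is not None]).sort_values())
            lev_of = {c: i for i, c in enumerate(levels)}
            eff_trait.append(k)
            eff_levels.append(np.array([lev_of.get(c, -1) for c in cg], dtype=np.int32))
            eff_names.append((tr, "cg", list(levels)))
            is_cow = tr in TRAITS and TRAITS[tr].animal_class == "cow"
            if is_cow:
                pclass = np.where(app, np.minimum(parity, 5), -1)
                plevels = sorted({int(p) for p in pclass[pclass >= 0]})
                if len(plevels) > 1:
                    pof = {p: i - 1 for i, p in enumerate(plevels)}  # drop-first reference
                    eff_trait.append(k)
                    eff_levels.append(
                        np.array([pof[int(p)] if p >= 0 else -1 for p in pclass], dtype=np.int32)
                    )
                    eff_names.append((tr, "parity", [str(p) for p in plevels[1:]]))
            if (is_cow or tr == "SPCh") and np.isfinite(age[app & self._observed[:, k]]).any():
                x = np.where(app & np.isfinite(age), age, np.nan)
                center = np.nanmean(np.where(self._observed[:, k], x, np.nan))
                xc = np.where(np.isfinite(x), x - center, 0.0)
                cov_trait.append(k)
                cov_x.append(xc)
                cov_names.append((tr, "age_months"))

        n_eff = len(eff_trait)
        nlev = [len(nm[2]) for nm in eff_names]
        eff_offset = np.concatenate([[0], np.cumsum(nlev)]).astype(np.int64)
        an_indptr, an_recs = _csr_groups(rec_animal, self.pedigree.n)

        # permanent-environment levels: one per animal with applicable records
        pe_idx = np.array(
            [k for k, tr in enumerate(self.traits) if tr in self.pe_traits], dtype=np.int64
        )
        if len(pe_idx):
            pe_applicable = applies[:, pe_idx[0]]
            pe_animals = pd.unique(df["animal_id"][pe_applicable])
            pe_of = {a: i for i, a in enumerate(pe_animals)}
            rec_pe = np.array(
                [pe_of.get(a, -1) if ap else -1 for a, ap in zip(df["animal_id"], pe_applicable)],
                dtype=np.int64,
            )
            pe_indptr, pe_recs = _csr_groups(rec_pe, len(pe_animals))
        else:
            rec_pe = np.full(n, -1, dtype=np.int64)
            pe_indptr, pe_recs = np.zeros(1, dtype=np.int64), np.zeros(0, dtype=np.int64)

        ainv = self._ainv.tocsr()
        self._design = {
            "y": y,
            "status": status,
            "eff_trait": np.array(eff_trait, dtype=np.int64),
            "eff_offset": eff_offset,
            "eff_levels": np.vstack(eff_levels) if n_eff else np.zeros((0, n), dtype=np.int32),
            "eff_names": eff_names,
            "cov_trait": np.array(cov_trait, dtype=np.int64),
            "cov_x": np.vstack(cov_x) if cov_x else np.zeros((0, n)),
            "cov_names": cov_names,
            "rec_animal": rec_animal,
            "an_indptr": an_indptr,
            "an_recs": an_recs,
            "rec_pe": rec_pe,
            "pe_indptr": pe_indptr,
            "pe_recs": pe_recs,
            "pe_traits": pe_idx,
            "ai_indptr": ainv.indptr.astype(np.int64),
            "ai_indices": ainv.indices.astype(np.int64),
            "ai_data": ainv.data.astype(np.float64),
            "is_thresh": np.array(
                [1 if tr in self.threshold else 0 for tr in self.traits], dtype=np.uint8
            ),
            "applies": applies,
            "vhat": vhat,
        }

    # ------------------------------------------------------------------
    @property
    def design(self) -> dict:
        """The assembled mixed-model components (read-only view)."""
        return self._design

    @property
    def n_records(self) -> int:
        return self._design["y"].shape[0]

    def default_priors(self, kind: str = "flat"):
        """Priors for the covariance matrices.

        ``"flat"`` (default) is the animal-breeding convention: a constant
        prior on each covariance matrix, i.e. inverse-Wishart with degrees of
        freedom ``-(dim + 1)`` and zero scale, so the posterior is driven by
        the data cross-products alone and posterior means track REML.
        ``"weak"`` gives proper weakly-informative inverse-Wisharts
        (df = dim + 1, scale 0.1 x the observed phenotypic variances; 1 on
        the liability scale) for small or poorly-anchored datasets.
        """
        t = len(self.traits)
        vhat = self._design["vhat"]
        pe_idx = self._design["pe_traits"]
        tpe = len(pe_idx)
        if kind == "flat":
            Z = np.zeros((t, t))
            Zp = np.zeros((tpe, tpe)) if tpe else np.ones((1, 1))
            return (-(t + 1), Z, -(max(tpe, 1) + 1), Zp, -(t + 1), Z.copy())
        S_g = 0.1 * np.diag(vhat)
        S_p = 0.1 * np.diag(vhat[pe_idx]) if tpe else np.ones((1, 1))
        S_r = 0.1 * np.diag(vhat)
        return (t + 1, S_g, max(tpe, 1) + 1, S_p, t + 1, S_r)

    def default_start(self):
        vhat = self._design["vhat"]
        pe_idx = self._design["pe_traits"]
        G0 = 0.3 * np.diag(vhat)
        P0 = 0.2 * np.diag(vhat[pe_idx]) if len(pe_idx) else None
        R0 = 0.5 * np.diag(vhat)
        return G0, P0, R0

    # ------------------------------------------------------------------
    def fit(
        self,
        method: str = "gibbs",
        n_iter: int = 300_000,
        burn_in: int = 50_000,
        thin: int = 10,
        seed: int = 0,
        start=None,
        priors=None,
        max_iter: int = 50,
    ):
        """Fit the model.

        ``method="gibbs"`` runs a single chain (default 300,000 cycles with a
        50,000-cycle burn-in, thinned by 10) and returns
        :class:`GibbsResults`; ``method="reml"`` runs dense AI-REML on the
        complete all-linear records and returns :class:`REMLResults`.
        """
        if method == "gibbs":
            G0, P0, R0 = start if start is not None else self.default_start()
            pri = priors if priors is not None else self.default_priors()
            G, P, R = _gibbs.run_chain(
                self._design, G0, P0, R0, pri, n_iter, burn_in, thin, seed
            )
            return GibbsResults(
                model=self,
                G=G,
                P=P,
                R=R,
                config={"n_iter": n_iter, "burn_in": burn_in, "thin": thin, "seed": seed},
            )
        if method == "reml":
            return self._fit_reml(start=start, max_iter=max_iter)
        raise ValueError(f"unknown method {method!r}")

    # ------------------------------------------------------------------
    def _reml_design(self):
        if self.threshold:
            raise _reml.REMLError(
                "the REML path does not allow categorical traits; use the Gibbs sampler"
            )
        d = self._design
        complete = self._obs_any.all(axis=1)
        if not complete.any():
            raise _reml.REMLError("no complete records for REML")
        idx = np.flatnonzero(complete)
        n, t = len(idx), len(self.traits)
        y = d["y"][idx]
        # dense X: per effect the levels present on complete records
        cols = []
        for j in range(len(d["eff_trait"])):
            k = d["eff_trait"][j]
            lev = d["eff_levels"][j, idx]
            for l in np.unique(lev[lev >= 0]):
                col = np.zeros((n, t))
                col[lev == l, k] = 1.0
                cols.append(col.reshape(-1))
        for c in range(len(d["cov_trait"])):
            k = d["cov_trait"][c]
            col = np.zeros((n, t))
            col[:, k] = d["cov_x"][c, idx]
            if np.any(col):
                cols.append(col.reshape(-1))
        X = np.column_stack(cols)
        A = self.pedigree.relationship_matrix()
        an = d["rec_animal"][idx]
        Arec = A[np.ix_(an, an)]
        Pemat = None
        if len(d["pe_traits"]):
            pe = d["rec_pe"][idx]
            Pemat = ((pe[:, None] == pe[None, :]) & (pe[:, None] >= 0)).astype(float)
        return y, X, Arec, Pemat

    def _fit_reml(self, start=None, max_iter=50):
        y, X, Arec, Pemat = self._reml_design()
        pe_idx = self._design["pe_traits"]
        if start is not None:
            G0, P0, R0 = start
        else:
            G0, P0, R0 = self.default_start()
        fit = _reml.ai_reml(
            y,
            X,
            Arec,
            G0=np.asarray(G0, dtype=float),
            R0=np.asarray(R0, dtype=float),
            P0=None if P0 is None else np.asarray(P0, dtype=float),
            Pemat=Pemat,
            pe_traits=pe_idx,
            max_iter=max_iter,
        )
        return REMLResults(model=self, fit=fit)


# ----------------------------------------------------------------------
# posterior summaries
# ----------------------------------------------------------------------
@dataclass
class GeneticParameterSummary:
    """Posterior means and SDs of h2, genetic and phenotypic correlations."""

    traits: list
    h2_mean: np.ndarray
    h2_sd: np.ndarray
    rg_mean: np.ndarray
    rg_sd: np.ndarray
    rp_mean: np.ndarray
    rp_sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.traits):
            rows.append((a, a, "h2", self.h2_mean[i], self.h2_sd[i]))
            for j in range(i + 1, len(self.traits)):
                b = self.traits[j]
                rows.append((a, b, "rg", self.rg_mean[i, j], self.rg_sd[i, j]))
                rows.append((a, b, "rp", self.rp_mean[i, j], self.rp_sd[i, j]))
        return pd.DataFrame(
            rows, columns=["trait_a", "trait_b", "statistic", "posterior_mean", "posterior_sd"]
        )


def _embed_pe(P, pe_idx, t):
    full = np.zeros((P.shape[0], t, t))
    if P is not None and len(pe_idx):
        full[np.ix_(range(P.shape[0]), pe_idx, pe_idx)] = P
    return full


def summarize_samples(G, P, R, traits, pe_idx=(), burn_in=0, thin=1) -> GeneticParameterSummary:
    """Ratio-then-average posterior summary of saved covariance samples.

    h2, rg and rp are computed at every saved iteration (after an optional
    extra ``burn_in``/``thin`` in saved-sample units) and then averaged; the
    SD is across those per-iteration values.  The pe variance enters the h2
    denominator only for the traits that carry a pe effect.
    """
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    if G.ndim == 2:
        G, R = G[None], R[None]
        P = None if P is None else np.asarray(P, dtype=float)[None]
    sl = slice(burn_in, None, thin)
    G, R = G[sl], R[sl]
    P = None if P is None else np.asarray(P, dtype=float)[sl]
    if G.shape[0] == 0:
        raise ValueError("no post-burn-in samples to summarize")
    t = G.shape[1]
    pe_idx = np.asarray(pe_idx, dtype=int)
    Pfull = _embed_pe(P, pe_idx, t) if P is not None else np.zeros_like(G)
    T = G + Pfull + R
    dg = np.sqrt(np.einsum("skk->sk", G))
    dt_ = np.sqrt(np.einsum("skk->sk", T))
    h2 = np.einsum("skk->sk", G) / np.einsum("skk->sk", T)
    rg = G / (dg[:, :, None] * dg[:, None, :])
    rp = T / (dt_[:, :, None] * dt_[:, None, :])
    return GeneticParameterSummary(
        traits=list(traits),
        h2_mean=h2.mean(axis=0),
        h2_sd=h2.std(axis=0, ddof=1) if h2.shape[0] > 1 else np.zeros(t),
        rg_mean=rg.mean(axis=0),
        rg_sd=rg.std(axis=0, ddof=1) if rg.shape[0] > 1 else np.zeros((t, t)),
        rp_mean=rp.mean(axis=0),
        rp_sd=rp.std(axis=0, ddof=1) if rp.shape[0] > 1 else np.zeros((t, t)),
    )


@dataclass
class GibbsResults:
    """Saved covariance samples from one Gibbs chain, with summaries.

    ``G``/``P``/``R`` are (n_saved, t, t) (P over the pe-trait subset).
    """

    model: AnimalModel
    G: np.ndarray
    P: np.ndarray | None
    R: np.ndarray
    config: dict

    @property
    def traits(self):
        return self.model.traits

    @property
    def n_saved(self) -> int:
        return self.G.shape[0]

    def summarize(self, burn_in: int = 0, thin: int = 1) -> GeneticParameterSummary:
        return summarize_samples(
            self.G, self.P, self.R, self.traits, self.model._design["pe_traits"], burn_in, thin
        )

    def posterior_mean(self, comp: str = "G") -> np.ndarray:
        return {"G": self.G, "P": self.P, "R": self.R}[comp].mean(axis=0)

    def h2_samples(self) -> np.ndarray:
        t = len(self.traits)
        pe_idx = self.model._design["pe_traits"]
        Pfull = _embed_pe(self.P, pe_idx, t) if self.P is not None else np.zeros_like(self.G)
        T = self.G + Pfull + self.R
        return np.einsum("skk->sk", self.G) / np.einsum("skk->sk", T)

    def rg_samples(self) -> np.ndarray:
        dg = np.sqrt(np.einsum("skk->sk", self.G))
        return self.G / (dg[:, :, None] * dg[:, None, :])

    def samples_frame(self) -> pd.DataFrame:
        """Long-format saved samples: iteration, component, trait_i, trait_j, value."""
        cfg = self.config
        rows = []
        pe_idx = self.model._design["pe_traits"]
        pe_names = [self.traits[k] for k in pe_idx]
        for s in range(self.n_saved):
            it = cfg["burn_in"] + (s + 1) * cfg["thin"]
            for arr, names, comp in (
                (self.G[s], self.traits, "G"),
                (self.R[s], self.traits, "R"),
            ):
                for i, a in enumerate(names):
                    for j in range(i, len(names)):
                        rows.append((it, comp, a, names[j], arr[i, j]))
            if self.P is not None:
                for i, a in enumerate(pe_names):
                    for j in range(i, len(pe_names)):
                        rows.append((it, "P", a, pe_names[j], self.P[s][i, j]))
        return pd.DataFrame(rows, columns=["iteration", "component", "trait_i", "trait_j", "value"])

    def diagnostics(self) -> pd.DataFrame:
        from .diagnostics import diagnostics_frame

        return diagnostics_frame(self)

    def summary(self) -> str:
        s = self.summarize()
        lines = [
            "Multi-trait animal model (Gibbs)",
            f"  traits: {', '.join(self.traits)}"
            + (f"  (threshold: {', '.join(self.model.threshold)})" if self.model.threshold else ""),
            f"  records: {self.model.n_records}   animals in pedigree: {self.model.pedigree.n}",
            "  chain: {n_iter} cycles, burn-in {burn_in}, thinning {thin}, seed {seed}".format(
                **self.config
            ),
            "",
            f"  {'trait':<8} {'h2':>8} {'sd':>8}",
        ]
        for i, tr in enumerate(self.traits):
            lines.append(f"  {tr:<8} {s.h2_mean[i]:8.3f} {s.h2_sd[i]:8.3f}")
        if len(self.traits) > 1:
            lines.append("")
            lines.append("  genetic (above) / phenotypic (below) correlations:")
            t = len(self.traits)
            hdr = "  " + " " * 8 + "".join(f"{tr:>9}" for tr in self.traits)
            lines.append(hdr)
            for i in range(t):
                cells = []
                for j in range(t):
                    if j > i:
                        cells.append(f"{s.rg_mean[i, j]:9.3f}")
                    elif j < i:
                        cells.append(f"{s.rp_mean[i, j]:9.3f}")
                    else:
                        cells.append(f"{'.':>9}")
                lines.append(f"  {self.traits[i]:<8}" + "".join(cells))
        return "\n".join(lines)


@dataclass
class REMLResults:
    """AI-REML variance-component estimates for all-linear models."""

    model: AnimalModel
    fit: _reml.REMLFit

    @property
    def traits(self):
        return self.model.traits

    @property
    def G0(self):
        return self.fit.G0

    @property
    def P0(self):
        return self.fit.P0

    @property
    def R0(self):
        return self.fit.R0

    @property
    def converged(self):
        return self.fit.converged

    @property
    def warnings(self):
        return self.fit.warnings

    def h2(self) -> np.ndarray:
        t = len(self.traits)
        pe_idx = self.model._design["pe_traits"]
        Pfull = np.zeros((t, t))
        if self.P0 is not None and len(pe_idx):
            Pfull[np.ix_(pe_idx, pe_idx)] = self.P0
        T = self.G0 + Pfull + self.R0
        return np.diag(self.G0) / np.diag(T)

    def rg(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.G0))
        return self.G0 / np.outer(d, d)

    def se(self, comp: str, k: int, l: int | None = None) -> float:
        return self.fit.se(comp, k, k if l is None else l)

    def summary(self) -> str:
        lines = [
            "Multi-trait animal model (AI-REML)",
            f"  traits: {', '.join(self.traits)}",
            f"  logL: {self.fit.loglik:.4f}  iterations: {self.fit.n_iter}"
            f"  converged: {self.fit.converged}",
        ]
        for w in self.fit.warnings:
            lines.append(f"  warning: {w}")
        h2 = self.h2()
        for i, tr in enumerate(self.traits):
            lines.append(
                f"  {tr:<8} s2_a={self.G0[i, i]:.4f} (se {self.se('G0', i):.4f})"
                f"  s2_e={self.R0[i, i]:.4f}  h2={h2[i]:.3f}"
            )
        return "\n".join(lines)
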