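"""Experiment driver and validation metrics for single-step genomic prediction.

Four nested models are compared on identical inputs:

================  =================  ==========================
model             G-matrix weights   pQTN fixed covariates
================  =================  ==========================
ssgblup           none (Gu)          no
ssgblup-pqtn      none (Gu)          yes (forward-CV selected)
ssgwablup         GWAS posterior PP  no
ssgwablup-pqtn    GWAS posterior PP  yes
================  =================  ==========================

All four share one EMMAX scan per training set: the smoothed-LR posterior
probabilities weight the G matrix, and the same scan's p-value ranking
seeds the pQTN candidate list.  In simulation mode the last generation is
the validation set and predictions are scored against true breeding values
with three metrics: Pearson correlation, bias = mean(GEBV) - mean(TBV),
and dispersion = Cov(GEBV, TBV) / Var(TBV) (the regression slope of GEBV
on TBV; 1 means neither inflation nor deflation).  For real data a k-fold
cross-validation against supplied phenotypes/EBVs replaces the
truth-based validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import genotypes as gt
from . import gwas as gw
from . import mme, pqtn
from .hmatrix import build_H_inverse
from .pedigree import Pedigree, build_A, build_A_inverse, partition_indices
from .simulate import SimulationConfig, SimulatedPopulation, simulate_population

MODELS = ("ssgblup", "ssgblup-pqtn", "ssgwablup", "ssgwablup-pqtn")


def design_matrix(groups: np.ndarray) -> np.ndarray:
    """Intercept plus dummy columns for a categorical fixed effect
    (first observed level as reference)."""
    levels = np.unique(groups)
    X = np.ones((groups.size, levels.size))
    for k, lev in enumerate(levels[1:]):
        X[:, k + 1] = (groups == lev).astype(float)
    return X


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Drop columns that are (numerically) linear combinations of earlier ones."""
    keep = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
    return X[:, keep]


@dataclass
class Metrics:
    correlation: float
    bias: float
    dispersion: float
    n: int


def validation_metrics(gebv: np.ndarray, tbv: np.ndarray) -> Metrics:
    """Correlation, bias and dispersion of predictions against truth.

    A constant GEBV vector has undefined correlation (reported NaN) and
    dispersion 0.
    """
    gebv = np.asarray(gebv, float).ravel()
    tbv = np.asarray(tbv, float).ravel()
    if gebv.size != tbv.size or gebv.size < 2:
        raise ValueError("gebv/tbv must be aligned vectors with n > 1")
    vt = np.var(tbv, ddof=1)
    if vt <= 0:
        raise ValueError("TBV variance must be positive")
    bias = float(gebv.mean() - tbv.mean())
    cov = float(np.cov(gebv, tbv, ddof=1)[0, 1])
    dispersion = cov / vt
    if np.var(gebv, ddof=1) <= 0:
        return Metrics(np.nan, bias, 0.0, gebv.size)
    corr = float(np.corrcoef(gebv, tbv)[0, 1])
    return Metrics(corr, bias, dispersion, gebv.size)


@dataclass
class Hyperparams:
    """Model hyperparameters (defaults are the standard choices)."""

    pp_prior: float = 0.001
    blend_weight: float = 0.95
    smooth_neighbors: int = 20
    r2_max: float = 0.3
    n_candidates: int = 15
    selection_folds: int = 5
    delta_min: float = 0.001

    def __post_init__(self):
        if not 0 < self.pp_prior < 1:
            raise ValueError("PP prior must lie in (0, 1)")
        if not 0 < self.blend_weight <= 1:
            raise ValueError("blend weight must lie in (0, 1]")


@dataclass
class SingleStepDataset:
    """Shared inputs for one evaluation: pedigree, QC'd genotypes, records."""

    ped: Pedigree
    geno: gt.GenotypeData  # QC'd, genotyped animals only, pedigree order
    rec_animal: np.ndarray  # record -> animal index (pedigree order)
    y: np.ndarray
    X: np.ndarray
    #: optional per-record response for the pQTN selection CV (true breeding
    #: values in simulation studies; defaults to adjusted phenotypes)
    cv_response: np.ndarray | None = None

    def __post_init__(self):
        g_idx = np.flatnonzero(self.ped.genotyped)
        if not np.array_equal(self.ped.ids[g_idx], self.geno.ids):
            raise ValueError("genotype ids must match pedigree genotyped animals in order")


class SingleStepFitter:
    """Lazy shared computation of A, G, H^-1 variants, GWAS and pQTN sets."""

    def __init__(self, data: SingleStepDataset, hp: Hyperparams = None, seed: int = 0,
                 vc: gw.VarianceComponents | None = None):
        self.data = data
        self.hp = hp or Hyperparams()
        self.seed = seed
        self._vc = vc
        self._cache: dict = {}
        self.ng_idx, self.g_idx = partition_indices(data.ped)

    # -- shared pieces -----------------------------------------------------
    def _get(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    @property
    def A(self):
        return self._get("A", lambda: build_A(self.data.ped))

    @property
    def ainv(self):
        return self._get("ainv", lambda: build_A_inverse(self.data.ped))

    @property
    def Agg(self):
        return self._get("Agg", lambda: self.A.values[np.ix_(self.g_idx, self.g_idx)])

    @property
    def Ang(self):
        return self._get("Ang", lambda: self.A.values[np.ix_(self.ng_idx, self.g_idx)])

    @property
    def Gu(self):
        return self._get("Gu", lambda: gt.build_G(self.data.geno))

    def _hinv(self, weighted: bool):
        key = "hinv_w" if weighted else "hinv_u"

        def make():
            G = self.Gw if weighted else self.Gu
            from .pedigree import RelationshipMatrix

            Agg_rm = RelationshipMatrix(self.Agg, G.ids, "A")
            Gom = gt.blend_G(G, Agg_rm, self.hp.blend_weight)
            return build_H_inverse(self.ainv, Gom, self.Agg, self.g_idx)

        return self._get(key, make)

    @property
    def scan_rows(self):
        """Genotyped animals that carry a phenotype record (GWAS set)."""

        def make():
            rec_set = set(self.data.rec_animal.tolist())
            return np.flatnonzero(np.isin(self.g_idx, list(rec_set)))

        return self._get("scan_rows", make)

    @property
    def gwas_result(self) -> gw.GwasResult:
        def make():
            rows = self.scan_rows
            if rows.size < 30:
                raise ValueError("too few genotyped, phenotyped animals for GWAS")
            anim = self.g_idx[rows]
            pos = {a: i for i, a in enumerate(self.data.rec_animal)}
            ri = np.array([pos[a] for a in anim])
            y = self.data.y[ri]
            X = _independent_columns(self.data.X[ri])
            K = self.Gu.values[np.ix_(rows, rows)]
            M = self.data.geno.matrix[rows]
            return gw.run_scan(
                y, X, M, K, markers=self.data.geno.markers,
                n_neighbors=self.hp.smooth_neighbors, prior=self.hp.pp_prior,
                vc=self._vc,
            )

        return self._get("gwas", make)

    @property
    def vc(self) -> gw.VarianceComponents:
        """Variance components used by the MME (REML from the GWAS set
        unless supplied)."""
        if self._vc is not None:
            return self._vc
        return self.gwas_result.vc

    @property
    def Gw(self):
        def make():
            pp = self.gwas_result.table["pp"].to_numpy()
            return gt.build_G(self.data.geno, weights=pp, normalize=True)

        return self._get("Gw", make)

    def pqtn_set(self, weighted: bool = False) -> pqtn.PqtnSet:
        """Forward-CV pQTN selection (one shared set per dataset).

        Selection is run against the plain (unweighted) single-step base
        model: the pQTN set is determined before marker weighting enters,
        and both pQTN models share it.  ``weighted=True`` selects against
        the weighted base instead.
        """
        key = "pqtn_w" if weighted else "pqtn_u"

        def make():
            cand = pqtn.prune_candidates(
                self.gwas_result.table,
                self.data.geno.matrix,
                r2_max=self.hp.r2_max,
                n_candidates=self.hp.n_candidates,
            )
            # covariates are the *centered* codes (M - 2p): the pedigree
            # imputation then sends unrelated animals to the population
            # mean and the pQTN contribution to GEBV is mean-anchored
            freq = self.data.geno.allele_freq
            codes = self.data.geno.matrix[:, cand] - 2.0 * freq[cand]
            cols = pqtn.full_covariates(
                codes, self.Ang, self.Agg, self.g_idx, self.ng_idx,
            )
            spec = self._base_spec(weighted)
            marker_ids = self.data.geno.markers["marker"].to_numpy()[cand]
            return pqtn.forward_cv_select(
                list(range(len(cand))), spec, self.data.y, cols,
                marker_ids=list(marker_ids),
                g_index=self.g_idx, ng_index=self.ng_idx,
                codes_g=codes,
                folds=self.hp.selection_folds,
                delta_min=self.hp.delta_min, seed=self.seed,
                response=self.data.cv_response,
            )

        return self._get(key, make)

    def _base_spec(self, weighted: bool, P=None) -> mme.ModelSpec:
        return mme.ModelSpec(
            X=self.data.X,
            record_animal=self.data.rec_animal,
            n_animals=self.data.ped.n,
            hinv=self._hinv(weighted),
            sigma_u2=self.vc.sigma_u2,
            sigma_e2=self.vc.sigma_e2,
            P=P,
        )

    # -- model fits --------------------------------------------------------
    def fit(self, model: str):
        """Fit one of the four models; returns (gebv per animal, MmeSolution,
        PqtnSet or None)."""
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
        weighted = model.startswith("ssgwablup")
        with_pqtn = model.endswith("-pqtn")
        pq = self.pqtn_set() if with_pqtn else None
        P_full = pq.full_P() if pq is not None and pq.k else None
        P_rec = P_full[self.data.rec_animal] if P_full is not None else None
        spec = self._base_spec(weighted, P=P_rec)
        sol = mme.solve_mme(spec, self.data.y, P_full=P_full)
        gebv = mme.predict_gebv(sol, P_full)
        return gebv, sol, pq


@dataclass
class ValidationReport:
    rows: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        num = self.rows.select_dtypes("number").columns.difference(["replicate"])
        return self.rows.groupby(["scenario", "model"])[list(num)].agg(["mean", "std"])


def run_replicate(
    pop: SimulatedPopulation,
    models=MODELS,
    hp: Hyperparams | None = None,
    seed: int = 0,
    vc: gw.VarianceComponents | None = None,
) -> list[dict]:
    """Run the chosen models on one simulated population; validate on the
    last generation against TBV.

    Variance components default to the simulation truth (sigma_u2 = h2,
    sigma_e2 = 1 - h2 on the phenotypic scale); pass ``vc`` to use REML
    estimates or other values.  The pQTN selection CV scores held-out
    predictions against TBV, as phenotype-based CV is biased under the
    phenotype-driven selection the simulator applies.
    """
    hp = hp or Hyperparams()
    if vc is None:
        vc = gw.VarianceComponents(pop.config.h2, 1.0 - pop.config.h2)
    ped = pop.pedigree(masked=True)
    geno_raw = pop.genotype_data()
    geno, _ = gt.qc_filter(geno_raw)
    ref = (pop.role == "reference") & ~np.isnan(pop.phenotype)
    rec = np.flatnonzero(ref)
    data = SingleStepDataset(
        ped=ped, geno=geno, rec_animal=rec, y=pop.phenotype[rec],
        X=design_matrix(pop.generation[rec]),
        cv_response=pop.tbv[rec],
    )
    fitter = SingleStepFitter(data, hp, seed=seed, vc=vc)
    val = np.flatnonzero(pop.role == "validation")
    rows = []
    for model in models:
        gebv, sol, pq = fitter.fit(model)
        m = validation_metrics(gebv[val], pop.tbv[val])
        row = {
            "model": model,
            "scenario": pop.config.scenario,
            "correlation": m.correlation,
            "bias": m.bias,
            "dispersion": m.dispersion,
            "n_val": m.n,
            "n_pqtn": pq.k if pq is not None else 0,
        }
        if pq is not None:
            if pq.k:
                part = pq.full_P() @ sol.q
                pv = part[val]
                row["pqtn_tbv_corr"] = (
                    float(np.corrcoef(pv, pop.tbv[val])[0, 1]) if np.std(pv) > 0 else 0.0
                )
            else:
                row["pqtn_tbv_corr"] = 0.0
        rows.append(row)
    return rows


def run_experiment(
    config: SimulationConfig,
    n_replicates: int = 10,
    models=MODELS,
    hp: Hyperparams | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Replicated simulation experiment over the chosen models.

    Every replicate draws a fresh population (seeded from the master seed),
    runs all models on identical inputs and scores the validation
    generation against TBV.
    """
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_replicates)]
    all_rows = []
    for r, s in enumerate(rep_seeds):
        cfg = SimulationConfig(**{**config.__dict__, "seed": s})
        pop = simulate_population(cfg)
        for row in run_replicate(pop, models=models, hp=hp, seed=s):
            row["replicate"] = r
            all_rows.append(row)
    return ValidationReport(pd.DataFrame(all_rows))


def kfold_cv(
    data: SingleStepDataset,
    model: str,
    k: int = 10,
    hp: Hyperparams | None = None,
    seed: int = 0,
    vc: gw.VarianceComponents | None = None,
) -> dict:
    """k-fold cross-validation of one model on real (or loaded) data.

    The phenotyped records are split into k seeded folds; per fold the full
    pipeline (GWAS, weights, pQTN selection, MME) is refit on the training
    portion only, and accuracy is the Pearson correlation between the
    held-out animals' GEBV and their responses.
    """
    nrec = data.rec_animal.size
    if nrec < k:
        raise ValueError("fewer phenotyped animals than folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, va in kf.split(np.arange(nrec)):
        if va.size == 0:
            raise ValueError("fold with no validation phenotypes")
        sub = SingleStepDataset(
            ped=data.ped, geno=data.geno,
            rec_animal=data.rec_animal[tr], y=data.y[tr], X=data.X[tr],
            cv_response=None if data.cv_response is None else data.cv_response[tr],
        )
        fitter = SingleStepFitter(sub, hp, seed=seed, vc=vc)
        gebv, _, _ = fitter.fit(model)
        pred = gebv[data.rec_animal[va]]
        resp = data.y[va]
        accs.append(float(np.corrcoef(pred, resp)[0, 1]) if np.std(pred) > 0 else 0.0)
    accs = np.asarray(accs)
    return {"fold_accuracy": accs, "mean": float(accs.mean()), "sd": float(accs.std(ddof=1))}
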