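"""Cross-validated prediction reliability and the marker-density study.

Reliability follows the usual genomic-prediction definition: phenotypes of
one fold are masked, the model is fitted on the remaining folds, and the
Pearson correlation between the masked animals' adjusted phenotypes
(y - X beta_hat) and their predicted genetic values is averaged over
folds.  Fixed effects and variance components are (re-)estimated within
each training fold by default, so no test information leaks into training.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import bayes as bayes_mod
from . import mixed_model as mm
from .genotypes import GenotypeMatrix
from .grm import Pedigree, RelationshipMatrix, build_grm, build_numerator_A, regularize

GBLUP_MODELS = {"gblup"}
BAYES_MODELS = {"bayesB": "B", "bayesCpi": "Cpi", "bayesN": "N", "bayesS": "S", "bayesR": "R"}
ALL_MODELS = ("blup", "gblup") + tuple(BAYES_MODELS)


@dataclasses.dataclass
class FoldAssignment:
    fold_of: dict
    k: int
    seed: int

    def test_ids(self, fold: int) -> list:
        return [a for a, f in self.fold_of.items() if f == fold]


@dataclasses.dataclass
class PredictionResult:
    fold_r: list
    model: str
    n_markers: int
    replicate: int = 0

    @property
    def mean_r(self) -> float:
        valid = [r for r in self.fold_r if np.isfinite(r)]
        return float(np.mean(valid)) if valid else np.nan


def kfold_assign(ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniform random partition of ids into k folds of near-equal size."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids passed to kfold_assign")
    if k < 2 or len(ids) < k:
        raise ValueError("need k >= 2 and at least k ids")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    return FoldAssignment(
        fold_of={ids[int(j)]: int(i % k) for i, j in enumerate(perm)}, k=k, seed=seed
    )


def adjusted_phenotypes(y: np.ndarray, x: np.ndarray, beta_hat: np.ndarray) -> np.ndarray:
    """y - X beta_hat; beta_hat must come from training data only."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    beta_hat = np.asarray(beta_hat, float)
    if x.shape != (len(y), len(beta_hat)):
        raise ValueError("dimension mismatch between y, X and beta_hat")
    return y - x @ beta_hat


def reliability(y_adj: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation; NaN (with a warning) for degenerate folds."""
    y_adj = np.asarray(y_adj, float)
    pred = np.asarray(pred, float)
    if len(y_adj) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(y_adj) == 0 or np.std(pred) == 0:
        warnings.warn("zero variance in a fold; reliability undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(y_adj, pred)[0, 1])


def _design_x(df: pd.DataFrame, fixed_effects) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in fixed_effects:
        if factor not in df.columns:
            continue
        levels = pd.unique(df[factor].astype(str))
        if len(levels) < 2:
            continue
        for level in levels[1:]:
            cols.append((df[factor].astype(str) == level).to_numpy(float))
            names.append(f"{factor}[{level}]")
    return np.column_stack(cols), names


def cross_validate(
    pheno: pd.DataFrame,
    trait: str,
    model: str,
    geno: GenotypeMatrix | None = None,
    pedigree: Pedigree | None = None,
    rel: RelationshipMatrix | None = None,
    grm_method: str = "IV",
    k: int = 5,
    seed: int = 0,
    fixed_effects: tuple = ("sex", "cross", "room"),
    chain_config: bayes_mod.ChainConfig | None = None,
    bayes_spec: bayes_mod.BayesModelSpec | None = None,
    folds: FoldAssignment | None = None,
    epsilon: float = 0.01,
    adjust: str = "per_fold",
) -> PredictionResult:
    """k-fold cross-validated reliability for one trait and one model.

    `model` is one of ``blup`` (pedigree), ``gblup`` (with `grm_method`),
    or ``bayesB``/``bayesCpi``/``bayesN``/``bayesS``/``bayesR``.  Passing
    the same `folds` object to several models gives paired comparisons.
    """
    if model not in ALL_MODELS:
        raise ValueError(f"model must be one of {ALL_MODELS}")
    records = pheno.loc[pheno[trait].notna()].reset_index(drop=True)
    ids = records["animal_id"].tolist()
    folds = folds or kfold_assign(ids, k=k, seed=seed)
    n_markers = geno.n_markers if geno is not None else 0

    beta_global = None
    if model in BAYES_MODELS:
        if geno is None:
            raise ValueError("Bayesian models require genotypes")
        spec = bayes_spec or bayes_mod.BayesModelSpec(model=BAYES_MODELS[model])
        cfg = chain_config or bayes_mod.ChainConfig()
        geno_lookup = {a: i for i, a in enumerate(geno.animal_ids)}
        fold_r = []
        for f in range(folds.k):
            test_mask = records["animal_id"].map(folds.fold_of).to_numpy() == f
            train_df = records.loc[~test_mask]
            test_df = records.loc[test_mask]
            if len(test_df) < 3:
                raise ValueError(f"fold {f} has fewer than 3 test records")
            x_all, _ = _design_x(records, fixed_effects)
            x_train, x_test = x_all[~test_mask], x_all[test_mask]
            rows_train = [geno_lookup[a] for a in train_df["animal_id"]]
            rows_test = [geno_lookup[a] for a in test_df["animal_id"]]
            fold_cfg = dataclasses.replace(cfg, seed=(cfg.seed * 1000 + f) & 0x7FFFFFFF)
            eff = bayes_mod.run_chain(
                train_df[trait].to_numpy(float), x_train,
                geno.subset(animals=rows_train), spec, fold_cfg,
            )
            pred = bayes_mod.predict_gebv(geno.subset(animals=rows_test), eff)
            y_adj = adjusted_phenotypes(test_df[trait].to_numpy(float), x_test, eff.beta)
            fold_r.append(reliability(y_adj, pred))
        return PredictionResult(fold_r=fold_r, model=model, n_markers=n_markers)

    # kernel-based models: pedigree BLUP or GBLUP
    if rel is None:
        if model == "blup":
            if pedigree is None:
                raise ValueError("pedigree BLUP requires a pedigree")
            rel = build_numerator_A(pedigree)
        else:
            if geno is None:
                raise ValueError("GBLUP requires genotypes")
            rel = regularize(build_grm(geno, grm_method), epsilon)
    if adjust == "global":
        y_all, x_all_d, z_all, names = mm.build_design(
            records, trait, rel, fixed_effects
        )
        vc0 = mm.reml_univariate(y_all, x_all_d, z_all, rel)
        beta_global = mm.solve_mme(y_all, x_all_d, z_all, rel, vc0, names).beta

    # one design over all records so train/test share the level coding
    x_all, names = _design_x(records, fixed_effects)
    fold_r = []
    for f in range(folds.k):
        test_mask = records["animal_id"].map(folds.fold_of).to_numpy() == f
        train_df = records.loc[~test_mask]
        test_df = records.loc[test_mask]
        if len(test_df) < 3:
            raise ValueError(f"fold {f} has fewer than 3 test records")
        y_t = train_df[trait].to_numpy(float)
        x_t = x_all[~test_mask]
        z_t = np.zeros((len(train_df), rel.n))
        z_t[np.arange(len(train_df)), rel.index_of(train_df["animal_id"].to_numpy())] = 1.0
        vc = mm.reml_univariate(y_t, x_t, z_t, rel)
        sol = mm.solve_mme(y_t, x_t, z_t, rel, vc, names)
        beta = beta_global if beta_global is not None else sol.beta
        y_adj = adjusted_phenotypes(test_df[trait].to_numpy(float), x_all[test_mask], beta)
        test_idx = rel.index_of(test_df["animal_id"].to_numpy())
        fold_r.append(reliability(y_adj, sol.u[test_idx]))
    return PredictionResult(fold_r=fold_r, model=model, n_markers=n_markers)


@dataclasses.dataclass
class DensityTable:
    """Tidy results of the marker-density permutation study."""

    records: pd.DataFrame       # density, replicate, fold, r
    grm_correlation: pd.Series  # mean between-replicate GRM entry correlation

    def mean_reliability(self) -> pd.Series:
        per_rep = self.records.groupby(["density", "replicate"])["r"].mean()
        return per_rep.groupby("density").mean()


def density_permutation(
    geno: GenotypeMatrix,
    pheno: pd.DataFrame,
    trait: str,
    densities,
    n_reps: int = 30,
    model: str = "gblup",
    grm_method: str = "IV",
    k: int = 5,
    seed: int = 0,
    fixed_effects: tuple = ("sex", "cross", "room"),
) -> DensityTable:
    """Reliability as a function of marker density.

    For each density, `n_reps` uniform random marker subsets (without
    replacement) are drawn, the GRM rebuilt and the cross-validation rerun.
    Between-replicate Pearson correlations of the GRM entries quantify how
    stable the relationship estimates are at each density.
    """
    m = geno.n_markers
    for d in densities:
        if d > m:
            raise ValueError(f"density {d} exceeds the {m} available markers")
    rng = np.random.default_rng(seed)
    rows = []
    grm_corr = {}
    iu = None
    for d in sorted(densities):
        entries = []
        for rep in range(n_reps):
            subset = np.sort(rng.choice(m, size=d, replace=False))
            sub = geno.subset(markers=subset)
            rel = regularize(build_grm(sub, grm_method))
            if iu is None:
                iu = np.triu_indices(rel.n, k=1)
            entries.append(rel.values[iu])
            res = cross_validate(
                pheno, trait, model, geno=sub, rel=rel, grm_method=grm_method,
                k=k, seed=seed, fixed_effects=fixed_effects,
            )
            for f, r in enumerate(res.fold_r):
                rows.append({"density": d, "replicate": rep, "fold": f, "r": r})
        if len(entries) > 1:
            stack = np.vstack(entries)
            cors = np.corrcoef(stack)
            grm_corr[d] = float(np.mean(cors[np.triu_indices(len(entries), k=1)]))
        else:
            grm_corr[d] = 1.0
    return DensityTable(
        records=pd.DataFrame(rows),
        grm_correlation=pd.Series(grm_corr, name="grm_correlation"),
    )


def predictive_capability(table: DensityTable) -> pd.Series:
    """Each density's mean reliability divided by the best density's."""
    means = table.mean_reliability()
    if len(means) < 2:
        raise ValueError("need at least 2 densities")
    best = means.max()
    if best <= 0:
        raise ValueError("best reliability is non-positive; capability undefined")
    return means / best
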