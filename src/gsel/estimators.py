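"""Scikit-learn style estimators wrapping the GBLUP and Bayesian models.

Both estimators take a plain animals x markers dosage array (0/1/2, NaN
for missing) as ``X`` and a phenotype vector as ``y``, so they compose
with sklearn pipelines and model selection.  Predicted values are the
fitted intercept plus the genomic estimated breeding value; non-genetic
covariates used at fit time are treated as nuisance adjustments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import bayes as bayes_mod
from . import mixed_model as mm
from .genotypes import MISSING, GenotypeMatrix, genotype_frequencies, mean_impute
from .grm import build_grm, marker_variance, regularize


def _as_genotype_matrix(x, positions=None, chrom=None) -> GenotypeMatrix:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("X must be a 2-D dosage array")
    dos = np.where(np.isnan(x), MISSING, x).astype(np.int8)
    n, m = dos.shape
    markers = pd.DataFrame(
        {
            "marker_id": [f"m{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else "1",
            "pos": positions if positions is not None else np.arange(m) * 10_000,
            "a1": "A",
            "a2": "B",
        }
    )
    ids = np.array([f"i{j}" for j in range(n)], dtype=object)
    return GenotypeMatrix(dos, ids, markers)


class GBLUP(BaseEstimator, RegressorMixin):
    """Genomic BLUP with a selectable GRM normalization.

    Parameters
    ----------
    grm_method : {"SP", "IP", "SV", "IV"}
        GRM construction: pooled/per-marker divisor crossed with the
        HWE (2p(1-p)) or empirical ("true") marker variance.
    epsilon : float
        Identity shrinkage applied to the GRM before inversion.
    max_iter, tol : AI-REML controls.

    Attributes (after fit)
    ----------------------
    sigma_a2_, sigma_e2_, h2_, h2_se_ : variance components and heritability
    u_ : breeding values of the training animals
    alpha_ : equivalent marker effects used by :meth:`predict`
    """

    def __init__(self, grm_method="IV", epsilon=0.01, max_iter=100, tol=1e-8):
        self.grm_method = grm_method
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, covariates=None):
        geno = _as_genotype_matrix(X)
        y = np.asarray(y, dtype=float)
        if len(y) != geno.n_animals:
            raise ValueError("X and y disagree on sample count")
        self.freqs_ = genotype_frequencies(geno)
        rel = regularize(build_grm(geno, self.grm_method, self.freqs_), self.epsilon)
        cols = [np.ones(len(y))]
        if covariates is not None:
            cols.append(np.asarray(covariates, dtype=float).reshape(len(y), -1))
        x_fix = np.column_stack(cols)
        z = np.eye(len(y))
        vc = mm.reml_univariate(
            y, x_fix, z, rel, max_iter=self.max_iter, tol=self.tol
        )
        sol = mm.solve_mme(y, x_fix, z, rel, vc)
        self.vc_ = vc
        self.sigma_a2_ = vc.sigma_a2
        self.sigma_e2_ = vc.sigma_e2
        self.h2_, self.h2_se_ = mm.heritability(vc)
        self.beta_ = sol.beta
        self.u_ = sol.u
        # equivalent marker effects: G = Z* D Z*' (or Z*Z*'/c) => alpha = D Z*' G^-1 u
        convention = "HWE" if self.grm_method.upper().endswith("P") else "TRUE"
        var = marker_variance(self.freqs_, convention)
        mat = mean_impute(geno, self.freqs_)
        if convention == "HWE":
            self.mu_ = 2.0 * self.freqs_.p
        else:
            self.mu_ = self.freqs_.p1 + 2.0 * self.freqs_.p2
        zc = mat - self.mu_
        m = zc.shape[1]
        ginv_u = np.linalg.solve(rel.values, sol.u)
        if self.grm_method.upper().startswith("S"):
            self.alpha_ = (1.0 - self.epsilon) * (zc.T @ ginv_u) / var.sum()
        else:
            self.alpha_ = (1.0 - self.epsilon) * (zc.T @ ginv_u) / (m * var)
        self.n_features_in_ = geno.n_markers
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.shape[1] != self.n_features_in_:
            raise ValueError("marker count differs from training")
        x = np.where(np.isnan(x), 2.0 * self.freqs_.p, x)
        return self.beta_[0] + (x - self.mu_) @ self.alpha_


class BayesAlphabet(BaseEstimator, RegressorMixin):
    """Bayesian whole-genome regression (BayesB/Cpi/N/S/R) as an estimator.

    Thin wrapper over :func:`gsel.bayes.run_chain`; posterior-mean marker
    effects drive :meth:`predict`.  Marker positions (for the BayesN
    windows) may be supplied to :meth:`fit`; by default markers are placed
    10 kb apart on one chromosome.
    """

    def __init__(
        self,
        model="Cpi",
        pi=0.05,
        n_iter=3000,
        burn_in=1000,
        thin=5,
        seed=0,
        window_size_bp=200_000,
    ):
        self.model = model
        self.pi = pi
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.window_size_bp = window_size_bp

    def fit(self, X, y, covariates=None, positions=None, chrom=None):
        geno = _as_genotype_matrix(X, positions=positions, chrom=chrom)
        y = np.asarray(y, dtype=float)
        cols = [np.ones(len(y))]
        if covariates is not None:
            cols.append(np.asarray(covariates, dtype=float).reshape(len(y), -1))
        x_fix = np.column_stack(cols)
        spec = bayes_mod.BayesModelSpec(
            model=self.model, pi=self.pi, window_size_bp=self.window_size_bp
        )
        cfg = bayes_mod.ChainConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin, seed=self.seed
        )
        self.result_ = bayes_mod.run_chain(y, x_fix, geno, spec, cfg)
        self.effects_ = self.result_.effects
        self.pip_ = self.result_.pip
        self.beta_ = self.result_.beta
        self.n_features_in_ = geno.n_markers
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.shape[1] != self.n_features_in_:
            raise ValueError("marker count differs from training")
        p = self.result_.train_p
        x = np.where(np.isnan(x), 2.0 * p, x)
        return self.beta_[0] + (x - 2.0 * p) @ self.effects_
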