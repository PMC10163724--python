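"""Gibbs samplers for Bayesian whole-genome regression (the "Bayesian
alphabet"): BayesB, BayesCpi, BayesN, BayesS and BayesR.

All five share the linear model y = X beta + W alpha + e with a
marker-effect prior that differs per model:

* **BayesCpi** — spike at 0 with probability 1-pi, N(0, sigma2) slab;
  pi sampled from its beta conditional.
* **BayesB** — spike at 0, scaled-t slab implemented hierarchically as a
  normal with per-marker variance under a scaled-inverse-chi-square prior;
  pi fixed.
* **BayesN** — nested BayesCpi: markers sit in non-overlapping 0.2 Mb
  windows; a window-level indicator gates the marker-level spike/slab.
* **BayesS** — BayesCpi with slab variance tied to allele frequency,
  sigma_j^2 = [2 p_j (1-p_j)]^S sigma2; S sampled by random-walk
  Metropolis with step adaptation during burn-in.
* **BayesR** — four-component normal mixture with variances
  gamma_k * sigma2, gamma = (0, 0.01, 0.1, 1), Dirichlet-updated weights.

Sampling uses single-site residual updating (O(n) per marker) inside a
numba kernel; a fixed seed gives bit-identical chains.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import GenotypeMatrix, genotype_frequencies, mean_impute

MODEL_CODES = {"Cpi": 0, "B": 1, "N": 2, "S": 3, "R": 4}


@dataclasses.dataclass
class BayesModelSpec:
    model: str = "Cpi"
    pi: float = 0.05                      # prior/initial probability of a non-zero effect
    pi_fixed: bool = False                # BayesB keeps pi fixed
    window_size_bp: int = 200_000
    gamma: tuple = (0.0, 0.01, 0.1, 1.0)
    pi_r: tuple = (0.85, 0.05, 0.05, 0.05)
    pi_r_fixed: bool = False
    s_value: float | None = None          # fix the BayesS exponent instead of sampling
    df_effect: float = 4.0
    df_resid: float = 4.0
    r2_prior: float = 0.5                 # prior share of phenotypic variance that is genetic

    def __post_init__(self) -> None:
        if self.model not in MODEL_CODES:
            raise ValueError(f"model must be one of {sorted(MODEL_CODES)}")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.model == "R":
            if abs(sum(self.pi_r) - 1.0) > 1e-9 or any(p < 0 for p in self.pi_r):
                raise ValueError("BayesR mixture probabilities must be a simplex")
        if self.window_size_bp <= 0:
            raise ValueError("window size must be positive")
        if self.model == "B":
            self.pi_fixed = True


@dataclasses.dataclass
class ChainConfig:
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclasses.dataclass
class MarkerEffects:
    """Posterior summaries of one chain."""

    marker_ids: np.ndarray
    effects: np.ndarray                   # posterior-mean effect per marker
    pip: np.ndarray                       # posterior inclusion probability
    beta: np.ndarray                      # posterior-mean fixed effects
    post_pi: float
    post_sigma2: float
    post_sigmae2: float
    post_s: float                         # BayesS exponent (nan otherwise)
    post_pi_r: np.ndarray
    window_pip: np.ndarray | None
    train_p: np.ndarray                   # training allele frequencies for centering
    loglik_trace: np.ndarray
    model: str


def window_partition(markers: pd.DataFrame, window_size_bp: int = 200_000) -> np.ndarray:
    """Assign each marker to a non-overlapping genomic window.

    Windows are half-open intervals [k*w, (k+1)*w) restarting at each
    chromosome; indices are dense (empty windows dropped).  Markers must be
    sorted by (chromosome, position).
    """
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    order_key = pd.DataFrame({"chrom": chrom, "pos": pos})
    if not order_key.sort_values(["chrom", "pos"], kind="mergesort").index.equals(
        order_key.index
    ):
        raise ValueError("markers must be sorted by (chromosome, position)")
    raw = [(c, p // window_size_bp) for c, p in zip(chrom, pos)]
    mapping: dict = {}
    out = np.empty(len(raw), dtype=np.int64)
    for i, key in enumerate(raw):
        if key not in mapping:
            mapping[key] = len(mapping)
        out[i] = mapping[key]
    return out


@njit(cache=True)
def _inv_chi2(df, scale):
    return df * scale / np.random.chisquare(df)


@njit(cache=True)
def _gibbs_kernel(
    w,                # (n, m) centered genotypes, Fortran order
    wtw,              # (m,)
    x,                # (n, p) fixed design, Fortran order
    xtx,              # (p,)
    y,                # (n,)
    model,            # 0 Cpi, 1 B, 2 N, 3 S, 4 R
    pi_init,
    pi_fixed,
    het,              # (m,) 2p(1-p) for BayesS
    gamma,            # (4,)
    pi_r_init,        # (4,)
    window_id,        # (m,) dense window index (model N)
    win_start,        # (n_windows,) first marker of each window
    win_end,          # (n_windows,) last marker of each window (inclusive)
    n_windows,
    nu, s2_marker, nu_e, s2_resid,
    pi_r_fixed, s_fixed, s_init,
    n_iter, burn_in, thin, seed,
):
    np.random.seed(seed)
    n, m = w.shape
    p = x.shape[1]
    alpha = np.zeros(m)
    delta = np.zeros(m, dtype=np.int8)
    comp = np.zeros(m, dtype=np.int8)      # BayesR component
    sigma_j2 = np.full(m, s2_marker)       # BayesB per-marker variance
    beta = np.zeros(p)
    e = y.copy()
    sigma2 = s2_marker
    sigmae2 = s2_resid
    pi = pi_init
    pi_w = 0.5
    s_par = s_init
    s_step = 0.3
    s_acc = 0
    s_try = 0
    pi_r = pi_r_init.copy()
    win_open = np.ones(n_windows, dtype=np.int8)

    n_kept = 0
    alpha_sum = np.zeros(m)
    pip_sum = np.zeros(m)
    beta_sum = np.zeros(p)
    pi_sum = 0.0
    sigma2_sum = 0.0
    sigmae2_sum = 0.0
    s_sum = 0.0
    pi_r_sum = np.zeros(4)
    win_pip_sum = np.zeros(n_windows)
    n_trace = (n_iter - burn_in + thin - 1) // thin
    ll_trace = np.zeros(n_trace)

    for it in range(n_iter):
        # --- fixed effects (flat prior) ---
        for c in range(p):
            rhs = np.dot(x[:, c], e) + xtx[c] * beta[c]
            bn = rhs / xtx[c] + np.random.normal() * np.sqrt(sigmae2 / xtx[c])
            diff = beta[c] - bn
            if diff != 0.0:
                for i in range(n):
                    e[i] += x[i, c] * diff
            beta[c] = bn

        m_in = 0
        ssq_scaled = 0.0                  # sum a^2 / (variance scale) for sigma2 update
        comp_counts = np.zeros(4)

        if model == 2:
            # --- BayesN: window indicator gates marker-level spike/slab ---
            n_open = 0
            for wi in range(n_windows):
                lo = win_start[wi]
                hi = win_end[wi]
                # window log-odds from per-marker marginal likelihoods
                lodds = np.log(pi_w + 1e-300) - np.log(1.0 - pi_w + 1e-300)
                for j in range(lo, hi + 1):
                    rhs = np.dot(w[:, j], e) + wtw[j] * alpha[j]
                    v_post = 1.0 / (wtw[j] / sigmae2 + 1.0 / sigma2)
                    mu_post = v_post * rhs / sigmae2
                    lbf = 0.5 * (np.log(v_post) - np.log(sigma2)) + 0.5 * mu_post * mu_post / v_post
                    # marker-level mixture marginal: (1-pi) + pi * BF
                    if lbf > 35.0:
                        term = np.log(pi + 1e-300) + lbf
                    else:
                        term = np.log((1.0 - pi) + pi * np.exp(lbf) + 1e-300)
                    lodds += term
                if lodds > 35.0:
                    p_open = 1.0
                elif lodds < -35.0:
                    p_open = 0.0
                else:
                    p_open = 1.0 / (1.0 + np.exp(-lodds))
                open_now = np.random.uniform(0.0, 1.0) < p_open
                if open_now:
                    win_open[wi] = 1
                    n_open += 1
                    for j in range(lo, hi + 1):
                        rhs = np.dot(w[:, j], e) + wtw[j] * alpha[j]
                        v_post = 1.0 / (wtw[j] / sigmae2 + 1.0 / sigma2)
                        mu_post = v_post * rhs / sigmae2
                        lbf = 0.5 * (np.log(v_post) - np.log(sigma2)) + 0.5 * mu_post * mu_post / v_post
                        if lbf > 35.0:
                            p_in = 1.0
                        else:
                            bf = np.exp(lbf)
                            p_in = pi * bf / (pi * bf + (1.0 - pi))
                        a_old = alpha[j]
                        if np.random.uniform(0.0, 1.0) < p_in:
                            a_new = mu_post + np.random.normal() * np.sqrt(v_post)
                            delta[j] = 1
                            m_in += 1
                            ssq_scaled += a_new * a_new
                        else:
                            a_new = 0.0
                            delta[j] = 0
                        diff = a_old - a_new
                        if diff != 0.0:
                            for i in range(n):
                                e[i] += w[i, j] * diff
                        alpha[j] = a_new
                else:
                    win_open[wi] = 0
                    for j in range(lo, hi + 1):
                        if alpha[j] != 0.0:
                            for i in range(n):
                                e[i] += w[i, j] * alpha[j]
                        alpha[j] = 0.0
                        delta[j] = 0
            if not pi_fixed:
                pi_w = np.random.beta(1.0 + n_open, 1.0 + n_windows - n_open)
                m_in_open = 0
                m_tot_open = 0
                for j in range(m):
                    if win_open[window_id[j]] == 1:
                        m_tot_open += 1
                        if delta[j] == 1:
                            m_in_open += 1
                if m_tot_open > 0:
                    pi = np.random.beta(1.0 + m_in_open, 1.0 + m_tot_open - m_in_open)
        else:
            # --- single-level marker loop (Cpi, B, S, R) ---
            for j in range(m):
                rhs = np.dot(w[:, j], e) + wtw[j] * alpha[j]
                a_old = alpha[j]
                if model == 4:
                    # BayesR: choose among 4 components
                    logp = np.empty(4)
                    logp[0] = np.log(pi_r[0] + 1e-300)
                    for k2 in range(1, 4):
                        vk = gamma[k2] * sigma2
                        v_post = 1.0 / (wtw[j] / sigmae2 + 1.0 / vk)
                        mu_post = v_post * rhs / sigmae2
                        logp[k2] = (
                            np.log(pi_r[k2] + 1e-300)
                            + 0.5 * (np.log(v_post) - np.log(vk))
                            + 0.5 * mu_post * mu_post / v_post
                        )
                    mx = logp[0]
                    for k2 in range(1, 4):
                        if logp[k2] > mx:
                            mx = logp[k2]
                    tot = 0.0
                    for k2 in range(4):
                        logp[k2] = np.exp(logp[k2] - mx)
                        tot += logp[k2]
                    u = np.random.uniform(0.0, 1.0) * tot
                    acc = 0.0
                    kc = 3
                    for k2 in range(4):
                        acc += logp[k2]
                        if u <= acc:
                            kc = k2
                            break
                    comp[j] = kc
                    comp_counts[kc] += 1.0
                    if kc == 0:
                        a_new = 0.0
                        delta[j] = 0
                    else:
                        vk = gamma[kc] * sigma2
                        v_post = 1.0 / (wtw[j] / sigmae2 + 1.0 / vk)
                        mu_post = v_post * rhs / sigmae2
                        a_new = mu_post + np.random.normal() * np.sqrt(v_post)
                        delta[j] = 1
                        m_in += 1
                        ssq_scaled += a_new * a_new / gamma[kc]
                else:
                    if model == 1:
                        vj = sigma_j2[j]
                    elif model == 3:
                        vj = (het[j] ** s_par) * sigma2
                    else:
                        vj = sigma2
                    v_post = 1.0 / (wtw[j] / sigmae2 + 1.0 / vj)
                    mu_post = v_post * rhs / sigmae2
                    lbf = 0.5 * (np.log(v_post) - np.log(vj)) + 0.5 * mu_post * mu_post / v_post
                    if pi >= 1.0:
                        p_in = 1.0
                    elif pi <= 0.0:
                        p_in = 0.0
                    elif lbf > 35.0:
                        p_in = 1.0
                    else:
                        bf = np.exp(lbf)
                        p_in = pi * bf / (pi * bf + (1.0 - pi))
                    if np.random.uniform(0.0, 1.0) < p_in:
                        a_new = mu_post + np.random.normal() * np.sqrt(v_post)
                        delta[j] = 1
                        m_in += 1
                        if model == 3:
                            ssq_scaled += a_new * a_new / (het[j] ** s_par)
                        else:
                            ssq_scaled += a_new * a_new
                    else:
                        a_new = 0.0
                        delta[j] = 0
                    if model == 1:
                        # per-marker variance: posterior if in, prior draw if out
                        if delta[j] == 1:
                            sigma_j2[j] = _inv_chi2(nu + 1.0, (nu * s2_marker + a_new * a_new) / (nu + 1.0))
                        else:
                            sigma_j2[j] = _inv_chi2(nu, s2_marker)
                diff = a_old - a_new
                if diff != 0.0:
                    for i in range(n):
                        e[i] += w[i, j] * diff
                alpha[j] = a_new
            if model != 1 and not pi_fixed and model != 4:
                pi = np.random.beta(1.0 + m_in, 1.0 + m - m_in)

        # --- common variance of non-zero effects ---
        if model != 1:
            sigma2 = _inv_chi2(nu + m_in, (nu * s2_marker + ssq_scaled) / (nu + m_in))

        # --- BayesR mixture weights (Dirichlet via gammas) ---
        if model == 4 and not pi_r_fixed:
            tot = 0.0
            for k2 in range(4):
                pi_r[k2] = np.random.gamma(1.0 + comp_counts[k2], 1.0)
                tot += pi_r[k2]
            for k2 in range(4):
                pi_r[k2] /= tot

        # --- BayesS exponent by random-walk Metropolis ---
        if model == 3 and not s_fixed and m_in > 0:
            s_prop = s_par + np.random.normal() * s_step
            ll_cur = 0.0
            ll_prop = 0.0
            for j in range(m):
                if delta[j] == 1:
                    lh = np.log(het[j])
                    v_cur = np.exp(s_par * lh) * sigma2
                    v_pro = np.exp(s_prop * lh) * sigma2
                    ll_cur += -0.5 * (np.log(v_cur) + alpha[j] * alpha[j] / v_cur)
                    ll_prop += -0.5 * (np.log(v_pro) + alpha[j] * alpha[j] / v_pro)
            ll_cur += -0.5 * s_par * s_par      # N(0,1) prior
            ll_prop += -0.5 * s_prop * s_prop
            s_try += 1
            if np.log(np.random.uniform(0.0, 1.0) + 1e-300) < ll_prop - ll_cur:
                s_par = s_prop
                s_acc += 1
            if it < burn_in and s_try >= 50:
                rate = s_acc / s_try
                if rate > 0.35:
                    s_step *= 1.2
                elif rate < 0.25:
                    s_step *= 0.8
                s_acc = 0
                s_try = 0

        # --- residual variance ---
        sse = np.dot(e, e)
        sigmae2 = (sse + nu_e * s2_resid) / np.random.chisquare(n + nu_e)
        if not np.isfinite(sigmae2) or sigmae2 <= 0.0:
            return (
                alpha_sum, pip_sum, beta_sum, pi_sum, sigma2_sum, sigmae2_sum,
                s_sum, pi_r_sum, win_pip_sum, ll_trace, n_kept, it + 1,
            )

        if it >= burn_in and (it - burn_in) % thin == 0:
            alpha_sum += alpha
            for j in range(m):
                pip_sum[j] += delta[j]
            beta_sum += beta
            pi_sum += pi
            sigma2_sum += sigma2
            sigmae2_sum += sigmae2
            s_sum += s_par
            pi_r_sum += pi_r
            for wi in range(n_windows):
                win_pip_sum[wi] += win_open[wi]
            ll_trace[n_kept] = -0.5 * n * np.log(sigmae2) - 0.5 * sse / sigmae2
            n_kept += 1

    return (
        alpha_sum, pip_sum, beta_sum, pi_sum, sigma2_sum, sigmae2_sum,
        s_sum, pi_r_sum, win_pip_sum, ll_trace, n_kept, 0,
    )


def run_chain(
    y: np.ndarray,
    x: np.ndarray,
    geno: GenotypeMatrix,
    spec: BayesModelSpec,
    cfg: ChainConfig,
) -> MarkerEffects:
    """Run one Gibbs chain and return post-burn-in thinned posterior means.

    Genotypes are mean-imputed and centered at the HWE mean 2p of the
    training animals; identical seed and config reproduce the chain
    bit-for-bit.
    """
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 records for a chain")
    if x.shape[0] != n or geno.n_animals != n:
        raise ValueError("y, X and genotypes disagree on record count")
    freqs = genotype_frequencies(geno)
    mat = mean_impute(geno, freqs)
    w = np.asfortranarray(mat - 2.0 * freqs.p)
    wtw = np.einsum("ij,ij->j", w, w)
    if np.any(wtw <= 0):
        raise ValueError("monomorphic markers present; run qc_filter first")
    x = np.asfortranarray(np.asarray(x, dtype=np.float64))
    xtx = np.einsum("ij,ij->j", x, x)
    het = 2.0 * freqs.p * (1.0 - freqs.p)

    if spec.model == "N":
        window_id = window_partition(geno.markers, spec.window_size_bp)
        n_windows = int(window_id.max()) + 1
        win_start = np.searchsorted(window_id, np.arange(n_windows), side="left")
        win_end = np.searchsorted(window_id, np.arange(n_windows), side="right") - 1
    else:
        window_id = np.zeros(geno.n_markers, dtype=np.int64)
        n_windows = 1
        win_start = np.zeros(1, dtype=np.int64)
        win_end = np.array([geno.n_markers - 1], dtype=np.int64)

    var_y = float(np.var(y))
    nu, nu_e = spec.df_effect, spec.df_resid
    # prior scale so the prior mean genetic variance is r2_prior * var(y)
    mean_het = float(np.mean(het))
    pi_eff = spec.pi
    if spec.model == "R":
        pi_eff = float(np.dot(spec.pi_r, spec.gamma))
        pi_eff = max(pi_eff, 1e-3)
    expected_m_in = max(pi_eff * geno.n_markers, 1.0)
    s2_marker = spec.r2_prior * var_y * (nu - 2.0) / nu / (expected_m_in * mean_het)
    s2_resid = (1.0 - spec.r2_prior) * var_y * (nu_e - 2.0) / nu_e

    out = _gibbs_kernel(
        w, wtw, x, xtx, y,
        MODEL_CODES[spec.model],
        float(spec.pi), spec.pi_fixed,
        het, np.asarray(spec.gamma, dtype=np.float64),
        np.asarray(spec.pi_r, dtype=np.float64),
        window_id.astype(np.int64),
        win_start.astype(np.int64), win_end.astype(np.int64), n_windows,
        float(nu), float(s2_marker), float(nu_e), float(s2_resid),
        bool(spec.pi_r_fixed), spec.s_value is not None,
        float(spec.s_value if spec.s_value is not None else 0.0),
        int(cfg.n_iter), int(cfg.burn_in), int(cfg.thin), int(cfg.seed) & 0x7FFFFFFF,
    )
    (alpha_sum, pip_sum, beta_sum, pi_sum, sigma2_sum, sigmae2_sum,
     s_sum, pi_r_sum, win_pip_sum, ll_trace, n_kept, diverged_at) = out
    if diverged_at:
        raise FloatingPointError(
            f"chain diverged (non-finite residual variance) at iteration {diverged_at}"
        )
    if n_kept == 0:
        raise RuntimeError("no post-burn-in samples were kept")
    return MarkerEffects(
        marker_ids=geno.markers["marker_id"].to_numpy(),
        effects=alpha_sum / n_kept,
        pip=pip_sum / n_kept,
        beta=beta_sum / n_kept,
        post_pi=float(pi_sum / n_kept),
        post_sigma2=float(sigma2_sum / n_kept),
        post_sigmae2=float(sigmae2_sum / n_kept),
        post_s=float(s_sum / n_kept) if spec.model == "S" else float("nan"),
        post_pi_r=pi_r_sum / n_kept,
        window_pip=(win_pip_sum / n_kept) if spec.model == "N" else None,
        train_p=freqs.p.copy(),
        loglik_trace=ll_trace[:n_kept],
        model=spec.model,
    )


def predict_gebv(
    geno_new: GenotypeMatrix,
    effects: MarkerEffects,
    train_p: np.ndarray | None = None,
) -> np.ndarray:
    """GEBV = centered new genotypes x posterior-mean marker effects.

    Centering uses the training allele frequencies so train and test
    animals share a reference point.
    """
    new_ids = geno_new.markers["marker_id"].to_numpy()
    if len(new_ids) != len(effects.marker_ids) or np.any(new_ids != effects.marker_ids):
        offenders = sorted(
            set(new_ids).symmetric_difference(effects.marker_ids)
        )
        raise ValueError(f"marker sets differ; offenders include {offenders[:5]}")
    p = effects.train_p if train_p is None else train_p
    freqs = genotype_frequencies(geno_new)
    mat = mean_impute(geno_new, freqs)
    return (mat - 2.0 * p) @ effects.effects


def effects_to_tsv(effects: MarkerEffects, path) -> None:
    pd.DataFrame(
        {
            "marker_id": effects.marker_ids,
            "effect": effects.effects,
            "pip": effects.pip,
        }
    ).to_csv(path, sep="\t", index=False)
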