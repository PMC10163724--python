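"""Synthetic genotype/pedigree/phenotype generator with known ground truth.

The generator emulates the study design the toolkit targets: an F2 cross
of two divergent lines (~1,000 animals), whole-genome SNP dosages with a
controllable departure from Hardy-Weinberg proportions (one inbreeding
coefficient F), polygenic or major-QTL trait architectures with a target
heritability, and categorical fixed effects (sex, reciprocal cross, feed
room).  All draws are bit-reproducible under the config seed.

Two genotype modes:

* ``independent_loci`` — markers drawn independently with genotype
  frequencies p^2 + F p(1-p) (alt hom), 2p(1-p)(1-F) (het); F = 0 gives
  exact HWE sampling, F = 1 eliminates heterozygotes.
* ``f2_cross`` — two founder lines fixed for alternate alleles are crossed
  to F1 and intercrossed to F2 with recombination (Poisson crossovers at
  1 cM/Mb), producing allele frequencies near 0.5 and LD decaying with
  distance, as in a real F2 mapping population.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .grm import Pedigree


@dataclasses.dataclass
class SimConfig:
    n_animals: int = 1000
    n_markers: int = 3000
    n_chrom: int = 5
    chrom_length_bp: int = 80_000_000
    maf_lo: float = 0.05
    maf_hi: float = 0.5
    inbreeding_f: float = 0.0
    mode: str = "f2_cross"
    n_qtl: int = 20
    target_h2: float = 0.5
    effect_dist: str = "normal"          # or "mixture" (BayesR-like components)
    fixed_effect_sd: float = 0.5         # per level contrast, in phenotypic SD
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding coefficient must lie in [0, 1]")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target h2 must lie in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl exceeds n_markers")
        if self.mode not in ("independent_loci", "f2_cross"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class TruthRecord:
    tbv: np.ndarray | None = None
    qtl_indices: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None
    realized_h2: float | None = None


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(cfg.n_chrom, cfg.n_markers // cfg.n_chrom)
    per[: cfg.n_markers % cfg.n_chrom] += 1
    rows = []
    for c in range(cfg.n_chrom):
        pos = np.sort(rng.choice(cfg.chrom_length_bp, size=per[c], replace=False))
        for p in pos:
            rows.append((f"snp_{c + 1}_{p}", str(c + 1), int(p)))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
    df["a1"] = "A"
    df["a2"] = "B"
    return df


def _gamete(haplotypes: np.ndarray, chrom_codes: np.ndarray, pos: np.ndarray,
            chrom_length: int, rng: np.random.Generator) -> np.ndarray:
    """Recombine a parent's two haplotypes into one gamete (1 cM/Mb map)."""
    m = haplotypes.shape[1]
    origin = np.empty(m, dtype=np.intp)
    morgans = chrom_length * 1e-8
    for c in np.unique(chrom_codes):
        sel = chrom_codes == c
        k = rng.poisson(morgans)
        phase = rng.integers(2)
        if k == 0:
            origin[sel] = phase
        else:
            cuts = np.sort(rng.uniform(0, chrom_length, size=k))
            origin[sel] = (phase + np.searchsorted(cuts, pos[sel])) % 2
    return haplotypes[origin, np.arange(m)]


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Generate a genotype matrix under the configured population model."""
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    n, m = cfg.n_animals, cfg.n_markers
    if cfg.mode == "independent_loci":
        p = rng.uniform(cfg.maf_lo, cfg.maf_hi, size=m)
        f = cfg.inbreeding_f
        f2 = p**2 + f * p * (1 - p)
        f1 = 2 * p * (1 - p) * (1 - f)
        u = rng.uniform(size=(n, m))
        dosages = np.where(u < f2, 2, np.where(u < f2 + f1, 1, 0)).astype(np.int8)
    else:
        chrom_codes = markers["chrom"].astype(int).to_numpy()
        pos = markers["pos"].to_numpy()
        # founder lines fixed for alternate alleles -> F1 uniformly heterozygous;
        # each F2 animal is two recombinant F1 gametes
        f1_hap = np.vstack([np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8)])
        dosages = np.empty((n, m), dtype=np.int8)
        for i in range(n):
            g1 = _gamete(f1_hap, chrom_codes, pos, cfg.chrom_length_bp, rng)
            g2 = _gamete(f1_hap, chrom_codes, pos, cfg.chrom_length_bp, rng)
            dosages[i] = g1 + g2
    if cfg.missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < cfg.missing_rate
        dosages[mask] = MISSING
    ids = np.array([f"A{i:05d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(dosages, ids, markers), TruthRecord()


def _draw_effects(n_qtl: int, dist: str, rng: np.random.Generator) -> np.ndarray:
    if dist == "normal":
        return rng.normal(0.0, 1.0, size=n_qtl)
    if dist == "mixture":
        comp_sd = np.sqrt(np.array([0.01, 0.1, 1.0]))
        which = rng.integers(0, 3, size=n_qtl)
        return rng.normal(0.0, 1.0, size=n_qtl) * comp_sd[which]
    raise ValueError(f"unknown effect distribution {dist!r}")


def simulate_phenotypes(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    trait_name: str = "trait",
    seed: int | None = None,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Overlay a quantitative trait with known architecture on genotypes.

    QTL are sampled among the markers, effects drawn, and the residual
    variance scaled so the realized heritability matches the target; sex,
    reciprocal cross and feed room are added as categorical fixed effects.
    """
    rng = np.random.default_rng(cfg.seed + 104729 if seed is None else seed)
    n, m = geno.n_animals, geno.n_markers
    dos = geno.dosages.astype(np.float64)
    dos[geno.dosages == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)

    qtl = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    effects = _draw_effects(cfg.n_qtl, cfg.effect_dist, rng)
    zq = dos[:, qtl] - col_mean[qtl]
    tbv = zq @ effects
    var_tbv = float(np.var(tbv))
    if cfg.target_h2 == 0.0:
        tbv = np.zeros(n)
        var_tbv = 0.0
        var_e = 1.0
    else:
        if var_tbv <= 0:
            raise ValueError("no genetic variance realized; increase n_qtl or MAF")
        var_e = var_tbv * (1.0 / cfg.target_h2 - 1.0)
    resid = rng.normal(0.0, np.sqrt(var_e) if var_e > 0 else 0.0, size=n)
    if cfg.target_h2 == 1.0:
        resid = np.zeros(n)
    sd_p = np.sqrt(var_tbv + var_e) if (var_tbv + var_e) > 0 else 1.0

    levels = {"sex": ["F", "M"], "cross": ["PxM", "MxP"], "room": ["R1", "R2", "R3"]}
    fixed = np.zeros(n)
    cols = {}
    for factor, lv in levels.items():
        assign = rng.integers(0, len(lv), size=n)
        cols[factor] = np.array(lv, dtype=object)[assign]
        fixed += cfg.fixed_effect_sd * sd_p * assign

    y = fixed + tbv + resid
    pheno = pd.DataFrame({"animal_id": geno.animal_ids, trait_name: y, **cols})
    realized = var_tbv / (var_tbv + var_e) if (var_tbv + var_e) > 0 else 0.0
    truth = TruthRecord(
        tbv=tbv, qtl_indices=qtl, qtl_effects=effects, realized_h2=float(realized)
    )
    return pheno, truth


def simulate_bivariate_phenotypes(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    r_g: float = 0.8,
    h2_pair: tuple[float, float] = (0.5, 0.5),
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Two traits with a chosen genetic correlation on shared QTL.

    QTL effects for the pair are drawn from a bivariate normal with
    correlation `r_g`; residuals are independent and scaled to the target
    heritabilities.  Returns the phenotype table (trait1, trait2 plus the
    categorical fixed effects) and a truth dict with the realized genetic
    correlation (the correlation of the two true-breeding-value vectors).
    """
    if not -1.0 <= r_g <= 1.0:
        raise ValueError("r_g must lie in [-1, 1]")
    rng = np.random.default_rng(cfg.seed + 15485863 if seed is None else seed)
    n, m = geno.n_animals, geno.n_markers
    dos = geno.dosages.astype(np.float64)
    dos[geno.dosages == MISSING] = np.nan
    col_mean = np.nanmean(dos, axis=0)
    dos = np.where(np.isnan(dos), col_mean, dos)
    qtl = np.sort(rng.choice(m, size=cfg.n_qtl, replace=False))
    cov = np.array([[1.0, r_g], [r_g, 1.0]])
    eff = rng.multivariate_normal(np.zeros(2), cov, size=cfg.n_qtl)
    zq = dos[:, qtl] - col_mean[qtl]
    tbv = zq @ eff                                   # (n, 2)
    out = {}
    cols = {}
    levels = {"sex": ["F", "M"], "cross": ["PxM", "MxP"], "room": ["R1", "R2", "R3"]}
    assigns = {
        f: rng.integers(0, len(lv), size=n) for f, lv in levels.items()
    }
    for f, lv in levels.items():
        cols[f] = np.array(lv, dtype=object)[assigns[f]]
    traits = {}
    for t in range(2):
        var_g = float(np.var(tbv[:, t]))
        h2 = h2_pair[t]
        var_e = var_g * (1.0 / h2 - 1.0) if h2 > 0 else 1.0
        resid = rng.normal(0.0, np.sqrt(var_e), size=n)
        sd_p = np.sqrt(var_g + var_e)
        fixed = np.zeros(n)
        for f in levels:
            fixed += cfg.fixed_effect_sd * sd_p * assigns[f]
        traits[f"trait{t + 1}"] = fixed + tbv[:, t] + resid
    realized_rg = float(np.corrcoef(tbv[:, 0], tbv[:, 1])[0, 1])
    pheno = pd.DataFrame({"animal_id": geno.animal_ids, **traits, **cols})
    out = {"tbv": tbv, "qtl_indices": qtl, "realized_r_g": realized_rg}
    return pheno, out


def simulate_pedigree(
    cfg: SimConfig,
    n_founders: int = 40,
    n_generations: int = 3,
) -> tuple[Pedigree, GenotypeMatrix]:
    """Random-mating discrete-generation pedigree with gene-dropped genotypes.

    Founder haplotypes are drawn from uniform allele frequencies; gametes
    recombine at 1 cM/Mb, so transmitted genotypes are Mendelian-consistent
    with the recorded sire/dam links.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders for mating")
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    m = cfg.n_markers
    chrom_codes = markers["chrom"].astype(int).to_numpy()
    pos = markers["pos"].to_numpy()
    p = rng.uniform(cfg.maf_lo, cfg.maf_hi, size=m)

    per_gen = max(2, (cfg.n_animals - n_founders) // max(n_generations, 1))
    haplos: list[np.ndarray] = []
    records = []
    sexes = []
    for i in range(n_founders):
        hap = (rng.uniform(size=(2, m)) < p).astype(np.int8)
        haplos.append(hap)
        records.append((f"P{i:05d}", None, None))
        sexes.append(i % 2)  # alternate male/female
    prev = list(range(n_founders))
    counter = n_founders
    for _ in range(n_generations):
        males = [i for i in prev if sexes[i] == 0]
        females = [i for i in prev if sexes[i] == 1]
        if not males or not females:
            raise ValueError("a generation lacks one sex; increase n_founders")
        cur = []
        for _ in range(per_gen):
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            g1 = _gamete(haplos[s], chrom_codes, pos, cfg.chrom_length_bp, rng)
            g2 = _gamete(haplos[d], chrom_codes, pos, cfg.chrom_length_bp, rng)
            haplos.append(np.vstack([g1, g2]))
            records.append((f"P{counter:05d}", records[s][0], records[d][0]))
            sexes.append(int(rng.integers(2)))
            cur.append(counter)
            counter += 1
        prev = cur
    dosages = np.array([h.sum(axis=0) for h in haplos], dtype=np.int8)
    ids = np.array([r[0] for r in records], dtype=object)
    ped = Pedigree(pd.DataFrame(records, columns=["id", "sire", "dam"]))
    return ped, GenotypeMatrix(dosages, ids, markers)
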