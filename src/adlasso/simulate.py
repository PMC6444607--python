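"""Synthetic genotype/phenotype generator with known QTL architecture.

Emulates the statistical structure the predictor consumes — biallelic
SNPs under Hardy-Weinberg proportions, two major additive QTLs (effects
-3 and +3 by default), a polygenic background of truncated-normal
additive effects (|a| < 2), and one locus each of dominance
(het 5.00 / hom2 5.01), over-dominance (het 5.00, homs -0.01/+0.01) and
under-dominance (het -5.00, homs -0.01/+0.01) — without reproducing the
original pedigree/coalescent machinery.  Everything is deterministic
given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .encoding import GenotypeMatrix, SplitPlan, make_splits

__all__ = [
    "DominanceLocus",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "assign_effects",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class DominanceLocus:
    """Per-genotype-class effect values for one non-additive locus."""

    type: str  # dominance | overdominance | underdominance
    het_effect: float
    hom0_effect: float = 0.0
    hom2_effect: float = 0.0

    def class_values(self) -> np.ndarray:
        return np.array([self.hom0_effect, self.het_effect, self.hom2_effect])


DEFAULT_DOMINANCE_SPEC = (
    DominanceLocus("dominance", het_effect=5.00, hom0_effect=0.0, hom2_effect=5.01),
    DominanceLocus("overdominance", het_effect=5.00, hom0_effect=-0.01, hom2_effect=0.01),
    DominanceLocus("underdominance", het_effect=-5.00, hom0_effect=-0.01, hom2_effect=0.01),
)


@dataclass
class SimulationConfig:
    n_individuals: int = 1000
    n_snps: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_random_qtl: int = 28
    random_qtl_truncation: float = 2.0
    random_qtl_sd: float = 1.0
    major_qtl_effects: tuple[float, ...] = (-3.0, 3.0)
    dominance_spec: tuple[DominanceLocus, ...] = DEFAULT_DOMINANCE_SPEC
    noise_sd: Optional[float] = None  # None -> sd of genetic values (h2 ~ 0.5)
    ld_mixing: float = 0.0  # in [0,1): correlation carry-over between adjacent SNPs
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.random_qtl_truncation <= 0:
            raise ValueError("random_qtl_truncation must be positive")
        if not 0.0 <= self.ld_mixing < 1.0:
            raise ValueError("ld_mixing must be in [0, 1)")
        n_qtl = self.n_random_qtl + len(self.major_qtl_effects) + len(self.dominance_spec)
        if n_qtl > self.n_snps:
            raise ValueError("more QTLs requested than SNPs")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: np.ndarray
    truth: pd.DataFrame
    split: SplitPlan
    noise_sd: float

    def write(self, outdir, delimiter: str = "\t") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_frame().to_csv(outdir / "genotypes.tsv", sep=delimiter, index_label="id")
        pd.Series(
            self.phenotypes, index=self.genotypes.individual_ids, name="phenotype"
        ).to_csv(outdir / "phenotypes.tsv", sep=delimiter, index_label="id")
        self.truth.to_csv(outdir / "truth.tsv", sep=delimiter, index=False)


def simulate_genotypes(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> GenotypeMatrix:
    """Draw HW genotypes: per SNP an allele frequency from maf_range, then
    two Bernoulli allele draws per individual.

    With ``ld_mixing`` > 0, each allele draw copies the previous SNP's
    draw with that probability, producing a crude LD block structure.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, p = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=p)
    if config.ld_mixing == 0.0:
        G = rng.binomial(2, freqs, size=(n, p)).astype(np.int8)
    else:
        alleles = np.empty((2, n, p), dtype=np.int8)
        for hap in range(2):
            draws = rng.random((n, p)) < freqs
            carry = rng.random((n, p)) < config.ld_mixing
            alleles[hap, :, 0] = draws[:, 0]
            for j in range(1, p):
                alleles[hap, :, j] = np.where(
                    carry[:, j], alleles[hap, :, j - 1], draws[:, j]
                )
        G = (alleles[0] + alleles[1]).astype(np.int8)
    return GenotypeMatrix(
        values=G,
        snp_ids=[f"snp{j:05d}" for j in range(p)],
        individual_ids=[f"ind{i:05d}" for i in range(n)],
    )


def _truncated_normal(rng: np.random.Generator, sd: float, bound: float, size: int) -> np.ndarray:
    """Rejection-sample N(0, sd^2) until |draw| < bound."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draws = rng.normal(0.0, sd, size=size - filled)
        keep = draws[np.abs(draws) < bound]
        out[filled : filled + len(keep)] = keep
        filled += len(keep)
    return out


def assign_effects(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place major, polygenic and dominance-type QTLs at distinct loci.

    Returns a truth table with one row per QTL: locus index, type, the
    additive effect (NaN for dominance-type loci) and the three
    per-genotype-class values actually added to the phenotype.
    """
    n_major = len(config.major_qtl_effects)
    n_dom = len(config.dominance_spec)
    n_total = n_major + config.n_random_qtl + n_dom
    if n_total > config.n_snps:
        raise ValueError("not enough SNPs for the requested QTLs")
    loci = rng.choice(config.n_snps, size=n_total, replace=False)
    random_effects = _truncated_normal(
        rng, config.random_qtl_sd, config.random_qtl_truncation, config.n_random_qtl
    )
    rows = []
    k = 0
    for eff in config.major_qtl_effects:
        rows.append(_additive_row(int(loci[k]), "major_additive", eff))
        k += 1
    for eff in random_effects:
        rows.append(_additive_row(int(loci[k]), "random_additive", float(eff)))
        k += 1
    for spec in config.dominance_spec:
        rows.append(
            {
                "locus": int(loci[k]),
                "type": spec.type,
                "additive_effect": np.nan,
                "value_gen0": spec.hom0_effect,
                "value_gen1": spec.het_effect,
                "value_gen2": spec.hom2_effect,
            }
        )
        k += 1
    cols = ["locus", "type", "additive_effect", "value_gen0", "value_gen1", "value_gen2"]
    return pd.DataFrame(rows, columns=cols).sort_values("locus", ignore_index=True)


def _additive_row(locus: int, kind: str, effect: float) -> dict:
    return {
        "locus": locus,
        "type": kind,
        "additive_effect": effect,
        "value_gen0": 0.0,
        "value_gen1": effect,
        "value_gen2": 2.0 * effect,
    }


def genetic_values(G: GenotypeMatrix, truth: pd.DataFrame) -> np.ndarray:
    """Sum of per-locus contributions via genotype-class lookup."""
    gv = np.zeros(G.n_individuals)
    for row in truth.itertuples(index=False):
        lookup = np.array([row.value_gen0, row.value_gen1, row.value_gen2])
        gv += lookup[G.values[:, row.locus]]
    return gv


def simulate_phenotypes(
    G: GenotypeMatrix,
    truth: pd.DataFrame,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if len(truth) and truth["locus"].max() >= G.n_snps:
        raise ValueError("truth table references a locus outside the genotype matrix")
    return genetic_values(G, truth) + rng.normal(0.0, noise_sd, size=G.n_individuals)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genotypes + effects + phenotypes + holdout-tail split, all from seed."""
    rng = np.random.default_rng(config.seed)
    G = simulate_genotypes(config, rng)
    truth = assign_effects(config, rng)
    noise_sd = config.noise_sd
    if noise_sd is None:
        gv = genetic_values(G, truth)
        noise_sd = float(gv.std(ddof=0))
        if noise_sd == 0.0:
            noise_sd = 1.0
    y = simulate_phenotypes(G, truth, noise_sd, rng)
    split = make_splits(
        config.n_individuals,
        mode="holdout_tail",
        test_fraction=config.test_fraction,
        seed=config.seed,
    )
    return SimulatedDataset(genotypes=G, phenotypes=y, truth=truth, split=split, noise_sd=noise_sd)
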