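"""Synthetic genotype/phenotype data with the structure of real GWP panels.

The generator emulates SNP matrices as used in genomic prediction studies:
n samples << p markers, a minor-allele-frequency (MAF) spectrum, blockwise
linkage disequilibrium (LD), and sparse pleiotropic QTL architectures with
shared and trait-specific additive effects (plus optional pairwise epistasis)
calibrated to a target per-trait heritability. It also implements the
standard QC/recoding operations: MAF filtering, marginal-distribution
imputation of missing genotypes, liability thresholding of two continuous
breeding values into four classes, and 70/10/20 train/validation/test splits.

LD model: blockwise Gaussian-copula haplotypes. Within a block, latent
haplotype values follow an AR(1) chain whose per-pair latent correlation is
calibrated numerically so that the *genotype* correlation of adjacent markers
matches ``ld_rho`` despite the attenuation introduced by thresholding.
Blocks are mutually independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "TraitData",
    "QTLTruth",
    "DataSplit",
    "simulate_genotypes",
    "simulate_traits",
    "liability_to_fourclass",
    "maf_filter",
    "impute_marginal",
    "split_data",
]

MISSING = -1  # sentinel in integer genotype matrices


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for one simulated genotype/phenotype dataset."""

    n_samples: int = 500
    n_markers: int = 2000
    n_traits: int = 3
    coding: str = "additive_012"  # or "dominant_01"
    maf_range: tuple = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.3
    n_qtl_shared: int = 20
    n_qtl_specific_per_trait: int = 0
    effect_sd: float = 1.0
    epistatic_pairs: int = 0
    heritability: tuple = (0.6, 0.6, 0.6)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.coding not in ("additive_012", "dominant_01"):
            raise ValueError(f"unknown coding {self.coding!r}")
        k = self.n_traits
        if len(self.heritability) != k:
            raise ValueError("heritability must have one value per trait")
        if any(not (0.0 <= h <= 1.0) for h in self.heritability):
            raise ValueError("heritability values must be in [0, 1]")
        need = self.n_qtl_shared + k * self.n_qtl_specific_per_trait
        if need > self.n_markers:
            raise ValueError(
                f"{need} causal markers requested but only {self.n_markers} markers"
            )
        if min(self.n_samples, self.n_markers, self.n_traits) < 1:
            raise ValueError("n_samples, n_markers, n_traits must be positive")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class GenotypeMatrix:
    """n x p integer marker matrix; missing entries hold the sentinel -1."""

    values: np.ndarray
    sample_ids: list
    marker_ids: list
    coding: str = "additive_012"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths inconsistent with matrix shape")
        if len(set(self.sample_ids)) != n or len(set(self.marker_ids)) != p:
            raise ValueError("sample/marker ids must be unique")
        obs = self.values[self.values != MISSING]
        if obs.size and (obs.min() < 0 or obs.max() > self.max_dosage):
            raise ValueError(f"genotype codes out of range for coding {self.coding}")

    @property
    def max_dosage(self) -> int:
        return 2 if self.coding == "additive_012" else 1

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def maf(self) -> np.ndarray:
        """Minor allele frequency per marker from non-missing entries."""
        vals = np.where(self.missing_mask, np.nan, self.values.astype(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(vals, axis=0) / self.max_dosage
        return np.minimum(f, 1.0 - f)


@dataclass
class TraitData:
    """Continuous trait matrix (regression) or class labels (classification)."""

    mode: str  # "regression" | "classification"
    values: np.ndarray
    trait_names: list = field(default_factory=list)
    n_classes: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.mode == "regression":
            if self.values.ndim == 1:
                self.values = self.values[:, None]
            if not np.all(np.isfinite(self.values)):
                raise ValueError("regression traits must be finite")
            if not self.trait_names:
                self.trait_names = [f"trait_{i}" for i in range(self.values.shape[1])]
        elif self.mode == "classification":
            self.values = self.values.astype(int).ravel()
            if self.n_classes < 2:
                raise ValueError("classification requires n_classes >= 2")
            if self.values.min() < 0 or self.values.max() >= self.n_classes:
                raise ValueError("labels must lie in {0..K-1}")
            if not self.trait_names:
                self.trait_names = ["class"]
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n_traits(self) -> int:
        return 1 if self.mode == "classification" else self.values.shape[1]


@dataclass
class QTLTruth:
    """Simulator ground truth for support-recovery checks."""

    causal_indices: list  # per trait, sorted marker indices
    effects: np.ndarray  # p x k, zero off-support
    epistatic_terms: list = field(default_factory=list)  # (i, j, trait, coef)

    def __post_init__(self):
        for t, idx in enumerate(self.causal_indices):
            nz = set(np.flatnonzero(self.effects[:, t]).tolist())
            if not nz.issubset(set(int(i) for i in idx)):
                raise ValueError("nonzero effects outside declared causal indices")

    @property
    def all_causal(self) -> np.ndarray:
        s = sorted(set(int(i) for idx in self.causal_indices for i in idx))
        return np.array(s, dtype=int)


@dataclass
class DataSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    fractions: tuple = (0.7, 0.1, 0.2)

    def __post_init__(self):
        a = [np.asarray(x, dtype=int) for x in (self.train_idx, self.val_idx, self.test_idx)]
        self.train_idx, self.val_idx, self.test_idx = a
        allidx = np.concatenate(a)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("split partitions overlap")

    @property
    def n(self) -> int:
        return self.train_idx.size + self.val_idx.size + self.test_idx.size


# ---------------------------------------------------------------------------
# LD calibration: latent AR(1) coefficient for a target genotype correlation
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _bvn_upper(h: np.ndarray, j: np.ndarray, r: np.ndarray) -> np.ndarray:
    """P(Z1 > h, Z2 > j) under standard bivariate normal with correlation r >= 0.

    Uses the Plackett identity: the orthant probability equals the
    independent product plus the integral of the bivariate density at (h, j)
    over correlations [0, r], evaluated with Gauss-Legendre quadrature.
    """
    h = np.asarray(h, float)
    j = np.asarray(j, float)
    r = np.asarray(r, float)
    t = 0.5 * r[..., None] * (_GL_NODES + 1.0)  # map nodes to [0, r]
    w = 0.5 * r[..., None] * _GL_WEIGHTS
    hh, jj = h[..., None], j[..., None]
    dens = np.exp(
        -(hh**2 - 2.0 * t * hh * jj + jj**2) / (2.0 * (1.0 - t**2))
    ) / (2.0 * np.pi * np.sqrt(1.0 - t**2))
    base = stats.norm.sf(h) * stats.norm.sf(j)
    return base + (dens * w).sum(axis=-1)


def _latent_corr_for_target(f_a, f_b, rho_target, iters: int = 50):
    """Latent correlations making corr(I(Z1>qa), I(Z2>qb)) = rho_target.

    Vectorized bisection; clamps at 0.999 when the target exceeds what the
    marginal frequencies allow.
    """
    f_a, f_b = np.asarray(f_a, float), np.asarray(f_b, float)
    qa = stats.norm.isf(f_a)
    qb = stats.norm.isf(f_b)
    denom = np.sqrt(f_a * (1 - f_a) * f_b * (1 - f_b))
    lo = np.zeros_like(f_a)
    hi = np.full_like(f_a, 0.999)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        phi = (_bvn_upper(qa, qb, mid) - f_a * f_b) / denom
        too_low = phi < rho_target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw an n x p genotype matrix with blockwise LD and the target MAFs."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_markers
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=p)
    thresholds = stats.norm.isf(freqs)

    # per-adjacent-pair latent AR(1) coefficients (0 at block starts)
    r_lat = np.zeros(p)
    if config.ld_rho > 0 and p > 1:
        adj = np.arange(1, p)
        inside = adj % config.ld_block_size != 0
        idx = adj[inside]
        if idx.size:
            r_lat[idx] = _latent_corr_for_target(
                freqs[idx - 1], freqs[idx], config.ld_rho
            )

    n_hap = 2 if config.coding == "additive_012" else 1
    geno = np.zeros((n, p), dtype=np.int16)
    for _ in range(n_hap):
        z = np.empty((n, p))
        eps = rng.standard_normal((n, p))
        z[:, 0] = eps[:, 0]
        for jcol in range(1, p):
            r = r_lat[jcol]
            z[:, jcol] = r * z[:, jcol - 1] + np.sqrt(1.0 - r * r) * eps[:, jcol]
        geno += (z > thresholds).astype(np.int16)

    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        geno[mask] = MISSING

    return GenotypeMatrix(
        values=geno,
        sample_ids=[f"S{i}" for i in range(n)],
        marker_ids=[f"M{j}" for j in range(p)],
        coding=config.coding,
    )


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mu) / sd


def simulate_traits(G: GenotypeMatrix, config: SimConfig):
    """Simulate k z-scored traits with shared + specific QTLs at target h^2.

    Genetic values are built on column-standardized genotypes; per-trait
    Gaussian noise is scaled so that var(genetic)/var(total) equals the
    requested heritability on this sample. Returns (TraitData, QTLTruth).
    """
    if G.missing_mask.any():
        raise ValueError("simulate_traits requires a complete genotype matrix")
    rng = np.random.default_rng(config.seed + 1)
    n, p = G.values.shape
    k = config.n_traits
    Z = _standardize_columns(G.values.astype(float))

    markers = rng.permutation(p)
    shared = np.sort(markers[: config.n_qtl_shared])
    rest = markers[config.n_qtl_shared :]
    specific = [
        np.sort(rest[t * config.n_qtl_specific_per_trait : (t + 1) * config.n_qtl_specific_per_trait])
        for t in range(k)
    ]

    effects = np.zeros((p, k))
    if shared.size:
        effects[shared, :] = rng.normal(0.0, config.effect_sd, size=(shared.size, k))
    for t in range(k):
        if specific[t].size:
            effects[specific[t], t] = rng.normal(0.0, config.effect_sd, size=specific[t].size)

    genetic = Z @ effects
    epi_terms = []
    if config.epistatic_pairs > 0:
        causal_union = np.concatenate([shared] + specific)
        causal_union = np.unique(causal_union)
        if causal_union.size >= 2:
            for _ in range(config.epistatic_pairs):
                i, j = rng.choice(causal_union, size=2, replace=False)
                t = int(rng.integers(k))
                coef = float(rng.normal(0.0, config.effect_sd))
                term = Z[:, i] * Z[:, j]
                sd = term.std()
                if sd > 1e-12:
                    genetic[:, t] += coef * (term - term.mean()) / sd
                epi_terms.append((int(i), int(j), t, coef))

    Y = np.empty((n, k))
    for t in range(k):
        h2 = config.heritability[t]
        g = genetic[:, t]
        if h2 == 0.0:
            Y[:, t] = rng.standard_normal(n)
        elif h2 == 1.0:
            Y[:, t] = g
        else:
            var_g = g.var()
            noise_sd = np.sqrt(var_g * (1.0 - h2) / h2) if var_g > 0 else 1.0
            Y[:, t] = g + rng.normal(0.0, noise_sd, size=n)

    Y = _standardize_columns(Y)
    causal = [np.sort(np.concatenate([shared, specific[t]])).astype(int) for t in range(k)]
    truth = QTLTruth(causal_indices=causal, effects=effects, epistatic_terms=epi_terms)
    traits = TraitData(mode="regression", values=Y,
                       trait_names=[f"trait_{t}" for t in range(k)])
    return traits, truth


def liability_to_fourclass(Y2: np.ndarray) -> TraitData:
    """Threshold two continuous breeding values at 0 and recode to 4 classes.

    Values strictly greater than 0 map to 1, otherwise 0 (exact zeros map to
    0); the binary pair [b1, b2] becomes class 2*b1 + b2.
    """
    Y2 = np.asarray(Y2, dtype=float)
    if Y2.ndim != 2 or Y2.shape[1] != 2:
        raise ValueError("liability_to_fourclass requires an n x 2 matrix")
    b = (Y2 > 0).astype(int)
    labels = 2 * b[:, 0] + b[:, 1]
    return TraitData(mode="classification", values=labels,
                     trait_names=["class"], n_classes=4)


def fourclass_to_binary(labels: np.ndarray) -> np.ndarray:
    """Inverse of the 4-class recoding: class -> (b1, b2) binary pair."""
    labels = np.asarray(labels, dtype=int)
    return np.stack([labels // 2, labels % 2], axis=1)


def maf_filter(G: GenotypeMatrix, threshold: float = 0.05):
    """Drop markers with minor allele frequency below `threshold`.

    MAF is min(f, 1-f) with f = mean allele dosage / max dosage over
    non-missing entries. Returns (filtered matrix, removed marker ids).
    """
    if not (0.0 <= threshold <= 0.5):
        raise ValueError("threshold must be in [0, 0.5]")
    maf = G.maf()
    keep = ~(maf < threshold)  # NaN-MAF (fully missing) markers are kept
    removed = [m for m, k in zip(G.marker_ids, keep) if not k]
    if not keep.any():
        warnings.warn("MAF filter removed every marker", stacklevel=2)
        return (
            GenotypeMatrix(
                values=G.values[:, keep],
                sample_ids=list(G.sample_ids),
                marker_ids=[],
                coding=G.coding,
            ),
            removed,
        )
    return (
        GenotypeMatrix(
            values=G.values[:, keep],
            sample_ids=list(G.sample_ids),
            marker_ids=[m for m, k in zip(G.marker_ids, keep) if k],
            coding=G.coding,
        ),
        removed,
    )


def impute_marginal(G: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Replace missing genotypes by draws from each marker's empirical marginal."""
    rng = np.random.default_rng(seed)
    vals = G.values.copy()
    miss = G.missing_mask
    for j in np.flatnonzero(miss.any(axis=0)):
        obs = vals[~miss[:, j], j]
        if obs.size == 0:
            raise ValueError(f"marker {G.marker_ids[j]!r} has no observed genotypes")
        vals[miss[:, j], j] = rng.choice(obs, size=int(miss[:, j].sum()))
    return GenotypeMatrix(values=vals, sample_ids=list(G.sample_ids),
                          marker_ids=list(G.marker_ids), coding=G.coding)


def split_data(n: int, fractions=(0.7, 0.1, 0.2), seed: int = 0) -> DataSplit:
    """Random disjoint train/validation/test index sets.

    Validation and test sizes are floor(n * fraction); the remainder goes to
    the training partition.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    f_train, f_val, f_test = fractions
    n_val = int(np.floor(n * f_val))
    n_test = int(np.floor(n * f_test))
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"empty partition for n={n}, fractions={fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    return DataSplit(
        train_idx=np.sort(perm[:n_train]),
        val_idx=np.sort(perm[n_train : n_train + n_val]),
        test_idx=np.sort(perm[n_train + n_val :]),
        fractions=tuple(fractions),
    )
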