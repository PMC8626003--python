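"""Synthetic imbalanced expression data with planted informative gene modules.

The generator emulates the structure of a severely imbalanced bulk RNA-seq
case/control cohort without requiring any external data: a gene x sample
count matrix with overdispersed counts, a block of *signal genes* whose
log-scale mean is shifted in cases, grouped into correlated modules (so a
similarity embedding co-locates them on the pixel grid, the mechanism the
image transform exploits), plus low-count genes, non-autosomal genes and
non-coding genes that exercise every upstream filter.

Counts follow a negative-binomial model: a Gaussian log-scale latent with
module-structured correlation sets each gene/sample mean, and a
gamma-Poisson draw adds counting noise with dispersion ``noise_dispersion``
(variance mu + alpha * mu^2). A ``gaussian`` mode skips the counting noise
(values are the exponentiated latent) for fast, exactly-continuous unit
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ExpressionMatrix, LabeledDataset

__all__ = ["SyntheticSpec", "generate_dataset", "expected_separability"]

NON_AUTOSOMAL = ("X", "Y", "MT")
NON_CODING_BIOTYPES = ("lincRNA", "pseudogene", "miRNA", "antisense")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic cohort.

    Defaults give a half-scale analogue of a 490-vs-60 cohort (245 cases,
    30 controls), 1000 genes of which 10 signal genes in 2 correlated
    modules, an e-fold (log-scale 1.0) case shift on signal genes, and 20%
    of genes constructed to fail the >=10-in->=10 high-expression filter.
    """

    n_case: int = 245
    n_control: int = 30
    n_genes: int = 1000
    n_signal_genes: int = 10
    n_modules: int = 2
    effect_size: float = 1.0  # natural-log shift of signal-gene means in cases
    within_module_correlation: float = 0.8
    noise_dispersion: float = 0.3  # NB dispersion alpha (var = mu + alpha mu^2)
    biological_sd: float = 0.4  # per-gene log-scale biological variability
    frac_low_count: float = 0.2
    frac_non_autosomal: float = 0.1
    frac_non_coding: float = 0.15
    frac_excluded: float = 0.02
    signal_log_mean: float = float(np.log(100.0))
    mode: str = "nb"  # nb | gaussian
    seed: int = 0

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per class")
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes exceeds n_genes")
        if self.n_modules > self.n_signal_genes or self.n_modules < 1:
            raise ValueError("n_modules must be in [1, n_signal_genes]")
        if not 0.0 <= self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must be in [0, 1)")
        for name in ("frac_low_count", "frac_non_autosomal", "frac_non_coding", "frac_excluded"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mode not in ("nb", "gaussian"):
            raise ValueError(f"mode must be 'nb' or 'gaussian', got {self.mode!r}")
        reserved = self.n_signal_genes
        flagged = int(self.n_genes * (self.frac_low_count + self.frac_non_autosomal + self.frac_non_coding))
        if reserved + flagged > self.n_genes:
            raise ValueError("flagged gene fractions leave no room for signal genes")


def _module_of(spec: SyntheticSpec) -> np.ndarray:
    """Signal gene -> module index, modules as equal as possible."""
    return np.arange(spec.n_signal_genes) % spec.n_modules


def generate_dataset(spec: SyntheticSpec):
    """Draw one cohort.

    Returns ``(dataset, annotation, truth)`` where ``truth`` records the
    planted signal genes, their modules, the constructed low-count genes and
    the generator parameters. Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_s = spec.n_case + spec.n_control
    y = np.concatenate([np.ones(spec.n_case, int), np.zeros(spec.n_control, int)])

    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n_s)]

    # gene roles: the first n_signal genes are signal; flags are drawn from the rest
    signal = np.zeros(spec.n_genes, bool)
    signal[: spec.n_signal_genes] = True
    rest = np.flatnonzero(~signal)
    rest = rng.permutation(rest)
    n_low = int(round(spec.frac_low_count * spec.n_genes))
    n_nonauto = int(round(spec.frac_non_autosomal * spec.n_genes))
    n_noncod = int(round(spec.frac_non_coding * spec.n_genes))
    n_excl = int(round(spec.frac_excluded * spec.n_genes))
    low = np.zeros(spec.n_genes, bool)
    low[rest[:n_low]] = True
    nonauto = np.zeros(spec.n_genes, bool)
    nonauto[rest[n_low : n_low + n_nonauto]] = True
    noncod = np.zeros(spec.n_genes, bool)
    noncod[rest[n_low + n_nonauto : n_low + n_nonauto + n_noncod]] = True
    excl = np.zeros(spec.n_genes, bool)
    excl[rest[n_low + n_nonauto + n_noncod : n_low + n_nonauto + n_noncod + n_excl]] = True

    # base log-means: expressed genes span ~20-500 counts, low-count genes << 10
    log_mu = rng.uniform(np.log(20.0), np.log(500.0), size=spec.n_genes)
    log_mu[signal] = spec.signal_log_mean
    log_mu[low] = rng.uniform(np.log(0.05), np.log(0.5), size=n_low)

    # latent log-scale expression with module-correlated signal genes
    z = log_mu[:, None] + spec.biological_sd * rng.standard_normal((spec.n_genes, n_s))
    rho = spec.within_module_correlation
    module = _module_of(spec)
    u = rng.standard_normal((spec.n_modules, n_s))
    for g in range(spec.n_signal_genes):
        eps = rng.standard_normal(n_s)
        z[g] = log_mu[g] + spec.biological_sd * (
            np.sqrt(rho) * u[module[g]] + np.sqrt(1.0 - rho) * eps
        )
    z[signal] += spec.effect_size * y[None, :]

    mu = np.exp(z)
    if spec.mode == "nb":
        if spec.noise_dispersion > 0:
            shape = 1.0 / spec.noise_dispersion
            lam = rng.gamma(shape, mu * spec.noise_dispersion)
        else:
            lam = mu
        values = rng.poisson(lam).astype(float)
    else:
        values = mu

    chromosome = np.array([str(rng.integers(1, 23)) for _ in range(spec.n_genes)], dtype=object)
    chromosome[nonauto] = rng.choice(NON_AUTOSOMAL, size=n_nonauto)
    biotype = np.full(spec.n_genes, "protein_coding", dtype=object)
    biotype[noncod] = rng.choice(NON_CODING_BIOTYPES, size=n_noncod)
    ann = pd.DataFrame(
        {"chromosome": chromosome, "biotype": biotype, "excluded": excl},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    labels = pd.Series(y, index=sample_ids, name="label")
    truth = {
        "signal_genes": [gene_ids[i] for i in range(spec.n_signal_genes)],
        "modules": {gene_ids[i]: int(module[i]) for i in range(spec.n_signal_genes)},
        "low_count_genes": [gene_ids[i] for i in np.flatnonzero(low)],
        "spec": asdict(spec),
    }
    return LabeledDataset(matrix, labels), ann, truth


def expected_separability(spec: SyntheticSpec) -> float:
    """Analytic approximation of the Bayes-optimal AUC for the planted shift.

    Considers the oracle statistic s = mean log-expression of the signal
    genes. Its class means differ by ``effect_size`` and its variance
    follows from the module-correlated latent plus (in nb mode) a
    delta-method approximation of the counting noise on the log scale
    (1/mu + alpha per gene). AUC = Phi(effect / sqrt(2 var_s)).
    """
    spec.validate()
    if spec.effect_size == 0:
        return 0.5
    m = spec.n_signal_genes
    rho = spec.within_module_correlation
    sigma2 = spec.biological_sd**2
    module = _module_of(spec)
    # var of mean of shared module factors: sum over modules of (n_m/m)^2
    w = np.bincount(module, minlength=spec.n_modules) / m
    var_shared = rho * sigma2 * float(np.sum(w**2))
    var_indep = (1.0 - rho) * sigma2 / m
    var_count = 0.0
    if spec.mode == "nb":
        mu = np.exp(spec.signal_log_mean)
        var_count = (1.0 / mu + spec.noise_dispersion) / m
    var_s = var_shared + var_indep + var_count
    return float(norm.cdf(spec.effect_size / np.sqrt(2.0 * var_s)))
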