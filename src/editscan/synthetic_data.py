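"""Seeded, truth-annotated generators for every pipeline stage.

All generators are pure functions of their configuration (including the
seed): the same inputs always yield byte-identical tables. Each returns its
data object together with a truth table recording the injected effect per
simulated entity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from editscan.errors import ValidationError
from editscan.pileup_io import (
    ExpressionMatrix,
    PeptideRatioTable,
    SiteCountTable,
    SiteKey,
)

_GROUP0, _GROUP1 = "WT", "KO"


@dataclass(frozen=True)
class PileupSimConfig:
    """Configuration for replicated binomial/beta-binomial pileup simulation.

    ``base_freq_beta`` gives the (a, b) of the Beta distribution baseline
    editing frequencies are drawn from; Beta(1, 9) keeps most frequencies
    low. ``overdispersion_rho`` is the beta-binomial intra-site correlation;
    0 means pure binomial sampling.
    """

    n_sites: int = 100
    n_null_sites: int = 50
    samples_per_group: int = 4
    coverage_mean: float = 50.0
    coverage_model: str = "poisson"  # or "negative-binomial"
    coverage_dispersion: float = 5.0  # nbinom size parameter
    base_freq_beta: tuple[float, float] = (1.0, 9.0)
    delta_f: float = 0.3
    overdispersion_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null_sites > self.n_sites:
            raise ValidationError("n_null_sites cannot exceed n_sites")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValidationError("overdispersion_rho must be in [0, 1)")
        if self.coverage_model not in ("poisson", "negative-binomial"):
            raise ValidationError(f"unknown coverage model {self.coverage_model!r}")
        if self.samples_per_group < 1:
            raise ValidationError("samples_per_group must be >= 1")


def _draw_counts(rng: np.random.Generator, n: np.ndarray, f: np.ndarray, rho: float) -> np.ndarray:
    """Binomial draws, or beta-binomial with intra-site correlation rho.

    Beta-binomial uses the standard mean/correlation parameterization
    alpha = f (1 - rho) / rho, beta = (1 - f) (1 - rho) / rho.
    """
    if rho == 0.0:
        return rng.binomial(n, f)
    scale = (1.0 - rho) / rho
    p = np.where(
        (f > 0) & (f < 1),
        rng.beta(np.clip(f * scale, 1e-12, None), np.clip((1.0 - f) * scale, 1e-12, None)),
        f,
    )
    return rng.binomial(n, p)


def simulate_pileups(config: PileupSimConfig) -> tuple[SiteCountTable, pd.DataFrame]:
    """Simulate a replicated two-group site-count table with known truth.

    Non-null sites get ``delta_f`` added to the group-1 frequency (truncated
    into [0, 1] with a warning when necessary). The truth table has one row
    per site with the realized effect and a null flag.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_sites
    spg = config.samples_per_group
    n_samples = 2 * spg
    samples = [f"{_GROUP0}{i + 1}" for i in range(spg)] + [
        f"{_GROUP1}{i + 1}" for i in range(spg)
    ]
    groups = {s: (_GROUP0 if s.startswith(_GROUP0) else _GROUP1) for s in samples}
    group1 = np.array([groups[s] == _GROUP1 for s in samples])

    a, b = config.base_freq_beta
    base = rng.beta(a, b, size=n_sites)
    is_null = np.zeros(n_sites, dtype=bool)
    is_null[: config.n_null_sites] = True
    f1 = base + np.where(is_null, 0.0, config.delta_f)
    clipped = (f1 < 0) | (f1 > 1)
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} sites had group-1 frequency truncated into [0, 1]",
            stacklevel=2,
        )
        f1 = np.clip(f1, 0.0, 1.0)

    if config.coverage_model == "poisson":
        n = rng.poisson(config.coverage_mean, size=(n_sites, n_samples))
    else:
        size = config.coverage_dispersion
        p = size / (size + config.coverage_mean)
        n = rng.negative_binomial(size, p, size=(n_sites, n_samples))

    f = np.where(group1[None, :], f1[:, None], base[:, None])
    k = _draw_counts(rng, n, f, config.overdispersion_rho)

    sites = [
        SiteKey(chrom="chrS", pos=i + 1, ref_base="A", edited_base="G",
                strand=".", gene=f"SGENE{i + 1:05d}")
        for i in range(n_sites)
    ]
    table = SiteCountTable(sites=sites, samples=samples, groups=groups, k=k, n=n)
    truth = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "gene": [s.gene for s in sites],
            "base_freq": base,
            "true_effect": f1 - base,
            "is_null": is_null,
        }
    )
    return table, truth


def simulate_expression(
    n_genes: int = 100,
    n_informative: int = 5,
    shift_sd_units: float = 4.0,
    samples_per_group: int = 6,
    n_female_per_group: int = 0,
    baseline_log_mean: float = 3.0,
    baseline_log_sd: float = 1.0,
    noise_log_sd: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Two-group log-normal expression matrix with a known informative subset.

    Informative genes carry a group mean shift of ``shift_sd_units`` noise
    standard deviations on the log scale. Samples are male by default;
    ``n_female_per_group`` adds female samples (to exercise the male-only
    preprocessing filter).
    """
    if n_informative > n_genes:
        raise ValidationError("n_informative cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    informative = np.zeros(n_genes, dtype=bool)
    informative[:n_informative] = True

    samples, sex, group = [], [], []
    for g, label in ((0, _GROUP0), (1, "AS")):
        for i in range(samples_per_group):
            samples.append(f"{label}{i + 1}")
            group.append(label)
            sex.append("F" if i < n_female_per_group else "M")
    is_case = np.array([g == "AS" for g in group])

    mu = rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes)
    log_expr = mu[:, None] + rng.normal(
        0.0, noise_log_sd, size=(n_genes, len(samples))
    )
    shift = shift_sd_units * noise_log_sd
    log_expr[np.ix_(informative, is_case)] += shift
    values = pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    meta = pd.DataFrame({"sample": samples, "group": group, "sex": sex}).set_index(
        "sample"
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "true_effect": np.where(informative, shift, 0.0),
            "is_null": ~informative,
        }
    )
    return ExpressionMatrix(values=values, sample_meta=meta), truth


def simulate_silac(
    n_proteins: int = 100,
    n_changed: int = 10,
    true_pct_change: float = 25.0,
    peptides_per_protein: int = 5,
    noise_sd: float = 0.0,
    n_experiments: int = 2,
    seed: int = 0,
) -> tuple[PeptideRatioTable, pd.DataFrame]:
    """Peptide-level H/L ratio table with planted protein-level changes.

    Changed proteins alternate up/down; the change is concordant across
    experiments. Peptide ratios are log-normal around the true protein
    ratio with log-sd ``noise_sd``.
    """
    if n_changed > n_proteins:
        raise ValidationError("n_changed cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    proteins = [f"PROT{i + 1:04d}" for i in range(n_proteins)]
    factor = 1.0 + true_pct_change / 100.0
    true_ratio = np.ones(n_proteins)
    for i in range(n_changed):
        true_ratio[i] = factor if i % 2 == 0 else 1.0 / factor
    rows = []
    for i, protein in enumerate(proteins):
        for e in range(1, n_experiments + 1):
            noise = rng.normal(0.0, noise_sd, size=peptides_per_protein) if noise_sd else np.zeros(peptides_per_protein)
            for j in range(peptides_per_protein):
                rows.append(
                    {
                        "protein": protein,
                        "peptide": f"{protein}_pep{j + 1}",
                        "ratio": true_ratio[i] * float(np.exp(noise[j])),
                        "experiment": f"exp{e}",
                    }
                )
    table = PeptideRatioTable(records=pd.DataFrame(rows))
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "true_ratio": true_ratio,
            "true_pct_change": 100.0 * (true_ratio - 1.0),
            "is_null": true_ratio == 1.0,
        }
    )
    return table, truth
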