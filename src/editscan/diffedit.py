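"""Replicated differential-editing test.

Pipeline per site: require coverage of at least ``min_reads`` in every
sample, estimate the per-replicate editing frequency with its Wilks CI,
regress frequency on the group indicator with inverse-variance weights
derived from the CI widths, and call the site significant when the slope
exceeds ``sd_threshold`` standard errors (strictly). Significant sites are
classified hyper (group1 edited more) or hypo.

The significance rule has two documented readings of "more than 3 standard
deviations from the confidence limits":

``zstat`` (default)
    |slope| / SE(slope) > sd_threshold.
``ci_margin``
    zero lies more than sd_threshold standard errors outside the slope's
    level-CI, i.e. |slope|/SE > sd_threshold + z(level). Stricter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from editscan.binomial_ci import ci_to_sd, wilks_ci
from editscan.errors import ValidationError
from editscan.pileup_io import GenePanel, SiteCountTable, SiteKey


@dataclass(frozen=True)
class DiffEditConfig:
    min_reads: int = 10
    sd_threshold: float = 3.0
    level: float = 0.95
    weighted: bool = True
    rule: str = "zstat"  # or "ci_margin"

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValidationError("min_reads must be >= 1")
        if self.sd_threshold <= 0:
            raise ValidationError("sd_threshold must be > 0")
        if self.rule not in ("zstat", "ci_margin"):
            raise ValidationError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class RegressionResult:
    """Weighted two-group comparison of editing frequency.

    slope is the weighted mean frequency of group 1 minus group 0; se comes
    from the weighted normal equations; zstat = slope / se.
    """

    slope: float
    se: float
    zstat: float
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"se must be positive, got {self.se}")
        if not np.isfinite(self.zstat):
            raise ValidationError(f"zstat must be finite, got {self.zstat}")


@dataclass(frozen=True)
class DiffEditResult:
    site: SiteKey
    passed_coverage: bool
    regression: RegressionResult | None
    significant: bool
    direction: str  # 'hyper' | 'hypo' | 'none'

    def __post_init__(self) -> None:
        if self.significant and not self.passed_coverage:
            raise ValidationError("significant result must have passed coverage")
        if (self.direction != "none") != self.significant:
            raise ValidationError("direction set iff significant")


@dataclass
class EditSummary:
    n_sites_tested: int
    n_significant: int
    n_hyper: int
    n_hypo: int
    genes: set[str]
    panel_counts: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sites_tested": self.n_sites_tested,
            "n_significant": self.n_significant,
            "n_hyper": self.n_hyper,
            "n_hypo": self.n_hypo,
            "n_genes": len(self.genes),
            "genes": sorted(self.genes),
            "panel_counts": self.panel_counts,
        }


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (16/113 -> 14%)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


def coverage_filter(table: SiteCountTable, config: DiffEditConfig) -> SiteCountTable:
    """Retain exactly the sites covered by >= min_reads in EVERY sample."""
    keep = np.flatnonzero((table.n >= config.min_reads).all(axis=1))
    return table.subset(keep)


def site_regression(
    k_by_sample: np.ndarray,
    n_by_sample: np.ndarray,
    groups: np.ndarray,
    level: float = 0.95,
    weighted: bool = True,
) -> RegressionResult:
    """Weighted least squares of per-replicate frequency on group indicator.

    With a binary covariate WLS reduces to the difference of weighted group
    means; the standard error follows from the weighted normal equations:
    Var(slope) = 1/sum(w_1) + 1/sum(w_0).
    """
    k = np.asarray(k_by_sample, dtype=np.int64)
    n = np.asarray(n_by_sample, dtype=np.int64)
    g = np.asarray(groups, dtype=np.int64)
    if k.shape != n.shape or k.shape != g.shape:
        raise ValidationError("k, n and groups must have equal length")
    if (n < 1).any():
        raise ValidationError("all samples must have coverage >= 1")
    if not ((g == 0).any() and (g == 1).any()):
        raise ValidationError("each group needs at least one sample")
    f_hat = k / n
    if weighted:
        sigma = np.array(
            [ci_to_sd(wilks_ci(int(ki), int(ni), level)) for ki, ni in zip(k, n)]
        )
        w = 1.0 / sigma**2
    else:
        w = np.ones_like(f_hat)
    w0, w1 = w[g == 0], w[g == 1]
    mean0 = float(np.sum(w0 * f_hat[g == 0]) / np.sum(w0))
    mean1 = float(np.sum(w1 * f_hat[g == 1]) / np.sum(w1))
    slope = mean1 - mean0
    if weighted:
        # model-based: Var(f_hat_i) = sigma_i^2 taken as known
        se = float(np.sqrt(1.0 / np.sum(w1) + 1.0 / np.sum(w0)))
    else:
        # OLS: residual-variance standard error (needs > 2 samples)
        n0, n1 = int(np.sum(g == 0)), int(np.sum(g == 1))
        if n0 + n1 <= 2:
            raise ValidationError("unweighted regression needs > 2 samples")
        resid = f_hat - np.where(g == 1, mean1, mean0)
        s2 = float(np.sum(resid**2) / (n0 + n1 - 2))
        se = float(np.sqrt(max(s2, 1e-300) * (1.0 / n0 + 1.0 / n1)))
    return RegressionResult(
        slope=slope, se=se, zstat=slope / se, weights=tuple(float(x) for x in w)
    )


def call_site(reg: RegressionResult, config: DiffEditConfig) -> tuple[bool, str]:
    """Apply the strict sd-threshold rule; slope 0 is never significant."""
    threshold = config.sd_threshold
    if config.rule == "ci_margin":
        threshold = threshold + float(stats.norm.ppf(0.5 * (1.0 + config.level)))
    significant = abs(reg.zstat) > threshold and reg.slope != 0.0
    if not significant:
        return False, "none"
    return True, ("hyper" if reg.slope > 0 else "hypo")


def run_diffedit(
    table: SiteCountTable,
    config: DiffEditConfig = DiffEditConfig(),
    group_order: tuple[str, str] | None = None,
) -> list[DiffEditResult]:
    """Coverage filter then regression + call for every site.

    Group 1 (the case/knockout group) is the second label of ``group_order``,
    or the lexicographically larger label when not given. Results cover ALL
    input sites; filtered sites carry ``passed_coverage=False`` and no
    regression.
    """
    labels = table.group_labels
    if len(labels) != 2:
        raise ValidationError(f"exactly two groups required, got {labels}")
    if group_order is None:
        group_order = (labels[0], labels[1])
    elif sorted(group_order) != labels:
        raise ValidationError(
            f"group_order {group_order} does not match table groups {labels}"
        )
    g = np.array(
        [0 if table.groups[s] == group_order[0] else 1 for s in table.samples],
        dtype=np.int64,
    )
    passed = (table.n >= config.min_reads).all(axis=1)
    results: list[DiffEditResult] = []
    for i, site in enumerate(table.sites):
        if not passed[i]:
            results.append(
                DiffEditResult(
                    site=site,
                    passed_coverage=False,
                    regression=None,
                    significant=False,
                    direction="none",
                )
            )
            continue
        reg = site_regression(
            table.k[i], table.n[i], g, level=config.level, weighted=config.weighted
        )
        significant, direction = call_site(reg, config)
        results.append(
            DiffEditResult(
                site=site,
                passed_coverage=True,
                regression=reg,
                significant=significant,
                direction=direction,
            )
        )
    return results


def summarize(
    results: list[DiffEditResult], panels: list[GenePanel] | None = None
) -> EditSummary:
    """Counts of tested/significant/hyper/hypo sites plus panel overlaps.

    A gene enters the summary when it labels at least one significant site.
    Panel percentages are rounded to the nearest integer, half away from
    zero; with zero significant genes they are reported as undefined.
    """
    tested = [r for r in results if r.passed_coverage]
    sig = [r for r in tested if r.significant]
    n_hyper = sum(1 for r in sig if r.direction == "hyper")
    n_hypo = sum(1 for r in sig if r.direction == "hypo")
    genes = {r.site.gene for r in sig if r.site.gene}
    panel_counts: dict[str, dict] = {}
    for panel in panels or []:
        count = sum(1 for gene in genes if gene in panel)
        if genes:
            entry = {
                "count": count,
                "percent": round_half_away(100.0 * count / len(genes)),
                "defined": True,
            }
        else:
            entry = {"count": 0, "percent": 0, "defined": False}
        panel_counts[panel.name] = entry
    return EditSummary(
        n_sites_tested=len(tested),
        n_significant=len(sig),
        n_hyper=n_hyper,
        n_hypo=n_hypo,
        genes=genes,
        panel_counts=panel_counts,
    )


def results_to_frame(results: list[DiffEditResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "ref": r.site.ref_base,
                "alt": r.site.edited_base,
                "strand": r.site.strand,
                "gene": r.site.gene,
                "passed_coverage": r.passed_coverage,
                "slope": r.regression.slope if r.regression else np.nan,
                "se": r.regression.se if r.regression else np.nan,
                "zstat": r.regression.zstat if r.regression else np.nan,
                "significant": r.significant,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
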