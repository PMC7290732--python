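"""SILAC peptide-to-protein pooling and proteome/transcriptome integration.

Threshold rules (defaults):

replicated_changes
    |change| >= 20% in BOTH experiments, same direction.
concordant_mrna_protein
    |change| > 15% in at least one experiment, mRNA p < 0.05, protein and
    mRNA change in the same direction.
protein_only_candidates
    |change| >= 20% in BOTH experiments, same direction, mRNA unchanged
    (p >= 0.05 and |log2 FC| < log2(1.2)); upregulated calls are flagged as
    candidate substrates.

Percent change is measured on the linear H/L ratio scale. The default
``symmetric`` convention treats a ratio r as changed by x% when
r >= 1 + x/100 (up) or r <= 1/(1 + x/100) (down), which is invariant under
swapping heavy and light channels; the ``linear`` convention uses
r <= 1 - x/100 for down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from editscan.errors import FormatError, ValidationError
from editscan.pileup_io import GenePanel, PeptideRatioTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRatioRecord:
    protein: str
    experiment: str
    ratio: float
    n_peptides: int
    fold_change_pct: float  # signed percent change, 100*(ratio - 1)

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValidationError(f"pooled ratio must be positive, got {self.ratio}")
        if self.n_peptides < 1:
            raise ValidationError("n_peptides must be >= 1")


@dataclass(frozen=True)
class IntegrationCall:
    id: str  # protein or gene identifier
    category: str  # replicated_protein_change | concordant_mrna_protein | protein_only_candidate
    direction: str  # up | down
    apoptosis_flag: bool = False
    mitochondria_flag: bool = False


def pool_ratios(peptides: PeptideRatioTable, method: str = "median") -> list[ProteinRatioRecord]:
    """Pool peptide H/L ratios into one ratio per (protein, experiment).

    ``median`` (default) is robust to outlier peptides; ``log_mean`` is the
    geometric mean (mean of log ratios).
    """
    if method not in ("median", "log_mean"):
        raise ValidationError(f"unknown pooling method {method!r}")
    records = []
    grouped = peptides.records.groupby(["protein", "experiment"], sort=True)
    for (protein, experiment), grp in grouped:
        ratios = grp["ratio"].to_numpy(dtype=float)
        if method == "median":
            pooled = float(np.median(ratios))
        else:
            pooled = float(np.exp(np.mean(np.log(ratios))))
        records.append(
            ProteinRatioRecord(
                protein=str(protein),
                experiment=str(experiment),
                ratio=pooled,
                n_peptides=len(ratios),
                fold_change_pct=100.0 * (pooled - 1.0),
            )
        )
    return records


def _changed(ratio: float, min_pct: float, convention: str, strict: bool = False) -> int:
    """Signed change test: +1 up, -1 down, 0 below threshold."""
    up_cut = 1.0 + min_pct / 100.0
    down_cut = 1.0 / up_cut if convention == "symmetric" else 1.0 - min_pct / 100.0
    if (ratio > up_cut) if strict else (ratio >= up_cut):
        return 1
    if (ratio < down_cut) if strict else (ratio <= down_cut):
        return -1
    return 0


def _by_protein(records: list[ProteinRatioRecord]) -> dict[str, dict[str, ProteinRatioRecord]]:
    out: dict[str, dict[str, ProteinRatioRecord]] = {}
    for rec in records:
        out.setdefault(rec.protein, {})[rec.experiment] = rec
    return out


def replicated_changes(
    records: list[ProteinRatioRecord],
    min_pct: float = 20.0,
    convention: str = "symmetric",
    n_experiments: int = 2,
) -> list[IntegrationCall]:
    """Proteins changed by >= min_pct in BOTH experiments, same direction."""
    calls = []
    for protein, by_exp in sorted(_by_protein(records).items()):
        if len(by_exp) < n_experiments:
            logger.info("protein %s present in %d/%d experiments; excluded",
                        protein, len(by_exp), n_experiments)
            continue
        signs = {_changed(r.ratio, min_pct, convention) for r in by_exp.values()}
        if signs == {1}:
            calls.append(IntegrationCall(protein, "replicated_protein_change", "up"))
        elif signs == {-1}:
            calls.append(IntegrationCall(protein, "replicated_protein_change", "down"))
    return calls


def concordant_mrna_protein(
    records: list[ProteinRatioRecord],
    mrna_stats: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    protein_pct: float = 15.0,
    mrna_p: float = 0.05,
    convention: str = "symmetric",
) -> list[IntegrationCall]:
    """Genes changed > protein_pct in >= 1 experiment with concordant
    significant mRNA change (p < mrna_p, same sign).

    ``mrna_stats`` is indexed by gene with columns ``log2fc`` and ``pvalue``;
    ``mapping`` maps protein id to gene symbol (identity when omitted).
    """
    _check_mrna_stats(mrna_stats)
    calls = []
    for protein, by_exp in sorted(_by_protein(records).items()):
        gene = (mapping or {}).get(protein, protein if mapping is None else None)
        if gene is None or gene not in mrna_stats.index:
            logger.info("protein %s has no mapped mRNA record; excluded", protein)
            continue
        signs = [_changed(r.ratio, protein_pct, convention, strict=True)
                 for r in by_exp.values()]
        prot_sign = 0
        if 1 in signs and -1 not in signs:
            prot_sign = 1
        elif -1 in signs and 1 not in signs:
            prot_sign = -1
        if prot_sign == 0:
            continue
        row = mrna_stats.loc[gene]
        if row["pvalue"] >= mrna_p:
            continue
        mrna_sign = int(np.sign(row["log2fc"]))
        if mrna_sign != prot_sign:
            continue
        calls.append(
            IntegrationCall(gene, "concordant_mrna_protein",
                            "up" if prot_sign > 0 else "down")
        )
    return calls


def protein_only_candidates(
    records: list[ProteinRatioRecord],
    mrna_stats: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    min_pct: float = 20.0,
    mrna_p: float = 0.05,
    mrna_fc_bound: float = 1.2,
    convention: str = "symmetric",
    n_experiments: int = 2,
) -> list[IntegrationCall]:
    """Proteins replicated-changed by >= min_pct with unchanged mRNA.

    "Unchanged" means p >= mrna_p AND |log2 FC| < log2(mrna_fc_bound).
    Upregulated calls are candidate degradation substrates.
    """
    _check_mrna_stats(mrna_stats)
    replicated = replicated_changes(records, min_pct, convention, n_experiments)
    calls = []
    for call in replicated:
        gene = (mapping or {}).get(call.id, call.id if mapping is None else None)
        if gene is None or gene not in mrna_stats.index:
            logger.info("protein %s has no mapped mRNA record; excluded", call.id)
            continue
        row = mrna_stats.loc[gene]
        unchanged = (
            row["pvalue"] >= mrna_p
            and abs(row["log2fc"]) < np.log2(mrna_fc_bound)
        )
        if unchanged:
            calls.append(
                IntegrationCall(call.id, "protein_only_candidate", call.direction)
            )
    return calls


def annotate_percentages(
    calls: list[IntegrationCall], panels: list[GenePanel]
) -> pd.DataFrame:
    """Per direction (up/down/all) and panel: count, members, percent.

    Percent is nearest-integer, half away from zero; undefined (None) when a
    direction has no calls.
    """
    from editscan.diffedit import round_half_away

    rows = []
    subsets = {
        "up": [c for c in calls if c.direction == "up"],
        "down": [c for c in calls if c.direction == "down"],
        "all": list(calls),
    }
    for direction, subset in subsets.items():
        for panel in panels:
            members = sum(1 for c in subset if c.id in panel)
            rows.append(
                {
                    "direction": direction,
                    "panel": panel.name,
                    "n_calls": len(subset),
                    "n_in_panel": members,
                    "percent": round_half_away(100.0 * members / len(subset))
                    if subset
                    else None,
                }
            )
    return pd.DataFrame(rows)


def read_mrna_stats(path) -> pd.DataFrame:
    """Read a (gene, log2fc, pvalue) TSV indexed by gene."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _check_mrna_stats(df.set_index("gene") if "gene" in df.columns else df)
    return df.set_index("gene")


def read_protein_gene_map(path) -> dict[str, str]:
    """Read a two-column (protein, gene) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"protein", "gene"}.issubset(df.columns):
        raise FormatError("mapping file needs columns 'protein' and 'gene'")
    return dict(zip(df["protein"].astype(str), df["gene"].astype(str)))


def _check_mrna_stats(df: pd.DataFrame) -> None:
    missing = [c for c in ("log2fc", "pvalue") if c not in df.columns]
    if missing:
        raise FormatError(f"mRNA stats missing columns: {missing}")
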