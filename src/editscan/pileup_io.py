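"""Input/output for site-level editing counts and companion tables.

Formats
-------
Site-count TSV
    Tab-delimited with ``#``-prefixed comment lines ignored. Header columns
    ``chrom, pos, ref, alt, strand, gene`` followed by paired per-sample
    columns ``<sample>_edited`` and ``<sample>_total``. Coordinates are
    1-based, matching mpileup.
Gene panel
    Plain text, one gene symbol per line; blank lines and ``#`` comments
    ignored. Duplicate symbols (case-insensitive) are dropped with a warning.
Expression TSV
    First column ``gene``, remaining columns one per sample; a separate
    metadata TSV carries ``sample, group, sex``.
Peptide-ratio TSV
    Columns ``protein, peptide, ratio, experiment``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from editscan.errors import FormatError, MpileupParseError, ValidationError

_BASES = frozenset("ACGT")
_SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "strand", "gene"]


@dataclass(frozen=True, order=True)
class SiteKey:
    """Identity of one candidate editing site.

    ``pos`` is 1-based. Strand may be '.', meaning unknown; the downstream
    statistics never use strand.
    """

    chrom: str
    pos: int
    ref_base: str
    edited_base: str
    strand: str = "."
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        for name in ("ref_base", "edited_base"):
            b = getattr(self, name)
            if b not in _BASES:
                raise ValidationError(f"{name} must be one of A/C/G/T, got {b!r}")
        if self.ref_base == self.edited_base:
            raise ValidationError(
                f"ref_base and edited_base must differ at {self.chrom}:{self.pos}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be +, - or '.', got {self.strand!r}")


@dataclass
class SiteCountTable:
    """Per-site, per-sample edited counts k and total coverage n.

    ``k`` and ``n`` are (sites x samples) integer arrays aligned with
    ``sites`` and ``samples``. ``groups`` maps each sample to one of
    exactly two group labels.
    """

    sites: list[SiteKey]
    samples: list[str]
    groups: dict[str, str]
    k: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.k.shape != shape or self.n.shape != shape:
            raise ValidationError(
                f"count arrays must be {shape}, got k{self.k.shape} n{self.n.shape}"
            )
        if set(self.samples) != set(self.groups):
            raise ValidationError("groups must map exactly the table's samples")
        labels = sorted(set(self.groups.values()))
        if len(labels) > 2:
            raise ValidationError(f"at most two groups allowed, got {labels}")
        if (self.k < 0).any() or (self.n < 0).any():
            raise ValidationError("counts must be non-negative")
        bad = np.argwhere(self.k > self.n)
        if bad.size:
            i, j = bad[0]
            site = self.sites[i]
            raise ValidationError(
                f"k > n at {site.chrom}:{site.pos} sample {self.samples[j]} "
                f"(k={self.k[i, j]}, n={self.n[i, j]})"
            )

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self.groups.values()))

    def __len__(self) -> int:
        return len(self.sites)

    def subset(self, row_indices: np.ndarray) -> "SiteCountTable":
        """New table with the given site rows, order preserved."""
        idx = np.asarray(row_indices)
        return SiteCountTable(
            sites=[self.sites[int(i)] for i in idx],
            samples=list(self.samples),
            groups=dict(self.groups),
            k=self.k[idx],
            n=self.n[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "chrom": [s.chrom for s in self.sites],
            "pos": [s.pos for s in self.sites],
            "ref": [s.ref_base for s in self.sites],
            "alt": [s.edited_base for s in self.sites],
            "strand": [s.strand for s in self.sites],
            "gene": [s.gene for s in self.sites],
        }
        for j, sample in enumerate(self.samples):
            rows[f"{sample}_edited"] = self.k[:, j]
            rows[f"{sample}_total"] = self.n[:, j]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols (e.g. apoptosis, proliferation)."""

    name: str
    genes: tuple[str, ...]
    _normalized: frozenset[str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"panel {self.name!r} is empty")
        norm = [g.casefold() for g in self.genes]
        if len(set(norm)) != len(norm):
            raise ValidationError(f"panel {self.name!r} has duplicate symbols")
        object.__setattr__(self, "_normalized", frozenset(norm))

    def __contains__(self, gene: str) -> bool:
        # comparison is case-normalized; stored symbols stay verbatim
        return gene.casefold() in self._normalized

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group/sex metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol {dup!r}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        for col in ("group", "sex"):
            if col not in self.sample_meta.columns:
                raise FormatError(f"sample metadata missing column {col!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PeptideRatioTable:
    """Peptide-level H/L ratios: (protein, peptide, ratio, experiment)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["protein", "peptide", "ratio", "experiment"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise FormatError(f"peptide table missing columns: {missing}")
        bad = self.records[self.records["ratio"] <= 0]
        if len(bad):
            row = bad.iloc[0]
            raise ValidationError(
                f"H/L ratio must be positive, got {row['ratio']} for "
                f"protein {row['protein']} peptide {row['peptide']}"
            )


def read_site_counts(path, design: dict[str, str]) -> SiteCountTable:
    """Read a site-count TSV, matching samples against a sample->group design.

    Raises :class:`FormatError` for missing columns, :class:`ValidationError`
    for k > n cells or design samples absent from the file.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in _SITE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"site-count file missing column {col!r}")
    samples = list(design)
    for sample in samples:
        for suffix in ("edited", "total"):
            col = f"{sample}_{suffix}"
            if col not in df.columns:
                raise FormatError(
                    f"design sample {sample!r} absent from file: "
                    f"missing column {col!r}"
                )
    sites = [
        SiteKey(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_base=str(r.ref).upper(),
            edited_base=str(r.alt).upper(),
            strand=str(r.strand),
            gene="" if pd.isna(r.gene) else str(r.gene),
        )
        for r in df.itertuples()
    ]
    k = df[[f"{s}_edited" for s in samples]].to_numpy(dtype=np.int64)
    n = df[[f"{s}_total" for s in samples]].to_numpy(dtype=np.int64)
    return SiteCountTable(sites=sites, samples=samples, groups=dict(design), k=k, n=n)


def write_site_counts(table: SiteCountTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def parse_mpileup_line(line: str, edited_base: str) -> tuple[int, int]:
    """Count edited (k) and total aligned (n) base calls in one mpileup line.

    Follows the samtools mpileup text dialect: ``^`` consumes the following
    mapping-quality character, ``$`` marks a read end, ``+N``/``-N`` indel
    runs are skipped, ``*`` deletion placeholders count toward neither k nor
    n, and ``.``/``,`` are reference calls. ``edited_base`` matches
    case-insensitively (uppercase forward, lowercase reverse strand).
    """
    edited_base = edited_base.upper()
    if edited_base not in _BASES:
        raise ValidationError(f"edited_base must be A/C/G/T, got {edited_base!r}")
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise FormatError(
            f"mpileup line has {len(fields)} fields, expected >= 5"
        )
    depth_field = int(fields[3])
    bases = fields[4]
    k = n = deletions = 0
    i = 0
    while i < len(bases):
        c = bases[i]
        if c == "^":
            if i + 1 >= len(bases):
                raise MpileupParseError(
                    f"dangling '^' at offset {i}", offset=i
                )
            i += 2
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise MpileupParseError(
                    f"indel marker {c!r} without length at offset {i}", offset=i
                )
            length = int(bases[i + 1 : j])
            if j + length > len(bases):
                raise MpileupParseError(
                    f"indel run of length {length} at offset {i} "
                    "exceeds base string",
                    offset=i,
                )
            i = j + length
        elif c in ".,":
            n += 1
            i += 1
        elif c == "*":
            deletions += 1
            i += 1
        elif c in "<>":
            i += 1
        elif c.isalpha():
            n += 1
            if c.upper() == edited_base:
                k += 1
            i += 1
        else:
            raise MpileupParseError(
                f"unexpected character {c!r} at offset {i}", offset=i
            )
    if abs(depth_field - n) > deletions:
        warnings.warn(
            f"mpileup depth field {depth_field} disagrees with parsed "
            f"coverage {n} (deletion placeholders: {deletions}); "
            "using parsed value",
            stacklevel=2,
        )
    return k, n


def read_gene_panel(path, name: str | None = None) -> GenePanel:
    """Read a one-symbol-per-line gene panel; duplicates dropped with warning."""
    if name is None:
        name = str(path)
    seen: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            symbol = line.strip()
            if not symbol or symbol.startswith("#"):
                continue
            key = symbol.casefold()
            if key in seen:
                warnings.warn(
                    f"panel {name!r}: duplicate symbol {symbol!r} dropped",
                    stacklevel=2,
                )
                continue
            seen[key] = symbol
    if not seen:
        raise ValidationError(f"panel file {path} contains no gene symbols")
    return GenePanel(name=name, genes=tuple(seen.values()))


def read_expression(path, meta_path) -> ExpressionMatrix:
    """Read an expression TSV plus its (sample, group, sex) metadata TSV."""
    values = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", comment="#")
    if "sample" not in meta.columns:
        raise FormatError("metadata file missing column 'sample'")
    meta = meta.set_index("sample")
    meta.index = meta.index.astype(str)
    return ExpressionMatrix(values=values, sample_meta=meta)


def read_peptide_ratios(path) -> PeptideRatioTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    return PeptideRatioTable(records=df)
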