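"""Input/output layer: gene signatures, expression matrices, sample metadata
and IHC patient tables.

All gene identifiers pass through :func:`normalize_symbol`, which uppercases,
strips whitespace and resolves a small built-in alias table (informal
spellings such as ``Snail2`` and ``PD-L1`` map to the HGNC symbols ``SNAI2``
and ``CD274``).  Expression matrices are genes x samples, tab-delimited, and
assumed to be already normalized on a log scale.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Missing-value tokens accepted in expression matrices.
MISSING_TOKENS = ("NA", "nan", "NaN", "")

#: Built-in alias table mapping informal spellings to HGNC symbols.
#: Extensible per call via the ``aliases`` argument of normalize_symbol.
ALIASES: dict[str, str] = {
    "SNAI1": "SNAI1",
    "SNAIL": "SNAI1",
    "SNAIL1": "SNAI1",
    "SNAIL2": "SNAI2",
    "SLUG": "SNAI2",
    "B7-H1": "CD274",
    "PD-L1": "CD274",
    "PDL1": "CD274",
}


def normalize_symbol(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Normalize a gene symbol: strip, uppercase, resolve aliases.

    Parameters
    ----------
    raw
        Raw gene label. Must be non-empty after stripping.
    aliases
        Optional extra alias map (upper-case keys), layered over the
        built-in table.

    Returns
    -------
    str
        The normalized HGNC-style symbol. Idempotent.
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if aliases and sym in aliases:
        return aliases[sym].strip().upper()
    return ALIASES.get(sym, sym)


@dataclass(frozen=True)
class GeneSignature:
    """A named pair of disjoint up/down gene sets with optional weights.

    ``up_genes`` are the genes elevated in the phenotype (mesenchymal genes
    for EMT, claudin-low-high genes for CL); ``down_genes`` are suppressed
    (epithelial/claudin genes).  Order is preserved for deterministic
    reporting.
    """

    name: str
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        up = tuple(normalize_symbol(g) for g in self.up_genes)
        down = tuple(normalize_symbol(g) for g in self.down_genes)
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)
        if len(set(up)) != len(up) or len(set(down)) != len(down):
            raise ValueError(f"signature {self.name!r}: duplicate genes within a set")
        overlap = set(up) & set(down)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both up and down sets: "
                f"{sorted(overlap)}"
            )
        if not up and not down:
            raise ValueError(f"signature {self.name!r}: no genes")
        if self.weights is not None:
            w = {normalize_symbol(g): float(v) for g, v in self.weights.items()}
            missing = (set(up) | set(down)) - set(w)
            if missing:
                raise ValueError(
                    f"signature {self.name!r}: weights missing for {sorted(missing)}"
                )
            object.__setattr__(self, "weights", w)

    @property
    def genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    def __len__(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


# The 17-gene EMT signature: 12 mesenchymal genes elevated during EMT and the
# 5 epithelial/junction genes suppressed during EMT (E-cadherin, three
# claudins, desmoplakin).
_EMT_UP = (
    "ZEB1", "ZEB2", "SNAI1", "SNAI2", "TWIST1", "TWIST2",
    "FOXC2", "VIM", "FN1", "SOX10", "MMP2", "MMP3",
)
_EMT_DOWN = ("CDH1", "CLDN3", "CLDN4", "CLDN7", "DSP")


def builtin_emt_signature() -> GeneSignature:
    """Return the built-in 17-gene EMT signature (12 up, 5 down)."""
    return GeneSignature("EMT", _EMT_UP, _EMT_DOWN)


def load_signature_gmt(
    path: str | Path, up_set_name: str, down_set_name: str
) -> GeneSignature:
    """Load a signature from a GMT file as an up-set / down-set pair.

    The GMT format is one gene set per line: name, description, then the
    member genes, tab-separated.  The signature takes its name from the
    common prefix of the two set names when they follow the
    ``<NAME>_UP`` / ``<NAME>_DN`` convention, else from ``up_set_name``.
    """
    sets = read_gmt(path)
    for wanted in (up_set_name, down_set_name):
        if wanted not in sets:
            raise KeyError(f"gene set {wanted!r} not found in {path}")
    up = sets[up_set_name]
    down = sets[down_set_name]
    if not up or not down:
        raise ValueError(f"empty gene set in {path}")
    name = up_set_name
    for suffix in ("_UP", "_DN"):
        if up_set_name.endswith("_UP") and down_set_name == up_set_name[:-3] + suffix:
            name = up_set_name[:-3]
    return GeneSignature(name, tuple(up), tuple(down))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: normalized gene list}."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            name = parts[0]
            genes = [normalize_symbol(g) for g in parts[2:] if g.strip()]
            sets[name] = genes
    return sets


def write_signature_gmt(sig: GeneSignature, path: str | Path) -> None:
    """Write a signature as two GMT sets, ``<NAME>_UP`` and ``<NAME>_DN``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([f"{sig.name}_UP", "up-regulated", *sig.up_genes]) + "\n")
        fh.write("\t".join([f"{sig.name}_DN", "down-regulated", *sig.down_genes]) + "\n")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of log-scale normalized expression.

    Wraps a pandas DataFrame whose index holds normalized gene symbols and
    whose columns hold sample identifiers; all values are finite floats.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def load_expression_matrix(
    path: str | Path,
    collapse: str = "mean",
    log2_transform: bool = False,
) -> ExpressionMatrix:
    """Load a tab-delimited genes x samples matrix.

    First column holds gene identifiers (normalized on load), the header row
    holds sample identifiers.  Duplicate gene rows (e.g. multiple array
    probes for one gene) are collapsed by ``collapse`` ("mean", the default,
    or "max").  Rows that are entirely missing are dropped with a warning;
    partially missing rows are an error, because the up-minus-down score is
    undefined under per-cell missingness.
    """
    if collapse not in ("mean", "max"):
        raise ValueError(f"unknown collapse policy {collapse!r}")
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value: {exc}") from exc

    all_missing = df.isna().all(axis=1)
    if all_missing.any():
        logger.warning(
            "%s: dropping %d all-missing gene rows", path, int(all_missing.sum())
        )
        df = df.loc[~all_missing]
    if df.isna().any().any():
        raise ValueError(f"{path}: partially missing gene rows are not supported")

    df.index = [normalize_symbol(str(g)) for g in df.index]
    if df.index.has_duplicates:
        grouped = df.groupby(level=0, sort=False)
        df = grouped.mean() if collapse == "mean" else grouped.max()
    if log2_transform:
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix in the same tab-delimited layout `load` expects."""
    matrix.data.to_csv(Path(path), sep="\t", index_label="gene")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample boolean flags (e.g. TNBC membership, true CL label)."""

    sample_id: str
    flags: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("empty sample id")
        if any(not k for k in self.flags):
            raise ValueError(f"sample {self.sample_id!r}: empty flag name")


_TRUE = {"1", "true", "yes", "pos", "positive", "t"}
_FALSE = {"0", "false", "no", "neg", "negative", "f"}


def _parse_bool(token: str, where: str) -> bool:
    low = token.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {token!r}")


def load_metadata(path: str | Path) -> list[SampleMetadata]:
    """Load sample metadata: a delimited table, first column sample_id,
    remaining columns boolean flags."""
    path = Path(path)
    records: list[SampleMetadata] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        if reader.fieldnames is None or len(reader.fieldnames) < 2:
            raise ValueError(f"{path}: need sample_id plus at least one flag column")
        id_col = reader.fieldnames[0]
        for row in reader:
            flags = {
                col: _parse_bool(row[col], f"{path}, sample {row[id_col]!r}")
                for col in reader.fieldnames[1:]
            }
            records.append(SampleMetadata(row[id_col], flags))
    return records


def write_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    path = Path(path)
    flag_names = sorted({k for r in records for k in r.flags})
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample_id", *flag_names])
        for r in records:
            writer.writerow(
                [r.sample_id, *(int(r.flags.get(k, False)) for k in flag_names)]
            )


@dataclass(frozen=True)
class IHCRecord:
    """One patient's immunohistochemistry readout.

    ``ecad_pct`` and ``vim_pct`` are the percentage of tumor cells staining
    positive for E-cadherin and vimentin respectively, in [0, 100];
    ``pdl1_positive`` is the dichotomous PD-L1 protein status.
    """

    patient_id: str
    pdl1_positive: bool
    ecad_pct: float
    vim_pct: float

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("empty patient id")
        for name in ("ecad_pct", "vim_pct"):
            v = float(getattr(self, name))
            if not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"patient {self.patient_id!r}: {name}={v} outside [0, 100]"
                )
            object.__setattr__(self, name, v)


IHC_COLUMNS = ("patient_id", "pdl1_positive", "ecad_pct", "vim_pct")


def load_ihc_table(path: str | Path) -> list[IHCRecord]:
    """Load an IHC patient table with the documented header contract
    ``patient_id, pdl1_positive, ecad_pct, vim_pct`` (comma or tab)."""
    path = Path(path)
    records: list[IHCRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        missing = set(IHC_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row in reader:
            records.append(
                IHCRecord(
                    patient_id=row["patient_id"],
                    pdl1_positive=_parse_bool(
                        row["pdl1_positive"], f"{path}, patient {row['patient_id']!r}"
                    ),
                    ecad_pct=float(row["ecad_pct"]),
                    vim_pct=float(row["vim_pct"]),
                )
            )
    return records


def write_ihc_table(records: Iterable[IHCRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(IHC_COLUMNS)
        for r in records:
            writer.writerow(
                [r.patient_id, int(r.pdl1_positive), f"{r.ecad_pct:g}", f"{r.vim_pct:g}"]
            )


def _sniff_delimiter(path: Path) -> str:
    with path.open() as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","
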