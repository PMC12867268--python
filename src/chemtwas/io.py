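"""On-disk formats and in-memory containers for the pipeline.

All tables are tab-separated UTF-8 with a single header line; missing values
are the literal ``NA``. Coordinates are 1-based inclusive. Validation is
eager: every reader fully validates its input at read time and raises
:class:`ValidationError` naming the offending record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SnpRecord",
    "GwasSummary",
    "LdMatrix",
    "WeightEntry",
    "WeightPanel",
    "ChemicalGeneSets",
    "ExpressionMatrix",
    "EdgeList",
    "Harmonized",
    "read_gwas",
    "write_gwas",
    "read_ld",
    "write_ld",
    "read_ld_dir",
    "write_ld_dir",
    "read_weights",
    "write_weights",
    "read_chemical_sets",
    "write_chemical_sets",
    "read_gmt",
    "read_expression",
    "write_expression",
    "read_edges",
    "write_edges",
    "harmonize",
    "CIS_WINDOW",
]

#: cis-regulatory window around the TSS, 1-based closed interval (±1 Mb).
CIS_WINDOW = 1_000_000

_NA = "NA"


class ValidationError(ValueError):
    """An input violated a container invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS summary-statistic row: the Z-score is for ``allele_alt``."""

    snp_id: str
    chromosome: str
    position: int
    allele_ref: str
    allele_alt: str
    zscore: float

    def validate(self) -> None:
        if self.position < 1:
            raise ValidationError(f"SNP {self.snp_id}: position must be >= 1")
        if self.allele_ref == self.allele_alt:
            raise ValidationError(f"SNP {self.snp_id}: ref and alt alleles are identical")
        if not np.isfinite(self.zscore):
            raise ValidationError(f"SNP {self.snp_id}: non-finite Z-score")


@dataclass
class GwasSummary:
    """Ordered GWAS summary statistics for one trait."""

    records: list[SnpRecord]
    trait_label: str = "trait"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            rec.validate()
            if rec.snp_id in seen:
                raise ValidationError(f"duplicate snp_id {rec.snp_id!r} in GWAS summary")
            seen.add(rec.snp_id)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def by_id(self) -> dict[str, SnpRecord]:
        return {r.snp_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LdMatrix:
    """SNP correlation matrix (LD structure) over an ordered SNP list."""

    snp_ids: list[str]
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = len(self.snp_ids)
        if self.corr.shape != (n, n):
            raise ValidationError(
                f"LD matrix shape {self.corr.shape} does not match {n} snp_ids"
            )
        if len(set(self.snp_ids)) != n:
            raise ValidationError("duplicate snp_id in LD matrix")
        if n == 0:
            return
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-8):
            raise ValidationError("LD matrix diagonal not 1 within 1e-8")
        if np.any(np.abs(self.corr) > 1 + 1e-8):
            raise ValidationError("LD matrix entries outside [-1, 1]")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValidationError("LD matrix not symmetric within 1e-10")
        w = np.linalg.eigvalsh(self.corr)
        if w.min() < -1e-8:
            raise ValidationError(
                f"LD matrix not positive semidefinite (min eigenvalue {w.min():.3g})"
            )

    def submatrix(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return LdMatrix(list(snp_ids), self.corr[np.ix_(idx, idx)])

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class WeightEntry:
    """One eQTL weight: SNP coefficient predicting a gene's expression.

    ``allele_ref``/``allele_alt`` orient the weight; if absent the weight is
    taken as already oriented to the GWAS alt allele.
    """

    gene_id: str
    tissue: str
    snp_id: str
    weight: float
    allele_ref: str | None = None
    allele_alt: str | None = None

    def validate(self) -> None:
        if not np.isfinite(self.weight):
            raise ValidationError(
                f"weight for gene {self.gene_id} SNP {self.snp_id}: non-finite"
            )


@dataclass
class WeightPanel:
    """Per-tissue sparse cis-eQTL weight vectors plus gene TSS positions.

    ``snp_pos`` (snp_id -> (chromosome, position)) is optional; when present
    the ±1 Mb cis-window invariant is enforced for every weighted SNP.
    """

    entries: list[WeightEntry]
    gene_tss: dict[str, tuple[str, int]]
    snp_pos: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        by_pair: dict[tuple[str, str], bool] = {}
        for e in self.entries:
            e.validate()
            key = (e.gene_id, e.tissue)
            by_pair[key] = by_pair.get(key, False) or e.weight != 0.0
            if e.gene_id not in self.gene_tss:
                raise ValidationError(f"gene {e.gene_id} has no TSS record")
        for (gene, tissue), has_nonzero in by_pair.items():
            if not has_nonzero:
                raise ValidationError(
                    f"gene {gene} tissue {tissue}: all weights are zero"
                )
        if self.snp_pos is not None:
            for e in self.entries:
                if e.snp_id not in self.snp_pos:
                    continue
                chrom, pos = self.snp_pos[e.snp_id]
                tss_chrom, tss = self.gene_tss[e.gene_id]
                if chrom != tss_chrom or abs(pos - tss) > CIS_WINDOW:
                    raise ValidationError(
                        f"SNP {e.snp_id} outside the ±1 Mb cis window of gene {e.gene_id}"
                    )

    @property
    def tissues(self) -> list[str]:
        return sorted({e.tissue for e in self.entries})

    @property
    def genes(self) -> list[str]:
        return sorted({e.gene_id for e in self.entries})

    def gene_entries(self, gene_id: str, tissue: str) -> list[WeightEntry]:
        return [e for e in self.entries if e.gene_id == gene_id and e.tissue == tissue]


@dataclass
class ChemicalGeneSets:
    """Chemical → interacting-gene sets (CTD-style)."""

    sets: dict[str, tuple[str, set[str]]]

    def __post_init__(self) -> None:
        for chem_id, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"chemical {chem_id}: empty gene set")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ExpressionMatrix:
    """Two-group log2-scale expression matrix (genes × samples)."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("expression matrix shape does not match id lists")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_id in expression matrix")
        counts = {"case": 0, "control": 0}
        for s in self.sample_ids:
            grp = self.group_labels.get(s)
            if grp not in counts:
                raise ValidationError(
                    f"sample {s}: group label must be 'case' or 'control', got {grp!r}"
                )
            counts[grp] += 1
        for grp, n in counts.items():
            if n < 2:
                raise ValidationError(f"group {grp!r} has {n} samples; need >= 2")

    def group_columns(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.group_labels[s] == group]
        return self.values[:, idx]


@dataclass
class EdgeList:
    """Weighted undirected edges with STRING-style combined scores in [0, 1]."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for a, b, s in self.edges:
            if a == b:
                raise ValidationError(f"self-loop on node {a!r}")
            if not (0.0 <= s <= 1.0):
                raise ValidationError(f"edge {a}-{b}: score {s} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA], keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _to_float(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    try:
        return df[col].astype(float).to_numpy()
    except ValueError as exc:
        for i, v in enumerate(df[col]):
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric value {v!r} in column {col!r} at data line {i + 2}"
                ) from exc
        raise


def read_gwas(path: str | Path, trait_label: str = "trait") -> GwasSummary:
    """Read GWAS summary statistics (columns snp_id, chr, pos, ref, alt, z)."""
    df = _read_tsv(path, ["snp_id", "chr", "pos", "ref", "alt", "z"])
    z = _to_float(df, "z", path)
    pos = _to_float(df, "pos", path).astype(int)
    records = [
        SnpRecord(r.snp_id, r.chr, int(p), r.ref, r.alt, float(zz))
        for r, p, zz in zip(df.itertuples(index=False), pos, z)
    ]
    return GwasSummary(records, trait_label=trait_label)


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in gwas.records],
            "chr": [r.chromosome for r in gwas.records],
            "pos": [r.position for r in gwas.records],
            "ref": [r.allele_ref for r in gwas.records],
            "alt": [r.allele_alt for r in gwas.records],
            "z": [repr(r.zscore) for r in gwas.records],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_ld(path: str | Path) -> LdMatrix:
    """Read an LD matrix TSV: first column snp_id, remaining columns the matrix.

    A sidecar variant is also accepted: if ``path`` has no header matching this
    layout but a file ``<path>.snps`` exists, the main file is parsed as a dense
    whitespace-delimited square matrix and the sidecar as one snp_id per line.
    """
    path = Path(path)
    sidecar = path.with_name(path.name + ".snps")
    if sidecar.exists():
        corr = np.loadtxt(path, dtype=float, ndmin=2)
        snp_ids = sidecar.read_text().split()
        return LdMatrix(snp_ids, corr)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    snp_ids = [str(s) for s in df.index]
    if list(df.columns) != snp_ids:
        raise ValidationError(f"{path}: LD row and column snp_ids disagree")
    return LdMatrix(snp_ids, df.to_numpy(dtype=float))


def write_ld(ld: LdMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ld.corr, index=ld.snp_ids, columns=ld.snp_ids)
    df.to_csv(path, sep="\t", index_label="snp_id", float_format="%.17g")


def read_ld_dir(directory: str | Path) -> dict[str, LdMatrix]:
    """Read every ``*.ld.tsv`` in a directory as locus_id → LdMatrix."""
    directory = Path(directory)
    out: dict[str, LdMatrix] = {}
    for p in sorted(directory.glob("*.ld.tsv")):
        out[p.name[: -len(".ld.tsv")]] = read_ld(p)
    if not out:
        raise ValidationError(f"{directory}: no *.ld.tsv files found")
    return out


def write_ld_dir(ld_by_locus: Mapping[str, LdMatrix], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for locus, ld in ld_by_locus.items():
        write_ld(ld, directory / f"{locus}.ld.tsv")


def read_weights(path: str | Path) -> WeightPanel:
    """Read a weight panel TSV.

    Columns: gene_id, tissue, snp_id, weight, ref, alt, gene_chr, gene_tss and
    optionally snp_chr, snp_pos. ref/alt may be NA (GWAS-oriented weights).
    """
    df = _read_tsv(path, ["gene_id", "tissue", "snp_id", "weight", "gene_chr", "gene_tss"])
    w = _to_float(df, "weight", path)
    tss = _to_float(df, "gene_tss", path).astype(int)
    entries: list[WeightEntry] = []
    gene_tss: dict[str, tuple[str, int]] = {}
    snp_pos: dict[str, tuple[str, int]] | None = None
    has_alleles = "ref" in df.columns and "alt" in df.columns
    has_pos = "snp_chr" in df.columns and "snp_pos" in df.columns
    if has_pos:
        snp_pos = {}
        pos_col = _to_float(df, "snp_pos", path).astype(int)
    for i, (row, ww, t) in enumerate(zip(df.itertuples(index=False), w, tss)):
        ref = alt = None
        if has_alleles:
            ref = None if pd.isna(row.ref) else str(row.ref)
            alt = None if pd.isna(row.alt) else str(row.alt)
        entries.append(WeightEntry(row.gene_id, row.tissue, row.snp_id, float(ww), ref, alt))
        gene_tss[row.gene_id] = (str(row.gene_chr), int(t))
        if has_pos:
            snp_pos[row.snp_id] = (str(row.snp_chr), int(pos_col[i]))  # type: ignore[index]
    return WeightPanel(entries, gene_tss, snp_pos)


def write_weights(panel: WeightPanel, path: str | Path) -> None:
    rows = []
    for e in panel.entries:
        chrom, tss = panel.gene_tss[e.gene_id]
        row = {
            "gene_id": e.gene_id,
            "tissue": e.tissue,
            "snp_id": e.snp_id,
            "weight": repr(e.weight),
            "ref": e.allele_ref if e.allele_ref is not None else _NA,
            "alt": e.allele_alt if e.allele_alt is not None else _NA,
            "gene_chr": chrom,
            "gene_tss": tss,
        }
        if panel.snp_pos is not None and e.snp_id in panel.snp_pos:
            row["snp_chr"], row["snp_pos"] = panel.snp_pos[e.snp_id]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_chemical_sets(
    path: str | Path,
    min_size: int = 1,
    max_size: int = 10**9,
    universe: set[str] | None = None,
) -> tuple[ChemicalGeneSets, int]:
    """Read CTD-style chemical-gene pairs and aggregate per chemical.

    Sets are optionally restricted to ``universe`` before the size filter.
    Returns the sets plus the number of chemicals excluded by the size filter.
    """
    df = _read_tsv(path, ["chemical_id", "chemical_name", "gene_symbol"])
    if df.empty:
        raise ValidationError(f"{path}: empty chemical-gene file")
    sets: dict[str, tuple[str, set[str]]] = {}
    for row in df.itertuples(index=False):
        name, genes = sets.setdefault(row.chemical_id, (row.chemical_name, set()))
        genes.add(row.gene_symbol)
    n_excluded = 0
    kept: dict[str, tuple[str, set[str]]] = {}
    for chem_id, (name, genes) in sets.items():
        eff = genes & universe if universe is not None else genes
        if min_size <= len(eff) <= max_size:
            kept[chem_id] = (name, genes)
        else:
            n_excluded += 1
    if not kept:
        raise ValidationError(f"{path}: no chemical sets within [{min_size}, {max_size}]")
    return ChemicalGeneSets(kept), n_excluded


def write_chemical_sets(sets: ChemicalGeneSets, path: str | Path) -> None:
    rows = [
        {"chemical_id": cid, "chemical_name": name, "gene_symbol": g}
        for cid, (name, genes) in sorted(sets.sets.items())
        for g in sorted(genes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """Read GMT gene sets: name, description, members (tab-separated)."""
    out: dict[str, tuple[str, set[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}: GMT line with < 3 fields: {line[:50]!r}")
        out[parts[0]] = (parts[1], set(parts[2:]))
    if not out:
        raise ValidationError(f"{path}: empty GMT file")
    return out


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read a log2 expression matrix (gene_id × samples) and a groups TSV."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    groups_df = _read_tsv(groups_path, ["sample_id", "group"])
    labels = dict(zip(groups_df.sample_id, groups_df.group))
    return ExpressionMatrix(
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
        labels,
    )


def write_expression(
    expr: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path
) -> None:
    pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids).to_csv(
        matrix_path, sep="\t", index_label="gene_id", float_format="%.17g"
    )
    pd.DataFrame(
        {"sample_id": expr.sample_ids, "group": [expr.group_labels[s] for s in expr.sample_ids]}
    ).to_csv(groups_path, sep="\t", index=False)


def read_edges(path: str | Path) -> EdgeList:
    df = _read_tsv(path, ["node_a", "node_b", "combined_score"])
    scores = _to_float(df, "combined_score", path)
    return EdgeList(
        [(r.node_a, r.node_b, float(s)) for r, s in zip(df.itertuples(index=False), scores)]
    )


def write_edges(edges: EdgeList, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node_a": [a for a, _, _ in edges.edges],
            "node_b": [b for _, b, _ in edges.edges],
            "combined_score": [repr(s) for _, _, s in edges.edges],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


@dataclass
class Harmonized:
    """Weight/Z/LD triple restricted to a shared, allele-aligned SNP frame."""

    snp_ids: list[str]
    w: np.ndarray
    z: np.ndarray
    L: np.ndarray
    n_dropped: int


def harmonize(
    gene_entries: Iterable[WeightEntry],
    gwas: GwasSummary,
    ld: LdMatrix,
) -> Harmonized:
    """Restrict weights, GWAS Z and LD to their shared SNPs, in LD order.

    A weight whose (ref, alt) is swapped relative to the GWAS record has its
    sign flipped; SNPs whose allele pair matches neither orientation are
    dropped and counted. Raises if no usable SNP remains.
    """
    gwas_by_id = gwas.by_id()
    weight_by_id = {e.snp_id: e for e in gene_entries}
    n_dropped = 0
    snp_ids: list[str] = []
    w: list[float] = []
    z: list[float] = []
    for sid in ld.snp_ids:
        if sid not in gwas_by_id or sid not in weight_by_id:
            continue
        entry = weight_by_id[sid]
        rec = gwas_by_id[sid]
        weight = entry.weight
        if entry.allele_ref is not None and entry.allele_alt is not None:
            if (entry.allele_ref, entry.allele_alt) == (rec.allele_ref, rec.allele_alt):
                pass
            elif (entry.allele_ref, entry.allele_alt) == (rec.allele_alt, rec.allele_ref):
                weight = -weight
            else:
                n_dropped += 1
                continue
        snp_ids.append(sid)
        w.append(weight)
        z.append(rec.zscore)
    if not snp_ids:
        raise ValidationError("no usable SNPs for gene after harmonization")
    sub = ld.submatrix(snp_ids)
    return Harmonized(snp_ids, np.array(w), np.array(z), sub.corr, n_dropped)
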