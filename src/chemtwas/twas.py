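"""Summary-statistics TWAS.

The gene-trait association statistic combines GWAS SNP Z-scores ``z``,
cis-eQTL weights ``w`` and the SNP LD correlation matrix ``L``:

    Z_twas = (w · z) / sqrt(w · (L w))

Under the null hypothesis z ~ MVN(0, L), Z_twas is standard normal, so
two-sided normal p-values apply. FDR control uses Benjamini–Hochberg,
computed both within each tissue and pooled across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import GwasSummary, Harmonized, LdMatrix, ValidationError, WeightPanel, harmonize

__all__ = [
    "TwasResult",
    "FeatureCluster",
    "twas_zscore",
    "bh_adjust",
    "run_twas",
    "pooled_fdr",
    "expression_correlation",
    "cluster_features",
    "segment_id",
]

_DEGENERATE_TOL = 1e-12

#: genomic feature segment length (bp) used for segment-id metadata.
SEGMENT_BP = 100_000


@dataclass
class TwasResult:
    gene_id: str
    tissue: str
    z: float
    p: float
    q: float  # BH within tissue
    n_snps_used: int
    n_snps_dropped: int
    segment_id: int | None = None
    q_pooled: float | None = None


@dataclass
class FeatureCluster:
    """Group of genes whose predicted expressions are mutually redundant."""

    member_genes: frozenset[str]
    representative: str
    relation: str  # merged | joint | independent


def twas_zscore(w: np.ndarray, z: np.ndarray, L: np.ndarray) -> float:
    """Gene-level association Z: (w·z) / sqrt(w·(Lw)).

    Raises on length mismatch or a degenerate predictor variance
    (w·(Lw) <= 1e-12).
    """
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    if w.shape != z.shape or L.shape != (w.size, w.size):
        raise ValueError(
            f"length mismatch: w {w.shape}, z {z.shape}, L {L.shape}"
        )
    var = float(w @ (L @ w))
    if var <= _DEGENERATE_TOL:
        raise ValueError(f"degenerate predictor: w·(Lw) = {var:.3g}")
    return float(w @ z) / np.sqrt(var)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1.

    adj_p[(i)] = min over j >= i of p[(j)] * m / j, in rank order; the output
    is returned in the input order and is invariant under permutation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        bad = p[(p <= 0) | (p > 1) | ~np.isfinite(p)][0]
        raise ValueError(f"p-value {bad} outside (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def segment_id(position: int) -> int:
    """Contiguous 100,000-bp genomic segment index for a position."""
    return position // SEGMENT_BP


def _locus_index(ld_by_locus: Mapping[str, LdMatrix]) -> dict[str, str]:
    idx: dict[str, str] = {}
    for locus, ld in ld_by_locus.items():
        for sid in ld.snp_ids:
            idx[sid] = locus
    return idx


def run_twas(
    panel: WeightPanel,
    gwas: GwasSummary,
    ld_by_locus: Mapping[str, LdMatrix] | LdMatrix,
    tissue: str,
) -> tuple[list[TwasResult], list[str]]:
    """Per-gene TWAS over one tissue.

    ``ld_by_locus`` maps locus ids to LD matrices (a single LdMatrix is also
    accepted). A gene's SNPs are taken from the single locus holding most of
    its weighted SNPs; weights on other loci are counted as dropped. Returns
    (results with within-tissue BH q-values, skip log of genes with no usable
    SNPs).
    """
    if isinstance(ld_by_locus, LdMatrix):
        ld_by_locus = {"locus0": ld_by_locus}
    entries = [e for e in panel.entries if e.tissue == tissue]
    if not entries:
        raise ValidationError(f"empty weight panel for tissue {tissue!r}")
    snp_to_locus = _locus_index(ld_by_locus)
    by_gene: dict[str, list] = {}
    for e in entries:
        by_gene.setdefault(e.gene_id, []).append(e)

    results: list[TwasResult] = []
    skipped: list[str] = []
    for gene_id in sorted(by_gene):
        gene_entries = by_gene[gene_id]
        loci = [snp_to_locus.get(e.snp_id) for e in gene_entries]
        counts: dict[str, int] = {}
        for loc in loci:
            if loc is not None:
                counts[loc] = counts.get(loc, 0) + 1
        if not counts:
            skipped.append(gene_id)
            continue
        locus = max(sorted(counts), key=counts.get)
        in_locus = [e for e, loc in zip(gene_entries, loci) if loc == locus]
        off_locus = len(gene_entries) - len(in_locus)
        try:
            h = harmonize(in_locus, gwas, ld_by_locus[locus])
            zstat = twas_zscore(h.w, h.z, h.L)
        except (ValidationError, ValueError):
            skipped.append(gene_id)
            continue
        p = 2.0 * stats.norm.sf(abs(zstat))
        p = max(p, np.nextafter(0, 1))  # keep p in (0, 1] for BH
        _, tss = panel.gene_tss[gene_id]
        results.append(
            TwasResult(
                gene_id=gene_id,
                tissue=tissue,
                z=zstat,
                p=p,
                q=np.nan,
                n_snps_used=len(h.snp_ids),
                n_snps_dropped=h.n_dropped + off_locus,
                segment_id=segment_id(tss),
            )
        )
    if results:
        q = bh_adjust([r.p for r in results])
        for r, qq in zip(results, q):
            r.q = float(qq)
    return results, skipped


def pooled_fdr(results: Iterable[TwasResult]) -> None:
    """Set q_pooled on every result by BH across all tissues jointly."""
    results = list(results)
    if not results:
        return
    q = bh_adjust([r.p for r in results])
    for r, qq in zip(results, q):
        r.q_pooled = float(qq)


def expression_correlation(
    w_i: np.ndarray, w_j: np.ndarray, L: np.ndarray
) -> float:
    """Correlation of two genes' predicted expressions on a shared SNP frame.

    r = w_i·(L w_j) / sqrt((w_i·(L w_i)) (w_j·(L w_j))). Weights for SNPs a
    gene does not use are zero-padded by the caller.
    """
    w_i = np.asarray(w_i, dtype=float)
    w_j = np.asarray(w_j, dtype=float)
    L = np.asarray(L, dtype=float)
    vi = float(w_i @ (L @ w_i))
    vj = float(w_j @ (L @ w_j))
    if vi <= _DEGENERATE_TOL or vj <= _DEGENERATE_TOL:
        raise ValueError("degenerate predictor variance in correlation")
    r = float(w_i @ (L @ w_j)) / np.sqrt(vi * vj)
    return float(np.clip(r, -1.0, 1.0))


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_features(
    results: Sequence[TwasResult],
    corr_fn: Callable[[str, str], float],
    r_merge: float = 0.9,
    r_indep: float = 0.008,
    p_include: float = 0.05,
) -> list[FeatureCluster]:
    """Group genes by predicted-expression correlation.

    Genes with p > p_include are excluded. Pairs with |r| > r_merge are merged
    (transitive closure); a gene whose every non-merged partner satisfies
    |r| < r_indep is an independent singleton; remaining correlated-but-
    distinct genes form 'joint' groups (transitive closure over
    r_indep <= |r| <= r_merge). Representative = smallest p, ties broken
    lexicographically by gene_id.
    """
    included = [r for r in results if r.p <= p_include]
    genes = sorted({r.gene_id for r in included})
    best_p = {}
    for r in included:
        if r.gene_id not in best_p or r.p < best_p[r.gene_id]:
            best_p[r.gene_id] = r.p
    if not genes:
        return []
    uf_merge = _UnionFind(genes)
    uf_joint = _UnionFind(genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            r = abs(corr_fn(a, b))
            if r > r_merge:
                uf_merge.union(a, b)
                uf_joint.union(a, b)
            elif r >= r_indep:
                uf_joint.union(a, b)
    merged_groups: dict[str, set[str]] = {}
    for g in genes:
        merged_groups.setdefault(uf_merge.find(g), set()).add(g)
    joint_groups: dict[str, set[str]] = {}
    for g in genes:
        joint_groups.setdefault(uf_joint.find(g), set()).add(g)

    clusters: list[FeatureCluster] = []
    for members in joint_groups.values():
        if len(members) == 1:
            relation = "independent"
        elif members == merged_groups[uf_merge.find(next(iter(members)))]:
            relation = "merged"  # whole component closed under |r| > r_merge
        else:
            relation = "joint"
        rep = min(members, key=lambda g: (best_p[g], g))
        clusters.append(FeatureCluster(frozenset(members), rep, relation))
    clusters.sort(key=lambda c: min(c.member_genes))
    return clusters
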