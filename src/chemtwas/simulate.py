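"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its config: sub-seeds are derived by
hashing (generator name, master seed), so adding a generator never perturbs
the others and identical configs give identical artifacts.

The generated world: SNPs live on one chromosome in ``n_blocks`` LD blocks
with AR(1) within-block correlation ``rho``; each gene draws a sparse cis
weight vector from one block, normalized so w·(Lw) = 1; the GWAS Z vector is
multivariate normal with covariance L and mean shifted by planted causal
genes, so a causal gene's own TWAS Z has expectation alpha; chemical sets,
a two-group log2 expression matrix and a PPI edge list carry planted signal
mirroring CTD enrichment, differential expression and dense modules.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .io import (
    ChemicalGeneSets,
    EdgeList,
    ExpressionMatrix,
    GwasSummary,
    LdMatrix,
    SnpRecord,
    ValidationError,
    WeightEntry,
    WeightPanel,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "subseed",
    "sim_ld",
    "ld_blocks_to_dense",
    "sim_weights",
    "sim_gwas_z",
    "sim_chemical_sets",
    "sim_expression",
    "sim_ppi",
    "simulate_all",
]

_SNP_SPACING = 1_000  # bp between adjacent simulated SNPs
_ALLELES = ("A", "G")


def subseed(name: str, master_seed: int) -> int:
    """Deterministic per-generator sub-seed < 2^31 from (name, master seed)."""
    digest = hashlib.blake2b(f"{name}:{master_seed}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic world.

    Defaults give a compact five-tissue scenario with moderate LD
    (rho = 0.6, the level typical of dense cis regions), unit-variance
    weights, 10 samples per expression group and STRING-like sparse
    background with two dense planted modules.
    """

    seed: int = 0
    n_blocks: int = 40
    block_size: int = 25
    rho: float = 0.6
    n_genes: int = 40
    snps_per_gene: int = 5
    causal_genes: dict[str, float] = field(default_factory=dict)
    n_tissues: int = 1
    tissue_weight_jitter: float = 0.25
    n_chemicals: int = 50
    active_chemicals: dict[str, float] = field(default_factory=dict)
    set_size_range: tuple[int, int] = (10, 30)
    n_samples_per_group: int = 10
    planted_lfc: dict[str, float] = field(default_factory=dict)
    expr_noise_sd: float = 0.3
    ppi_planted_modules: list[tuple[int, float]] = field(
        default_factory=lambda: [(6, 0.9), (4, 0.9)]
    )
    ppi_background_prob: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValidationError(f"rho must be in [0, 1), got {self.rho}")
        for name in ("n_blocks", "block_size", "n_genes", "snps_per_gene",
                     "n_tissues", "n_chemicals", "n_samples_per_group"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.snps_per_gene > self.block_size:
            raise ValidationError("snps_per_gene exceeds block_size")
        if not (0.0 <= self.ppi_background_prob <= 1.0):
            raise ValidationError("ppi_background_prob outside [0, 1]")
        for size, p in self.ppi_planted_modules:
            if not (0.0 <= p <= 1.0) or size < 1:
                raise ValidationError("invalid planted module spec")
        for frac in self.active_chemicals.values():
            if not (0.0 <= frac <= 1.0):
                raise ValidationError("active chemical fraction outside [0, 1]")

    # -- deterministic universes -------------------------------------------
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def chemical_ids(self) -> list[str]:
        width = len(str(self.n_chemicals))
        return [f"C{i:0{width}d}" for i in range(1, self.n_chemicals + 1)]

    def tissue_ids(self) -> list[str]:
        return [f"tissue{i}" for i in range(self.n_tissues)]

    def gene_block(self, gene_index: int) -> int:
        return gene_index % self.n_blocks

    def snp_ids_for_block(self, block: int) -> list[str]:
        start = block * self.block_size
        return [f"rs{start + j + 1}" for j in range(self.block_size)]

    def snp_position(self, block: int, offset: int) -> int:
        return (block * self.block_size + offset) * _SNP_SPACING + 1


@dataclass
class SimTruth:
    """Ground-truth ledger for parameter-recovery tests."""

    causal_genes: dict[str, float]
    active_chemicals: dict[str, float]
    planted_deg_genes: dict[str, float]
    planted_module_memberships: list[set[str]]


@dataclass
class SimBundle:
    config: SimConfig
    ld: dict[str, LdMatrix]
    panel: WeightPanel
    gwas: GwasSummary
    chem_sets: ChemicalGeneSets
    expr: ExpressionMatrix
    edges: EdgeList
    truth: SimTruth


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def sim_ld(config: SimConfig) -> dict[str, LdMatrix]:
    """AR(1) within-block LD: corr(i, j) = rho^|i-j|, one LdMatrix per block."""
    k = np.arange(config.block_size)
    corr = config.rho ** np.abs(k[:, None] - k[None, :])
    out: dict[str, LdMatrix] = {}
    for b in range(config.n_blocks):
        out[f"block{b:04d}"] = LdMatrix(config.snp_ids_for_block(b), corr.copy())
    return out


def ld_blocks_to_dense(ld_by_locus: Mapping[str, LdMatrix]) -> LdMatrix:
    """Assemble per-block matrices into one block-diagonal LdMatrix."""
    from scipy.linalg import block_diag

    keys = sorted(ld_by_locus)
    snp_ids = [s for k in keys for s in ld_by_locus[k].snp_ids]
    return LdMatrix(snp_ids, block_diag(*[ld_by_locus[k].corr for k in keys]))


def sim_weights(config: SimConfig, ld: Mapping[str, LdMatrix]) -> WeightPanel:
    """Sparse cis weight panel: per gene, ``snps_per_gene`` SNPs from one block.

    Weights are standard-normal draws rescaled so w·(Lw) = 1. Tissue 0 carries
    the base weights; later tissues add Gaussian jitter
    (sd = tissue_weight_jitter) before renormalization, emulating shared but
    not identical cis architecture across tissues.
    """
    rng = np.random.default_rng(subseed("weights", config.seed))
    entries: list[WeightEntry] = []
    gene_tss: dict[str, tuple[str, int]] = {}
    all_pos: dict[str, tuple[str, int]] = {}
    for b in range(config.n_blocks):
        for j, sid in enumerate(config.snp_ids_for_block(b)):
            all_pos[sid] = ("1", config.snp_position(b, j))
    for gi, gene in enumerate(config.gene_ids()):
        b = config.gene_block(gi)
        block_key = f"block{b:04d}"
        block = ld[block_key]
        offsets = np.sort(
            rng.choice(config.block_size, size=config.snps_per_gene, replace=False)
        )
        snp_ids = [block.snp_ids[o] for o in offsets]
        L_sub = block.corr[np.ix_(offsets, offsets)]
        base = rng.standard_normal(config.snps_per_gene)
        tss = config.snp_position(b, config.block_size // 2)
        gene_tss[gene] = ("1", tss)
        for t, tissue in enumerate(config.tissue_ids()):
            w = base.copy()
            if t > 0 and config.tissue_weight_jitter > 0:
                w = w + config.tissue_weight_jitter * rng.standard_normal(w.size)
            scale = np.sqrt(float(w @ (L_sub @ w)))
            if scale <= 0:
                w = np.ones_like(w)
                scale = np.sqrt(float(w @ (L_sub @ w)))
            w = w / scale
            for sid, ww in zip(snp_ids, w):
                entries.append(WeightEntry(gene, tissue, sid, float(ww), "A", "G"))
    snp_pos = {e.snp_id: all_pos[e.snp_id] for e in entries}
    return WeightPanel(entries, gene_tss, snp_pos)


def sim_gwas_z(
    config: SimConfig, ld: Mapping[str, LdMatrix], panel: WeightPanel
) -> GwasSummary:
    """GWAS Z vector: MVN(mu, L) per block.

    mu = sum over causal genes g of alpha_g * (L w_g) / sqrt(w_g·(L w_g)),
    using tissue-0 weights, so the causal gene's own tissue-0 TWAS Z has
    expectation alpha_g. With no causal genes mu = 0 and each Z is marginally
    standard normal.
    """
    rng = np.random.default_rng(subseed("gwas", config.seed))
    gene_ids = config.gene_ids()
    tissue0 = config.tissue_ids()[0]
    unknown = set(config.causal_genes) - set(gene_ids)
    if unknown:
        raise ValidationError(f"causal genes not in universe: {sorted(unknown)}")

    w_by_gene: dict[str, dict[str, float]] = {}
    for e in panel.entries:
        if e.tissue == tissue0:
            w_by_gene.setdefault(e.gene_id, {})[e.snp_id] = e.weight

    records: list[SnpRecord] = []
    for b in range(config.n_blocks):
        block_key = f"block{b:04d}"
        block = ld[block_key]
        n = len(block)
        mu = np.zeros(n)
        pos_in_block = {sid: i for i, sid in enumerate(block.snp_ids)}
        for gi, gene in enumerate(gene_ids):
            alpha = config.causal_genes.get(gene, 0.0)
            if alpha == 0.0 or config.gene_block(gi) != b:
                continue
            w_full = np.zeros(n)
            for sid, ww in w_by_gene[gene].items():
                w_full[pos_in_block[sid]] = ww
            var = float(w_full @ (block.corr @ w_full))
            mu += alpha * (block.corr @ w_full) / np.sqrt(var)
        chol = np.linalg.cholesky(block.corr + 1e-12 * np.eye(n))
        z = mu + chol @ rng.standard_normal(n)
        for j, sid in enumerate(block.snp_ids):
            records.append(
                SnpRecord(sid, "1", config.snp_position(b, j), *_ALLELES, float(z[j]))
            )
    return GwasSummary(records, trait_label=f"sim-seed{config.seed}")


def sim_chemical_sets(config: SimConfig) -> ChemicalGeneSets:
    """Chemical-gene sets with planted enrichment.

    An active chemical draws round(fraction × size) members from the causal
    genes (capped at their number) and the rest uniformly from non-causal
    genes; inactive chemicals draw uniformly from all genes.
    """
    rng = np.random.default_rng(subseed("chemicals", config.seed))
    genes = np.array(config.gene_ids())
    causal = np.array(sorted(g for g in config.causal_genes if config.causal_genes[g] != 0.0))
    non_causal = np.array([g for g in genes if g not in set(causal)])
    lo, hi = config.set_size_range
    hi = max(1, min(hi, len(genes)))
    lo = max(1, min(lo, hi))
    sets: dict[str, tuple[str, set[str]]] = {}
    for ci, chem in enumerate(config.chemical_ids()):
        size = int(rng.integers(lo, hi + 1))
        frac = config.active_chemicals.get(chem, 0.0)
        if frac > 0.0 and len(causal) > 0:
            n_causal = min(int(round(frac * size)), len(causal), size)
            chosen = list(rng.choice(causal, size=n_causal, replace=False))
            n_rest = min(size - n_causal, len(non_causal))
            if n_rest > 0:
                chosen += list(rng.choice(non_causal, size=n_rest, replace=False))
        else:
            chosen = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
        sets[chem] = (f"chem-{ci + 1:03d}", set(chosen))
    return ChemicalGeneSets(sets)


def sim_expression(config: SimConfig) -> ExpressionMatrix:
    """Two-group log2 expression: baseline + planted log2FC in cases + noise."""
    rng = np.random.default_rng(subseed("expression", config.seed))
    genes = config.gene_ids()
    n = config.n_samples_per_group
    samples = [f"case{i + 1:03d}" for i in range(n)] + [
        f"ctrl{i + 1:03d}" for i in range(n)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in samples}
    baseline = rng.normal(6.0, 1.0, size=len(genes))
    lfc = np.array([config.planted_lfc.get(g, 0.0) for g in genes])
    values = baseline[:, None] + rng.normal(
        0.0, config.expr_noise_sd, size=(len(genes), 2 * n)
    )
    values[:, :n] += lfc[:, None]
    return ExpressionMatrix(genes, samples, values, groups)


def sim_ppi(config: SimConfig) -> tuple[EdgeList, list[set[str]]]:
    """STRING-like edge list with dense planted modules.

    Planted modules are disjoint Erdős–Rényi subgraphs on consecutive gene
    blocks with their own within-module edge probability; all remaining node
    pairs connect with ``ppi_background_prob``. Combined scores are uniform
    on [0.4, 1]. Returns (edges, planted module memberships).
    """
    rng = np.random.default_rng(subseed("ppi", config.seed))
    genes = config.gene_ids()
    modules: list[set[str]] = []
    cursor = 0
    for size, _ in config.ppi_planted_modules:
        if cursor + size > len(genes):
            raise ValidationError("planted modules exceed gene universe")
        modules.append(set(genes[cursor : cursor + size]))
        cursor += size
    member_of: dict[str, int] = {}
    for mi, members in enumerate(modules):
        for g in members:
            member_of[g] = mi
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            same = member_of.get(a) is not None and member_of.get(a) == member_of.get(b)
            p = config.ppi_planted_modules[member_of[a]][1] if same else config.ppi_background_prob
            if rng.random() < p:
                edges.append((a, b, float(rng.uniform(0.4, 1.0))))
    return EdgeList(edges), modules


def simulate_all(config: SimConfig) -> SimBundle:
    """Generate the full fixture bundle plus its ground-truth ledger."""
    ld = sim_ld(config)
    panel = sim_weights(config, ld)
    gwas = sim_gwas_z(config, ld, panel)
    chem_sets = sim_chemical_sets(config)
    expr = sim_expression(config)
    edges, modules = sim_ppi(config)
    truth = SimTruth(
        causal_genes=dict(config.causal_genes),
        active_chemicals=dict(config.active_chemicals),
        planted_deg_genes={g: f for g, f in config.planted_lfc.items() if f != 0.0},
        planted_module_memberships=modules,
    )
    return SimBundle(config, ld, panel, gwas, chem_sets, expr, edges, truth)
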