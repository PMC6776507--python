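"""Synthetic inputs with known ground truth for the whole pipeline.

Generates a phased reference panel with block LD structure (haplotype
mosaics, no coalescent realism), multi-source SNP–CpG ASM catalogs,
daner-style GWAS summary statistics with a tunable ASM enrichment
effect, and the annotation tables (TSS, histone marks, brain eQTLs,
volume GWAS). Every generator writes into a ground-truth manifest that
predicts all downstream filter/selection outputs exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .ld_toolkit import LdPanel
from .functional_integration import (
    BRAIN_REGIONS,
    ENHANCER_MARKS,
    PROMOTER_MARKS,
    VOLUME_STRUCTURES,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "ConfigError",
    "PanelGenerationError",
    "generate_panel",
    "generate_asm_catalog",
    "generate_sumstats",
    "generate_annotation_tables",
    "simulate",
    "simulate_enrichment_pvalues",
    "asm_significance_prob",
    "expansion_fixture",
]

# unambiguous ref/alt pairs so that the default panel never produces
# strand-ambiguous (A/T, C/G) drops at the sumstats join
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]

_EQTL_TISSUES = (
    "cerebellum",
    "cortex",
    "caudate basal ganglia",
    "hippocampus",
    "putamen basal ganglia",
)

_SOURCES = [
    ("study_a", "frontal cortex"),
    ("study_a", "cerebellum"),
    ("study_a", "temporal cortex"),
    ("study_a", "caudal pons"),
    ("study_b", "cerebellum"),
]


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


class PanelGenerationError(RuntimeError):
    """Requested LD/MAF combination could not be realized."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the synthetic data generators.

    The LD target ``within_block_r2`` is the expected pairwise r² between
    SNPs of the same block; cross-block r² is ~0 by construction.
    ``enrichment_or`` is the odds ratio for ASM SNPs being significant at
    p < 0.05 relative to non-ASM SNPs. ``consistency_rate`` is the
    probability that a promoter-CpG gene's eQTL direction is planted
    inverse to the methylation direction.
    """

    n_haplotypes: int = 600
    n_blocks: int = 30
    snps_per_block: int = 6
    within_block_r2: float = 0.97
    maf_range: tuple[float, float] = (0.15, 0.5)
    n_asm_pairs: int = 150
    asm_r2_range: tuple[float, float] = (0.25, 0.95)
    enrichment_or: float = 1.5
    consistency_rate: float = 1.0
    seed: int = 0
    # extra knobs exercising specific pipeline paths
    n_signal_blocks: int = 4
    source_overlap: float = 0.3
    low_r2_fraction: float = 0.1
    chrx_fraction: float = 0.05
    omit_fraction: float = 0.05
    signal_p_range: tuple[float, float] = (1e-8, 3e-7)

    def validate(self) -> None:
        for name in ("n_haplotypes", "n_blocks", "snps_per_block", "n_asm_pairs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.n_haplotypes % 2:
            raise ConfigError("n_haplotypes must be even (diploid VCF output)")
        if not (0.0 <= self.within_block_r2 <= 1.0):
            raise ConfigError("within_block_r2 must lie in [0,1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must be ordered within (0, 0.5]")
        lo, hi = self.asm_r2_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("asm_r2_range must be ordered within [0,1]")
        if self.asm_r2_range[1] < 0.2:
            raise ConfigError("asm_r2_range must reach the 0.2 filter threshold")
        if self.enrichment_or < 1.0:
            raise ConfigError("enrichment_or must be >= 1")
        for name in ("consistency_rate", "source_overlap", "low_r2_fraction",
                     "chrx_fraction", "omit_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0,1]")
        if self.n_signal_blocks < 0 or self.n_signal_blocks > self.n_blocks:
            raise ConfigError("n_signal_blocks must lie in [0, n_blocks]")
        lo, hi = self.signal_p_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError("signal_p_range must be ordered within (0,1)")

    def rngs(self) -> dict[str, np.random.Generator]:
        """One independent stream per generator, all derived from the
        master seed, so adding a generator does not shift the others."""
        ss = np.random.SeedSequence(self.seed)
        names = ["panel", "catalog", "sumstats", "annotations"]
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


@dataclass
class SimTruth:
    """Ground-truth manifest: sufficient to predict every downstream
    filter/selection output exactly."""

    pairs: pd.DataFrame = None
    snps: pd.DataFrame = None
    blocks: pd.DataFrame = None
    predictions: dict = field(default_factory=dict)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(directory / "truth_pairs.tsv", sep="\t", index=False)
        self.snps.to_csv(directory / "truth_snps.tsv", sep="\t", index=False)
        self.blocks.to_csv(directory / "truth_blocks.tsv", sep="\t", index=False)
        with open(directory / "truth_summary.json", "w") as fh:
            json.dump(self.predictions, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, directory) -> "SimTruth":
        directory = Path(directory)
        return cls(
            pairs=pd.read_csv(directory / "truth_pairs.tsv", sep="\t",
                              dtype={"snp_chrom": str, "cpg_chrom": str}),
            snps=pd.read_csv(directory / "truth_snps.tsv", sep="\t",
                             dtype={"chrom": str}),
            blocks=pd.read_csv(directory / "truth_blocks.tsv", sep="\t"),
            predictions=json.load(open(directory / "truth_summary.json")),
        )


# ---------------------------------------------------------------------------
# panel


def _sample_block(
    rng: np.random.Generator,
    n_hap: int,
    n_snps: int,
    maf: float,
    copy_prob: float,
    max_tries: int = 50,
) -> np.ndarray:
    """Haplotype columns for one block via anchor copying.

    Each SNP copies a shared anchor haplotype with probability
    ``copy_prob`` (else an independent Bernoulli(maf) draw), giving
    expected pairwise r² of copy_prob**4 between block members. Columns
    that come out monomorphic are redrawn; exhausting the retries raises
    :class:`PanelGenerationError`.
    """
    for _ in range(max_tries):
        anchor = (rng.random(n_hap) < maf).astype(np.int8)
        if 0 < anchor.sum() < n_hap:
            break
    else:
        raise PanelGenerationError(
            f"could not draw a polymorphic anchor at MAF={maf:.3f} "
            f"with {n_hap} haplotypes"
        )
    cols = np.empty((n_hap, n_snps), dtype=np.int8)
    for j in range(n_snps):
        for _ in range(max_tries):
            keep = rng.random(n_hap) < copy_prob
            fresh = (rng.random(n_hap) < maf).astype(np.int8)
            col = np.where(keep, anchor, fresh)
            if 0 < col.sum() < n_hap:
                cols[:, j] = col
                break
        else:
            raise PanelGenerationError(
                f"could not draw a polymorphic block column at MAF={maf:.3f}; "
                f"requested r²={copy_prob ** 4:.3f} is unattainable for this "
                f"MAF/haplotype-count combination"
            )
    return cols


def _min_within_r2(cols: np.ndarray) -> float:
    if cols.shape[1] < 2:
        return 1.0
    r = np.corrcoef(cols.astype(float), rowvar=False)
    r2 = r**2
    mask = ~np.eye(r2.shape[0], dtype=bool)
    return float(r2[mask].min())


def generate_panel(config: SimConfig) -> LdPanel:
    """Phased 0/1 panel with block LD structure.

    Blocks are laid out over autosomes 1..22 (cycling); when
    ``chrx_fraction`` > 0 the trailing block(s) sit on chromosome X so
    the catalog can place non-autosomal pairs. For high LD targets
    (within_block_r2 >= 0.9) every within-block pair is verified to
    exceed r² = 0.86 so that downstream tag/expansion manifests are
    exact; failing blocks are redrawn.
    """
    config.validate()
    rng = config.rngs()["panel"]
    copy_prob = config.within_block_r2**0.25
    enforce_floor = 0.86 if config.within_block_r2 >= 0.9 else None

    n_x_blocks = (
        max(1, round(config.chrx_fraction * config.n_blocks))
        if config.chrx_fraction > 0
        else 0
    )
    if n_x_blocks >= config.n_blocks:
        raise ConfigError("chrx_fraction leaves no autosomal blocks")
    chroms = [str(1 + b % 22) for b in range(config.n_blocks - n_x_blocks)]
    chroms += ["X"] * n_x_blocks

    per_chrom_count: dict[str, int] = {}
    rows = []
    col_blocks = []
    snp_counter = 0
    for b, chrom in enumerate(chroms):
        maf = float(rng.uniform(*config.maf_range))
        for _ in range(30):
            cols = _sample_block(
                rng, config.n_haplotypes, config.snps_per_block, maf, copy_prob
            )
            if enforce_floor is None or _min_within_r2(cols) >= enforce_floor:
                break
        else:
            raise PanelGenerationError(
                f"block {b}: could not realize within-block r² floor "
                f"{enforce_floor} (target {config.within_block_r2})"
            )
        col_blocks.append(cols)
        k = per_chrom_count.get(chrom, 0)
        per_chrom_count[chrom] = k + 1
        base = 10_000 + k * 1_000_000
        for j in range(config.snps_per_block):
            ref, alt = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            rows.append(
                {
                    "snp_id": f"rs{snp_counter + 1:06d}",
                    "chrom": chrom,
                    "pos": base + j * 1_000,
                    "ref": ref,
                    "alt": alt,
                    "block": b,
                }
            )
            snp_counter += 1
    haps = np.concatenate(col_blocks, axis=1)
    return LdPanel(haps, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ASM catalog


def generate_asm_catalog(
    panel: LdPanel, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Multi-source SNP–CpG pair table plus the ground-truth manifest.

    Returns a long table with one row per (pair, source) — splitting on
    the (study, tissue) columns recovers the per-source input tables —
    and a :class:`SimTruth` whose ``pairs`` frame records exactly which
    pairs pass the cis/R²/autosome filters and whose ``snps`` frame
    carries the planted risk alleles.
    """
    config.validate()
    rng = config.rngs()["catalog"]
    variants = panel.variants
    block_ids = sorted(variants["block"].unique())
    auto_blocks = [
        b for b in block_ids
        if variants.loc[variants["block"] == b, "chrom"].iloc[0] != "X"
    ]
    x_blocks = [b for b in block_ids if b not in auto_blocks]
    if config.n_signal_blocks > len(auto_blocks):
        raise ConfigError("not enough autosomal blocks for n_signal_blocks")
    signal_blocks = auto_blocks[: config.n_signal_blocks]

    n = config.n_asm_pairs
    n_x = round(config.chrx_fraction * n) if x_blocks else 0
    n_low = round(config.low_r2_fraction * n)
    n_signal = config.n_signal_blocks * config.snps_per_block
    n_rest = n - n_x - n_low - n_signal
    if n_rest < 0:
        raise ConfigError(
            "n_asm_pairs too small for the requested signal/low-R²/X fractions"
        )

    block_snps = {
        b: list(variants.loc[variants["block"] == b, "snp_id"])
        for b in block_ids
    }
    block_chrom = {
        b: str(variants.loc[variants["block"] == b, "chrom"].iloc[0])
        for b in block_ids
    }
    block_start = {
        b: int(variants.loc[variants["block"] == b, "pos"].min()) for b in block_ids
    }

    cpg_counter = 0
    block_cpg: dict[tuple[int, int], tuple[str, int]] = {}

    def cpg_for(block: int, tier: int = 0) -> tuple[str, int]:
        # tier 1 hosts the low-R² pairs on a second CpG so a SNP never
        # carries two conflicting R² values for the same (snp, cpg) key
        nonlocal cpg_counter
        key = (block, tier)
        if key not in block_cpg:
            cpg_counter += 1
            pos = block_start[block] - 2_000 - (cpg_counter % 7) * 60 - tier * 400
            block_cpg[key] = (f"cg{cpg_counter:08d}", pos)
        return block_cpg[key]

    # (snp, block, kind) slots; kind in {signal, rest, low, x}
    slots: list[tuple[str, int, str]] = []
    for b in signal_blocks:
        slots.extend((s, b, "signal") for s in block_snps[b])
    rest_blocks = [b for b in auto_blocks if b not in signal_blocks]
    if not rest_blocks and (n_rest or n_low):
        raise ConfigError("no non-signal autosomal blocks to host extra pairs")

    def round_robin(blocks: list[int], count: int, kind: str) -> None:
        order = []
        depth = max(len(block_snps[b]) for b in blocks)
        for j in range(depth):
            for b in blocks:
                if j < len(block_snps[b]):
                    order.append((block_snps[b][j], b))
        if count > len(order):
            raise ConfigError("n_asm_pairs exceeds catalog capacity")
        slots.extend((s, b, kind) for s, b in order[:count])

    if n_rest:
        round_robin(rest_blocks, n_rest, "rest")
    if n_low:
        round_robin(rest_blocks, n_low, "low")
    if n_x:
        round_robin(x_blocks, n_x, "x")

    # planted per-SNP risk alleles and per-CpG methylation sign of the
    # risk allele (shared by all pairs of the CpG, as in the source data)
    snp_rows = []
    risk_allele: dict[str, str] = {}
    for _, v in variants.iterrows():
        risk = v["alt"] if rng.random() < 0.5 else v["ref"]
        risk_allele[v["snp_id"]] = risk
        snp_rows.append(
            {
                "snp_id": v["snp_id"],
                "chrom": v["chrom"],
                "pos": v["pos"],
                "ref": v["ref"],
                "alt": v["alt"],
                "block": v["block"],
                "risk_allele": risk,
            }
        )
    snps_df = pd.DataFrame(snp_rows)

    cpg_sign: dict[str, int] = {}
    pair_rows = []
    truth_rows = []
    lo, hi = config.asm_r2_range
    for snp, b, kind in slots:
        cpg_id, cpg_pos = cpg_for(b, tier=1 if kind == "low" else 0)
        if cpg_id not in cpg_sign:
            cpg_sign[cpg_id] = 1 if rng.random() < 0.5 else -1
        s_c = cpg_sign[cpg_id]
        vrow = variants.loc[variants["snp_id"] == snp].iloc[0]
        if kind == "low":
            r2 = float(rng.uniform(0.01, 0.199))
        else:
            r2 = float(rng.uniform(max(lo, 0.2), max(hi, 0.2)))
        effect = vrow["alt"] if rng.random() < 0.5 else vrow["ref"]
        direction = s_c if effect == risk_allele[snp] else -s_c
        chrom = block_chrom[b]
        base = {
            "snp_id": snp,
            "snp_chrom": chrom,
            "snp_pos": int(vrow["pos"]),
            "cpg_id": cpg_id,
            "cpg_chrom": chrom,
            "cpg_pos": cpg_pos,
            "r2_meth": round(r2, 6),
            "meth_effect_allele": effect,
            "meth_direction": direction,
        }
        src = _SOURCES[rng.integers(len(_SOURCES))]
        sources = [src]
        if rng.random() < config.source_overlap:
            others = [s for s in _SOURCES if s != src]
            sources.append(others[rng.integers(len(others))])
        for study, tissue in sources:
            pair_rows.append({**base, "tissue": tissue, "study": study})
        pass_r2 = r2 >= 0.2
        pass_auto = chrom != "X"
        truth_rows.append(
            {
                **{k: base[k] for k in ("snp_id", "snp_chrom", "cpg_id", "cpg_pos")},
                "block": b,
                "r2_meth": base["r2_meth"],
                "meth_risk_sign": s_c,
                "n_sources": len(sources),
                "pass_cis": True,
                "pass_r2": pass_r2,
                "pass_autosome": pass_auto,
                "passes_all": pass_r2 and pass_auto,
                "is_signal": b in signal_blocks,
            }
        )

    catalog = pd.DataFrame(pair_rows)
    truth = SimTruth(
        pairs=pd.DataFrame(truth_rows),
        snps=snps_df,
        blocks=pd.DataFrame(
            {
                "block": block_ids,
                "chrom": [block_chrom[b] for b in block_ids],
                "is_signal": [b in signal_blocks for b in block_ids],
                "cpg_id": [block_cpg.get((b, 0), ("", 0))[0] for b in block_ids],
                "cpg_pos": [block_cpg.get((b, 0), ("", 0))[1] for b in block_ids],
            }
        ),
    )
    truth.predictions["n_pairs_union"] = int(
        truth.pairs[["snp_id", "cpg_id"]].drop_duplicates().shape[0]
    )
    truth.predictions["n_filtered_pairs"] = int(truth.pairs["passes_all"].sum())
    truth.predictions["filtered_pair_keys"] = sorted(
        f"{r.snp_id}|{r.cpg_id}"
        for r in truth.pairs[truth.pairs["passes_all"]].itertuples()
    )
    return catalog, truth


# ---------------------------------------------------------------------------
# summary statistics


def asm_significance_prob(enrichment_or: float, tau: float = 0.05) -> float:
    """Probability of p < tau for an ASM SNP given the target enrichment
    odds ratio against a uniform-null background."""
    x = tau / (1.0 - tau)
    odds = enrichment_or * x
    return odds / (1.0 + odds)


def generate_sumstats(
    panel: LdPanel, truth: SimTruth, config: SimConfig
) -> pd.DataFrame:
    """daner-style records for every panel variant.

    Null variants draw p uniform on (0,1); catalog (ASM) SNPs are boosted
    so their marginal probability of p < 0.05 matches
    :func:`asm_significance_prob`; pass-filter SNPs of signal blocks
    receive p in ``signal_p_range``. A fraction ``omit_fraction`` of the
    non-signal ASM SNPs is left out of the output. The planted risk
    allele determines the OR direction. Updates ``truth.snps`` in place
    with per-variant class, p and omission flags.
    """
    config.validate()
    rng = config.rngs()["sumstats"]
    snps = truth.snps.set_index("snp_id")
    asm_pass = set(truth.pairs.loc[truth.pairs["passes_all"], "snp_id"])
    asm_all = set(truth.pairs["snp_id"])
    signal_snps = set(
        truth.pairs.loc[truth.pairs["passes_all"] & truth.pairs["is_signal"], "snp_id"]
    )
    pi = asm_significance_prob(config.enrichment_or)
    boost_prob = max(0.0, (pi - 0.05) / 0.95)

    records = []
    classes, pvals = {}, {}
    for _, v in panel.variants.iterrows():
        snp = v["snp_id"]
        if snp in signal_snps:
            lo, hi = config.signal_p_range
            p = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
            cls = "signal"
        elif snp in asm_all and rng.random() < boost_prob:
            p = float(rng.uniform(0.0, 0.05))
            cls = "boosted"
        else:
            p = float(rng.uniform(0.0, 1.0))
            cls = "null"
        p = min(max(p, 1e-300), 1.0)
        z = float(ndtri(1.0 - p / 2.0))
        se = float(rng.uniform(0.02, 0.05))
        risk = snps.loc[snp, "risk_allele"]
        beta = z * se if risk == v["alt"] else -z * se
        records.append(
            {
                "CHR": v["chrom"],
                "SNP": snp,
                "BP": int(v["pos"]),
                "A1": v["alt"],
                "A2": v["ref"],
                "OR": float(np.exp(beta)),
                "SE": se,
                "P": p,
            }
        )
        classes[snp], pvals[snp] = cls, p

    omit_pool = sorted(asm_all - signal_snps)
    n_omit = round(config.omit_fraction * len(asm_all))
    if n_omit > len(omit_pool):
        raise ConfigError("omit_fraction too large for the non-signal ASM pool")
    omitted = set(
        rng.choice(omit_pool, size=n_omit, replace=False)
    ) if n_omit else set()

    sumstats = pd.DataFrame(records)
    sumstats = sumstats[~sumstats["SNP"].isin(omitted)].reset_index(drop=True)

    truth.snps["p_class"] = truth.snps["snp_id"].map(classes)
    truth.snps["p"] = truth.snps["snp_id"].map(pvals)
    truth.snps["omitted"] = truth.snps["snp_id"].isin(omitted)
    truth.snps["is_asm"] = truth.snps["snp_id"].isin(asm_all)
    truth.predictions["n_omitted"] = int(n_omit)
    return sumstats


def simulate_enrichment_pvalues(
    n_snps: int,
    n_asm: int,
    enrichment_or: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Lightweight (panel-free) draw of (is_asm, p) for enrichment
    power/type-I simulations, using the same boosting scheme as
    :func:`generate_sumstats`."""
    if n_asm > n_snps:
        raise ValueError("n_asm cannot exceed n_snps")
    is_asm = np.zeros(n_snps, dtype=bool)
    is_asm[:n_asm] = True
    p = rng.uniform(0.0, 1.0, size=n_snps)
    pi = asm_significance_prob(enrichment_or)
    boost_prob = max(0.0, (pi - 0.05) / 0.95)
    if boost_prob > 0:
        boosted = is_asm & (rng.random(n_snps) < boost_prob)
        p[boosted] = rng.uniform(0.0, 0.05, size=int(boosted.sum()))
    return is_asm, np.clip(p, 1e-300, 1.0)


# ---------------------------------------------------------------------------
# annototation tables


def generate_annotation_tables(
    panel: LdPanel, truth: SimTruth, config: SimConfig
):
    """TSS / histone / eQTL / volume tables plus planted direction truth.

    Signal blocks get a gene whose TSS puts the block CpG < 5000 bp
    upstream (strand-aware); their SNPs get brain eQTLs whose
    risk-aligned sign opposes the methylation sign with probability
    ``consistency_rate``. Histone flags cover the ten brain regions for
    all pass-filter ASM SNPs. The volume table holds mostly-null
    p-values with hits planted in half of the signal blocks.
    """
    from .functional_integration import AnnotationBundle

    config.validate()
    rng = config.rngs()["annotations"]
    snps = truth.snps.set_index("snp_id")
    blocks = truth.blocks.set_index("block")
    pairs = truth.pairs

    # --- TSS table: promoter genes for signal blocks, decoys elsewhere
    tss_rows = []
    gene_of_block: dict[int, str] = {}
    cons_of_block: dict[int, bool] = {}
    for b, brow in blocks.iterrows():
        if not brow["cpg_id"]:
            continue
        chrom = str(brow["chrom"])
        cpg_pos = int(brow["cpg_pos"])
        if brow["is_signal"]:
            gene = f"GENE{b:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            d = int(rng.integers(200, 4500))
            tss = cpg_pos + d if strand == "+" else cpg_pos - d
            gene_of_block[b] = gene
            tss_rows.append(
                {"gene": gene, "chrom": chrom, "strand": strand, "tss_pos": tss}
            )
        elif rng.random() < 0.3:
            # decoy gene too far from the CpG to promoter-map
            tss_rows.append(
                {
                    "gene": f"DECOY{b:03d}",
                    "chrom": chrom,
                    "strand": "+",
                    "tss_pos": cpg_pos + 6_000 + int(rng.integers(0, 50_000)),
                }
            )
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "strand", "tss_pos"])

    # --- eQTL table
    eqtl_rows = []
    pass_pairs = pairs[pairs["passes_all"]]
    for b in sorted(gene_of_block):
        gene = gene_of_block[b]
        cons = bool(rng.random() < config.consistency_rate)
        cons_of_block[b] = cons
        members = pass_pairs[pass_pairs["block"] == b]
        tissues = list(rng.choice(_EQTL_TISSUES, size=2, replace=False))
        for _, pr in members.iterrows():
            snp = pr["snp_id"]
            s_c = int(pr["meth_risk_sign"])
            aligned = -s_c if cons else s_c
            risk = snps.loc[snp, "risk_allele"]
            ref, alt = snps.loc[snp, "ref"], snps.loc[snp, "alt"]
            for tissue in tissues:
                effect = alt if rng.random() < 0.5 else ref
                slope = aligned if effect == risk else -aligned
                eqtl_rows.append(
                    {
                        "snp_id": snp,
                        "gene": gene,
                        "tissue": tissue,
                        "effect_allele": effect,
                        "slope_sign": slope,
                    }
                )
    # decoy eQTLs on a few non-signal ASM SNPs (random direction/gene)
    decoy_snps = sorted(set(pass_pairs.loc[~pass_pairs["is_signal"], "snp_id"]))
    for snp in decoy_snps[: max(2, len(decoy_snps) // 10)]:
        ref, alt = snps.loc[snp, "ref"], snps.loc[snp, "alt"]
        eqtl_rows.append(
            {
                "snp_id": snp,
                "gene": f"DECOY{int(snps.loc[snp, 'block']):03d}",
                "tissue": str(rng.choice(_EQTL_TISSUES)),
                "effect_allele": alt if rng.random() < 0.5 else ref,
                "slope_sign": 1 if rng.random() < 0.5 else -1,
            }
        )
    eqtl = pd.DataFrame(
        eqtl_rows,
        columns=["snp_id", "gene", "tissue", "effect_allele", "slope_sign"],
    )

    # --- histone marks over the ten regions for all pass-filter ASM SNPs
    hist_rows = []
    for snp in sorted(set(pass_pairs["snp_id"])):
        for region in BRAIN_REGIONS:
            for mark in ENHANCER_MARKS + PROMOTER_MARKS:
                hist_rows.append(
                    {
                        "snp_id": snp,
                        "region": region,
                        "mark": mark,
                        "present": int(rng.random() < 0.35),
                    }
                )
    histone = pd.DataFrame(hist_rows, columns=["snp_id", "region", "mark", "present"])

    # --- volume GWAS: mostly null; hits planted in half the signal blocks
    signal_blocks = sorted(gene_of_block)
    hit_blocks = set(signal_blocks[: max(1, len(signal_blocks) // 2)]) if signal_blocks else set()
    vol_rows = []
    vol_truth: dict[str, list] = {}
    for b in signal_blocks:
        members = pass_pairs[pass_pairs["block"] == b]
        hit_struct = str(rng.choice(VOLUME_STRUCTURES)) if b in hit_blocks else None
        hit_sign = (1 if rng.random() < 0.5 else -1) if b in hit_blocks else 0
        for _, pr in members.iterrows():
            snp = pr["snp_id"]
            if rng.random() < 0.15:  # absent SNP -> "?" downstream
                continue
            risk = snps.loc[snp, "risk_allele"]
            ref, alt = snps.loc[snp, "ref"], snps.loc[snp, "alt"]
            planted = []
            for structure in VOLUME_STRUCTURES:
                if structure == hit_struct:
                    p = float(rng.uniform(1e-5, 6e-4))
                    aligned = hit_sign
                    planted.append((structure, aligned, p))
                else:
                    p = float(rng.uniform(0.05, 1.0))
                    aligned = 1 if rng.random() < 0.5 else -1
                effect = alt if rng.random() < 0.5 else ref
                beta = aligned if effect == risk else -aligned
                vol_rows.append(
                    {
                        "snp_id": snp,
                        "structure": structure,
                        "effect_allele": effect,
                        "beta_sign": beta,
                        "p": p,
                    }
                )
            vol_truth[snp] = planted
    volume = pd.DataFrame(
        vol_rows, columns=["snp_id", "structure", "effect_allele", "beta_sign", "p"]
    )

    bundle = AnnotationBundle(
        tss_table=tss, histone_table=histone, eqtl_table=eqtl, volume_table=volume
    )
    truth.blocks["gene"] = truth.blocks["block"].map(gene_of_block).fillna("")
    truth.blocks["planted_consistent"] = truth.blocks["block"].map(cons_of_block)
    truth.predictions["volume_planted"] = {
        s: [[st, sg, p] for st, sg, p in v] for s, v in vol_truth.items()
    }
    return bundle, truth


# ---------------------------------------------------------------------------
# outcome prediction (the manifest's downstream expectations)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Independent Benjamini–Hochberg used only for manifest prediction."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def predict_outcomes(truth: SimTruth, bundle, config: SimConfig, alpha: float = 0.05) -> None:
    """Fill ``truth.predictions`` with the exact expected downstream
    outputs: tag per CpG, retrieved counts, FDR-significant tags,
    expanded variants, LD-block labels, prioritized candidates and
    consistency verdicts.

    Relies on the construction guarantees: within-block r² > 0.85 for
    every pair (verified at panel generation), cross-block r² ~ 0, and
    fewer than 100 tags (so the screen's pi0 falls back to 1 and
    q-values reduce to Benjamini–Hochberg).
    """
    pairs = truth.pairs
    snps = truth.snps.set_index("snp_id")
    fp = pairs[pairs["passes_all"]]

    def sort_key(snp: str):
        p = snps.loc[snp, "p"] if not snps.loc[snp, "omitted"] else math.inf
        return (p, str(snps.loc[snp, "chrom"]), int(snps.loc[snp, "pos"]), snp)

    # one tag per CpG: the min-(p, pos) member (complete within-block LD)
    tags: dict[str, str] = {}
    for cpg, grp in fp.groupby("cpg_id"):
        tags[cpg] = min(grp["snp_id"], key=sort_key)
    tag_list = sorted(set(tags.values()))
    retrieved = [t for t in tag_list if not snps.loc[t, "omitted"]]

    p_ret = np.array([snps.loc[t, "p"] for t in retrieved])
    q = _bh_qvalues(p_ret)  # pi0 = 1 below 100 tests
    significant = sorted(t for t, qv in zip(retrieved, q) if qv <= alpha)

    # expansion: every pass-filter SNP sharing a CpG with a significant tag
    expanded: set[str] = set()
    for t in significant:
        t_cpgs = set(fp.loc[fp["snp_id"] == t, "cpg_id"])
        expanded |= set(fp.loc[fp["cpg_id"].isin(t_cpgs), "snp_id"])
        expanded.add(t)
    sig_blocks = sorted(set(fp.loc[fp["snp_id"].isin(expanded), "block"]))

    # block labels ordered by leftmost (chrom-string, pos) of members
    def block_min(b: int):
        members = fp.loc[fp["block"] == b, "snp_id"]
        return min((str(snps.loc[s, "chrom"]), int(snps.loc[s, "pos"])) for s in members)

    ordered = sorted(sig_blocks, key=block_min)
    block_label = {b: i + 1 for i, b in enumerate(ordered)}

    # per-variant annotation scores
    hist = bundle.histone_table
    marks = hist[hist["present"] == 1]
    enh_counts = (
        marks[marks["mark"].isin(ENHANCER_MARKS)].groupby("snp_id").size().to_dict()
    )
    prom_counts = (
        marks[marks["mark"].isin(PROMOTER_MARKS)].groupby("snp_id").size().to_dict()
    )
    eqtl_genes = bundle.eqtl_table.groupby("snp_id")["gene"].nunique().to_dict()

    vol_available = set(bundle.volume_table["snp_id"])
    queried = [s for s in sorted(expanded) if s in vol_available]
    vol_thr = alpha / len(queried) if queried else math.nan
    vol_hits: dict[str, int] = {}
    for s in queried:
        rows = bundle.volume_table[bundle.volume_table["snp_id"] == s]
        vol_hits[s] = int((rows["p"] <= vol_thr).sum())

    candidates = {}
    verdicts = {}
    blocks_meta = truth.blocks.set_index("block")
    for b in sig_blocks:
        members = sorted(set(fp.loc[fp["block"] == b, "snp_id"]))
        scored = []
        for s in members:
            score = (
                enh_counts.get(s, 0)
                + prom_counts.get(s, 0)
                + eqtl_genes.get(s, 0)
                + vol_hits.get(s, 0)
            )
            p = math.inf if snps.loc[s, "omitted"] else float(snps.loc[s, "p"])
            scored.append((-score, p, int(snps.loc[s, "pos"]), s))
        winner = min(scored)[3]
        candidates[str(block_label[b])] = winner
        gene = blocks_meta.loc[b, "gene"]
        if gene:
            verdicts[str(block_label[b])] = {
                str(gene): "consistent"
                if bool(blocks_meta.loc[b, "planted_consistent"])
                else "inconsistent"
            }
        else:
            verdicts[str(block_label[b])] = {}

    truth.predictions.update(
        {
            "alpha": alpha,
            "expected_tags": {c: t for c, t in sorted(tags.items())},
            "n_tags": len(tag_list),
            "n_retrieved": len(retrieved),
            "retrieved_fraction": len(retrieved) / len(tag_list) if tag_list else None,
            "expected_significant": significant,
            "expected_expanded": sorted(expanded),
            "n_expanded": len(expanded),
            "expected_block_labels": {
                s: block_label[int(fp.loc[fp["snp_id"] == s, "block"].iloc[0])]
                for s in sorted(expanded)
            },
            "n_blocks": len(sig_blocks),
            "expected_candidates": candidates,
            "expected_verdicts": verdicts,
            "volume_threshold": vol_thr,
            "volume_n_queried": len(queried),
        }
    )


# ---------------------------------------------------------------------------
# top-level driver


def simulate(config: SimConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` and return paths.

    Layout: ``inputs/`` (panel VCF + hap TSV, per-source catalogs,
    sumstats, annotation tables) and ``manifest/`` (ground truth).
    Identical configs produce byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    panel = generate_panel(config)
    catalog_long, truth = generate_asm_catalog(panel, config)
    sumstats = generate_sumstats(panel, truth, config)
    bundle, truth = generate_annotation_tables(panel, truth, config)
    predict_outcomes(truth, bundle, config)

    panel.to_vcf(inputs / "panel.vcf")
    panel.to_hap_tsv(inputs / "panel_hap.tsv")
    catalog_paths = []
    for (study, tissue), grp in catalog_long.groupby(["study", "tissue"]):
        name = f"catalog_{study}_{tissue.replace(' ', '_')}.tsv"
        grp.to_csv(inputs / name, sep="\t", index=False)
        catalog_paths.append(str(inputs / name))
    sumstats.to_csv(inputs / "sumstats.tsv", sep="\t", index=False)
    bundle.write(inputs)
    truth.write(outdir / "manifest")

    return {
        "panel_vcf": str(inputs / "panel.vcf"),
        "panel_hap": str(inputs / "panel_hap.tsv"),
        "catalogs": sorted(catalog_paths),
        "sumstats": str(inputs / "sumstats.tsv"),
        "annotations": str(inputs),
        "manifest": str(outdir / "manifest"),
    }


# ---------------------------------------------------------------------------
# purpose-built fixture for expansion bookkeeping


def expansion_fixture(
    partner_counts: Sequence[int],
    seed: int = 0,
    n_haplotypes: int = 1000,
    within_block_r2: float = 0.97,
) -> tuple[LdPanel, pd.DataFrame, list[str]]:
    """Panel + catalog with planted per-tag high-LD partner counts.

    Builds one block per entry of ``partner_counts`` holding
    ``count + 1`` variants in mutual r² > 0.85 (verified), one CpG per
    block shared by all its variants, and designates one tag per block.
    Returns ``(panel, merged-catalog-like frame, tags)`` so that LD
    expansion of the tags yields exactly ``len(partner_counts) +
    sum(partner_counts)`` distinct variants.
    """
    rng = np.random.default_rng(seed)
    copy_prob = within_block_r2**0.25
    rows, col_blocks = [], []
    cat_rows = []
    tags = []
    counter = 0
    for b, n_partners in enumerate(partner_counts):
        k = n_partners + 1
        for _ in range(50):
            cols = _sample_block(rng, n_haplotypes, k, 0.3, copy_prob)
            if _min_within_r2(cols) >= 0.86:
                break
        else:
            raise PanelGenerationError(f"block {b}: LD floor not reached")
        col_blocks.append(cols)
        chrom = str(b + 1)
        cpg = f"cg{b + 1:08d}"
        for j in range(k):
            counter += 1
            snp = f"rs{counter:06d}"
            rows.append(
                {
                    "snp_id": snp,
                    "chrom": chrom,
                    "pos": 10_000 + j * 1_000,
                    "ref": "A",
                    "alt": "G",
                    "block": b,
                }
            )
            cat_rows.append(
                {
                    "snp_id": snp,
                    "snp_chrom": chrom,
                    "snp_pos": 10_000 + j * 1_000,
                    "cpg_id": cpg,
                    "cpg_chrom": chrom,
                    "cpg_pos": 9_000,
                    "r2_meth": 0.5,
                    "meth_effect_allele": "G",
                    "meth_direction": 1,
                }
            )
            if j == 0:
                tags.append(snp)
    panel = LdPanel(np.concatenate(col_blocks, axis=1), pd.DataFrame(rows))
    return panel, pd.DataFrame(cat_rows), tags
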