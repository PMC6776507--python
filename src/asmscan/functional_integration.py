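"""Direction-consistent functional annotation of associated ASM variants.

Risk-allele orientation, strand-aware promoter mapping of CpGs,
methylation/expression inverse-direction checks, histone-mark counting,
brain-volume lookups, and per-LD-block prioritization of a putative
causal variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationBundle",
    "RiskOrientation",
    "BRAIN_REGIONS",
    "ENHANCER_MARKS",
    "PROMOTER_MARKS",
    "VOLUME_STRUCTURES",
    "orient_risk",
    "align_sign",
    "promoter_map",
    "consistency_check",
    "count_marks",
    "volume_lookup",
    "prioritize",
    "build_report",
]

# the ten brain areas used for histone-mark counting
BRAIN_REGIONS = (
    "hippocampus middle",
    "substantia nigra",
    "anterior caudate",
    "cingulate gyrus",
    "inferior temporal lobe",
    "angular gyrus",
    "dorsolateral prefrontal cortex",
    "germinal matrix",
    "fetal brain male",
    "fetal brain female",
)

ENHANCER_MARKS = ("H3K4me1", "H3K27ac")
PROMOTER_MARKS = ("H3K4me3", "H3K9ac")

VOLUME_STRUCTURES = (
    "nucleus accumbens",
    "amygdala",
    "caudate nucleus",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class AnnotationBundle:
    """File-backed stand-ins for the external annotation services.

    tss_table:     gene, chrom, strand, tss_pos
    histone_table: snp_id, region, mark, present (0/1)
    eqtl_table:    snp_id, gene, tissue, effect_allele, slope_sign (+1/-1)
    volume_table:  snp_id, structure, effect_allele, beta_sign, p
    """

    tss_table: pd.DataFrame
    histone_table: pd.DataFrame
    eqtl_table: pd.DataFrame
    volume_table: pd.DataFrame

    def __post_init__(self) -> None:
        bad_strand = set(self.tss_table["strand"]) - {"+", "-"}
        if bad_strand:
            raise ValueError(f"invalid strands: {bad_strand}")
        bad_struct = set(self.volume_table["structure"]) - set(VOLUME_STRUCTURES)
        if bad_struct:
            raise ValueError(f"unknown volume structures: {bad_struct}")
        if not self.histone_table["present"].isin((0, 1)).all():
            raise ValueError("histone presence flags must be 0/1")

    _FILES = {
        "tss_table": "tss.tsv",
        "histone_table": "histone.tsv",
        "eqtl_table": "eqtl.tsv",
        "volume_table": "volume.tsv",
    }

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_csv(directory / fname, sep="\t", index=False)

    @classmethod
    def read(cls, directory) -> "AnnotationBundle":
        directory = Path(directory)
        kwargs = {
            attr: pd.read_csv(directory / fname, sep="\t", dtype={"chrom": str})
            for attr, fname in cls._FILES.items()
        }
        return cls(**kwargs)


@dataclass(frozen=True)
class RiskOrientation:
    snp_id: str
    risk_allele: str | None
    other_allele: str | None
    undetermined: bool = False


def orient_risk(snp_id: str, effect_allele: str, other_allele: str, or_: float) -> RiskOrientation:
    """The risk allele is the effect allele when OR > 1, else the other
    allele. OR exactly 1 is flagged undetermined and excluded from all
    direction logic."""
    if or_ <= 0:
        raise ValueError(f"odds ratio must be positive, got {or_}")
    if or_ == 1.0:
        return RiskOrientation(snp_id, None, None, undetermined=True)
    if or_ > 1.0:
        return RiskOrientation(snp_id, effect_allele, other_allele)
    return RiskOrientation(snp_id, other_allele, effect_allele)


def align_sign(
    sign: int, effect_allele: str, orientation: RiskOrientation
) -> int | None:
    """Re-express an annotation's effect sign relative to the risk allele.

    The sign is kept when the annotation's effect allele is the risk
    allele (directly or as its strand complement), negated when it is the
    non-risk allele, and None when it matches neither or the risk allele
    is undetermined.
    """
    if orientation.undetermined:
        return None
    risk, other = orientation.risk_allele, orientation.other_allele
    if effect_allele in (risk, _COMPLEMENT.get(risk)):
        return int(sign)
    if effect_allele in (other, _COMPLEMENT.get(other)):
        return -int(sign)
    return None


def promoter_map(
    cpg_chrom: str,
    cpg_pos: int,
    tss_table: pd.DataFrame,
    window: int = 5000,
) -> list[str]:
    """Genes whose TSS lies strictly within ``window`` bp downstream of
    the CpG, i.e. the CpG is < ``window`` bp upstream of the TSS on the
    gene's strand (distance 0, at the TSS, included; gene-body CpGs are
    not promoter-mapped)."""
    genes = []
    for _, row in tss_table.iterrows():
        if str(row["chrom"]) != str(cpg_chrom):
            continue
        if row["strand"] == "+":
            dist = int(row["tss_pos"]) - int(cpg_pos)
        else:
            dist = int(cpg_pos) - int(row["tss_pos"])
        if 0 <= dist < window:
            genes.append(str(row["gene"]))
    return sorted(set(genes))


def consistency_check(
    meth_sign: int | None, eqtl_signs: Mapping[str, int | None]
) -> str:
    """Verdict on methylation/expression direction opposition for one gene.

    ``meth_sign`` is the risk-aligned methylation direction of a promoter
    CpG of the gene; ``eqtl_signs`` maps tissue -> risk-aligned slope
    sign. Verdicts:

    - ``consistent``: every tissue eQTL is inverse to methylation
      (sign product -1 throughout);
    - ``inconsistent``: every tissue shares the methylation sign;
    - ``discordant-across-tissues``: tissues disagree;
    - ``insufficient-data``: either side missing.
    """
    signs = [s for s in eqtl_signs.values() if s is not None]
    if meth_sign is None or not signs:
        return "insufficient-data"
    products = {int(meth_sign) * int(s) for s in signs}
    if products == {-1}:
        return "consistent"
    if products == {1}:
        return "inconsistent"
    return "discordant-across-tissues"


def count_marks(
    snp_id: str, histone_table: pd.DataFrame
) -> tuple[int, int, bool]:
    """(enhancer_count, promoter_count, has_data) for one SNP.

    Counts set (region, mark) flags over the brain regions: enhancer
    marks are H3K4me1/H3K27ac, promoter marks H3K4me3/H3K9ac (each class
    maxes out at 2 x number of regions). A SNP absent from the table
    gets (0, 0, False).
    """
    rows = histone_table[histone_table["snp_id"] == snp_id]
    if rows.empty:
        return 0, 0, False
    present = rows[rows["present"] == 1].drop_duplicates(["region", "mark"])
    enh = int(present["mark"].isin(ENHANCER_MARKS).sum())
    prom = int(present["mark"].isin(PROMOTER_MARKS).sum())
    return enh, prom, True


def volume_lookup(
    snp_ids: Sequence[str],
    volume_table: pd.DataFrame,
    orientations: Mapping[str, RiskOrientation],
    alpha: float = 0.05,
) -> tuple[dict[str, object], float, int]:
    """Brain-volume hits per SNP under a per-run Bonferroni threshold.

    The denominator is the number of queried SNPs actually present in the
    volume table. Returns ``(per-SNP result, threshold, n_queried)``;
    a SNP absent from the table maps to the string ``"?"`` (no
    information available), otherwise to a list of
    ``(structure, risk-aligned direction)`` for structures with
    p <= alpha / n_queried.
    """
    available = set(volume_table["snp_id"])
    queried = [s for s in snp_ids if s in available]
    n_queried = len(queried)
    threshold = alpha / n_queried if n_queried else float("nan")
    out: dict[str, object] = {}
    for snp in snp_ids:
        if snp not in available:
            out[snp] = "?"
            continue
        hits = []
        rows = volume_table[volume_table["snp_id"] == snp]
        for _, row in rows.iterrows():
            if float(row["p"]) <= threshold:
                aligned = align_sign(
                    int(row["beta_sign"]),
                    str(row["effect_allele"]),
                    orientations[snp],
                )
                if aligned is not None:
                    hits.append((str(row["structure"]), int(aligned)))
        out[snp] = sorted(hits)
    return out, threshold, n_queried


def prioritize(block_variants: pd.DataFrame) -> pd.Series:
    """One putative causal variant per LD block.

    ``block_variants`` carries one row per variant with columns
    ``snp_id, p, pos, enhancer_count, promoter_count, n_eqtl_genes,
    n_volume_hits``. The annotation score is the sum of the four counts;
    the argmax wins, with ties broken by smaller GWAS p, then leftmost
    position, then id.
    """
    if block_variants.empty:
        raise ValueError("cannot prioritize an empty LD block")
    df = block_variants.copy()
    df["score"] = (
        df["enhancer_count"]
        + df["promoter_count"]
        + df["n_eqtl_genes"]
        + df["n_volume_hits"]
    )
    df = df.sort_values(
        ["score", "p", "pos", "snp_id"], ascending=[False, True, True, True]
    )
    return df.iloc[0]


def _arrow(sign: int) -> str:
    return "up" if sign > 0 else "down"


def build_report(
    candidates: Sequence[Mapping],
) -> pd.DataFrame:
    """Assemble the final per-block report table.

    Each candidate mapping provides: block_id, snp_id, risk_allele, p,
    meth_directions ({cpg_id: sign}), enhancer_count, promoter_count,
    eqtl_effects ({gene: sign}), promoter_genes (set), volume_hits
    ("?" or [(structure, sign)]), consistency ({gene: verdict}), and
    underline (bool: survives Bonferroni + Meff).
    """
    rows = []
    for c in candidates:
        meth = "; ".join(
            f"{_arrow(s)} {cpg}" for cpg, s in sorted(c["meth_directions"].items())
        )
        expr_parts = []
        for gene, sign in sorted(c["eqtl_effects"].items()):
            label = f"{_arrow(sign)} {gene}"
            if gene in c["promoter_genes"]:
                label += "*"  # promoter-CpG gene
            expr_parts.append(label)
        vh = c["volume_hits"]
        if vh == "?":
            volume = "?"
        elif not vh:
            volume = "-"
        else:
            volume = "; ".join(f"{_arrow(s)} {st}" for st, s in vh)
        verdicts = "; ".join(
            f"{g}:{v}" for g, v in sorted(c.get("consistency", {}).items())
        )
        rows.append(
            {
                "block_id": c["block_id"],
                "snp_id": c["snp_id"],
                "risk_allele": c["risk_allele"],
                "p": c["p"],
                "methylation": meth,
                "enhancer_count": c["enhancer_count"],
                "promoter_count": c["promoter_count"],
                "expression": "; ".join(expr_parts) if expr_parts else "-",
                "volume": volume,
                "consistency": verdicts if verdicts else "-",
                "underline": bool(c["underline"]),
            }
        )
    columns = [
        "block_id",
        "snp_id",
        "risk_allele",
        "p",
        "methylation",
        "enhancer_count",
        "promoter_count",
        "expression",
        "volume",
        "consistency",
        "underline",
    ]
    return pd.DataFrame(rows, columns=columns)
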