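"""GWAS summary-statistics screen for ASM tagSNPs.

Covers the daner-style reader/writer, allele harmonization at the
tag/sumstats join, set-enrichment of ASM SNPs over a ladder of p-value
thresholds (one-sided Fisher exact test), Storey q-values with smoothed
pi0, and the three multiple-testing regimes (FDR, Bonferroni, effective
number of tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats

__all__ = [
    "DANER_COLUMNS",
    "DEFAULT_THRESHOLD_LADDER",
    "SumstatsError",
    "read_daner",
    "write_daner",
    "harmonize_and_join",
    "enrichment_scan",
    "storey_qvalues",
    "QValueResult",
    "bonferroni_threshold",
    "format_threshold",
    "screen",
    "ScreenResult",
]

DANER_COLUMNS = ["CHR", "SNP", "BP", "A1", "A2", "OR", "SE", "P"]

#: Enrichment threshold ladder: the endpoints 5e-2 and 5e-8 with one step
#: per decade in between.
DEFAULT_THRESHOLD_LADDER = (5e-2, 5e-3, 5e-4, 5e-5, 5e-6, 5e-7, 5e-8)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset(_COMPLEMENT)


class SumstatsError(ValueError):
    """Summary statistics violate the expected daner-like contract."""


def read_daner(path) -> pd.DataFrame:
    """Read daner-style summary statistics (CHR SNP BP A1 A2 OR SE P).

    Extra columns are preserved; P must lie in (0,1] and OR must be
    positive.
    """
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "SNP": str})
    missing = [c for c in DANER_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"sumstats missing columns: {missing}")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        raise SumstatsError("P outside (0,1]")
    if (df["OR"] <= 0).any():
        raise SumstatsError("non-positive odds ratio")
    return df


def write_daner(df: pd.DataFrame, path) -> None:
    cols = DANER_COLUMNS + [c for c in df.columns if c not in DANER_COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False)


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_and_join(
    tags: pd.DataFrame,
    sumstats: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Join tag variants to summary statistics with allele reconciliation.

    ``tags`` needs columns ``snp_id, effect_allele, other_allele`` (the
    orientation the downstream direction logic will use, typically the
    panel alt/ref). Records are matched by id; sumstats alleles are
    reconciled to the tag orientation by identity, allele swap (with OR
    inversion), strand flip, or both. Strand-ambiguous pairs (A/T, C/G)
    and irreconcilable allele sets are dropped with reason codes. The
    p-value is never altered.

    Returns the joined table and a retrieval report with per-reason drop
    counts and the retrieved fraction.
    """
    if sumstats["SNP"].duplicated().any():
        dupes = sorted(set(sumstats.loc[sumstats["SNP"].duplicated(), "SNP"]))
        raise SumstatsError(f"duplicate SNP ids in sumstats: {dupes}")
    ss = sumstats.set_index("SNP")

    rows, drops = [], []
    for _, tag in tags.iterrows():
        snp = tag["snp_id"]
        e, o = str(tag["effect_allele"]), str(tag["other_allele"])
        if snp not in ss.index:
            drops.append({"snp_id": snp, "reason": "absent_from_sumstats"})
            continue
        rec = ss.loc[snp]
        a1, a2 = str(rec["A1"]), str(rec["A2"])
        if not {a1, a2, e, o} <= _VALID_ALLELES:
            drops.append({"snp_id": snp, "reason": "invalid_allele"})
            continue
        if _is_ambiguous(a1, a2) or _is_ambiguous(e, o):
            drops.append({"snp_id": snp, "reason": "strand_ambiguous"})
            continue
        fa1, fa2 = _COMPLEMENT[a1], _COMPLEMENT[a2]
        if (a1, a2) == (e, o) or (fa1, fa2) == (e, o):
            or_ = float(rec["OR"])
        elif (a2, a1) == (e, o) or (fa2, fa1) == (e, o):
            or_ = 1.0 / float(rec["OR"])
        else:
            drops.append({"snp_id": snp, "reason": "allele_mismatch"})
            continue
        rows.append(
            {
                "snp_id": snp,
                "chrom": str(rec["CHR"]),
                "pos": int(rec["BP"]),
                "effect_allele": e,
                "other_allele": o,
                "or_": or_,
                "se": float(rec["SE"]),
                "p": float(rec["P"]),
            }
        )

    joined = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "or_",
            "se",
            "p",
        ],
    )
    drop_df = pd.DataFrame(drops, columns=["snp_id", "reason"])
    report = {
        "n_tags": len(tags),
        "n_retrieved": len(joined),
        "retrieved_fraction": len(joined) / len(tags) if len(tags) else float("nan"),
        "drops_by_reason": drop_df["reason"].value_counts().to_dict(),
        "dropped": drop_df,
    }
    return joined, report


@dataclass(frozen=True)
class EnrichmentResult:
    threshold: float
    n_asm_sig: int
    n_asm_nonsig: int
    n_other_sig: int
    n_other_nonsig: int
    odds_ratio: float
    p: float


def enrichment_scan(
    is_asm: Sequence[bool],
    pvalues: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLD_LADDER,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Fisher exact enrichment of ASM SNPs among significant GWAS hits.

    For each threshold t the 2x2 table [ASM vs not] x [p < t vs not] is
    tested (one-sided 'greater' by default: enrichment direction). When a
    table margin is empty the sample odds ratio is undefined (NaN) but
    the exact p is still reported.
    """
    asm = np.asarray(is_asm, dtype=bool)
    p = np.asarray(pvalues, dtype=float)
    if asm.shape != p.shape:
        raise ValueError("is_asm and pvalues must align")
    results = []
    for tau in thresholds:
        sig = p < tau
        a = int(np.sum(asm & sig))
        b = int(np.sum(asm & ~sig))
        c = int(np.sum(~asm & sig))
        d = int(np.sum(~asm & ~sig))
        fisher_p = float(
            stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue
        )
        or_ = (a * d) / (b * c) if (b * c) > 0 else float("nan")
        results.append(
            EnrichmentResult(
                threshold=float(tau),
                n_asm_sig=a,
                n_asm_nonsig=b,
                n_other_sig=c,
                n_other_nonsig=d,
                odds_ratio=or_,
                p=fisher_p,
            )
        )
    return pd.DataFrame([r.__dict__ for r in results])


@dataclass(frozen=True)
class QValueResult:
    qvalues: np.ndarray
    pi0: float
    fdr_p_star: float  # largest observed p with q <= alpha (0 when none)


def _pi0_smoother(p: np.ndarray, lambdas: np.ndarray) -> float:
    m = len(p)
    pi0_lam = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas], dtype=float
    )
    spline = interpolate.UnivariateSpline(lambdas, pi0_lam, k=3)
    pi0 = float(spline(lambdas.max()))
    if not np.isfinite(pi0) or pi0 <= 0:
        raise ValueError("pi0 smoothing failed")
    return min(pi0, 1.0)


def storey_qvalues(
    pvalues: Sequence[float],
    alpha: float = 0.05,
    lambdas: Sequence[float] | None = None,
    pi0: float | None = None,
) -> QValueResult:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated by a cubic smoothing spline through
    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid
    0.05..0.95 (step 0.05), evaluated at the largest lambda. For fewer
    than 100 tests, or when smoothing fails, pi0 falls back to 1 (the
    q-values then equal Benjamini–Hochberg adjusted p-values). ``pi0``
    may also be forced explicitly.

    ``fdr_p_star`` is the largest observed p-value with q <= ``alpha``
    (0.0 when no test passes).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            grid = (
                np.asarray(lambdas, dtype=float)
                if lambdas is not None
                else np.arange(0.05, 0.96, 0.05)
            )
            try:
                pi0 = _pi0_smoother(p, grid)
            except Exception:
                pi0 = 1.0
    if not (0 < pi0 <= 1):
        raise ValueError(f"pi0 must be in (0,1], got {pi0}")

    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted

    passing = ranked[q_sorted <= alpha]
    fdr_p_star = float(passing.max()) if len(passing) else 0.0
    return QValueResult(qvalues=q, pi0=float(pi0), fdr_p_star=fdr_p_star)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """alpha / m, the family-wise threshold for m tests."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def format_threshold(x: float, digits: int = 3, truncate: bool = False) -> str:
    """Render a threshold like ``1.32E-05`` with ``digits`` significant
    figures; with ``truncate`` the final digit is cut, not rounded (some
    published thresholds are rendered that way)."""
    if x <= 0 or not math.isfinite(x):
        raise ValueError(f"cannot format {x}")
    exp = math.floor(math.log10(x))
    mant = x / 10**exp
    if truncate:
        scale = 10 ** (digits - 1)
        mant = math.floor(mant * scale + 1e-9) / scale
    else:
        mant = round(mant, digits - 1)
        if mant >= 10:  # rounding rolled the mantissa over
            mant /= 10
            exp += 1
    return f"{mant:.{digits - 1}f}E{exp:+03d}"


@dataclass(frozen=True)
class ScreenResult:
    """Per-tagSNP verdicts under the three multiple-testing regimes."""

    table: pd.DataFrame  # snp_id p q pass_fdr pass_bonferroni pass_meff
    pi0: float
    fdr_p_star: float
    alpha_over_m: float
    alpha_over_meff: float
    meff: float

    @property
    def significant(self) -> list[str]:
        return sorted(self.table.loc[self.table["pass_fdr"], "snp_id"])

    @property
    def strict(self) -> list[str]:
        mask = self.table["pass_bonferroni"] & self.table["pass_meff"]
        return sorted(self.table.loc[mask, "snp_id"])


def screen(
    joined: pd.DataFrame,
    alpha: float = 0.05,
    meff: float | None = None,
    pi0: float | None = None,
) -> ScreenResult:
    """Flag each retrieved tagSNP under FDR / Bonferroni / Meff regimes.

    ``joined`` is the harmonized table (needs ``snp_id`` and ``p``).
    ``meff`` is the effective number of independent tests (defaults to
    the raw test count m, i.e. no relaxation).
    """
    m = len(joined)
    if m == 0:
        raise ValueError("no retrieved tagSNPs to screen")
    p = joined["p"].to_numpy(dtype=float)
    qres = storey_qvalues(p, alpha=alpha, pi0=pi0)
    if meff is None:
        meff = float(m)
    if not (1.0 <= meff <= m):
        raise ValueError(f"meff must lie in [1, {m}], got {meff}")
    thr_bonf = bonferroni_threshold(alpha, m)
    thr_meff = alpha / meff
    table = joined.copy()
    table["q"] = qres.qvalues
    table["pass_fdr"] = table["q"] <= alpha
    table["pass_bonferroni"] = p <= thr_bonf
    table["pass_meff"] = p <= thr_meff
    return ScreenResult(
        table=table,
        pi0=qres.pi0,
        fdr_p_star=qres.fdr_p_star,
        alpha_over_m=thr_bonf,
        alpha_over_meff=thr_meff,
        meff=float(meff),
    )
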