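"""Linkage-disequilibrium computations on haplotype reference panels.

Provides pairwise r²/|D′| from phased haplotypes (exact haplotype
counting) or from unphased dosages (EM over the double-heterozygote
ambiguity), greedy per-CpG tagSNP selection, LD expansion of significant
tags, LD-block assignment as connected components, and the effective
number of independent tests from the eigenvalues of the variant
correlation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "LdPanel",
    "LdResult",
    "TagAssignment",
    "MonomorphicVariantError",
    "EmConvergenceError",
    "PanelFormatError",
    "r2_phased",
    "r2_unphased_em",
    "r2_matrix",
    "select_tags",
    "ld_expand",
    "assign_blocks",
    "effective_tests",
    "meff_from_correlation",
]

_VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


class MonomorphicVariantError(ValueError):
    """r² is undefined for a variant with no allelic variation."""


class EmConvergenceError(RuntimeError):
    """EM failed to converge; ``.last_estimate`` carries the final LdResult."""

    def __init__(self, message: str, last_estimate: "LdResult"):
        super().__init__(message)
        self.last_estimate = last_estimate


class PanelFormatError(ValueError):
    """The panel file or matrix violates the expected layout."""


@dataclass
class LdPanel:
    """Phased reference panel: binary haplotype matrix plus a variant index.

    Parameters
    ----------
    haplotypes:
        ``(n_haplotypes, n_variants)`` array of alt-allele indicators
        (0/1 per haplotype).
    variants:
        One row per column of ``haplotypes`` with at least the columns
        ``snp_id, chrom, pos, ref, alt``. Positions are 1-based and must
        be sorted within each chromosome.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    _col: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise PanelFormatError("haplotype matrix must be 2-D")
        bad = ~np.isin(self.haplotypes, (0, 1))
        if bad.any():
            raise PanelFormatError("haplotype entries must be 0 or 1")
        missing = [c for c in _VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise PanelFormatError(f"variant table missing columns: {missing}")
        if len(self.variants) != self.haplotypes.shape[1]:
            raise PanelFormatError(
                "variant table length does not match haplotype matrix width"
            )
        if self.variants["snp_id"].duplicated().any():
            dupes = self.variants.loc[self.variants["snp_id"].duplicated(), "snp_id"]
            raise PanelFormatError(f"duplicate variant ids: {sorted(set(dupes))}")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise PanelFormatError("positions not sorted within chromosome")
        self.variants = self.variants.reset_index(drop=True)
        self._col = {s: i for i, s in enumerate(self.variants["snp_id"])}

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._col

    def column(self, snp_id: str) -> np.ndarray:
        """Alt-allele indicator vector for one variant."""
        try:
            return self.haplotypes[:, self._col[snp_id]]
        except KeyError:
            raise KeyError(f"variant {snp_id!r} not in panel") from None

    def variant_row(self, snp_id: str) -> pd.Series:
        return self.variants.iloc[self._col[snp_id]]

    def position(self, snp_id: str) -> tuple[str, int]:
        row = self.variant_row(snp_id)
        return str(row["chrom"]), int(row["pos"])

    # --- plain-text round-trips -------------------------------------------

    def to_hap_tsv(self, path) -> None:
        """Write variants + haplotype columns as a headered TSV."""
        df = self.variants[_VARIANT_COLUMNS].copy()
        hap_cols = {f"h{i}": self.haplotypes[i, :] for i in range(self.n_haplotypes)}
        df = pd.concat([df, pd.DataFrame(hap_cols)], axis=1)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_hap_tsv(cls, path) -> "LdPanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        hap_cols = [c for c in df.columns if c.startswith("h") and c[1:].isdigit()]
        if not hap_cols:
            raise PanelFormatError(f"no haplotype columns found in {path}")
        hap_cols.sort(key=lambda c: int(c[1:]))
        haps = df[hap_cols].to_numpy(dtype=np.int8).T
        return cls(haps, df[_VARIANT_COLUMNS])

    def to_vcf(self, path) -> None:
        """Write a minimal phased VCF (GT-only, one diploid sample per
        haplotype pair); requires an even haplotype count."""
        if self.n_haplotypes % 2:
            raise PanelFormatError("VCF output needs an even number of haplotypes")
        n_samples = self.n_haplotypes // 2
        samples = [f"S{i:04d}" for i in range(n_samples)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in dict.fromkeys(self.variants["chrom"].astype(str)):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(samples)
                + "\n"
            )
            for j, row in self.variants.iterrows():
                gts = "\t".join(
                    f"{self.haplotypes[2 * i, j]}|{self.haplotypes[2 * i + 1, j]}"
                    for i in range(n_samples)
                )
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                    f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "LdPanel":
        """Read a phased, biallelic, GT-only VCF written by :meth:`to_vcf`
        (or any plain-text VCF with '|'-phased genotypes)."""
        rows, cols = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
                if "," in alt:
                    raise PanelFormatError(f"multiallelic record {vid} unsupported")
                gt_idx = f[8].split(":").index("GT")
                alleles = []
                for sample in f[9:]:
                    gt = sample.split(":")[gt_idx]
                    if "|" not in gt:
                        raise PanelFormatError(f"unphased genotype at {vid}: {gt}")
                    alleles.extend(int(a) for a in gt.split("|"))
                rows.append((vid, chrom, pos, ref, alt))
                cols.append(alleles)
        if not rows:
            raise PanelFormatError(f"no variant records in {path}")
        variants = pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
        return cls(np.array(cols, dtype=np.int8).T, variants)


@dataclass(frozen=True)
class LdResult:
    """Pairwise LD between two biallelic variants."""

    snp_a: str
    snp_b: str
    r2: float
    d_prime: float
    n_haplotypes: int
    ambiguous: bool = False


@dataclass(frozen=True)
class TagAssignment:
    """A tagSNP and the candidate variants it covers for one CpG."""

    cpg_id: str
    tag_snp: str
    tagged_snps: Mapping[str, float]  # snp_id -> r2 with the tag


def _check_polymorphic(x: np.ndarray, snp_id: str) -> float:
    p = float(x.mean())
    if p <= 0.0 or p >= 1.0:
        raise MonomorphicVariantError(
            f"variant {snp_id!r} is monomorphic in the panel; r2 undefined"
        )
    return p


def _ld_from_freqs(pa: float, pb: float, pab: float) -> tuple[float, float]:
    """(r², |D′|) from marginal and joint alt-allele haplotype frequencies."""
    d = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = d * d / denom
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return 0.0, 0.0
    return r2, abs(d) / dmax


def r2_phased(panel: LdPanel, a: str, b: str) -> LdResult:
    """Exact LD between two panel variants by haplotype-frequency counting.

    Raises :class:`MonomorphicVariantError` if either variant carries no
    variation (r² is undefined there, never reported as 0).
    """
    x, y = panel.column(a), panel.column(b)
    pa = _check_polymorphic(x, a)
    pb = _check_polymorphic(y, b)
    pab = float(np.mean((x == 1) & (y == 1)))
    r2, dp = _ld_from_freqs(pa, pb, pab)
    return LdResult(a, b, r2, dp, panel.n_haplotypes)


def r2_unphased_em(
    genotypes: np.ndarray,
    a: int | str = 0,
    b: int | str = 1,
    variant_ids: Sequence[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdResult:
    """LD from unphased diploid dosages via EM (Hill-type scheme).

    ``genotypes`` is an ``(n_individuals, n_variants)`` matrix of 0/1/2
    alt-allele dosages; ``a``/``b`` are column indices (or ids when
    ``variant_ids`` is given). Only the double heterozygote is ambiguous;
    its expected phase split is re-estimated until the log-likelihood
    changes by less than ``tol``.
    """
    g = np.asarray(genotypes)
    if variant_ids is not None:
        idx = {v: i for i, v in enumerate(variant_ids)}
        a_i, b_i = idx[a], idx[b]
        name_a, name_b = str(a), str(b)
    else:
        a_i, b_i = int(a), int(b)
        name_a, name_b = f"var{a_i}", f"var{b_i}"
    ga, gb = g[:, a_i], g[:, b_i]
    if not np.isin(ga, (0, 1, 2)).all() or not np.isin(gb, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0,1,2}")
    n_ind = len(ga)
    pa = float(ga.mean()) / 2.0
    pb = float(gb.mean()) / 2.0
    if pa in (0.0, 1.0):
        raise MonomorphicVariantError(f"variant {name_a!r} is monomorphic")
    if pb in (0.0, 1.0):
        raise MonomorphicVariantError(f"variant {name_b!r} is monomorphic")

    # 3x3 genotype counts
    counts = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        counts[i, j] += 1
    n_dh = counts[1, 1]
    all_double_het = n_dh == n_ind

    # haplotype counts that are fully determined by the genotypes
    # haplotypes: 11 (alt/alt), 10, 01, 00
    fixed = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            # each individual contributes two haplotypes; dosage splits are
            # unambiguous except for the double heterozygote
            ha = [1] * i + [0] * (2 - i)
            hb = [1] * j + [0] * (2 - j)
            for k in range(2):
                hap = (ha[k], hb[k])
                fixed[{(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[hap]] += c

    f = np.full(4, 0.25)  # f11, f10, f01, f00
    last_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        # E: split double hets between cis (11/00) and trans (10/01)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        w = 0.5 if cis + trans == 0 else cis / (cis + trans)
        hap_counts = fixed.copy()
        hap_counts[0] += n_dh * w
        hap_counts[3] += n_dh * w
        hap_counts[1] += n_dh * (1 - w)
        hap_counts[2] += n_dh * (1 - w)
        # M
        f = hap_counts / hap_counts.sum()
        ll = 0.0
        if n_dh:
            ll += n_dh * math.log(2 * (f[0] * f[3] + f[1] * f[2]))
        with np.errstate(divide="ignore"):
            lf = np.where(fixed > 0, np.log(np.where(f > 0, f, 1)), 0.0)
        ll += float((fixed * lf).sum())
        if abs(ll - last_ll) < tol:
            converged = True
            break
        last_ll = ll

    pa_hat = f[0] + f[1]
    pb_hat = f[0] + f[2]
    r2, dp = _ld_from_freqs(pa_hat, pb_hat, f[0])
    result = LdResult(name_a, name_b, r2, dp, 2 * n_ind, ambiguous=all_double_het)
    if not converged:
        raise EmConvergenceError(
            f"EM did not converge within {max_iter} iterations", result
        )
    return result


def r2_matrix(panel: LdPanel, snp_ids: Sequence[str]) -> np.ndarray:
    """Pairwise r² matrix over the given variants (haplotype correlation
    squared, identical to the frequency-based definition on 0/1 data)."""
    cols = np.stack([panel.column(s) for s in snp_ids], axis=1).astype(float)
    for s, c in zip(snp_ids, cols.T):
        _check_polymorphic(c, s)
    r = np.corrcoef(cols, rowvar=False)
    if r.ndim == 0:  # single variant
        r = np.array([[1.0]])
    return r**2


def select_tags(
    candidates: Mapping[str, Sequence[str]],
    panel: LdPanel,
    r2_min: float = 0.85,
    pvalues: Mapping[str, float] | None = None,
) -> tuple[list[TagAssignment], list[str]]:
    """Greedy per-CpG tagSNP selection (pairwise set cover).

    For each CpG, repeatedly pick the candidate covering the largest
    number of still-untagged candidates at r² >= ``r2_min`` (a candidate
    always covers itself). Ties are broken by smaller GWAS p-value when
    ``pvalues`` is supplied, then by leftmost position, then id.

    Returns the assignments plus the list of candidates that were absent
    from the panel (excluded with a warning entry, never silently).
    """
    assignments: list[TagAssignment] = []
    missing: list[str] = []
    for cpg_id in candidates:
        snps = list(dict.fromkeys(candidates[cpg_id]))
        present = [s for s in snps if s in panel]
        missing.extend(s for s in snps if s not in panel)
        if not present:
            continue
        r2 = r2_matrix(panel, present)
        cover = {
            s: {present[j] for j in range(len(present)) if r2[i, j] >= r2_min}
            for i, s in enumerate(present)
        }
        untagged = set(present)

        def sort_key(s: str):
            p = pvalues.get(s, math.inf) if pvalues else math.inf
            chrom, pos = panel.position(s)
            return (-len(cover[s] & untagged), p, chrom, pos, s)

        while untagged:
            tag = min(sorted(untagged), key=sort_key)
            covered = cover[tag] & untagged
            i_tag = present.index(tag)
            assignments.append(
                TagAssignment(
                    cpg_id=cpg_id,
                    tag_snp=tag,
                    tagged_snps={
                        s: float(r2[i_tag, present.index(s)]) for s in sorted(covered)
                    },
                )
            )
            untagged -= covered
    return assignments, missing


def ld_expand(
    tags: Sequence[str],
    catalog: pd.DataFrame,
    panel: LdPanel,
    r2_min: float = 0.85,
    same_cpg: bool = True,
) -> tuple[dict[str, set[str]], set[str]]:
    """Expand significant tags to all catalog SNPs in high LD with them.

    ``catalog`` needs ``snp_id`` and ``cpg_id`` columns (one row per
    pair). When ``same_cpg`` is set, a partner must share at least one
    CpG with the tag. Each tag is always a member of its own expansion.

    Returns ``(per-tag partner sets including the tag, union)``.
    """
    snp_cpgs: dict[str, set[str]] = {}
    for snp, grp in catalog.groupby("snp_id"):
        snp_cpgs[str(snp)] = set(grp["cpg_id"])
    expansion: dict[str, set[str]] = {}
    for tag in tags:
        members = {tag}
        tag_cpgs = snp_cpgs.get(tag, set())
        for snp, cpgs in snp_cpgs.items():
            if snp == tag or snp not in panel:
                continue
            if same_cpg and not (tag_cpgs & cpgs):
                continue
            if tag in panel and r2_phased(panel, tag, snp).r2 >= r2_min:
                members.add(snp)
        expansion[tag] = members
    union: set[str] = set().union(*expansion.values()) if expansion else set()
    return expansion, union


def assign_blocks(
    variant_ids: Sequence[str], panel: LdPanel, r2_min: float = 0.85
) -> dict[str, int]:
    """LD blocks as connected components of the r² >= ``r2_min`` graph.

    Blocks are labelled 1..k ordered by their leftmost variant
    (chromosome, then position), so labels are deterministic.
    """
    ids = list(dict.fromkeys(variant_ids))
    g = nx.Graph()
    g.add_nodes_from(ids)
    if len(ids) > 1:
        r2 = r2_matrix(panel, ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if r2[i, j] >= r2_min:
                    g.add_edge(ids[i], ids[j])
    comps = sorted(
        nx.connected_components(g),
        key=lambda c: min(panel.position(s) for s in c),
    )
    labels: dict[str, int] = {}
    for k, comp in enumerate(comps, start=1):
        for s in comp:
            labels[s] = k
    return labels


def meff_from_correlation(r: np.ndarray) -> float:
    """Effective number of independent tests from a correlation matrix.

    Meff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ] over the
    eigenvalues lam_i of the signed correlation matrix (the piecewise
    eigenvalue estimator). Always within [1, M].
    """
    r = np.asarray(r, dtype=float)
    if r.ndim == 0:
        r = np.array([[1.0]])
    m = r.shape[0]
    lam = np.linalg.eigvalsh(r)
    if lam.min() < -1e-6:
        raise ValueError(
            f"correlation matrix not PSD after numerical cleanup "
            f"(min eigenvalue {lam.min():.3g})"
        )
    lam = np.clip(lam, 0.0, None)
    # snap integer-boundary eigenvalues before floor()/the indicator
    # (duplicated variants give lam = M up to float error; floor() must
    # not drop a whole unit) but keep exact values in the sum
    snapped = np.where(np.abs(lam - np.round(lam)) < 1e-9, np.round(lam), lam)
    meff = float(
        lam.sum() - np.floor(snapped).sum() + np.count_nonzero(snapped >= 1.0)
    )
    return float(min(max(meff, 1.0), m))


def effective_tests(panel: LdPanel, variant_ids: Sequence[str]) -> float:
    """Effective number of independent tests for a set of panel variants
    (see :func:`meff_from_correlation`)."""
    ids = list(dict.fromkeys(variant_ids))
    if not ids:
        raise ValueError("effective_tests requires at least one variant")
    cols = np.stack([panel.column(s) for s in ids], axis=1).astype(float)
    for s, c in zip(ids, cols.T):
        _check_polymorphic(c, s)
    r = np.corrcoef(cols, rowvar=False)
    return meff_from_correlation(r)
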