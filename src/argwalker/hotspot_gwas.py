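"""Association scan between hotspot-strength phenotypes and SNP genotypes.

Each hotspot's per-haplotype recombination strengths form a quantitative
phenotype; every SNP partitions the haplotypes into allele-0 and allele-1
carriers, and a two-sided unpaired Student t-test (pooled variance, Welch
available behind a flag) compares strengths between the two groups.  The
scan reports one row per (hotspot, testable SNP) with significance at a
fixed threshold of 10^-7.3 (5e-8 for the MHC screen); no further
multiple-testing correction is applied.

Hotspot phenotypes on a chromosome can also be merged into one chromosomal
phenotype: each hotspot vector is standardized to (x - mean)/SD and the
standardized vectors are averaged per haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("argwalker")

__all__ = [
    "GWAS_THRESHOLD",
    "MHC_THRESHOLD",
    "AssocResult",
    "ChromosomePhenotype",
    "ttest_association",
    "gwas_scan",
    "maf_filter",
    "combine_by_chromosome",
]

#: genome-wide significance threshold used by the scan (p < 1e-7.3)
GWAS_THRESHOLD = 10 ** (-7.3)
#: stricter threshold used when screening the MHC region
MHC_THRESHOLD = 5e-8


@dataclass(frozen=True)
class AssocResult:
    hotspot_id: str
    snp_id: str
    t_stat: float
    p_value: float
    n_group0: int
    n_group1: int
    significant: bool
    testable: bool = True


@dataclass(frozen=True)
class ChromosomePhenotype:
    chromosome: str
    values: dict[str, float]  # haplotype/individual id -> combined z-score mean
    n_hotspots_combined: int


def ttest_association(
    phenotype: Sequence[float],
    alleles: Sequence[int],
    *,
    welch: bool = False,
) -> tuple[float, float]:
    """Two-sided unpaired t-test of strength between allele-0 and allele-1 carriers.

    Uses the pooled-variance Student test by default (``welch=True`` for the
    unequal-variance variant).  Returns ``(t, p)``; raises ``ValueError``
    ("untestable") when either allele group has fewer than two members or
    the pooled variance is zero.
    """
    y = np.asarray(phenotype, dtype=float)
    a = np.asarray(alleles)
    g0, g1 = y[a == 0], y[a == 1]
    if g0.size < 2 or g1.size < 2:
        raise ValueError("untestable: an allele group has fewer than 2 members")
    if np.var(g0, ddof=1) + np.var(g1, ddof=1) == 0:
        if g0.mean() == g1.mean():
            return 0.0, 1.0
        raise ValueError("untestable: zero pooled variance with distinct means")
    t, p = stats.ttest_ind(g0, g1, equal_var=not welch)
    return float(t), float(p)


def maf_filter(genotypes: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """Drop SNP columns with minor allele frequency below ``floor``.

    ``genotypes`` is a haplotype × SNP 0/1 DataFrame.  The number of removed
    columns is logged; ``floor=0`` is the identity.
    """
    if not 0.0 <= floor <= 0.5:
        raise ValueError("MAF floor must be in [0, 0.5]")
    freq = genotypes.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    keep = maf >= floor
    removed = int((~keep).sum())
    if removed:
        logger.info("maf_filter: removed %d of %d SNPs below MAF %g",
                    removed, genotypes.shape[1], floor)
    out = genotypes.loc[:, keep]
    if out.shape[1] == 0:
        import warnings

        warnings.warn("maf_filter: no SNP passed the MAF floor")
    return out


def gwas_scan(
    profiles: Mapping[str, Mapping[str, float]],
    genotypes: pd.DataFrame,
    threshold: float = GWAS_THRESHOLD,
    *,
    hotspot_chrom: Mapping[str, str] | None = None,
    snp_chrom: Mapping[str, str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Scan every (hotspot phenotype, SNP) pair with the unpaired t-test.

    Parameters
    ----------
    profiles
        ``hotspot_id -> {haplotype_id -> strength}``.  The association unit
        is the haplotype (phased allele groups).
    genotypes
        Haplotype × SNP 0/1 DataFrame indexed by haplotype id.
    threshold
        Fixed significance level on the p-value.
    hotspot_chrom, snp_chrom
        Optional chromosome annotations; when both are given, each result
        row is annotated cis (same chromosome) or trans.

    Returns a tidy DataFrame with columns ``hotspot_id, snp_id,
    chrom_hotspot, chrom_snp, t, p, significant, cis_trans``.  Untestable
    SNPs (monomorphic group or zero variance) are excluded and counted in
    the log.  Raises on haplotype-id mismatch, listing the first unmatched
    ids.
    """
    rows = []
    n_untestable = 0
    for hid, strengths in profiles.items():
        ids = sorted(strengths)
        missing = [h for h in ids if h not in genotypes.index]
        if missing:
            raise KeyError(
                f"hotspot {hid}: haplotype ids missing from genotypes: "
                f"{missing[:10]}"
            )
        y = np.asarray([strengths[h] for h in ids], dtype=float)
        geno = genotypes.loc[ids]
        for snp in genotypes.columns:
            try:
                t, p = ttest_association(y, geno[snp].to_numpy(), welch=welch)
            except ValueError:
                n_untestable += 1
                continue
            ch_h = str(hotspot_chrom[hid]) if hotspot_chrom else ""
            ch_s = str(snp_chrom[snp]) if snp_chrom else ""
            cis_trans = ""
            if ch_h and ch_s:
                cis_trans = "cis" if ch_h == ch_s else "trans"
            rows.append(
                {
                    "hotspot_id": hid,
                    "snp_id": str(snp),
                    "chrom_hotspot": ch_h,
                    "chrom_snp": ch_s,
                    "t": t,
                    "p": p,
                    "significant": bool(p < threshold),
                    "cis_trans": cis_trans,
                }
            )
    if n_untestable:
        logger.info("gwas_scan: %d (hotspot, SNP) pairs untestable", n_untestable)
    return pd.DataFrame(
        rows,
        columns=[
            "hotspot_id", "snp_id", "chrom_hotspot", "chrom_snp",
            "t", "p", "significant", "cis_trans",
        ],
    )


def combine_by_chromosome(
    profiles_by_chrom: Mapping[str, Mapping[str, Mapping[str, float]]],
) -> dict[str, ChromosomePhenotype]:
    """Merge hotspot phenotypes per chromosome into one combined phenotype.

    Each hotspot vector is standardized with (x - mean)/SD over its ids and
    the standardized vectors are averaged id-wise.  Hotspots with zero SD
    are skipped with a warning; a chromosome with no usable hotspot is
    omitted (with a warning).  All profiles on a chromosome must cover the
    same id set.
    """
    import warnings

    out: dict[str, ChromosomePhenotype] = {}
    for chrom, hotspots in profiles_by_chrom.items():
        z_vectors = []
        id_set: tuple[str, ...] | None = None
        for hid, strengths in hotspots.items():
            ids = tuple(sorted(strengths))
            if id_set is None:
                id_set = ids
            elif ids != id_set:
                raise ValueError(
                    f"chromosome {chrom}: hotspot {hid} covers a different id set"
                )
            x = np.asarray([strengths[h] for h in ids], dtype=float)
            sd = x.std(ddof=0)
            if sd == 0:
                warnings.warn(f"hotspot {hid}: zero SD, skipped in combination")
                continue
            z_vectors.append((x - x.mean()) / sd)
        if not z_vectors or id_set is None:
            warnings.warn(f"chromosome {chrom}: no usable hotspot, omitted")
            continue
        combined = np.mean(z_vectors, axis=0)
        out[chrom] = ChromosomePhenotype(
            chromosome=str(chrom),
            values=dict(zip(id_set, combined.tolist())),
            n_hotspots_combined=len(z_vectors),
        )
    return out
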