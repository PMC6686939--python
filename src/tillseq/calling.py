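"""Per-pool candidate variants from pooled allele counts.

A rare induced mutation carried by one individual in a pool of P
diploids is expected at allele fraction 1/(2P) (heterozygous) or 1/P
(homozygous) -- 0.00195 and 0.0039 at the study's P=256.  The caller
here is a thresholded one-sided exact binomial test of the alt count
against the per-base sequencing-error rate; candidates are then passed
through the common-variant filter (AF strictly below 5% by default),
which removes natural polymorphisms shared by many pool members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .panel import AmpliconPanel
from .simulate import BASES, BASE_INDEX, PoolAlleleCounts, Zygosity

__all__ = [
    "CandidateVariant",
    "call_pool_variants",
    "filter_common",
    "expected_allele_fraction",
    "min_coverage_for_reads",
    "scaled_af_max",
    "write_vcf",
    "read_vcf",
]


@dataclass(frozen=True, order=True)
class CandidateVariant:
    """One putative variant in one pool: an alt base with read support."""

    pool_id: int
    amplicon: str
    position: int  # 1-based
    ref_base: str
    alt_base: str
    alt_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )

    @property
    def af(self) -> float:
        """Allele fraction: alt reads over total depth at the site."""
        return self.alt_count / self.depth


def call_pool_variants(
    counts: PoolAlleleCounts,
    min_alt_reads: int = 2,
    error_rate: float = 0.001,
    alpha: float = 1e-4,
) -> list[CandidateVariant]:
    """Emit candidates where the alt count is inconsistent with noise.

    A candidate is emitted for each (pool, amplicon, position, alt base)
    with ``alt_count >= min_alt_reads`` AND a one-sided exact binomial
    tail P(X >= alt_count | depth, error_rate/3) strictly below
    ``alpha``.  Zero-depth positions are skipped.  Deterministic.
    """
    if min_alt_reads < 1:
        raise ValueError(f"min_alt_reads must be >= 1, got {min_alt_reads}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    p_null = error_rate / 3.0
    out: list[CandidateVariant] = []
    for (pool, amp), arr in sorted(counts.counts.items()):
        codes = counts.ref_codes[amp]
        length = arr.shape[1]
        depth = arr.sum(axis=0)
        positions = np.arange(length)
        is_ref = np.zeros((4, length), dtype=bool)
        is_ref[codes, positions] = True
        candidate = (~is_ref) & (arr >= min_alt_reads) & (depth[None, :] > 0)
        if not candidate.any():
            continue
        alt_rows, alt_cols = np.nonzero(candidate)
        k = arr[alt_rows, alt_cols]
        n = depth[alt_cols]
        pvals = stats.binom.sf(k - 1, n, p_null)
        keep = pvals < alpha
        for row, col, kk, nn in zip(
            alt_rows[keep], alt_cols[keep], k[keep], n[keep]
        ):
            out.append(
                CandidateVariant(
                    pool_id=pool,
                    amplicon=amp,
                    position=int(col) + 1,
                    ref_base=BASES[codes[col]],
                    alt_base=BASES[row],
                    alt_count=int(kk),
                    depth=int(nn),
                )
            )
    return out


def filter_common(
    candidates: Iterable[CandidateVariant], af_max: float = 0.05
) -> list[CandidateVariant]:
    """Keep candidates with allele fraction strictly below ``af_max``.

    Rare induced mutations sit far below common natural variants in
    pooled AF; the default 5% cutoff matches the ``AF < 0.05`` filter
    convention (a candidate at exactly the cutoff is removed).
    Idempotent.
    """
    return [c for c in candidates if c.af < af_max]


def expected_allele_fraction(
    zygosity: Zygosity, pool_size: int, carriers: int = 1
) -> float:
    """Expected pooled allele fraction: ``carriers * c / (2 * pool_size)``.

    ``c`` is 1 for a heterozygous and 2 for a homozygous carrier, so one
    het in a pool of 256 diploids is expected at 0.5/256 = 0.00195 and
    one hom at 1/256 = 0.0039.
    """
    if pool_size < 1:
        raise ValueError(f"pool_size must be >= 1, got {pool_size}")
    if carriers < 0:
        raise ValueError(f"carriers must be >= 0, got {carriers}")
    return carriers * Zygosity(zygosity).allele_copies / (2.0 * pool_size)


def min_coverage_for_reads(k: int, zygosity: Zygosity, pool_size: int) -> int:
    """Minimum pool depth at which k mutant reads are expected.

    The inverse of the expected allele fraction: one heterozygous
    mutant read in a pool of 256 needs depth 512.  Computed with exact
    integer arithmetic (ceiling of ``k * 2 * pool_size / c``).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    c = Zygosity(zygosity).allele_copies
    return math.ceil(k * 2 * pool_size / c)


def scaled_af_max(
    pool_size: int, base_af_max: float = 0.05, base_pool_size: int = 256
) -> float:
    """Common-variant cutoff rescaled to a pool size.

    The reference cutoff (0.05 at P=256) sits 12.8x above the
    homozygous expectation 1/P; keeping that ratio fixed makes the
    filter equally permissive toward true mutants at any pool size.
    """
    return base_af_max * base_pool_size / pool_size


# ---------------------------------------------------------------------------
# VCF interchange (one file per pool)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tillseq
##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction in pool">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth at site">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt read count">
"""


def write_vcf(
    candidates: Sequence[CandidateVariant],
    path: Union[str, Path],
    panel: Optional[AmpliconPanel] = None,
) -> None:
    """Write one pool's candidates as minimal VCF 4.2.

    CHROM is the amplicon name; AF/DP/AC go to INFO.  All candidates
    must come from the same pool (VCFs are per-pool objects here).
    """
    pools = {c.pool_id for c in candidates}
    if len(pools) > 1:
        raise ValueError(
            f"write_vcf expects candidates from a single pool, got pools {sorted(pools)}"
        )
    lines = [_VCF_HEADER.rstrip("\n")]
    if panel is not None:
        for amp in panel:
            lines.append(f"##contig=<ID={amp.name},length={amp.length_bp}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in sorted(candidates):
        lines.append(
            f"{c.amplicon}\t{c.position}\t.\t{c.ref_base}\t{c.alt_base}\t.\t.\t"
            f"AF={c.af:.6g};DP={c.depth};AC={c.alt_count}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: Union[str, Path], pool_id: int) -> list[CandidateVariant]:
    """Read per-pool candidates from a VCF (e.g. an external caller's output).

    Uses AC/DP INFO fields when present; otherwise reconstructs the alt
    count from AF and DP.  Multi-allelic records expand to one candidate
    per alt allele; non-SNV alleles are skipped.
    """
    import pysam

    out: list[CandidateVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.ref is None or len(rec.ref) != 1 or rec.alts is None:
                continue
            depth = rec.info.get("DP")
            afs = rec.info.get("AF")
            acs = rec.info.get("AC")
            for i, alt in enumerate(rec.alts):
                if len(alt) != 1 or alt == rec.ref:
                    continue
                if acs is not None:
                    ac = int(acs[i] if isinstance(acs, tuple) else acs)
                elif afs is not None and depth is not None:
                    af = float(afs[i] if isinstance(afs, tuple) else afs)
                    ac = round(af * int(depth))
                else:
                    continue
                if depth is None:
                    continue
                out.append(
                    CandidateVariant(
                        pool_id=pool_id,
                        amplicon=str(rec.chrom),
                        position=int(rec.pos),
                        ref_base=str(rec.ref),
                        alt_base=str(alt),
                        alt_count=ac,
                        depth=int(depth),
                    )
                )
    return out
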