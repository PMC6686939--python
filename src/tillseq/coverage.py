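"""Coverage QC for pooled amplicon sequencing.

All statistics operate on the mean read coverage per (pool, amplicon)
cell -- the level at which a pooled amplicon assay is judged:

* assay failures: cells below 5% of their amplicon's mean across pools;
* sufficiency: the percentage of cells deep enough that a heterozygous
  mutant allele is expected in at least k reads (k * 2P at pool size P,
  i.e. multiples of 512 at P=256);
* Pearson correlations of per-amplicon mean coverage with amplicon
  length and GC%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .panel import AmpliconPanel
from .simulate import PoolAlleleCounts, Zygosity
from .calling import min_coverage_for_reads

__all__ = [
    "CoverageTable",
    "AmpliconMeans",
    "CorrelationTriple",
    "QCReport",
    "amplicon_means",
    "failure_points",
    "sufficiency_table",
    "coverage_correlations",
    "qc_report",
]


class CoverageTable:
    """Mean coverage per (pool, amplicon), a complete rectangle.

    Wraps a DataFrame with pool IDs as the index and amplicon names as
    columns; every cell must be present and non-negative (0 allowed).
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        if frame.empty:
            raise ValueError("coverage table must be non-empty")
        if frame.isna().any().any():
            raise ValueError("coverage table has missing cells; must be a complete rectangle")
        if (frame.values < 0).any():
            raise ValueError("coverage values must be non-negative")
        self.frame = frame.astype(float)

    @property
    def n_cells(self) -> int:
        return self.frame.size

    @property
    def pool_ids(self) -> list:
        return list(self.frame.index)

    @property
    def amplicon_names(self) -> list[str]:
        return list(self.frame.columns)

    @classmethod
    def from_counts(cls, counts: PoolAlleleCounts) -> "CoverageTable":
        """Mean depth over positions for every (pool, amplicon) cell."""
        data = {
            pool: {
                amp: counts.mean_depth(pool, amp) for amp in counts.amplicon_names
            }
            for pool in counts.pool_ids
        }
        return cls(pd.DataFrame(data).T)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CoverageTable":
        missing = {"pool_id", "amplicon", "coverage"} - set(df.columns)
        if missing:
            raise ValueError(f"long-format table missing columns: {sorted(missing)}")
        wide = df.pivot(index="pool_id", columns="amplicon", values="coverage")
        return cls(wide)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "CoverageTable":
        """Read either dialect: long (pool_id/amplicon/coverage) or wide."""
        df = pd.read_csv(path, sep="\t")
        if {"pool_id", "amplicon", "coverage"} <= set(df.columns):
            return cls.from_long(df)
        return cls(df.set_index(df.columns[0]))

    def to_long(self) -> pd.DataFrame:
        long = self.frame.stack().rename("coverage").reset_index()
        long.columns = ["pool_id", "amplicon", "coverage"]
        return long

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.4f")


@dataclass(frozen=True)
class AmpliconMeans:
    per_amplicon: pd.DataFrame  # index amplicon; columns mean/min/max over pools
    grand_mean: float


def amplicon_means(table: CoverageTable) -> AmpliconMeans:
    """Per-amplicon mean/min/max coverage across pools, plus the grand mean."""
    frame = table.frame
    summary = pd.DataFrame(
        {"mean": frame.mean(axis=0), "min": frame.min(axis=0), "max": frame.max(axis=0)}
    )
    return AmpliconMeans(per_amplicon=summary, grand_mean=float(frame.values.mean()))


def failure_points(
    table: CoverageTable, threshold_frac: float = 0.05
) -> tuple[list[tuple[int, str]], float]:
    """Cells that fell below ``threshold_frac`` of their amplicon's mean.

    The per-amplicon mean includes the candidate cell itself; the
    comparison is strict (<), so a cell exactly at the threshold is not
    a failure.  Returns the failing (pool, amplicon) cells and the
    failure rate as a percentage of all cells.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    frame = table.frame
    thresholds = threshold_frac * frame.mean(axis=0)
    failing = frame.lt(thresholds, axis=1)
    points = [
        (pool, amp)
        for pool in frame.index
        for amp in frame.columns
        if failing.at[pool, amp]
    ]
    rate = 100.0 * len(points) / table.n_cells
    return points, rate


def sufficiency_table(
    table: CoverageTable,
    pool_size: int,
    multiples: Sequence[int] = (1, 2, 4, 8),
    zygosity: Zygosity = Zygosity.HETEROZYGOUS,
) -> dict[int, float]:
    """Percent of cells deep enough for k expected mutant reads.

    The unit depth is ``min_coverage_for_reads(1, zygosity, pool_size)``
    (512 for a het at P=256); a cell at exactly k units counts (>=).
    Because a homozygote needs half the depth of a heterozygote, the
    homozygous value at 2k equals the heterozygous value at k.
    """
    if any(k < 1 for k in multiples):
        raise ValueError("multiples must be positive")
    unit = min_coverage_for_reads(1, zygosity, pool_size)
    values = table.frame.values
    return {
        int(k): float(100.0 * (values >= k * unit).sum() / values.size)
        for k in multiples
    }


@dataclass(frozen=True)
class CorrelationTriple:
    r_size_cov: float
    r_gc_cov: float
    r_size_gc: float


def _pearson(x: np.ndarray, y: np.ndarray, label: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError(f"undefined correlation ({label}): zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def coverage_correlations(
    table: CoverageTable, panel: AmpliconPanel
) -> CorrelationTriple:
    """Pearson r between per-amplicon mean coverage, length and GC%."""
    if len(table.amplicon_names) < 2:
        raise ValueError("need at least two amplicons for correlations")
    unknown = [a for a in table.amplicon_names if a not in panel]
    if unknown:
        raise ValueError(f"amplicons missing from panel: {unknown}")
    mean_cov = table.frame.mean(axis=0)
    sizes = np.array([panel[a].length_bp for a in mean_cov.index], dtype=float)
    gcs = np.array([panel[a].gc_percent for a in mean_cov.index], dtype=float)
    cov = mean_cov.to_numpy()
    return CorrelationTriple(
        r_size_cov=_pearson(sizes, cov, "size vs coverage"),
        r_gc_cov=_pearson(gcs, cov, "GC vs coverage"),
        r_size_gc=_pearson(sizes, gcs, "size vs GC"),
    )


@dataclass(frozen=True)
class QCReport:
    amplicon_summary: pd.DataFrame
    grand_mean: float
    failure_points: list[tuple[int, str]]
    failure_rate: float  # percent of cells
    sufficiency: dict[int, float]  # multiple k -> percent of cells
    correlations: CorrelationTriple
    n_cells: int

    def summary_text(self) -> str:
        lines = [
            f"cells: {self.n_cells}",
            f"grand mean coverage: {self.grand_mean:.1f}",
            f"assay failures: {len(self.failure_points)} ({self.failure_rate:.2f}%)",
        ]
        for k, pct in sorted(self.sufficiency.items()):
            lines.append(f"heterozygous sufficiency {k}x: {pct:.2f}%")
        c = self.correlations
        lines.append(
            f"pearson r: size~coverage {c.r_size_cov:.2f}, "
            f"GC~coverage {c.r_gc_cov:.2f}, size~GC {c.r_size_gc:.2f}"
        )
        return "\n".join(lines)

    def write_tsv(self, path: Union[str, Path]) -> None:
        rows = [("n_cells", self.n_cells), ("grand_mean", self.grand_mean),
                ("failure_rate_percent", self.failure_rate)]
        rows += [(f"sufficiency_{k}x_percent", v) for k, v in sorted(self.sufficiency.items())]
        rows += [
            ("r_size_coverage", self.correlations.r_size_cov),
            ("r_gc_coverage", self.correlations.r_gc_cov),
            ("r_size_gc", self.correlations.r_size_gc),
        ]
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )


def qc_report(
    table: CoverageTable,
    panel: AmpliconPanel,
    pool_size: int,
    multiples: Sequence[int] = (1, 2, 4, 8),
    threshold_frac: float = 0.05,
) -> QCReport:
    """Aggregate the coverage statistics into one report."""
    unknown = [a for a in table.amplicon_names if a not in panel]
    if unknown:
        raise ValueError(
            f"coverage table names not in panel: {unknown}"
        )
    means = amplicon_means(table)
    points, rate = failure_points(table, threshold_frac)
    return QCReport(
        amplicon_summary=means.per_amplicon,
        grand_mean=means.grand_mean,
        failure_points=points,
        failure_rate=rate,
        sufficiency=sufficiency_table(table, pool_size, multiples),
        correlations=coverage_correlations(table, panel),
        n_cells=table.n_cells,
    )
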