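"""Amplicon target panels: loading, validation, and GC statistics.

A TILLING-by-sequencing assay targets a fixed set of PCR amplicons
(here: gene fragments of roughly 0.7--1.5 kb).  This module reads the
panel from a multi-record FASTA, validates it, and computes the
per-amplicon and panel-level GC statistics used downstream for
coverage QC.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Amplicon",
    "AmpliconPanel",
    "GCSummary",
    "PanelError",
    "gc_percent",
    "read_panel",
    "panel_gc_summary",
]

VALID_BASES = frozenset("ACGTN")


class PanelError(ValueError):
    """Raised for malformed amplicon panels (duplicates, empty files, bad bases)."""


def gc_percent(sequence: str) -> float:
    """GC content of a DNA sequence as a percentage in [0, 100].

    ``N`` bases count toward the length but not toward the GC numerator,
    matching the behaviour of common sequence-statistics tools.

    Raises
    ------
    ValueError
        If the sequence is empty or contains characters outside ACGTN.
    """
    if not sequence:
        raise ValueError("cannot compute GC content of an empty sequence")
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid DNA characters {sorted(bad)} in sequence")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


@dataclass(frozen=True)
class Amplicon:
    """A single PCR target: name, optional sequence, length and GC%.

    Metadata-only amplicons (``sequence is None``) are allowed so that
    coverage tables can be analysed against a published length/GC table
    without the underlying sequences.
    """

    name: str
    length_bp: int
    gc_percent: float
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("amplicon name must be non-empty")
        if self.length_bp <= 0:
            raise PanelError(f"amplicon {self.name!r}: length_bp must be positive")
        if not 0.0 <= self.gc_percent <= 100.0:
            raise PanelError(f"amplicon {self.name!r}: gc_percent outside [0, 100]")
        if self.sequence is not None:
            seq = self.sequence.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise PanelError(
                    f"amplicon {self.name!r}: invalid DNA characters {sorted(bad)}"
                )
            object.__setattr__(self, "sequence", seq)
            if len(seq) != self.length_bp:
                raise PanelError(
                    f"amplicon {self.name!r}: length_bp={self.length_bp} but "
                    f"sequence has {len(seq)} bases"
                )
            if not math.isclose(gc_percent(seq), self.gc_percent, abs_tol=0.01):
                raise PanelError(
                    f"amplicon {self.name!r}: stated GC% {self.gc_percent} "
                    f"disagrees with sequence GC% {gc_percent(seq):.4f}"
                )

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "Amplicon":
        seq = sequence.upper()
        return cls(
            name=name,
            length_bp=len(seq),
            gc_percent=gc_percent(seq),
            sequence=seq,
        )


@dataclass(frozen=True)
class AmpliconPanel:
    """Ordered collection of uniquely named amplicons."""

    amplicons: tuple[Amplicon, ...]
    _by_name: dict[str, Amplicon] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.amplicons:
            raise PanelError("panel must contain at least one amplicon")
        by_name: dict[str, Amplicon] = {}
        for amp in self.amplicons:
            if amp.name in by_name:
                raise PanelError(f"duplicate amplicon name {amp.name!r} in panel")
            by_name[amp.name] = amp
        object.__setattr__(self, "_by_name", by_name)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, name: str) -> Amplicon:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.amplicons)

    @property
    def total_bp(self) -> int:
        return sum(a.length_bp for a in self.amplicons)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [a.name for a in self.amplicons],
                "length_bp": [a.length_bp for a in self.amplicons],
                "gc_percent": [a.gc_percent for a in self.amplicons],
            }
        )

    def write_metadata(self, path: Union[str, Path]) -> None:
        self.metadata_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def read_metadata(cls, path: Union[str, Path]) -> "AmpliconPanel":
        """Build a metadata-only panel from a name/length_bp/gc_percent TSV."""
        df = pd.read_csv(path, sep="\t")
        missing = {"name", "length_bp", "gc_percent"} - set(df.columns)
        if missing:
            raise PanelError(f"metadata TSV missing columns: {sorted(missing)}")
        return cls(
            tuple(
                Amplicon(
                    name=str(row["name"]),
                    length_bp=int(row["length_bp"]),
                    gc_percent=float(row["gc_percent"]),
                )
                for _, row in df.iterrows()
            )
        )

    def write_fasta(self, path: Union[str, Path]) -> None:
        records = []
        for amp in self.amplicons:
            if amp.sequence is None:
                raise PanelError(
                    f"amplicon {amp.name!r} has no sequence; cannot write FASTA"
                )
            records.append(SeqRecord(Seq(amp.sequence), id=amp.name, description=""))
        SeqIO.write(records, str(path), "fasta")


def read_panel(fasta_source: Union[str, Path]) -> AmpliconPanel:
    """Read a multi-record FASTA into an :class:`AmpliconPanel`.

    Record order is preserved; sequences are normalised to upper case;
    lengths and GC% are computed from the sequences.

    Raises
    ------
    PanelError
        On duplicate record IDs, an empty file, or non-ACGTN characters
        (the offending record is named).
    """
    amplicons: list[Amplicon] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta_source), "fasta"):
        if record.id in seen:
            raise PanelError(f"duplicate record ID {record.id!r} in {fasta_source}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise PanelError(
                f"record {record.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        if not seq:
            raise PanelError(f"record {record.id!r} has an empty sequence")
        amplicons.append(Amplicon.from_sequence(record.id, seq))
    if not amplicons:
        raise PanelError(f"no FASTA records found in {fasta_source}")
    return AmpliconPanel(tuple(amplicons))


@dataclass(frozen=True)
class GCSummary:
    min: float
    max: float
    mean: float
    sd: float
    median: float


def panel_gc_summary(panel: AmpliconPanel) -> GCSummary:
    """Min/max/mean/sd/median of per-amplicon GC%.

    The standard deviation is the population form
    ``sqrt(sum(x^2)/N - (sum(x)/N)^2)`` (divide by N, not N-1), the
    convention used when summarising a complete target panel rather
    than a sample from it.
    """
    values = [a.gc_percent for a in panel.amplicons]
    n = len(values)
    mean = sum(values) / n
    var = sum(v * v for v in values) / n - mean * mean
    return GCSummary(
        min=min(values),
        max=max(values),
        mean=mean,
        sd=math.sqrt(max(var, 0.0)),
        median=statistics.median(values),
    )
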