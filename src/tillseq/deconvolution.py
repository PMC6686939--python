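"""Resolving pool-level variants to individual carriers.

A true induced mutation is private to one plant, so in a D-dimensional
pooling grid it must surface in exactly one pool of every dimension;
the coordinate tuple of those pools identifies the plant.  The
procedure is:

1. per dimension, keep variant keys seen in exactly one pool of that
   dimension (keys in two or more pools are PCR/sequencing artefacts or
   shared natural variants, and are dropped with a report entry);
2. intersect the D per-dimension unique lists; a key present in all of
   them yields a full call at its coordinate tuple;
3. rescue: a key unique in D-1 dimensions is looked up in a more
   permissive candidate set for the missing dimension -- if it appears
   in exactly one pool there, the call is completed with status
   "rescued"; otherwise it is reported unresolved;
4. the mean observed AF over supporting pools classifies zygosity
   against the expectations 1/(2P) (het) and 1/P (hom).
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import pandas as pd

from .calling import CandidateVariant, expected_allele_fraction
from .pooling import PoolingDesign
from .simulate import Zygosity

__all__ = [
    "VariantKey",
    "ZygosityEstimate",
    "CallStatus",
    "DeconvolvedCall",
    "DeconvolutionReport",
    "DeconvolutionResult",
    "group_by_dimension",
    "unique_in_dimension",
    "intersect_dimensions",
    "rescue",
    "classify_zygosity",
    "deconvolve",
]


class VariantKey(NamedTuple):
    """Identity used to match a variant across pools."""

    amplicon: str
    position: int
    ref_base: Optional[str]
    alt_base: Optional[str]


def _key_of(c: CandidateVariant, match_alleles: bool) -> VariantKey:
    if match_alleles:
        return VariantKey(c.amplicon, c.position, c.ref_base, c.alt_base)
    return VariantKey(c.amplicon, c.position, None, None)


class ZygosityEstimate(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    AMBIGUOUS = "ambiguous"


class CallStatus(str, enum.Enum):
    FULL = "full"
    RESCUED = "rescued"


@dataclass(frozen=True)
class DeconvolvedCall:
    """A variant resolved to a single individual."""

    key: VariantKey
    sample: int
    coords: tuple[int, ...]  # one 0-based pool coordinate per dimension
    pool_ids: tuple[int, ...]  # global pool IDs, one per dimension
    per_dim_af: tuple[float, ...]
    zygosity_estimate: ZygosityEstimate
    status: CallStatus


@dataclass
class DeconvolutionReport:
    """Everything that could not be resolved, surfaced rather than guessed.

    ``dropped_multi_pool``: (dimension, key, pool_ids) for keys seen in
    two or more pools of one dimension.
    ``unresolved``: (key, present_dims, reason) for keys unique in some
    but not all dimensions that rescue could not complete.
    """

    dropped_multi_pool: list[tuple[int, VariantKey, tuple[int, ...]]] = field(
        default_factory=list
    )
    unresolved: list[tuple[VariantKey, tuple[int, ...], str]] = field(
        default_factory=list
    )


@dataclass
class DeconvolutionResult:
    calls: list[DeconvolvedCall]
    report: DeconvolutionReport

    def to_frame(self) -> pd.DataFrame:
        n_dims = len(self.calls[0].coords) if self.calls else 3
        rows = []
        for c in self.calls:
            row = {
                "amplicon": c.key.amplicon,
                "position": c.key.position,
                "ref": c.key.ref_base,
                "alt": c.key.alt_base,
                "sample_index": c.sample,
            }
            for d in range(n_dims):
                row[f"pool_d{d + 1}"] = c.pool_ids[d]
            for d in range(n_dims):
                row[f"af_d{d + 1}"] = c.per_dim_af[d]
            row["zygosity"] = c.zygosity_estimate.value
            row["status"] = c.status.value
            rows.append(row)
        columns = (
            ["amplicon", "position", "ref", "alt", "sample_index"]
            + [f"pool_d{d + 1}" for d in range(n_dims)]
            + [f"af_d{d + 1}" for d in range(n_dims)]
            + ["zygosity", "status"]
        )
        return pd.DataFrame(rows, columns=columns)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def group_by_dimension(
    candidates: Iterable[CandidateVariant], design: PoolingDesign
) -> dict[int, list[CandidateVariant]]:
    """Split candidates by the pooling dimension of their pool."""
    by_dim: dict[int, list[CandidateVariant]] = {
        d: [] for d in range(design.n_dims)
    }
    for c in candidates:
        dim, _ = design.dim_and_coord(c.pool_id)  # raises for unknown pools
        by_dim[dim].append(c)
    return by_dim


def unique_in_dimension(
    by_dim: Mapping[int, Sequence[CandidateVariant]],
    design: PoolingDesign,
    match_alleles: bool = True,
    report: Optional[DeconvolutionReport] = None,
) -> dict[int, dict[VariantKey, tuple[int, int, float]]]:
    """Per dimension, keep keys occurring in exactly one pool.

    Returns ``{dim: {key: (coord, pool_id, af)}}``.  Keys seen in two
    or more pools of a dimension are dropped from that dimension (and
    logged in the report when one is supplied).  Several candidates for
    the same key in the same pool (position-only matching) collapse to
    the highest-AF record.
    """
    out: dict[int, dict[VariantKey, tuple[int, int, float]]] = {}
    for dim in range(design.n_dims):
        pools_of_key: dict[VariantKey, dict[int, float]] = defaultdict(dict)
        for c in by_dim.get(dim, ()):
            key = _key_of(c, match_alleles)
            prev = pools_of_key[key].get(c.pool_id)
            if prev is None or c.af > prev:
                pools_of_key[key][c.pool_id] = c.af
        uniques: dict[VariantKey, tuple[int, int, float]] = {}
        for key, pools in pools_of_key.items():
            if len(pools) == 1:
                ((pool_id, af),) = pools.items()
                _, coord = design.dim_and_coord(pool_id)
                uniques[key] = (coord, pool_id, af)
            elif report is not None:
                report.dropped_multi_pool.append(
                    (dim, key, tuple(sorted(pools)))
                )
        out[dim] = uniques
    return out


def intersect_dimensions(
    uniques: Mapping[int, Mapping[VariantKey, tuple[int, int, float]]],
) -> list[tuple[VariantKey, tuple[int, ...], tuple[int, ...], tuple[float, ...]]]:
    """Keys unique in every dimension, with their coordinate tuples.

    Returns ``(key, coords, pool_ids, per_dim_af)`` records, sorted by
    key so the output is independent of input order.
    """
    dims = sorted(uniques)
    if not dims:
        return []
    shared = set(uniques[dims[0]])
    for d in dims[1:]:
        shared &= set(uniques[d])
    out = []
    for key in sorted(shared):
        coords, pool_ids, afs = zip(*(uniques[d][key] for d in dims))
        out.append((key, coords, pool_ids, afs))
    return out


def rescue(
    uniques: Mapping[int, Mapping[VariantKey, tuple[int, int, float]]],
    raw_by_dim: Mapping[int, Sequence[CandidateVariant]],
    design: PoolingDesign,
    match_alleles: bool = True,
    report: Optional[DeconvolutionReport] = None,
) -> list[tuple[VariantKey, tuple[int, ...], tuple[int, ...], tuple[float, ...]]]:
    """Complete keys unique in all but one dimension from a permissive set.

    For each key unique in exactly ``n_dims - 1`` dimensions, the raw
    candidates of the missing dimension are searched: exactly one pool
    there completes the call (status "rescued"); zero or two-plus pools
    leave the key unresolved, with the reason reported.  Keys missing
    two or more dimensions are reported, never called.
    """
    n_dims = design.n_dims
    membership: dict[VariantKey, set[int]] = defaultdict(set)
    for dim, keys in uniques.items():
        for key in keys:
            membership[key].add(dim)
    out = []
    for key, present in sorted(membership.items()):
        if len(present) == n_dims:
            continue  # full call, handled by intersect_dimensions
        if len(present) < n_dims - 1:
            if report is not None:
                report.unresolved.append(
                    (key, tuple(sorted(present)), "unique in fewer than n_dims-1 dimensions")
                )
            continue
        (missing,) = set(range(n_dims)) - present
        hits: dict[int, float] = {}
        for c in raw_by_dim.get(missing, ()):
            if _key_of(c, match_alleles) == key:
                prev = hits.get(c.pool_id)
                if prev is None or c.af > prev:
                    hits[c.pool_id] = c.af
        if len(hits) == 1:
            ((pool_id, af),) = hits.items()
            _, coord = design.dim_and_coord(pool_id)
            per_dim = {d: uniques[d][key] for d in present}
            per_dim[missing] = (coord, pool_id, af)
            coords, pool_ids, afs = zip(*(per_dim[d] for d in range(n_dims)))
            out.append((key, coords, pool_ids, afs))
        elif report is not None:
            reason = (
                f"absent from dimension {missing + 1} raw candidates"
                if not hits
                else f"ambiguous in dimension {missing + 1}: pools {tuple(sorted(hits))}"
            )
            report.unresolved.append((key, tuple(sorted(present)), reason))
    return out


def classify_zygosity(
    per_dim_af: Sequence[float], pool_size: int
) -> ZygosityEstimate:
    """Assign zygosity from mean observed AF against 1/(2P) and 1/P.

    The mean AF over supporting pools is compared to the heterozygous
    and homozygous expectations on a log scale and assigned the nearer
    (an exact log-midpoint tie goes to heterozygous, the more common
    state).  Means above 4x the homozygous expectation or below 1/4 of
    the heterozygous one are ambiguous.
    """
    if not per_dim_af:
        raise ValueError("need at least one AF observation")
    mean_af = sum(per_dim_af) / len(per_dim_af)
    f_het = expected_allele_fraction(Zygosity.HETEROZYGOUS, pool_size)
    f_hom = expected_allele_fraction(Zygosity.HOMOZYGOUS, pool_size)
    if mean_af > 4.0 * f_hom or mean_af < f_het / 4.0:
        return ZygosityEstimate.AMBIGUOUS
    if abs(log(mean_af) - log(f_het)) <= abs(log(mean_af) - log(f_hom)):
        return ZygosityEstimate.HETEROZYGOUS
    return ZygosityEstimate.HOMOZYGOUS


def deconvolve(
    candidates: Iterable[CandidateVariant],
    design: PoolingDesign,
    raw_candidates: Optional[Iterable[CandidateVariant]] = None,
    match_alleles: bool = True,
) -> DeconvolutionResult:
    """Full pipeline: uniqueness -> intersection -> rescue -> resolution.

    ``candidates`` must already be AF-filtered.  ``raw_candidates`` is
    an optional more permissive set (lower calling thresholds) searched
    only during rescue; without it, partially supported keys are
    reported unresolved.  Deterministic and independent of input order.
    """
    report = DeconvolutionReport()
    by_dim = group_by_dimension(candidates, design)
    uniques = unique_in_dimension(
        by_dim, design, match_alleles=match_alleles, report=report
    )
    full = intersect_dimensions(uniques)
    if raw_candidates is not None:
        raw_by_dim = group_by_dimension(raw_candidates, design)
    else:
        raw_by_dim = by_dim
    rescued = rescue(
        uniques, raw_by_dim, design, match_alleles=match_alleles, report=report
    )
    pool_size = design.samples_per_pool
    calls = []
    for status, records in ((CallStatus.FULL, full), (CallStatus.RESCUED, rescued)):
        for key, coords, pool_ids, afs in records:
            calls.append(
                DeconvolvedCall(
                    key=key,
                    sample=design.sample_at(coords),
                    coords=coords,
                    pool_ids=pool_ids,
                    per_dim_af=afs,
                    zygosity_estimate=classify_zygosity(afs, pool_size),
                    status=status,
                )
            )
    calls.sort(key=lambda c: (c.key, c.sample))
    return DeconvolutionResult(calls=calls, report=report)
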