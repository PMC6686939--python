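"""Synthetic mutant populations and pooled allele counts.

The generator emulates the statistical structure of a chemically
mutagenized diploid population screened by pooled amplicon sequencing:

* each individual carries a Poisson number of induced SNVs (densities of
  one mutation per 150,000--700,000 bp are typical of diploid TILLING
  populations), placed uniformly over the amplicon panel;
* individuals are pooled on a D-dimensional grid, so a heterozygous
  carrier contributes an expected allele fraction of 1/(2P) to each of
  its pools of P diploids, a homozygote 1/P;
* per-(pool, amplicon) sequencing depth is drawn from a heavy-tailed
  log-normal coverage model, constant across the positions of an
  amplicon (fragmented amplicons sequence evenly along their length);
* read counts at every position are binomial in the planted allele
  fraction plus a uniform sequencing-error rate split over the three
  non-reference bases.

The observable produced here -- per pool x amplicon x position base
counts -- is exactly what the calling and deconvolution stages consume.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .panel import Amplicon, AmpliconPanel
from .pooling import PoolingDesign, build_design

__all__ = [
    "Zygosity",
    "Mutation",
    "MutationSet",
    "CoverageModel",
    "PoolAlleleCounts",
    "simulate_population",
    "simulate_pool_counts",
    "synthetic_panel",
    "make_fixture",
    "Fixture",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"

    @property
    def allele_copies(self) -> int:
        """Mutant allele copies in a diploid carrier: 1 het, 2 hom."""
        return 1 if self is Zygosity.HETEROZYGOUS else 2


@dataclass(frozen=True)
class Mutation:
    """One planted induced SNV in one individual (simulator ground truth)."""

    sample: int
    amplicon: str
    position: int  # 1-based within the amplicon
    ref_base: str
    alt_base: str
    zygosity: Zygosity

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")


@dataclass(frozen=True)
class MutationSet:
    mutations: tuple[Mutation, ...]
    density_per_bp: float
    seed: int

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_index": [m.sample for m in self.mutations],
                "amplicon": [m.amplicon for m in self.mutations],
                "position": [m.position for m in self.mutations],
                "ref": [m.ref_base for m in self.mutations],
                "alt": [m.alt_base for m in self.mutations],
                "zygosity": [m.zygosity.value for m in self.mutations],
            }
        )

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, path: Union[str, Path], density_per_bp: float = float("nan"), seed: int = -1
    ) -> "MutationSet":
        df = pd.read_csv(path, sep="\t")
        muts = tuple(
            Mutation(
                sample=int(r.sample_index),
                amplicon=str(r.amplicon),
                position=int(r.position),
                ref_base=str(r.ref),
                alt_base=str(r.alt),
                zygosity=Zygosity(r.zygosity),
            )
            for r in df.itertuples(index=False)
        )
        return cls(mutations=muts, density_per_bp=density_per_bp, seed=seed)


@dataclass(frozen=True)
class CoverageModel:
    """Log-normal read-depth model across (pool, amplicon) cells.

    ``depth = round(S_pool * LogNormal(log_mean, log_sd))`` with
    ``S_pool`` an optional per-pool multiplier, itself log-normal with
    sd ``per_pool_log_sd`` unless explicit ``per_pool_scale`` values are
    given.  Depths are clipped to >= 1.  ``log_mean``/``log_sd`` are the
    mean and sd of the natural log of depth, so ``exp(log_mean)`` is the
    median cell depth.
    """

    log_mean: float
    log_sd: float
    per_pool_log_sd: float = 0.0
    per_pool_scale: Optional[Mapping[int, float]] = None
    seed: int = 0

    def depth_matrix(
        self, pool_ids: Iterable[int], amplicon_names: Iterable[str]
    ) -> pd.DataFrame:
        """Integer depths indexed by pool, one column per amplicon."""
        pool_ids = list(pool_ids)
        amplicon_names = list(amplicon_names)
        rng = np.random.default_rng(self.seed)
        if self.per_pool_scale is not None:
            scale = np.array([self.per_pool_scale[p] for p in pool_ids])
        elif self.per_pool_log_sd > 0:
            scale = rng.lognormal(0.0, self.per_pool_log_sd, size=len(pool_ids))
        else:
            scale = np.ones(len(pool_ids))
        cells = rng.lognormal(
            self.log_mean, self.log_sd, size=(len(pool_ids), len(amplicon_names))
        )
        depths = np.maximum(np.rint(cells * scale[:, None]), 1).astype(np.int64)
        return pd.DataFrame(depths, index=pool_ids, columns=amplicon_names)


class PoolAlleleCounts:
    """Per pool x amplicon x position read counts for A/C/G/T.

    Counts are stored as one ``(4, L)`` integer array per
    ``(pool_id, amplicon)`` cell; depth at a position is the column sum,
    so the conservation invariant (base counts sum to depth) holds by
    construction.  Reference bases are kept per amplicon as integer
    codes into ``"ACGT"``.
    """

    def __init__(
        self,
        counts: dict[tuple[int, str], np.ndarray],
        ref_codes: dict[str, np.ndarray],
    ) -> None:
        for (pool, amp), arr in counts.items():
            if arr.shape != (4, len(ref_codes[amp])):
                raise ValueError(
                    f"count array for pool {pool}, amplicon {amp!r} has shape "
                    f"{arr.shape}; expected (4, {len(ref_codes[amp])})"
                )
            if (arr < 0).any():
                raise ValueError("negative base counts")
        self.counts = counts
        self.ref_codes = ref_codes

    @property
    def pool_ids(self) -> tuple[int, ...]:
        return tuple(sorted({p for p, _ in self.counts}))

    @property
    def amplicon_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, a in self.counts:
            seen.setdefault(a)
        return tuple(seen)

    def depth(self, pool_id: int, amplicon: str) -> np.ndarray:
        return self.counts[(pool_id, amplicon)].sum(axis=0)

    def mean_depth(self, pool_id: int, amplicon: str) -> float:
        return float(self.depth(pool_id, amplicon).mean())

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for (pool, amp), arr in sorted(self.counts.items()):
            length = arr.shape[1]
            ref = np.array(list(BASES))[self.ref_codes[amp]]
            frames.append(
                pd.DataFrame(
                    {
                        "pool_id": pool,
                        "amplicon": amp,
                        "position": np.arange(1, length + 1),
                        "ref": ref,
                        "depth": arr.sum(axis=0),
                        "A": arr[0],
                        "C": arr[1],
                        "G": arr[2],
                        "T": arr[3],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "PoolAlleleCounts":
        df = pd.read_csv(path, sep="\t")
        required = {"pool_id", "amplicon", "position", "ref", "depth", "A", "C", "G", "T"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
        bad = df[df[list(BASES)].sum(axis=1) != df["depth"]]
        if not bad.empty:
            row = bad.iloc[0]
            raise ValueError(
                "base counts do not sum to depth at pool "
                f"{row.pool_id}, {row.amplicon}:{row.position}"
            )
        ref_codes: dict[str, np.ndarray] = {}
        counts: dict[tuple[int, str], np.ndarray] = {}
        for (pool, amp), grp in df.groupby(["pool_id", "amplicon"], sort=False):
            grp = grp.sort_values("position")
            length = int(grp["position"].max())
            if len(grp) != length or (grp["position"].values != np.arange(1, length + 1)).any():
                raise ValueError(
                    f"positions for pool {pool}, amplicon {amp!r} are not contiguous 1..L"
                )
            if amp not in ref_codes:
                ref_codes[amp] = np.array([BASE_INDEX[b] for b in grp["ref"]], dtype=np.int8)
            counts[(int(pool), str(amp))] = grp[list(BASES)].to_numpy().T.astype(np.int64)
        return cls(counts, ref_codes)


def _ref_codes(panel: AmpliconPanel) -> dict[str, np.ndarray]:
    codes = {}
    for amp in panel:
        if amp.sequence is None:
            raise ValueError(f"amplicon {amp.name!r} has no sequence; cannot simulate")
        if "N" in amp.sequence:
            raise ValueError(
                f"amplicon {amp.name!r} contains N bases; simulation requires ACGT"
            )
        codes[amp.name] = np.array(
            [BASE_INDEX[b] for b in amp.sequence], dtype=np.int8
        )
    return codes


_EMS_TRANSITION = {"G": "A", "C": "T"}


def simulate_population(
    panel: AmpliconPanel,
    design: PoolingDesign,
    density_per_bp: float,
    het_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    ems_bias: bool = False,
) -> MutationSet:
    """Plant induced SNVs into a diploid population.

    Per sample, the mutation count is Poisson with mean
    ``density_per_bp * panel.total_bp``; positions are uniform over the
    panel (without replacement within a sample); the alt base is uniform
    over the three non-reference bases, unless ``ems_bias`` is set, in
    which case G/C sites always take the EMS transition (G->A, C->T).
    Zygosity is heterozygous with probability ``het_fraction`` (default
    2/3, the Mendelian het:hom ratio among M2 carriers segregating from
    a heterozygous M1).
    """
    if not 0.0 < density_per_bp < 1.0:
        raise ValueError(f"density_per_bp must be in (0, 1), got {density_per_bp}")
    if not 0.0 <= het_fraction <= 1.0:
        raise ValueError(f"het_fraction must be in [0, 1], got {het_fraction}")
    rng = np.random.default_rng(seed)
    total_bp = panel.total_bp
    # map a flat panel offset -> (amplicon, 1-based position)
    names = panel.names
    lengths = np.array([panel[n].length_bp for n in names])
    starts = np.concatenate([[0], np.cumsum(lengths)])
    ref_codes = _ref_codes(panel)

    n_mut = rng.poisson(density_per_bp * total_bp, size=design.n_samples)
    mutations: list[Mutation] = []
    for sample in np.nonzero(n_mut)[0]:
        k = int(n_mut[sample])
        offsets = rng.choice(total_bp, size=k, replace=False)
        for off in sorted(offsets):
            amp_idx = int(np.searchsorted(starts, off, side="right") - 1)
            amp = names[amp_idx]
            pos = int(off - starts[amp_idx]) + 1
            ref = BASES[ref_codes[amp][pos - 1]]
            if ems_bias and ref in _EMS_TRANSITION:
                alt = _EMS_TRANSITION[ref]
            else:
                choices = [b for b in BASES if b != ref]
                alt = choices[rng.integers(3)]
            zyg = (
                Zygosity.HETEROZYGOUS
                if rng.random() < het_fraction
                else Zygosity.HOMOZYGOUS
            )
            mutations.append(
                Mutation(
                    sample=int(sample),
                    amplicon=amp,
                    position=pos,
                    ref_base=ref,
                    alt_base=alt,
                    zygosity=zyg,
                )
            )
    return MutationSet(
        mutations=tuple(mutations), density_per_bp=density_per_bp, seed=seed
    )


def simulate_pool_counts(
    mutations: MutationSet,
    panel: AmpliconPanel,
    design: PoolingDesign,
    coverage_model: CoverageModel,
    error_rate: float = 0.001,
    seed: int = 0,
) -> PoolAlleleCounts:
    """Realise pooled base counts from planted mutations.

    Each carrier contributes ``c / (2 P)`` to the mutant-allele fraction
    of every pool it belongs to (c = allele copies, P = samples per
    pool).  At every position the count of each non-reference base is
    Binomial(depth, planted fraction + error_rate/3); the reference
    count takes the remainder, so counts always sum to depth.
    """
    if not 0.0 <= error_rate < 0.25:
        raise ValueError(f"error_rate must be in [0, 0.25), got {error_rate}")
    rng = np.random.default_rng(seed)
    ref_codes = _ref_codes(panel)
    depths = coverage_model.depth_matrix(design.pool_ids, panel.names)

    pool_size = design.samples_per_pool
    # planted fractions: (pool, amplicon) -> {(pos0, alt_code): fraction}
    planted: dict[tuple[int, str], dict[tuple[int, int], float]] = {}
    for mut in mutations:
        frac = mut.zygosity.allele_copies / (2.0 * pool_size)
        alt_code = BASE_INDEX[mut.alt_base]
        for pool in design.pool_ids_for_sample(mut.sample):
            cell = planted.setdefault((pool, mut.amplicon), {})
            key = (mut.position - 1, alt_code)
            cell[key] = cell.get(key, 0.0) + frac

    counts: dict[tuple[int, str], np.ndarray] = {}
    for pool in design.pool_ids:
        for amp in panel.names:
            codes = ref_codes[amp]
            length = len(codes)
            depth = int(depths.loc[pool, amp])
            p = np.zeros((4, length))
            if error_rate > 0:
                p[:, :] = error_rate / 3.0
            p[codes, np.arange(length)] = 0.0
            for (pos0, alt_code), frac in planted.get((pool, amp), {}).items():
                p[alt_code, pos0] += frac
            arr = rng.binomial(depth, np.clip(p, 0.0, 1.0))
            alt_sum = arr.sum(axis=0) - arr[codes, np.arange(length)]
            arr[codes, np.arange(length)] = np.maximum(depth - alt_sum, 0)
            counts[(pool, amp)] = arr.astype(np.int64)
    return PoolAlleleCounts(counts, ref_codes)


def synthetic_panel(
    n_amplicons: int,
    length_range: tuple[int, int],
    gc_range: tuple[float, float],
    seed: int = 0,
    name_prefix: str = "AMP",
) -> AmpliconPanel:
    """Random amplicon panel with lengths and GC targets drawn uniformly."""
    rng = np.random.default_rng(seed)
    amplicons = []
    for i in range(n_amplicons):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        gc = rng.uniform(*gc_range)
        # per-base draw: G/C with probability gc, split evenly within group
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
        seq = "".join(rng.choice(list(BASES), size=length, p=probs))
        amplicons.append(
            Amplicon.from_sequence(f"{name_prefix}{i + 1:02d}", seq)
        )
    return AmpliconPanel(tuple(amplicons))


@dataclass(frozen=True)
class Fixture:
    """A complete simulated experiment plus its ground truth."""

    panel: AmpliconPanel
    design: PoolingDesign
    mutations: MutationSet
    counts: PoolAlleleCounts
    truth_path: Optional[Path] = None


# Fixture profiles: the study conditions each one emulates.
# "toy" is a fast miniature (4 amplicons, 4x4x4 grid, depth ~2000);
# "paper_scale" matches the barley experiment's shape (32 amplicons of
# 670-1513 bp, 16x16x16 grid, heavy-tailed pool depths, median ~6365).
_PROFILES = {
    "toy": dict(
        n_amplicons=4,
        length_range=(700, 1400),
        gc_range=(0.35, 0.69),
        n_dims=3,
        pools_per_dim=4,
        log_mean=float(np.log(2000.0)),
        log_sd=0.3,
        per_pool_log_sd=0.3,
        density_per_bp=1e-4,
    ),
    "paper_scale": dict(
        n_amplicons=32,
        length_range=(670, 1513),
        gc_range=(0.35, 0.69),
        n_dims=3,
        pools_per_dim=16,
        log_mean=float(np.log(6365.0)),
        log_sd=0.5,
        per_pool_log_sd=0.7,
        density_per_bp=1.0 / 150_000.0,
    ),
}


def make_fixture(
    profile: str,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
    **overrides,
) -> Fixture:
    """Generate a named simulated experiment.

    Parameters
    ----------
    profile : {"toy", "paper_scale"}
        Which preset conditions to use.
    seed : int
        Master seed; panel, population and read noise derive child seeds
        from it deterministically.
    out_dir : path, optional
        If given, the ground-truth mutation TSV is written there as
        ``truth.tsv``.
    **overrides
        Any profile key (e.g. ``density_per_bp``, ``error_rate``,
        ``het_fraction``) can be overridden.
    """
    if profile not in _PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {sorted(_PROFILES)}"
        )
    params = dict(_PROFILES[profile])
    params.setdefault("error_rate", 0.001)
    params.setdefault("het_fraction", 2.0 / 3.0)
    params.setdefault("ems_bias", False)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown fixture overrides: {sorted(unknown)}")
    params.update(overrides)

    panel_seed, pop_seed, cov_seed, read_seed = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(4)
    )
    panel = synthetic_panel(
        params["n_amplicons"],
        params["length_range"],
        params["gc_range"],
        seed=panel_seed,
    )
    design = build_design(params["n_dims"], params["pools_per_dim"])
    mutations = simulate_population(
        panel,
        design,
        density_per_bp=params["density_per_bp"],
        het_fraction=params["het_fraction"],
        seed=pop_seed,
        ems_bias=params["ems_bias"],
    )
    coverage = CoverageModel(
        log_mean=params["log_mean"],
        log_sd=params["log_sd"],
        per_pool_log_sd=params["per_pool_log_sd"],
        seed=cov_seed,
    )
    counts = simulate_pool_counts(
        mutations,
        panel,
        design,
        coverage,
        error_rate=params["error_rate"],
        seed=read_seed,
    )
    truth_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        truth_path = out_dir / "truth.tsv"
        mutations.write_tsv(truth_path)
    return Fixture(
        panel=panel,
        design=design,
        mutations=mutations,
        counts=counts,
        truth_path=truth_path,
    )
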