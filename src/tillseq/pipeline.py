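"""Stage orchestration: simulate -> call -> deconvolve -> qc.

Each stage reads/writes TSV files in a run directory and appends to a
manifest (config echo + seed + version) sufficient to reproduce the run
exactly.  A single global seed is expanded deterministically into
per-stage child seeds, so stages can be rerun independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calling import (
    call_pool_variants,
    filter_common,
    min_coverage_for_reads,
    scaled_af_max,
)
from .coverage import CoverageTable, qc_report
from .deconvolution import deconvolve
from .panel import AmpliconPanel, read_panel
from .pooling import build_design
from .simulate import (
    CoverageModel,
    MutationSet,
    PoolAlleleCounts,
    Zygosity,
    make_fixture,
    simulate_pool_counts,
    simulate_population,
)

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "stage_simulate",
    "stage_call",
    "stage_deconvolve",
    "stage_qc",
    "run_all",
    "recovery_summary",
]

log = logging.getLogger("tillseq")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Everything a run needs; YAML-serialisable.

    Either ``profile`` (synthetic fixture) or explicit ``panel_fasta`` +
    ``counts_tsv`` inputs must be provided.
    """

    output_dir: str
    seed: int = 0
    # simulation
    profile: Optional[str] = None  # "toy" | "paper_scale"
    density_per_bp: Optional[float] = None
    het_fraction: Optional[float] = None
    error_rate: float = 0.001
    ems_bias: bool = False
    # explicit inputs (alternative to profile)
    panel_fasta: Optional[str] = None
    counts_tsv: Optional[str] = None
    truth_tsv: Optional[str] = None
    n_dims: int = 3
    pools_per_dim: int = 16
    # caller
    min_alt_reads: int = 2
    alpha: float = 1e-4
    rescue_alpha: float = 1e-2
    af_max: Optional[float] = None  # None -> scaled_af_max(pool size)
    match_alleles: bool = True
    # qc
    multiples: Sequence[int] = (1, 2, 4, 8)
    failure_threshold: float = 0.05

    REQUIRED = ("output_dir",)

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in cls.REQUIRED if k not in raw]
        if missing:
            raise ConfigError(f"missing required config field(s): {missing}")
        return cls(**raw)

    def validate(self) -> None:
        if self.profile is None and (self.panel_fasta is None or self.counts_tsv is None):
            raise ConfigError(
                "config needs either 'profile' or both 'panel_fasta' and 'counts_tsv'"
            )
        for key in ("panel_fasta", "counts_tsv", "truth_tsv"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{key} path does not exist: {value}")

    def stage_seed(self, stage_index: int) -> int:
        children = np.random.SeedSequence(self.seed).spawn(8)
        return int(children[stage_index].generate_state(1)[0] % (2**31))

    def design(self):
        # a fixture profile owns its grid shape; explicit n_dims /
        # pools_per_dim apply only to externally supplied counts
        if self.profile is not None:
            from .simulate import _PROFILES

            params = _PROFILES[self.profile]
            return build_design(params["n_dims"], params["pools_per_dim"])
        return build_design(self.n_dims, self.pools_per_dim)

    def effective_af_max(self) -> float:
        if self.af_max is not None:
            return self.af_max
        return scaled_af_max(self.design().samples_per_pool)

    def outdir(self) -> Path:
        out = Path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out

    def write_manifest(self, stage: str) -> None:
        out = self.outdir() / "manifest.json"
        manifest = {}
        if out.exists():
            manifest = json.loads(out.read_text())
        manifest["version"] = __version__
        manifest["seed"] = self.seed
        manifest["config"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        manifest.setdefault("stages", [])
        if stage not in manifest["stages"]:
            manifest["stages"].append(stage)
        out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _fixture_overrides(cfg: RunConfig) -> dict:
    overrides = {}
    if cfg.density_per_bp is not None:
        overrides["density_per_bp"] = cfg.density_per_bp
    if cfg.het_fraction is not None:
        overrides["het_fraction"] = cfg.het_fraction
    overrides["error_rate"] = cfg.error_rate
    overrides["ems_bias"] = cfg.ems_bias
    return overrides


def stage_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Write panel FASTA, truth TSV and counts TSV for a fixture profile."""
    cfg.validate()
    if cfg.profile is None:
        raise StageError("simulate: config has no fixture 'profile'")
    out = cfg.outdir()
    try:
        fixture = make_fixture(
            cfg.profile,
            seed=cfg.stage_seed(0),
            out_dir=out,
            **_fixture_overrides(cfg),
        )
    except ValueError as exc:
        raise StageError(f"simulate: {exc}") from exc
    paths = {
        "panel": out / "panel.fasta",
        "truth": out / "truth.tsv",
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
    }
    fixture.panel.write_fasta(paths["panel"])
    fixture.counts.write_tsv(paths["counts"])
    fixture.design.write_tsv(paths["design"])
    log.info(
        "simulate: %d amplicons, %d pools, %d samples, %d planted mutations",
        len(fixture.panel),
        fixture.design.n_pools,
        fixture.design.n_samples,
        len(fixture.mutations),
    )
    cfg.write_manifest("simulate")
    return paths


def _load_inputs(cfg: RunConfig) -> tuple[AmpliconPanel, PoolAlleleCounts]:
    out = cfg.outdir()
    panel_path = cfg.panel_fasta or out / "panel.fasta"
    counts_path = cfg.counts_tsv or out / "counts.tsv"
    for p, stage in ((panel_path, "panel"), (counts_path, "counts")):
        if not Path(p).exists():
            raise StageError(f"call: missing input file {p} (run simulate first?)")
    panel = read_panel(panel_path)
    counts = PoolAlleleCounts.read_tsv(counts_path)
    design = cfg.design()
    bad_pools = [p for p in counts.pool_ids if not 1 <= p <= design.n_pools]
    if bad_pools:
        raise StageError(
            f"call: counts reference unknown pool id(s) {bad_pools} for a "
            f"{design.n_dims}x{design.pools_per_dim} design"
        )
    return panel, counts


def stage_call(cfg: RunConfig) -> dict[str, Path]:
    """Binomial candidate calling + common-variant AF filter.

    Writes the strict candidate set and a permissive 'raw' set used only
    for rescue during deconvolution.
    """
    cfg.validate()
    panel, counts = _load_inputs(cfg)
    out = cfg.outdir()
    af_max = cfg.effective_af_max()
    strict = call_pool_variants(
        counts, cfg.min_alt_reads, cfg.error_rate, cfg.alpha
    )
    kept = filter_common(strict, af_max)
    raw = filter_common(
        call_pool_variants(counts, cfg.min_alt_reads, cfg.error_rate, cfg.rescue_alpha),
        af_max,
    )
    log.info(
        "call: %d candidates, %d after AF<%.4g filter, %d in rescue set",
        len(strict), len(kept), af_max, len(raw),
    )
    paths = {"candidates": out / "candidates.tsv", "raw_candidates": out / "raw_candidates.tsv"}
    for name, cands in (("candidates", kept), ("raw_candidates", raw)):
        pd.DataFrame(
            [
                {
                    "pool_id": c.pool_id, "amplicon": c.amplicon, "position": c.position,
                    "ref": c.ref_base, "alt": c.alt_base,
                    "alt_count": c.alt_count, "depth": c.depth, "af": c.af,
                }
                for c in cands
            ],
            columns=["pool_id", "amplicon", "position", "ref", "alt", "alt_count", "depth", "af"],
        ).to_csv(paths[name], sep="\t", index=False, float_format="%.6g")
    cfg.write_manifest("call")
    return paths


def _read_candidates(path: Path):
    from .calling import CandidateVariant

    df = pd.read_csv(path, sep="\t")
    return [
        CandidateVariant(
            pool_id=int(r.pool_id), amplicon=str(r.amplicon), position=int(r.position),
            ref_base=str(r.ref), alt_base=str(r.alt),
            alt_count=int(r.alt_count), depth=int(r.depth),
        )
        for r in df.itertuples(index=False)
    ]


def stage_deconvolve(cfg: RunConfig) -> dict[str, Path]:
    """Resolve candidates to individuals; write calls and report TSVs."""
    cfg.validate()
    out = cfg.outdir()
    cand_path = out / "candidates.tsv"
    if not cand_path.exists():
        raise StageError(f"deconvolve: missing {cand_path} (run call first?)")
    candidates = _read_candidates(cand_path)
    raw_path = out / "raw_candidates.tsv"
    raw = _read_candidates(raw_path) if raw_path.exists() else None
    design = cfg.design()
    try:
        result = deconvolve(candidates, design, raw_candidates=raw,
                            match_alleles=cfg.match_alleles)
    except ValueError as exc:
        raise StageError(f"deconvolve: {exc}") from exc
    paths = {"calls": out / "calls.tsv", "report": out / "deconvolution_report.tsv"}
    result.write_tsv(paths["calls"])
    report_rows = [
        {"kind": "dropped_multi_pool", "dimension": dim + 1,
         "amplicon": key.amplicon, "position": key.position,
         "ref": key.ref_base, "alt": key.alt_base,
         "detail": f"pools {list(pools)}"}
        for dim, key, pools in result.report.dropped_multi_pool
    ] + [
        {"kind": "unresolved", "dimension": None,
         "amplicon": key.amplicon, "position": key.position,
         "ref": key.ref_base, "alt": key.alt_base,
         "detail": f"unique in dims {[d + 1 for d in dims]}: {reason}"}
        for key, dims, reason in result.report.unresolved
    ]
    pd.DataFrame(
        report_rows,
        columns=["kind", "dimension", "amplicon", "position", "ref", "alt", "detail"],
    ).to_csv(paths["report"], sep="\t", index=False)
    log.info(
        "deconvolve: %d calls (%d full, %d rescued); %d dropped keys, %d unresolved",
        len(result.calls),
        sum(c.status.value == "full" for c in result.calls),
        sum(c.status.value == "rescued" for c in result.calls),
        len(result.report.dropped_multi_pool),
        len(result.report.unresolved),
    )
    cfg.write_manifest("deconvolve")
    return paths


def stage_qc(cfg: RunConfig) -> dict[str, Path]:
    """Coverage QC report from the counts table."""
    cfg.validate()
    panel, counts = _load_inputs(cfg)
    out = cfg.outdir()
    table = CoverageTable.from_counts(counts)
    design = cfg.design()
    try:
        report = qc_report(
            table, panel, design.samples_per_pool,
            multiples=tuple(cfg.multiples), threshold_frac=cfg.failure_threshold,
        )
    except ValueError as exc:
        raise StageError(f"qc: {exc}") from exc
    paths = {"coverage": out / "coverage.tsv", "qc": out / "qc_report.tsv"}
    table.write_tsv(paths["coverage"])
    report.write_tsv(paths["qc"])
    log.info("qc:\n%s", report.summary_text())
    cfg.write_manifest("qc")
    return paths


_DEPTH_BINS = (0, 512, 2048, 8192)


def _depth_bin(depth: float) -> str:
    lo = max(b for b in _DEPTH_BINS if depth >= b)
    idx = _DEPTH_BINS.index(lo)
    hi = _DEPTH_BINS[idx + 1] if idx + 1 < len(_DEPTH_BINS) else None
    return f"[{lo},{hi})" if hi is not None else f">={lo}"


def recovery_summary(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    counts: PoolAlleleCounts,
    design,
) -> pd.DataFrame:
    """Sensitivity and false calls versus simulator ground truth.

    Rows are (zygosity, depth bin) strata; the depth of a planted
    mutation is the minimum mean coverage over its supporting pools.  A
    call is true when (sample, amplicon, position, alt) matches a
    planted mutation.
    """
    truth_keys = {
        (int(r.sample_index), str(r.amplicon), int(r.position), str(r.alt)): str(r.zygosity)
        for r in truth.itertuples(index=False)
    }
    call_keys = {
        (int(r.sample_index), str(r.amplicon), int(r.position), str(r.alt))
        for r in calls.itertuples(index=False)
    }
    rows = []
    # sensitivity strata over truth
    strata: dict[tuple[str, str], list[bool]] = {}
    for key, zyg in truth_keys.items():
        sample, amp, pos, alt = key
        depths = [
            counts.mean_depth(p, amp)
            for p in design.pool_ids_for_sample(sample)
            if (p, amp) in counts.counts
        ]
        depth = min(depths) if depths else 0.0
        strata.setdefault((zyg, _depth_bin(depth)), []).append(key in call_keys)
    for (zyg, dbin), hits in sorted(strata.items()):
        rows.append(
            {
                "zygosity": zyg, "depth_bin": dbin, "planted": len(hits),
                "recovered": sum(hits),
                "sensitivity_percent": 100.0 * sum(hits) / len(hits),
                "false_calls": 0,
            }
        )
    false = sorted(call_keys - set(truth_keys))
    rows.append(
        {
            "zygosity": "all", "depth_bin": "all",
            "planted": len(truth_keys), "recovered": len(call_keys & set(truth_keys)),
            "sensitivity_percent": (
                100.0 * len(call_keys & set(truth_keys)) / len(truth_keys)
                if truth_keys else 100.0
            ),
            "false_calls": len(false),
        }
    )
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict[str, Path]:
    """Run all stages; returns every output path.

    Produces a recovery summary against the truth file when one exists.
    Stage failures propagate as :class:`StageError` with the stage name.
    """
    cfg.validate()
    out = cfg.outdir()
    paths: dict[str, Path] = {}
    if cfg.profile is not None:
        paths.update(stage_simulate(cfg))
    paths.update(stage_call(cfg))
    paths.update(stage_deconvolve(cfg))
    paths.update(stage_qc(cfg))

    truth_path = Path(cfg.truth_tsv) if cfg.truth_tsv else out / "truth.tsv"
    if truth_path.exists():
        calls = pd.read_csv(paths["calls"], sep="\t")
        truth = pd.read_csv(truth_path, sep="\t")
        _, counts = _load_inputs(cfg)
        summary = recovery_summary(calls, truth, counts, cfg.design())
        paths["recovery"] = out / "recovery_summary.tsv"
        summary.to_csv(paths["recovery"], sep="\t", index=False, float_format="%.4f")
        log.info("recovery:\n%s", summary.to_string(index=False))
    cfg.write_manifest("run-all")
    return paths
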