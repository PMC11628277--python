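"""End-to-end pipeline: pooled effects -> score table -> scored cohort
-> validation report, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from .cohort import DEFAULT_CUTPOINTS, read_cohort_csv, score_cohort
from .meta import pool_all, read_study_effects, write_pooled
from .score import (build_derived_table, canonical_table,
                    published_pooled_effects, verify_against_canonical)
from .simulate import GeneratorConfig, generate
from .validation import (DEFAULT_DCA_RANGE, plot_dca, plot_km, plot_roc,
                         validate_scored)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: Path
    study_effects: Path | None = None   # per-study CSV; packaged pooled RRs otherwise
    cohort: Path | None = None          # patient CSV; synthetic cohort otherwise
    simulate_n: int = 416
    seed: int = 0
    rounding: str = "nearest_integer"
    cutpoints: Sequence[float] = DEFAULT_CUTPOINTS
    dca_range: tuple[float, float] = DEFAULT_DCA_RANGE
    invert_remission_factors: bool = False
    default_p0: float = 0.447
    force_model: str | None = None
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["study_effects"] = str(self.study_effects) if self.study_effects else None
        d["cohort"] = str(self.cohort) if self.cohort else None
        d["cutpoints"] = list(self.cutpoints)
        d["dca_range"] = list(self.dca_range)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write every stage's outputs.

    Returns the manifest (also written to ``manifest.json``): config,
    package version, and SHA-256 checksums of every produced file, so two
    runs with identical config and seed can be compared byte for byte.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    @_stage("meta-pooling")
    def stage_pool():
        if config.study_effects is not None:
            if not Path(config.study_effects).exists():
                raise FileNotFoundError(config.study_effects)
            effects = read_study_effects(config.study_effects)
            pooled = pool_all(effects, default_p0=config.default_p0,
                              force_model=config.force_model)
            write_pooled(pooled, out / "pooled.json")
            written.append(out / "pooled.json")
            return pooled
        logger.info("no study file given; using packaged pooled RRs")
        return published_pooled_effects()

    @_stage("score-table")
    def stage_table(pooled):
        derived = build_derived_table(pooled, rounding=config.rounding)
        canonical = canonical_table(config.invert_remission_factors)
        report = verify_against_canonical(derived, canonical)
        derived.save(out / "derived_table.json")
        with open(out / "table_verification.json", "w", encoding="utf-8") as fh:
            json.dump({
                "passed": report.passed,
                "tol": report.tol,
                "max_discrepancy": report.max_discrepancy,
                "checks": [asdict(c) for c in report.checks],
            }, fh, indent=2, sort_keys=True)
        written.extend([out / "derived_table.json",
                        out / "table_verification.json"])
        return canonical

    @_stage("cohort-scoring")
    def stage_score(table):
        if config.cohort is not None:
            if not Path(config.cohort).exists():
                raise FileNotFoundError(config.cohort)
            patients = read_cohort_csv(config.cohort)
        else:
            patients = generate(
                GeneratorConfig(n=config.simulate_n, seed=config.seed), table)
        scored = score_cohort(patients, table, config.cutpoints)
        scored.to_csv(out / "scored.csv", index=False)
        written.append(out / "scored.csv")
        return scored

    @_stage("validation")
    def stage_validate(scored):
        report = validate_scored(scored, dca_range=config.dca_range)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        written.append(out / "report.json")
        if config.make_plots:
            plot_roc(report.roc, out / "roc.png")
            plot_dca(report.dca_curve, out / "dca.png")
            if report.km is not None:
                plot_km(report.km, out / "km.png")
        return report

    pooled = stage_pool()
    table = stage_table(pooled)
    scored = stage_score(table)
    stage_validate(scored)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
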