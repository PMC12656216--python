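"""End-to-end orchestration: config, cohort I/O, staged analysis, reports.

The pipeline runs the full mixture analysis in order: Spearman
correlation screen, GAM/RCS non-linearity screen (deriving the quadratic
term configuration), then per outcome the two-index WQS with AIC
direction resolution and repeated-holdout estimation.  All artifacts are
written as delimited text plus a JSON provenance record; writes are
atomic (temp file + rename) and the input file is never mutated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import DecileMatrix, decile_matrix, spearman_matrix
from .metals import CANONICAL_METALS
from .screen import ScreenTable, run_screen
from .simulate import EffectTruth, generate_cohort, write_cohort, write_truth
from .study import COVARIATE_COLUMNS, OUTCOME_COLUMNS
from .wqs import AnalysisData, WQSConfig, WQSFit, run_wqs

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "LoadedCohort",
    "ReportBundle",
    "load_config",
    "read_cohort",
    "run_full_analysis",
    "write_bundle",
]


@dataclass(frozen=True)
class ScreenSettings:
    edf_threshold: float = 1.5
    alpha: float = 0.05
    n_knots: int = 4
    bh_adjust: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration with the reference defaults."""

    input_path: str | None = None
    synthetic_n: int | None = None
    outcomes: tuple[str, ...] = OUTCOME_COLUMNS
    covariates: tuple[str, ...] = COVARIATE_COLUMNS
    screen: ScreenSettings = field(default_factory=ScreenSettings)
    wqs: WQSConfig = field(default_factory=WQSConfig)
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("outcome list must be non-empty")


_TOP_KEYS = {
    "input", "outcomes", "covariates", "screen", "wqs", "seed",
    "output_dir", "log_level",
}
_WQS_KEYS = {f.name for f in dataclasses.fields(WQSConfig)}
_SCREEN_KEYS = {f.name for f in dataclasses.fields(ScreenSettings)}


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config, filling defaults.

    Every problem (unknown key, bad range, unknown column) is collected
    and reported in a single aggregated error.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    for k in raw:
        if k not in _TOP_KEYS:
            errors.append(f"unknown top-level key {k!r}")

    input_path, synthetic_n = None, None
    inp = raw.get("input", {}) or {}
    if isinstance(inp, str):
        input_path = inp
    elif isinstance(inp, dict):
        for k in inp:
            if k not in {"path", "synthetic"}:
                errors.append(f"unknown input key {k!r}")
        input_path = inp.get("path")
        syn = inp.get("synthetic")
        if syn is not None:
            synthetic_n = int(syn.get("n", 0)) if isinstance(syn, dict) else int(syn)
    else:
        errors.append("input must be a path or a mapping")

    outcomes = tuple(raw.get("outcomes", OUTCOME_COLUMNS))
    for o in outcomes:
        if o not in OUTCOME_COLUMNS:
            errors.append(f"unknown outcome column {o!r}")
    covariates = tuple(raw.get("covariates", COVARIATE_COLUMNS))
    for c in covariates:
        if c not in COVARIATE_COLUMNS:
            errors.append(f"unknown covariate column {c!r}")

    def build(cls, block: dict, allowed: set, label: str):
        bad = [k for k in block if k not in allowed]
        errors.extend(f"unknown {label} key {k!r}" for k in bad)
        try:
            return cls(**{k: v for k, v in block.items() if k in allowed})
        except (TypeError, ValueError) as exc:
            errors.append(f"invalid {label} settings: {exc}")
            return cls()

    screen = build(ScreenSettings, raw.get("screen", {}) or {}, _SCREEN_KEYS, "screen")
    wqs_block = dict(raw.get("wqs", {}) or {})
    wqs_block.setdefault("seed", int(raw.get("seed", 0)))
    wqs = build(WQSConfig, wqs_block, _WQS_KEYS, "wqs")

    if errors:
        raise ValueError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    return PipelineConfig(
        input_path=input_path,
        synthetic_n=synthetic_n,
        outcomes=outcomes,
        covariates=covariates,
        screen=screen,
        wqs=wqs,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "results")),
        log_level=str(raw.get("log_level", "INFO")),
    )


@dataclass(frozen=True)
class LoadedCohort:
    """A cohort read from the delimited-text contract (no ground truth)."""

    exposures: pd.DataFrame
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    deciles: DecileMatrix
    subject_ids: pd.Series


def read_cohort(path: str | Path) -> LoadedCohort:
    """Read a cohort table, enforcing the documented column contract.

    Metal columns may appear in any order and are reordered canonically.
    Subjects missing any exposure or covariate are dropped complete-case
    (count logged); a missing outcome cell only excludes the subject from
    that outcome's models.
    """
    df = pd.read_csv(path)
    missing = [
        c
        for c in ("subject_id", *CANONICAL_METALS, *COVARIATE_COLUMNS)
        if c not in df.columns
    ]
    if missing:
        raise ValueError(f"cohort file is missing mandatory columns: {missing}")
    outcome_cols = [c for c in OUTCOME_COLUMNS if c in df.columns]
    if not outcome_cols:
        raise ValueError("cohort file has no recognized outcome columns")
    numeric_cols = [*CANONICAL_METALS, *COVARIATE_COLUMNS, *outcome_cols]
    for c in numeric_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            r = int(np.where(bad)[0][0])
            raise ValueError(
                f"non-numeric value {df[c].iloc[r]!r} at row {r + 2}, column {c!r}"
            )
        df[c] = coerced

    modeled = df[[*CANONICAL_METALS, *COVARIATE_COLUMNS]]
    keep = modeled.notna().all(axis=1)
    if (~keep).any():
        log.info("dropping %d subjects with missing exposures/covariates", (~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    exposures = df[list(CANONICAL_METALS)]
    return LoadedCohort(
        exposures=exposures,
        covariates=df[list(COVARIATE_COLUMNS)],
        outcomes=df[outcome_cols],
        deciles=decile_matrix(exposures),
        subject_ids=df["subject_id"],
    )


@dataclass
class ReportBundle:
    """Everything one pipeline run produces."""

    correlation: pd.DataFrame
    screen: ScreenTable
    fits: dict[str, WQSFit]
    failures: dict[str, str]
    provenance: dict


def _outcome_seed(master: int, i: int) -> int:
    return int(np.random.SeedSequence([master, i]).generate_state(1)[0] % 2**31)


def run_full_analysis(cohort, config: PipelineConfig) -> ReportBundle:
    """Execute all stages in order on a loaded or generated cohort.

    Stage failures for individual outcomes are recorded in
    ``failures`` and the bundle is still produced.
    """
    outcomes = [o for o in config.outcomes if o in cohort.outcomes.columns]
    log.info("stage 1/3: Spearman correlation matrix")
    correlation = spearman_matrix(cohort.exposures)
    log.info("stage 2/3: non-linearity screen (%d outcomes)", len(outcomes))
    screen = run_screen(
        cohort,
        outcomes=outcomes,
        edf_threshold=config.screen.edf_threshold,
        alpha=config.screen.alpha,
        n_knots=config.screen.n_knots,
        bh_adjust=config.screen.bh_adjust,
    )
    quadratic = screen.quadratic_config()
    fits: dict[str, WQSFit] = {}
    failures: dict[str, str] = {}
    log.info("stage 3/3: two-index WQS per outcome")
    for i, out_name in enumerate(outcomes):
        y = cohort.outcomes[out_name]
        rows = y.notna().to_numpy()
        data = AnalysisData(
            deciles=DecileMatrix(
                ranks=cohort.deciles.ranks.loc[rows].reset_index(drop=True),
                thresholds=cohort.deciles.thresholds,
            ),
            covariates=cohort.covariates.loc[rows].reset_index(drop=True),
            outcomes=cohort.outcomes.loc[rows].reset_index(drop=True),
        )
        if rows.sum() < len(y):
            log.info("%s: %d subjects excluded (missing outcome)", out_name, len(y) - rows.sum())
        cfg = dataclasses.replace(
            config.wqs,
            quadratic=quadratic,
            seed=_outcome_seed(config.seed, i),
        )
        try:
            fits[out_name] = run_wqs(data, out_name, cfg)
        except (ValueError, RuntimeError) as exc:
            failures[out_name] = str(exc)
            log.error("%s: WQS stage failed: %s", out_name, exc)
    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            "outcomes": list(outcomes),
            "covariates": list(config.covariates),
            "screen": dataclasses.asdict(config.screen),
            "wqs": {
                k: v
                for k, v in dataclasses.asdict(config.wqs).items()
                if k != "quadratic"
            },
        },
        "quadratic_config": {k: list(v) for k, v in quadratic.items()},
        "n_subjects": len(cohort.exposures),
        "holdout_failures": {k: f.n_failed for k, f in fits.items()},
        "failed_outcomes": failures,
    }
    return ReportBundle(
        correlation=correlation,
        screen=screen,
        fits=fits,
        failures=failures,
        provenance=provenance,
    )


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_bundle(bundle: ReportBundle, outdir: str | Path) -> None:
    """Write all bundle artifacts as delimited text + JSON provenance."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _atomic_write(outdir / "correlation.csv", bundle.correlation.to_csv())
    _atomic_write(outdir / "screen.csv", bundle.screen.records.to_csv(index=False))
    for (metal, out_name), rr in bundle.screen.rcs_results.items():
        _atomic_write(outdir / f"rcs_{metal}_{out_name}.csv", rr.curve.to_csv(index=False))
    for out_name, fit in bundle.fits.items():
        _atomic_write(
            outdir / f"wqs_{out_name}.csv",
            fit.terms.rename_axis("term").to_csv(),
        )
        wrows = []
        for idx_name, w in fit.final_weights.items():
            iqr = fit.weights_iqr[idx_name]
            for metal in w.index:
                wrows.append((idx_name, metal, w[metal], iqr[metal]))
        _atomic_write(
            outdir / f"weights_{out_name}.csv",
            pd.DataFrame(
                wrows, columns=["index", "metal", "mean_weight", "holdout_iqr"]
            ).to_csv(index=False),
        )
    _atomic_write(
        outdir / "provenance.json", json.dumps(bundle.provenance, indent=2, default=str)
    )


def generate_input(config: PipelineConfig):
    """Materialize the configured input: read a file or simulate."""
    if config.input_path:
        return read_cohort(config.input_path)
    n = config.synthetic_n or None
    cohort = generate_cohort(n=n, truth=EffectTruth(), seed=config.seed)
    return cohort
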