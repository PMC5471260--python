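"""Staged pipeline: generate -> extract -> select -> associate.

Each stage persists plain CSV/NIfTI/JSON artifacts in the run directory so
any stage is independently testable and replaceable.  A run manifest records
the effective config, seeds and per-stage output digests; two runs with the
same config and seed produce byte-identical reports.  ``resume=True`` skips
a stage when its recorded config/seed digest matches the current one and its
outputs exist (digest-based, not timestamp-based).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as rio
from .association import AssociationScreen
from .features import RadiomicFeatureExtractor
from .filters import FilterBankConfig
from .selection import SpearmanRedundancyFilter
from .synthetic import generate_cohort

__all__ = ["PipelineConfig", "run_generate", "run_extract", "run_select",
           "run_associate", "run_all"]

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "cohort": {"n", "seed", "marginals", "grid_shape", "spacing",
               "base_radius_range_mm"},
    "filters": {"log_sigmas_mm", "wavelet", "subbands", "enabled"},
    "features": {"bin_width_hu", "glcm_distance"},
    "selection": {"rho_threshold"},
    "association": {"alpha"},
}


@dataclass
class PipelineConfig:
    """Serializable configuration of the whole pipeline."""

    cohort: dict = field(default_factory=lambda: {"n": 20, "seed": 0})
    filters: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for block, known in _KNOWN_KEYS.items():
            unknown = set(getattr(self, block)) - known
            if unknown:
                raise ValueError(
                    f"unknown config key(s) in block {block!r}: {sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(_KNOWN_KEYS)
        if unknown:
            raise ValueError(f"unknown config block(s): {sorted(unknown)}")
        return cls(**{k: raw.get(k, {}) for k in _KNOWN_KEYS})

    def filter_bank(self) -> FilterBankConfig | None:
        f = self.filters
        if not f.get("enabled", True):
            return None
        kwargs = {}
        if "log_sigmas_mm" in f:
            kwargs["log_sigmas_mm"] = tuple(f["log_sigmas_mm"])
        if "wavelet" in f:
            kwargs["wavelet_kernel"] = f["wavelet"]
        if "subbands" in f:
            kwargs["subbands"] = tuple(f["subbands"])
        return FilterBankConfig(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, run_dir: Path, config: PipelineConfig):
        self.path = run_dir / "manifest.json"
        self.config = config
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config_digest": config.digest(), "stages": {}}
        if self.data.get("config_digest") != config.digest():
            logger.info("config changed; previous stage records invalidated")
            self.data = {"config_digest": config.digest(), "stages": {}}

    def stage_current(self, stage: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None or not all(Path(p).exists() for p in rec["outputs"]):
            return False
        return all(
            _file_digest(Path(p)) == d for p, d in zip(rec["outputs"], rec["digests"])
        )

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.data["stages"][stage] = {
            "outputs": [str(p) for p in outputs],
            "digests": [_file_digest(p) for p in outputs],
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def _prepare(run_dir: str | Path, config: PipelineConfig) -> tuple[Path, _Manifest]:
    run = Path(run_dir)
    run.mkdir(parents=True, exist_ok=True)
    with open(run / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh)
    return run, _Manifest(run, config)


def run_generate(config: PipelineConfig, run_dir: str | Path,
                 resume: bool = False) -> Path:
    """Stage 1: write the synthetic cohort into ``run_dir/cohort``."""
    run, manifest = _prepare(run_dir, config)
    cohort_dir = run / "cohort"
    marker = [cohort_dir / "semantic_scores.csv", cohort_dir / "ground_truth.json"]
    if resume and manifest.stage_current("generate", marker):
        logger.info("generate: up to date, skipped")
        return cohort_dir
    c = config.cohort
    generate_cohort(
        n=int(c.get("n", 20)),
        out_dir=cohort_dir,
        seed=int(c.get("seed", 0)),
        marginals=c.get("marginals"),
        grid_shape=tuple(c.get("grid_shape", (64, 64, 64))),
        spacing=tuple(c.get("spacing", (1.0, 1.0, 1.0))),
        base_radius_range_mm=tuple(c.get("base_radius_range_mm", (8.0, 11.0))),
    )
    manifest.record("generate", marker)
    return cohort_dir


def run_extract(config: PipelineConfig, run_dir: str | Path,
                cohort_dir: str | Path | None = None,
                resume: bool = False) -> Path:
    """Stage 2: extract the configured feature inventory for every subject."""
    run, manifest = _prepare(run_dir, config)
    cohort_dir = Path(cohort_dir or run / "cohort")
    out_csv = run / "features.csv"
    if resume and manifest.stage_current("extract", [out_csv]):
        logger.info("extract: up to date, skipped")
        return out_csv
    scores = rio.read_semantic_scores(cohort_dir / "semantic_scores.csv")
    extractor = RadiomicFeatureExtractor(
        filter_config=config.filter_bank(),
        bin_width_hu=float(config.features.get("bin_width_hu", 25.0)),
        glcm_distance=int(config.features.get("glcm_distance", 1)),
    ).fit()
    rows = []
    for sid in scores.subject_ids:
        vpath = cohort_dir / f"{sid}_volume.nii.gz"
        mpath = cohort_dir / f"{sid}_mask.nii.gz"
        if not vpath.exists() or not mpath.exists():
            raise FileNotFoundError(f"missing volume/mask for subject {sid}")
        volume = rio.read_volume(vpath)
        mask = rio.read_mask(mpath, volume)
        logger.info("extract: subject %s", sid)
        rows.append((volume, mask))
    table = extractor.transform(rows)
    table.index = scores.subject_ids
    rio.write_feature_table(table, out_csv)
    manifest.record("extract", [out_csv])
    return out_csv


def run_select(config: PipelineConfig, run_dir: str | Path,
               features_csv: str | Path | None = None,
               resume: bool = False) -> Path:
    """Stage 3: Spearman-redundancy pruning; writes pruned table + report."""
    run, manifest = _prepare(run_dir, config)
    features_csv = Path(features_csv or run / "features.csv")
    pruned_csv = run / "features_pruned.csv"
    report_csv = run / "selection_report.csv"
    report_json = run / "selection_report.json"
    outputs = [pruned_csv, report_csv, report_json]
    if resume and manifest.stage_current("select", outputs):
        logger.info("select: up to date, skipped")
        return pruned_csv
    table = rio.read_feature_table(features_csv)
    sel = SpearmanRedundancyFilter(
        threshold=float(config.selection.get("rho_threshold", 0.85))
    ).fit(table)
    pruned = sel.transform(table)
    rio.write_feature_table(pruned, pruned_csv)
    sel.report_.to_frame().to_csv(report_csv, index=False)
    report_json.write_text(json.dumps({
        "threshold": sel.report_.threshold,
        "n_input": len(sel.feature_names_in_),
        "kept": sel.report_.kept,
        "dropped": [d.name for d in sel.report_.dropped],
    }, indent=1))
    manifest.record("select", outputs)
    return pruned_csv


def run_associate(config: PipelineConfig, run_dir: str | Path,
                  pruned_csv: str | Path | None = None,
                  semantic_csv: str | Path | None = None,
                  resume: bool = False) -> Path:
    """Stage 4: association screening; writes the long-format report and the
    per-semantic summary (significant counts + estimate ranges)."""
    run, manifest = _prepare(run_dir, config)
    pruned_csv = Path(pruned_csv or run / "features_pruned.csv")
    semantic_csv = Path(semantic_csv or run / "cohort" / "semantic_scores.csv")
    report_csv = run / "associations.csv"
    summary_csv = run / "association_summary.csv"
    outputs = [report_csv, summary_csv]
    if resume and manifest.stage_current("associate", outputs):
        logger.info("associate: up to date, skipped")
        return report_csv
    features = rio.read_feature_table(pruned_csv)
    cohort = rio.read_semantic_scores(semantic_csv)
    screen = AssociationScreen(
        alpha=float(config.association.get("alpha", 0.05))
    ).fit(features, cohort)
    screen.report_.to_long_frame().to_csv(report_csv, index=False)
    screen.summary().to_csv(summary_csv, index=False)
    manifest.record("associate", outputs)
    return report_csv


def run_all(config: PipelineConfig, run_dir: str | Path,
            resume: bool = False) -> Path:
    """All four stages chained; returns the association report path."""
    stages = [("generate", run_generate), ("extract", run_extract),
              ("select", run_select), ("associate", run_associate)]
    result = None
    for name, fn in stages:
        try:
            result = fn(config, run_dir, resume=resume)
        except Exception as exc:
            raise RuntimeError(f"pipeline halted at stage {name!r}: {exc}") from exc
    return result
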