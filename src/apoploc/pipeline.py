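"""End-to-end runs and parameter sweeps.

A run reads (or simulates) a labeled dataset, builds the fused
PseAAC + PsePSSM matrix, optionally wavelet-denoises it, evaluates a
classifier under the requested protocol and writes every artifact —
feature tables, report JSON/TSV, ROC points and a manifest recording all
parameters and thresholds — into an output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .classify import make_classifier
from .denoise import WaveletSpec, denoise_matrix, denoise_rows_1d
from .evaluate import EvalReport, jackknife, self_consistency
from .fusion import FeatureMatrix, build_matrix, write_feature_table
from .io import LabeledDataset, load_dataset

logger = logging.getLogger("apoploc")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    fasta: str | None = None
    labels: str | None = None
    pssm_dir: str | None = None
    lam: int = 15
    omega: float = 0.05
    xi: int = 10
    wavelet: str = "db8"
    level: int = 4
    threshold_rule: str = "default_global"
    threshold_mode: str = "soft"
    denoise: str = "2d"  # 2d | 1d | none
    classifier: str = "svm"
    kernel: str = "linear"
    C: float = 1.0
    protocol: str = "jackknife"  # jackknife | self_consistency
    denoise_mode: str = "paper_faithful"  # paper_faithful | leak_free
    seed: int = 0
    outdir: str = "apoploc_run"
    extra: dict = field(default_factory=dict)

    def wavelet_spec(self) -> WaveletSpec:
        return WaveletSpec(
            family=self.wavelet, level=self.level,
            threshold_rule=self.threshold_rule,
            threshold_mode=self.threshold_mode,
        )


def _validate(cfg: RunConfig, data: LabeledDataset) -> None:
    min_len = data.min_length()
    if cfg.lam >= min_len or cfg.xi >= min_len:
        raise ValueError(
            f"lambda={cfg.lam} / xi={cfg.xi} inadmissible: shortest sequence "
            f"has length {min_len}"
        )


def run_pipeline(cfg: RunConfig, data: LabeledDataset | None = None) -> EvalReport:
    """Execute read -> features -> denoise -> evaluate and write artifacts."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if data is None:
        if cfg.fasta is None:
            raise ValueError("no dataset: provide cfg.fasta or pass data directly")
        data = load_dataset(cfg.fasta, cfg.labels, cfg.pssm_dir)
    _validate(cfg, data)
    logger.info("dataset: %d records, %d classes", len(data), len(data.class_names))

    matrix = build_matrix(data, lam=cfg.lam, omega=cfg.omega, xi=cfg.xi,
                          seed=cfg.seed)
    write_feature_table(matrix, outdir / "features.tsv")
    logger.info("features: %d x %d", matrix.n, matrix.d)

    spec = cfg.wavelet_spec()
    if cfg.denoise == "2d" and cfg.denoise_mode == "paper_faithful":
        matrix = denoise_matrix(matrix, spec)
        write_feature_table(matrix, outdir / "features_denoised.tsv")
    elif cfg.denoise == "1d":
        matrix = denoise_rows_1d(matrix, spec)
        write_feature_table(matrix, outdir / "features_denoised.tsv")

    model = make_classifier(kind=cfg.classifier, kernel=cfg.kernel, C=cfg.C,
                            seed=cfg.seed) if cfg.classifier == "svm" else \
        make_classifier(kind=cfg.classifier, seed=cfg.seed)

    if cfg.protocol == "self_consistency":
        report = self_consistency(matrix, model)
    elif cfg.protocol == "jackknife":
        mode = ("leak_free" if cfg.denoise == "2d"
                and cfg.denoise_mode == "leak_free" else "none")
        report = jackknife(matrix, model, denoise_mode=mode, wavelet_spec=spec)
    else:
        raise ValueError(f"unknown protocol {cfg.protocol!r}")

    _write_report(report, cfg, outdir, elapsed=time.time() - t0)
    return report


def _write_report(report: EvalReport, cfg: RunConfig, outdir: Path,
                  elapsed: float) -> None:
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    with open(outdir / "report.tsv", "w", encoding="utf-8") as fh:
        fh.write("class\tsens\tspec\tmcc\n")
        for name, m in report.per_class.items():
            fh.write(f"{name}\t{m['sens']:.4f}\t{m['spec']:.4f}\t{m['mcc']:.4f}\n")
        fh.write(f"OA\t{report.oa:.4f}\t\t\n")
    with open(outdir / "roc.tsv", "w", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in report.roc_points:
            fh.write(f"{fpr:.4f}\t{tpr:.6f}\n")
    manifest = {"config": asdict(cfg), "matrix_params": report.params,
                "elapsed_s": round(elapsed, 3)}
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("report written to %s (OA %.4f)", outdir, report.oa)


def sweep(cfg: RunConfig, data: LabeledDataset, grid: dict[str, list]) -> list[dict]:
    """Run the pipeline over a parameter grid (full Cartesian product).

    Returns one result row per grid point; points violating sequence-length
    bounds are marked skipped rather than fatal.
    """
    from itertools import product

    keys = list(grid)
    rows: list[dict] = []
    for combo in product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        sub = RunConfig(**{**asdict(cfg), **point})
        sub.outdir = str(Path(cfg.outdir) / "_".join(
            f"{k}-{v}" for k, v in point.items()
        ))
        row = dict(point)
        try:
            report = run_pipeline(sub, data=data)
        except ValueError as exc:
            row.update(status="skipped", reason=str(exc))
            rows.append(row)
            continue
        row.update(
            status="ok", oa=report.oa, macro_mcc=report.macro_mcc, auc=report.auc,
            **{f"sens_{name}": m["sens"] for name, m in report.per_class.items()},
        )
        rows.append(row)
    return rows
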