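"""Batch orchestration: manifest in, metric/statistics report bundle out.

``run_study`` mirrors the shape of a paired reconstruction-comparison
analysis: for every subject/sequence row it computes reference metrics
(DLR vs CR), no-reference metrics per member, and the three edge-sharpness
features per detector per member; it then aggregates per-sequence
mean +/- SD summaries, paired tests, and cross-detector agreement tables.
All outputs are plain CSV; a JSON run log materializes every parameter so
a run is exactly reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as iqm
from .edges import DETECTORS
from .features import summarize_edge_features
from .image import GrayImage, load_image, normalize_intensity
from .stats import detector_agreement_report, paired_t, wilcoxon_signed_rank

log = logging.getLogger("orbitsharp")

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "run_study_on_pairs",
    "parse_min_sec",
    "time_saving_percent",
]

FEATURES = ("steepness", "width", "contrast")


@dataclass
class StudyConfig:
    detectors: tuple[str, ...] = DETECTORS
    reference_metrics: tuple[str, ...] = ("ssim", "ms_ssim", "snr", "psnr", "blur_percentage")
    noref_metrics: tuple[str, ...] = ("psi", "perceptual_blur")
    steepness_window: int = 3
    contrast_window: int = 7
    half_length: float = 5.0
    spacing: float = 0.25
    contrast_floor: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}


@dataclass
class StudyReport:
    per_pair: pd.DataFrame
    summary: pd.DataFrame
    paired_tests: pd.DataFrame
    detector_agreement: pd.DataFrame
    run_log: dict
    n_skipped: int = 0

    @property
    def exit_code(self) -> int:
        return 2 if self.n_skipped else 0

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kwargs = dict(index=False, float_format="%.10g", na_rep="nan")
        self.per_pair.to_csv(out / "per_pair.csv", **kwargs)
        self.summary.to_csv(out / "summary.csv", **kwargs)
        self.paired_tests.to_csv(out / "paired_tests.csv", **kwargs)
        self.detector_agreement.to_csv(out / "detector_agreement.csv", **kwargs)
        (out / "run_log.json").write_text(json.dumps(self.run_log, indent=2, default=str))


def _pair_metrics(
    sid: str, seq: str, cr: GrayImage, dlr: GrayImage, config: StudyConfig
) -> tuple[list[dict], dict]:
    """Long-format metric rows for one pair, plus per-detector features."""
    rows: list[dict] = []

    def add(metric, recon, value, detector=""):
        rows.append(
            {
                "subject_id": sid,
                "sequence": seq,
                "metric": metric,
                "detector": detector,
                "recon": recon,
                "value": value,
            }
        )

    for name in config.reference_metrics:
        fn, is_ref = iqm.get_metric(name)
        if not is_ref:
            raise ValueError(f"{name} is not a reference metric")
        add(name, "DLR_vs_CR", fn(cr, dlr))
    for name in config.noref_metrics:
        fn, is_ref = iqm.get_metric(name)
        if is_ref:
            raise ValueError(f"{name} is not a no-reference metric")
        for recon, img in (("CR", cr), ("DLR", dlr)):
            add(name, recon, fn(img))

    feats: dict[str, dict[str, object]] = {"CR": {}, "DLR": {}}
    for det in config.detectors:
        for recon, img in (("CR", cr), ("DLR", dlr)):
            res = summarize_edge_features(
                img,
                det,
                steepness_window=config.steepness_window,
                contrast_window=config.contrast_window,
                half_length=config.half_length,
                spacing=config.spacing,
                contrast_floor=config.contrast_floor,
            )
            feats[recon][det] = res
            add("steepness", recon, res.mean_steepness, det)
            add("width", recon, res.mean_width_px, det)
            add("contrast", recon, res.mean_contrast, det)
    return rows, feats


def run_study_on_pairs(pairs, config: StudyConfig | None = None) -> StudyReport:
    """Run the full analysis on in-memory (subject_id, sequence, cr, dlr)
    tuples or :class:`orbitsharp.phantom.PhantomPair` objects."""
    config = config or StudyConfig()
    all_rows: list[dict] = []
    feature_results: dict[str, dict[str, list]] = {}
    for item in pairs:
        if hasattr(item, "subject_id") and hasattr(item, "cr"):
            sid, seq, cr, dlr = item.subject_id, "phantom", item.cr, item.dlr
        else:
            sid, seq, cr, dlr = item
        rows, feats = _pair_metrics(sid, seq, cr, dlr, config)
        all_rows.extend(rows)
        for recon in ("CR", "DLR"):
            key = f"{seq}:{recon}"
            feature_results.setdefault(key, {})[sid] = list(feats[recon].values())
    return _assemble(all_rows, feature_results, config, n_skipped=0, manifest=None)


def run_study(manifest: pd.DataFrame, config: StudyConfig | None = None) -> StudyReport:
    """Run the analysis from a manifest with columns
    subject_id, sequence, cr_path, dlr_path (plus optional plane).

    Unreadable images skip the row (logged) and the run continues; the
    report's ``exit_code`` is 2 when any row was skipped.
    """
    config = config or StudyConfig()
    required = {"subject_id", "sequence", "cr_path", "dlr_path"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    dup = manifest.duplicated(subset=["subject_id", "sequence"])
    if dup.any():
        raise ValueError("duplicate (subject_id, sequence) rows in manifest")
    all_rows: list[dict] = []
    feature_results: dict[str, dict[str, list]] = {}
    n_skipped = 0
    for _, row in manifest.iterrows():
        sid, seq = str(row.subject_id), str(row.sequence)
        try:
            cr = normalize_intensity(load_image(row.cr_path))
            dlr = normalize_intensity(load_image(row.dlr_path))
        except (OSError, ValueError) as exc:
            log.warning("skipping %s/%s: %s", sid, seq, exc)
            n_skipped += 1
            continue
        rows, feats = _pair_metrics(sid, seq, cr, dlr, config)
        all_rows.extend(rows)
        for recon in ("CR", "DLR"):
            key = f"{seq}:{recon}"
            feature_results.setdefault(key, {})[sid] = list(feats[recon].values())
    return _assemble(all_rows, feature_results, config, n_skipped, manifest)


def _assemble(all_rows, feature_results, config, n_skipped, manifest) -> StudyReport:
    per_pair = pd.DataFrame(all_rows)
    if per_pair.empty:
        raise ValueError("no pairs could be processed")

    summary = (
        per_pair.groupby(["sequence", "metric", "detector", "recon"], dropna=False)["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )

    tests = []
    paired = per_pair[per_pair.recon.isin(["CR", "DLR"])]
    for (seq, metric, det), grp in paired.groupby(["sequence", "metric", "detector"]):
        wide = grp.pivot(index="subject_id", columns="recon", values="value").dropna()
        if len(wide) < 3 or {"CR", "DLR"} - set(wide.columns):
            continue
        pairs = list(zip(wide["CR"], wide["DLR"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_stat, t_p = paired_t(pairs)
            w_stat, w_p = wilcoxon_signed_rank(pairs)
        tests.append(
            {
                "sequence": seq,
                "metric": metric,
                "detector": det,
                "n": len(wide),
                "mean_cr": wide["CR"].mean(),
                "mean_dlr": wide["DLR"].mean(),
                "t": t_stat,
                "t_p": t_p,
                "wilcoxon_w": w_stat,
                "wilcoxon_p": w_p,
            }
        )
    paired_tests = pd.DataFrame(tests)

    agree_rows = []
    for key, subj_map in feature_results.items():
        seq, recon = key.split(":")
        if len(subj_map) < 3:
            warnings.warn(f"group {key}: fewer than 3 subjects, agreement skipped")
            continue
        rep = detector_agreement_report(subj_map)
        rep.insert(0, "recon", recon)
        rep.insert(0, "sequence", seq)
        agree_rows.append(rep)
    detector_agreement = (
        pd.concat(agree_rows, ignore_index=True) if agree_rows else pd.DataFrame()
    )

    run_log = {
        "config": config.to_dict(),
        "n_pairs": int(per_pair.subject_id.nunique()),
        "n_skipped": n_skipped,
        "manifest_rows": None if manifest is None else len(manifest),
    }
    report = StudyReport(per_pair, summary, paired_tests, detector_agreement, run_log, n_skipped)
    if config.out_dir:
        report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# protocol arithmetic helpers (scan-time bookkeeping for acquisition tables)


def parse_min_sec(text: str) -> int:
    """Parse a 'm:ss' scan duration into seconds."""
    m, s = text.strip().split(":")
    return int(m) * 60 + int(s)


def time_saving_percent(cr_times: list[str] | str, dlr_times: list[str] | str) -> float:
    """Acquisition-time saving of accelerated vs conventional scans, percent.

    Accepts single 'm:ss' strings or lists (summed before the ratio).
    """
    if isinstance(cr_times, str):
        cr_times = [cr_times]
    if isinstance(dlr_times, str):
        dlr_times = [dlr_times]
    cr = sum(parse_min_sec(t) for t in cr_times)
    dlr = sum(parse_min_sec(t) for t in dlr_times)
    if cr <= 0:
        raise ValueError("conventional scan time must be positive")
    return 100.0 * (cr - dlr) / cr
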