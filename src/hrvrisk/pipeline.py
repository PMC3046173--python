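"""End-to-end orchestration: preprocess -> clean -> extract -> select ->
normalize -> classify, plus the breathing-rate validity check.

The pipeline is driven by a plain config mapping (typically loaded from
YAML by the CLI).  Keys::

    input:
      synthetic: {n_per_class: 45, risk_scaling: 0.5, ...}   # or
      rr_dir: path        # one-interval-per-line files
      labels: path        # CSV with id,class rows (class in {N, R})
      ecg_dir: path       # delimited ECG files (requires fs)
      fs: 250
    clean:   {alpha: 0.05, k_max: null}
    features: {fs_interp: 4.0, lam: 500.0, ar_order: 16, k: 0.2, m_max: 4}
    select:  {alpha: 0.01, top_k: 5}
    classify: {scheme: mlp, repeats: 1}
    seed: 1
    outdir: results/

Artifacts written: ``features.csv``, ``selection.json``,
``classifier.json``.  A record whose respiration channel fails the
12-breaths/min constancy check is flagged advisory, never dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import classifiers as clf
from .errors import ConfigurationError, HRVError, LabelingError
from .io import (
    FeatureVector,
    RRSeries,
    features_to_frame,
    order_features,
    read_ecg,
    read_rr,
)
from .nonlinear import complexity_features, poincare_features
from .preprocessing import detect_r_peaks, rosner_filter, rr_from_peaks
from .selection import select_features
from .spectral import spectral_features
from .synthetic import CohortSpec, generate_cohort
from .time_domain import time_domain_features
from .wavelet import wp_features

__all__ = ["run_pipeline", "breathing_check", "extract_features", "BreathingReport"]

log = logging.getLogger("hrvrisk")

EXPECTED_BREATH_RATE = 12.0  # breaths/min
BREATH_RATE_TOL = 3.0
BREATH_SD_TOL = 2.0


@dataclass
class BreathingReport:
    rate: float
    valid: bool
    status: str  # "checked" | "unchecked"


def breathing_check(
    respiration: np.ndarray | None,
    fs: float,
    expected: float = EXPECTED_BREATH_RATE,
    tol: float = BREATH_RATE_TOL,
) -> BreathingReport:
    """Estimate the breathing rate and flag departures from ~12 breaths/min.

    The rate is the dominant spectral frequency of the respiration
    channel in [0.05, 0.7] Hz times 60.  Validity additionally requires
    the rate to be steady: the standard deviation of per-60-s-window
    rates must stay within 2 breaths/min.
    """
    if respiration is None:
        return BreathingReport(rate=float("nan"), valid=False, status="unchecked")
    resp = np.asarray(respiration, dtype=float)
    if resp.size < 60 * fs:
        raise ConfigurationError("need >= 60 s of respiration signal")

    def dominant_rate(x: np.ndarray) -> float:
        freqs, power = sps.periodogram(x - x.mean(), fs=fs)
        band = (freqs >= 0.05) & (freqs <= 0.7)
        return 60.0 * float(freqs[band][np.argmax(power[band])])

    rate = dominant_rate(resp)
    win = int(60 * fs)
    window_rates = [
        dominant_rate(resp[s : s + win])
        for s in range(0, resp.size - win + 1, win // 2)
    ]
    steady = float(np.std(window_rates)) <= BREATH_SD_TOL if window_rates else True
    valid = abs(rate - expected) <= tol and steady
    return BreathingReport(rate=rate, valid=valid, status="checked")


def extract_features(
    rr: RRSeries,
    fs_interp: float = 4.0,
    lam: float = 500.0,
    ar_order: int = 16,
    wavelet: str = "db4",
    wp_level: int = 5,
    k: float = 0.2,
    m_max: int = 4,
    bin_ms: float = 7.8125,
) -> dict[str, float]:
    """All four feature families for one cleaned NN series."""
    out: dict[str, float] = {}
    out.update(time_domain_features(rr).as_dict())
    out.update(spectral_features(rr, fs_i=fs_interp, lam=lam, order=ar_order).as_dict())
    out.update(wp_features(rr, wavelet=wavelet, level=wp_level).as_dict())
    out.update(poincare_features(rr, bin_ms=bin_ms).as_dict())
    out.update(complexity_features(rr, k=k, m_max=m_max))
    return out


def _load_cohort(cfg: dict, seed: int) -> tuple[list[RRSeries], list[str], list[BreathingReport]]:
    inp = cfg.get("input", {})
    breathing: list[BreathingReport] = []
    if "synthetic" in inp:
        spec = CohortSpec(seed=seed, **inp["synthetic"])
        records, labels = generate_cohort(spec)
        return records, labels, breathing
    if "rr_dir" in inp:
        label_map = _read_labels(inp["labels"])
        records, labels = [], []
        for path in sorted(Path(inp["rr_dir"]).glob("*.txt")):
            rr = read_rr(path)
            if rr.id not in label_map:
                raise LabelingError(f"no label for record {rr.id!r}")
            records.append(rr)
            labels.append(label_map[rr.id])
        return records, labels, breathing
    if "ecg_dir" in inp:
        fs = inp.get("fs")
        if not fs:
            raise ConfigurationError("ecg_dir input requires 'fs'")
        label_map = _read_labels(inp["labels"])
        level = cfg.get("detect", {}).get("level", 4)
        records, labels = [], []
        for path in sorted(Path(inp["ecg_dir"]).glob("*")):
            ecg = read_ecg(path, fs=fs)
            breathing.append(breathing_check(ecg.respiration, fs))
            peaks = detect_r_peaks(ecg, level=level)
            records.append(rr_from_peaks(peaks, id=ecg.id))
            labels.append(label_map[ecg.id])
        return records, labels, breathing
    raise ConfigurationError("config['input'] must define synthetic, rr_dir or ecg_dir")


def _read_labels(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, dtype=str)
    id_col, cls_col = table.columns[:2]
    return dict(zip(table[id_col], table[cls_col]))


def run_pipeline(config: dict) -> dict:
    """Run the full prognosis pipeline from a config mapping.

    Returns a result dict with the feature table, the selection report
    and one classifier report per repeat; when ``outdir`` is set the
    three artifacts are also written there.
    """
    seed = int(config.get("seed", 0))
    scheme = config.get("classify", {}).get("scheme", "mlp")
    if scheme not in clf.SCHEMES:
        raise ConfigurationError(
            f"unknown scheme {scheme!r}; expected one of {clf.SCHEMES}"
        )

    records, labels, breathing = _load_cohort(config, seed)
    log.info("cohort: %d records (%s)", len(records), dict(zip(*np.unique(labels, return_counts=True))))

    clean_cfg = config.get("clean", {})
    cleaned = []
    for rr in records:
        try:
            rr_clean, rep = rosner_filter(
                rr, k_max=clean_cfg.get("k_max"), alpha=clean_cfg.get("alpha", 0.05)
            )
        except HRVError as exc:
            raise type(exc)(f"record {rr.id!r}, stage 'clean': {exc}") from exc
        cleaned.append(rr_clean)
    log.info("cleaning done (alpha=%s)", clean_cfg.get("alpha", 0.05))

    feat_cfg = config.get("features", {})
    rows = []
    for rr in cleaned:
        try:
            rows.append((rr.id, extract_features(rr, **feat_cfg)))
        except HRVError as exc:
            raise type(exc)(f"record {rr.id!r}, stage 'extract': {exc}") from exc
    table = features_to_frame([FeatureVector(rid, vals) for rid, vals in rows])
    log.info("extracted %d features for %d records", table.shape[1], table.shape[0])

    sel_cfg = config.get("select", {})
    report = select_features(
        table,
        np.asarray(labels),
        alpha_select=sel_cfg.get("alpha", 0.01),
        top_k=sel_cfg.get("top_k", 5),
    )
    log.info("selected features: %s", report.selected)
    if not report.selected:
        raise LabelingError("no feature passed the selection threshold")

    cls_cfg = {k: v for k, v in config.get("classify", {}).items() if k != "scheme"}
    y = (np.asarray(labels) == "R").astype(int)
    reports = clf.cross_validate(
        table[report.selected],
        y,
        scheme=scheme,
        seed=seed,
        repeats=int(cls_cfg.pop("repeats", 1)),
        **cls_cfg,
    )

    result = {
        "features": table,
        "labels": list(labels),
        "selection": report,
        "classifier_reports": reports,
        "breathing": breathing,
        "scheme": scheme,
        "seed": seed,
    }
    outdir = config.get("outdir")
    if outdir:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ordered = table[order_features(table.columns)]
        ordered.insert(0, "label", labels)
        ordered.to_csv(outdir / "features.csv", index_label="id")
        (outdir / "selection.json").write_text(json.dumps(report.as_dict(), indent=2))
        payload = {
            "scheme": scheme,
            "seed": seed,
            "repeats": [r.as_dict() for r in reports],
            "mean_Ac": float(np.mean([r.Ac for r in reports])),
            "breathing": [
                {"rate": b.rate, "valid": b.valid, "status": b.status}
                for b in breathing
            ],
        }
        (outdir / "classifier.json").write_text(json.dumps(payload, indent=2))
    return result
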