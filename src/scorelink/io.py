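"""File formats, run configuration and the end-to-end pipeline.

CSV conventions: comma delimiter, UTF-8, header row required; missing cells
are empty or "NA"; category coding is 0-based (a declared ``offset`` shifts
1-based files, never auto-detected).  Item-parameter files carry columns
``item_id, slope, b1..b4, fixed`` (threshold columns blank-padded for items
with fewer categories); a JSON variant has identical fields.  Readers reject
rather than coerce invalid data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import CalibrationConfig, CalibrationResult, fixed_parameter_calibrate
from .crosswalk import CrosswalkTable, apply_crosswalk, build_crosswalk
from .grm import MISSING, GRMItem, ResponseMatrix, ThetaGrid
from .scoring import pattern_eap
from .validation import score_agreement

logger = logging.getLogger(__name__)

__all__ = [
    "read_responses",
    "write_responses",
    "read_item_params",
    "write_item_params",
    "read_crosswalk",
    "write_crosswalk",
    "write_calibration_result",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# responses


def read_responses(path: str | Path, offset: int = 0) -> ResponseMatrix:
    """Read a persons x items response CSV.

    An optional leading ``person_id`` column supplies row labels.  Cells must
    be integers (after subtracting ``offset``), empty, or "NA".
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no columns")
    cols = list(df.columns)
    person_ids: tuple[str, ...] = ()
    if cols[0].lower() in ("person_id", "person", "id"):
        pid = df[cols[0]].tolist()
        if len(set(pid)) != len(pid):
            dup = pd.Series(pid)[pd.Series(pid).duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate person id {dup!r}")
        person_ids = tuple(pid)
        df = df[cols[1:]]
        cols = cols[1:]
    if not cols:
        raise ValueError(f"{path}: no item columns")
    n = df.shape[0]
    values = np.full((n, len(cols)), MISSING, dtype=np.int64)
    for j, c in enumerate(cols):
        for i, cell in enumerate(df[c].tolist()):
            s = cell.strip()
            if s == "" or s.upper() == "NA":
                continue
            try:
                v = int(s)
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer response {cell!r} at row {i + 1}, column {c!r}"
                ) from None
            v -= offset
            if v < 0:
                raise ValueError(
                    f"{path}: negative response code {v} at row {i + 1}, column {c!r} "
                    f"(offset={offset})"
                )
            values[i, j] = v
    return ResponseMatrix(values, tuple(cols), person_ids)


def write_responses(responses: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(responses.values.astype(object), columns=list(responses.item_ids))
    df = df.mask(df == MISSING, "")
    df.insert(0, "person_id", list(responses.person_ids))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# item parameters


_MAX_THRESHOLDS = 4  # 5-category instruments; smaller K blank-pads


def read_item_params(path: str | Path) -> list[GRMItem]:
    """Read item parameters from CSV (or a JSON file with the same fields)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict) and "items" in records:
            records = records["items"]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = df.to_dict(orient="records")
    items = []
    for rec in records:
        b = []
        for k in range(1, _MAX_THRESHOLDS + 1):
            key = f"b{k}"
            val = rec.get(key, "")
            if val is None or (isinstance(val, str) and val.strip() in ("", "NA")):
                continue
            b.append(float(val))
        fixed_raw = rec.get("fixed", 0)
        fixed = bool(int(fixed_raw)) if str(fixed_raw).strip() not in ("", "NA") else False
        try:
            items.append(
                GRMItem(
                    item_id=str(rec["item_id"]),
                    slope=float(rec["slope"]),
                    thresholds=tuple(b),
                    fixed=fixed,
                )
            )
        except ValueError as e:
            raise ValueError(f"{path}: {e}") from None
    if not items:
        raise ValueError(f"{path}: no items")
    return items


def write_item_params(items: Sequence[GRMItem], path: str | Path) -> None:
    """Write item parameters (CSV or JSON by extension) at 6-decimal precision."""
    path = Path(path)
    recs = []
    for it in items:
        rec = {"item_id": it.item_id, "slope": round(it.slope, 6)}
        for k in range(_MAX_THRESHOLDS):
            rec[f"b{k + 1}"] = round(it.thresholds[k], 6) if k < len(it.thresholds) else ""
        rec["fixed"] = int(it.fixed)
        recs.append(rec)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps({"items": recs}, indent=2))
    else:
        pd.DataFrame(recs).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# crosswalk tables


def write_crosswalk(cw: CrosswalkTable, path: str | Path) -> None:
    """Crosswalk CSV: theta columns at 4 decimals, T columns at 1 decimal."""
    df = cw.to_frame()
    out = pd.DataFrame(
        {
            "raw_score": df.raw_score,
            "theta_eap": df.theta_eap.map(lambda v: f"{v:.4f}"),
            "theta_psd": df.theta_psd.map(lambda v: f"{v:.4f}"),
            "t_score": df.t_score.map(lambda v: f"{v:.1f}"),
            "t_sem": df.t_sem.map(lambda v: f"{v:.1f}"),
        }
    )
    out.to_csv(path, index=False)


def read_crosswalk(path: str | Path, prior_label: str = "file") -> CrosswalkTable:
    df = pd.read_csv(path)
    return CrosswalkTable(
        raw_score=df["raw_score"].to_numpy(),
        theta_eap=df["theta_eap"].to_numpy(float),
        theta_psd=df["theta_psd"].to_numpy(float),
        t_score=df["t_score"].to_numpy(float),
        t_sem=df["t_sem"].to_numpy(float),
        prior_label=prior_label,
    )


def write_calibration_result(result: CalibrationResult, path: str | Path) -> None:
    """Serialize a calibration result to structured JSON."""
    payload = {
        "converged": result.converged,
        "n_cycles": result.n_cycles,
        "n_persons_used": result.n_persons_used,
        "n_persons_dropped": result.n_persons_dropped,
        "loglik_trace": [float(v) for v in result.loglik_trace],
        "collapsed_categories": {
            k: {str(a): int(b) for a, b in v.items()}
            for k, v in result.collapsed_categories.items()
        },
        "latent_weights": {
            "points": [float(p) for p in result.latent_weights.points],
            "weights": [float(w) for w in result.latent_weights.weights],
        },
        "items": [
            {
                "item_id": it.item_id,
                "slope": it.slope,
                "thresholds": list(it.thresholds),
                "fixed": it.fixed,
                "se": [float(s) for s in result.standard_errors[it.item_id]]
                if it.item_id in result.standard_errors
                else None,
            }
            for it in result.items
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# pipeline


_KNOWN_KEYS = {
    "responses",
    "params",
    "free_items",
    "legacy_items",
    "grid_points",
    "grid_lo",
    "grid_hi",
    "D",
    "param_tol",
    "loglik_tol",
    "max_cycles",
    "prior",
    "ci_z",
    "seed",
    "offset",
    "out_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Settings for :func:`run_pipeline`.

    ``responses`` and ``params`` are input paths; ``legacy_items`` names the
    columns whose summed score the crosswalk maps (defaults to all free
    items); ``prior`` is ``"normal"`` or ``"empirical"``.
    """

    responses: str
    params: str
    out_dir: str
    legacy_items: tuple[str, ...] = ()
    grid_points: int = 49
    grid_lo: float = -4.0
    grid_hi: float = 4.0
    D: float = 1.0
    param_tol: float = 1e-4
    loglik_tol: float = 1e-7
    max_cycles: int = 500
    prior: str = "normal"
    ci_z: float = 1.96
    seed: int = 0
    offset: int = 0

    def __post_init__(self) -> None:
        if self.D not in (1.0, 1.702):
            raise ValueError("D must be 1.0 (logistic) or 1.702 (normal-ogive)")
        for key in ("grid_points", "max_cycles"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        for key in ("param_tol", "loglik_tol", "ci_z"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        if self.prior not in ("normal", "empirical"):
            raise ValueError("prior must be 'normal' or 'empirical'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "legacy_items" in data:
            data["legacy_items"] = tuple(data["legacy_items"])
        return cls(**data)

    def grid(self) -> ThetaGrid:
        return ThetaGrid.equally_spaced(self.grid_points, self.grid_lo, self.grid_hi)


def run_pipeline(config: RunConfig) -> dict:
    """calibrate -> crosswalk -> score -> validate; writes all artifacts.

    Returns a dict of artifact paths plus the headline agreement numbers.
    Any stage failure raises with a stage-labelled message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("scorelink")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        import scipy

        logger.info(
            "pipeline start: numpy %s scipy %s pandas %s seed %d",
            np.__version__, scipy.__version__, pd.__version__, config.seed,
        )
        logger.info("config: %s", dataclasses.asdict(config))

        def stage(name: str):
            logger.info("stage: %s", name)

        stage("read")
        try:
            responses = read_responses(config.responses, offset=config.offset)
            items = read_item_params(config.params)
        except Exception as e:
            raise RuntimeError(f"[read] {e}") from e

        stage("calibrate")
        try:
            result = fixed_parameter_calibrate(
                responses,
                items,
                config.grid(),
                CalibrationConfig(
                    param_tol=config.param_tol,
                    loglik_tol=config.loglik_tol,
                    max_cycles=config.max_cycles,
                    D=config.D,
                ),
            )
        except Exception as e:
            raise RuntimeError(f"[calibrate] {e}") from e
        write_calibration_result(result, out / "calibration.json")
        write_item_params(result.items, out / "items_calibrated.csv")

        stage("crosswalk")
        try:
            legacy_ids = list(config.legacy_items) or [
                it.item_id for it in result.items if not it.fixed
            ]
            legacy = [result.item(i) for i in legacy_ids]
            prior = result.latent_weights if config.prior == "empirical" else "normal"
            cw = build_crosswalk(legacy, config.grid(), prior=prior, D=config.D)
        except Exception as e:
            raise RuntimeError(f"[crosswalk] {e}") from e
        write_crosswalk(cw, out / "crosswalk.csv")

        stage("score")
        try:
            anchors = [it for it in result.items if it.fixed]
            anchor_resp = responses.subset_items([it.item_id for it in anchors])
            scores = pattern_eap(anchor_resp, anchors, config.grid(), D=config.D)
        except Exception as e:
            raise RuntimeError(f"[score] {e}") from e
        scores.to_csv(out / "scores.csv", index=False, float_format="%.4f")

        stage("validate")
        try:
            legacy_resp = result.recode_responses(responses.subset_items(legacy_ids))
            obs_mask = legacy_resp.observed_mask().all(axis=1)
            raw = legacy_resp.values.sum(axis=1).astype(float)
            raw[~obs_mask] = np.nan
            derived = apply_crosswalk(cw, raw)
            merged = pd.DataFrame(
                {"person_id": list(responses.person_ids), "derived_t": derived}
            ).merge(scores, on="person_id")
            ok = merged["derived_t"].notna()
            report = score_agreement(
                merged.loc[ok, "t_score"], merged.loc[ok, "derived_t"]
            )
        except Exception as e:
            raise RuntimeError(f"[validate] {e}") from e
        report_dict = {
            "pearson_r": report.pearson_r,
            "mean_diff": report.mean_diff,
            "sd_diff": report.sd_diff,
            "rmsd": report.rmsd,
            "icc": report.icc,
            "icc_variant": report.icc_variant,
            "bland_altman": report.bland_altman,
            "n": report.n,
            "convention": report.convention,
            "provenance": {
                "responses": str(config.responses),
                "params": str(config.params),
                "crosswalk": str(out / "crosswalk.csv"),
                "prior": config.prior,
                "seed": config.seed,
            },
        }
        (out / "validation.json").write_text(json.dumps(report_dict, indent=2))
        logger.info("pipeline done: r=%.3f icc=%.3f", report.pearson_r, report.icc)
        return {
            "out_dir": str(out),
            "calibration": str(out / "calibration.json"),
            "crosswalk": str(out / "crosswalk.csv"),
            "scores": str(out / "scores.csv"),
            "validation": str(out / "validation.json"),
            "agreement": report_dict,
        }
    finally:
        root.removeHandler(handler)
        handler.close()
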