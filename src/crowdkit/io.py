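"""Delimited-text I/O and run configuration.

All tables are comma-separated UTF-8 with "." decimals; fit records are
JSON. Trial tables carry one row per stimulus cell with the header

    eccentricity_deg, letter_size_deg, spacing, spacing_convention,
    n_alternatives, n_correct, n_trials

where ``spacing`` may be the literal token "unflanked" and
``spacing_convention`` is one of center_to_center, edge_to_edge,
nominal_multiple (conversion to center-to-center happens on ingest).
``spacing_deg`` and ``nominal_multiple`` are accepted as alternative
spacing column names, the latter implying the nominal convention.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import UNFLANKED, SpacingConvention, SpacingValue, TaskSpec
from .meta import MetaPoint
from .psychometric import StimulusCell
from .threshold_curves import ThresholdPoint

__all__ = [
    "read_trials",
    "write_trials",
    "read_thresholds",
    "write_thresholds",
    "read_meta_table",
    "write_meta_table",
    "write_meta_template",
    "RunConfig",
    "config_hash",
]

_UNFLANKED_TOKEN = "unflanked"


class TrialTableError(ValueError):
    """Malformed trial table; message lists offending line numbers."""


def _parse_spacing(raw, convention: str, letter_size: float, line: int, errors: list[str]) -> float | None:
    if isinstance(raw, str) and raw.strip().lower() == _UNFLANKED_TOKEN:
        return UNFLANKED
    try:
        value = float(raw)
    except (TypeError, ValueError):
        errors.append(f"line {line}: unparseable spacing {raw!r}")
        return None
    if math.isinf(value):
        return UNFLANKED
    try:
        return SpacingValue(value, SpacingConvention(convention), letter_size).to_center_to_center()
    except ValueError as exc:
        errors.append(f"line {line}: {exc}")
        return None


def read_trials(path: str | Path) -> list[StimulusCell]:
    """Read a trial-level/cell-aggregated table into validated StimulusCells."""
    df = pd.read_csv(path, dtype={"spacing": str, "spacing_deg": str, "nominal_multiple": str})
    spacing_col, default_conv = None, None
    for cand, conv in (("spacing", None), ("spacing_deg", "center_to_center"),
                       ("nominal_multiple", "nominal_multiple")):
        if cand in df.columns:
            spacing_col, default_conv = cand, conv
            break
    if spacing_col is None:
        raise TrialTableError("no spacing column (expected spacing, spacing_deg, or nominal_multiple)")
    required = {"eccentricity_deg", "letter_size_deg", "n_alternatives", "n_correct", "n_trials"}
    missing = required - set(df.columns)
    if missing:
        raise TrialTableError(f"missing required columns: {sorted(missing)}")
    cells: list[StimulusCell] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rd = row._asdict()
        conv = rd.get("spacing_convention", default_conv) or default_conv or "center_to_center"
        try:
            size = float(rd["letter_size_deg"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: unparseable letter_size_deg {rd['letter_size_deg']!r}")
            continue
        spacing = _parse_spacing(rd[spacing_col], str(conv), size, line, errors)
        if spacing is None:
            continue
        try:
            n_correct, n_trials = int(rd["n_correct"]), int(rd["n_trials"])
            if n_correct > n_trials:
                raise ValueError(f"n_correct {n_correct} > n_trials {n_trials}")
            cells.append(StimulusCell(
                eccentricity=float(rd["eccentricity_deg"]), letter_size=size, spacing=spacing,
                task=TaskSpec(int(rd["n_alternatives"])), n_correct=n_correct, n_trials=n_trials,
            ))
        except (TypeError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise TrialTableError("malformed trial table:\n  " + "\n  ".join(errors))
    return cells


def write_trials(cells: Sequence[StimulusCell], path: str | Path) -> None:
    """Write cells as a center-to-center trial table (round-trips with read_trials)."""
    rows = []
    for c in cells:
        rows.append({
            "eccentricity_deg": c.eccentricity,
            "letter_size_deg": c.letter_size,
            "spacing": _UNFLANKED_TOKEN if c.is_unflanked else repr(float(c.spacing)),
            "spacing_convention": SpacingConvention.CENTER_TO_CENTER.value,
            "n_alternatives": c.task.n_alternatives,
            "n_correct": c.n_correct,
            "n_trials": c.n_trials,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_thresholds(path: str | Path) -> list[ThresholdPoint]:
    """Read a (spacing_deg, threshold[, se]) table; "unflanked" marks the baseline."""
    df = pd.read_csv(path, dtype={"spacing_deg": str})
    pts = []
    for i, row in enumerate(df.itertuples(index=False)):
        rd = row._asdict()
        raw = rd["spacing_deg"]
        spacing = UNFLANKED if str(raw).strip().lower() == _UNFLANKED_TOKEN else float(raw)
        se = rd.get("se")
        se = float(se) if se is not None and np.isfinite(float(se)) else None
        pts.append(ThresholdPoint(spacing=spacing, threshold=float(rd["threshold"]), se=se))
    return pts


def write_thresholds(points: Sequence[ThresholdPoint], path: str | Path) -> None:
    pd.DataFrame([
        {"spacing_deg": _UNFLANKED_TOKEN if p.is_unflanked else repr(float(p.spacing)),
         "threshold": p.threshold, "se": p.se if p.se is not None else ""}
        for p in points
    ]).to_csv(path, index=False)


_META_COLUMNS = ["study", "eccentricity_vf", "duration_s", "bouma_fraction", "se",
                 "n_flankers", "visual_field", "a_priori_exclude"]


def read_meta_table(path: str | Path) -> list[MetaPoint]:
    """Read a study-level meta-analysis table into MetaPoints."""
    df = pd.read_csv(path)
    missing = {"study", "duration_s", "bouma_fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"meta table missing columns: {sorted(missing)}")
    pts = []
    errors = []
    for i, row in enumerate(df.itertuples(index=False)):
        rd = row._asdict()
        line = i + 2
        try:
            se = rd.get("se")
            se = float(se) if se is not None and str(se).strip() != "" and np.isfinite(float(se)) else None
            pts.append(MetaPoint(
                study=str(rd["study"]), duration=float(rd["duration_s"]),
                bouma_fraction=float(rd["bouma_fraction"]), se=se,
                n_flankers=str(rd.get("n_flankers", "4") or "4"),
                visual_field=str(rd.get("visual_field", "") or ""),
                excluded_a_priori=bool(rd.get("a_priori_exclude", False))
                if str(rd.get("a_priori_exclude", "")).strip() not in ("", "nan") else False,
            ))
        except (TypeError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError("malformed meta table:\n  " + "\n  ".join(errors))
    return pts


def write_meta_table(points: Sequence[MetaPoint], path: str | Path) -> None:
    pd.DataFrame([
        {"study": p.study, "eccentricity_vf": p.visual_field, "duration_s": p.duration,
         "bouma_fraction": p.bouma_fraction, "se": p.se if p.se is not None else "",
         "n_flankers": p.n_flankers, "visual_field": p.visual_field,
         "a_priori_exclude": p.excluded_a_priori}
        for p in points
    ]).to_csv(path, index=False)


def write_meta_template(path: str | Path) -> None:
    """Empty meta-analysis template for users to populate from the literature.

    Mirrors the columns of published study-survey tables (study label,
    eccentricity/visual field, duration, flanker count); value fields
    are intentionally blank — no digitized figure data ship with the
    package.
    """
    df = pd.DataFrame(columns=_META_COLUMNS)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run.

    Unknown keys are rejected so typos fail loudly before any
    computation starts.
    """

    input: str | None = None
    output_dir: str = "."
    seed: int = 0
    form: str = "logistic"
    asymptote: str | float = "free"
    criteria: list[dict] = field(default_factory=lambda: [{"family": "proportion_of_asymptote", "level": 0.5}])
    n_boot: int = 199
    verbosity: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
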