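"""Shelf-life decision logic and integrated reporting.

Sensory rejection (panel QI reaching the protocol maximum) and indicator
limit crossings are pooled into one shelf-life estimate: the product is
acceptable through the greatest sampling day strictly before the first
rejection day. On the standard grid {1,4,8,11,14,18} a rejection observed at
day 14 therefore yields an 11-day shelf-life — the last day the fish was
still observed acceptable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

from .calibration import _round_half_away
from .protocol import PanelQi, QimProtocol, max_qi


class ReportError(ValueError):
    pass


@dataclass(frozen=True)
class RejectionFinding:
    """One rejection criterion's verdict: the sampling day it first fired,
    or None if it never did within the study."""

    criterion: str  # "sensory_qi_max" or an indicator name
    rejection_day: float | None
    evidence: str = ""


@dataclass(frozen=True)
class ShelfLifeResult:
    sampling_days: tuple[float, ...]
    findings: tuple[RejectionFinding, ...]
    first_rejection_day: float | None
    shelf_life_days: float | None
    status: str  # "established" | "not reached within study" | "rejected at first observation"


def sensory_rejection_day(
    panel: Sequence[PanelQi],
    protocol: QimProtocol,
    any_referee: bool = False,
    panel_max: Iterable[float] | None = None,
) -> RejectionFinding:
    """First day the panel rejects the samples.

    Default rule: the rounded panel-mean QI reaches the protocol maximum.
    With any_referee=True a single sheet at the maximum suffices (panel_max
    must then supply the per-day maximum sheet QI).
    """
    if not panel:
        raise ReportError("empty panel")
    top = max_qi(protocol)
    if any_referee:
        if panel_max is None:
            raise ReportError("any_referee rule needs per-day maximum sheet QIs")
        series = zip((p.storage_day for p in panel), panel_max)
    else:
        series = ((p.storage_day, _round_half_away(p.qi_mean)) for p in panel)
    for day, value in sorted(series):
        if value >= top:
            return RejectionFinding(
                criterion="sensory_qi_max",
                rejection_day=day,
                evidence=f"panel QI reached the protocol maximum ({top}) on day {day:g}",
            )
    return RejectionFinding(
        criterion="sensory_qi_max",
        rejection_day=None,
        evidence=f"panel QI stayed below the protocol maximum ({top})",
    )


def integrate_shelf_life(
    findings: Iterable[RejectionFinding], sampling_days: Sequence[float]
) -> ShelfLifeResult:
    """Pool rejection findings into one shelf-life estimate.

    first_rejection_day is the earliest rejection over all criteria;
    shelf_life_days is the greatest sampling day strictly before it. No
    rejection -> shelf-life undetermined ("not reached within study");
    rejection already at the first sampling day -> no acceptable day exists
    ("rejected at first observation").
    """
    days = list(sampling_days)
    if any(b <= a for a, b in zip(days, days[1:])) or not days:
        raise ReportError("sampling_days must be non-empty and strictly increasing")
    findings = tuple(findings)
    fired = [f.rejection_day for f in findings if f.rejection_day is not None]
    if not fired:
        return ShelfLifeResult(
            sampling_days=tuple(days),
            findings=findings,
            first_rejection_day=None,
            shelf_life_days=None,
            status="not reached within study",
        )
    first = min(fired)
    before = [d for d in days if d < first]
    if not before:
        return ShelfLifeResult(
            sampling_days=tuple(days),
            findings=findings,
            first_rejection_day=first,
            shelf_life_days=None,
            status="rejected at first observation",
        )
    return ShelfLifeResult(
        sampling_days=tuple(days),
        findings=findings,
        first_rejection_day=first,
        shelf_life_days=max(before),
        status="established",
    )


# ---------------------------------------------------------------------------
# Report document


def _jsonable(obj):
    if hasattr(obj, "__dict__") or hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict, is_dataclass

        if is_dataclass(obj):
            return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def build_report(
    protocol: QimProtocol | None = None,
    calibration: dict | None = None,
    pls: dict | None = None,
    crossings: dict | None = None,
    correlations: dict | None = None,
    shelf_life: ShelfLifeResult | None = None,
) -> dict:
    """Assemble the single JSON-serializable report document.

    Missing stages are marked {"status": "stage skipped"} rather than
    failing, so partial pipelines still report. Canonical key order makes
    the serialized report reproducible bit-for-bit for identical inputs.
    """
    skipped = {"status": "stage skipped"}

    def stage(value):
        return _jsonable(value) if value is not None else skipped

    report = {
        "protocol": (
            {
                "name": protocol.name,
                "n_groups": len(protocol.groups),
                "n_parameters": len(protocol.parameters),
                "max_qi": max_qi(protocol),
            }
            if protocol is not None
            else skipped
        ),
        "calibration": stage(calibration),
        "pls": stage(pls),
        "crossings": stage(crossings),
        "correlations": stage(correlations),
        "shelf_life": stage(shelf_life),
    }
    return report


def report_json(report: dict) -> str:
    """Canonical serialization (sorted keys, fixed separators)."""
    return json.dumps(report, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def report_hash(report: dict) -> str:
    return hashlib.sha256(report_json(report).encode("utf-8")).hexdigest()


def render_markdown(report: dict) -> str:
    """Human-readable rendering of the report document."""
    lines = ["# Shelf-life report", ""]
    for section, content in report.items():
        lines.append(f"## {section}")
        if isinstance(content, dict) and content.get("status") == "stage skipped":
            lines.append("_stage skipped_")
        else:
            lines.append("```json")
            lines.append(json.dumps(content, sort_keys=True, indent=2))
            lines.append("```")
        lines.append("")
    return "\n".join(lines)
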