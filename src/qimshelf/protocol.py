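"""QIM protocol definition, validation, scoring, and panel aggregation.

A Quality Index Method (QIM) protocol is a demerit scheme: sensory attribute
groups (overall aspect, gills, eyes, ...), each holding parameters (gill odor,
eyeball, ...), each parameter holding ordered descriptors with integer demerit
points starting at 0. A referee scores every parameter of one fish on one
sheet; the Quality Index (QI) is the plain sum of demerits, so it runs from 0
(peak freshness) to the protocol maximum (sensory rejection).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("qimshelf")

#: Bundled protocol for whole king weakfish (Macrodon ancylodon) stored in ice.
DEFAULT_PROTOCOL_PATH = Path(__file__).parent / "data" / "king_weakfish.json"

PROTOCOL_SCHEMA_VERSION = 1


class ProtocolError(ValueError):
    """Raised when a protocol file or score sheet violates the demerit scheme."""


@dataclass(frozen=True)
class Descriptor:
    description: str
    demerit: int


@dataclass(frozen=True)
class Parameter:
    parameter_name: str
    descriptors: tuple[Descriptor, ...]

    @property
    def max_demerit(self) -> int:
        return max(d.demerit for d in self.descriptors)


@dataclass(frozen=True)
class AttributeGroup:
    group_name: str
    parameters: tuple[Parameter, ...]


@dataclass(frozen=True)
class QimProtocol:
    """A validated demerit scheme.

    Invariants enforced at construction: each parameter's demerit points are
    consecutive integers starting at 0, and parameter names are unique across
    the whole protocol (group labels do not disambiguate sheets).
    """

    name: str
    groups: tuple[AttributeGroup, ...]
    version: int = PROTOCOL_SCHEMA_VERSION

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            for param in group.parameters:
                if param.parameter_name in seen:
                    raise ProtocolError(
                        f"duplicate parameter name {param.parameter_name!r}"
                    )
                seen.add(param.parameter_name)
                demerits = [d.demerit for d in param.descriptors]
                if demerits != list(range(len(demerits))):
                    raise ProtocolError(
                        f"parameter {param.parameter_name!r}: demerit points "
                        f"{demerits} are not consecutive integers from 0"
                    )

    @property
    def parameters(self) -> tuple[Parameter, ...]:
        return tuple(p for g in self.groups for p in g.parameters)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.parameter_name for p in self.parameters)

    def parameter(self, name: str) -> Parameter:
        for p in self.parameters:
            if p.parameter_name == name:
                return p
        raise ProtocolError(f"unknown parameter {name!r}")

    def group_of(self, parameter_name: str) -> str:
        for g in self.groups:
            for p in g.parameters:
                if p.parameter_name == parameter_name:
                    return g.group_name
        raise ProtocolError(f"unknown parameter {parameter_name!r}")


@dataclass(frozen=True)
class Assessment:
    """One referee's complete score sheet for one fish on one storage day."""

    lot: str
    fish_id: str
    referee_id: str
    storage_day: float
    scores: Mapping[str, int]


@dataclass(frozen=True)
class PanelQi:
    """Panel aggregate for one storage day: mean QI over all sheets and the
    per-parameter mean demerits (the quantities plotted per attribute)."""

    storage_day: float
    qi_mean: float
    qi_sd: float
    n_assessments: int
    per_parameter_mean: dict[str, float] = field(compare=False)


# ---------------------------------------------------------------------------
# Protocol I/O


def load_protocol(path: str | Path = DEFAULT_PROTOCOL_PATH) -> QimProtocol:
    """Load and validate a protocol from its JSON document.

    Raises ProtocolError naming the offending parameter on schema or
    invariant violations (gapped demerits, duplicate parameter names).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ProtocolError(f"cannot parse protocol file {path}: {exc}") from exc
    try:
        groups = tuple(
            AttributeGroup(
                group_name=g["group_name"],
                parameters=tuple(
                    Parameter(
                        parameter_name=p["parameter_name"],
                        descriptors=tuple(
                            Descriptor(d["description"], int(d["demerit"]))
                            for d in p["descriptors"]
                        ),
                    )
                    for p in g["parameters"]
                ),
            )
            for g in doc["groups"]
        )
    except (KeyError, TypeError) as exc:
        raise ProtocolError(f"protocol file {path} missing field: {exc}") from exc
    return QimProtocol(
        name=doc["name"], groups=groups, version=int(doc.get("version", 1))
    )


def write_protocol(protocol: QimProtocol, path: str | Path) -> None:
    """Serialize a protocol back to its JSON document (normalized key order)."""
    doc = {
        "name": protocol.name,
        "version": protocol.version,
        "groups": [
            {
                "group_name": g.group_name,
                "parameters": [
                    {
                        "parameter_name": p.parameter_name,
                        "descriptors": [
                            {"description": d.description, "demerit": d.demerit}
                            for d in p.descriptors
                        ],
                    }
                    for p in g.parameters
                ],
            }
            for g in protocol.groups
        ],
    }
    Path(path).write_text(
        json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Scoring


def max_qi(protocol: QimProtocol) -> int:
    """Protocol maximum: sum over parameters of the largest demerit (21 for
    the bundled king weakfish scheme)."""
    return sum(p.max_demerit for p in protocol.parameters)


def score_assessment(assessment: Assessment, protocol: QimProtocol) -> int:
    """QI of one sheet: the sum of its demerits.

    The sheet must be complete (every protocol parameter scored) and every
    demerit must lie within its parameter's descriptor range.
    """
    total = 0
    for param in protocol.parameters:
        name = param.parameter_name
        if name not in assessment.scores:
            raise ProtocolError(f"sheet is missing parameter {name!r}")
        demerit = assessment.scores[name]
        if not (0 <= demerit <= param.max_demerit) or int(demerit) != demerit:
            raise ProtocolError(
                f"parameter {name!r}: demerit {demerit!r} outside 0..{param.max_demerit}"
            )
        total += int(demerit)
    extras = set(assessment.scores) - set(protocol.parameter_names)
    if extras:
        raise ProtocolError(f"sheet scores unknown parameter(s) {sorted(extras)}")
    return total


def aggregate_panel(
    assessments: Iterable[Assessment],
    protocol: QimProtocol,
    days: Sequence[float] | None = None,
) -> list[PanelQi]:
    """Aggregate sheets into one PanelQi per storage day.

    Panel QI per day is the arithmetic mean of the sheet QIs over all
    (referee x fish) combinations; dispersion is the sample SD (0 when a day
    holds a single sheet). Per-parameter means are reported alongside.
    Requested days with no sheets are omitted with a logged warning.
    """
    assessments = list(assessments)
    by_day: dict[float, list[Assessment]] = {}
    for a in assessments:
        by_day.setdefault(a.storage_day, []).append(a)
    wanted = sorted(by_day) if days is None else list(days)
    out: list[PanelQi] = []
    for day in wanted:
        sheets = by_day.get(day, [])
        if not sheets:
            logger.warning("no assessments for day %s; day omitted", day)
            continue
        qis = pd.Series([score_assessment(a, protocol) for a in sheets], dtype=float)
        per_param = {
            name: float(pd.Series([a.scores[name] for a in sheets]).mean())
            for name in protocol.parameter_names
        }
        out.append(
            PanelQi(
                storage_day=day,
                qi_mean=float(qis.mean()),
                qi_sd=float(qis.std(ddof=1)) if len(qis) > 1 else 0.0,
                n_assessments=len(sheets),
                per_parameter_mean=per_param,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Score-sheet CSV dialect: long format `lot,fish_id,referee_id,storage_day,parameter,demerit`

SHEET_COLUMNS = ["lot", "fish_id", "referee_id", "storage_day", "parameter", "demerit"]


def read_score_sheets(path: str | Path) -> list[Assessment]:
    """Read score sheets from the long-format CSV dialect."""
    df = pd.read_csv(path)
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ProtocolError(f"score-sheet CSV missing columns {sorted(missing)}")
    out = []
    keys = ["lot", "fish_id", "referee_id", "storage_day"]
    for (lot, fish, ref, day), grp in df.groupby(keys, sort=True):
        out.append(
            Assessment(
                lot=str(lot),
                fish_id=str(fish),
                referee_id=str(ref),
                storage_day=float(day),
                scores={
                    str(r.parameter): int(r.demerit) for r in grp.itertuples()
                },
            )
        )
    return out


def write_score_sheets(assessments: Iterable[Assessment], path: str | Path) -> None:
    rows = [
        (a.lot, a.fish_id, a.referee_id, a.storage_day, param, demerit)
        for a in assessments
        for param, demerit in a.scores.items()
    ]
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, index=False)
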