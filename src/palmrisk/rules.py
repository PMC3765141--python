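"""Suitability rule tables: per-indicator risk classification.

Sustainability standards for oil palm (RSPO, RSB, RES-D and the HCV
toolkits) translate into per-indicator thresholds that map a measured
value (rainfall, slope, erosion rate, carbon stock, soil depth) or a
named category (soil texture class, community-use class, conservation
status) to one of four ordinal non-compliance risk classes::

    LOW(0) < MEDIUM(1) < HIGH(2) < VERY_HIGH(3)

``VERY_HIGH`` is synonymous with "unsuitable" in the standards'
vocabulary; both labels are accepted when parsing.  A fifth state,
``NODATA``, marks missing input and never participates in the ordering.

The default registry shipped with the package encodes the full
indicator hierarchy of the methodology (17 rule tables under three
principles: conservation values, human wellbeing / land rights, and
biophysical suitability).

Boundary convention for continuous tables: printed threshold tables use
touching bands ("8-15 %", "15-30 %").  Intervals here are explicit about
closed/open endpoints, and the shipped defaults close each shared
boundary on the *less risky* side — slope exactly 15 % is MEDIUM, not
HIGH; rainfall exactly 1750 mm is LOW; carbon exactly 80 t/ha is HIGH.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .grid import CLASS_NODATA, Grid

logger = logging.getLogger("palmrisk")

INF = float("inf")


class RuleConfigError(ValueError):
    """A rule-registry configuration document is invalid."""


@enum.unique
class RiskClass(enum.Enum):
    """Ordinal non-compliance risk class.

    The four risk labels carry ranks 0-3 and are totally ordered;
    ``NODATA`` is unranked and any order comparison with it raises.
    """

    LOW = 0
    MEDIUM = 1
    HIGH = 2
    VERY_HIGH = 3
    NODATA = CLASS_NODATA

    @property
    def rank(self) -> int:
        if self is RiskClass.NODATA:
            raise ValueError("NODATA has no rank")
        return self.value

    def _cmp_key(self, other: "RiskClass") -> tuple[int, int]:
        if not isinstance(other, RiskClass):
            raise TypeError(f"cannot compare RiskClass with {type(other).__name__}")
        return self.rank, other.rank

    def __lt__(self, other):
        a, b = self._cmp_key(other)
        return a < b

    def __le__(self, other):
        a, b = self._cmp_key(other)
        return a <= b

    def __gt__(self, other):
        a, b = self._cmp_key(other)
        return a > b

    def __ge__(self, other):
        a, b = self._cmp_key(other)
        return a >= b

    @classmethod
    def from_label(cls, label: str) -> "RiskClass":
        norm = label.strip().upper().replace(" ", "_").replace("-", "_")
        if norm in {"UNSUITABLE", "VERYHIGH"}:  # standards' alternate wording
            return cls.VERY_HIGH
        try:
            return cls[norm]
        except KeyError:
            raise RuleConfigError(f"unknown risk label: {label!r}") from None

    @classmethod
    def from_rank(cls, rank: int) -> "RiskClass":
        return cls(int(rank))


RISK_CLASSES = (RiskClass.LOW, RiskClass.MEDIUM, RiskClass.HIGH, RiskClass.VERY_HIGH)


@dataclass(frozen=True)
class Interval:
    """A real interval with explicit endpoint closure."""

    lower: float
    upper: float
    closed_lower: bool = True
    closed_upper: bool = False

    def __post_init__(self):
        if not self.lower < self.upper:
            raise RuleConfigError(
                f"malformed interval: lower {self.lower} >= upper {self.upper}"
            )

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.closed_lower and value == self.lower)
        below = value < self.upper or (self.closed_upper and value == self.upper)
        return above and below

    def contains_array(self, values: np.ndarray) -> np.ndarray:
        above = (values > self.lower) | (
            (values == self.lower) if self.closed_lower else False
        )
        below = (values < self.upper) | (
            (values == self.upper) if self.closed_upper else False
        )
        return above & below

    def __str__(self) -> str:
        lo = "[" if self.closed_lower else "("
        hi = "]" if self.closed_upper else ")"
        return f"{lo}{self.lower}, {self.upper}{hi}"


def _norm_cat(category: str) -> str:
    return " ".join(str(category).strip().lower().split())


@dataclass(frozen=True)
class Rule:
    """One row of a rule table: an interval or a category set -> class."""

    risk: RiskClass
    interval: Interval | None = None
    categories: frozenset[str] | None = None

    def __post_init__(self):
        if (self.interval is None) == (self.categories is None):
            raise RuleConfigError("rule needs exactly one of interval / categories")


@dataclass
class RuleTable:
    """The complete classification rule for one indicator."""

    indicator_id: str
    kind: str  # "continuous" | "categorical"
    rules: list[Rule]
    units: str | None = None
    name: str = ""
    domain: Interval | None = None
    default_class: RiskClass = RiskClass.LOW
    notes: str = ""

    def __post_init__(self):
        if self.kind not in {"continuous", "categorical"}:
            raise RuleConfigError(
                f"table {self.indicator_id}: unknown kind {self.kind!r}"
            )
        if self.kind == "continuous" and self.domain is None:
            self.domain = Interval(0.0, INF, True, False)

    def emitted_classes(self) -> set[RiskClass]:
        return {r.risk for r in self.rules}

    def __eq__(self, other) -> bool:
        if not isinstance(other, RuleTable):
            return NotImplemented
        return (
            self.indicator_id == other.indicator_id
            and self.kind == other.kind
            and self.units == other.units
            and self.domain == other.domain
            and self.default_class == other.default_class
            and self.rules == other.rules
        )


@dataclass
class ValidationReport:
    """Gaps and overlaps found in a rule table's covered domain."""

    indicator_id: str
    gaps: list[str] = field(default_factory=list)
    overlaps: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.gaps and not self.overlaps

    def __str__(self) -> str:
        if self.ok:
            return f"{self.indicator_id}: partition OK"
        lines = [f"{self.indicator_id}:"]
        lines += [f"  gap at {g}" for g in self.gaps]
        lines += [f"  overlap: {o}" for o in self.overlaps]
        return "\n".join(lines)


def validate_rule_table(table: RuleTable) -> ValidationReport:
    """Report gaps and overlaps; the report is empty iff the rules partition
    the declared domain (continuous) or the category sets are disjoint
    (categorical).  Validation never raises."""
    report = ValidationReport(table.indicator_id)
    if table.kind == "categorical":
        seen: dict[str, RiskClass] = {}
        for rule in table.rules:
            for cat in sorted(rule.categories or ()):
                key = _norm_cat(cat)
                if key in seen:
                    report.overlaps.append(
                        f"category {cat!r} in both {seen[key].name} and {rule.risk.name}"
                    )
                else:
                    seen[key] = rule.risk
        return report

    intervals = sorted(
        (r.interval for r in table.rules),
        key=lambda iv: (iv.lower, not iv.closed_lower),
    )
    # pairwise overlap check
    for i, a in enumerate(intervals):
        for b in intervals[i + 1 :]:
            lo = max(a.lower, b.lower)
            hi = min(a.upper, b.upper)
            if lo < hi or (lo == hi and a.contains(lo) and b.contains(lo)):
                report.overlaps.append(f"{a} and {b}")
    # Gap sweep against the declared domain.  (cover_at, cover_closed)
    # tracks how far coverage extends: cover_closed=True means the point
    # cover_at itself is covered.
    domain = table.domain
    cover_at = domain.lower
    cover_closed = not domain.closed_lower  # closed domain start must be covered
    for iv in intervals:
        starts_beyond = iv.lower > cover_at or (
            iv.lower == cover_at and not iv.closed_lower and not cover_closed
        )
        if starts_beyond and cover_at <= domain.upper:
            lo_b = "(" if cover_closed else "["
            hi_b = ")" if iv.closed_lower else "]"
            report.gaps.append(f"{lo_b}{cover_at}, {iv.lower}{hi_b}")
        if iv.upper > cover_at:
            cover_at = iv.upper
            cover_closed = iv.closed_upper
        elif iv.upper == cover_at:
            cover_closed = cover_closed or iv.closed_upper
    ends_short = cover_at < domain.upper or (
        cover_at == domain.upper and domain.closed_upper and not cover_closed
    )
    if ends_short:
        lo_b = "(" if cover_closed else "["
        hi_b = "]" if domain.closed_upper else ")"
        report.gaps.append(f"{lo_b}{cover_at}, {domain.upper}{hi_b}")
    return report


def classify_value(table: RuleTable, value) -> RiskClass:
    """Classify one value (continuous) or category (categorical).

    Missing input (None or NaN) maps to ``NODATA`` — never silently to
    LOW.  An unknown category falls to the table's ``default_class`` with
    a logged warning.  A continuous value outside the declared domain
    maps to ``NODATA`` with a logged warning.
    """
    if value is None:
        return RiskClass.NODATA
    if table.kind == "continuous":
        try:
            v = float(value)
        except (TypeError, ValueError):
            return RiskClass.NODATA
        if math.isnan(v):
            return RiskClass.NODATA
        for rule in table.rules:
            if rule.interval.contains(v):
                return rule.risk
        logger.warning(
            "%s: value %s outside declared domain %s -> NODATA",
            table.indicator_id, v, table.domain,
        )
        return RiskClass.NODATA
    if isinstance(value, float) and math.isnan(value):
        return RiskClass.NODATA
    key = _norm_cat(value)
    for rule in table.rules:
        if key in {_norm_cat(c) for c in rule.categories}:
            return rule.risk
    logger.warning(
        "%s: unknown category %r -> default class %s",
        table.indicator_id, value, table.default_class.name,
    )
    return table.default_class


def classify_grid(
    table: RuleTable,
    values: Grid,
    categories: Mapping[int, str] | None = None,
) -> Grid:
    """Apply a rule table cell-wise to a raster.

    The result is a rank-encoded uint8 grid (0-3, 255 = nodata) sharing
    the input's georeferencing.  For categorical tables the raster may
    hold category strings directly (object dtype) or integer codes with
    a ``categories`` code->name mapping.
    """
    out = np.full(values.cells.shape, CLASS_NODATA, dtype=np.uint8)
    valid = values.valid_mask()
    if table.kind == "continuous":
        data = values.cells.astype(float)
        with np.errstate(invalid="ignore"):
            for rule in table.rules:
                m = valid & rule.interval.contains_array(data)
                out[m] = rule.risk.rank
    else:
        cells = values.cells
        if categories is not None:
            lut = {int(code): name for code, name in categories.items()}
            flat_valid = valid.ravel()
            flat = cells.ravel()
            res = out.ravel()
            cls_cache: dict[int, int] = {}
            for idx in np.nonzero(flat_valid)[0]:
                code = int(flat[idx])
                if code not in cls_cache:
                    name = lut.get(code)
                    cls = (
                        classify_value(table, name)
                        if name is not None
                        else table.default_class
                    )
                    cls_cache[code] = (
                        CLASS_NODATA if cls is RiskClass.NODATA else cls.rank
                    )
                res[idx] = cls_cache[code]
        else:
            it = np.nditer(cells, flags=["multi_index", "refs_ok"])
            for cell in it:
                i, j = it.multi_index
                if not valid[i, j]:
                    continue
                cls = classify_value(table, cell.item())
                out[i, j] = CLASS_NODATA if cls is RiskClass.NODATA else cls.rank
    return values.like(out, nodata=CLASS_NODATA)


# -- registry -------------------------------------------------------------


@dataclass
class RuleRegistry:
    """All rule tables of the methodology, keyed by indicator id."""

    tables: dict[str, RuleTable] = field(default_factory=dict)
    metadata: dict[str, dict] = field(default_factory=dict)

    def __getitem__(self, indicator_id: str) -> RuleTable:
        return self.tables[indicator_id]

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self.tables

    def __len__(self) -> int:
        return len(self.tables)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RuleRegistry):
            return NotImplemented
        return self.tables == other.tables

    def validate(self) -> list[ValidationReport]:
        return [validate_rule_table(t) for t in self.tables.values()]


def _parse_bound(x) -> float:
    if isinstance(x, str):
        s = x.strip().lower()
        if s in {".inf", "inf", "+inf", "infinity"}:
            return INF
        if s in {"-.inf", "-inf", "-infinity"}:
            return -INF
    return float(x)


_CLOSURES = {
    "both": (True, True),
    "lower": (True, False),
    "upper": (False, True),
    "neither": (False, False),
}


def _rule_from_doc(doc: dict, table_id: str) -> Rule:
    try:
        risk = RiskClass.from_label(doc["class"])
    except KeyError:
        raise RuleConfigError(f"table {table_id}: rule missing 'class'") from None
    if "categories" in doc:
        return Rule(risk=risk, categories=frozenset(str(c) for c in doc["categories"]))
    if "min" not in doc or "max" not in doc:
        raise RuleConfigError(
            f"table {table_id}: continuous rule needs 'min' and 'max'"
        )
    closed = doc.get("closed", "lower")
    if closed not in _CLOSURES:
        raise RuleConfigError(f"table {table_id}: unknown closure {closed!r}")
    cl, cu = _CLOSURES[closed]
    try:
        interval = Interval(_parse_bound(doc["min"]), _parse_bound(doc["max"]), cl, cu)
    except RuleConfigError as exc:
        raise RuleConfigError(f"table {table_id}: {exc}") from None
    return Rule(risk=risk, interval=interval)


def _table_from_doc(doc: dict) -> RuleTable:
    table_id = str(doc.get("id", "?"))
    kind = doc.get("kind")
    domain = None
    if "domain" in doc:
        lo, hi = doc["domain"]
        domain = Interval(_parse_bound(lo), _parse_bound(hi), True, False)
    rules = [_rule_from_doc(r, table_id) for r in doc.get("rules", [])]
    default = RiskClass.from_label(doc.get("default_class", "LOW"))
    return RuleTable(
        indicator_id=table_id,
        kind=kind,
        rules=rules,
        units=doc.get("units"),
        name=doc.get("name", ""),
        domain=domain,
        default_class=default,
        notes=doc.get("notes", ""),
    )


def load_rule_registry(source=None) -> RuleRegistry:
    """Load a rule registry from a config document.

    ``source`` may be a path to a YAML file, a YAML string, or an
    already-parsed mapping.  With no argument the built-in default
    registry (the methodology's 17 indicator tables) is returned.
    """
    if source is None:
        ref = resources.files("palmrisk.data") / "default_rules.yaml"
        doc = yaml.safe_load(ref.read_text())
    elif isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "tables" not in doc:
        raise RuleConfigError("registry document must contain a 'tables' list")

    registry = RuleRegistry(metadata=dict(doc.get("metadata", {})))
    deferred: list[tuple[dict, str]] = []
    for tdoc in doc["tables"]:
        table_id = str(tdoc.get("id", "?"))
        if table_id in registry.tables or any(d[1] == table_id for d in deferred):
            raise RuleConfigError(f"duplicate indicator_id: {table_id}")
        if "same_rules_as" in tdoc:
            deferred.append((tdoc, table_id))
        else:
            registry.tables[table_id] = _table_from_doc(tdoc)
    for tdoc, table_id in deferred:
        ref_id = str(tdoc["same_rules_as"])
        if ref_id not in registry.tables:
            raise RuleConfigError(
                f"table {table_id}: same_rules_as references unknown table {ref_id}"
            )
        ref = registry.tables[ref_id]
        registry.tables[table_id] = RuleTable(
            indicator_id=table_id,
            kind=ref.kind,
            rules=ref.rules,  # shared on purpose: identical thresholds
            units=tdoc.get("units", ref.units),
            name=tdoc.get("name", ref.name),
            domain=ref.domain,
            default_class=ref.default_class,
            notes=tdoc.get("notes", ""),
        )
    return registry


def registry_to_doc(registry: RuleRegistry) -> dict:
    """Serialize a registry back to the config-document structure."""
    tables = []
    for table in registry.tables.values():
        tdoc: dict = {"id": table.indicator_id, "kind": table.kind}
        if table.name:
            tdoc["name"] = table.name
        if table.units:
            tdoc["units"] = table.units
        if table.kind == "continuous" and table.domain is not None:
            tdoc["domain"] = [table.domain.lower, table.domain.upper]
        if table.default_class is not RiskClass.LOW:
            tdoc["default_class"] = table.default_class.name
        rules = []
        for rule in table.rules:
            if rule.categories is not None:
                rules.append(
                    {"categories": sorted(rule.categories), "class": rule.risk.name}
                )
            else:
                iv = rule.interval
                closure = {v: k for k, v in _CLOSURES.items()}[
                    (iv.closed_lower, iv.closed_upper)
                ]
                rules.append(
                    {
                        "min": iv.lower,
                        "max": iv.upper,
                        "closed": closure,
                        "class": rule.risk.name,
                    }
                )
        tdoc["rules"] = rules
        tables.append(tdoc)
    return {"metadata": registry.metadata, "tables": tables}


def save_rule_registry(registry: RuleRegistry, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(registry_to_doc(registry), sort_keys=False, allow_unicode=True)
    )
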