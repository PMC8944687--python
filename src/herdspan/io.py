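"""Readers and writers for the delimited table formats, plus run configuration.

Formats (comma-delimited by default, tab accepted on read; decimal points
only — thousands separators like "20,528" are stripped from quoted fields):

* cohort table: header ``lactation,count``, one row per lactation.
* disposal table: header ``lactation,exits,rate,exit_fraction``.
* composition table: header ``year,total,pct_1,pct_2,pct_3,pct_4_5,...``;
  the bin scheme is recovered from the header (``pct_4_5`` = lactations
  4–5, ``pct_10p`` = 10 and more).
* yield table: header ``lactation,yield_305d`` (kg); grouped variant
  ``t_max,lactation,yield_305d``.
* mixture spec: YAML with ``label`` and a ``subcohorts`` list of
  ``{B, c, n1}`` records.
"""

from __future__ import annotations

import csv
import dataclasses
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .core import CohortSeries, DisposalSeries
from .errors import ParseError
from .heterogeneity import MixtureSpec, SubcohortSpec
from .milk import YieldSeries
from .unbinning import Bin, CompositionTable

__all__ = [
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "write_disposal",
    "read_composition",
    "write_composition",
    "read_yields",
    "write_yields",
    "read_group_yields",
    "read_mixture_spec",
    "write_mixture_spec",
]


def _rows(path) -> List[Tuple[int, List[str]]]:
    """Parsed rows with 1-based line numbers; delimiter comma or tab."""
    text = Path(path).read_text()
    if not text.strip():
        raise ParseError(f"{path}: file is empty")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    out = []
    for lineno, row in enumerate(csv.reader(text.splitlines(), delimiter=delimiter), 1):
        if row and any(cell.strip() for cell in row):
            out.append((lineno, [cell.strip() for cell in row]))
    return out


def _num(cell: str, path, lineno: int) -> float:
    try:
        return float(cell.replace(",", "").replace(" ", ""))
    except ValueError:
        raise ParseError(f"{path}:{lineno}: not a number: {cell!r}") from None


def read_cohort(path) -> CohortSeries:
    """Read a ``lactation,count`` table into a CohortSeries."""
    rows = _rows(path)
    header = [h.lower() for h in rows[0][1]]
    if header[:2] != ["lactation", "count"]:
        raise ParseError(f"{path}:1: expected header 'lactation,count'")
    t, N = [], []
    for lineno, row in rows[1:]:
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        t.append(int(_num(row[0], path, lineno)))
        n = _num(row[1], path, lineno)
        if n < 0:
            raise ParseError(f"{path}:{lineno}: negative count")
        N.append(n)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 data rows")
    for i, (a, b) in enumerate(zip(t, t[1:])):
        if b != a + 1:
            raise ParseError(f"{path}:{rows[2 + i][0]}: gap in lactation numbers")
    try:
        return CohortSeries.from_counts(N, start=t[0])
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_cohort(path, cohort: CohortSeries) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lactation", "count"])
        for t, n in zip(cohort.t, cohort.N):
            w.writerow([int(t), f"{n:.10g}"])


def write_disposal(path, disposal: DisposalSeries) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lactation", "exits", "rate", "exit_fraction"])
        for t, dN, y, dn in zip(disposal.t, disposal.dN, disposal.y, disposal.dn):
            w.writerow([int(t), f"{dN:g}", f"{y:.6g}", f"{dn:.6g}"])


_PCT_RE = re.compile(r"^pct_(\d+)(?:_(\d+)|(p))?$")


def _bins_from_header(header: Sequence[str], path) -> Tuple[Bin, ...]:
    bins: List[Bin] = []
    for name in header[2:]:
        m = _PCT_RE.match(name)
        if not m:
            raise ParseError(f"{path}:1: unrecognised bin column {name!r}")
        lo = int(m.group(1))
        if m.group(3):
            bins.append((lo, None))
        elif m.group(2):
            bins.append((lo, int(m.group(2))))
        else:
            bins.append((lo, lo))
    return tuple(bins)


def _bin_column(b: Bin) -> str:
    lo, hi = b
    if hi is None:
        return f"pct_{lo}p"
    return f"pct_{lo}" if lo == hi else f"pct_{lo}_{hi}"


def read_composition(path) -> CompositionTable:
    """Read a per-year herd composition table; validates percentage sums."""
    rows = _rows(path)
    header = [h.lower() for h in rows[0][1]]
    if header[:2] != ["year", "total"]:
        raise ParseError(f"{path}:1: expected header starting 'year,total'")
    bins = _bins_from_header(header, path)
    years, totals, pcts = [], [], []
    for lineno, row in rows[1:]:
        if len(row) != 2 + len(bins):
            raise ParseError(f"{path}:{lineno}: expected {2 + len(bins)} columns")
        years.append(int(_num(row[0], path, lineno)))
        totals.append(_num(row[1], path, lineno))
        pct = tuple(_num(c, path, lineno) for c in row[2:])
        if abs(sum(pct) - 100.0) > 0.5:
            raise ParseError(
                f"{path}:{lineno}: year {years[-1]} percentages sum to "
                f"{sum(pct):g}, not 100 +/- 0.5"
            )
        pcts.append(pct)
    try:
        return CompositionTable(
            bins=bins, years=tuple(years), totals=tuple(totals),
            percentages=tuple(pcts),
        )
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_composition(path, table: CompositionTable) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["year", "total"] + [_bin_column(b) for b in table.bins])
        for year, total, pct in zip(table.years, table.totals, table.percentages):
            w.writerow([year, f"{total:g}"] + [f"{p:.6g}" for p in pct])


def read_yields(path) -> YieldSeries:
    rows = _rows(path)
    header = [h.lower() for h in rows[0][1]]
    if header[:2] != ["lactation", "yield_305d"]:
        raise ParseError(f"{path}:1: expected header 'lactation,yield_305d'")
    t, ym = [], []
    for lineno, row in rows[1:]:
        t.append(int(_num(row[0], path, lineno)))
        ym.append(_num(row[1], path, lineno))
    try:
        return YieldSeries(t=t, ym=ym)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_yields(path, series: YieldSeries) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["lactation", "yield_305d"])
        for t, y in zip(series.t, series.ym):
            w.writerow([int(t), f"{y:.6g}"])


def read_group_yields(path) -> Dict[int, YieldSeries]:
    """Read a ``t_max,lactation,yield_305d`` table into per-group series."""
    rows = _rows(path)
    header = [h.lower() for h in rows[0][1]]
    if header[:3] != ["t_max", "lactation", "yield_305d"]:
        raise ParseError(f"{path}:1: expected header 't_max,lactation,yield_305d'")
    groups: Dict[int, List[Tuple[int, float]]] = {}
    for lineno, row in rows[1:]:
        tm = int(_num(row[0], path, lineno))
        groups.setdefault(tm, []).append(
            (int(_num(row[1], path, lineno)), _num(row[2], path, lineno))
        )
    out: Dict[int, YieldSeries] = {}
    for tm, pts in groups.items():
        pts.sort()
        out[tm] = YieldSeries(t=[p[0] for p in pts], ym=[p[1] for p in pts])
    return out


def read_mixture_spec(path) -> MixtureSpec:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "subcohorts" not in data:
        raise ParseError(f"{path}: expected a mapping with a 'subcohorts' list")
    subs = []
    for i, rec in enumerate(data["subcohorts"], 1):
        unknown = set(rec) - {"B", "c", "n1"}
        if unknown:
            raise ParseError(f"{path}: subcohort {i}: unknown keys {sorted(unknown)}")
        try:
            subs.append(SubcohortSpec(B=float(rec["B"]), c=float(rec["c"]),
                                      n1=float(rec["n1"])))
        except KeyError as exc:
            raise ParseError(f"{path}: subcohort {i}: missing key {exc}") from None
    return MixtureSpec(subcohorts=tuple(subs), label=str(data.get("label", "")))


def write_mixture_spec(path, spec: MixtureSpec) -> None:
    data = {
        "label": spec.label,
        "subcohorts": [{"B": s.B, "c": s.c, "n1": s.n1} for s in spec.subcohorts],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a command-line run; fully serializable."""

    command: str = ""
    input: Optional[str] = None
    output: Optional[str] = None
    convention: str = "destination"
    fit_window: Optional[Tuple[int, int]] = None
    b_assumed: float = 0.45
    horizon: int = 20
    seed: Optional[int] = None
    verbosity: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.fit_window is not None:
            d["fit_window"] = list(self.fit_window)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        if data.get("fit_window") is not None:
            data = dict(data)
            data["fit_window"] = tuple(data["fit_window"])
        return cls(**data)
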