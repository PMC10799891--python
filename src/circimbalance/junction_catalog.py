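"""Consensus back-splice junction cataloguing.

Circular RNAs are identified by the back-splice junction (BSJ) that
closes them. Individual detection tools disagree substantially, so the
high-confidence catalogue keeps only junctions that (a) reach a minimum
read count in a minimum number of individuals within at least one tool's
quantification, and (b) are called by a minimum number of tools. Each
catalogued BSJ is then annotated with its host gene, matched to the
forward-splice junctions (FSJs) flanking it, and summarised through a
per-sample circular-to-linear ratio.

Coordinates are 1-based inclusive throughout; a junction's canonical
display form is ``chrom:start-end:strand``. Inputs in a half-open
dialect must be converted at the reader boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from circimbalance.containers import CountMatrix, as_frame

INTERGENIC = "intergenic"

COORD_COLUMNS = ["chrom", "start", "end", "strand"]

_JUNCTION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+):(?P<strand>[+-])$")


@dataclass(frozen=True, order=True)
class JunctionId:
    """Genomic identity of a splice junction (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "BSJ"  # BSJ | FSJ

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"junction start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.kind not in ("BSJ", "FSJ"):
            raise ValueError(f"kind must be BSJ or FSJ, got {self.kind!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str, kind: str = "BSJ") -> "JunctionId":
        m = _JUNCTION_RE.match(text)
        if m is None:
            raise ValueError(f"cannot parse junction string {text!r}")
        return cls(
            chrom=m.group("chrom"),
            start=int(m.group("start")),
            end=int(m.group("end")),
            strand=m.group("strand"),
            kind=kind,
        )


@dataclass
class ConsensusReport:
    """Outcome of the consensus + abundance filtering of BSJ calls."""

    n_initial: int
    n_retained: int
    retained: set[JunctionId] = field(default_factory=set)
    tool_support: dict[JunctionId, int] = field(default_factory=dict)

    @property
    def percent_retained(self) -> float:
        if self.n_initial <= 0:
            raise ValueError("percent_retained undefined for empty initial catalogue")
        return 100.0 * self.n_retained / self.n_initial


def _call_table_key(table: pd.DataFrame) -> pd.MultiIndex:
    missing = [c for c in COORD_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"call table missing coordinate columns {missing}")
    return pd.MultiIndex.from_frame(table[COORD_COLUMNS])


def _sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in COORD_COLUMNS and c != "tool"]


def consensus_filter(
    tool_calls: Mapping[str, pd.DataFrame],
    min_tools: int = 2,
    min_count: int = 2,
    min_individuals: int = 2,
) -> ConsensusReport:
    """Build the high-confidence BSJ catalogue from per-tool call tables.

    A junction is retained iff at least ``min_individuals`` samples show a
    read count of at least ``min_count`` within a single tool's table
    (counts are never summed across tools), and the junction is called by
    at least ``min_tools`` tools.

    Parameters
    ----------
    tool_calls
        Mapping from tool name to a call table with columns
        ``chrom, start, end, strand`` plus one count column per sample.
        All tables must cover the same sample set.
    """
    if not tool_calls:
        raise ValueError("at least one tool call table is required")
    if min_tools > len(tool_calls):
        raise ValueError(
            f"min_tools={min_tools} exceeds number of supplied tools ({len(tool_calls)})"
        )

    sample_sets = {tool: frozenset(_sample_columns(t)) for tool, t in tool_calls.items()}
    reference = next(iter(sample_sets.values()))
    for tool, cols in sample_sets.items():
        if cols != reference:
            raise ValueError(f"tool {tool!r} reports a different sample set")

    support: dict[tuple, int] = {}
    abundant: set[tuple] = set()
    for tool, table in tool_calls.items():
        keys = _call_table_key(table)
        counts = table[_sample_columns(table)].to_numpy()
        ok = (counts >= min_count).sum(axis=1) >= min_individuals
        for key, passed in zip(keys, ok):
            support[key] = support.get(key, 0) + 1
            if passed:
                abundant.add(key)

    retained = {
        JunctionId(chrom=k[0], start=int(k[1]), end=int(k[2]), strand=k[3], kind="BSJ")
        for k, n in support.items()
        if n >= min_tools and k in abundant
    }
    tool_support = {
        JunctionId(chrom=k[0], start=int(k[1]), end=int(k[2]), strand=k[3], kind="BSJ"): n
        for k, n in support.items()
    }
    return ConsensusReport(
        n_initial=len(support),
        n_retained=len(retained),
        retained=retained,
        tool_support=tool_support,
    )


@dataclass
class FsjMatchResult:
    """BSJ-to-flanking-FSJ correspondence.

    ``pairs`` maps each matched BSJ to its per-sample linear signal, the
    mean count over the FSJs sharing one of its boundaries. BSJs with no
    corresponding FSJ are listed in ``unmatched``.
    """

    pairs: dict[JunctionId, pd.Series]
    matched_fsjs: dict[JunctionId, list[JunctionId]]
    unmatched: set[JunctionId]
    fraction_unmatched: float


def match_fsj(
    bsj_set: Iterable[JunctionId],
    fsj_counts: "CountMatrix | pd.DataFrame",
) -> FsjMatchResult:
    """Match BSJs to the forward junctions that share a splice boundary.

    An FSJ corresponds to a BSJ when, on the same chromosome and strand,
    the FSJ ends at the BSJ start or starts at the BSJ end. The linear
    signal of a matched BSJ is the per-sample mean of its flanking FSJs.
    """
    bsjs = list(bsj_set)
    if not bsjs:
        raise ValueError("fraction_unmatched is undefined for an empty BSJ set")

    frame = as_frame(fsj_counts)
    fsj_ids = [JunctionId.parse(str(ix), kind="FSJ") for ix in frame.index]

    by_end: dict[tuple, list[int]] = {}
    by_start: dict[tuple, list[int]] = {}
    for i, f in enumerate(fsj_ids):
        by_end.setdefault((f.chrom, f.strand, f.end), []).append(i)
        by_start.setdefault((f.chrom, f.strand, f.start), []).append(i)

    pairs: dict[JunctionId, pd.Series] = {}
    matched_fsjs: dict[JunctionId, list[JunctionId]] = {}
    unmatched: set[JunctionId] = set()
    values = frame.to_numpy(dtype=float)
    for b in bsjs:
        rows = list(by_end.get((b.chrom, b.strand, b.start), []))
        rows += by_start.get((b.chrom, b.strand, b.end), [])
        if not rows:
            unmatched.add(b)
            continue
        pairs[b] = pd.Series(values[rows].mean(axis=0), index=frame.columns)
        matched_fsjs[b] = [fsj_ids[i] for i in rows]

    return FsjMatchResult(
        pairs=pairs,
        matched_fsjs=matched_fsjs,
        unmatched=unmatched,
        fraction_unmatched=len(unmatched) / len(bsjs),
    )


def circular_ratio(bsj_count, linear_signal):
    """Per-sample circular-to-linear proportion 2B / (2B + L).

    The back-splice count is doubled because a circular molecule
    contributes one junction where the linear form contributes two.
    Bounded in [0, 1]; defined as 0 where both signals are 0 (no
    evidence of either form).
    """
    b = np.asarray(bsj_count, dtype=float)
    lin = np.asarray(linear_signal, dtype=float)
    if (b < 0).any() or (lin < 0).any():
        raise ValueError("counts and linear signals must be non-negative")
    denom = 2.0 * b + lin
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, 2.0 * b / np.where(denom > 0, denom, 1.0), 0.0)
    return ratio


def annotate_host(
    junctions: Iterable[JunctionId],
    gene_model: pd.DataFrame,
) -> dict[JunctionId, str]:
    """Assign each junction to the gene whose span contains it.

    The host is the gene (same strand) whose interval contains both
    junction boundaries. When several genes qualify, the smallest
    containing span wins; remaining ties break lexicographically by gene
    id. Junctions contained in no gene map to ``"intergenic"``.
    """
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in gene_model.columns]
    if missing:
        raise ValueError(f"gene model missing columns {missing}")
    for row_number, row in enumerate(gene_model.itertuples(index=False)):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise ValueError(f"malformed gene model row {row_number}: non-integer bounds")
        if start > end or row.strand not in ("+", "-"):
            raise ValueError(f"malformed gene model row {row_number}: {tuple(row)}")

    by_key: dict[tuple, list[tuple[int, int, str]]] = {}
    for row in gene_model.itertuples(index=False):
        by_key.setdefault((row.chrom, row.strand), []).append(
            (int(row.start), int(row.end), str(row.gene_id))
        )

    hosts: dict[JunctionId, str] = {}
    for j in junctions:
        candidates = [
            (end - start, gene_id)
            for start, end, gene_id in by_key.get((j.chrom, j.strand), [])
            if start <= j.start and j.end <= end
        ]
        hosts[j] = min(candidates)[1] if candidates else INTERGENIC
    return hosts


def catalog_to_frame(report: ConsensusReport) -> pd.DataFrame:
    """Tabulate a consensus catalogue with canonical junction strings."""
    rows = [
        {
            "junction": str(j),
            "chrom": j.chrom,
            "start": j.start,
            "end": j.end,
            "strand": j.strand,
            "n_tools": report.tool_support.get(j, 0),
        }
        for j in sorted(report.retained)
    ]
    return pd.DataFrame(rows, columns=["junction", "chrom", "start", "end", "strand", "n_tools"])
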