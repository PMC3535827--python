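"""Tabulated text report.

One TSV per run: a ``#`` comment block echoing every run parameter (so each
report is self-describing), a single header line, then one row per oligo.
Primer-set rows share a ``product_id`` and appear in forward / probe /
reverse order; all-oligos rows are sorted by (start, length, strand).
Coordinates are 1-based inclusive; temperatures and GC percentages carry one
decimal.  For RNA runs every reported sequence maps T back to U.

Output is byte-identical across reruns on identical input and parameters.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import logging
import sys
from pathlib import Path
from typing import Sequence, Union

from .consensus import ConsensusSequence
from .search import Oligo, PrimerSet, SearchParams

log = logging.getLogger(__name__)

COLUMNS = [
    "role",
    "sequence",
    "start",
    "end",
    "strand",
    "length",
    "degenerate_count",
    "degeneracy",
    "gc_min",
    "gc_max",
    "td_min",
    "td_max",
    "tm_nn",
    "tm_on_modal",
    "product_id",
    "product_len",
    "product_seq",
]

Results = Union[Sequence[PrimerSet], Sequence[Oligo]]


def _seq_out(seq: str, rna: bool) -> str:
    return seq.replace("T", "U") if rna else seq


def _oligo_row(
    o: Oligo, rna: bool, product_id: str = "", product_len: str = "",
    product_seq: str = "",
) -> dict[str, str]:
    t = o.thermo
    return {
        "role": o.role,
        "sequence": _seq_out(o.seq, rna),
        "start": str(o.start + 1),
        "end": str(o.end),
        "strand": o.strand,
        "length": str(o.length),
        "degenerate_count": str(o.degenerate_count),
        "degeneracy": str(o.degeneracy),
        "gc_min": f"{t.gc_min:.1f}",
        "gc_max": f"{t.gc_max:.1f}",
        "td_min": f"{float(t.td_min):.1f}",
        "td_max": f"{float(t.td_max):.1f}",
        "tm_nn": "" if t.tm_nn is None else f"{t.tm_nn:.1f}",
        "tm_on_modal": str(int(t.tm_on_modal)),
        "product_id": product_id,
        "product_len": product_len,
        "product_seq": product_seq,
    }


def report_rows(results: Results, rna: bool = False) -> list[dict[str, str]]:
    """Flatten search results (primer sets or plain oligos) to report rows."""
    rows: list[dict[str, str]] = []
    for item in results:
        if isinstance(item, Oligo):
            rows.append(_oligo_row(item, rna))
    sets = [s for s in results if isinstance(s, PrimerSet)]
    for k, ps in enumerate(sets, start=1):
        pid = f"P{k}"
        plen = str(ps.product_len)
        rows.append(
            _oligo_row(ps.forward, rna, pid, plen, _seq_out(ps.product_seq, rna))
        )
        if ps.probe is not None:
            rows.append(_oligo_row(ps.probe, rna, pid, plen))
        rows.append(_oligo_row(ps.reverse, rna, pid, plen))
    return rows


def _param_comments(cons: ConsensusSequence, params: SearchParams, rna: bool) -> list[str]:
    lines = ["# consoligo report"]
    lines.append(f"# consensus_length={len(cons)}")
    lines.append(f"# consensus_source={cons.source}")
    lines.append(f"# alphabet={'RNA' if rna else 'DNA'}")
    for key, value in sorted(dataclasses.asdict(params).items()):
        if key == "window_size" and value is None:
            value = params.resolved_window()
        if isinstance(value, bool):
            value = str(value).lower()
        lines.append(f"# param {key}={value}")
    return lines


def render_report(
    results: Results,
    cons: ConsensusSequence,
    params: SearchParams,
    rna: bool = False,
) -> str:
    """Render the full report to a string (deterministic)."""
    buf = io.StringIO()
    for line in _param_comments(cons, params, rna):
        buf.write(line + "\n")
    buf.write("\t".join(COLUMNS) + "\n")
    rows = report_rows(results, rna=rna)
    if not rows:
        log.warning("no valid oligos found; report contains no data rows")
    for row in rows:
        buf.write("\t".join(row[c] for c in COLUMNS) + "\n")
    return buf.getvalue()


def write_report(
    results: Results,
    cons: ConsensusSequence,
    params: SearchParams,
    path: str | Path,
    rna: bool = False,
) -> None:
    """Write the TSV report; path ``-`` streams to stdout."""
    text = render_report(results, cons, params, rna=rna)
    if str(path) == "-":
        sys.stdout.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")


def read_report(path: str | Path) -> tuple[dict[str, str], list[dict[str, str]]]:
    """Parse a report back into (parameter metadata, data rows).

    Used for round-trip verification; numeric fields stay strings exactly as
    printed.
    """
    meta: dict[str, str] = {}
    data_lines: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("param "):
                key, _, value = body[len("param "):].partition("=")
                meta[key] = value
            elif "=" in body:
                key, _, value = body.partition("=")
                meta[key] = value
            continue
        data_lines.append(line)
    reader = csv.DictReader(data_lines, delimiter="\t")
    return meta, list(reader)
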