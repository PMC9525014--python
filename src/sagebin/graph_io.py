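"""Readers and writers for the binner's on-disk formats.

The binning unit is the GFA *segment* (the assembly-graph "edge" in
Flye terminology): long-read assemblies represent most contigs as a
single graph edge, so segments are binned directly and P-lines
(contig paths) are ignored.

Supported formats:

* GFA v1 — ``S`` and ``L`` lines; per-segment read-coverage tags in the
  ``dp:i:``, ``dp:f:`` or ``KC:i:`` dialects.
* FASTA contig sequences.
* MetaBAT2/VAMB-style depth tables (``contigName``, ``contigLen``,
  ``totalAvgDepth``, then alternating per-sample mean/variance columns).
* Single-copy marker-gene CSVs, two dialects (one ``contig,marker`` pair
  per row, or ``contig,"m1;m2;..."``).
* Two-column bin-assignment and gold-label TSVs.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_NONACGTN = re.compile(r"[^ACGTN]")


class GraphParseError(ValueError):
    """Raised on malformed GFA content in strict mode."""


@dataclass
class AssemblyGraph:
    """Assembly graph: contigs ``C``, undirected adjacency with per-edge
    read coverage ``rc`` (number of reads supporting the junction).

    Edges are stored as frozen unordered pairs; self-loops are never
    stored, so the adjacency used for neighborhood sampling is loop-free.
    Absent edges have coverage 0.
    """

    contig_ids: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    edge_coverage: dict[frozenset, float] = field(default_factory=dict)

    @property
    def edges(self) -> set[frozenset]:
        return set(self.edge_coverage)

    @property
    def contig_length(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def coverage(self, u: str, v: str) -> float:
        return self.edge_coverage.get(frozenset((u, v)), 0.0)

    def neighbors(self, u: str) -> list[str]:
        out = []
        for e in self.edge_coverage:
            if u in e:
                (v,) = e - {u}
                out.append(v)
        return sorted(out)

    def add_edge(self, u: str, v: str, coverage: float) -> None:
        if u == v:
            return
        key = frozenset((u, v))
        # duplicate links (reverse orientation etc.) collapse, keeping max rc
        prev = self.edge_coverage.get(key)
        self.edge_coverage[key] = coverage if prev is None else max(prev, coverage)

    def validate(self) -> None:
        known = set(self.contig_ids)
        for e in self.edge_coverage:
            if not e <= known:
                raise GraphParseError(f"edge endpoint(s) {set(e) - known} unknown")
            if self.edge_coverage[e] <= 0:
                raise GraphParseError(f"edge {sorted(e)} has non-positive coverage")


@dataclass
class DepthTable:
    """Per-contig abundance: mean base coverage and variance per sample."""

    means: dict[str, list[float]]
    variances: dict[str, list[float]]
    n_samples: int

    def require(self, contig_ids) -> None:
        missing = [c for c in contig_ids if c not in self.means]
        if missing:
            raise KeyError(f"depth table missing {len(missing)} contig(s): {missing[:10]}")


@dataclass
class MarkerTable:
    """Multiset of single-copy marker genes per contig.

    A contig absent from ``markers`` carries no markers. The universe is
    the set of all distinct marker ids seen anywhere.
    """

    markers: dict[str, Counter] = field(default_factory=dict)

    @property
    def universe(self) -> set[str]:
        u: set[str] = set()
        for c in self.markers.values():
            u |= set(c)
        return u

    def __bool__(self) -> bool:
        return bool(self.markers)


_COV_TAG = re.compile(r"\b(?:dp:i:(\d+)|dp:f:([0-9.eE+-]+)|KC:i:(\d+))\b")


def _segment_coverage(fields: list[str], seq_len: int) -> float | None:
    for f in fields:
        m = _COV_TAG.fullmatch(f)
        if m:
            if m.group(1) is not None:
                return float(m.group(1))
            if m.group(2) is not None:
                return float(m.group(2))
            # KC = k-mer count; convert to depth by segment length
            return float(m.group(3)) / max(seq_len, 1)
    return None


def read_gfa(path, strict: bool = False) -> AssemblyGraph:
    """Parse a GFA v1 assembly graph.

    Segments become contigs. Links become undirected edges; a link's
    coverage is the mean of its endpoint segments' coverage tags. When no
    coverage information exists anywhere in the file, every edge gets
    coverage 1.0, i.e. all edges have the same relevance.

    In strict mode malformed or dangling lines raise
    :class:`GraphParseError` naming the line number; in lenient mode they
    are skipped with a logged warning.
    """
    graph = AssemblyGraph()
    seg_cov: dict[str, float] = {}
    links: list[tuple[int, str, str]] = []

    def fail(lineno: int, msg: str) -> None:
        if strict:
            raise GraphParseError(f"line {lineno}: {msg}")
        logger.warning("GFA line %d skipped: %s", lineno, msg)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line[0] in "#HP":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3 or not fields[1]:
                    fail(lineno, f"malformed S line: {line!r}")
                    continue
                name, seq = fields[1], fields[2]
                if name in graph.sequences:
                    fail(lineno, f"duplicate segment {name!r}")
                    continue
                seq = "*" if seq == "*" else _NONACGTN.sub("N", seq.upper())
                graph.contig_ids.append(name)
                graph.sequences[name] = "" if seq == "*" else seq
                cov = _segment_coverage(fields[3:], len(seq))
                if cov is not None:
                    seg_cov[name] = cov
            elif fields[0] == "L":
                if len(fields) < 5:
                    fail(lineno, f"malformed L line: {line!r}")
                    continue
                # links may carry their own coverage tag; it wins over
                # the endpoint-mean fallback
                link_cov = _segment_coverage(fields[5:], 1)
                links.append((lineno, fields[1], fields[3], link_cov))

    for lineno, u, v, link_cov in links:
        if u not in graph.sequences or v not in graph.sequences:
            fail(lineno, f"link references unknown segment: {u!r} -- {v!r}")
            continue
        if u == v:
            continue  # self-loops excluded from the sampling adjacency
        if link_cov is not None:
            cov = link_cov
        elif u in seg_cov or v in seg_cov:
            vals = [seg_cov[s] for s in (u, v) if s in seg_cov]
            cov = sum(vals) / len(vals)
        else:
            cov = 1.0
        graph.add_edge(u, v, cov)
    graph.validate()
    return graph


def read_fasta(path) -> dict[str, str]:
    """Read FASTA; headers truncated at the first whitespace, sequences
    uppercased with non-ACGTN characters mapped to N."""
    out: dict[str, str] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        if rec.id in out:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        out[rec.id] = _NONACGTN.sub("N", str(rec.seq).upper())
    if n == 0:
        raise ValueError(f"empty FASTA file: {path}")
    return out


def read_depth(path) -> DepthTable:
    """Read a MetaBAT2/VAMB depth table (TSV or CSV).

    Layout: contigName, contigLen, totalAvgDepth, then one (mean, var)
    column pair per sample, so ``S = (ncol - 3) / 2``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 5:
        raise ValueError(
            f"depth table needs >=5 columns (contigName, contigLen, "
            f"totalAvgDepth, mean/var pairs); got {df.shape[1]}"
        )
    n_sample_cols = df.shape[1] - 3
    if n_sample_cols % 2 != 0:
        raise ValueError(f"odd number of per-sample columns ({n_sample_cols}); expected mean/var pairs")
    s = n_sample_cols // 2
    vals = df.iloc[:, 3:].to_numpy()
    try:
        vals = vals.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric depth value in {path}: {exc}") from exc
    if (vals < 0).any():
        raise ValueError("negative depth or variance in depth table")
    means: dict[str, list[float]] = {}
    variances: dict[str, list[float]] = {}
    for i, contig in enumerate(df.iloc[:, 0].astype(str)):
        means[contig] = [float(vals[i, 2 * j]) for j in range(s)]
        variances[contig] = [float(vals[i, 2 * j + 1]) for j in range(s)]
    return DepthTable(means=means, variances=variances, n_samples=s)


def read_markers(path) -> MarkerTable:
    """Read a marker-gene CSV in either accepted dialect.

    Dialect A: one ``contig_id,marker_id`` row per observation.
    Dialect B: ``contig_id,"m1;m2;..."`` with a ;-joined (or ,-joined,
    quoted) marker list. Multiset semantics: the same marker appearing
    twice on a contig counts twice.
    """
    import csv

    table = MarkerTable()
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            contig = row[0].strip()
            cells = [c.strip() for c in row[1:] if c.strip()]
            if not cells:
                raise ValueError(
                    "unrecognised marker CSV row; accepted forms: "
                    "'contig,marker' or 'contig,\"m1;m2\"'"
                )
            ids: list[str] = []
            for cell in cells:
                ids.extend(m.strip() for m in cell.split(";") if m.strip())
            counter = table.markers.setdefault(contig, Counter())
            counter.update(ids)
    return table


def read_labels(path) -> dict[str, str]:
    """Read a two-column contig -> genome label TSV (no header required;
    a header line starting with 'contig' is skipped)."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"label file needs 2 tab-separated columns, got: {line!r}")
            if parts[0].lower() in ("contig", "contigname", "contig_id"):
                continue
            labels[parts[0]] = parts[1]
    return labels


def write_bins(assignment, path) -> None:
    """Write a two-column ``contig_id<TAB>bin_id`` TSV sorted by contig id.

    No filtering by bin size is applied.
    """
    contig_to_bin = assignment.contig_to_bin if hasattr(assignment, "contig_to_bin") else dict(assignment)
    if not contig_to_bin:
        logger.warning("writing empty bin assignment to %s", path)
    with open(path, "w") as fh:
        for contig in sorted(contig_to_bin):
            fh.write(f"{contig}\t{contig_to_bin[contig]}\n")


def read_bins(path) -> dict[str, str]:
    """Read a bin TSV written by :func:`write_bins`."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            contig, bin_id = line.split("\t")
            out[contig] = bin_id
    return out
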