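"""Readers and writers for the TSV formats the tool consumes and emits.

Two expression dialects are supported:

``dream4``
    Tab-separated; header row starts with ``Time`` followed by gene names;
    blank lines separate independent time series (perturbation experiments).
    The time column is dropped after parsing but kept as ``time_labels``.

``plain``
    One matrix per file, genes in rows, time points in columns, no header.
    An optional non-numeric first field per row is taken as the gene name;
    otherwise names ``G1..Gp`` are assigned.

Gold standards are edge-list TSVs ``regulator  target  {1,0}`` with an
optional fourth sign column (``+``/``-``); ranked predictions are written as
``regulator  target  sign  score`` sorted by descending score.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np

from .datatypes import (
    ACTIVATION,
    INHIBITION,
    DiscretizedDataset,
    GoldStandard,
    Pair,
    ScoredEdge,
    TimeSeriesDataset,
    rank_edges,
)

PathLike = Union[str, Path]

_SIGN_TOKENS = {"+": ACTIVATION, "+1": ACTIVATION, "1": ACTIVATION,
                "-": INHIBITION, "-1": INHIBITION}


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _parse_float(token: str, path: PathLike, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}:{lineno}: non-numeric cell {token!r}"
        ) from None


def read_expression(path: PathLike, dialect: str = "dream4") -> TimeSeriesDataset:
    """Load a continuous expression matrix file into a :class:`TimeSeriesDataset`."""
    if dialect == "dream4":
        return _read_dream4(path)
    if dialect == "plain":
        return _read_plain(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_dream4(path: PathLike) -> TimeSeriesDataset:
    lines = Path(path).read_text().splitlines()
    header: Optional[List[str]] = None
    blocks: List[List[Tuple[int, List[str]]]] = []
    current: List[Tuple[int, List[str]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        fields = [f.strip().strip('"') for f in line.split("\t")]
        if fields[0].lower() == "time":
            if header is None:
                header = fields[1:]
            elif fields[1:] != header:
                raise ParseError(f"{path}:{lineno}: repeated header does not match first header")
            continue
        current.append((lineno, fields))
    if current:
        blocks.append(current)
    if header is None:
        raise ParseError(f"{path}: missing 'Time' header row")
    if len(set(header)) != len(header):
        raise ValueError(f"{path}: duplicate gene name in header")
    p = len(header)
    series, labels = [], []
    for block in blocks:
        mat, times = [], []
        for lineno, fields in block:
            if len(fields) != p + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {p + 1} columns, found {len(fields)}"
                )
            times.append(_parse_float(fields[0], path, lineno))
            mat.append([_parse_float(f, path, lineno) for f in fields[1:]])
        series.append(np.array(mat, dtype=float).T)  # rows -> genes
        labels.append(times)
    return TimeSeriesDataset(gene_names=header, series=series, time_labels=labels)


def _read_plain(path: PathLike) -> TimeSeriesDataset:
    rows: List[List[float]] = []
    names: List[str] = []
    named: Optional[bool] = None
    width: Optional[int] = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        has_name = not _is_number(fields[0])
        if named is None:
            named = has_name
        elif named != has_name:
            raise ParseError(f"{path}:{lineno}: inconsistent gene-name column")
        if named:
            names.append(fields[0].strip())
            fields = fields[1:]
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ParseError(
                f"{path}:{lineno}: ragged row, expected {width} values, found {len(fields)}"
            )
        rows.append([_parse_float(f, path, lineno) for f in fields])
    if not rows:
        raise ParseError(f"{path}: empty expression file")
    if not named:
        names = [f"G{i + 1}" for i in range(len(rows))]
    return TimeSeriesDataset(gene_names=names, series=[np.array(rows, dtype=float)])


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_expression(data: TimeSeriesDataset, path: PathLike,
                     dialect: str = "dream4") -> None:
    """Inverse of :func:`read_expression`; floats printed with 6 significant digits."""
    out: List[str] = []
    if dialect == "dream4":
        out.append("\t".join(["Time"] + data.gene_names))
        for s, mat in enumerate(data.series):
            if s > 0:
                out.append("")
            labels = (data.time_labels[s] if data.time_labels
                      else list(range(mat.shape[1])))
            for t in range(mat.shape[1]):
                out.append("\t".join([_fmt(labels[t])] + [_fmt(v) for v in mat[:, t]]))
    elif dialect == "plain":
        if data.n_series != 1:
            raise ValueError("plain dialect holds exactly one series per file")
        for g, name in enumerate(data.gene_names):
            out.append("\t".join([name] + [_fmt(v) for v in data.series[0][g]]))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    Path(path).write_text("\n".join(out) + "\n")


def _fmt(value: float) -> str:
    if float(value) == int(value):
        return str(int(value))
    return f"{value:.6g}"


def read_discretized(path: PathLike, n_bins: int,
                     dialect: str = "dream4") -> DiscretizedDataset:
    """Load a pre-binned matrix (integer levels) in either expression dialect."""
    ts = read_expression(path, dialect=dialect)
    return DiscretizedDataset(
        gene_names=ts.gene_names,
        series=[mat.astype(int) for mat in ts.series],
        n_bins=n_bins,
    )


def write_discretized(data: DiscretizedDataset, path: PathLike,
                      dialect: str = "dream4") -> None:
    ts = TimeSeriesDataset(gene_names=data.gene_names,
                           series=[mat.astype(float) for mat in data.series])
    write_expression(ts, path, dialect=dialect)


def read_tf_list(path: PathLike) -> List[str]:
    """One gene name per line; order preserved, duplicates rejected."""
    names = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate transcription factor name")
    return names


def write_tf_list(tfs: Sequence[str], path: PathLike) -> None:
    Path(path).write_text("\n".join(tfs) + "\n")


def read_gold_standard(path: PathLike) -> GoldStandard:
    """Edge-list TSV: regulator, target, presence flag {1,0}, optional sign."""
    edges: set = set()
    signs: Dict[Pair, int] = {}
    n_edge_rows = 0
    n_signed_rows = 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) not in (3, 4):
            raise ParseError(f"{path}:{lineno}: expected 3 or 4 columns, found {len(fields)}")
        reg, tgt, flag = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if flag not in ("0", "1"):
            raise ParseError(f"{path}:{lineno}: presence flag must be 0 or 1, got {flag!r}")
        if flag == "0":
            continue
        n_edge_rows += 1
        edges.add((reg, tgt))
        if len(fields) == 4 and fields[3].strip():
            token = fields[3].strip()
            if token not in _SIGN_TOKENS:
                raise ParseError(f"{path}:{lineno}: unknown sign {token!r}")
            signs[(reg, tgt)] = _SIGN_TOKENS[token]
            n_signed_rows += 1
    if n_signed_rows and n_signed_rows != n_edge_rows:
        raise ParseError(f"{path}: sign column present for some edges but not all")
    signed = n_signed_rows > 0
    return GoldStandard(edges=edges, signs=signs if signed else None, signed=signed)


def write_gold_standard(gold: GoldStandard, path: PathLike) -> None:
    lines = []
    for reg, tgt in sorted(gold.edges):
        row = [reg, tgt, "1"]
        if gold.signed:
            row.append("+" if gold.signs[(reg, tgt)] == ACTIVATION else "-")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


_SIGN_CHAR = {ACTIVATION: "+", INHIBITION: "-", 0: "."}
_CHAR_SIGN = {v: k for k, v in _SIGN_CHAR.items()}


def write_ranked_edges(edges: Sequence[ScoredEdge], path: PathLike) -> None:
    """Ranked TSV: score non-increasing, ties broken by (regulator, target)."""
    lines = [
        f"{e.regulator}\t{e.target}\t{_SIGN_CHAR[e.sign]}\t{e.score:.6g}"
        for e in rank_edges(edges)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ranked_edges(path: PathLike) -> List[ScoredEdge]:
    out = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, found {len(fields)}")
        if fields[2] not in _CHAR_SIGN:
            raise ParseError(f"{path}:{lineno}: unknown sign {fields[2]!r}")
        out.append(ScoredEdge(fields[0], fields[1], _CHAR_SIGN[fields[2]],
                              _parse_float(fields[3], path, lineno)))
    return out


def export_pepn_structure(edges: Sequence[ScoredEdge], path: PathLike,
                          decay_prob: Optional[Mapping[str, float]] = None) -> nx.DiGraph:
    """Dump the extended-Petri-net structure implied by an edge set as GraphML.

    Every regulator becomes a control place; every target an output place
    with one synthesis and one decay transition.  Activating edges connect
    their control place to the synthesis transition via a read arc,
    inhibiting edges via an inhibitory arc; the decay transition carries the
    estimated per-gene decay probability when one is supplied.
    """
    g = nx.DiGraph()
    targets = sorted({e.target for e in edges})
    regulators = sorted({e.regulator for e in edges})
    for reg in regulators:
        g.add_node(f"control:{reg}", kind="control_place", gene=reg)
    for tgt in targets:
        g.add_node(f"place:{tgt}", kind="output_place", gene=tgt)
        g.add_node(f"synthesis:{tgt}", kind="synthesis_transition", gene=tgt)
        dp = float(decay_prob.get(tgt, 0.0)) if decay_prob else 0.0
        g.add_node(f"decay:{tgt}", kind="decay_transition", gene=tgt, decay_prob=dp)
        g.add_edge(f"synthesis:{tgt}", f"place:{tgt}", arc="produce")
        g.add_edge(f"place:{tgt}", f"decay:{tgt}", arc="consume")
    for e in edges:
        arc = "read" if e.sign == ACTIVATION else "inhibit"
        g.add_edge(f"control:{e.regulator}", f"synthesis:{e.target}",
                   arc=arc, score=float(e.score))
    nx.write_graphml(g, path)
    return g
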