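"""Plain-text interchange formats for every pipeline artifact.

All formats are tab-separated, self-describing (header rows) and
locale-independent (period decimal separator); floats are written with
enough digits that write-then-read is an identity to ~1e-12.  Parse
failures raise :class:`ParseError` naming the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .classifier import LabeledImageSet
from .connectivity import ConnectivityGraph, Recording
from .embedding import EmbeddingMatrix
from .imaging import GraphImage

__all__ = [
    "ParseError",
    "write_recording", "read_recording",
    "write_adjacency", "read_adjacency",
    "write_edge_list", "read_edge_list",
    "write_embedding", "read_embedding",
    "write_image", "read_image",
    "write_manifest", "read_manifest", "load_image_set",
    "write_results", "read_results",
    "write_config", "read_config",
]

_FLOAT_FMT = "%.17g"
RESULTS_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """Malformed interchange file; message includes the 1-based line number."""


def _fail(path, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}: line {lineno}: {msg}")


def _parse_floats(path, lineno: int, fields: list[str]) -> list[float]:
    try:
        return [float(f) for f in fields]
    except ValueError:
        _fail(path, lineno, f"expected numeric fields, got {fields!r}")


def _read_lines(path) -> list[str]:
    text = Path(path).read_text()
    return [ln for ln in text.splitlines() if ln.strip() != ""]


# ---- recordings ------------------------------------------------------

def write_recording(path, rec: Recording) -> None:
    """Header row of channel ids, then one row per channel (columns = samples)."""
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channel_ids) + "\n")
        np.savetxt(fh, rec.samples, fmt=_FLOAT_FMT, delimiter="\t")


def read_recording(path, sampling_rate: float, has_header: bool = True) -> Recording:
    lines = _read_lines(path)
    if not lines:
        _fail(path, 1, "empty file")
    start = 0
    if has_header:
        ids = lines[0].split("\t")
        start = 1
    rows = []
    for off, ln in enumerate(lines[start:]):
        rows.append(_parse_floats(path, start + off + 1, ln.split("\t")))
    if not rows:
        _fail(path, start + 1, "no data rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        _fail(path, start + 1, "rows have inconsistent lengths (truncated file?)")
    samples = np.array(rows)
    if not has_header:
        ids = [f"ch{i:03d}" for i in range(samples.shape[0])]
    if len(ids) != samples.shape[0]:
        _fail(path, 1, f"{len(ids)} channel ids but {samples.shape[0]} rows")
    return Recording(ids, samples, sampling_rate)


# ---- adjacency / edge list ------------------------------------------

def write_adjacency(path, graph: ConnectivityGraph) -> None:
    """Header row of node ids, then the square weight matrix."""
    with open(path, "w") as fh:
        fh.write("\t".join(graph.node_ids) + "\n")
        np.savetxt(fh, graph.weights, fmt=_FLOAT_FMT, delimiter="\t")


def read_adjacency(path) -> ConnectivityGraph:
    lines = _read_lines(path)
    if not lines:
        _fail(path, 1, "empty file")
    ids = lines[0].split("\t")
    n = len(ids)
    if len(lines) - 1 != n:
        _fail(path, len(lines), f"expected {n} matrix rows, found {len(lines) - 1}")
    rows = []
    for i, ln in enumerate(lines[1:]):
        fields = ln.split("\t")
        if len(fields) != n:
            _fail(path, i + 2, f"expected {n} columns, found {len(fields)}")
        rows.append(_parse_floats(path, i + 2, fields))
    return ConnectivityGraph(ids, np.array(rows))


def write_edge_list(path, graph: ConnectivityGraph) -> None:
    """Upper-triangle weighted edge list: node_a TAB node_b TAB weight."""
    n = graph.n_nodes
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                fh.write(f"{graph.node_ids[i]}\t{graph.node_ids[j]}\t"
                         f"{graph.weights[i, j]:.17g}\n")


def read_edge_list(path) -> ConnectivityGraph:
    """Rebuild the full symmetric matrix from an upper-triangle edge list."""
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != ["node_a", "node_b", "weight"]:
        _fail(path, 1, "missing 'node_a\\tnode_b\\tweight' header")
    ids: list[str] = []
    index: dict[str, int] = {}
    edges = []
    for i, ln in enumerate(lines[1:]):
        fields = ln.split("\t")
        if len(fields) != 3:
            _fail(path, i + 2, f"expected 3 fields, found {len(fields)}")
        a, b, w = fields[0], fields[1], _parse_floats(path, i + 2, [fields[2]])[0]
        for node in (a, b):
            if node not in index:
                index[node] = len(ids)
                ids.append(node)
        edges.append((index[a], index[b], w))
    n = len(ids)
    weights = np.zeros((n, n))
    for a, b, w in edges:
        weights[a, b] = weights[b, a] = w
    return ConnectivityGraph(ids, weights)


# ---- embedding table -------------------------------------------------

def write_embedding(path, emb: EmbeddingMatrix) -> None:
    d = emb.dim
    with open(path, "w") as fh:
        fh.write("node_id\t" + "\t".join(f"dim_{j}" for j in range(d)) + "\n")
        for node_id, row in zip(emb.node_ids, emb.vectors):
            fh.write(node_id + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_embedding(path) -> EmbeddingMatrix:
    lines = _read_lines(path)
    if not lines or not lines[0].startswith("node_id\t"):
        _fail(path, 1, "missing embedding header")
    d = len(lines[0].split("\t")) - 1
    ids, rows = [], []
    for i, ln in enumerate(lines[1:]):
        fields = ln.split("\t")
        if len(fields) != d + 1:
            _fail(path, i + 2, f"expected {d + 1} fields, found {len(fields)}")
        ids.append(fields[0])
        rows.append(_parse_floats(path, i + 2, fields[1:]))
    return EmbeddingMatrix(ids, np.array(rows))


# ---- image tensors ---------------------------------------------------

def write_image(path, img: GraphImage) -> None:
    """Channel-blocked text: '# channel c' header before each r x r block."""
    with open(path, "w") as fh:
        fh.write(f"# graph image: resolution={img.resolution} channels={img.n_channels}\n")
        for c in range(img.n_channels):
            fh.write(f"# channel {c}\n")
            np.savetxt(fh, img.channels[:, :, c], fmt="%d", delimiter="\t")


def read_image(path) -> GraphImage:
    lines = _read_lines(path)
    if not lines or not lines[0].startswith("# graph image:"):
        _fail(path, 1, "missing graph-image header")
    blocks: list[list[list[float]]] = []
    for i, ln in enumerate(lines[1:]):
        if ln.startswith("# channel"):
            blocks.append([])
        elif ln.startswith("#"):
            _fail(path, i + 2, f"unexpected comment {ln!r}")
        else:
            if not blocks:
                _fail(path, i + 2, "pixel row before any '# channel' header")
            blocks[-1].append(_parse_floats(path, i + 2, ln.split("\t")))
    r = len(blocks[0])
    for b in blocks:
        if len(b) != r or any(len(row) != r for row in b):
            _fail(path, 2, "channel blocks are not square or differ in size")
    channels = np.stack([np.array(b, dtype=np.int64) for b in blocks], axis=-1)
    return GraphImage(channels, r)


# ---- cohort manifest -------------------------------------------------

def write_manifest(path, subject_ids: list[str], labels, paths: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tlabel\tpath\n")
        for sid, lab, p in zip(subject_ids, labels, paths):
            fh.write(f"{sid}\t{int(lab)}\t{p}\n")


def read_manifest(path) -> tuple[list[str], np.ndarray, list[str]]:
    lines = _read_lines(path)
    if not lines or lines[0].split("\t") != ["subject_id", "label", "path"]:
        _fail(path, 1, "missing 'subject_id\\tlabel\\tpath' header")
    sids, labels, paths = [], [], []
    for i, ln in enumerate(lines[1:]):
        fields = ln.split("\t")
        if len(fields) != 3:
            _fail(path, i + 2, f"expected 3 fields, found {len(fields)}")
        sids.append(fields[0])
        try:
            labels.append(int(fields[1]))
        except ValueError:
            _fail(path, i + 2, f"label must be an integer, got {fields[1]!r}")
        paths.append(fields[2])
    return sids, np.array(labels), paths


def load_image_set(manifest_path) -> LabeledImageSet:
    """Read a manifest and the image files it points to (paths relative to it)."""
    sids, labels, paths = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    images = []
    for p in paths:
        full = Path(p) if Path(p).is_absolute() else base / p
        images.append(read_image(full).channels)
    return LabeledImageSet(np.stack(images), labels, sids)


# ---- results / config ------------------------------------------------

def write_results(path, results: dict) -> None:
    payload = {"schema_version": RESULTS_SCHEMA_VERSION, **results}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


def write_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
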