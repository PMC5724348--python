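"""FASTA input, PHYLIP distance-matrix output and TSV helpers."""

from __future__ import annotations

import gzip
from dataclasses import asdict, dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = ["RunConfig", "read_fasta", "write_phylip", "read_phylip"]


@dataclass
class RunConfig:
    """Run parameters echoed into TSV output headers for provenance."""

    k: int | None = None
    w: int | None = None
    ratio: float = 10.0
    x: int = 4
    pool_directions: bool = True
    q_override: float | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def header_lines(self) -> list[str]:
        from . import __version__

        items = {**{f: v for f, v in asdict(self).items() if f != "extra"}, **self.extra}
        body = " ".join(f"{key}={val}" for key, val in items.items() if val is not None)
        return [f"# kpeakdist {__version__}", f"# {body}"]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (label, uppercased sequence) records; gzip transparent.

    Raises on an empty file, a file not starting with a FASTA header (with
    the offending line number) and on duplicate labels.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: expected FASTA header, got {line[:30]!r}")
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    with _open_text(path) as handle:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    labels = [lab for lab, _ in records]
    if len(set(labels)) != len(labels):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise ValueError(f"{path}: duplicate FASTA labels: {dupes}")
    for lab, seq in records:
        if not seq:
            raise ValueError(f"{path}: record {lab!r} has an empty sequence")
    return records


def write_phylip(matrix, path, na: str = "NA", drop_failed: bool = False) -> None:
    """Square PHYLIP distance matrix with relaxed (whitespace-free) labels.

    Failed pairs are written as the ``na`` token (non-standard; consumers
    that cannot handle it can pass ``drop_failed=True`` to remove any taxon
    involved in a failed pair instead).
    """
    labels = list(matrix.labels)
    values = np.asarray(matrix.values, dtype=float)
    if drop_failed:
        keep = ~np.isnan(values).any(axis=1)
        labels = [lab for lab, k_ in zip(labels, keep) if k_]
        values = values[np.ix_(keep, keep)]
    width = max(10, max((len(l) for l in labels), default=10)) + 2
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, values):
            cells = [na if np.isnan(v) else f"{v:.6f}" for v in row]
            fh.write(lab.ljust(width) + " ".join(cells) + "\n")


def read_phylip(path, na: str = "NA"):
    """Read back a square PHYLIP matrix written by :func:`write_phylip`."""
    from .estimator import DistanceMatrix

    with open(path) as fh:
        n = int(fh.readline().strip())
        labels, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            labels.append(parts[0])
            rows.append([np.nan if tok == na else float(tok) for tok in parts[1:]])
    return DistanceMatrix(labels, np.asarray(rows, dtype=float))
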