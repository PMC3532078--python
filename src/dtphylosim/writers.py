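"""FASTA and parameter-file output (and the matching re-parsers).

The parameter file is a line-oriented text format: header fields, then one
block per edge in the canonical order (terminal edges first, by leaf
appearance; internal edges top-down from the root).  Matrix entries are
printed with 17 significant digits so re-parsing reproduces the exact
double-precision values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix_sampler import SubstitutionMatrix
from .models import RootDistribution, get_model
from .sequence_evolver import Alignment, SimulationRecord

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_params",
    "read_params",
    "ParamsFormatError",
]


class ParamsFormatError(ValueError):
    """Raised when a parameter file cannot be re-parsed."""


def write_fasta(aln: Alignment, path) -> None:
    """Write the alignment as FASTA, one record per leaf in Newick order."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in aln.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Alignment:
    """Read a FASTA alignment back; record order is preserved."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("FASTA records have unequal lengths")
    return Alignment(sequences=seqs, length=lengths.pop())


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_params(rec: SimulationRecord, path) -> None:
    """Write the full parameter set of a simulation as plain text."""
    lines = ["# simulation parameters"]
    lines.append(f"model: {rec.model}")
    if rec.seed is not None:
        lines.append(f"seed: {rec.seed}")
    lines.append(f"tree: {rec.tree_text}")
    lines.append(
        "root_distribution: "
        + " ".join(_fmt(p) for p in rec.root_distribution.as_array())
    )
    lines.append(f"n_edges: {len(rec.edge_matrices)}")
    for label, matrix in rec.edge_matrices:
        lines.append(f"edge: {label}")
        lines.append(f"length: {_fmt(matrix.branch_length)}")
        lines.append("matrix:")
        for row in matrix.entries:
            lines.append(" ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> SimulationRecord:
    """Re-parse a parameter file into a :class:`SimulationRecord`."""
    raw = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]

    fields: dict[str, str] = {}
    i = 0
    while i < len(raw) and not raw[i].startswith("edge:"):
        key, _, value = raw[i].partition(":")
        fields[key.strip()] = value.strip()
        i += 1
    for required in ("model", "tree", "root_distribution", "n_edges"):
        if required not in fields:
            raise ParamsFormatError(f"missing header field {required!r}")

    model = get_model(fields["model"])
    pi = RootDistribution(tuple(float(v) for v in fields["root_distribution"].split()))
    seed = int(fields["seed"]) if "seed" in fields else None

    edge_matrices: list[tuple[str, SubstitutionMatrix]] = []
    while i < len(raw):
        if not raw[i].startswith("edge:"):
            raise ParamsFormatError(f"expected an 'edge:' line, got {raw[i]!r}")
        label = raw[i].partition(":")[2].strip()
        if not raw[i + 1].startswith("length:"):
            raise ParamsFormatError(f"edge {label!r}: missing length line")
        length = float(raw[i + 1].partition(":")[2])
        if raw[i + 2] != "matrix:":
            raise ParamsFormatError(f"edge {label!r}: missing matrix block")
        rows = [[float(v) for v in raw[i + 3 + r].split()] for r in range(4)]
        entries = np.array(rows, dtype=float)
        if entries.shape != (4, 4):
            raise ParamsFormatError(f"edge {label!r}: matrix is not 4x4")
        edge_matrices.append(
            (label, SubstitutionMatrix(entries, model, length))
        )
        i += 7

    if len(edge_matrices) != int(fields["n_edges"]):
        raise ParamsFormatError(
            f"header announces {fields['n_edges']} edges, found {len(edge_matrices)}"
        )
    return SimulationRecord(
        model=model.name,
        tree_text=fields["tree"],
        root_distribution=pi,
        edge_matrices=edge_matrices,
        seed=seed,
    )
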