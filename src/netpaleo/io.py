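"""Readers and writers for the plain-text formats the pipeline touches.

All tabular files are tab-separated with a header row; lines starting
with ``#`` are comments.  Writers sort rows so that write→read
round-trips are byte-deterministic.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

from .data import (
    BranchOmegaTable,
    GeneOmegaTable,
    InteractionNetwork,
    PresenceMatrix,
    canonical_pair,
)
from .phylogeny import SPECIES

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _rows(path, expected_cols: int, header: list[str] | None = None):
    """Yield (lineno, fields) for non-comment rows, validating width."""
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if not saw_header:
                saw_header = True
                if header is not None and fields != header:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {header}, got {fields}"
                    )
                continue
            if len(fields) != expected_cols or any(f == "" for f in fields):
                raise ParseError(
                    f"{path}:{lineno}: expected {expected_cols} non-empty "
                    f"tab-separated fields, got {fields!r}"
                )
            yield lineno, fields


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

NETWORK_HEADER = ["gene_a", "gene_b"]


def read_network(path) -> InteractionNetwork:
    """Read a two-column edge list into a simple undirected graph.

    Self-loop rows and duplicate rows (in either orientation) are
    dropped, with counts logged; an empty file yields an empty network
    with a warning.
    """
    edges: set = set()
    n_self = n_dup = 0
    for lineno, (a, b) in (
        (ln, fs) for ln, fs in _rows(path, 2, header=NETWORK_HEADER)
    ):
        if a == b:
            n_self += 1
            continue
        pair = canonical_pair(a, b)
        if pair in edges:
            n_dup += 1
            continue
        edges.add(pair)
    if n_self or n_dup:
        log.info(
            "read_network(%s): dropped %d self-loop and %d duplicate rows",
            path,
            n_self,
            n_dup,
        )
    if not edges:
        log.warning("read_network(%s): no edges", path)
    return InteractionNetwork(edges=sorted(edges))


def write_network(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(NETWORK_HEADER) + "\n")
        for a, b in network.pairs():
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------


def read_presence_matrix(path) -> PresenceMatrix:
    """Read a gene × species 0/1 matrix; header must name the 8 species."""
    header = ["gene"] + list(SPECIES)
    entries: dict[str, list[int]] = {}
    for lineno, fields in _rows(path, len(header), header=header):
        gene, values = fields[0], fields[1:]
        row = []
        for sp, v in zip(SPECIES, values):
            if v not in ("0", "1"):
                raise ParseError(
                    f"{path}:{lineno}: presence value for {sp} must be 0 or 1, got {v!r}"
                )
            row.append(int(v))
        if gene in entries:
            raise ParseError(f"{path}:{lineno}: duplicate gene row {gene!r}")
        entries[gene] = row
    import pandas as pd

    frame = pd.DataFrame.from_dict(entries, orient="index", columns=list(SPECIES))
    return PresenceMatrix(frame)


def write_presence_matrix(matrix: PresenceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(SPECIES) + "\n")
        frame = matrix.frame.sort_index()
        for gene, row in frame.iterrows():
            fh.write(gene + "\t" + "\t".join("1" if v else "0" for v in row) + "\n")


# ---------------------------------------------------------------------------
# omega tables
# ---------------------------------------------------------------------------

BRANCH_OMEGA_HEADER = ["gene", "branch", "omega"]
GENE_OMEGA_HEADER = ["gene", "omega"]


def _parse_omega(path, lineno, text) -> float:
    try:
        omega = float(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: omega {text!r} is not a number") from None
    if not omega >= 0:
        raise ParseError(f"{path}:{lineno}: omega must be nonnegative, got {omega}")
    return omega


def read_branch_omega(path) -> BranchOmegaTable:
    """Read per-gene per-branch ω rows; duplicate (gene, branch) rows error."""
    entries: dict[str, dict[str, float]] = {}
    for lineno, (gene, branch, omega) in _rows(path, 3, header=BRANCH_OMEGA_HEADER):
        row = entries.setdefault(gene, {})
        if branch in row:
            raise ParseError(f"{path}:{lineno}: duplicate entry ({gene!r}, {branch!r})")
        row[branch] = _parse_omega(path, lineno, omega)
    return BranchOmegaTable(entries)


def write_branch_omega(table: BranchOmegaTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(BRANCH_OMEGA_HEADER) + "\n")
        for gene, branch, omega in table.items():
            fh.write(f"{gene}\t{branch}\t{omega!r}\n")


def read_gene_omega(path) -> GeneOmegaTable:
    entries: dict[str, float] = {}
    for lineno, (gene, omega) in _rows(path, 2, header=GENE_OMEGA_HEADER):
        if gene in entries:
            raise ParseError(f"{path}:{lineno}: duplicate gene {gene!r}")
        entries[gene] = _parse_omega(path, lineno, omega)
    return GeneOmegaTable(entries)


def write_gene_omega(table: GeneOmegaTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_OMEGA_HEADER) + "\n")
        for gene, omega in table.items():
            fh.write(f"{gene}\t{omega!r}\n")


# ---------------------------------------------------------------------------
# annotations (flat gene -> term table, for enrichment)
# ---------------------------------------------------------------------------

ANNOTATION_HEADER = ["gene", "term"]


def read_annotations(path) -> dict[str, frozenset[str]]:
    """Read a flat two-column gene→term table into gene → set of terms."""
    anns: dict[str, set[str]] = {}
    for _lineno, (gene, term) in _rows(path, 2, header=ANNOTATION_HEADER):
        anns.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in anns.items()}


def write_annotations(annotations: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
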