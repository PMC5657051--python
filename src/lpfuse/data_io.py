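"""Input parsing, identifier reconciliation and dataset filtering.

All tabular inputs are tab-separated UTF-8 text; lines starting with ``#``
and blank lines are skipped.  Identifier joining across sources is by exact
string match after stripping surrounding whitespace — ids differing only by
case are distinct.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO*]*$", re.IGNORECASE)


class ParseError(ValueError):
    """Raised for malformed input files; message carries the line number."""


@dataclass
class ProteinRecord:
    """One protein: id, optional sequence, Pfam domain set, GO term set."""

    id: str
    sequence: str | None = None
    domains: set[str] = field(default_factory=set)
    go_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if self.sequence is not None and not _AA_RE.match(self.sequence):
            bad = next(c for c in self.sequence if not _AA_RE.match(c))
            raise ValueError(f"non-amino-acid character {bad!r} in sequence of {self.id}")


@dataclass
class InteractionTable:
    """Known lncRNA-protein interaction pairs with deterministic id indices."""

    pairs: set[tuple[str, str]]
    lncrna_index: tuple[str, ...]
    protein_index: tuple[str, ...]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "InteractionTable":
        pset = set(pairs)
        return cls(
            pairs=pset,
            lncrna_index=tuple(sorted({l for l, _ in pset})),
            protein_index=tuple(sorted({p for _, p in pset})),
        )

    def partner_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {l: 0 for l in self.lncrna_index}
        for l, _ in self.pairs:
            counts[l] += 1
        return counts


@dataclass
class ScoredEdgeList:
    """STRING-style scored protein-protein edges, confidence in [0, 999]."""

    edges: list[tuple[str, str, int]]


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into sequence-bearing records.

    The id is the header token up to the first whitespace.  An entry with no
    sequence lines yields a record with an empty sequence and a warning.
    """
    # Reject a sequence line before any header with a line number; SeqIO
    # silently skips such preambles.
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(f"{path}: line {lineno}: sequence data before any FASTA header")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            logger.warning("FASTA entry %s has an empty sequence", rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def read_pair_table(path: str | Path, kind: str):
    """Read a two-column TSV as interactions or as per-id annotation sets.

    kind="interactions" -> InteractionTable (duplicates collapsed);
    kind="annotations"  -> dict id -> set of tokens.
    """
    if kind not in ("interactions", "annotations"):
        raise ValueError(f"unknown kind {kind!r}")
    rows: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        rows.append((parts[0], parts[1]))
    if kind == "interactions":
        return InteractionTable.from_pairs(rows)
    mapping: dict[str, set[str]] = {}
    for key, token in rows:
        mapping.setdefault(key, set()).add(token)
    return mapping


def read_string_edges(path: str | Path) -> ScoredEdgeList:
    """Read a 3-column STRING-style edge file (protein_a, protein_b, score)."""
    edges: list[tuple[str, str, int]] = []
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != 3:
            raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
        a, b, raw_score = parts
        try:
            score = int(raw_score)
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer score {raw_score!r}") from exc
        if not 0 <= score <= 999:
            raise ParseError(f"{path}: line {lineno}: score {score} outside [0, 999]")
        if a == b:
            continue
        edges.append((a, b, score))
    return ScoredEdgeList(edges=edges)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for l, p in sorted(table.pairs):
            fh.write(f"{l}\t{p}\n")


def filter_interactions(table: InteractionTable, min_partners: int = 2) -> InteractionTable:
    """Drop lncRNAs with fewer than ``min_partners`` distinct protein partners.

    A single pass: held-out validation of an interaction needs at least one
    remaining partner, so single-partner lncRNAs cannot be evaluated.  The
    protein index is rebuilt from surviving pairs; proteins are not re-checked.
    """
    if min_partners < 1:
        raise ValueError("min_partners must be >= 1")
    counts = table.partner_counts()
    keep = {pair for pair in table.pairs if counts[pair[0]] >= min_partners}
    return InteractionTable.from_pairs(keep)


@dataclass
class Universe:
    """Aligned id universes plus per-source missing-protein flags."""

    protein_index: tuple[str, ...]
    lncrna_index: tuple[str, ...]
    missing: dict[str, tuple[str, ...]]


def align_universe(
    records: Iterable[ProteinRecord],
    interactions: InteractionTable,
    edges: ScoredEdgeList | None = None,
    go_map: Mapping[str, set] | None = None,
    pfam_map: Mapping[str, set] | None = None,
) -> Universe:
    """Build the prediction universe: proteins appearing in the interactions.

    Proteins missing from a similarity source are retained and flagged; they
    get zero off-diagonal rows in that source's matrix so network fusion can
    fill in from the other sources.  Ordering is lexicographic, hence
    deterministic across runs.
    """
    if not interactions.pairs:
        raise ValueError("interaction table is empty: nothing to predict")
    protein_index = tuple(sorted({p for _, p in interactions.pairs}))
    lncrna_index = tuple(sorted({l for l, _ in interactions.pairs}))
    missing: dict[str, tuple[str, ...]] = {}
    with_seq = {r.id for r in records if r.sequence}
    missing["Seqs"] = tuple(p for p in protein_index if p not in with_seq)
    if go_map is not None:
        annotated = {p for p, terms in go_map.items() if terms}
        missing["Go"] = tuple(p for p in protein_index if p not in annotated)
    if pfam_map is not None:
        annotated = {p for p, doms in pfam_map.items() if doms}
        missing["Pfam"] = tuple(p for p in protein_index if p not in annotated)
    if edges is not None:
        in_string = {a for a, _, _ in edges.edges} | {b for _, b, _ in edges.edges}
        missing["String"] = tuple(p for p in protein_index if p not in in_string)
    for source, ids in missing.items():
        if ids:
            logger.warning("%d proteins missing from source %s: %s", len(ids), source, ids[:5])
    return Universe(protein_index=protein_index, lncrna_index=lncrna_index, missing=missing)
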