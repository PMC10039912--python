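"""Readers, writers and harmonization rules for association data and networks.

The file formats are deliberately plain: two-column TSV for association
tables (``entity<TAB>annotation``), diagnosis records
(``patient<TAB>icd10_code``) and ID-mapping tables (``source<TAB>target``);
networks are stored either as a TSV edge list
(``source<TAB>target<TAB>weight`` plus ``#node`` lines for isolated nodes)
or as GraphML with a ``weight`` edge attribute.

Harmonization implements the usual cleanup applied to heterogeneous disease
data before network construction: truncation of ICD-10 codes to the
three-character level, removal of whole ICD-10 chapters that do not encode
diseases proper (pregnancy, injuries, external causes, ...), a minimum
incidence filter, vocabulary cross-mapping, and pruning of overly general
terms from hierarchical vocabularies such as HPO.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "DiagnosisRecords",
    "MappingTable",
    "TermHierarchy",
    "ICD10_CHAPTER_RANGES",
    "DEFAULT_EXCLUDED_CHAPTERS",
    "read_association_table",
    "write_association_table",
    "read_diagnosis_records",
    "write_diagnosis_records",
    "read_mapping_table",
    "apply_id_mapping",
    "compute_mappability",
    "harmonize_icd10",
    "prune_hierarchy_levels",
    "read_network",
    "write_network",
]


# --------------------------------------------------------------------------
# domain containers
# --------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """Map from entities (diseases, drugs, genes, ...) to annotation sets.

    ``entries[e]`` is the annotation set :math:`A_e` used to build
    Jaccard-index networks.  After :meth:`clean`, no entity carries an empty
    annotation set — entities without annotations are treated as missing
    data and removed.
    """

    entity_vocabulary: str
    annotation_type: str
    entries: dict[str, set[str]] = field(default_factory=dict)

    def clean(self) -> int:
        """Drop entities with empty annotation sets; return the drop count."""
        empty = [e for e, anns in self.entries.items() if not anns]
        for e in empty:
            del self.entries[e]
        if empty:
            logger.info("dropped %d entities with empty annotation sets", len(empty))
        return len(empty)

    @property
    def n_entities(self) -> int:
        return len(self.entries)

    def copy(self) -> "AssociationTable":
        return AssociationTable(
            self.entity_vocabulary,
            self.annotation_type,
            {e: set(a) for e, a in self.entries.items()},
        )


@dataclass
class DiagnosisRecords:
    """Patient-level diagnosis codes; ``N`` is the total patient count."""

    patients: dict[str, set[str]] = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.patients)

    def incidences(self) -> dict[str, int]:
        """Number of patients diagnosed with each code."""
        counts: dict[str, int] = {}
        for codes in self.patients.values():
            for c in codes:
                counts[c] = counts.get(c, 0) + 1
        return counts


@dataclass
class MappingTable:
    """Set of (source_id, target_id) pairs between two vocabularies.

    A source term may map to zero, one, or several targets; mappings are
    generally lossy and unmapped terms are dropped by consumers.
    """

    source_vocabulary: str
    target_vocabulary: str
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def targets_of(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, set()).add(t)
        return out


@dataclass
class TermHierarchy:
    """Parent-child edges over a term vocabulary (e.g., the HPO hierarchy)."""

    edges: set[tuple[str, str]] = field(default_factory=set)

    def depths(self) -> dict[str, int]:
        """Minimum depth of every term (roots at level 0).

        Terms with several parents take the minimum depth over all paths.
        Raises ``ValueError`` on a cyclic hierarchy.
        """
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term hierarchy contains a cycle")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        depth: dict[str, int] = {}
        for root in roots:
            for node, d in nx.single_source_shortest_path_length(g, root).items():
                if node not in depth or d < depth[node]:
                    depth[node] = d
        return depth


# --------------------------------------------------------------------------
# TSV tables
# --------------------------------------------------------------------------

def _read_two_column_tsv(path: str | Path) -> tuple[tuple[str, str], list[tuple[str, str]]]:
    """Return (header, rows) of a strict two-column TSV file."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row") from None
        if len(header) != 2:
            raise ValueError(f"{path}: header must have exactly 2 columns, got {len(header)}")
        rows: list[tuple[str, str]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields, got {len(row)}")
            a, b = row[0].strip(), row[1].strip()
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty field")
            rows.append((a, b))
    return (header[0].strip(), header[1].strip()), rows


def read_association_table(path: str | Path) -> AssociationTable:
    """Read a two-column ``entity<TAB>annotation`` TSV into an AssociationTable.

    Duplicate rows are deduplicated; the header names become the entity
    vocabulary and annotation type.  Malformed rows raise ``ValueError``
    naming the offending line.
    """
    (entity_col, annotation_col), rows = _read_two_column_tsv(path)
    entries: dict[str, set[str]] = {}
    for entity, annotation in rows:
        entries.setdefault(entity, set()).add(annotation)
    table = AssociationTable(entity_col, annotation_col, entries)
    if not rows:
        logger.warning("%s: no data rows after header", path)
    table.clean()
    return table


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([table.entity_vocabulary, table.annotation_type])
        for entity in sorted(table.entries):
            for annotation in sorted(table.entries[entity]):
                writer.writerow([entity, annotation])


def read_diagnosis_records(path: str | Path) -> DiagnosisRecords:
    """Read a ``patient<TAB>icd10_code`` TSV."""
    _, rows = _read_two_column_tsv(path)
    patients: dict[str, set[str]] = {}
    for patient, code in rows:
        patients.setdefault(patient, set()).add(code)
    return DiagnosisRecords(patients)


def write_diagnosis_records(records: DiagnosisRecords, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["patient", "icd10_code"])
        for patient in sorted(records.patients):
            for code in sorted(records.patients[patient]):
                writer.writerow([patient, code])


def read_mapping_table(path: str | Path) -> MappingTable:
    """Read a ``source<TAB>target`` TSV; duplicate pairs collapse to one."""
    (src_col, tgt_col), rows = _read_two_column_tsv(path)
    return MappingTable(src_col, tgt_col, set(rows))


# --------------------------------------------------------------------------
# vocabulary mapping
# --------------------------------------------------------------------------

def apply_id_mapping(
    table: AssociationTable, mapping: MappingTable, side: str
) -> AssociationTable:
    """Translate entity or annotation IDs through a vocabulary mapping.

    One-to-many mappings expand to all targets; entities mapping to the same
    target have their annotation sets unioned.  Unmapped IDs are dropped
    (and counted in the log) rather than raising — vocabulary mappings are
    lossy by nature.
    """
    if side not in ("entity", "annotation"):
        raise ValueError(f"side must be 'entity' or 'annotation', got {side!r}")
    own_vocab = table.entity_vocabulary if side == "entity" else table.annotation_type
    if mapping.source_vocabulary != own_vocab:
        raise ValueError(
            f"mapping source vocabulary {mapping.source_vocabulary!r} does not "
            f"match table {side} vocabulary {own_vocab!r}"
        )
    targets = mapping.targets_of()
    dropped = 0
    if side == "entity":
        entries: dict[str, set[str]] = {}
        for entity, anns in table.entries.items():
            tgt = targets.get(entity)
            if not tgt:
                dropped += 1
                continue
            for t in tgt:
                entries.setdefault(t, set()).update(anns)
        out = AssociationTable(mapping.target_vocabulary, table.annotation_type, entries)
    else:
        entries = {}
        for entity, anns in table.entries.items():
            mapped: set[str] = set()
            for a in anns:
                tgt = targets.get(a)
                if tgt:
                    mapped.update(tgt)
                else:
                    dropped += 1
            entries[entity] = mapped
        out = AssociationTable(table.entity_vocabulary, mapping.target_vocabulary, entries)
    if dropped:
        logger.info("apply_id_mapping: dropped %d unmapped %s ids", dropped, side)
    out.clean()
    return out


def compute_mappability(source_terms: Iterable[str], mapping: MappingTable) -> float:
    """Percentage of source terms with at least one target in the mapping."""
    terms = set(source_terms)
    if not terms:
        raise ValueError("source_terms must be non-empty")
    mapped_sources = {s for s, _ in mapping.pairs}
    return 100.0 * len(terms & mapped_sources) / len(terms)


# --------------------------------------------------------------------------
# ICD-10 harmonization
# --------------------------------------------------------------------------

# Chapter membership resolved by code ranges on three-character codes.
ICD10_CHAPTER_RANGES: dict[str, tuple[str, str]] = {
    "XV": ("O00", "O99"),    # pregnancy, childbirth and the puerperium
    "XVI": ("P00", "P96"),   # conditions originating in the perinatal period
    "XVIII": ("R00", "R99"),  # symptoms, signs, abnormal findings
    "XIX": ("S00", "T98"),   # injury, poisoning, external-cause consequences
    "XX": ("V01", "Y98"),    # external causes of morbidity and mortality
    "XXI": ("Z00", "Z99"),   # factors influencing health status
    "XXII": ("U00", "U99"),  # codes for special purposes
}

DEFAULT_EXCLUDED_CHAPTERS: frozenset[str] = frozenset(ICD10_CHAPTER_RANGES)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[A-Za-z0-9]{1,4})?$")


def _in_excluded_chapter(
    code3: str, excluded: Iterable[str], ranges: Mapping[str, tuple[str, str]]
) -> bool:
    for chapter in excluded:
        lo, hi = ranges[chapter]
        if lo <= code3 <= hi:
            return True
    return False


def harmonize_icd10(
    records: DiagnosisRecords,
    min_incidence: int = 5,
    excluded_chapters: Iterable[str] | None = None,
    chapter_ranges: Mapping[str, tuple[str, str]] | None = None,
) -> DiagnosisRecords:
    """Harmonize mixed-granularity ICD-10 diagnosis records.

    In this order: (1) truncate every code to the three-character level,
    (2) remove codes falling in the excluded chapters, (3) remove diseases
    with incidence below ``min_incidence``.  Incidence filtering runs last
    because incidence is only well-defined at the final code granularity.
    Patients are never removed, so ``N`` is preserved.  The operation is
    idempotent.
    """
    excluded = set(DEFAULT_EXCLUDED_CHAPTERS if excluded_chapters is None else excluded_chapters)
    ranges = dict(ICD10_CHAPTER_RANGES if chapter_ranges is None else chapter_ranges)
    unknown = excluded - set(ranges)
    if unknown:
        raise ValueError(f"excluded chapters without a code range: {sorted(unknown)}")

    truncated: dict[str, set[str]] = {}
    for patient, codes in records.patients.items():
        out: set[str] = set()
        for code in codes:
            if not _ICD10_RE.match(code):
                raise ValueError(f"patient {patient!r}: invalid ICD-10 code {code!r}")
            code3 = code[:3]
            if not _in_excluded_chapter(code3, excluded, ranges):
                out.add(code3)
        truncated[patient] = out

    counts: dict[str, int] = {}
    for codes in truncated.values():
        for c in codes:
            counts[c] = counts.get(c, 0) + 1
    rare = {c for c, n in counts.items() if n < min_incidence}
    if rare:
        logger.info("harmonize_icd10: removed %d diseases below incidence %d", len(rare), min_incidence)
    return DiagnosisRecords({p: codes - rare for p, codes in truncated.items()})


# --------------------------------------------------------------------------
# hierarchy pruning
# --------------------------------------------------------------------------

def prune_hierarchy_levels(
    table: AssociationTable, hierarchy: TermHierarchy, levels_removed: int
) -> AssociationTable:
    """Remove annotations from the top ``levels_removed`` hierarchy levels.

    A term's level is its minimum depth over all paths from a root (roots
    are level 0).  Annotation IDs absent from the hierarchy pass through
    unchanged (counted in the log).  Entities left with no annotations are
    dropped.
    """
    if levels_removed < 0:
        raise ValueError("levels_removed must be >= 0")
    depth = hierarchy.depths()
    unknown = 0
    entries: dict[str, set[str]] = {}
    for entity, anns in table.entries.items():
        kept: set[str] = set()
        for a in anns:
            d = depth.get(a)
            if d is None:
                unknown += 1
                kept.add(a)
            elif d >= levels_removed:
                kept.add(a)
        entries[entity] = kept
    if unknown:
        logger.info("prune_hierarchy_levels: %d annotation ids not in hierarchy", unknown)
    out = AssociationTable(table.entity_vocabulary, table.annotation_type, entries)
    out.clean()
    return out


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

def _check_simple(g: nx.Graph, where: str) -> None:
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValueError(f"{where}: self-loop at {loops[0][0]!r}")


def write_network(g: nx.Graph, path: str | Path, dialect: str = "tsv") -> None:
    """Write a weighted network as a TSV edge list or GraphML.

    The TSV dialect serializes weights with 17 significant digits so that a
    write/read round trip reproduces them bit-exactly; isolated nodes are
    kept via ``#node`` lines and the vocabulary via a ``#vocabulary`` line.
    """
    path = Path(path)
    if dialect == "graphml":
        nx.write_graphml(g, path)
        return
    if dialect != "tsv":
        raise ValueError(f"unknown network dialect {dialect!r}")
    with path.open("w") as fh:
        vocab = g.graph.get("vocabulary")
        if vocab:
            fh.write(f"#vocabulary\t{vocab}\n")
        # isolated nodes need a line of their own; typed nodes need one to
        # carry the type attribute
        for n in sorted(g.nodes, key=str):
            ntype = g.nodes[n].get("type")
            if ntype:
                fh.write(f"#node\t{n}\t{ntype}\n")
            elif g.degree(n) == 0:
                fh.write(f"#node\t{n}\n")
        for u, v, data in sorted(g.edges(data=True), key=lambda e: (str(min(e[0], e[1])), str(max(e[0], e[1])))):
            a, b = (u, v) if str(u) <= str(v) else (v, u)
            w = data.get("weight", 1.0)
            fh.write(f"{a}\t{b}\t{w:.17g}\n")


def read_network(path: str | Path, dialect: str = "tsv") -> nx.Graph:
    """Read a network written by :func:`write_network`.

    Duplicate undirected edges and self-loops raise ``ValueError``.
    """
    path = Path(path)
    if dialect == "graphml":
        g = nx.read_graphml(path)
        if g.is_multigraph() or g.is_directed():
            raise ValueError(f"{path}: expected an undirected simple graph")
        _check_simple(g, str(path))
        for _, _, data in g.edges(data=True):
            data.setdefault("weight", 1.0)
        return g
    if dialect != "tsv":
        raise ValueError(f"unknown network dialect {dialect!r}")
    g = nx.Graph()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if fields[0] == "#vocabulary":
                g.graph["vocabulary"] = fields[1]
                continue
            if fields[0] == "#node":
                if len(fields) == 3:
                    g.add_node(fields[1], type=fields[2])
                else:
                    g.add_node(fields[1])
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 fields, got {len(fields)}")
            u, v, w = fields
            if u == v:
                raise ValueError(f"{path}: line {lineno}: self-loop at {u!r}")
            if g.has_edge(u, v):
                raise ValueError(f"{path}: line {lineno}: duplicate edge {u!r}-{v!r}")
            g.add_edge(u, v, weight=float(w))
    return g
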