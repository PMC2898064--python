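"""Readers and writers for the text dialects used across the pipeline.

Formats:

* pathway TSV — line-oriented pathway content::

      PATHWAY <TAB> id <TAB> source_label
      REACTION <TAB> id <TAB> input=A;B <TAB> catalyst=C <TAB> output=E
      COMPLEX <TAB> id <TAB> A;B;complex:other

  ``complex:<id>`` members reference complexes defined in the same pathway.
* pair TSV — two or more accessions per line; a line with n > 2 columns is
  one n-ary interaction record.
* PSI-MI TAB subset — columns 1-2 hold ``db:accession`` identifiers; rows
  sharing a column-14 interaction identifier form one n-ary record.
* GAF-like TSV — ``protein <TAB> term <TAB> aspect`` annotation rows.
* ortholog map TSV — ``foreign_id <TAB> human_accession``.
* domain TSV — ``protein <TAB> domain`` and ``domainA <TAB> domainB``.
* FI network TSV — ``proteinA proteinB provenance direction direction_source
  sources`` with sources comma-joined.
* cohort TSV — ``sample <TAB> gene``; sample label TSV — ``sample <TAB> label``.
* GMT — ``set_name <TAB> description <TAB> gene ...``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .pathway import (
    ComplexRecord,
    Direction,
    FunctionalInteraction,
    PathwayRecord,
    PathwayStructureError,
    ProteinRef,
    ReactionRecord,
)

__all__ = [
    "read_pathways",
    "write_pathways",
    "read_pairs",
    "read_pair_records",
    "read_psimitab_records",
    "read_evidence_records",
    "read_annotations",
    "write_annotations",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_domain_map",
    "read_domain_pairs",
    "write_pair_file",
    "read_fi_tsv",
    "write_fi_tsv",
    "read_tf_targets",
    "read_cohort",
    "write_cohort",
    "read_sample_labels",
    "read_gmt",
    "write_gmt",
    "write_graphml",
    "write_json",
    "read_json",
]

_ROLES = ("input", "catalyst", "activator", "inhibitor", "output")


class ParseError(ValueError):
    """A malformed input line; carries the file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def _lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# pathway TSV


def read_pathways(path) -> List[PathwayRecord]:
    """Parse the pathway TSV dialect into :class:`PathwayRecord` objects."""
    pathways: List[PathwayRecord] = []
    current: Optional[PathwayRecord] = None
    # raw rows are collected per pathway, then complex references resolved
    pending: List[Tuple[int, List[str]]] = []

    def finish() -> None:
        nonlocal pending
        if current is None:
            return
        _resolve_pathway_rows(path, current, pending)
        pathways.append(current)
        pending = []

    for lineno, line in _lines(path):
        fields = line.split("\t")
        kind = fields[0].upper()
        if kind == "PATHWAY":
            if len(fields) < 3:
                raise ParseError(path, lineno, "PATHWAY needs id and source")
            finish()
            current = PathwayRecord(id=fields[1], source=fields[2])
        elif kind in ("REACTION", "COMPLEX"):
            if current is None:
                raise ParseError(path, lineno, f"{kind} before any PATHWAY")
            if len(fields) < 3:
                raise ParseError(path, lineno, f"{kind} needs id and members")
            pending.append((lineno, fields))
        else:
            raise ParseError(path, lineno, f"unknown record type {fields[0]!r}")
    finish()
    return pathways


def _resolve_pathway_rows(path, pw: PathwayRecord, rows) -> None:
    complex_rows = {}
    for lineno, fields in rows:
        if fields[0].upper() == "COMPLEX":
            complex_rows[fields[1]] = (lineno, fields[2].split(";"))

    resolved: Dict[str, ComplexRecord] = {}

    def resolve_complex(cid: str, stack: Tuple[str, ...]) -> ComplexRecord:
        if cid in resolved:
            return resolved[cid]
        if cid in stack:
            raise PathwayStructureError(
                f"{path}: cyclic complex nesting at {cid!r}"
            )
        lineno, members = complex_rows[cid]
        comps: Set = set()
        for m in members:
            m = m.strip()
            if not m:
                continue
            if m.startswith("complex:"):
                ref = m[len("complex:"):]
                if ref not in complex_rows:
                    raise ParseError(path, lineno, f"unknown complex {ref!r}")
                comps.add(resolve_complex(ref, stack + (cid,)))
            else:
                comps.add(ProteinRef(m))
        rec = ComplexRecord(id=cid, components=frozenset(comps))
        resolved[cid] = rec
        return rec

    for cid in complex_rows:
        pw.complexes.append(resolve_complex(cid, ()))

    for lineno, fields in rows:
        if fields[0].upper() != "REACTION":
            continue
        roles: Dict[str, Set] = {r: set() for r in _ROLES}
        for spec in fields[2:]:
            if "=" not in spec:
                raise ParseError(path, lineno, f"bad role field {spec!r}")
            role, members = spec.split("=", 1)
            role = role.strip().lower()
            if role not in roles:
                raise ParseError(path, lineno, f"unknown role {role!r}")
            for m in members.split(";"):
                m = m.strip()
                if not m:
                    continue
                if m.startswith("complex:"):
                    ref = m[len("complex:"):]
                    if ref not in complex_rows:
                        raise ParseError(
                            path, lineno, f"unknown complex {ref!r}"
                        )
                    roles[role].add(resolve_complex(ref, ()))
                else:
                    roles[role].add(ProteinRef(m))
        pw.reactions.append(
            ReactionRecord(
                id=fields[1],
                inputs=frozenset(roles["input"]),
                catalysts=frozenset(roles["catalyst"]),
                activators=frozenset(roles["activator"]),
                inhibitors=frozenset(roles["inhibitor"]),
                outputs=frozenset(roles["output"]),
            )
        )


def write_pathways(path, pathways: Iterable[PathwayRecord]) -> None:
    def member_str(m) -> str:
        if isinstance(m, ComplexRecord):
            return f"complex:{m.id}"
        return m.accession

    with open(path, "w") as fh:
        for pw in pathways:
            fh.write(f"PATHWAY\t{pw.id}\t{pw.source}\n")
            for c in sorted(pw.complexes, key=lambda c: c.id):
                members = ";".join(
                    sorted(member_str(m) for m in c.components)
                )
                fh.write(f"COMPLEX\t{c.id}\t{members}\n")
            for r in sorted(pw.reactions, key=lambda r: r.id):
                fields = [f"REACTION\t{r.id}"]
                for role, members in (
                    ("input", r.inputs),
                    ("catalyst", r.catalysts),
                    ("activator", r.activators),
                    ("inhibitor", r.inhibitors),
                    ("output", r.outputs),
                ):
                    if members:
                        joined = ";".join(
                            sorted(member_str(m) for m in members)
                        )
                        fields.append(f"{role}={joined}")
                fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# pair / evidence files


def _norm_pair(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_pair_records(path) -> List[Set[str]]:
    """Plain TSV: each line's columns are the participants of one record."""
    records = []
    for lineno, line in _lines(path):
        fields = [f.strip() for f in line.split("\t") if f.strip()]
        if len(fields) < 2:
            raise ParseError(path, lineno, "need at least two participants")
        records.append(set(fields))
    return records


def _mitab_id(field: str, path, lineno: int) -> str:
    first = field.split("|")[0].strip()
    if ":" not in first:
        raise ParseError(path, lineno, f"bad PSI-MI identifier {field!r}")
    return first.split(":", 1)[1]


def read_psimitab_records(path) -> List[Set[str]]:
    """PSI-MI TAB subset: binary rows, grouped into n-ary records when rows
    share a column-14 interaction identifier."""
    groups: Dict[str, Set[str]] = {}
    singles: List[Set[str]] = []
    for lineno, line in _lines(path):
        if line.startswith("ID(s) interactor"):  # header
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "need two interactor columns")
        a = _mitab_id(fields[0], path, lineno)
        b = _mitab_id(fields[1], path, lineno)
        key = fields[13].strip() if len(fields) > 13 else "-"
        if key and key != "-":
            groups.setdefault(key, set()).update((a, b))
        else:
            singles.append({a, b})
    return list(groups.values()) + singles


def read_evidence_records(path) -> List[Set[str]]:
    """Dispatch on content: PSI-MI TAB if identifiers look like ``db:acc``."""
    path = Path(path)
    for _, line in _lines(path):
        if line.startswith("ID(s) interactor"):
            return read_psimitab_records(path)
        first = line.split("\t")[0]
        if ":" in first.split("|")[0]:
            return read_psimitab_records(path)
        break
    return read_pair_records(path)


def read_pairs(path) -> Set[Tuple[str, str]]:
    """Two-column pair list as a set of unordered pairs (self-pairs dropped)."""
    pairs: Set[Tuple[str, str]] = set()
    for rec in read_pair_records(path):
        rec = sorted(rec)
        if len(rec) == 2:
            pairs.add(_norm_pair(rec[0], rec[1]))
    return pairs


def write_pair_file(path, pairs: Iterable[Tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# annotations / maps


def read_annotations(path, aspect: Optional[str] = None) -> Dict[str, Set[str]]:
    """GAF-like TSV (protein, term, aspect) -> protein -> set of terms."""
    ann: Dict[str, Set[str]] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "need protein and term columns")
        if aspect is not None and len(fields) > 2 and fields[2] != aspect:
            continue
        ann.setdefault(fields[0], set()).add(fields[1])
    return ann


def write_annotations(path, ann: Dict[str, Set[str]], aspect: str = "P") -> None:
    with open(path, "w") as fh:
        for protein in sorted(ann):
            for term in sorted(ann[protein]):
                fh.write(f"{protein}\t{term}\t{aspect}\n")


def read_ortholog_map(path) -> Dict[str, Set[str]]:
    m: Dict[str, Set[str]] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "need foreign and human columns")
        m.setdefault(fields[0], set()).add(fields[1])
    return m


def write_ortholog_map(path, m: Dict[str, Set[str]]) -> None:
    with open(path, "w") as fh:
        for foreign in sorted(m):
            for human in sorted(m[foreign]):
                fh.write(f"{foreign}\t{human}\n")


def read_domain_map(path) -> Dict[str, Set[str]]:
    """protein -> set of domains (same shape as an annotation table)."""
    return read_annotations(path)


def read_domain_pairs(path) -> Set[Tuple[str, str]]:
    pairs: Set[Tuple[str, str]] = set()
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "need two domain columns")
        pairs.add(_norm_pair(fields[0], fields[1]))
    return pairs


# ---------------------------------------------------------------------------
# FI lists / networks


def read_tf_targets(path, source: str = "tf_target") -> Set[FunctionalInteraction]:
    """TF -> target rows as expression-regulation FIs (pathway provenance)."""
    fis: Set[FunctionalInteraction] = set()
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "need TF and target columns")
        tf, target = fields[0], fields[1]
        if tf == target:
            continue
        fis.add(
            FunctionalInteraction(
                pair=(tf, target),
                provenance="pathway",
                direction=Direction.EXPRESSION,
                direction_source=tf,
                sources=frozenset({source}),
            )
        )
    return fis


def write_fi_tsv(path, fis: Iterable[FunctionalInteraction]) -> None:
    with open(path, "w") as fh:
        fh.write("proteinA\tproteinB\tprovenance\tdirection\t"
                 "direction_source\tsources\n")
        for fi in sorted(fis, key=lambda f: f.pair):
            fh.write(
                "\t".join(
                    (
                        fi.pair[0],
                        fi.pair[1],
                        fi.provenance,
                        fi.direction,
                        fi.direction_source or "-",
                        ",".join(sorted(fi.sources)) or "-",
                    )
                )
                + "\n"
            )


def read_fi_tsv(path) -> Set[FunctionalInteraction]:
    fis: Set[FunctionalInteraction] = set()
    for lineno, line in _lines(path):
        if line.startswith("proteinA\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ParseError(path, lineno, "need six FI columns")
        src = None if fields[4] == "-" else fields[4]
        sources = frozenset() if fields[5] == "-" else frozenset(
            fields[5].split(",")
        )
        fis.add(
            FunctionalInteraction(
                pair=(fields[0], fields[1]),
                provenance=fields[2],
                direction=fields[3],
                direction_source=src,
                sources=sources,
            )
        )
    return fis


def write_graphml(path, graph: nx.Graph) -> None:
    """GraphML export; set-valued edge attributes are comma-joined."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for a, b, data in graph.edges(data=True):
        clean = {}
        for k, v in data.items():
            if isinstance(v, (set, frozenset)):
                clean[k] = ",".join(sorted(v))
            elif v is None:
                clean[k] = "-"
            else:
                clean[k] = v
        g.add_edge(a, b, **clean)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# cohorts / gene sets / JSON


def read_cohort(path) -> Dict[str, Set[str]]:
    cohort: Dict[str, Set[str]] = {}
    for lineno, line in _lines(path):
        if line.lower().startswith("sample\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "need sample and gene columns")
        cohort.setdefault(fields[0], set()).add(fields[1].upper())
    return cohort


def write_cohort(path, cohort: Dict[str, Set[str]]) -> None:
    with open(path, "w") as fh:
        for sample in sorted(cohort):
            for gene in sorted(cohort[sample]):
                fh.write(f"{sample}\t{gene}\n")


def read_sample_labels(path) -> Dict[str, str]:
    labels: Dict[str, str] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "need sample and label columns")
        labels[fields[0]] = fields[1]
    return labels


def read_gmt(path) -> Dict[str, Set[str]]:
    sets: Dict[str, Set[str]] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, "GMT needs name, description, genes")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(path, sets: Dict[str, Iterable[str]], description: str = "-") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
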