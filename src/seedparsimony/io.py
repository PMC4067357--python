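"""Readers and writers for character matrices, trees and constraint files.

Matrices travel in two dialects:

* a restricted morphology NEXUS dialect — a ``DATA``/``CHARACTERS`` block with
  ``DIMENSIONS``, ``FORMAT ... SYMBOLS=".." MISSING=?``, optional
  ``CHARSTATELABELS``, and a non-interleaved ``MATRIX``.  ``(01)`` codes a
  polymorphic cell, ``{01}`` an uncertain one, ``?`` missing data;
* delimited text (TSV/CSV) with a header row, one taxon per row, and the same
  cell tokens.

Trees are newick, parsed and written with :mod:`dendropy`.  Constraints are a
small YAML document::

    constraints:
      - name: Leandra_monophyletic
        ingroup: [Leandra_acutiflora, Leandra_aristigera, ...]
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path
from typing import List, Sequence, Union

import dendropy
import yaml

from .matrix import (
    Cell,
    CharacterDefinition,
    CharacterMatrix,
    Constraint,
    normalize_taxon,
)

Source = Union[str, Path]


class MatrixFormatError(ValueError):
    """Malformed matrix input (duplicate taxa, bad tokens, ragged rows ...)."""


class TreeFormatError(ValueError):
    """Malformed tree input."""


def _read_text(source: Source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        # treat as literal content if it looks like one, else as a path
        if "\n" in source or source.lstrip().startswith(("#NEXUS", "(")):
            return source
        p = Path(source)
        if p.exists():
            return p.read_text()
        return source
    raise TypeError(f"unsupported source type: {type(source)!r}")


# ---------------------------------------------------------------------------
# NEXUS tokenization (shared by the matrix reader)
# ---------------------------------------------------------------------------

_PUNCT = set(";,/=(){}")


def _strip_nexus_comments(text: str) -> str:
    return re.sub(r"\[[^\]]*\]", " ", text)


def _tokenize(text: str):
    """Yield NEXUS tokens: quoted labels, punctuation, bare words."""
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "'":
            j = i + 1
            out = []
            while True:
                if j >= n:
                    raise MatrixFormatError("unterminated quoted label")
                if text[j] == "'":
                    if j + 1 < n and text[j + 1] == "'":
                        out.append("'")
                        j += 2
                        continue
                    break
                out.append(text[j])
                j += 1
            yield ("quoted", "".join(out))
            i = j + 1
        elif ch in _PUNCT:
            yield ("punct", ch)
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in _PUNCT and text[j] != "'":
                j += 1
            yield ("word", text[i:j])
            i = j


# ---------------------------------------------------------------------------
# Matrix reading
# ---------------------------------------------------------------------------


def read_matrix(source: Source, format: str | None = None) -> CharacterMatrix:
    """Read a :class:`CharacterMatrix` from NEXUS or delimited text.

    Parameters
    ----------
    source : str or Path
        Path to a file, or the file content itself.
    format : {"nexus", "tsv", "csv"}, optional
        Auto-detected when omitted: content starting with ``#NEXUS`` is
        NEXUS; otherwise the delimiter is sniffed from the header line.
    """
    text = _read_text(source)
    if format is None:
        format = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "delimited"
    if format == "nexus":
        return _parse_nexus_matrix(text)
    if format in ("delimited", "tsv", "csv"):
        delim = {"tsv": "\t", "csv": ","}.get(format)
        return _parse_delimited_matrix(text, delim)
    raise ValueError(f"unknown matrix format {format!r}")


def _parse_cell_token(token: str, kind_hint: str | None = None) -> Cell:
    """Parse one cell token: ``0``, ``?``, ``(01)``, ``{01}`` or bare ``01``."""
    token = token.strip()
    if token == "?":
        return Cell.missing()
    if token.startswith("(") and token.endswith(")"):
        states = [int(c) for c in token[1:-1].replace(",", "") if not c.isspace()]
        return Cell.polymorphic(states)
    if token.startswith("{") and token.endswith("}"):
        states = [int(c) for c in token[1:-1].replace(",", "") if not c.isspace()]
        return Cell.uncertain(states)
    if not token.isdigit():
        raise MatrixFormatError(f"unrecognized cell token {token!r}")
    if len(token) == 1:
        return Cell.single(int(token))
    # bare multi-digit delimited cell: polymorphic by default
    if kind_hint == "uncertain":
        return Cell.uncertain(int(c) for c in token)
    return Cell.polymorphic(int(c) for c in token)


def _parse_nexus_matrix(text: str) -> CharacterMatrix:
    clean = _strip_nexus_comments(text)
    m = re.search(
        r"BEGIN\s+(?:DATA|CHARACTERS)\s*;(.*?)\bEND\s*;", clean, re.I | re.S
    )
    if not m:
        raise MatrixFormatError("no DATA or CHARACTERS block found")
    block = m.group(1)
    statements = _split_statements(block)

    ntax = nchar = None
    missing_sym = "?"
    charstatelabels: list[tuple[str, list[str]]] | None = None
    matrix_stmt = None
    for stmt in statements:
        head = stmt[0][1].upper() if stmt else ""
        if head == "DIMENSIONS":
            kv = _parse_keyvals(stmt[1:])
            ntax = int(kv.get("NTAX", 0)) or None
            nchar = int(kv.get("NCHAR", 0)) or None
        elif head == "FORMAT":
            kv = _parse_keyvals(stmt[1:])
            missing_sym = kv.get("MISSING", "?")
            if "INTERLEAVE" in kv:
                raise MatrixFormatError("interleaved matrices are not supported")
        elif head == "CHARSTATELABELS":
            charstatelabels = _parse_charstatelabels(stmt[1:])
        elif head == "MATRIX":
            matrix_stmt = stmt[1:]
    if matrix_stmt is None:
        raise MatrixFormatError("missing MATRIX statement")
    if nchar is None:
        raise MatrixFormatError("missing DIMENSIONS NCHAR")

    taxa: list[str] = []
    rows: list[list[Cell]] = []
    i = 0
    toks = matrix_stmt
    while i < len(toks):
        ttype, tval = toks[i]
        taxon = normalize_taxon(tval)
        if taxon in taxa:
            raise MatrixFormatError(f"duplicate taxon {taxon!r} in matrix")
        i += 1
        cells: list[Cell] = []
        while i < len(toks) and len(cells) < nchar:
            ttype, tval = toks[i]
            if ttype == "punct" and tval == "(":
                group, i = _collect_group(toks, i, ")")
                cells.append(Cell.polymorphic(int(s) for s in group))
            elif ttype == "punct" and tval == "{":
                group, i = _collect_group(toks, i, "}")
                cells.append(Cell.uncertain(int(s) for s in group))
            elif ttype in ("word", "quoted"):
                for ch in tval:
                    if len(cells) >= nchar:
                        raise MatrixFormatError(
                            f"row for taxon {taxon!r} has more than {nchar} cells"
                        )
                    if ch == missing_sym:
                        cells.append(Cell.missing())
                    elif ch.isdigit():
                        cells.append(Cell.single(int(ch)))
                    else:
                        raise MatrixFormatError(
                            f"bad state symbol {ch!r} for taxon {taxon!r}"
                        )
                i += 1
            else:
                raise MatrixFormatError(
                    f"unexpected token {tval!r} in row for taxon {taxon!r}"
                )
        if len(cells) != nchar:
            raise MatrixFormatError(
                f"row for taxon {taxon!r} has {len(cells)} cells, expected {nchar}"
            )
        taxa.append(taxon)
        rows.append(cells)
    if ntax is not None and len(taxa) != ntax:
        raise MatrixFormatError(f"matrix has {len(taxa)} taxa, DIMENSIONS says {ntax}")

    characters = _build_characters(nchar, rows, charstatelabels)
    return _assemble(taxa, characters, rows)


def _split_statements(block: str):
    stmts, current = [], []
    for tok in _tokenize(block):
        if tok == ("punct", ";"):
            if current:
                stmts.append(current)
            current = []
        else:
            current.append(tok)
    if current:
        stmts.append(current)
    return stmts


def _parse_keyvals(tokens):
    kv, i = {}, 0
    while i < len(tokens):
        key = tokens[i][1].upper()
        if i + 2 < len(tokens) and tokens[i + 1] == ("punct", "="):
            kv[key] = tokens[i + 2][1]
            i += 3
        elif i + 1 < len(tokens) and tokens[i + 1] == ("punct", "="):
            kv[key] = ""
            i += 2
        else:
            kv[key] = True
            i += 1
    return kv


def _parse_charstatelabels(tokens):
    # entries separated by commas: <index> <label> [/ state labels...]
    entries, current = [], []
    for tok in tokens:
        if tok == ("punct", ","):
            entries.append(current)
            current = []
        else:
            current.append(tok)
    if current:
        entries.append(current)
    out = []
    for entry in entries:
        if not entry:
            continue
        # entry[0] is the 1-based character number
        label = entry[1][1] if len(entry) > 1 else f"char{entry[0][1]}"
        states: list[str] = []
        if ("punct", "/") in entry:
            k = entry.index(("punct", "/"))
            states = [t[1] for t in entry[k + 1 :]]
        out.append((label, states))
    return out


def _collect_group(toks, i, closer):
    group = []
    i += 1
    while i < len(toks) and toks[i] != ("punct", closer):
        ttype, tval = toks[i]
        if ttype == "punct" and tval == ",":
            i += 1
            continue
        group.extend(tval)
        i += 1
    if i >= len(toks):
        raise MatrixFormatError(f"unterminated {closer!r} group in matrix")
    return group, i + 1


def _parse_delimited_matrix(text: str, delimiter: str | None) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise MatrixFormatError("delimited matrix needs a header and >= 1 row")
    if delimiter is None:
        delimiter = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delimiter)]
    char_labels = header[1:]
    nchar = len(char_labels)
    if nchar == 0:
        raise MatrixFormatError("header row declares no characters")
    taxa, rows = [], []
    for ln in lines[1:]:
        fields = [f.strip() for f in ln.split(delimiter)]
        taxon = normalize_taxon(fields[0])
        if taxon in taxa:
            raise MatrixFormatError(f"duplicate taxon {taxon!r} in matrix")
        if len(fields) - 1 != nchar:
            raise MatrixFormatError(
                f"row for taxon {taxon!r} has {len(fields) - 1} cells, expected {nchar}"
            )
        taxa.append(taxon)
        rows.append([_parse_cell_token(tok) for tok in fields[1:]])
    characters = _build_characters(nchar, rows, [(lbl, []) for lbl in char_labels])
    return _assemble(taxa, characters, rows)


def _build_characters(nchar, rows, charstatelabels):
    characters = []
    for j in range(nchar):
        max_obs = max((row[j].max_state() for row in rows), default=-1)
        label, state_labels = f"char{j + 1}", []
        if charstatelabels and j < len(charstatelabels):
            label, state_labels = charstatelabels[j]
        if len(state_labels) >= 2:
            # an explicit state list is authoritative; codes beyond it are a
            # format error (reported with the offending row/column)
            if max_obs >= len(state_labels):
                for i, row in enumerate(rows):
                    if row[j].max_state() >= len(state_labels):
                        raise MatrixFormatError(
                            f"state code {row[j].max_state()} out of range for "
                            f"character {label!r} ({len(state_labels)} states) "
                            f"at row {i + 1}, column {j + 1}"
                        )
            n_states = len(state_labels)
        else:
            n_states = max(max_obs + 1, 2)
            state_labels = list(state_labels) + [
                f"state{i}" for i in range(len(state_labels), n_states)
            ]
        characters.append(CharacterDefinition(label, tuple(state_labels)))
    return characters


def _assemble(taxa, characters, rows) -> CharacterMatrix:
    try:
        return CharacterMatrix(taxa, characters, rows)
    except ValueError as exc:
        raise MatrixFormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Matrix writing
# ---------------------------------------------------------------------------


def _needs_quoting(label: str) -> bool:
    return bool(re.search(r"[^\w.]", label))


def _quote(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _cell_token(cell: Cell) -> str:
    if cell.is_missing:
        return "?"
    codes = "".join(str(s) for s in sorted(cell.states))
    if cell.kind.value == "polymorphic":
        return f"({codes})"
    if cell.kind.value == "uncertain":
        return "{" + codes + "}"
    return codes


def write_matrix(matrix: CharacterMatrix, dialect: str = "nexus") -> str:
    """Serialize a matrix to NEXUS or TSV text (lossless round trip)."""
    if dialect == "nexus":
        return _write_nexus(matrix)
    if dialect in ("delimited", "tsv"):
        return _write_delimited(matrix, "\t")
    if dialect == "csv":
        return _write_delimited(matrix, ",")
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_nexus(matrix: CharacterMatrix) -> str:
    max_state = max(c.n_states for c in matrix.characters) - 1
    symbols = "".join(str(i) for i in range(max_state + 1))
    out = _io.StringIO()
    out.write("#NEXUS\n")
    out.write("BEGIN DATA;\n")
    out.write(
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
    )
    out.write(f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=?;\n')
    out.write("    CHARSTATELABELS\n")
    entries = []
    for j, char in enumerate(matrix.characters):
        states = " ".join(_quote(s) for s in char.state_labels)
        entries.append(f"        {j + 1} {_quote(char.label)} / {states}")
    out.write(",\n".join(entries) + ";\n")
    out.write("    MATRIX\n")
    width = max(len(_quote(t)) for t in matrix.taxa) + 2
    for taxon, row in zip(matrix.taxa, matrix.cells):
        tokens = "".join(_cell_token(c) for c in row)
        out.write(f"        {_quote(taxon):<{width}}{tokens}\n")
    out.write("    ;\nEND;\n")
    return out.getvalue()


def _write_delimited(matrix: CharacterMatrix, delimiter: str) -> str:
    lines = [delimiter.join(["taxon"] + [c.label for c in matrix.characters])]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        lines.append(delimiter.join([taxon] + [_cell_token(c) for c in row]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_trees(source: Source, schema: str = "newick") -> List[dendropy.Tree]:
    """Read one or more trees (newick or NEXUS TREES block) via dendropy.

    Each returned tree gets its own taxon namespace, with labels normalized
    the same way as matrix taxa.
    """
    text = _read_text(source)
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        if "Duplicate taxon labels" in str(exc):
            raise TreeFormatError(f"duplicate leaf label: {exc}") from exc
        raise TreeFormatError(f"could not parse {schema} tree input: {exc}") from exc
    trees = []
    for tree in tree_list:
        seen = set()
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None:
                raise TreeFormatError("tree contains an unlabelled leaf")
            label = normalize_taxon(leaf.taxon.label)
            if label in seen:
                raise TreeFormatError(f"duplicate leaf label {label!r}")
            seen.add(label)
            leaf.taxon.label = label
        trees.append(tree)
    return trees


def write_trees(trees: Sequence[dendropy.Tree], path: Path | None = None) -> str:
    """Serialize trees to a multi-tree newick string (optionally to a file)."""
    chunks = []
    for tree in trees:
        chunks.append(
            tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
            ).strip()
        )
    text = "\n".join(chunks) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------


def read_constraints(source: Source) -> List[Constraint]:
    """Read named monophyly constraints from a YAML document."""
    text = _read_text(source)
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "constraints" not in doc:
        raise ValueError("constraint file must contain a top-level 'constraints' list")
    out = []
    for entry in doc["constraints"]:
        out.append(Constraint(entry["name"], frozenset(entry["ingroup"])))
    return out
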