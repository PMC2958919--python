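"""Data model and readers/writers for the pipeline's external representations.

Central objects:

* :class:`AFLPMatrix` — a specimens x markers table of dominant band phenotypes
  (present / absent / missing), the input to all population-genetic stages.
* :class:`SpecimenTable` — per-specimen metadata (species label, locality,
  coordinates, mitochondrial haplotype group).
* :class:`Alignment` — an equal-length DNA alignment with a known codon frame.
* :class:`GeneTree` — a rooted gene tree with branch lengths, consumed (never
  inferred) by the concordance stage.

Readers never coerce missing data to absence: a missing AFLP cell stays coded
as missing (−1 internally, ``?`` on disk, ``-9`` in the assignment-program
interchange format) through the whole pipeline.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PRESENT",
    "ABSENT",
    "MISSING",
    "AFLPMatrix",
    "SpecimenTable",
    "Alignment",
    "GeneTree",
    "AFLPParseError",
    "read_aflp_table",
    "write_aflp_table",
    "write_structure_file",
    "read_structure_file",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "parse_newick_tree",
    "read_specimen_table",
    "write_specimen_table",
]

PRESENT: int = 1
ABSENT: int = 0
MISSING: int = -1

#: scored fragment sizes are restricted to this window (bases); larger
#: fragments are not reproducible enough to score.
FRAGMENT_SIZE_RANGE: tuple[int, int] = (70, 322)

_ALIGNMENT_ALPHABET = frozenset("ACGTRYN-")


class AFLPParseError(ValueError):
    """Raised when an AFLP table cannot be parsed (bad cell, duplicate id...)."""


def _fragment_size(label: str) -> int | None:
    """Extract a fragment size (in bases) from a marker label, if any.

    Labels of the form ``<primer-combination>-<size>`` (e.g. ``AG-CA-162``)
    carry the scored fragment length after the final dash; labels without
    that suffix carry no size information.
    """
    m = re.search(r"-(\d+)\s*$", label)
    return int(m.group(1)) if m else None


@dataclass
class AFLPMatrix:
    """Binary dominant-phenotype table: specimens x markers.

    ``values`` holds int8 codes: 1 present, 0 absent, −1 missing.  Missing is a
    first-class state and is never folded into absence.
    """

    specimen_ids: list[str]
    marker_labels: list[str]
    values: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = self.values.shape
        if n != len(self.specimen_ids) or m != len(self.marker_labels):
            raise ValueError(
                f"value array {self.values.shape} inconsistent with "
                f"{len(self.specimen_ids)} specimens x {len(self.marker_labels)} markers"
            )
        if len(set(self.specimen_ids)) != n:
            raise AFLPParseError("duplicate specimen ids")
        if len(set(self.marker_labels)) != m:
            raise AFLPParseError("duplicate marker labels")
        bad = ~np.isin(self.values, (PRESENT, ABSENT, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise AFLPParseError(
                f"invalid cell value {self.values[i, j]} at specimen "
                f"{self.specimen_ids[i]!r}, marker {self.marker_labels[j]!r}"
            )
        lo, hi = FRAGMENT_SIZE_RANGE
        for lab in self.marker_labels:
            size = _fragment_size(lab)
            if size is not None and not lo <= size <= hi:
                raise ValueError(
                    f"marker {lab!r} encodes fragment size {size} outside [{lo}, {hi}]"
                )
        # an all-absent profile is biologically suspect but not fatal: flag it
        for i in range(n):
            row = self.values[i]
            if not (row == PRESENT).any():
                self.flags.append(
                    f"specimen {self.specimen_ids[i]!r} has no present band"
                )

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def present(self) -> np.ndarray:
        """Boolean mask of present bands."""
        return self.values == PRESENT

    def missing(self) -> np.ndarray:
        """Boolean mask of missing cells."""
        return self.values == MISSING

    def subset(self, specimen_ids: Sequence[str]) -> "AFLPMatrix":
        """Row-subset the matrix to the given specimens, preserving order."""
        index = {s: i for i, s in enumerate(self.specimen_ids)}
        rows = [index[s] for s in specimen_ids]
        return AFLPMatrix(list(specimen_ids), list(self.marker_labels), self.values[rows])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AFLPMatrix):
            return NotImplemented
        return (
            self.specimen_ids == other.specimen_ids
            and self.marker_labels == other.marker_labels
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SpecimenTable:
    """Per-specimen metadata keyed on ``specimen_id``.

    ``species_label`` is the morphological species name; ``mito_group`` an
    optional mitochondrial haplotype-group label; coordinates are decimal
    degrees and optional (NaN when absent).
    """

    table: pd.DataFrame

    COLUMNS = (
        "specimen_id",
        "species_label",
        "locality_code",
        "latitude",
        "longitude",
        "mito_group",
    )

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                df[col] = np.nan if col in ("latitude", "longitude") else None
        df = df[list(self.COLUMNS)]
        if df["specimen_id"].duplicated().any():
            dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
            raise ValueError(f"duplicate specimen_id {dup!r}")
        lat = pd.to_numeric(df["latitude"], errors="coerce")
        lon = pd.to_numeric(df["longitude"], errors="coerce")
        if ((lat < -90) | (lat > 90)).any():
            raise ValueError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValueError("longitude outside [-180, 180]")
        df["latitude"], df["longitude"] = lat, lon
        self.table = df.reset_index(drop=True)

    @property
    def specimen_ids(self) -> list[str]:
        return self.table["specimen_id"].tolist()

    def species_of(self) -> dict[str, str]:
        """Mapping specimen_id -> species_label."""
        return dict(zip(self.table["specimen_id"], self.table["species_label"]))

    def coordinates_of(self) -> dict[str, tuple[float, float]]:
        """Mapping specimen_id -> (latitude, longitude) for georeferenced rows."""
        out = {}
        for _, row in self.table.iterrows():
            if not (math.isnan(row["latitude"]) or math.isnan(row["longitude"])):
                out[row["specimen_id"]] = (row["latitude"], row["longitude"])
        return out

    def species(self) -> list[str]:
        """Distinct species labels in table order."""
        seen: dict[str, None] = {}
        for s in self.table["species_label"]:
            if s is not None and s == s:
                seen.setdefault(s, None)
        return list(seen)


@dataclass
class Alignment:
    """Equal-length DNA alignment over {A,C,G,T,R,Y,N,-}.

    ``frame_offset`` gives the codon position (0, 1 or 2) of the first column,
    so codon-position classes can be selected without reading-frame detection.
    """

    taxon_ids: list[str]
    sequences: list[str]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.taxon_ids) != len(self.sequences):
            raise ValueError("taxon id / sequence count mismatch")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            ragged = [
                t for t, s in zip(self.taxon_ids, self.sequences)
                if len(s) != len(self.sequences[0])
            ]
            raise ValueError(f"ragged alignment; offending records: {ragged}")
        self.sequences = [s.upper() for s in self.sequences]
        for t, s in zip(self.taxon_ids, self.sequences):
            extra = set(s) - _ALIGNMENT_ALPHABET
            if extra:
                raise ValueError(f"record {t!r} contains invalid symbols {sorted(extra)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def codon_positions(self, position: int) -> list[int]:
        """Column indices belonging to codon position ``position`` (1, 2 or 3)."""
        if position not in (1, 2, 3):
            raise ValueError("codon position must be 1, 2 or 3")
        return [
            j for j in range(self.n_sites)
            if (j + self.frame_offset) % 3 == position - 1
        ]

    def to_array(self) -> np.ndarray:
        """Character matrix (n_taxa x n_sites) of single-byte strings."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


@dataclass
class GeneTree:
    """Rooted gene tree with non-negative branch lengths over specimen tips."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def root_height(self, exclude: Iterable[str] = ()) -> float:
        """Maximum root-to-tip path length, optionally excluding some tips."""
        excluded = set(exclude)
        best = 0.0
        for leaf, depth in _leaf_depths(self.tree).items():
            if leaf not in excluded:
                best = max(best, depth)
        return best

    def newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def _leaf_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


# ---------------------------------------------------------------------------
# AFLP table text format: comma-separated (tab accepted on read), header row of
# marker labels, first column specimen id, cells 0 / 1 / ? for missing.
# ---------------------------------------------------------------------------

def _as_text(source: str | Path | io.TextIOBase) -> str:
    if isinstance(source, io.TextIOBase):
        return source.read()
    path = Path(source)
    if path.exists():
        return path.read_text()
    text = str(source)
    if "\n" in text or "," in text or "\t" in text:
        return text
    raise FileNotFoundError(source)


def read_aflp_table(source: str | Path | io.TextIOBase) -> AFLPMatrix:
    """Read a delimited presence/absence table into an :class:`AFLPMatrix`.

    First column: specimen id.  Header row: marker labels.  Body cells:
    ``0`` (absent), ``1`` (present), ``?`` (missing).  Comma- or tab-delimited.
    """
    text = _as_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise AFLPParseError("AFLP table needs a header and at least one specimen row")
    sep = "\t" if ("\t" in lines[0] and "," not in lines[0]) else ","
    header = [c.strip() for c in lines[0].split(sep)]
    marker_labels = header[1:]
    ids: list[str] = []
    rows: list[list[int]] = []
    code = {"0": ABSENT, "1": PRESENT, "?": MISSING}
    for line in lines[1:]:
        cells = [c.strip() for c in line.split(sep)]
        if len(cells) != len(header):
            raise AFLPParseError(
                f"row {cells[0]!r} has {len(cells) - 1} cells, expected {len(marker_labels)}"
            )
        ids.append(cells[0])
        row = []
        for j, cell in enumerate(cells[1:]):
            if cell not in code:
                raise AFLPParseError(
                    f"non-binary cell {cell!r} at specimen {cells[0]!r}, "
                    f"marker {marker_labels[j]!r}"
                )
            row.append(code[cell])
        rows.append(row)
    if len(set(ids)) != len(ids):
        raise AFLPParseError("duplicate specimen id in table")
    return AFLPMatrix(ids, marker_labels, np.array(rows, dtype=np.int8))


def write_aflp_table(m: AFLPMatrix, path: str | Path | None = None) -> str:
    """Write an :class:`AFLPMatrix` in the comma-separated dialect read above."""
    symbol = {PRESENT: "1", ABSENT: "0", MISSING: "?"}
    lines = ["specimen," + ",".join(m.marker_labels)]
    for i, sid in enumerate(m.specimen_ids):
        lines.append(sid + "," + ",".join(symbol[int(v)] for v in m.values[i]))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# STRUCTURE-style interchange format: one row per specimen, haploid
# single-digit dominant coding, missing as -9, optional population column.
# ---------------------------------------------------------------------------

def write_structure_file(
    m: AFLPMatrix,
    meta: SpecimenTable | None = None,
    path: str | Path | None = None,
) -> str:
    """Write the assignment-program interchange format (haploid dominant rows).

    Each row: specimen id, optional population label (from ``meta``'s species
    column), then one allele column per marker with missing coded as −9.
    """
    if m.n_specimens == 0 or m.n_markers == 0:
        raise ValueError("cannot write an empty matrix")
    species = meta.species_of() if meta is not None else {}
    pops = {s: k + 1 for k, s in enumerate(dict.fromkeys(species.values()))}
    lines = []
    for i, sid in enumerate(m.specimen_ids):
        cells = [sid]
        if meta is not None:
            cells.append(str(pops.get(species.get(sid), 0)))
        cells += ["-9" if v == MISSING else str(int(v)) for v in m.values[i]]
        lines.append(" ".join(cells))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_structure_file(
    source: str | Path | io.TextIOBase,
    marker_labels: Sequence[str] | None = None,
    has_pop_column: bool = False,
) -> AFLPMatrix:
    """Read the interchange format back into an :class:`AFLPMatrix`."""
    text = _as_text(source) if not isinstance(source, (str, Path)) else None
    if text is None:
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
    ids, rows = [], []
    skip = 2 if has_pop_column else 1
    for line in text.splitlines():
        if not line.strip():
            continue
        cells = line.split()
        ids.append(cells[0])
        rows.append([MISSING if c == "-9" else int(c) for c in cells[skip:]])
    values = np.array(rows, dtype=np.int8)
    if marker_labels is None:
        marker_labels = [f"L{j + 1}" for j in range(values.shape[1])]
    return AFLPMatrix(ids, list(marker_labels), values)


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(source: str | Path | io.TextIOBase, frame_offset: int = 0) -> Alignment:
    """Read a FASTA alignment; sequences are uppercased, lengths must agree.

    The codon frame of the first column is not detectable from the file and
    must be supplied by the caller.
    """
    from Bio import SeqIO

    handle = source if isinstance(source, io.TextIOBase) else io.StringIO(_as_fasta_text(source))
    ids, seqs = [], []
    for rec in SeqIO.parse(handle, "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError("no FASTA records found")
    return Alignment(ids, seqs, frame_offset)


def _as_fasta_text(source: str | Path) -> str:
    path = Path(source)
    if path.exists():
        return path.read_text()
    text = str(source)
    if text.lstrip().startswith(">"):
        return text
    raise FileNotFoundError(source)


def write_fasta_alignment(a: Alignment, path: str | Path | None = None) -> str:
    text = "".join(f">{t}\n{s}\n" for t, s in zip(a.taxon_ids, a.sequences))
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Newick gene trees
# ---------------------------------------------------------------------------

def parse_newick_tree(
    source: str | Path | io.TextIOBase,
    outgroup: Iterable[str] | None = None,
) -> GeneTree:
    """Parse a rooted newick tree, optionally re-rooting on an outgroup edge.

    Internal polytomies are preserved; only a basal polytomy is resolved, and
    only when an outgroup is supplied, by re-rooting at the midpoint of the
    edge subtending the outgroup (the outgroup's MRCA edge).
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        path = Path(str(source))
        text = path.read_text() if path.exists() else str(source)
    try:
        tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    if outgroup is not None:
        labels = set(outgroup)
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        unknown = labels - tips
        if unknown:
            raise ValueError(f"outgroup labels not in tree: {sorted(unknown)}")
        if len(labels) == 1:
            node = next(
                leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label in labels
            )
        else:
            node = tree.mrca(taxon_labels=sorted(labels))
        if node is tree.seed_node:
            raise ValueError("outgroup is not monophyletic below the root")
        length = node.edge.length or 0.0
        tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return GeneTree(tree)


# ---------------------------------------------------------------------------
# Specimen metadata tables (CSV)
# ---------------------------------------------------------------------------

def read_specimen_table(source: str | Path | io.TextIOBase) -> SpecimenTable:
    df = pd.read_csv(source if isinstance(source, io.TextIOBase) else Path(source))
    return SpecimenTable(df)


def write_specimen_table(t: SpecimenTable, path: str | Path) -> None:
    t.table.to_csv(Path(path), index=False)
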