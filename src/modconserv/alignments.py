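"""Readers and in-memory containers for multi-strain alignments, modification
tables, paralog-pair tables, abundance tables and the strain phylogeny.

Coordinate conventions
----------------------
Residue positions in all tables are 1-based indices into the *ungapped*
reference protein sequence (the biology/SGD convention).  Alignment columns
are 1-based as well.  :class:`StrainAlignment` precomputes the map between
the two when first needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._tables import ALIGNMENT_ALPHABET, GAP_SYMBOLS, MODIFICATION_TYPES

logger = logging.getLogger(__name__)


class AlignmentFormatError(ValueError):
    """Rows of unequal length, illegal symbols, or duplicated strain ids."""


class MissingReferenceError(KeyError):
    """The designated reference strain is absent from the alignment."""


class EmptyInputError(ValueError):
    """A file that should contain records contains none."""


class ModificationTableError(ValueError):
    """Malformed or internally inconsistent modification table."""


class MissingLeafError(KeyError):
    """A strain identifier is not a leaf of the phylogeny."""


@dataclass(frozen=True)
class StrainAlignment:
    """One protein's alignment across N strains (rows) and L columns."""

    orf_id: str
    strain_ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_strain: str
    _ref_column_of_position: tuple[int, ...] = field(
        init=False, repr=False, compare=False, default=()
    )

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.strain_ids):
            raise AlignmentFormatError("strain_ids and rows differ in length")
        if len(self.rows) < 2:
            raise AlignmentFormatError("an alignment needs at least 2 strains")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise AlignmentFormatError("duplicate strain identifiers")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"unequal row lengths: {sorted(lengths)}")
        if self.length == 0:
            raise EmptyInputError("alignment has zero columns")
        for sid, row in zip(self.strain_ids, self.rows):
            bad = set(row) - ALIGNMENT_ALPHABET
            if bad:
                raise AlignmentFormatError(
                    f"illegal symbols {sorted(bad)} in strain {sid}"
                )
        if self.reference_strain not in self.strain_ids:
            raise MissingReferenceError(
                f"reference strain {self.reference_strain!r} not in alignment"
            )
        ref = self.reference_row
        cols = tuple(
            i + 1 for i, sym in enumerate(ref) if sym not in GAP_SYMBOLS
        )
        object.__setattr__(self, "_ref_column_of_position", cols)

    @property
    def n_strains(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def reference_row(self) -> str:
        return self.rows[self.strain_ids.index(self.reference_strain)]

    @property
    def reference_sequence(self) -> str:
        """Ungapped reference protein sequence."""
        return "".join(
            s for s in self.reference_row if s not in GAP_SYMBOLS
        )

    def column(self, column: int) -> tuple[str, ...]:
        """Symbols of a 1-based alignment column, one per strain."""
        if not 1 <= column <= self.length:
            raise IndexError(f"column {column} outside 1..{self.length}")
        return tuple(row[column - 1] for row in self.rows)

    def column_by_strain(self, column: int) -> dict[str, str]:
        return dict(zip(self.strain_ids, self.column(column)))

    def column_of_position(self, position: int) -> int:
        """Alignment column holding ungapped reference position (both 1-based)."""
        n = len(self._ref_column_of_position)
        if not 1 <= position <= n:
            raise IndexError(f"reference position {position} outside 1..{n}")
        return self._ref_column_of_position[position - 1]


@dataclass(frozen=True)
class ModificationRecord:
    orf_id: str
    position: int
    residue: str
    mod_type: str
    study_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ModificationTableError(f"position {self.position} < 1")
        if self.residue not in set("ACDEFGHIKLMNPQRSTVWY"):
            raise ModificationTableError(f"nonstandard residue {self.residue!r}")
        if self.mod_type not in MODIFICATION_TYPES:
            raise ModificationTableError(f"unknown mod_type {self.mod_type!r}")


@dataclass(frozen=True)
class ParalogPair:
    orf_a: str
    orf_b: str

    def __post_init__(self) -> None:
        if self.orf_a == self.orf_b:
            raise ValueError("a paralog pair needs two distinct ORFs")


@dataclass(frozen=True)
class AbundanceRecord:
    orf_id: str
    median_abundance: float

    def __post_init__(self) -> None:
        if not self.median_abundance > 0:
            raise ValueError("median abundance must be positive")


def read_alignment_fasta(path: str | Path, reference_strain: str,
                         orf_id: str | None = None) -> StrainAlignment:
    """Read one ORF's aligned FASTA; headers are strain identifiers."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    strain_ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    return StrainAlignment(
        orf_id=orf_id or path.stem,
        strain_ids=strain_ids,
        rows=rows,
        reference_strain=reference_strain,
    )


def write_alignment_fasta(aln: StrainAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.strain_ids, aln.rows)
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


def read_modification_table(path: str | Path) -> list[ModificationRecord]:
    """Read a TSV of modification sites (orf, position, residue, mod_type, study).

    Rows sharing (orf, position, mod_type) merge their study identifiers.
    Rows with a mod_type outside the five canonical classes are dropped with a
    logged count.  Conflicting residues at one (orf, position) raise.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"orf", "position", "residue", "mod_type", "study"}
    missing = required - set(df.columns)
    if missing:
        raise ModificationTableError(f"missing columns: {sorted(missing)}")
    try:
        positions = df["position"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ModificationTableError(f"non-integer position: {exc}") from exc
    df = df.assign(position=positions)

    known = df["mod_type"].isin(MODIFICATION_TYPES)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropped %d rows with noncanonical modification types", n_dropped)
    df = df[known]

    conflicts = (
        df.groupby(["orf", "position"])["residue"].nunique()
    )
    if (conflicts > 1).any():
        bad = conflicts[conflicts > 1].index.tolist()
        raise ModificationTableError(f"residue conflict at {bad}")

    out: list[ModificationRecord] = []
    for (orf, pos, mod), grp in df.groupby(["orf", "position", "mod_type"], sort=True):
        out.append(
            ModificationRecord(
                orf_id=str(orf),
                position=int(pos),
                residue=str(grp["residue"].iloc[0]),
                mod_type=str(mod),
                study_ids=frozenset(grp["study"].astype(str)),
            )
        )
    return out


def write_modification_table(mods: Iterable[ModificationRecord],
                             path: str | Path) -> None:
    rows = [
        {"orf": m.orf_id, "position": m.position, "residue": m.residue,
         "mod_type": m.mod_type, "study": sid}
        for m in mods for sid in sorted(m.study_ids)
    ]
    pd.DataFrame(rows, columns=["orf", "position", "residue", "mod_type", "study"]
                 ).to_csv(path, sep="\t", index=False)


def read_paralog_pairs(path: str | Path) -> list[ParalogPair]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("paralog-pair table needs two ORF columns")
    a, b = df.columns[:2]
    return [ParalogPair(str(r[a]), str(r[b])) for _, r in df.iterrows()]


def read_abundance_table(path: str | Path) -> dict[str, AbundanceRecord]:
    df = pd.read_csv(path, sep="\t")
    a, b = df.columns[:2]
    out: dict[str, AbundanceRecord] = {}
    for _, r in df.iterrows():
        rec = AbundanceRecord(str(r[a]), float(r[b]))
        out[rec.orf_id] = rec
    return out


def column_frequencies(aln: StrainAlignment, column: int) -> pd.DataFrame:
    """Counts and proportions of every symbol observed in one column.

    Returns a DataFrame indexed by symbol with columns ``count`` and
    ``proportion``; proportions sum to 1 over observed symbols.
    """
    symbols = aln.column(column)
    counts = pd.Series(list(symbols)).value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()}
    )


class StrainTree:
    """Strain phylogeny with patristic (path-length) distances between leaves."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._pdm = tree.phylogenetic_distance_matrix()
        self._taxa = {t.label: t for t in tree.taxon_namespace}

    @classmethod
    def from_newick(cls, source: str | Path) -> "StrainTree":
        text = str(source)
        looks_like_newick = text.lstrip().startswith("(") or text.rstrip().endswith(";")
        src = Path(source)
        if not looks_like_newick and src.exists():
            tree = dendropy.Tree.get(path=str(src), schema="newick")
        else:
            tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    def distance(self, strain: str, reference: str) -> float:
        try:
            t1, t2 = self._taxa[strain], self._taxa[reference]
        except KeyError as exc:
            raise MissingLeafError(f"unknown leaf {exc.args[0]!r}") from exc
        if strain == reference:
            return 0.0
        return float(self._pdm.patristic_distance(t1, t2))

    def diameter(self) -> float:
        labels = self.leaf_labels
        return max(
            (self.distance(a, b) for a in labels for b in labels),
            default=0.0,
        )


def strain_distance_to_reference(tree: StrainTree, strain: str,
                                 reference: str) -> float:
    """Patristic distance between a strain and the reference strain."""
    return tree.distance(strain, reference)
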