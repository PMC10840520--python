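"""Aligned barcode panels: FASTA + metadata I/O, validation, coverage accounting.

A *panel* is an aligned set of DNA barcode sequences (typically the 658-bp
5' region of mitochondrial *cox1*) joined with per-sample metadata: species,
family, collection locality, an optional locality-group number used by the
paired diversity analyses, country, and database accession.

Sequences are validated against the IUPAC nucleotide alphabet (including
ambiguity codes, ``N`` and the gap character ``-``) and must all share one
alignment length; unequal lengths are an error, never silently padded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CHARS",
    "AlignedSeqRecord",
    "BarcodePanel",
    "CoverageSummary",
    "PanelError",
    "AlignmentLengthError",
    "MetadataJoinError",
    "SequenceValidationError",
    "read_panel",
    "write_panel",
    "coverage_summary",
    "write_newick",
    "METADATA_COLUMNS",
]

#: Accepted sequence characters: the four bases, IUPAC ambiguity codes,
#: ``N`` (undetermined) and ``-`` (alignment gap).
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Required metadata header (tab-separated). ``locality_group`` may be empty;
#: samples without a group number are kept in the panel but excluded from the
#: locality-paired analyses.
METADATA_COLUMNS = (
    "sample_code",
    "species",
    "family",
    "locality",
    "locality_group",
    "country",
    "accession",
)

# Integer codes used throughout the distance machinery: A,C,G,T -> 0..3,
# everything else (gap, N, ambiguity codes) -> 4 = indeterminate.
_CODE_MISSING = 4
_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i
for _c in "RYSWKMBDHVN-":
    _ENCODE_TABLE[ord(_c)] = _CODE_MISSING
    _ENCODE_TABLE[ord(_c.lower())] = _CODE_MISSING


class PanelError(ValueError):
    """Base class for panel construction failures."""


class AlignmentLengthError(PanelError):
    """Sequences do not share a single alignment length."""


class MetadataJoinError(PanelError):
    """FASTA identifiers missing from the metadata table (or vice versa)."""


class SequenceValidationError(PanelError):
    """A sequence contains characters outside the IUPAC nucleotide set."""


@dataclass(frozen=True)
class AlignedSeqRecord:
    """One aligned barcode sequence with its sample metadata."""

    seq_id: str
    sequence: str
    species: str
    family: str = ""
    locality: str = ""
    locality_group: int | None = None
    country: str = ""
    accession: str | None = None

    def __post_init__(self) -> None:
        bad = [
            (i + 1, c)
            for i, c in enumerate(self.sequence)
            if c.upper() not in IUPAC_CHARS
        ]
        if bad:
            pos, char = bad[0]
            raise SequenceValidationError(
                f"sequence {self.seq_id!r}: illegal character {char!r} at "
                f"position {pos} (and {len(bad) - 1} more)"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.species:
            raise PanelError(f"record {self.seq_id!r} has an empty species label")


@dataclass
class BarcodePanel:
    """An ordered collection of aligned, annotated barcode sequences."""

    records: list[AlignedSeqRecord]
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise PanelError("a panel needs at least 2 records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            by_len: dict[int, list[str]] = {}
            for r in self.records:
                by_len.setdefault(len(r.sequence), []).append(r.seq_id)
            detail = "; ".join(
                f"length {L}: {', '.join(ids[:5])}" for L, ids in sorted(by_len.items())
            )
            raise AlignmentLengthError(f"unequal sequence lengths ({detail})")
        ids = [r.seq_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate sequence IDs: {', '.join(dupes)}")

    @property
    def alignment_length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def species_of(self) -> dict[str, str]:
        return {r.seq_id: r.species for r in self.records}

    def record(self, seq_id: str) -> AlignedSeqRecord:
        for r in self.records:
            if r.seq_id == seq_id:
                return r
        raise KeyError(seq_id)

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix: A,C,G,T -> 0..3; gap/N/ambiguity -> 4."""
        if self._encoded is None:
            raw = np.frombuffer(
                "".join(r.sequence for r in self.records).encode("ascii"),
                dtype=np.uint8,
            ).reshape(len(self.records), self.alignment_length)
            self._encoded = _ENCODE_TABLE[raw]
        return self._encoded

    def subset(self, seq_ids: Sequence[str]) -> "BarcodePanel":
        wanted = set(seq_ids)
        return BarcodePanel([r for r in self.records if r.seq_id in wanted])

    def to_metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_code": r.seq_id,
                "species": r.species,
                "family": r.family,
                "locality": r.locality,
                "locality_group": "" if r.locality_group is None else r.locality_group,
                "country": r.country,
                "accession": r.accession or "",
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


@dataclass(frozen=True)
class CoverageSummary:
    """How much of a regional species checklist has at least one barcode."""

    n_species_listed: int
    n_species_barcoded: int

    @property
    def fraction_barcoded(self) -> float:
        return self.n_species_barcoded / self.n_species_listed


def read_panel(fasta_path: str | Path, metadata_path: str | Path) -> BarcodePanel:
    """Read an aligned FASTA and its metadata TSV into a joined panel.

    Every FASTA identifier must appear in the metadata table (keyed by
    ``sample_code``). Records keep FASTA order; sequences are upper-cased.
    """
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seqs:
        raise PanelError(f"no FASTA records in {fasta_path}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise MetadataJoinError(
            f"metadata {metadata_path} lacks required columns: "
            + ", ".join(missing_cols)
        )
    dup = meta["sample_code"][meta["sample_code"].duplicated()]
    if not dup.empty:
        raise MetadataJoinError(
            "duplicate sample_code rows in metadata: " + ", ".join(sorted(set(dup)))
        )
    meta_by_id = meta.set_index("sample_code")

    absent = [s.id for s in seqs if s.id not in meta_by_id.index]
    if absent:
        raise MetadataJoinError(
            "FASTA IDs missing from metadata: " + ", ".join(absent)
        )

    records = []
    for s in seqs:
        row = meta_by_id.loc[s.id]
        group_raw = str(row["locality_group"]).strip()
        records.append(
            AlignedSeqRecord(
                seq_id=s.id,
                sequence=str(s.seq),
                species=str(row["species"]),
                family=str(row["family"]),
                locality=str(row["locality"]),
                locality_group=int(group_raw) if group_raw else None,
                country=str(row["country"]),
                accession=str(row["accession"]) or None,
            )
        )
    return BarcodePanel(records)


def write_panel(
    panel: BarcodePanel, fasta_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a panel back to the aligned-FASTA + metadata-TSV dialect."""
    bio_records = [
        SeqRecord(Seq(r.sequence), id=r.seq_id, description="")
        for r in panel.records
    ]
    SeqIO.write(bio_records, str(fasta_path), "fasta")
    panel.to_metadata_frame().to_csv(metadata_path, sep="\t", index=False)


def coverage_summary(
    checklist: pd.DataFrame | Iterable[tuple[str, bool]],
) -> CoverageSummary:
    """Count checklist species with at least one barcode available.

    ``checklist`` is a DataFrame with columns ``species`` and ``barcoded``
    (boolean), or an iterable of ``(species, barcoded)`` pairs.
    """
    if isinstance(checklist, pd.DataFrame):
        if "species" not in checklist or "barcoded" not in checklist:
            raise PanelError("checklist needs 'species' and 'barcoded' columns")
        flags = checklist["barcoded"].tolist()
    else:
        rows = list(checklist)
        flags = [f for _, f in rows]
    if not flags:
        raise PanelError("empty species checklist")
    if not all(isinstance(f, (bool, np.bool_)) for f in flags):
        raise PanelError("barcoded flags must be boolean")
    return CoverageSummary(
        n_species_listed=len(flags), n_species_barcoded=int(sum(flags))
    )


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]{}:;,'\"]")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node) -> str:
    # node: barcodediv.njtree.TreeNode duck type (name, length, children)
    if node.children:
        inner = ",".join(_newick_node(c) for c in node.children)
        label = _newick_label(node.name) if node.name else ""
        out = f"({inner}){label}"
    else:
        out = _newick_label(node.name or "")
    if node.length is not None:
        out += f":{node.length:.10g}"
    return out


def newick_string(tree) -> str:
    """Serialize an :class:`~barcodediv.njtree.NJTree` (or bare root node)."""
    root = getattr(tree, "root", tree)
    return _newick_node(root) + ";"


def write_newick(tree, path: str | Path) -> None:
    """Write a tree as standard Newick (branch lengths, quoted labels)."""
    Path(path).write_text(newick_string(tree) + "\n")
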