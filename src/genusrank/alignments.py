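"""Aligned-sequence and taxonomy-table I/O.

The pipeline works from three plain-text inputs: a pre-aligned FASTA file of
DNA sequences (one or more records per species), a TSV taxonomy table mapping
``species_id`` to ``genus`` (optionally ``higher_group`` and ``accession``),
and a rooted Newick tree (see :mod:`genusrank.sisters`).  ``species_id`` is
the join key across all three.

FASTA headers are parsed as whitespace-separated ``record_id [species_id
[accession]]``; when only a record id is present it doubles as the species
id.  A custom ``header_regex`` with named groups ``record_id``,
``species_id`` and ``accession`` can be supplied for other dialects.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    DuplicateSpeciesError,
    InputError,
    SchemaError,
    SequenceValidationError,
)

logger = logging.getLogger("genusrank")

#: IUPAC nucleotide codes, the alignment gap and the two missing-data codes.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
GAP_OR_MISSING = frozenset("-?N")
ALLOWED_RESIDUES = IUPAC_DNA | frozenset("-?")
#: Residues that carry distance information.
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class AlignedSequence:
    """One aligned DNA record tied to a species.

    ``residues`` is the aligned residue string (uppercase); its length is the
    alignment width and must match every other record in the same alignment.
    """

    record_id: str
    species_id: str
    accession: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_informative(self) -> int:
        """Number of unambiguous A/C/G/T residues (gaps, Ns, ambiguity codes
        contribute nothing to a pairwise distance)."""
        return sum(1 for c in self.residues if c in UNAMBIGUOUS)


class TaxonTable:
    """Species-to-genus assignments backed by a pandas DataFrame.

    Columns: ``species_id`` (unique), ``genus`` (nonempty), and optional
    ``higher_group`` / ``accession``.
    """

    REQUIRED = ("species_id", "genus")
    OPTIONAL = ("higher_group", "accession")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"taxonomy table missing required column(s): {missing}")
        df = df.copy()
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = ""
        df = df[list(self.REQUIRED + self.OPTIONAL)].astype(str).fillna("")
        dup = df["species_id"][df["species_id"].duplicated()].tolist()
        if dup:
            raise DuplicateSpeciesError(f"duplicate species_id rows: {sorted(set(dup))}")
        empty = df.loc[df["genus"].str.strip() == "", "species_id"].tolist()
        if empty:
            raise SchemaError(f"empty genus for species: {empty}")
        self.df = df.reset_index(drop=True)
        self._genus_of = dict(zip(self.df["species_id"], self.df["genus"]))

    @classmethod
    def from_tsv(cls, path) -> "TaxonTable":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError as exc:
            raise InputError(f"empty taxonomy table: {path}") from exc
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._genus_of

    @property
    def species(self) -> list[str]:
        return list(self.df["species_id"])

    @property
    def genera(self) -> list[str]:
        """Genus names in first-appearance order."""
        return list(dict.fromkeys(self.df["genus"]))

    def genus_of(self, species_id: str) -> str:
        return self._genus_of[species_id]

    def species_in(self, genus: str) -> list[str]:
        return list(self.df.loc[self.df["genus"] == genus, "species_id"])

    def with_aliases(self, aliases: dict[str, Iterable[str]]) -> "TaxonTable":
        """Merge several genera under one analysis label.

        ``aliases`` maps a label (e.g. ``Lasiurus_sensu_lato``) to the genera
        it absorbs; a sensu-lato versus split analysis is then a pure
        configuration change.  Unknown genera in an alias raise.
        """
        if not aliases:
            return self
        known = set(self.df["genus"])
        mapping: dict[str, str] = {}
        for label, members in aliases.items():
            members = list(members)
            unknown = [g for g in members if g not in known]
            if unknown:
                raise SchemaError(f"alias {label!r} references unknown genera: {unknown}")
            for g in members:
                mapping[g] = label
        df = self.df.copy()
        df["genus"] = df["genus"].map(lambda g: mapping.get(g, g))
        return TaxonTable(df)


_DEFAULT_HEADER = re.compile(
    r"^(?P<record_id>\S+)(?:\s+(?P<species_id>\S+))?(?:\s+(?P<accession>\S+))?"
)


def _parse_header(description: str, header_regex: str | None) -> tuple[str, str, str]:
    pattern = re.compile(header_regex) if header_regex else _DEFAULT_HEADER
    m = pattern.match(description)
    if m is None:
        raise InputError(f"FASTA header does not match parsing convention: {description!r}")
    groups = m.groupdict()
    record_id = groups.get("record_id") or groups.get("species_id")
    if not record_id:
        raise InputError(
            "header regex must capture a 'record_id' or 'species_id' group"
        )
    species_id = groups.get("species_id") or record_id
    accession = groups.get("accession") or ""
    return record_id, species_id, accession


def read_fasta_alignment(path, header_regex: str | None = None) -> list[AlignedSequence]:
    """Read and validate a pre-aligned FASTA file.

    Records are returned in file order.  All records must have the same
    length; residues are uppercased and restricted to the IUPAC DNA alphabet
    plus ``-`` (gap) and ``?``/``N`` (missing).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    out: list[AlignedSequence] = []
    for rec in records:
        record_id, species_id, accession = _parse_header(rec.description, header_regex)
        residues = str(rec.seq).upper()
        for pos, ch in enumerate(residues, start=1):
            if ch not in ALLOWED_RESIDUES:
                raise SequenceValidationError(
                    f"record {record_id!r}: invalid residue {ch!r} at column {pos}"
                )
        out.append(AlignedSequence(record_id, species_id, accession, residues))
    lengths = {len(s) for s in out}
    if len(lengths) > 1:
        raise AlignmentLengthError(
            f"alignment has records of unequal length: {sorted(lengths)}"
        )
    if lengths == {0}:
        raise InputError("alignment records are empty")
    return out


def select_representatives(
    seqs: Sequence[AlignedSequence], table: TaxonTable
) -> list[AlignedSequence]:
    """Pick one record per species: the most informative one.

    The record with the greatest count of unambiguous A/C/G/T residues wins;
    ties break by lexicographic accession, then record_id.  Species whose
    records carry no informative sites at all are dropped with a warning.
    Idempotent: output species each have exactly one record.
    """
    missing = sorted({s.species_id for s in seqs if s.species_id not in table})
    if missing:
        raise InputError(f"species absent from taxonomy table: {missing}")
    by_species: dict[str, list[AlignedSequence]] = {}
    order: list[str] = []
    for s in seqs:
        if s.species_id not in by_species:
            order.append(s.species_id)
        by_species.setdefault(s.species_id, []).append(s)
    out: list[AlignedSequence] = []
    for sp in order:
        best = min(
            by_species[sp],
            key=lambda s: (-s.n_informative, s.accession, s.record_id),
        )
        if best.n_informative == 0:
            logger.warning(
                "species %s dropped: no record with usable A/C/G/T sites", sp
            )
            continue
        out.append(best)
    return out


def write_fasta_alignment(seqs: Iterable[AlignedSequence], path) -> None:
    """Write records as FASTA with the ``record_id species_id accession``
    header convention (trailing empty fields omitted)."""
    with open(path, "w") as fh:
        for s in seqs:
            fields = [s.record_id]
            if s.species_id != s.record_id or s.accession:
                fields.append(s.species_id)
            if s.accession:
                fields.append(s.accession)
            fh.write(">" + " ".join(fields) + "\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i : i + 70] + "\n")


def rename(seq: AlignedSequence, **fields) -> AlignedSequence:
    """Return a copy of ``seq`` with the given fields replaced."""
    return replace(seq, **fields)
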