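"""Kimura two-parameter (K2P) distances.

The K2P model corrects observed differences for multiple hits while
distinguishing transitions (purine<->purine: A<->G; pyrimidine<->pyrimidine:
C<->T) from transversions.  With P and Q the per-site proportions of
transition and transversion differences over the L sites that are
unambiguous (A/C/G/T) in *both* sequences,

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Distances are handled internally at full precision in percent substitutions
per site (the scale on which genus-level Cytb divergences are conventionally
reported) and rounded only when written out.

Gap handling: by default a column is excluded from a pair only when either
member is gapped/ambiguous there ("pairwise deletion", robust to ragged
GenBank fragments).  "complete deletion" — excluding a column whenever *any*
sequence in the alignment is gapped/ambiguous — is available via the
``deletion`` switch and changes matrix values on gappy data.  IUPAC ambiguity
codes are treated as missing, not as fractional observations.

Saturation: when ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0`` the logarithms are
undefined and the distance is reported as undefined (NaN here, ``NA`` in TSV
output); downstream statistics exclude such pairs with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignments import AlignedSequence
from .errors import AlignmentLengthError, InputError, NoOverlapError

logger = logging.getLogger("genusrank")

#: Sentinel for a saturated (undefined) distance.
UNDEFINED = float("nan")

# base codes: A=0, C=1, G=2, T=3; anything else = 255 (excluded pairwise).
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class PairCounts:
    """Site-pattern counts for one sequence pair under pairwise deletion.

    L  -- sites unambiguous (A/C/G/T) in both sequences
    ts -- transition differences among those sites
    tv -- transversion differences among those sites
    """

    L: int
    ts: int
    tv: int

    def __post_init__(self):
        if not (0 <= self.ts + self.tv <= self.L):
            raise ValueError(f"inconsistent counts: L={self.L} ts={self.ts} tv={self.tv}")

    @property
    def P(self) -> float:
        return self.ts / self.L

    @property
    def Q(self) -> float:
        return self.tv / self.L


def _encode(seq: AlignedSequence) -> np.ndarray:
    return _CODE[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]


def _counts_from_codes(a: np.ndarray, b: np.ndarray) -> PairCounts:
    valid = (a != 255) & (b != 255)
    L = int(valid.sum())
    if L == 0:
        raise NoOverlapError("sequence pair shares no unambiguous A/C/G/T columns")
    diff = valid & (a != b)
    # purines (A=0, G=2) have even codes, pyrimidines (C=1, T=3) odd: a
    # substitution is a transition iff the two codes have equal parity.
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return PairCounts(L=L, ts=ts, tv=tv)


def count_site_patterns(a: AlignedSequence, b: AlignedSequence) -> PairCounts:
    """Classify aligned columns of a pair into valid / transition /
    transversion under pairwise deletion."""
    if len(a) != len(b):
        raise AlignmentLengthError(
            f"sequences {a.record_id!r} and {b.record_id!r} have unequal lengths"
        )
    return _counts_from_codes(_encode(a), _encode(b))


def k2p_distance(counts: PairCounts) -> float:
    """K2P distance in percent, or NaN (:data:`UNDEFINED`) at saturation."""
    if counts.L == 0:
        raise NoOverlapError("no valid sites")
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return 100.0 * (-0.5 * math.log(w1) - 0.25 * math.log(w2))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric percent-distance matrix with a zero diagonal.

    ``values[i, j]`` is the K2P distance between ``labels[i]`` and
    ``labels[j]``; NaN marks an undefined (saturated) pair.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def to_tsv(self, path) -> None:
        """Square TSV: header row/column of species ids, ``NA`` for
        undefined entries, full precision."""
        with open(path, "w") as fh:
            fh.write("species_id\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                row = [
                    "NA" if math.isnan(v) else repr(float(v)) for v in self.values[i]
                ]
                fh.write(lab + "\t" + "\t".join(row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            labels = tuple(header[1:])
            rows = []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([math.nan if p == "NA" else float(p) for p in parts[1:]])
        values = np.asarray(rows, dtype=float)
        return cls(labels=labels, values=values)


def distance_matrix(
    seqs: Sequence[AlignedSequence], deletion: str = "pairwise"
) -> DistanceMatrix:
    """Full symmetric K2P matrix over ``seqs`` (labelled by species_id).

    ``deletion`` is ``"pairwise"`` (default) or ``"complete"``.  Undefined
    (saturated) pairs are logged with their identifiers and stored as NaN.
    """
    if len(seqs) < 2:
        raise InputError("a distance matrix needs at least two sequences")
    if len({len(s) for s in seqs}) != 1:
        raise AlignmentLengthError("sequences have unequal lengths")
    if deletion not in ("pairwise", "complete"):
        raise InputError(f"unknown deletion mode: {deletion!r}")
    codes = np.stack([_encode(s) for s in seqs])
    if deletion == "complete":
        keep = (codes != 255).all(axis=0)
        if not keep.any():
            raise NoOverlapError("complete deletion removed every column")
        codes = codes[:, keep]
    n = len(seqs)
    labels = tuple(s.species_id for s in seqs)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_distance(_counts_from_codes(codes[i], codes[j]))
            if math.isnan(d):
                logger.warning(
                    "K2P distance undefined (saturation) for pair %s / %s",
                    labels[i],
                    labels[j],
                )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)
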