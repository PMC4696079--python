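"""Aligned mtDNA sequence data with per-sequence deme labels.

The central container is :class:`Alignment`: a rectangular block of
equal-length DNA sequences, each tagged with the sampling deme it came
from.  Everything downstream (diversity statistics, AMOVA, the ABC
summary vector) consumes this object.  Sequences use the alphabet
``A C G T N -``; ``N`` and ``-`` are treated as missing data and are
handled by a configurable deletion policy (complete deletion by default:
any site with missing data in any sequence is dropped alignment-wide
before statistics are computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "HaplotypeTable",
    "AlignmentError",
    "DemeMapError",
    "read_alignment",
    "read_deme_map",
    "write_alignment",
    "collapse_haplotypes",
    "pool_demes",
]

# Numeric encoding used throughout: A=0 C=1 G=2 T=3, missing (N or -) = -1.
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}
_DECODE = np.array(list("ACGT"))

# IUPAC ambiguity codes that may optionally be collapsed to N.
_IUPAC_AMBIG = set("RYSWKMBDHV")


class AlignmentError(ValueError):
    """Malformed alignment (ragged lengths, bad characters, empty input)."""


class DemeMapError(KeyError):
    """Sequence id without a deme assignment, or grouping missing a deme."""


@dataclass
class Alignment:
    """Equal-length, deme-labelled DNA sequences.

    Parameters
    ----------
    ids
        Sequence identifiers, in file order.
    seqs
        Upper-case sequence strings over ``ACGTN-``, all of length `L`.
    deme_of
        Mapping from sequence id to deme label.
    """

    ids: list[str]
    seqs: list[str]
    deme_of: dict[str, str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no sequences")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs differ in length")
        L = len(self.seqs[0])
        if L < 1:
            raise AlignmentError("sequences must have length >= 1")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != L:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(s)}, expected {L}"
                )
        missing = [sid for sid in self.ids if sid not in self.deme_of]
        if missing:
            raise DemeMapError(f"ids missing from deme map: {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return len(self.seqs[0])

    @property
    def demes(self) -> list[str]:
        """Deme labels in order of first appearance."""
        seen: dict[str, None] = {}
        for sid in self.ids:
            seen.setdefault(self.deme_of[sid], None)
        return list(seen)

    @property
    def deme_labels(self) -> list[str]:
        """Per-sequence deme label, aligned with `ids`."""
        return [self.deme_of[sid] for sid in self.ids]

    def matrix(self) -> np.ndarray:
        """Integer-coded matrix (n x L, int8): A=0 C=1 G=2 T=3, missing=-1."""
        if self._matrix is None:
            n, L = self.n, self.L
            m = np.empty((n, L), dtype=np.int8)
            table = np.full(128, -2, dtype=np.int8)
            for ch, code in _CODE.items():
                table[ord(ch)] = code
            for i, s in enumerate(self.seqs):
                row = table[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
                if (row == -2).any():
                    bad = s[int(np.argmax(row == -2))]
                    raise AlignmentError(f"invalid character {bad!r} in {self.ids[i]!r}")
                m[i] = row
            self._matrix = m
        return self._matrix

    def subset(self, deme: str) -> "Alignment":
        """Sequences belonging to a single deme."""
        ids = [sid for sid in self.ids if self.deme_of[sid] == deme]
        if not ids:
            raise DemeMapError(f"no sequences in deme {deme!r}")
        seqs = [self.seqs[self.ids.index(sid)] for sid in ids]
        return Alignment(ids, seqs, {sid: deme for sid in ids})

    def take(self, indices: list[int]) -> "Alignment":
        ids = [self.ids[i] for i in indices]
        seqs = [self.seqs[i] for i in indices]
        return Alignment(ids, seqs, {sid: self.deme_of[sid] for sid in ids})

    def analysed_sites(self, deletion: str = "complete") -> np.ndarray:
        """Boolean mask of sites retained under the deletion policy.

        ``complete``: drop any site with missing data in any sequence.
        ``pairwise``: keep all sites (missing data handled pair by pair
        downstream).
        """
        m = self.matrix()
        if deletion == "complete":
            return (m >= 0).all(axis=0)
        if deletion == "pairwise":
            return np.ones(self.L, dtype=bool)
        raise ValueError(f"unknown deletion policy {deletion!r}")


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-deme copy counts."""

    haplotypes: list[str]
    demes: list[str]
    counts: np.ndarray  # haplotype x deme, non-negative ints

    @property
    def hap_count(self) -> dict[str, int]:
        """Number of distinct haplotypes observed in each deme."""
        return {
            d: int((self.counts[:, j] > 0).sum()) for j, d in enumerate(self.demes)
        }


def read_deme_map(path) -> dict[str, str]:
    """Two-column TSV (id, deme); '#' comments and an optional header allowed."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise DemeMapError(f"{path}:{lineno}: expected two columns")
            sid, deme = parts[0], parts[1]
            if lineno == 1 and sid.lower() in {"id", "sequence", "sample"}:
                continue
            mapping[sid] = deme
    if not mapping:
        raise DemeMapError(f"deme map {path} is empty")
    return mapping


def read_alignment(fasta_path, deme_map_path, ambiguity: str = "reject") -> Alignment:
    """Read an aligned FASTA plus a tab-separated deme map.

    Parameters
    ----------
    ambiguity
        ``"reject"`` raises on IUPAC ambiguity codes other than N;
        ``"to_n"`` maps them to N (missing).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    deme_of = read_deme_map(deme_map_path)
    ids, seqs = [], []
    for rec in records:
        s = str(rec.seq).upper()
        if ambiguity == "to_n":
            s = "".join("N" if c in _IUPAC_AMBIG else c for c in s)
        elif any(c in _IUPAC_AMBIG for c in s):
            bad = next(c for c in s if c in _IUPAC_AMBIG)
            raise AlignmentError(
                f"ambiguity code {bad!r} in {rec.id!r} (use ambiguity='to_n' to accept)"
            )
        if rec.id not in deme_of:
            raise DemeMapError(f"id {rec.id!r} missing from deme map")
        ids.append(rec.id)
        seqs.append(s)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    return Alignment(ids, seqs, {sid: deme_of[sid] for sid in ids})


def write_alignment(a: Alignment, fasta_path, deme_map_path=None) -> None:
    """Write FASTA (and optionally the deme map) back to disk."""
    records = [
        SeqRecord(Seq(s), id=sid, description="") for sid, s in zip(a.ids, a.seqs)
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")
    if deme_map_path is not None:
        with open(deme_map_path, "w") as fh:
            for sid in a.ids:
                fh.write(f"{sid}\t{a.deme_of[sid]}\n")


def collapse_haplotypes(a: Alignment, deletion: str = "complete") -> HaplotypeTable:
    """Collapse identical sequences into haplotypes with per-deme counts.

    Identity is plain string equality over the sites retained by the
    deletion policy.
    """
    keep = a.analysed_sites(deletion)
    demes = a.demes
    deme_index = {d: j for j, d in enumerate(demes)}
    order: dict[str, int] = {}
    rows: list[str] = []
    counts: list[np.ndarray] = []
    for sid, s in zip(a.ids, a.seqs):
        key = "".join(c for c, k in zip(s, keep) if k)
        if key not in order:
            order[key] = len(rows)
            rows.append(key)
            counts.append(np.zeros(len(demes), dtype=int))
        counts[order[key]][deme_index[a.deme_of[sid]]] += 1
    return HaplotypeTable(rows, demes, np.array(counts, dtype=int))


def pool_demes(a: Alignment, grouping: dict[str, str]) -> Alignment:
    """Replace deme labels by region labels; sequences are untouched."""
    missing = [d for d in a.demes if d not in grouping]
    if missing:
        raise DemeMapError(f"grouping omits demes: {missing}")
    deme_of = {sid: grouping[a.deme_of[sid]] for sid in a.ids}
    return Alignment(list(a.ids), list(a.seqs), deme_of)


def alignment_from_matrix(
    m: np.ndarray, deme_labels: list[str], ids: list[str] | None = None
) -> Alignment:
    """Build an Alignment from an integer-coded matrix (simulator output)."""
    n, L = m.shape
    if ids is None:
        ids = [f"seq{i:04d}" for i in range(n)]
    seqs = ["".join(_DECODE[row]) for row in np.asarray(m, dtype=np.int64)]
    a = Alignment(ids, seqs, dict(zip(ids, deme_labels)))
    a._matrix = np.ascontiguousarray(m, dtype=np.int8)
    return a
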