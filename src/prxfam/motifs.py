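"""Degenerate IUPAC consensus scanning over promoter sets.

Cis-regulatory elements (CREs) are represented as named IUPAC consensi
(e.g. ``TATCCAYMOTIFOSRAMY3D`` = ``TATCCAY``, where Y matches C or T).
Scanning tests every window on both strands, counts overlapping matches,
and summarises results as a motif x promoter incidence matrix of hit
counts from which presence/absence set algebra is derived.

Coordinate conventions: internally 0-based half-open on the forward
strand of the scanned sequence; reports can translate to 1-based
negative ATG-relative positions (-1 = base immediately upstream of ATG).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import pandas as pd

#: IUPAC nucleotide degeneracy codes.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidConsensusError(ValueError):
    """Raised when a consensus string contains a non-IUPAC symbol."""


@dataclass(frozen=True)
class MotifRecord:
    """A named degenerate consensus.

    Attributes
    ----------
    name:
        Motif identifier, e.g. ``ABREOSRAB21``.
    consensus:
        IUPAC string, length >= 4.
    """

    name: str
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise InvalidConsensusError(
                f"consensus {self.consensus!r} shorter than 4"
            )
        validate_consensus(self.consensus)

    @property
    def degeneracy(self) -> int:
        """Number of concrete words the consensus denotes."""
        n = 1
        for sym in self.consensus.upper():
            n *= len(IUPAC_CODES[sym])
        return n


@dataclass
class PromoterRecord:
    """A promoter sequence with its region bookkeeping.

    ``sequence`` is the concatenation upstream -> first-intron/exon on the
    forward strand; ``upstream_length`` marks where the optional
    intron/exon segment begins. ``atg_offset`` maps internal 0-based
    coordinates back to ATG-relative ones: position i (0-based) is
    ``i - upstream_length`` relative to the ATG, i.e. upstream base
    ``upstream_length - 1`` sits at ATG-relative -1.
    """

    gene_id: str
    sequence: str
    upstream_length: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.upstream_length is None:
            self.upstream_length = len(self.sequence)
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: invalid sequence symbols {bad}")

    def atg_relative(self, start: int) -> int:
        """1-based ATG-relative position of an internal 0-based coordinate.

        Upstream positions are negative (-1 is the base before ATG);
        positions inside the first intron/exon are positive (+1 onward).
        """
        delta = start - self.upstream_length
        # no position 0 in the 1-based convention: -1 abuts +1 at the ATG
        return delta if delta < 0 else delta + 1


@dataclass(frozen=True)
class MotifHit:
    """One match of a consensus to a promoter window.

    ``start`` is 0-based on forward coordinates regardless of strand; on
    the minus strand the reverse complement of the window matches the
    consensus.
    """

    motif: str
    gene_id: str
    start: int
    strand: str
    matched: str


class MotifLibrary:
    """Ordered collection of :class:`MotifRecord` with unique names."""

    def __init__(self, records: Iterable[MotifRecord]):
        self.records: list[MotifRecord] = list(records)
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate motif names in library")
        self._by_name = {r.name: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> MotifRecord:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "consensus": [r.consensus for r in self.records]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MotifLibrary":
        return cls(
            MotifRecord(str(n), str(c))
            for n, c in zip(df["name"], df["consensus"])
        )


def validate_consensus(consensus: str) -> None:
    """Raise :class:`InvalidConsensusError` naming the first bad position."""
    for i, sym in enumerate(consensus.upper()):
        if sym not in IUPAC_CODES:
            raise InvalidConsensusError(
                f"invalid IUPAC symbol {sym!r} at position {i} in {consensus!r}"
            )


def iupac_expand(consensus: str, limit: int = 65536) -> set[str]:
    """Enumerate the concrete ACGT words a consensus denotes.

    The expansion size is the product of per-symbol degeneracies; an
    expansion larger than ``limit`` raises (use :func:`iupac_matcher`
    for a predicate instead).
    """
    validate_consensus(consensus)
    sets = [sorted(IUPAC_CODES[s]) for s in consensus.upper()]
    size = 1
    for s in sets:
        size *= len(s)
    if size > limit:
        raise ValueError(f"expansion size {size} exceeds limit {limit}")
    return {"".join(w) for w in product(*sets)}


def iupac_matcher(consensus: str):
    """Predicate word -> bool testing membership in the consensus.

    Sequence-side ``N`` never matches: the per-position base sets contain
    only A/C/G/T, so an N in the scanned word fails every position.
    """
    validate_consensus(consensus)
    sets = [IUPAC_CODES[s] for s in consensus.upper()]

    def match(word: str) -> bool:
        if len(word) != len(sets):
            return False
        return all(b in s for b, s in zip(word.upper(), sets))

    return match


def _consensus_regex(consensus: str) -> re.Pattern:
    # lookahead so overlapping windows are all reported
    parts = []
    for sym in consensus.upper():
        bases = "".join(sorted(IUPAC_CODES[sym]))
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


def scan_sequence(
    promoter: PromoterRecord,
    motif: MotifRecord,
    strands: str = "both",
) -> list[MotifHit]:
    """All (possibly overlapping) matches of ``motif`` in ``promoter``.

    ``strands`` is ``'+'``, ``'-'`` or ``'both'``. Minus-strand hits are
    windows whose reverse complement satisfies the consensus, reported at
    forward coordinates. A sequence shorter than the consensus yields an
    empty list. N in the sequence matches nothing.
    """
    if strands not in {"+", "-", "both"}:
        raise ValueError(f"invalid strand policy {strands!r}")
    seq = promoter.sequence
    hits: list[MotifHit] = []
    if len(seq) < len(motif.consensus):
        return hits
    if strands in {"+", "both"}:
        pat = _consensus_regex(motif.consensus)
        for m in pat.finditer(seq):
            hits.append(
                MotifHit(motif.name, promoter.gene_id, m.start(), "+", m.group(1))
            )
    if strands in {"-", "both"}:
        # a window matches on '-' iff its revcomp satisfies the consensus,
        # i.e. the forward window satisfies revcomp(consensus)
        pat = _consensus_regex(reverse_complement(motif.consensus))
        for m in pat.finditer(seq):
            hits.append(
                MotifHit(motif.name, promoter.gene_id, m.start(), "-", m.group(1))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


class PromoterSet:
    """Ordered set of :class:`PromoterRecord` keyed by unique gene id."""

    def __init__(self, records: Iterable[PromoterRecord]):
        self.records: list[PromoterRecord] = list(records)
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in promoter set")
        self._by_id = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]


def scan_promoters(
    promoters: PromoterSet,
    library: MotifLibrary,
    strands: str = "both",
) -> list[MotifHit]:
    """Scan every promoter with every library motif."""
    hits: list[MotifHit] = []
    for p in promoters:
        for m in library:
            hits.extend(scan_sequence(p, m, strands=strands))
    return hits


def build_incidence(
    promoters: PromoterSet,
    library: MotifLibrary,
    strands: str = "both",
) -> pd.DataFrame:
    """Motif x promoter matrix of hit counts (explicit zeros).

    Rows follow library order, columns follow promoter input order.
    """
    if len(promoters) == 0 or len(library) == 0:
        raise ValueError("empty promoter set or motif library")
    counts = pd.DataFrame(
        0, index=library.names, columns=promoters.gene_ids, dtype=int
    )
    for hit in scan_promoters(promoters, library, strands=strands):
        counts.at[hit.motif, hit.gene_id] += 1
    return counts


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Hits as a tidy table (motif, gene_id, start, strand, matched)."""
    return pd.DataFrame(
        [(h.motif, h.gene_id, h.start, h.strand, h.matched) for h in hits],
        columns=["motif", "gene_id", "start", "strand", "matched"],
    )


def hits_to_gff3(hits: Sequence[MotifHit], promoters: PromoterSet) -> str:
    """GFF3 text for motif hits (feature type ``nucleotide_motif``)."""
    lines = ["##gff-version 3"]
    for h in hits:
        end = h.start + len(h.matched)
        lines.append(
            "\t".join(
                [
                    h.gene_id,
                    "prxfam",
                    "nucleotide_motif",
                    str(h.start + 1),  # GFF is 1-based inclusive
                    str(end),
                    ".",
                    h.strand,
                    ".",
                    f"Name={h.motif};matched={h.matched}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
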