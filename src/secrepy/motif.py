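"""C-terminal ER-retrieval motif detection and consensus profiling.

ER-resident proteins carry a tetrapeptide retrieval signal at the extreme
C-terminus (canonically KDEL) that KDEL receptors at the early Golgi
recognise, pulling escaped residents back to the ER lumen. Functional
variants abound, but the last two residues are almost invariably E-L; the
relaxed pattern used for filtering is therefore "XXEL": any two residues
from a permissive class followed by the fixed EL tail, anchored at the very
end of the sequence.

:func:`derive_consensus` recovers such a consensus empirically from a set
of ER-resident sequences by per-position frequency profiling of the final
k residues -- for an anchored C-terminal motif this reproduces what a
multiple-sequence alignment's consensus column would give.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, ValidationError
from .records import ProteinRecord

#: 22-letter residue class allowed at motif positions 1-2: the 20 standard
#: amino acids plus the Asx/Glx ambiguity codes B and Z. U and X are excluded.
XXEL_POSITION_CLASS = "ARNDCQEGHILKMFPSTWYVBZ"

#: Full upper-case alphabet accepted by the scanner; validation rejects
#: anything outside it (digits, gap characters, ...).
RESIDUE_CODE_SPACE = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

_CLASS_RE = re.compile(r"^\[([A-Z]+)\]\{2\}([A-Z]{2})$")


@dataclass(frozen=True)
class MotifMatch:
    tetrapeptide: str
    start: int  # 1-based position of the tetrapeptide's first residue


@dataclass(frozen=True)
class MotifPattern:
    """Anchored C-terminal tetrapeptide pattern.

    Either positional (residue classes for positions 1-2 plus a fixed
    two-residue tail) or an explicit allow-list of tetrapeptides, for
    swapping in the experimentally verified KDEL-variant catalogue.
    """

    allowed_first: frozenset[str] = frozenset(XXEL_POSITION_CLASS)
    allowed_second: frozenset[str] = frozenset(XXEL_POSITION_CLASS)
    fixed_tail: str = "EL"
    explicit: frozenset[str] | None = None

    @classmethod
    def default(cls) -> "MotifPattern":
        return cls()

    @classmethod
    def from_character_class(cls, spec: str) -> "MotifPattern":
        """Build from a character-class string such as
        ``[ARNDCQEGHILKMFPSTWYVBZ]{2}EL`` (the config-file syntax)."""
        m = _CLASS_RE.match(spec.strip().upper())
        if m is None:
            raise ConfigurationError(
                f"cannot parse motif pattern {spec!r}; expected '[CLASS]{{2}}EL' form"
            )
        residues, tail = m.groups()
        return cls(
            allowed_first=frozenset(residues),
            allowed_second=frozenset(residues),
            fixed_tail=tail,
        )

    @classmethod
    def from_allow_list(cls, tetrapeptides: list[str] | set[str]) -> "MotifPattern":
        tetras = frozenset(t.strip().upper() for t in tetrapeptides)
        for t in tetras:
            if len(t) != 4:
                raise ConfigurationError(f"allow-list entry {t!r} is not a tetrapeptide")
        return cls(explicit=tetras)

    def matches(self, tetrapeptide: str) -> bool:
        if len(tetrapeptide) != 4:
            return False
        if self.explicit is not None:
            return tetrapeptide in self.explicit
        return (
            tetrapeptide[0] in self.allowed_first
            and tetrapeptide[1] in self.allowed_second
            and tetrapeptide[2:] == self.fixed_tail
        )


def match_xxel(sequence: str, pattern: MotifPattern | None = None) -> MotifMatch | None:
    """Scan the final four residues of ``sequence`` for the ER-retrieval motif.

    The match is anchored: an "EL" anywhere but the extreme C-terminus never
    matches, and sequences shorter than four residues cannot match. Matching
    is case-insensitive (sequences are upper-cased first).

    Raises
    ------
    ValidationError
        If the sequence contains a character outside the residue code space;
        the message names the offending character and its 1-based position.
    """
    pattern = pattern or MotifPattern.default()
    seq = sequence.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in RESIDUE_CODE_SPACE:
            raise ValidationError(
                f"invalid residue {ch!r} at position {pos} in sequence"
            )
    if len(seq) < 4:
        return None
    tail = seq[-4:]
    if pattern.matches(tail):
        return MotifMatch(tetrapeptide=tail, start=len(seq) - 3)
    return None


@dataclass
class ConsensusProfile:
    """Per-position residue frequencies over the final ``k`` residues.

    ``consensus`` carries the dominant residue at each position, or ``X``
    where no residue reaches the dominance threshold. ``tetrapeptide_counts``
    iterates in descending count order (ties broken lexicographically).
    """

    k: int
    n_sequences: int
    counts: list[Counter] = field(default_factory=list)
    tetrapeptide_counts: dict[str, int] = field(default_factory=dict)
    consensus: str = ""

    def position_frequencies(self, position: int) -> dict[str, float]:
        """Residue frequencies at 1-based ``position`` within the window."""
        tally = self.counts[position - 1]
        return {aa: c / self.n_sequences for aa, c in sorted(tally.items())}

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "position": i + 1,
                "residue": aa,
                "count": c,
                "frequency": c / self.n_sequences,
            }
            for i, tally in enumerate(self.counts)
            for aa, c in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["position", "residue", "count", "frequency"])


def derive_consensus(
    sequences: list[str], k: int = 4, dominance: float = 1.0
) -> ConsensusProfile:
    """Profile the final ``k`` residues of each sequence and call a consensus.

    A position is assigned a residue only when that residue's frequency is at
    least ``dominance`` (default 1.0: unanimity), otherwise ``X``. With
    ``dominance`` restricted to (0.5, 1.0] at most one residue can qualify,
    so the call is unambiguous.
    """
    if not sequences:
        raise ValidationError("cannot derive a consensus from an empty sequence set")
    if not 0.5 < dominance <= 1.0:
        raise ValidationError(f"dominance must lie in (0.5, 1.0], got {dominance}")
    if k < 1:
        raise ValidationError(f"window length k must be >= 1, got {k}")

    tails: list[str] = []
    for i, seq in enumerate(sequences):
        s = seq.upper()
        if len(s) < k:
            raise ValidationError(
                f"sequence #{i + 1} ({s!r}) is shorter than the window k={k}"
            )
        tails.append(s[-k:])

    n = len(tails)
    counts = [Counter(tail[pos] for tail in tails) for pos in range(k)]
    tetra_counts = Counter(tails)
    ordered = dict(sorted(tetra_counts.items(), key=lambda kv: (-kv[1], kv[0])))

    consensus_chars = []
    for tally in counts:
        residue, top = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        consensus_chars.append(residue if top / n >= dominance else "X")

    return ConsensusProfile(
        k=k,
        n_sequences=n,
        counts=counts,
        tetrapeptide_counts=ordered,
        consensus="".join(consensus_chars),
    )


def select_er_residents(
    records: list[ProteinRecord], er_terms: list[str]
) -> list[ProteinRecord]:
    """Keep records whose location list matches at least one ER term by
    case-insensitive substring; input order is preserved."""
    terms = [t.strip().lower() for t in er_terms if t.strip()]
    selected = [
        r
        for r in records
        if any(term in loc.lower() for loc in r.locations for term in terms)
    ]
    return selected
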