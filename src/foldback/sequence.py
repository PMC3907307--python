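"""DNA-string primitives shared by the simulator, analyzer and null model.

Sequences are plain Python strings over the alphabet ``{A, C, G, T, N}``,
uppercased on input.  Coordinates are 0-based, half-open everywhere in this
package; 1-based inclusive coordinates appear only in BED/report output.

Two distinct inverted-microhomology operators live here:

``inverted_mh_self``
    Compares the 3' end of a sequence with the reverse complement of its own
    5' end — the statistic applied to randomly drawn spacers in the null
    model.  It pairs ``S[n-1-i]`` with ``complement(S[i])``.

``junction_mh``
    The junction-level operator: pairs ``seq[e-1-i]`` with
    ``complement(seq[d+i])``.  This is the microhomology a fold-back anneal
    uses and the one a split alignment of the derivative chromosome
    recovers as query overlap.  ``inverted_mh_self(S)`` equals
    ``junction_mh(S, len(S), 0)``.

``inverted_mh_block``
    Largest k with ``seq[e-k:e] == revcomp(seq[d-k:d])`` — a block
    comparison anchored below both coordinates.  Kept as a separate,
    documented operator; note its pairing is not nested in k, so it is not
    an extension statistic.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass
from typing import Iterator, TextIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TELOMERE_UNIT = "TTAGGG"
TELOMERE_UNIT_RC = "CCCTAA"


class AlphabetError(ValueError):
    """Sequence contains a character outside {A, C, G, T, N}."""


def _validate(seq: str) -> str:
    seq = seq.upper()
    if not set(seq) <= VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise AlphabetError(f"invalid characters in sequence: {bad}")
    return seq


def revcomp(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    return _validate(seq).translate(_COMPLEMENT)[::-1]


_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _bases_pair(a: str, b: str) -> bool:
    # N never pairs with anything, including N (conservative counts).
    return (a, b) in _PAIRS


def inverted_mh_self(spacer: str) -> int:
    """Inverted microhomology between a sequence's own two ends.

    Largest k such that the k-bp suffix equals the reverse complement of
    the k-bp prefix, exact match only, capped at ``floor(n/2)`` so the two
    blocks never overlap.
    """
    s = _validate(spacer)
    n = len(s)
    if n < 2:
        raise ValueError("inverted_mh_self requires a sequence of length >= 2")
    k = 0
    cap = n // 2
    while k < cap and _bases_pair(s[n - 1 - k], s[k]):
        k += 1
    return k


def junction_mh(seq: str, e: int, d: int, cap: int | None = None) -> int:
    """Junction-level inverted microhomology between breakpoints e and d.

    Counts the maximal run of pairings ``seq[e-1-i] == complement(seq[d+i])``,
    i.e. the bases shared by the forward segment ending at ``e`` and the
    reverse-complemented segment starting (in reference orientation) at
    ``d``.  Bounded by ``floor((e - d) / 2)`` so the paired blocks never
    cross, and by the sequence bounds.
    """
    s = seq  # hot path: caller guarantees a validated uppercase sequence
    n = len(s)
    if not (0 <= d <= e <= n):
        raise IndexError(f"breakpoints out of range: d={d}, e={e}, n={n}")
    limit = (e - d) // 2
    if cap is not None:
        limit = min(limit, cap)
    k = 0
    while k < limit and _bases_pair(s[e - 1 - k], s[d + k]):
        k += 1
    return k


def inverted_mh_block(seq: str, e: int, d: int) -> int:
    """Largest k with ``seq[e-k:e] == revcomp(seq[d-k:d])`` (exact match).

    Search is limited to ``min(d, e - d)`` so the blocks stay inside the
    sequence and do not overlap.
    """
    s = _validate(seq)
    if not (0 <= d < e <= len(s)):
        raise IndexError(f"breakpoints out of range: d={d}, e={e}, n={len(s)}")
    best = 0
    for k in range(1, min(d, e - d) + 1):
        block = s[d - k:d]
        if "N" in block or "N" in s[e - k:e]:
            continue
        if s[e - k:e] == revcomp(block):
            best = k
    return best


def telomere_run(seq: str) -> tuple[int, str, int]:
    """Longest terminal run of tandem telomere units at either sequence end.

    Scans for ``(TTAGGG)n`` (+ strand) and ``(CCCTAA)n`` (- strand) at both
    ends of the sequence, over all six phase offsets, counting complete
    units only.  Returns ``(units, strand, phase)`` of the best run; a side
    is conventionally called telomeric when ``units >= 2``.
    """
    s = _validate(seq)
    best = (0, "+", 0)
    for unit, strand in ((TELOMERE_UNIT, "+"), (TELOMERE_UNIT_RC, "-")):
        for phase in range(6):
            rotated = unit[phase:] + unit[:phase]
            # run anchored at the left end
            units = 0
            while s.startswith(rotated * (units + 1)):
                units += 1
            if units > best[0]:
                best = (units, strand, phase)
            # run anchored at the right end
            units = 0
            while s.endswith(rotated * (units + 1)):
                units += 1
            if units > best[0]:
                best = (units, strand, phase)
    return best


def telomere_array(units: int, phase: int = 0) -> str:
    """A ``(TTAGGG)n`` array of complete units, starting at a phase offset."""
    rotated = TELOMERE_UNIT[phase:] + TELOMERE_UNIT[:phase]
    return rotated * units


@dataclass(frozen=True)
class GenomeInterval:
    """0-based, half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA I/O (multi-record, 60-column wrapping, case-insensitive input)

def read_fasta(handle: TextIO | str) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered dict of uppercase sequences."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(handle, "fasta"):
        records[rec.id] = _validate(str(rec.seq))
    return records


def write_fasta(handle: TextIO, records: dict[str, str] | Iterator[tuple[str, str]],
                width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    items = records.items() if isinstance(records, dict) else records
    for name, seq in items:
        handle.write(f">{name}\n")
        for line in textwrap.wrap(seq, width, break_on_hyphens=False):
            handle.write(line + "\n")
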