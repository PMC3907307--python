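"""Mechanistic simulation of fold-back inverted duplications.

The model: a double-strand break removes the terminal segment ``[b, L)`` of
a q arm.  5'->3' resection exposes a 3' overhang whose effective end is
``e <= b``; the overhang folds back and intrastrand-pairs at a more
proximal site ``d < e`` where the sequence just below ``e`` is
reverse-complementary to the sequence just above ``d`` (the junction
microhomology, ``k = junction_mh(ref, e, d)``).  Fill-in synthesis and
replication yield a dicentric chromosome ``ref[0:e] + revcomp(ref[0:d])``
whose single-copy "disomic spacer" ``[d, e)`` corresponds to the fold-back
loop.  A second break at ``p`` (between the two centromere copies) during a
breakage-fusion-bridge cycle yields a monocentric inverted-duplication
product ``ref[0:e] + revcomp(ref[p:d])`` — duplication ``[p, d)``, spacer
``[d, e)``, terminal deletion ``[e, L)`` — plus a sibling simple terminal
deletion ``ref[0:p]``.  The product is stabilized by telomere healing,
translocation capture, or ring fusion.

Breakpoint bookkeeping uses the canonical maximal-forward-shift convention:
shared junction bases are attributed to the forward (disomic) side, so the
coordinates recorded here are exactly the coordinates a split alignment of
the derivative recovers, and copy-number dosage over the reference is 2 on
``[p, d)``, 1 on ``[0, p)`` and ``[d, e)``, 0 on ``[e, L)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, mito_window, random_dna
from .sequence import (
    TELOMERE_UNIT,
    _bases_pair,
    junction_mh,
    revcomp,
    telomere_array,
)

DUP_LOG2 = float(np.log2(3 / 2))   # one extra copy on a diploid background
DEL_LOG2 = -1.0                    # heterozygous loss

DISOMY_INVERSION = "disomy_inversion"
INVERSION_TELOMERE = "inversion_telomere"
INVERSION_TRANSLOCATION = "inversion_translocation"
RING_FUSION = "ring_fusion"


class SimulationFailure(RuntimeError):
    """No admissible fold-back anneal site in the scanned window."""


class InvalidBreakError(ValueError):
    """Dicentric break position not strictly between the two centromeres."""


# ---------------------------------------------------------------------------
# events and truth records

@dataclass
class FoldbackEvent:
    chrom: str
    dsb_pos: int          # b: terminal deletion removes [b, L)
    resection_len: int    # r >= b - e (only its consequence e is observable)
    e: int                # distal-most retained disomic base + 1
    d: int                # reverse-copy breakpoint == dup distal end
    mh_len: int           # junction microhomology at the anneal
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.d < self.e <= self.dsb_pos:
            raise ValueError(f"require d < e <= b, got d={self.d}, e={self.e}, b={self.dsb_pos}")

    @property
    def spacer_size(self) -> int:
        return self.e - self.d


@dataclass
class InsertionTruth:
    junction_type: str
    kind: str             # templated_direct | templated_inverted | slippage | mitochondrial | untemplated
    length: int
    sequence: str
    template_chrom: str | None = None
    template_start: int | None = None
    template_end: int | None = None
    orientation: str | None = None   # relative to the reference


@dataclass
class JunctionTruth:
    junction_type: str
    der_pos: int                       # junction point in the derivative (left edge)
    left: tuple[str, int, str]         # (chrom, breakpoint, strand) of the left side
    right: tuple[str, int, str] | None
    mh_len: int = 0
    spacer_size: int | None = None
    insertion: InsertionTruth | None = None


@dataclass
class RearrangementTruth:
    event: FoldbackEvent
    break_pos: int                      # p
    resolution: str
    chrom_length: int
    junctions: list[JunctionTruth] = field(default_factory=list)

    @property
    def deletion_size(self) -> int:
        return self.chrom_length - self.event.e

    @property
    def dup_size(self) -> int:
        return self.event.d - self.break_pos

    @property
    def spacer_size(self) -> int:
        return self.event.spacer_size

    def dosage(self, pos: int) -> int:
        """Copy count of reference base ``pos`` on the rearranged homolog."""
        p, d, e = self.break_pos, self.event.d, self.event.e
        if pos < p:
            return 1
        if pos < d:
            return 2
        if pos < e:
            return 1
        return 0

    def to_json(self) -> dict:
        rec = asdict(self)
        rec["deletion_size"] = self.deletion_size
        rec["dup_size"] = self.dup_size
        rec["spacer_size"] = self.spacer_size
        return rec


# ---------------------------------------------------------------------------
# derivative chromosomes as segment lists (exact truth mapping, no aligner)

@dataclass(frozen=True)
class Segment:
    """One block of a derivative: a reference slice or an inserted sequence."""

    kind: str                  # "ref" | "ins"
    chrom: str | None = None
    start: int = 0
    end: int = 0
    strand: str = "+"
    seq: str = ""
    label: str = ""

    def length(self) -> int:
        return self.end - self.start if self.kind == "ref" else len(self.seq)

    def materialize(self, genome: ReferenceGenome) -> str:
        if self.kind == "ins":
            return self.seq
        s = genome[self.chrom][self.start:self.end]
        return revcomp(s) if self.strand == "-" else s


@dataclass
class Derivative:
    segments: list[Segment]
    circular: bool = False

    def length(self) -> int:
        return sum(s.length() for s in self.segments)

    def sequence(self, genome: ReferenceGenome) -> str:
        return "".join(s.materialize(genome) for s in self.segments)

    def map_position(self, pos: int) -> tuple[Segment, int]:
        """Segment containing derivative position ``pos`` and the offset into it."""
        if self.circular:
            pos %= self.length()
        off = pos
        for seg in self.segments:
            if off < seg.length():
                return seg, off
            off -= seg.length()
        raise IndexError(f"position {pos} outside derivative of length {self.length()}")

    def ref_coord(self, pos: int) -> tuple[str, int, str] | None:
        """Reference (chrom, position, strand) of a derivative base, or None if inserted."""
        seg, off = self.map_position(pos)
        if seg.kind == "ins":
            return None
        if seg.strand == "+":
            return seg.chrom, seg.start + off, "+"
        return seg.chrom, seg.end - 1 - off, "-"


@dataclass
class DicentricChromosome:
    derivative: Derivative
    centromere_positions: tuple[int, int]
    event: FoldbackEvent

    def sequence(self, genome: ReferenceGenome) -> str:
        return self.derivative.sequence(genome)


# ---------------------------------------------------------------------------
# core operations

def simulate_foldback(
    genome: ReferenceGenome,
    chrom: str,
    b: int,
    *,
    min_mh: int = 2,
    max_loop: int = 70_466,
    min_spacer: int = 1,
    r_max: int = 0,
    site_choice: str = "nearest",
    seed: int | None = None,
) -> FoldbackEvent:
    """Scan for an admissible fold-back anneal site below the DSB.

    For each candidate effective end ``e`` in ``[b - r_max, b]`` (descending
    from ``b``) the scan walks ``d`` downward from ``e - min_spacer`` to
    ``e - max_loop`` and accepts the first site with
    ``junction_mh(ref, e, d) >= min_mh`` or with a planted inverted repeat
    pair whose copies flank ``(d, e)``.  ``site_choice="nearest"`` therefore
    yields the admissible site with the smallest spacer.  The returned
    event is canonicalized (maximal forward shift), so its coordinates are
    the ones the junction analyzer recovers.
    """
    if min_mh < 1:
        raise ValueError("min_mh must be >= 1")
    if site_choice != "nearest":
        raise ValueError(f"unknown site_choice {site_choice!r}")
    ref = genome[chrom]
    cen = genome.centromeres[chrom]
    if b <= cen:
        raise ValueError("DSB must lie beyond the centromere (q-arm terminal deletion)")
    pair_sites = {}
    for rep in genome.repeats:
        if rep.orientation != "inverted":
            continue
        iv1, iv2 = rep.copies
        if iv1.chrom == chrom:
            pair_sites[(iv1.start, iv2.start)] = rep
    for e in range(b, max(b - r_max, cen + 2) - 1, -1):
        lo = max(e - max_loop, cen + 1)
        for d in range(e - min_spacer, lo - 1, -1):
            k = junction_mh(ref, e, d)
            if k >= min_mh:
                event = FoldbackEvent(chrom, b, b - e, e, d, k, seed)
                return canonicalize_event(genome, event)
        # repeat-pair mediated anneal: copies bracketing the loop
        for rep in pair_sites.values():
            iv1, iv2 = rep.copies
            if iv1.end <= e - min_spacer and iv2.start < e <= iv2.end and e - iv1.end <= max_loop:
                d = iv1.end - (e - iv2.start)   # homologous offset in the proximal copy
                if cen < d < e:
                    k = junction_mh(ref, e, d)
                    event = FoldbackEvent(chrom, b, b - e, e, d, max(k, 1), seed)
                    return canonicalize_event(genome, event)
    raise SimulationFailure(
        f"no anneal site with mh >= {min_mh} within {max_loop} bp below e for b={b}")


def canonicalize_event(genome: ReferenceGenome, event: FoldbackEvent) -> FoldbackEvent:
    """Shift shared junction bases maximally onto the forward (disomic) side.

    The derivative sequence is invariant under ``(e, d) -> (e+1, d-1)``
    whenever ``ref[e]`` pairs with ``ref[d-1]``; the canonical form takes
    the largest such ``e``.  The recorded DSB position is raised to ``e``
    when the shift passes it (it is only a lower bound on the true break).
    """
    ref = genome[event.chrom]
    e, d = event.e, event.d
    n = len(ref)
    while e < n and d > 0 and _bases_pair(ref[e], ref[d - 1]):
        e += 1
        d -= 1
    k = junction_mh(ref, e, d)
    b = max(event.dsb_pos, e)
    return FoldbackEvent(event.chrom, b, max(b - e, event.resection_len), e, d, k, event.seed)


def design_foldback_event(
    genome: ReferenceGenome,
    chrom: str,
    *,
    deletion: int,
    duplication: int,
    spacer: int,
    mh: int = 4,
) -> tuple[ReferenceGenome, FoldbackEvent, int]:
    """Plant a junction of exactly the requested sizes and return the event.

    Writes ``mh`` reverse-complementary bases just above ``d`` (paired with
    the bases just below ``e``), plus two guard bases so the microhomology
    run is exactly ``mh`` and the event is already canonical.  Returns the
    edited genome, the event, and the dicentric break position ``p``.
    """
    L = genome.length(chrom)
    e = L - deletion
    d = e - spacer
    p = d - duplication
    cen = genome.centromeres[chrom]
    cap = 6 * genome.telomere_units
    if not cen < p < d:
        raise ValueError("duplication must start beyond the centromere")
    if e > L - cap:
        raise ValueError("deletion too small: breakpoint falls inside the q telomere cap")
    if spacer < 2 * mh + 2:
        raise ValueError("spacer too short for the requested microhomology")
    ref = genome[chrom]
    planted = "".join(revcomp(ref[e - mh:e]))                 # ref[d+i] = comp(ref[e-1-i])
    guard_stop = ref[e - 1 - mh]                              # never pairs with itself
    genome = genome.with_edit(chrom, d, planted + guard_stop)
    ref = genome[chrom]
    if _bases_pair(ref[e], ref[d - 1]):                       # enforce canonical form
        genome = genome.with_edit(chrom, d - 1, ref[e])
    event = FoldbackEvent(chrom, e, 0, e, d, mh)
    realized = junction_mh(genome[chrom], event.e, event.d)
    assert realized == mh, f"planted mh {mh} realized as {realized}"
    return genome, event, p


def form_dicentric(genome: ReferenceGenome, event: FoldbackEvent) -> DicentricChromosome:
    """Post-replication dicentric: ``ref[0:e] + revcomp(ref[0:d])``."""
    c, e, d = event.chrom, event.e, event.d
    cen = genome.centromeres[c]
    der = Derivative([
        Segment("ref", c, 0, e, "+"),
        Segment("ref", c, 0, d, "-"),
    ])
    return DicentricChromosome(der, (cen, e + d - 1 - cen), event)


def break_dicentric(
    genome: ReferenceGenome,
    dicentric: DicentricChromosome,
    p: int,
) -> tuple[Derivative, Derivative]:
    """Second DSB between the centromeres -> (inv-dup product, sibling terminal deletion).

    ``p`` is a reference coordinate; the cut falls where reference base ``p``
    sits in the reverse copy, producing ``ref[0:e] + revcomp(ref[p:d])`` and
    the sibling ``ref[0:p]``, each with exactly one centromere.
    """
    ev = dicentric.event
    cen = genome.centromeres[ev.chrom]
    if not cen < p < ev.d:
        raise InvalidBreakError(
            f"break {p} not strictly between the centromere copies (cen={cen}, d={ev.d})")
    invdup = Derivative([
        Segment("ref", ev.chrom, 0, ev.e, "+"),
        Segment("ref", ev.chrom, p, ev.d, "-"),
    ])
    sibling = Derivative([Segment("ref", ev.chrom, 0, p, "+")])
    return invdup, sibling


def _pattern_base_left(phase: int, i: int) -> str:
    """Base of the (TTAGGG)n pattern ``i+1`` positions left of phase offset ``phase``."""
    return TELOMERE_UNIT[(phase - 1 - i) % 6]


def resolve_derivative(
    genome: ReferenceGenome,
    invdup: Derivative,
    truth: RearrangementTruth,
    mode: str,
    *,
    telomere_units: int = 50,
    telomere_mh: int = 0,
    donor_chrom: str | None = None,
    donor_break: int | None = None,
    seed: int | None = None,
) -> tuple[Derivative, RearrangementTruth]:
    """Stabilize the inverted-duplication product and record its junctions.

    ``telomere`` mode appends a new ``(TTAGGG)n`` array, choosing the repeat
    phase so the junction shares ``telomere_mh`` bases with the chromosome
    end when the end sequence allows it (the realized, maximal shared run
    is what gets recorded).  ``translocation`` appends the terminal segment
    of a donor chromosome.  ``ring`` joins the free end to the p-arm of the
    same chromosome, dropping the p telomere cap (fusion requires uncapped
    ends); the result is circular.
    """
    ev = truth.event
    p = truth.break_pos
    ref = genome[ev.chrom]
    # the disomy-inversion junction is shared by every resolution mode
    dis_inv = JunctionTruth(
        DISOMY_INVERSION,
        der_pos=ev.e,
        left=(ev.chrom, ev.e, "+"),
        right=(ev.chrom, ev.d, "-"),
        mh_len=ev.mh_len,
        spacer_size=ev.spacer_size,
    )
    junctions = [dis_inv]
    segments = list(invdup.segments)
    end_len = invdup.length()
    circular = False

    if mode == "telomere":
        end_seq = _segment_tail(genome, segments[-1], 30)
        realized = {}
        for phase in range(6):
            m = 0
            while m < len(end_seq) and end_seq[-1 - m] == _pattern_base_left(phase, m):
                m += 1
            realized[phase] = m
        if telomere_mh in realized.values():
            best_phase = min(ph for ph, m in realized.items() if m == telomere_mh)
        else:
            best_phase = min(realized, key=lambda ph: (abs(realized[ph] - telomere_mh), ph))
        best_m = realized[best_phase]
        array = telomere_array(telomere_units, best_phase)
        # forward extension of the reference-side alignment into the array
        delta = 0
        while delta < len(array) and p - 1 - delta >= 0 and \
                _bases_pair(array[delta], ref[p - 1 - delta]):
            delta += 1
        segments.append(Segment("ins", seq=array, label="telomere"))
        junctions.append(JunctionTruth(
            INVERSION_TELOMERE,
            der_pos=end_len,
            # maximal-shift convention: ref-aligned side keeps shared bases
            left=(ev.chrom, p - delta, "-"),
            right=None,
            mh_len=best_m + delta,
        ))
    elif mode == "translocation":
        if donor_chrom is None or donor_break is None:
            raise ValueError("translocation mode needs donor_chrom and donor_break")
        L2 = genome.length(donor_chrom)
        seg = Segment("ref", donor_chrom, donor_break, L2, "+")
        # shared bases at the junction, computed with the analyzer's convention
        don = genome[donor_chrom]
        ext_l = 0
        while _bases_pair(don[donor_break + ext_l], ref[p - 1 - ext_l]):
            ext_l += 1
        ext_r = 0
        while donor_break - 1 - ext_r >= 0 and \
                _bases_pair(ref[p + ext_r], don[donor_break - 1 - ext_r]):
            ext_r += 1
        segments.append(seg)
        junctions.append(JunctionTruth(
            INVERSION_TRANSLOCATION,
            der_pos=end_len,
            # maximal-shift convention: left (inverted-dup) side keeps shared bases
            left=(ev.chrom, p - ext_l, "-"),
            right=(donor_chrom, donor_break + ext_l, "+"),
            mh_len=ext_l + ext_r,
        ))
    elif mode == "ring":
        cap = 6 * genome.telomere_units
        segments[0] = Segment("ref", ev.chrom, cap, ev.e, "+")
        circular = True
        junctions = [JunctionTruth(
            RING_FUSION,
            der_pos=(ev.e - cap) + (ev.d - p),
            left=(ev.chrom, p, "-"),
            right=(ev.chrom, cap, "+"),
            mh_len=0,
        ), JunctionTruth(
            DISOMY_INVERSION,
            der_pos=ev.e - cap,
            left=(ev.chrom, ev.e, "+"),
            right=(ev.chrom, ev.d, "-"),
            mh_len=ev.mh_len,
            spacer_size=ev.spacer_size,
        )]
    else:
        raise ValueError(f"unknown resolution mode {mode!r}")

    final = Derivative(segments, circular=circular)
    truth.resolution = mode
    truth.junctions = junctions
    return final, truth


def add_complex_insertion(
    genome: ReferenceGenome,
    derivative: Derivative,
    truth: RearrangementTruth,
    junction_index: int,
    kind: str,
    *,
    length: int = 10,
    template_offset: int = 200,
    seed: int | None = None,
) -> tuple[Derivative, RearrangementTruth]:
    """Insert sequence at a junction and record its origin.

    ``templated_direct``/``templated_inverted`` copy a reference segment
    ``template_offset`` bp inside the side nearest the junction (within the
    default +/-1 kb search window of the origin classifier); ``slippage``
    re-copies the <=10 bases immediately left of the junction in direct
    orientation; ``mitochondrial`` copies a window of the circular donor;
    ``untemplated`` is random sequence.  Junction microhomology and an
    insertion are mutually exclusive, so the junction's recorded mh drops
    to 0.
    """
    junction = truth.junctions[junction_index]
    j = junction.der_pos
    rng = np.random.default_rng(seed if seed is not None else 0)
    chrom_l, bp_l, strand_l = junction.left
    ins = InsertionTruth(junction.junction_type, kind, length, "")
    if kind in ("templated_direct", "templated_inverted"):
        # template drawn from just inside the left (reference) side of the junction
        if strand_l == "+":
            t0 = bp_l - template_offset - length
        else:
            t0 = bp_l + template_offset
        template = genome[chrom_l][t0:t0 + length]
        ins.sequence = template if kind == "templated_direct" else revcomp(template)
        ins.template_chrom, ins.template_start, ins.template_end = chrom_l, t0, t0 + length
        ins.orientation = "+" if kind == "templated_direct" else "-"
    elif kind == "slippage":
        if length > 10:
            raise ValueError("slippage insertions duplicate at most 10 junction-local bases")
        local = derivative.sequence(genome)[j - length:j]
        ins.sequence = local
        ins.orientation = "+"
    elif kind == "mitochondrial":
        start = int(rng.integers(len(genome.mito_donor)))
        ins.sequence = mito_window(genome.mito_donor, start, length)
        ins.template_chrom = "mito_donor"
        ins.template_start, ins.template_end = start, start + length
        ins.orientation = "+"
    elif kind == "untemplated":
        ins.sequence = random_dna(rng, length)
    else:
        raise ValueError(f"unknown insertion kind {kind!r}")

    # splice the insertion into the segment list at derivative position j
    new_segments: list[Segment] = []
    off = 0
    inserted = False
    for seg in derivative.segments:
        if not inserted and off <= j <= off + seg.length():
            cut = j - off
            if seg.kind == "ins":
                raise ValueError("junction already carries an insertion")
            left, right = _split_ref_segment(seg, cut)
            if left:
                new_segments.append(left)
            new_segments.append(Segment("ins", seq=ins.sequence, label=kind))
            if right:
                new_segments.append(right)
            inserted = True
        else:
            new_segments.append(seg)
        off += seg.length()
    if not inserted:
        raise ValueError("junction position outside derivative")

    junction.insertion = ins
    junction.mh_len = 0
    for other in truth.junctions:
        if other is not junction and other.der_pos > j:
            other.der_pos += length
    return Derivative(new_segments, circular=derivative.circular), truth


def _split_ref_segment(seg: Segment, cut: int) -> tuple[Segment | None, Segment | None]:
    if cut == 0:
        return None, seg
    if cut == seg.length():
        return seg, None
    if seg.strand == "+":
        a = Segment("ref", seg.chrom, seg.start, seg.start + cut, "+")
        b = Segment("ref", seg.chrom, seg.start + cut, seg.end, "+")
    else:
        a = Segment("ref", seg.chrom, seg.end - cut, seg.end, "-")
        b = Segment("ref", seg.chrom, seg.start, seg.end - cut, "-")
    return a, b


def emit_amplicon(
    genome: ReferenceGenome,
    derivative: Derivative,
    junction: JunctionTruth,
    flank: int = 400,
) -> tuple[str, bool]:
    """Junction amplicon: ``flank`` bases each side of the junction point.

    Insertions at the junction are contained in full, so the amplicon is
    ``2*flank + insertion`` long.  Returns ``(sequence, truncated)`` where
    ``truncated`` flags a junction closer than ``flank`` to a sequence end
    (circular derivatives wrap instead).
    """
    if flank < 50:
        raise ValueError("flank must be >= 50")
    seq = derivative.sequence(genome)
    ins_len = junction.insertion.length if junction.insertion else 0
    j_left = junction.der_pos
    j_right = j_left + ins_len
    lo, hi = j_left - flank, j_right + flank
    if derivative.circular:
        doubled = seq + seq
        return doubled[lo % len(seq): lo % len(seq) + (hi - lo)], False
    truncated = lo < 0 or hi > len(seq)
    return seq[max(lo, 0):hi], truncated


def simulate_paired_end_reads(
    genome: ReferenceGenome,
    derivative: Derivative,
    *,
    coverage: float = 30.0,
    insert_mean: int = 400,
    insert_sd: int = 40,
    read_len: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform paired-end fragment sampling from the derivative.

    Each pair carries its derivative coordinates and the reference-space
    alignment induced through the truth mapping (a read overlapping a
    junction is assigned to the block holding the larger share of it), so
    discordance is decidable without an external aligner.  Read 1 is the
    derivative-forward read, read 2 the derivative-reverse read.
    """
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed 2 * read_len")
    rng = np.random.default_rng(seed)
    n = derivative.length()
    n_pairs = int(round(coverage * n / (2 * read_len)))
    frags = np.clip(rng.normal(insert_mean, insert_sd, n_pairs).round().astype(int),
                    2 * read_len, None)
    max_start = n - frags if not derivative.circular else np.full(n_pairs, n)
    starts = (rng.random(n_pairs) * np.maximum(max_start, 1)).astype(int)
    rows = []
    for i in range(n_pairs):
        s, f = int(starts[i]), int(frags[i])
        r1 = (s, s + read_len)
        r2 = (s + f - read_len, s + f)
        m1 = _map_read(derivative, *r1)
        m2 = _map_read(derivative, *r2)
        rows.append({
            "pair_id": i,
            "der_start1": r1[0], "der_end1": r1[1],
            "der_start2": r2[0], "der_end2": r2[1],
            "chrom1": m1[0], "ref_start1": m1[1], "ref_end1": m1[2],
            "strand1": m1[3],
            "chrom2": m2[0], "ref_start2": m2[1], "ref_end2": m2[2],
            "strand2": _flip(m2[3]),   # read 2 is derivative-reverse
        })
    return pd.DataFrame(rows)


def _flip(strand: str) -> str:
    return {"+": "-", "-": "+", ".": "."}[strand]


def _segment_tail(genome: ReferenceGenome, seg: Segment, n: int) -> str:
    """Last ``n`` bases of a segment without materializing the whole block."""
    if seg.kind == "ins":
        return seg.seq[-n:]
    if seg.strand == "+":
        return genome[seg.chrom][max(seg.start, seg.end - n):seg.end]
    return revcomp(genome[seg.chrom][seg.start:min(seg.end, seg.start + n)])


def _map_read(derivative: Derivative, start: int, end: int) -> tuple[str, int, int, str]:
    """Induced reference alignment of a derivative interval (majority block)."""
    n = derivative.length()
    shifts = (0,) if not derivative.circular else (0, -n)
    best: tuple[int, Segment, int] | None = None   # (overlap, segment, seg_offset_of_start)
    off = 0
    for seg in derivative.segments:
        seg_lo, seg_hi = off, off + seg.length()
        off = seg_hi
        for sh in shifts:
            a = max(start + sh, seg_lo)
            b = min(end + sh, seg_hi)
            if b - a > 0 and (best is None or b - a > best[0]):
                best = (b - a, seg, a - seg_lo)
    if best is None:
        return (".", -1, -1, ".")
    overlap, seg, seg_off = best
    if seg.kind == "ins":
        return (".", -1, -1, ".")
    if seg.strand == "+":
        lo = seg.start + seg_off
        return (seg.chrom, lo, lo + overlap, "+")
    hi = seg.end - seg_off
    return (seg.chrom, hi - overlap, hi, "-")


def simulate_cgh(
    genome: ReferenceGenome,
    truth: RearrangementTruth,
    *,
    probe_spacing: int = 200,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated array-CGH profile of the rearranged chromosome.

    One probe every ``probe_spacing`` bp.  Expected log2 test/reference
    ratio on a diploid with one rearranged homolog: 0 for disomy,
    ``log2(3/2)`` over the duplication, ``-1`` over the deletion, plus
    Gaussian noise.
    """
    if probe_spacing < 1:
        raise ValueError("probe_spacing must be >= 1")
    rng = np.random.default_rng(seed)
    L = truth.chrom_length
    pos = np.arange(probe_spacing // 2, L, probe_spacing)
    log2 = np.zeros(len(pos))
    p, d, e = truth.break_pos, truth.event.d, truth.event.e
    log2[(pos >= p) & (pos < d)] = DUP_LOG2
    log2[pos >= e] = DEL_LOG2
    if noise_sd > 0:
        log2 = log2 + rng.normal(0.0, noise_sd, len(pos))
    return pd.DataFrame({"chrom": truth.event.chrom, "pos": pos, "log2": log2})


# ---------------------------------------------------------------------------
# truth serialization

def truths_to_json(truths: list[RearrangementTruth]) -> str:
    return json.dumps([t.to_json() for t in truths], indent=1)
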